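"""Nonlinear coupling estimators operating on segment coefficients.

Every estimator takes two aligned sequences of complex coefficients
``z1, z2`` — one value per segment, at one frequency — and returns a
scalar.  Conventions follow the signed definitions:

* wPLI  = <Im(z1 z2*)> / <|Im(z1 z2*)|>           (sign kept)
* PLI   = <sign(Im(z1 z2*))>
* PLV   = <z1 z2* / (|z1||z2|)>                    (kept complex; its
  magnitude is the classical PLV and its imaginary part the
  mixing-robust ImPLV)
* PEC   = Pearson correlation across segments of |z|^2, |z| or log|z|
* OPEC  = PEC after removing from z2 the component collinear with z1,
  either globally (one regression coefficient alpha = Re(coherency)
  for all segments) or locally (per-segment projection, Hipp-style).

wPLI, PLI and Im(PLV) are antisymmetric under exchange of the two
channels; |PLV| and PEC are symmetric; OPEC is directional (channel 2 is
orthogonalized with respect to channel 1) with an opt-in symmetrized
average of both directions.
"""

from __future__ import annotations

import warnings

import numpy as np

from .spectral import SegmentedSpectra, check_boundary_bin

__all__ = [
    "wpli",
    "pli",
    "plv",
    "pec",
    "opec_global",
    "opec_local",
    "CouplingMatrix",
    "coupling_matrix",
    "MEASURES",
]

PEC_VARIANTS = ("power", "amplitude", "log")

#: fraction of zero-amplitude segments tolerated (dropped with a warning)
ZERO_AMP_TOLERANCE = 0.01


def _as_pair(z1, z2) -> tuple[np.ndarray, np.ndarray]:
    z1 = np.asarray(z1, dtype=complex).ravel()
    z2 = np.asarray(z2, dtype=complex).ravel()
    if z1.shape != z2.shape:
        raise ValueError("z1 and z2 must have the same number of segments")
    if z1.size < 2:
        raise ValueError("need at least 2 segments")
    if not (np.all(np.isfinite(z1)) and np.all(np.isfinite(z2))):
        raise ValueError("non-finite segment coefficients")
    return z1, z2


def _drop_zero_amplitude(z1: np.ndarray, z2: np.ndarray):
    """Drop segments where either amplitude vanishes (< 1% tolerated)."""
    keep = (np.abs(z1) > 0) & (np.abs(z2) > 0)
    n_bad = int(np.size(keep) - np.count_nonzero(keep))
    if n_bad == 0:
        return z1, z2
    if n_bad > ZERO_AMP_TOLERANCE * keep.size or keep.sum() < 2:
        raise ValueError(
            f"{n_bad}/{keep.size} segments have zero amplitude; too many to drop"
        )
    warnings.warn(
        f"dropping {n_bad} zero-amplitude segment(s)", RuntimeWarning, stacklevel=3
    )
    return z1[keep], z2[keep]


def wpli(z1, z2) -> float:
    """Weighted phase lag index (signed).

    Amplitude-weighted average sign of the imaginary cross-spectral term.
    In the Gaussian limit it equals ``2*lc / (1 + lc**2)`` with ``lc``
    the lagged coherence of the pair.
    """
    z1, z2 = _as_pair(z1, z2)
    num = np.imag(z1 * z2.conj())
    denom = np.abs(num).mean()
    if denom == 0:
        raise ValueError("wPLI undefined: Im(z1 z2*) is identically zero")
    return float(num.mean() / denom)


def pli(z1, z2) -> float:
    """Phase lag index: average sign of Im(z1 z2*).

    Segments with exactly zero imaginary part contribute sign(0) = 0.
    Gaussian limit: equals the lagged coherence.
    """
    z1, z2 = _as_pair(z1, z2)
    return float(np.sign(np.imag(z1 * z2.conj())).mean())


def plv(z1, z2) -> complex:
    """Complex phase locking value ``<z1 z2* / (|z1||z2|)>``.

    Gaussian limit: ``c * f(|c|)`` with ``f`` the PLV scaling function
    of the coherency ``c``.
    """
    z1, z2 = _as_pair(z1, z2)
    z1, z2 = _drop_zero_amplitude(z1, z2)
    return complex(np.mean(z1 * z2.conj() / (np.abs(z1) * np.abs(z2))))


def _envelope_transform(a: np.ndarray, variant: str) -> np.ndarray:
    if variant == "power":
        return a**2
    if variant == "amplitude":
        return a
    if variant == "log":
        if np.any(a <= 0):
            raise ValueError("log variant requires strictly positive amplitudes")
        return np.log(a)
    raise ValueError(f"unknown PEC variant {variant!r}; choose from {PEC_VARIANTS}")


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero envelope variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def pec(z1, z2, variant: str = "power") -> float:
    """Power envelope correlation across segments.

    Pearson correlation of ``|z|**2`` (power), ``|z|`` (amplitude) or
    ``log|z|``.  Gaussian limit of the power variant: ``|c|**2``.
    """
    z1, z2 = _as_pair(z1, z2)
    return _corr(
        _envelope_transform(np.abs(z1), variant),
        _envelope_transform(np.abs(z2), variant),
    )


def _normalize_pair(z1: np.ndarray, z2: np.ndarray):
    p1 = np.mean(np.abs(z1) ** 2)
    p2 = np.mean(np.abs(z2) ** 2)
    if p1 == 0 or p2 == 0:
        raise ValueError("zero mean power; cannot normalize")
    return z1 / np.sqrt(p1), z2 / np.sqrt(p2)


def opec_global(z1, z2, variant: str = "power", symmetrize: bool = False) -> float:
    """Orthogonalized PEC with a global (time-independent) regression.

    Both channels are normalized to unit mean power; ``z2`` is replaced
    by the residual ``z2 - alpha*z1`` with ``alpha = Re(c)`` estimated
    from the same segments, then the plain PEC of ``(z1, residual)`` is
    returned.  Directional 1->2 by default.  Gaussian limit of the
    power variant: squared lagged coherence.
    """
    if symmetrize:
        return 0.5 * (
            opec_global(z1, z2, variant) + opec_global(z2, z1, variant)
        )
    z1, z2 = _as_pair(z1, z2)
    z1, z2 = _normalize_pair(z1, z2)
    alpha = float(np.mean(z2 * z1.conj()).real)  # = Re(c) for unit-power signals
    resid = z2 - alpha * z1
    if np.allclose(resid, 0):
        raise ValueError("orthogonalized residual is identically zero (|c|=1, real)")
    return _corr(
        _envelope_transform(np.abs(z1), variant),
        _envelope_transform(np.abs(resid), variant),
    )


def opec_local(z1, z2, variant: str = "power", symmetrize: bool = False) -> float:
    """Orthogonalized PEC with per-segment (local) orthogonalization.

    The envelope of ``z2`` is replaced by ``|Im(z2 z1*) / |z1||``, the
    magnitude of the component of ``z2`` orthogonal to ``z1`` within
    each segment (equivalent to fitting the regression coefficient
    separately per segment).  Directional 1->2 by default.
    """
    if symmetrize:
        return 0.5 * (opec_local(z1, z2, variant) + opec_local(z2, z1, variant))
    z1, z2 = _as_pair(z1, z2)
    z1, z2 = _drop_zero_amplitude(z1, z2)
    ortho = np.abs(np.imag(z2 * z1.conj()) / np.abs(z1))
    if np.all(ortho <= 1e-12 * np.abs(z2)):
        raise ValueError(
            "orthogonalized envelope is zero: channels are collinear per segment"
        )
    a1 = np.abs(z1)
    if variant == "log" and np.any(ortho == 0):
        raise ValueError("log variant requires nonzero orthogonalized amplitudes")
    return _corr(_envelope_transform(a1, variant), _envelope_transform(ortho, variant))


# ---------------------------------------------------------------------------
# measure registry and matrix-level application

def _measure_entry(func, symmetry, diagonal, complex_valued=False):
    return {
        "func": func,
        "symmetry": symmetry,  # 'antisymmetric' | 'symmetric' | 'directional'
        "diagonal": diagonal,  # value placed on the matrix diagonal
        "complex": complex_valued,
    }


MEASURES: dict[str, dict] = {
    "wpli": _measure_entry(wpli, "antisymmetric", 0.0),
    "pli": _measure_entry(pli, "antisymmetric", 0.0),
    "plv": _measure_entry(plv, "hermitian", 1.0, complex_valued=True),
    "pec_power": _measure_entry(lambda a, b: pec(a, b, "power"), "symmetric", 1.0),
    "pec_amplitude": _measure_entry(
        lambda a, b: pec(a, b, "amplitude"), "symmetric", 1.0
    ),
    "pec_log": _measure_entry(lambda a, b: pec(a, b, "log"), "symmetric", 1.0),
    "opec_power": _measure_entry(
        lambda a, b: opec_global(a, b, "power"), "directional", np.nan
    ),
    "opec_amplitude": _measure_entry(
        lambda a, b: opec_global(a, b, "amplitude"), "directional", np.nan
    ),
    "opec_log": _measure_entry(
        lambda a, b: opec_global(a, b, "log"), "directional", np.nan
    ),
    "lopec_power": _measure_entry(
        lambda a, b: opec_local(a, b, "power"), "directional", np.nan
    ),
    "lopec_amplitude": _measure_entry(
        lambda a, b: opec_local(a, b, "amplitude"), "directional", np.nan
    ),
    "lopec_log": _measure_entry(
        lambda a, b: opec_local(a, b, "log"), "directional", np.nan
    ),
}


class CouplingMatrix:
    """Channel-by-channel values of one measure at one frequency."""

    def __init__(
        self,
        values: np.ndarray,
        measure_name: str,
        frequency: float,
        channel_labels: list[str] | None = None,
        time_index: float | None = None,
    ):
        self.values = np.asarray(values)
        self.measure_name = measure_name
        self.frequency = frequency
        self.channel_labels = channel_labels
        self.time_index = time_index

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CouplingMatrix({self.measure_name!r}, f={self.frequency} Hz, "
            f"{self.n_channels} channels)"
        )


def coupling_matrix(
    spectra: SegmentedSpectra, measure: str, frequency: float
) -> CouplingMatrix:
    """Apply one coupling measure to every channel pair at one frequency.

    Symmetry conventions are enforced per measure: antisymmetric
    measures get ``M[j, i] = -M[i, j]``, symmetric ones
    ``M[j, i] = M[i, j]``, the complex PLV matrix is Hermitian, and
    directional OPEC measures are computed for every ordered pair.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    entry = MEASURES[measure]
    z = spectra.at_frequency(frequency)
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels")
    check_boundary_bin(spectra, frequency)
    dtype = complex if entry["complex"] else float
    out = np.full((n, n), entry["diagonal"], dtype=dtype)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                vij = entry["func"](z[i], z[j])
            except ValueError as err:
                labels = spectra.channel_labels or [str(k) for k in range(n)]
                raise ValueError(
                    f"{measure} failed for pair ({labels[i]}, {labels[j]}): {err}"
                ) from err
            out[i, j] = vij
            if entry["symmetry"] == "antisymmetric":
                out[j, i] = -vij
            elif entry["symmetry"] == "symmetric":
                out[j, i] = vij
            elif entry["symmetry"] == "hermitian":
                out[j, i] = np.conj(vij)
            else:  # directional: compute the reverse direction explicitly
                out[j, i] = entry["func"](z[j], z[i])
    return CouplingMatrix(
        values=out,
        measure_name=measure,
        frequency=float(spectra.frequencies[spectra.frequency_index(frequency)]),
        channel_labels=spectra.channel_labels,
    )
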