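"""Gaussian-model predictions of nonlinear coupling from complex coherency.

For Gaussian distributed (i.e., linear, stationary) data the complex
coherency ``c`` of a channel pair determines every normalized coupling
measure at that frequency.  This module evaluates those functional
relations so that a nonlinear measure can be *predicted* from the linear
statistics alone; the gap between the prediction and the estimated
measure then quantifies non-Gaussianity of the data.

Closed forms (``lc`` denotes the signed lagged coherence
``Im(c)/sqrt(1 - Re(c)^2)``):

=====================  =======================================
measure                Gaussian-model value
=====================  =======================================
wPLI                   ``2*lc / (1 + lc**2)``
PLI                    ``lc``
complex PLV            ``c * f(|c|)``
PEC (power variant)    ``|c|**2``
OPEC (global, power)   ``lc**2``
=====================  =======================================

The PLV scaling function ``f`` is known only as a series expansion,

    f(x) = pi * (1 - x^2) * sum_{k>=1} k * ((2k-1)!! / (k! 2^k))^2 * x^(2k-2),

with exact boundary values f(0) = pi/4 and f(1) = 1; a closed-form
approximation ``f~(x) = 1 - (1 - pi/4) * sqrt(1 - x^2)`` is accurate to
better than 0.012 in the resulting PLV magnitude and is the default.

Amplitude and log variants of PEC/OPEC have no known closed form; they
are unique functions of coherence (PEC) or lagged coherence (OPEC) and
are served from a precomputed Monte-Carlo lookup table
(``data/gaussian_lookup.csv``, regenerated by
``scripts/build_lookup_tables.py``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import gammaln

from .coupling import MEASURES, CouplingMatrix
from .spectral import CoherencyMatrix, lagged_coherence

__all__ = [
    "ScalingFunctionSpec",
    "scaling_f",
    "scaling_f_approx",
    "model_wpli",
    "model_pli",
    "model_plv",
    "model_pec",
    "model_opec",
    "model_value",
    "model_matrix",
    "lookup_model",
]


@dataclass
class ScalingFunctionSpec:
    """Truncation / approximation choice for the PLV scaling function."""

    n_terms: int = 500
    use_approximation: bool = True

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


def scaling_f(coh: float | np.ndarray, n_terms: int = 500) -> float | np.ndarray:
    """PLV scaling function ``f(|c|)`` via its truncated series.

    Series terms are accumulated in log space through cumulative ratios
    of log-gamma values; the double factorial in the coefficient
    overflows a naive evaluation near k ~ 150.  ``f(0) = pi/4`` exactly
    (only the k=1 term survives) and ``f -> 1`` as ``coh -> 1``, but
    the series converges poorly there: for ``coh > 0.99`` use
    :func:`scaling_f_approx`.
    """
    x = np.asarray(coh, dtype=float)
    if np.any((x < 0) | (x >= 1)):
        raise ValueError(
            "scaling_f requires 0 <= coh < 1; at coh = 1 the exact value is "
            "f(1) = 1, and scaling_f_approx covers the full closed interval"
        )
    if np.any(x > 0.99):
        warnings.warn(
            "series convergence is poor for coh > 0.99; consider scaling_f_approx",
            RuntimeWarning,
            stacklevel=2,
        )
    k = np.arange(1, n_terms + 1, dtype=float)
    # a_k = (2k-1)!! / (k! 2^k) = C(2k, k) / 4^k ; log a_k via gammaln
    log_ak = gammaln(2 * k + 1) - 2 * gammaln(k + 1) - k * np.log(4.0)
    log_k = np.log(k)
    x2 = np.atleast_1d(x) ** 2
    with np.errstate(divide="ignore"):
        logx2 = np.where(x2 > 0, np.log(x2), -np.inf)
    # log term_k = log k + 2 log a_k + (k-1) log x^2 ; the k=1 term has
    # exponent 0 and must survive x = 0 (0 * -inf would be nan)
    with np.errstate(invalid="ignore"):
        power = (k - 1)[None, :] * logx2[:, None]
    power[:, 0] = 0.0
    log_terms = log_k[None, :] + 2 * log_ak[None, :] + power
    series = np.exp(log_terms).sum(axis=1)
    out = np.pi * (1.0 - x2) * series
    return float(out[0]) if np.ndim(coh) == 0 else out.reshape(np.shape(coh))


def scaling_f_approx(coh: float | np.ndarray) -> float | np.ndarray:
    """Closed-form approximation ``f~(x) = 1 - (1 - pi/4)*sqrt(1 - x^2)``.

    Linear in ``sqrt(1 - x^2)`` with the exact boundary values
    ``f~(0) = pi/4`` and ``f~(1) = 1``.
    """
    x = np.asarray(coh, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("coherence must lie in [0, 1]")
    out = 1.0 - (1.0 - np.pi / 4.0) * np.sqrt(1.0 - x**2)
    return float(out) if np.ndim(coh) == 0 else out


def model_wpli(c: complex | np.ndarray) -> float | np.ndarray:
    """Gaussian-model wPLI: ``2*lc / (1 + lc**2)``."""
    lc = lagged_coherence(c)
    return 2.0 * lc / (1.0 + lc**2)


def model_pli(c: complex | np.ndarray) -> float | np.ndarray:
    """Gaussian-model PLI: the signed lagged coherence itself."""
    return lagged_coherence(c)


def model_plv(
    c: complex | np.ndarray, spec: ScalingFunctionSpec | None = None
) -> complex | np.ndarray:
    """Gaussian-model complex PLV: ``c * f(|c|)``.

    Uses the closed-form approximation of ``f`` by default; with
    ``spec.use_approximation = False`` the truncated series is used and
    values with ``|c| > 0.99`` fall back to the approximation (the
    series converges too slowly there).
    """
    spec = spec or ScalingFunctionSpec()
    c = np.asarray(c, dtype=complex)
    mag = np.abs(c)
    if np.any(mag > 1 + 1e-9):
        raise ValueError("|c| must be <= 1")
    mag = np.minimum(mag, 1.0)
    if spec.use_approximation:
        f = scaling_f_approx(mag)
    else:
        f = np.asarray(scaling_f_approx(mag), dtype=float)
        ok = np.atleast_1d(mag) <= 0.99
        if np.any(ok):
            vals = scaling_f(np.atleast_1d(mag)[ok], n_terms=spec.n_terms)
            f = np.array(f, ndmin=1)
            f[ok] = vals
            f = f.reshape(np.shape(mag))
        if not np.all(ok):
            warnings.warn(
                "using the closed-form approximation for |c| > 0.99",
                RuntimeWarning,
                stacklevel=2,
            )
    out = c * f
    return complex(out) if out.ndim == 0 else out


def model_pec(c: complex | np.ndarray) -> float | np.ndarray:
    """Gaussian-model PEC (power variant): squared coherence ``|c|**2``."""
    out = np.abs(np.asarray(c)) ** 2
    if np.any(out > 1 + 1e-9):
        raise ValueError("|c| must be <= 1")
    return float(out) if out.ndim == 0 else out


def model_opec(c: complex | np.ndarray) -> float | np.ndarray:
    """Gaussian-model OPEC (global, power variant): ``lc**2``."""
    lc = lagged_coherence(c)
    return lc**2


# ---------------------------------------------------------------------------
# Monte-Carlo lookup table for amplitude / log variants

_LOOKUP_CACHE: dict[str, PchipInterpolator] = {}

#: measures served by the lookup table, with the linear predictor each
#: one is a unique function of ('coh' -> |c|, 'lagcoh' -> |lagged coherence|)
LOOKUP_MEASURES = {
    "pec_amplitude": "coh",
    "pec_log": "coh",
    "opec_amplitude": "lagcoh",
    "opec_log": "lagcoh",
    "lopec_power": "lagcoh",
    "lopec_amplitude": "lagcoh",
    "lopec_log": "lagcoh",
}


def _load_lookup(measure: str) -> PchipInterpolator:
    if measure not in _LOOKUP_CACHE:
        with resources.files("gausscoup").joinpath("data/gaussian_lookup.csv").open() as fh:
            rows = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        header = rows[0].split(",")
        table = np.array([[float(v) for v in r.split(",")] for r in rows[1:]])
        for name in LOOKUP_MEASURES:
            col = header.index(name)
            _LOOKUP_CACHE[name] = PchipInterpolator(table[:, 0], table[:, col])
    return _LOOKUP_CACHE[measure]


def lookup_model(measure: str, c: complex | np.ndarray) -> float | np.ndarray:
    """Gaussian-model value of an amplitude/log PEC-OPEC variant.

    Interpolates the precomputed circular-Gaussian Monte-Carlo table on
    ``|c|`` (PEC variants) or ``|lagged coherence|`` (OPEC variants,
    whose Gaussian values collapse onto a single curve of lagged
    coherence).
    """
    if measure not in LOOKUP_MEASURES:
        raise ValueError(f"no lookup table for measure {measure!r}")
    if LOOKUP_MEASURES[measure] == "coh":
        arg = np.abs(np.asarray(c))
    else:
        arg = np.abs(np.asarray(lagged_coherence(c)))
    out = _load_lookup(measure)(np.clip(arg, 0.0, 0.99))
    return float(out) if out.ndim == 0 else out


_CLOSED_FORM = {
    "wpli": model_wpli,
    "pli": model_pli,
    "plv": model_plv,
    "pec_power": model_pec,
    "opec_power": model_opec,
}


def model_value(measure: str, c: complex | np.ndarray, spec: ScalingFunctionSpec | None = None):
    """Gaussian-model value of any supported measure at coherency ``c``."""
    if measure in _CLOSED_FORM:
        if measure == "plv":
            return model_plv(c, spec)
        return _CLOSED_FORM[measure](c)
    if measure in LOOKUP_MEASURES:
        return lookup_model(measure, c)
    raise ValueError(f"no Gaussian model available for measure {measure!r}")


def model_matrix(
    C: CoherencyMatrix, measure: str, spec: ScalingFunctionSpec | None = None
) -> CouplingMatrix:
    """Elementwise Gaussian-model prediction for a whole coherency matrix.

    Power-variant PEC/OPEC and the phase measures use their closed
    forms; amplitude/log variants go through the Monte-Carlo lookup
    table.  The diagonal follows the same convention as the
    corresponding estimator matrix.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    entry = MEASURES[measure]
    n = C.matrix.shape[0]
    dtype = complex if entry["complex"] else float
    out = np.full((n, n), entry["diagonal"], dtype=dtype)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = model_value(measure, C.matrix[i, j], spec)
    return CouplingMatrix(
        values=out,
        measure_name=f"model:{measure}",
        frequency=C.frequency,
        channel_labels=C.channel_labels,
    )
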