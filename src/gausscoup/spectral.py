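"""Segmented Fourier spectra, cross-spectra and coherency.

The estimation pipeline follows the standard Welch-style scheme used in
sensor-level EEG/MEG connectivity work: the multichannel recording is cut
into (possibly overlapping) segments, each segment is demeaned, windowed
and Fourier transformed, and expected values at a given frequency are
estimated by averaging over segments.  The complex coefficients
``z_i(f, k)`` (channel i, frequency f, segment k) are the universal input
for every coupling estimator in this package.

Linear quantities derived here:

* cross-spectrum            ``S_ij = <z_i z_j*>``
* complex coherency         ``C_ij = S_ij / sqrt(S_ii S_jj)``
* imaginary coherence       ``Im(c)``
* lagged coherence (signed) ``Im(c) / sqrt(1 - Re(c)^2)``

Lagged coherence is, up to sign, invariant to real-valued mixing of two
sources and is the quantity through which almost all Gaussian-model
predictions of nonlinear coupling are expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

__all__ = [
    "TimeSeriesData",
    "SegmentedSpectra",
    "CrossSpectrum",
    "CoherencyMatrix",
    "segment_and_transform",
    "cross_spectrum",
    "coherency",
    "imaginary_coherence",
    "lagged_coherence",
]

#: relative tolerance for Hermiticity / positivity checks
HERMITICITY_RTOL = 1e-8


@dataclass
class TimeSeriesData:
    """Real multichannel recording (channels x samples)."""

    values: np.ndarray
    sampling_rate: float
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match data")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SegmentedSpectra:
    """Complex coefficients z_i(f, k): channel x frequency x segment."""

    coefficients: np.ndarray
    frequencies: np.ndarray
    segment_length: int
    overlap_fraction: float
    window_name: str = "hann"
    origin: str = "fourier"
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must be channel x frequency x segment")
        if self.coefficients.shape[1] != self.frequencies.size:
            raise ValueError("frequency axis mismatch")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite spectral coefficients")

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_segments(self) -> int:
        return self.coefficients.shape[2]

    def frequency_index(self, frequency: float) -> int:
        """Index of the bin matching `frequency` (within half a bin width)."""
        idx = int(np.argmin(np.abs(self.frequencies - frequency)))
        df = np.median(np.diff(self.frequencies)) if self.frequencies.size > 1 else 1.0
        if abs(self.frequencies[idx] - frequency) > 1e-6 * df + 1e-9:
            raise ValueError(
                f"frequency {frequency} Hz not present "
                f"(nearest bin: {self.frequencies[idx]} Hz)"
            )
        return idx

    def at_frequency(self, frequency: float) -> np.ndarray:
        """Coefficients (channel x segment) at one frequency bin."""
        return self.coefficients[:, self.frequency_index(frequency), :]


@dataclass
class CrossSpectrum:
    """Hermitian cross-spectral matrix at a single frequency."""

    matrix: np.ndarray
    frequency: float
    n_segments: int
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)
        scale = np.abs(self.matrix).max()
        if scale > 0 and np.abs(self.matrix - self.matrix.conj().T).max() > HERMITICITY_RTOL * scale:
            raise ValueError("cross-spectrum is not Hermitian within tolerance")
        diag = np.diag(self.matrix)
        if np.any(diag.real < -HERMITICITY_RTOL * max(scale, 1.0)) or np.any(
            np.abs(diag.imag) > HERMITICITY_RTOL * max(scale, 1.0)
        ):
            raise ValueError("cross-spectrum diagonal must be real and non-negative")


@dataclass
class CoherencyMatrix:
    """Normalized complex coherency at a single frequency (unit diagonal)."""

    matrix: np.ndarray
    frequency: float
    n_segments: int = 0
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=complex)


def _n_segments(n_samples: int, nper: int, step: int) -> int:
    if n_samples < nper:
        return 0
    return (n_samples - nper) // step + 1


def segment_and_transform(
    data: TimeSeriesData,
    segment_length: float = 1.0,
    overlap_fraction: float = 0.5,
    window: str = "hann",
    demean_segments: bool = True,
) -> SegmentedSpectra:
    """Cut a recording into windowed segments and Fourier transform each.

    Parameters
    ----------
    data
        Multichannel real recording.
    segment_length
        Segment duration in seconds.  The frequency resolution is its
        inverse.
    overlap_fraction
        Fractional overlap of consecutive segments in [0, 1).  ``0.5``
        is the conventional default; a value so close to 1 that the hop
        rounds below one sample is clipped to a one-sample hop (maximal
        overlap, used for time-resolved envelope work).
    window
        Taper name understood by :func:`scipy.signal.get_window`
        ("hann", "hamming", "boxcar", ...).
    demean_segments
        Remove each segment's mean before windowing.  This suppresses
        leakage of the DC offset; disable to demean globally instead.

    Returns
    -------
    SegmentedSpectra
        One complex coefficient per channel, frequency bin and segment.
        Frequencies run from 0 to Nyquist with spacing
        ``1/segment_length``.  No ``1/N`` factor is applied to the
        forward transform; every coupling measure downstream is
        normalization-invariant, so the convention only affects raw
        power values.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    nper = int(round(segment_length * data.sampling_rate))
    if nper < 2:
        raise ValueError("segment_length must span at least 2 samples")
    if data.n_samples < nper:
        raise ValueError(
            f"data ({data.n_samples} samples) shorter than one segment ({nper})"
        )
    step = max(1, int(round(nper * (1.0 - overlap_fraction))))
    n_seg = _n_segments(data.n_samples, nper, step)

    taper = get_window(window, nper, fftbins=True)
    starts = np.arange(n_seg) * step
    # (n_seg, nper) gather -> (channel, n_seg, nper)
    idx = starts[:, None] + np.arange(nper)[None, :]
    segs = data.values[:, idx]
    if demean_segments:
        segs = segs - segs.mean(axis=-1, keepdims=True)
    segs = segs * taper
    coeff = np.fft.rfft(segs, axis=-1)  # (channel, segment, freq)
    freqs = np.fft.rfftfreq(nper, d=1.0 / data.sampling_rate)
    return SegmentedSpectra(
        coefficients=np.transpose(coeff, (0, 2, 1)),
        frequencies=freqs,
        segment_length=nper,
        overlap_fraction=overlap_fraction,
        window_name=window,
        channel_labels=list(data.channel_labels),
    )


def cross_spectrum(spectra: SegmentedSpectra, frequency: float) -> CrossSpectrum:
    """Segment-averaged cross-spectral matrix ``S_ij = <z_i z_j*>``."""
    z = spectra.at_frequency(frequency)  # (channel, segment)
    if z.shape[1] < 2:
        raise ValueError("need at least 2 segments to average a cross-spectrum")
    S = z @ z.conj().T / z.shape[1]
    S = (S + S.conj().T) / 2.0  # enforce exact Hermiticity against round-off
    return CrossSpectrum(
        matrix=S,
        frequency=float(spectra.frequencies[spectra.frequency_index(frequency)]),
        n_segments=z.shape[1],
        channel_labels=spectra.channel_labels,
    )


def coherency(S: CrossSpectrum) -> CoherencyMatrix:
    """Complex coherency ``C_ij = S_ij / sqrt(S_ii S_jj)``."""
    power = np.diag(S.matrix).real
    if np.any(power <= 0):
        bad = int(np.argmin(power))
        label = S.channel_labels[bad] if S.channel_labels else str(bad)
        raise ValueError(f"zero spectral power on channel {label!r}; cannot normalize")
    norm = np.sqrt(power)
    C = S.matrix / np.outer(norm, norm)
    np.fill_diagonal(C, 1.0)
    return CoherencyMatrix(
        matrix=C,
        frequency=S.frequency,
        n_segments=S.n_segments,
        channel_labels=S.channel_labels,
    )


def imaginary_coherence(c: complex | np.ndarray) -> float | np.ndarray:
    """Imaginary part of coherency (ImCoh).

    Vanishes in the infinite-data limit for independent sources mixed
    instantaneously into sensors, which is why it is used as a
    volume-conduction-robust coupling index.
    """
    out = np.imag(c)
    return float(out) if np.isscalar(c) or np.ndim(c) == 0 else out


def lagged_coherence(c: complex | np.ndarray) -> float | np.ndarray:
    """Signed lagged coherence ``Im(c) / sqrt(1 - Re(c)^2)``.

    For two sources this quantity is, apart from a possible sign flip,
    invariant to any real invertible mixing of the sources into the two
    sensors, and it parameterizes the Gaussian-model value of most
    mixing-robust nonlinear measures.

    Raises
    ------
    ValueError
        If ``|Re(c)| >= 1`` (degenerate, perfectly real coupling).
    """
    c = np.asarray(c, dtype=complex)
    re = c.real
    if np.any(np.abs(re) >= 1):
        raise ValueError("lagged coherence undefined for |Re(c)| >= 1")
    out = c.imag / np.sqrt(1.0 - re**2)
    return float(out) if out.ndim == 0 else out


def check_boundary_bin(spectra: SegmentedSpectra, frequency: float) -> None:
    """Warn when a requested bin is DC or Nyquist.

    Spectra of real signals are real there, so every lagged or imaginary
    quantity is identically zero and phase-based measures degenerate.
    """
    i = spectra.frequency_index(frequency)
    full_axis = spectra.frequencies.size > 1 and spectra.frequencies[0] == 0
    if spectra.frequencies[i] == 0 or (full_axis and i == spectra.frequencies.size - 1):
        warnings.warn(
            f"frequency {spectra.frequencies[i]} Hz is a DC/Nyquist bin: "
            "imaginary and lagged quantities are identically zero there",
            RuntimeWarning,
            stacklevel=3,
        )
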