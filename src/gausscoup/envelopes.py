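"""Short-time Fourier versus filter+Hilbert envelope estimation.

Two common routes to a complex, time-resolved narrow-band signal:

* **Fourier route** — convolve the data with a complex wavelet
  ``h(t, f0) = h0(t) * exp(-i 2 pi f0 t / L)`` (a taper ``h0``, e.g., a
  Hanning window, modulated to the center frequency ``f0``).  This is
  exactly a sliding windowed Fourier coefficient at maximal overlap.

* **Hilbert route** — filter the data with the real part of the same
  wavelet, then take the analytic signal (zero the negative
  frequencies, double the positive ones).

In the frequency domain the Fourier route keeps ``h^0(f - f0)`` at all
frequencies while the Hilbert route keeps ``h^0(f - f0) + h^0(f + f0)``
at positive frequencies only.  The two coincide whenever the taper's
spectral support around ``f0`` does not reach 0 or the Nyquist
frequency; deviations appear exactly at the spectral boundaries.  The
deviation statistic

    Delta(f) = || Im(y) - Im(H(Re(y))) ||_F / || Im(y) ||_F

measures how well the real and imaginary parts of the Fourier-route
signal ``y`` are linked by the Hilbert transform ``H``.

All convolutions here are circular (periodic boundary conditions);
``boundary_mode='truncate'`` drops one window length at each end of the
output, which is how empirical (non-periodic) records should be
handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "WaveletSpec",
    "fourier_envelope",
    "hilbert_envelope",
    "deviation_delta",
    "delta_sweep",
]


@dataclass
class WaveletSpec:
    """Real taper (odd length) and a center-frequency bin index."""

    window: np.ndarray
    center_bin: int

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim != 1 or self.window.size % 2 == 0:
            raise ValueError("wavelet window must be a 1-D odd-length sequence")
        if not np.all(np.isfinite(self.window)):
            raise ValueError("wavelet window must be finite")


def _taper_spectrum(spec: WaveletSpec, n: int) -> np.ndarray:
    """FFT of the taper zero-padded to length n and centered at t=0."""
    m = spec.window.size
    if m > n:
        raise ValueError("wavelet longer than the data")
    h = np.zeros(n)
    half = m // 2
    # place the taper symmetrically around sample 0 (circular time axis)
    h[: half + 1] = spec.window[half:]
    h[-half:] = spec.window[:half]
    return np.fft.fft(h)


def _truncate(y: np.ndarray, spec: WaveletSpec, mode: str) -> np.ndarray:
    if mode == "periodic":
        return y
    if mode == "truncate":
        m = spec.window.size
        return y[m : y.size - m]
    raise ValueError("boundary_mode must be 'periodic' or 'truncate'")


def fourier_envelope(
    x: np.ndarray, spec: WaveletSpec, boundary_mode: str = "periodic"
) -> np.ndarray:
    """Complex wavelet coefficient ``y(t, f0)`` at every time point.

    Circular convolution of the (demeaned) data with the modulated
    taper, evaluated in the Fourier domain: the taper spectrum is
    shifted to the center bin and applied at *all* frequencies.
    ``abs`` of the result is the time-resolved envelope.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    h0_hat = _taper_spectrum(spec, n)
    h_hat = np.roll(h0_hat, spec.center_bin)  # h^(f) = h^0(f - f0), periodic in f
    y = np.fft.ifft(np.fft.fft(x) * h_hat) / n
    return _truncate(y, spec, boundary_mode)


def hilbert_envelope(
    x: np.ndarray, spec: WaveletSpec, boundary_mode: str = "periodic"
) -> np.ndarray:
    """Analytic signal of the data filtered with ``Re(wavelet)``.

    The filter spectrum is ``(h^0(f - f0) + h^0(f + f0)) / 2``; the
    analytic signal then zeroes negative frequencies and doubles the
    positive ones (DC and Nyquist kept unscaled).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    h0_hat = _taper_spectrum(spec, n)
    filt = (np.roll(h0_hat, spec.center_bin) + np.roll(h0_hat, -spec.center_bin)) / 2.0
    x_f = np.fft.ifft(np.fft.fft(x) * filt).real / n
    return _truncate(hilbert(x_f), spec, boundary_mode)


def deviation_delta(y: np.ndarray) -> float:
    """Hilbert-consistency deviation of one complex signal.

    ``Delta = ||Im(y) - Im(H(Re(y)))||_F / ||Im(y)||_F`` where ``H`` is
    the discrete (FFT-based, periodic) Hilbert transform.  Zero to
    machine precision when ``y`` is analytic; invariant under global
    rescaling of ``y``.
    """
    y = np.asarray(y, dtype=complex)
    im = y.imag
    denom = np.linalg.norm(im)
    if denom == 0:
        raise ValueError("imaginary part has zero norm; deviation undefined")
    im_hilbert = hilbert(y.real).imag
    return float(np.linalg.norm(im - im_hilbert) / denom)


def delta_sweep(
    x: np.ndarray, window: np.ndarray, sampling_rate: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Delta(f) for every positive-frequency bin of a record.

    Runs :func:`fourier_envelope` with periodic boundaries at every
    center bin from 1 to just below Nyquist and evaluates
    :func:`deviation_delta` on each.  Returns ``(frequencies_hz, delta)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    n_bins = n // 2  # positive frequencies, excluding DC
    freqs = np.arange(1, n_bins) * sampling_rate / n
    deltas = np.empty(freqs.size)
    x_hat = np.fft.fft(x - x.mean())
    spec = WaveletSpec(window=window, center_bin=1)
    h0_hat = _taper_spectrum(spec, n)
    for i, bin_ in enumerate(range(1, n_bins)):
        y = np.fft.ifft(x_hat * np.roll(h0_hat, bin_)) / n
        deltas[i] = deviation_delta(y)
    return freqs, deltas
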