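"""Sliding-window Fourier envelopes vs filter+Hilbert envelopes.

Computes the complex 10 Hz signal of a noisy recording by (a) convolving
with a Hanning-tapered complex wavelet (the maximal-overlap windowed
Fourier coefficient) and (b) filtering with the wavelet's real part and
taking the analytic signal, then sweeps the deviation Delta(f) over all
center frequencies on white noise.
"""

import numpy as np

import gausscoup as gc

rng = np.random.default_rng(3)
fs, n = 100.0, 6001
x = rng.standard_normal(n)

win = np.hanning(101)  # 1 s Hanning taper
spec = gc.WaveletSpec(window=win, center_bin=round(10.0 / fs * n))
y_fourier = gc.fourier_envelope(x, spec)
y_hilbert = gc.hilbert_envelope(x, spec)
mismatch = np.linalg.norm(y_fourier - y_hilbert) / np.linalg.norm(y_fourier)
print(f"10 Hz complex-signal mismatch between the two routes: {mismatch:.2e}")

freqs, deltas = gc.delta_sweep(x, win, sampling_rate=fs)
print("\nDelta(f) = ||Im(y) - Im(H(Re(y)))|| / ||Im(y)||  (periodic boundaries)")
for f0 in (1, 2, 5, 10, 25, 40, 45, 48, 49):
    i = np.argmin(abs(freqs - f0))
    print(f"  f = {freqs[i]:5.1f} Hz   Delta = {deltas[i]:.2e}")

print("""
Mid-band the two routes agree to a fraction of a percent: the windowed
Fourier coefficient is already (nearly) analytic.  Only when the taper's
~2 Hz bandwidth touches 0 Hz or the 50 Hz Nyquist frequency do the real
and imaginary parts decouple from the Hilbert relation.""")
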