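# Methods

## Model

Segment coefficients `z_i(f, k)` (channel i, frequency f, segment k) of
a stationary linear system are circular complex Gaussian: their joint
density depends only on the Hermitian cross-spectrum `S_ij = <z_i z_j*>`
and is invariant under a global phase rotation, so `<z z^T> = 0`.  Every
coupling measure in this package is normalized (invariant under
`z_i -> a_i z_i`, `a_i > 0`), hence for Gaussian data it is a function
of the complex coherency `c = S12 / sqrt(S11 S22)` alone.  The package
implements those functions:

* `wPLI = <Im(z1 z2*)> / <|Im(z1 z2*)|>` has model `2 lc / (1 + lc^2)`;
* `PLI = <sign Im(z1 z2*)>` has model `lc`;
* complex `PLV = <z1 z2* / (|z1||z2|)>` has model `c f(|c|)`;
* power-envelope correlation `corr(|z1|^2, |z2|^2)` has model `|c|^2`;
* globally orthogonalized PEC `corr(|z1|^2, |z2 - Re(c) z1|^2)` (unit-power
  channels) has model `lc^2`,

where `lc = Im(c) / sqrt(1 - Re(c)^2)` is the signed lagged coherence.
Signed definitions are used throughout (no final absolute value): the
sign carries information and avoids the positive bias an absolute value
introduces into group statistics.

The amplitude (`corr(|z1|, |z2|)`) and log (`corr(log|z1|, log|z2|)`)
variants of PEC/OPEC, and all locally orthogonalized (per-segment,
Hipp-style `|Im(z2 z1*)/|z1||`) variants, have no known closed form.
Numerically they are unique functions of `|c|` (plain PEC) or of lagged
coherence (every orthogonalized variant) — the package verifies this
collapse on random-mixing ensembles — so their model values are served
from a Monte-Carlo lookup table (`src/gausscoup/data/gaussian_lookup.csv`),
100 grid points, 10^6 realizations per point, monotone cubic (PCHIP)
interpolation.  Table error is at the 10^-3 level, below the sampling
noise of any realistic estimate.  `scripts/build_lookup_tables.py`
regenerates it (seed recorded in the file header).

### PLV scaling function

`f(x) = pi (1 - x^2) sum_{k>=1} k ((2k-1)!!/(k! 2^k))^2 x^(2k-2)` is
evaluated with terms accumulated in log space via log-gamma (the double
factorial overflows a direct evaluation near k ≈ 150).  Defaults: 500
terms, which is converged to < 10^-6 for `|c| <= 0.9`; the series loses
accuracy slowly as `|c| -> 1` (a warning is issued above 0.99 and
`model_plv` falls back to the closed-form approximation there).  The
approximation `f~(x) = 1 - (1 - pi/4) sqrt(1 - x^2)` is exact at both
boundaries (`pi/4`, 1) and keeps the PLV error below 0.012 over the full
range; it is the default for `model_plv` since that error is negligible
against estimation noise in practice.

## Estimation pipeline

Recordings are segmented (default 1 s windows, 50% overlap), each
segment demeaned, tapered (Hanning default; Hamming/rectangular
selectable) and Fourier transformed without a 1/N factor — all coupling
measures are normalization-invariant, so the convention only affects raw
power.  Demeaning is applied per segment (configurable) to suppress DC
leakage.  DC and Nyquist bins are computed but flagged with a warning
when used: real spectra make every imaginary/lagged quantity identically
zero there.  Cross-spectra are segment averages, symmetrized exactly
against round-off; Hermiticity/positivity checks use a relative
tolerance of 1e-8.

Conventions and edge cases:

* PLI counts exactly-real cross-terms as `sign(0) = 0` (mathematically
  forced; a measure-zero event for continuous data, but the rule matters
  at DC/Nyquist where coefficients are exactly real).
* Segments with zero amplitude are dropped with a warning by PLV and
  local OPEC when they are < 1% of segments, and are an error otherwise.
* Envelope correlations are plain Pearson correlations across segments;
  no Fisher transform.
* OPEC is directional (channel 2 orthogonalized with respect to channel
  1), matching its defining formulas; a symmetrized mean of both
  directions is available via `symmetrize=True` but is not the default,
  since the defining formulas fix one direction.  The global
  regression coefficient is the plug-in `Re(c)` estimated from the same
  segments being correlated.
* Locally orthogonalized pairs that are segment-wise collinear (e.g.,
  `z2 = z1`) are rejected as degenerate rather than correlating rounding
  noise.

## Simulators (the study conditions)

The generators' defaults are the validation conditions and are not
tuning knobs:

* **Circular-Gaussian pairs** — `z = A x`, `x` two unit-variance complex
  Gaussians, `A = A_R + i A_I` with all entries standard normal; the
  population cross-spectrum is `S = 2 A A^+`.  An ensemble of random `A`
  sweeps coherency over the unit disk.
* **AR(5)** — two channels, coefficients i.i.d. N(0, 0.25^2),
  rejection-sampled until the companion matrix is stable, unit white
  Gaussian innovations, 100 Hz.  Burn-in of `10 * order * sampling_rate`
  samples is discarded (the stationarity transient is much shorter for
  stable draws; the margin is cheap).
* **Kuramoto** — two phase oscillators,
  `theta(t+1,i) = theta(t,i) + dt (omega + sigma eta + sum_j a_ij
  sin(theta_i - theta_j(t - tau_ij)))`, with `dt = 1/100`,
  `omega = 20 pi` (10 Hz), `sigma = 5`, off-diagonal couplings
  N(0, 0.5^2), integer delays uniform up to 100 ms, output
  `x = sin(theta)`.  The noise enters multiplied by `dt`, following the
  defining difference equation literally; the Euler–Maruyama `sqrt(dt)`
  scaling is available as `noise_scaling="sqrt_dt"` for users who want
  the diffusion-consistent variant.  Initial phases are uniform on
  [0, 2 pi) and the delay buffer is pre-filled with them.

Validation runs use 10-minute records (the estimator-model gap scales as
1/sqrt(duration), and at 10 minutes the Gaussian floor is already an
order of magnitude below the nonlinear effects being demonstrated) and
ensembles of 20 systems / 50 mixing matrices with 10^5 realizations
each.  What passing these tests shows: the analytic relations and their
estimators are correct under the stated distributional assumptions.
What they do not show: anything about volume-conducted sensor mixtures
of many sources, nonstationarity, 1/f backgrounds, or artifacts present
in real EEG/MEG — the generators emulate none of these.

## Deviation statistics

`E_M(f)` is the subject-mean relative Frobenius distance between the
observed coupling matrix and its model prediction; `E_S(f)` replaces the
model by coupling matrices recomputed from segment bootstrap resamples
(20 by default, original segment count preserved).  Frobenius norms
exclude the diagonal by default: self-coupling is undefined for OPEC and
trivially fixed elsewhere, and a common convention keeps E_M comparable
across measures.  Only `E_M` clearly above `E_S` indicates
non-Gaussianity.

Event-related data: trials (ERP-subtracted by default, so coupling
refers to fluctuations around the evoked response) are cut by a sliding
window — 200 ms with 180 ms overlap over 1.2 s trials gives 51 time
points — with the trials at a fixed window position serving as the
segment ensemble.  Time courses are tested against the first
(pre-stimulus) time point with a paired permutation test: per subject
and time point, baseline and value are randomly exchanged (a sign flip
of their difference), the statistic is the absolute subject-mean
difference, and `p` is the plain fraction of surrogates at or above the
observed statistic (the `+1` finite-sample correction is available as an
option).  Significance uses Bonferroni `alpha / (n_times * n_freqs)`.
Note the granularity: with K subjects only `2^K` distinct sign patterns
exist, so very small p-values need enough subjects as well as enough
permutations.

## Fourier vs Hilbert envelopes

The sliding-window Fourier coefficient at center frequency `f0` is a
circular convolution with the complex wavelet `h0(t) exp(i 2 pi f0 t/L)`;
the Hilbert route filters with the wavelet's real part (a cosine-
modulated taper — filters are deliberately matched so only the conceptual
difference remains) and takes the FFT analytic signal (negative
frequencies zeroed, positive doubled, DC/Nyquist kept unscaled).  In the
frequency domain the routes differ only by taper leakage across 0 and
Nyquist, so they agree whenever `f0` is a few taper bandwidths away from
both.  For a 1 s Hanning taper the main-lobe half-width is 2 Hz; at
100 Hz sampling the two complex signals agree to < 10^-3 (relative) for
`f0` in roughly [6, 44] Hz, and the deviation statistic
`Delta(f) = ||Im(y) - Im(H(Re(y)))||_F / ||Im(y)||_F` (periodic
boundaries) stays below 10^-2 there while rising steeply within ~2 Hz of
either boundary.  For empirical (non-periodic) records,
`boundary_mode="truncate"` drops one window length at each end instead
of assuming periodicity.

## Known limitations

* The series form of `f` converges poorly near `|c| = 1`; above 0.99 the
  closed-form approximation is used (error < 0.012 in PLV units).
* Lookup-table models interpolate Monte-Carlo values (~10^-3 accuracy)
  and rely on the numerically observed — not proven — uniqueness of the
  lagged-coherence dependence for amplitude/log OPEC variants.
* Overlapping segments are statistically dependent; the segment
  bootstrap treats them as exchangeable, which slightly understates
  `E_S` at high overlap.
* AR/Kuramoto generators are written for two channels (matrix forms
  allow more, untested); analyses are sensor-space only — no source
  reconstruction, no cross-frequency coupling.
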