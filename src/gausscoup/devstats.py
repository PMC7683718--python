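"""Model-error, bootstrap and permutation statistics.

Non-Gaussianity of a dataset is quantified as the normalized gap
between an observed coupling matrix ``D`` and its Gaussian-model
prediction ``D_M`` computed from the coherency matrix of the same data:

    E_M(f) = (1/K) sum_k  ||D(f,k) - D_M(f,k)||_F / ||D(f,k)||_F

averaged over K subjects (datasets).  A nonzero E_M can also arise from
pure sampling noise, so a statistical error E_S is estimated by
replacing D_M with coupling matrices recomputed from bootstrap
resamples of the segments:

    E_S(f) = (1/(K N)) sum_{k,n}  ||D(f,k) - D_S(f,k,n)||_F / ||D(f,k)||_F

Only when E_M clearly exceeds E_S should it be read as evidence of
non-Gaussian dynamics.  For event-related data the same model error is
evaluated per segment-center time point, and time courses are tested
against the first (pre-stimulus) time point with a paired permutation
test under Bonferroni correction.

Frobenius norms exclude the matrix diagonal by default: self-coupling is
undefined for the orthogonalized measures and trivially fixed for the
others, so excluding it keeps E_M comparable across measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import CouplingMatrix, coupling_matrix
from .model import ScalingFunctionSpec, model_matrix
from .spectral import (
    SegmentedSpectra,
    TimeSeriesData,
    coherency,
    cross_spectrum,
    segment_and_transform,
)

__all__ = [
    "ModelErrorCurve",
    "PermutationResult",
    "relative_frobenius",
    "model_error",
    "bootstrap_statistical_error",
    "time_resolved_model_error",
    "paired_permutation_test",
]


@dataclass
class ModelErrorCurve:
    """E_M (and optionally E_S) per frequency and, optionally, time."""

    frequencies: np.ndarray
    model_error: np.ndarray  # (n_freq,) or (n_freq, n_times)
    statistical_error: np.ndarray | None = None
    times: np.ndarray | None = None
    n_subjects: int = 1
    n_boot: int = 0
    measure_name: str = ""


@dataclass
class PermutationResult:
    p_values: np.ndarray  # (n_times, n_freqs)
    alpha_bonferroni: float
    significant_mask: np.ndarray
    n_permutations: int


def _offdiag(M: np.ndarray) -> np.ndarray:
    mask = ~np.eye(M.shape[0], dtype=bool)
    return M[mask]


def relative_frobenius(
    D: np.ndarray, D_ref: np.ndarray, include_diagonal: bool = False
) -> float:
    """``||D - D_ref||_F / ||D||_F`` (off-diagonal entries by default)."""
    D = np.asarray(D)
    D_ref = np.asarray(D_ref)
    if D.shape != D_ref.shape:
        raise ValueError("matrix shapes differ")
    a, b = (D.ravel(), D_ref.ravel()) if include_diagonal else (_offdiag(D), _offdiag(D_ref))
    denom = np.linalg.norm(a)
    if denom == 0:
        raise ValueError("zero-norm coupling matrix; relative error undefined")
    return float(np.linalg.norm(a - b) / denom)


def model_error(
    D_stack: list[CouplingMatrix] | list[np.ndarray],
    DM_stack: list[CouplingMatrix] | list[np.ndarray],
    include_diagonal: bool = False,
) -> float:
    """Subject-averaged relative Frobenius model error E_M.

    ``D_stack`` holds one observed coupling matrix per subject and
    ``DM_stack`` the matching Gaussian-model predictions.
    """
    if len(D_stack) != len(DM_stack):
        raise ValueError("need one model matrix per subject")
    if len(D_stack) == 0:
        raise ValueError("empty subject stack")
    errs = []
    for k, (D, DM) in enumerate(zip(D_stack, DM_stack)):
        Dv = D.values if isinstance(D, CouplingMatrix) else np.asarray(D)
        Mv = DM.values if isinstance(DM, CouplingMatrix) else np.asarray(DM)
        try:
            errs.append(relative_frobenius(Dv, Mv, include_diagonal))
        except ValueError as err:
            raise ValueError(f"subject {k}: {err}") from err
    return float(np.mean(errs))


def _coupling_and_model(
    spectra: SegmentedSpectra,
    measure: str,
    frequency: float,
    spec: ScalingFunctionSpec | None = None,
) -> tuple[CouplingMatrix, CouplingMatrix]:
    D = coupling_matrix(spectra, measure, frequency)
    C = coherency(cross_spectrum(spectra, frequency))
    return D, model_matrix(C, measure, spec)


def bootstrap_statistical_error(
    spectra_per_subject: list[SegmentedSpectra],
    measure: str,
    frequency: float,
    n_boot: int = 20,
    seed: int | np.random.Generator = 0,
    include_diagonal: bool = False,
) -> float:
    """Bootstrap noise floor E_S for one measure at one frequency.

    For each subject, segments are resampled with replacement (keeping
    the original segment count), the coupling matrix is recomputed, and
    the relative Frobenius distance to the original matrix is averaged
    over ``n_boot`` replicates and subjects.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    errs = []
    for spectra in spectra_per_subject:
        D = coupling_matrix(spectra, measure, frequency)
        n_seg = spectra.n_segments
        for _ in range(n_boot):
            idx = rng.integers(0, n_seg, size=n_seg)
            boot = SegmentedSpectra(
                coefficients=spectra.coefficients[:, :, idx],
                frequencies=spectra.frequencies,
                segment_length=spectra.segment_length,
                overlap_fraction=spectra.overlap_fraction,
                window_name=spectra.window_name,
                channel_labels=spectra.channel_labels,
            )
            D_s = coupling_matrix(boot, measure, frequency)
            errs.append(relative_frobenius(D.values, D_s.values, include_diagonal))
    return float(np.mean(errs))


def time_resolved_model_error(
    trials_per_subject: list[np.ndarray],
    sampling_rate: float,
    measure: str = "pec_power",
    segment_length: float = 0.2,
    overlap: float = 0.18,
    frequencies: np.ndarray | None = None,
    subtract_erp: bool = True,
    include_diagonal: bool = False,
) -> ModelErrorCurve:
    """Model error E_M(f, t) for event-related trial data.

    Parameters
    ----------
    trials_per_subject
        One array per subject, shaped (n_trials, n_channels, n_samples),
        trials time-locked to the stimulus.
    segment_length, overlap
        Sliding-window duration and overlap in seconds; with 1.2 s
        trials, 0.2 s windows and 0.18 s overlap the window slides in
        20 ms steps over 51 positions.
    subtract_erp
        Remove the trial-averaged evoked response per subject before
        segmentation, so coupling reflects fluctuations around the ERP.

    At each window position the coefficients of all trials form the
    segment ensemble from which both the coupling matrix and its model
    are computed.
    """
    nper = int(round(segment_length * sampling_rate))
    step = nper - int(round(overlap * sampling_rate))
    if step < 1:
        raise ValueError("overlap leaves no positive hop")
    n_samples = trials_per_subject[0].shape[2]
    if n_samples < nper:
        raise ValueError("trials shorter than one segment")
    n_times = (n_samples - nper) // step + 1
    freq_axis = np.fft.rfftfreq(nper, d=1.0 / sampling_rate)
    if frequencies is None:
        frequencies = freq_axis[1:-1]
    frequencies = np.asarray(frequencies, dtype=float)
    times = (np.arange(n_times) * step + nper / 2.0) / sampling_rate

    E = np.zeros((frequencies.size, n_times))
    for trials in trials_per_subject:
        trials = np.asarray(trials, dtype=float)
        if subtract_erp:
            trials = trials - trials.mean(axis=0, keepdims=True)
        n_trials, n_ch, _ = trials.shape
        # windowed FFT of every trial at every window position
        starts = np.arange(n_times) * step
        idx = starts[:, None] + np.arange(nper)[None, :]
        segs = trials[:, :, idx]  # (trial, channel, time, nper)
        segs = segs - segs.mean(axis=-1, keepdims=True)
        taper = np.hanning(nper)
        coeff = np.fft.rfft(segs * taper, axis=-1)  # (trial, ch, time, freq)
        for ti in range(n_times):
            spectra = SegmentedSpectra(
                coefficients=np.transpose(coeff[:, :, ti, :], (1, 2, 0)),
                frequencies=freq_axis,
                segment_length=nper,
                overlap_fraction=0.0,
            )
            for fi, f in enumerate(frequencies):
                D, DM = _coupling_and_model(spectra, measure, f)
                E[fi, ti] += relative_frobenius(D.values, DM.values, include_diagonal)
    E /= len(trials_per_subject)
    return ModelErrorCurve(
        frequencies=frequencies,
        model_error=E,
        times=times,
        n_subjects=len(trials_per_subject),
        measure_name=measure,
    )


def paired_permutation_test(
    values: np.ndarray,
    baseline: np.ndarray | None = None,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    add_one_correction: bool = False,
) -> PermutationResult:
    """Paired permutation test of time courses against a baseline.

    Parameters
    ----------
    values
        (n_subjects, n_times, n_freqs) per-subject statistics (e.g.,
        per-subject relative model errors).
    baseline
        (n_subjects, n_freqs) baseline values.  If None, the first time
        point of ``values`` is used.
    n_perm
        Number of surrogates; for each subject, time point and
        frequency, baseline and value are randomly exchanged.
    add_one_correction
        If True, p = (1 + #{surrogate >= observed}) / (n_perm + 1)
        instead of the plain fraction of surrogates.

    The observed statistic is the absolute subject-mean difference
    between a time point and the baseline; the p-value is the fraction
    of surrogates with a larger absolute difference.  Significance uses
    a Bonferroni threshold ``alpha / (n_times * n_freqs)``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    n_sub, n_times, n_freq = values.shape
    if n_sub < 2:
        raise ValueError("paired test needs at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if baseline is None:
        baseline = values[:, 0, :]
    baseline = np.asarray(baseline, dtype=float).reshape(n_sub, n_freq)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    diff = values - baseline[:, None, :]  # (sub, time, freq)
    observed = np.abs(diff.mean(axis=0))  # (time, freq)
    # exchanging baseline and value for subject s flips the sign of diff[s];
    # surrogates are processed in blocks to bound memory
    exceed = np.zeros((n_times, n_freq), dtype=int)
    block = max(1, int(2_000_000 / max(1, n_sub * n_times * n_freq)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(b, n_sub, n_times, n_freq))
        surrogate = np.abs((signs * diff[None]).mean(axis=1))  # (b, time, freq)
        exceed += (surrogate >= observed[None]).sum(axis=0)
        done += b
    if add_one_correction:
        p = (exceed + 1.0) / (n_perm + 1.0)
    else:
        p = exceed / float(n_perm)
    alpha_bonf = alpha / (n_times * n_freq)
    return PermutationResult(
        p_values=p,
        alpha_bonferroni=alpha_bonf,
        significant_mask=p < alpha_bonf,
        n_permutations=n_perm,
    )
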