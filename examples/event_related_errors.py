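"""Time-resolved model error with a paired permutation test.

Builds synthetic event-related trials (1.2 s, several subjects) whose
middle portion switches from strongly non-Gaussian amplitude coupling to
coupled Gaussian noise, slides a 200 ms window in 20 ms steps (51 time
points), computes the power-envelope-correlation model error per window,
and tests each time point against the pre-stimulus baseline with a
paired permutation test under Bonferroni correction.
"""

import numpy as np

import gausscoup as gc

rng = np.random.default_rng(8)
fs, n_tr, n_ch = 250.0, 100, 4
n_samp = int(1.2 * fs)
t = np.arange(n_samp) / fs


def one_subject(rng):
    # non-Gaussian: one shared random amplitude per trial, independent phases
    trials = np.empty((n_tr, n_ch, n_samp))
    for k in range(n_tr):
        amp = 1.0 + 2.0 * rng.random()
        ph = rng.uniform(0, 2 * np.pi, size=n_ch)
        trials[k] = amp * np.sin(2 * np.pi * 10 * t[None, :] + ph[:, None])
    trials += 0.05 * rng.standard_normal(trials.shape)
    # "event": mid-trial Gaussianization (coupled noise), 0.4-0.8 s
    third = n_samp // 3
    shared = rng.standard_normal((n_tr, third + 1))
    for k_ch in range(n_ch):
        src = shared[:, 1:] if k_ch % 2 == 0 else 0.9 * shared[:, :-1]
        trials[:, k_ch, third : 2 * third] = src + 0.8 * rng.standard_normal(
            (n_tr, third)
        )
    return trials


# 16 subjects: enough sign-flip combinations (2^16) to resolve p-values
# below the Bonferroni threshold 0.05/51
subjects = [one_subject(rng) for _ in range(16)]
curves = [
    gc.time_resolved_model_error([s], fs, "pec_power", 0.2, 0.18,
                                 frequencies=[10.0], subtract_erp=False)
    for s in subjects
]
E = np.stack([c.model_error[0] for c in curves])  # (subject, time)
times = curves[0].times

res = gc.paired_permutation_test(E[:, :, None], n_perm=2000, seed=4)
print("time [s]   mean E_M   p-value   significant (Bonferroni)")
for i in range(0, len(times), 5):
    print(f"  {times[i]:5.2f}    {E[:, i].mean():7.3f}   {res.p_values[i, 0]:7.4f}"
          f"   {'*' if res.significant_mask[i, 0] else ''}")

n_sig = int(res.significant_mask.sum())
print(f"\n{n_sig} of {len(times)} time points differ significantly from the "
      "baseline (alpha = 0.05 Bonferroni-corrected across time points).")
print("The model error drops where the data turn Gaussian: E_M tracks the")
print("event-related change in non-Gaussian amplitude coupling.")
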