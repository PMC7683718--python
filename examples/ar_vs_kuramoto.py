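"""Linear (AR) vs nonlinear (Kuramoto) dynamics against the Gaussian model.

Simulates a stable random two-channel AR(5) process and a stochastic
delayed Kuramoto oscillator pair (both 10 minutes at 100 Hz), analyzes
coupling at 10 Hz with 1 s Hanning segments at 50% overlap, and prints
each measure next to its model prediction from coherency.
"""

import numpy as np

import gausscoup as gc


def analyze(ts, label):
    sp = gc.segment_and_transform(ts, 1.0, 0.5, "hann")
    z1, z2 = sp.at_frequency(10.0)
    C = gc.coherency(gc.cross_spectrum(sp, 10.0))
    c = C.matrix[0, 1]
    print(f"\n{label}:  c(10 Hz) = {c:.3f}")
    print(f"  {'measure':<14}{'estimated':>11}{'model':>9}")
    for name, est, model in [
        ("wPLI", gc.wpli(z1, z2), gc.model_wpli(c)),
        ("PLI", gc.pli(z1, z2), gc.model_pli(c)),
        ("|PLV|", abs(gc.plv(z1, z2)), abs(gc.model_plv(c))),
        ("PEC (power)", gc.pec(z1, z2), gc.model_pec(c)),
        ("OPEC (power)", gc.opec_global(z1, z2), gc.model_opec(c)),
    ]:
        print(f"  {name:<14}{est:>11.3f}{model:>9.3f}")


rng = np.random.default_rng(12)
ar = gc.simulate_ar(gc.random_stable_ar(rng), n_samples=60_000, sampling_rate=100.0)
analyze(ar, "AR(5), linear -> Gaussian")

ku = gc.simulate_kuramoto(gc.random_kuramoto(rng), n_samples=60_000)
analyze(ku, "Kuramoto, nonlinear")

print("""
Reading the table: for the linear system every estimate sits on its model
value (deviations are sampling noise).  For the Kuramoto pair the phase
measures deviate only mildly, but the amplitude coupling (PEC) is near
zero while the model predicts |c|^2 -- amplitude predictions from
coherency fail for nonlinear dynamics.""")
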