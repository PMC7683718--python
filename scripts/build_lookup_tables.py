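"""Regenerate the circular-Gaussian Monte-Carlo lookup table.

Amplitude and log variants of the power-envelope correlations have no
closed-form Gaussian model; their Gaussian values are unique functions
of coherence (plain PEC) or of lagged coherence (all orthogonalized
variants).  This script tabulates those functions by direct simulation:
pairs with a prescribed coherency are drawn as

    z1 = u,   z2 = c * u + sqrt(1 - |c|^2) * v

with u, v independent unit-power circular Gaussians, so the population
coherency of (z1, z2) is exactly c.  PEC variants are tabulated over
|c| (their distribution depends on |c| only); OPEC variants over the
lagged coherence, realized with purely imaginary c where Re(c) = 0 and
the lagged coherence equals Im(c).

Usage:  python scripts/build_lookup_tables.py [--seed 12345] [--n 1000000]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from gausscoup.coupling import opec_global, opec_local, pec

OUT = Path(__file__).resolve().parents[1] / "src" / "gausscoup" / "data" / "gaussian_lookup.csv"

COLUMNS = [
    "pec_amplitude",
    "pec_log",
    "opec_amplitude",
    "opec_log",
    "lopec_power",
    "lopec_amplitude",
    "lopec_log",
]


def prescribed_pair(c: complex, n: int, rng: np.random.Generator):
    u = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    v = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    z2 = np.conj(c) * u + np.sqrt(max(0.0, 1.0 - abs(c) ** 2)) * v
    return u, z2


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=12345)
    ap.add_argument("--n", type=int, default=1_000_000)
    ap.add_argument("--grid", type=int, default=100)
    args = ap.parse_args()

    grid = np.linspace(0.0, 0.99, args.grid)
    rng = np.random.default_rng(args.seed)
    rows = np.zeros((grid.size, 1 + len(COLUMNS)))
    rows[:, 0] = grid
    for gi, g in enumerate(grid):
        # PEC variants: coherence |c| = g (real c; phase is irrelevant)
        z1, z2 = prescribed_pair(g + 0j, args.n, rng)
        rows[gi, 1] = pec(z1, z2, "amplitude")
        rows[gi, 2] = pec(z1, z2, "log") if g < 1 else np.nan
        # OPEC variants: lagged coherence = g, realized with c = i*g
        z1, z2 = prescribed_pair(1j * g, args.n, rng)
        rows[gi, 3] = opec_global(z1, z2, "amplitude")
        rows[gi, 4] = opec_global(z1, z2, "log")
        rows[gi, 5] = opec_local(z1, z2, "power")
        rows[gi, 6] = opec_local(z1, z2, "amplitude")
        rows[gi, 7] = opec_local(z1, z2, "log")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as fh:
        fh.write(
            "# Monte-Carlo Gaussian values of amplitude/log envelope correlations.\n"
            f"# Generated by scripts/build_lookup_tables.py --seed {args.seed} "
            f"--n {args.n} --grid {args.grid}\n"
            "# Column 1: |c| for pec_* rows interpretation; |lagged coherence| "
            "for opec_*/lopec_* columns.\n"
        )
        fh.write("predictor," + ",".join(COLUMNS) + "\n")
        for row in rows:
            fh.write(",".join(f"{v:.6f}" for v in row) + "\n")
    print(f"wrote {OUT} ({grid.size} rows)")


if __name__ == "__main__":
    main()
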