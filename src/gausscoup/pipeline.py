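"""End-to-end workflows: model-vs-data comparison and fixture generation.

These functions orchestrate the full analysis the package exists for:
estimate a nonlinear coupling matrix, predict it from coherency under
the Gaussian assumption, and report the relative model error together
with its bootstrap noise floor, per frequency (and per measure), for an
ensemble of datasets ("subjects").
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coupling import coupling_matrix
from .devstats import bootstrap_statistical_error, model_error, relative_frobenius
from .io import write_timeseries_csv
from .model import model_matrix
from .simulate import (
    GaussianPairSpec,
    random_kuramoto,
    random_mixing_matrix,
    random_stable_ar,
    simulate_ar,
    simulate_gaussian_pairs,
    simulate_kuramoto,
)
from .spectral import (
    SegmentedSpectra,
    TimeSeriesData,
    coherency,
    cross_spectrum,
    segment_and_transform,
)

__all__ = ["compare_model", "generate_fixtures"]


def compare_model(
    datasets: list[TimeSeriesData] | list[SegmentedSpectra],
    measures: list[str],
    frequencies: list[float],
    segment_length: float = 1.0,
    overlap_fraction: float = 0.5,
    window: str = "hann",
    n_boot: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Model error E_M and bootstrap error E_S per measure and frequency.

    Each dataset is treated as one subject.  Raw recordings are
    segmented and Fourier transformed first; pre-segmented spectra are
    used as-is.  Returns a tidy frame with columns
    (measure, frequency, model_error, statistical_error, n_subjects,
    n_boot).
    """
    spectra = [
        d
        if isinstance(d, SegmentedSpectra)
        else segment_and_transform(d, segment_length, overlap_fraction, window)
        for d in datasets
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for measure in measures:
        for f in frequencies:
            D_stack, DM_stack = [], []
            for sp in spectra:
                D_stack.append(coupling_matrix(sp, measure, f))
                C = coherency(cross_spectrum(sp, f))
                DM_stack.append(model_matrix(C, measure))
            e_m = model_error(D_stack, DM_stack)
            e_s = bootstrap_statistical_error(
                spectra, measure, f, n_boot=n_boot, seed=rng
            )
            rows.append(
                {
                    "measure": measure,
                    "frequency": f,
                    "model_error": e_m,
                    "statistical_error": e_s,
                    "n_subjects": len(spectra),
                    "n_boot": n_boot,
                }
            )
    return pd.DataFrame(rows)


def write_provenance(path: str | Path, config: dict) -> None:
    """JSON sidecar with the full configuration, seeds and version."""
    payload = dict(config)
    payload["package_version"] = __version__
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


def generate_fixtures(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Deterministic small datasets exercising every generator.

    Writes four CSV files (with JSON sidecars) under ``out_dir``:

    * ``gaussian_pair.csv`` — 10^4 circular-Gaussian coefficient pairs
      (real/imag columns) from a random mixing matrix;
    * ``ar_run.csv`` — 60 s of a random stable two-channel AR(5) process
      at 100 Hz;
    * ``kuramoto_run.csv`` — 60 s of the stochastic delayed Kuramoto
      pair at 100 Hz;
    * ``multichannel.csv`` — 60 s of a 5-channel linearly mixed, lagged
      Gaussian dataset.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    A = random_mixing_matrix(rng)
    z1, z2 = simulate_gaussian_pairs(
        GaussianPairSpec(mixing_matrix=A, n_realizations=10_000,
                         seed=int(rng.integers(2**31 - 1)))
    )
    gp = out_dir / "gaussian_pair.csv"
    pd.DataFrame(
        {"z1_real": z1.real, "z1_imag": z1.imag, "z2_real": z2.real, "z2_imag": z2.imag}
    ).to_csv(gp, index=False)
    write_provenance(gp.with_suffix(".csv.json"),
                    {"generator": "gaussian_pairs", "seed": seed,
                     "mixing_matrix_real": A.real.tolist(),
                     "mixing_matrix_imag": A.imag.tolist()})
    paths["gaussian_pair"] = gp

    ar_spec = random_stable_ar(rng)
    ar = simulate_ar(ar_spec, n_samples=6000, sampling_rate=100.0)
    arp = out_dir / "ar_run.csv"
    write_timeseries_csv(ar, arp)
    paths["ar_run"] = arp

    ku_spec = random_kuramoto(rng)
    ku = simulate_kuramoto(ku_spec, n_samples=6000)
    kup = out_dir / "kuramoto_run.csv"
    write_timeseries_csv(ku, kup)
    paths["kuramoto_run"] = kup

    # 5-channel dataset: instantaneous mixing plus one-sample lags of
    # shared noise, giving nonzero imaginary coherency between channels
    n = 6000
    src = rng.standard_normal((5, n + 1))
    M = rng.standard_normal((5, 5))
    x = M @ src[:, 1:] + 0.5 * rng.standard_normal((5, 5)) @ src[:, :-1]
    mc = out_dir / "multichannel.csv"
    write_timeseries_csv(TimeSeriesData(values=x, sampling_rate=100.0), mc)
    paths["multichannel"] = mc
    return paths
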