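"""Synthetic systems for validating the Gaussian-model relations.

Three generators:

* **Circular-Gaussian pairs** — pairs of complex coefficients
  ``z = A x`` with ``x`` a vector of two unit-variance complex Gaussians
  and ``A`` a random complex 2x2 mixing matrix.  The population
  cross-spectrum is ``S = <z z^+> = 2 A A^+`` (the factor 2 because the
  unit variances of real and imaginary parts add), so the coherency is
  known exactly and every estimator can be checked against its model.
  These are segment coefficients directly; no time series is involved.

* **Stable AR(5) processes** — two-channel autoregressive models
  ``x(t) = sum_tau A(tau) x(t-tau) + eta(t)`` with Gaussian-random
  coefficients (sd 0.25), rejection-sampled for stability via the
  companion-matrix criterion, driven by unit white Gaussian noise.
  These are linear, hence Gaussian: every coupling measure should match
  its model prediction.

* **Stochastic delayed Kuramoto oscillators** — two phase oscillators
  with noisy Euler updates, pairwise delayed sine coupling and output
  ``x = sin(theta)``.  A genuinely nonlinear system: phase measures
  deviate mildly from the Gaussian model while amplitude coupling is
  nearly absent and the model prediction for it fails.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import TimeSeriesData

__all__ = [
    "GaussianPairSpec",
    "ARModelSpec",
    "KuramotoSpec",
    "random_mixing_matrix",
    "simulate_gaussian_pairs",
    "population_cross_spectrum",
    "ar_is_stable",
    "random_stable_ar",
    "simulate_ar",
    "simulate_kuramoto",
]


# ---------------------------------------------------------------------------
# circular-Gaussian pairs

@dataclass
class GaussianPairSpec:
    mixing_matrix: np.ndarray
    n_realizations: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=complex)
        if self.mixing_matrix.shape != (2, 2):
            raise ValueError("mixing_matrix must be 2x2")
        if not np.all(np.isfinite(self.mixing_matrix)):
            raise ValueError("mixing_matrix must be finite")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


def random_mixing_matrix(seed: int | np.random.Generator = 0) -> np.ndarray:
    """Random complex 2x2 mixing matrix A = A_R + i*A_I.

    All elements of A_R and A_I are independent standard normal.  An
    ensemble of such matrices sweeps coherency roughly uniformly over
    the complex unit disk.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))


def simulate_gaussian_pairs(spec: GaussianPairSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_realizations`` circular-Gaussian coefficient pairs.

    Returns ``(z1, z2)``, each of length ``n_realizations``, with
    population cross-spectrum ``2 A A^+`` and vanishing pseudo-covariance
    ``<z z^T> = 0`` (circularity).
    """
    rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal((2, spec.n_realizations)) + 1j * rng.standard_normal(
        (2, spec.n_realizations)
    )
    z = spec.mixing_matrix @ x
    return z[0], z[1]


def population_cross_spectrum(A: np.ndarray) -> np.ndarray:
    """Exact cross-spectrum ``S = 2 A A^+`` of the mixed pair."""
    A = np.asarray(A, dtype=complex)
    return 2.0 * A @ A.conj().T


def population_coherency(A: np.ndarray) -> complex:
    """Exact coherency of the pair generated by mixing matrix ``A``."""
    S = population_cross_spectrum(A)
    return complex(S[0, 1] / np.sqrt(S[0, 0].real * S[1, 1].real))


# ---------------------------------------------------------------------------
# autoregressive model

@dataclass
class ARModelSpec:
    coefficients: np.ndarray  # (P, n_channels, n_channels)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 3 or (
            self.coefficients.shape[1] != self.coefficients.shape[2]
        ):
            raise ValueError("coefficients must be (order, n_channels, n_channels)")

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]


def ar_is_stable(coefficients: np.ndarray) -> bool:
    """Stability of a vector AR model via its companion matrix.

    True iff every eigenvalue of the ``(n*P) x (n*P)`` companion matrix
    has magnitude < 1.
    """
    A = np.asarray(coefficients, dtype=float)
    if A.ndim != 3 or A.shape[1] != A.shape[2]:
        raise ValueError("coefficients must be (order, n, n)")
    P, n, _ = A.shape
    companion = np.zeros((n * P, n * P))
    companion[:n, :] = A.transpose(1, 0, 2).reshape(n, n * P)
    if P > 1:
        companion[n:, :-n] = np.eye(n * (P - 1))
    return bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1.0)


def random_stable_ar(
    seed: int | np.random.Generator = 0,
    order: int = 5,
    n_channels: int = 2,
    coeff_sd: float = 0.25,
    noise_sd: float = 1.0,
    max_tries: int = 1000,
) -> ARModelSpec:
    """Draw AR coefficients from N(0, coeff_sd^2), rejecting unstable sets.

    Rejection sampling reuses the same random stream; the accepted draw
    is recorded in the returned spec together with a child seed for the
    innovation noise.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(max_tries):
        coeffs = rng.standard_normal((order, n_channels, n_channels)) * coeff_sd
        if ar_is_stable(coeffs):
            return ARModelSpec(
                coefficients=coeffs,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
    raise RuntimeError("could not draw a stable AR model")  # pragma: no cover


def simulate_ar(
    spec: ARModelSpec,
    n_samples: int,
    sampling_rate: float = 100.0,
    burn_in: int | None = None,
) -> TimeSeriesData:
    """Simulate a stable vector AR process driven by white Gaussian noise.

    A burn-in of ``10 * order * sampling_rate`` samples (by default) is
    simulated and discarded so the returned stretch is stationary.
    """
    if not ar_is_stable(spec.coefficients):
        raise ValueError("AR model is unstable; refusing to simulate")
    P, n = spec.order, spec.n_channels
    if burn_in is None:
        burn_in = int(10 * P * sampling_rate)
    total = n_samples + burn_in + P
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((total, n)) * spec.noise_sd
    x = np.zeros((total, n))
    # stack lags into one (n, n*P) matrix: one matvec per time step
    A_flat = np.concatenate([spec.coefficients[p] for p in range(P)], axis=1)
    for t in range(P, total):
        window = x[t - P : t][::-1].reshape(-1)  # [x(t-1), ..., x(t-P)]
        x[t] = A_flat @ window + noise[t]
    out = x[P + burn_in :].T
    return TimeSeriesData(values=out, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# stochastic delayed Kuramoto oscillators

@dataclass
class KuramotoSpec:
    dt: float = 1.0 / 100.0
    omega: float = 20.0 * np.pi
    sigma: float = 5.0
    coupling: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2))
    )  # a(i, j), zero diagonal
    delays: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2), dtype=int)
    )  # integer steps
    seed: int = 0
    noise_scaling: str = "dt"  # 'dt' (literal Euler) or 'sqrt_dt' (Euler-Maruyama)

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.delays = np.asarray(self.delays, dtype=int)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if self.noise_scaling not in ("dt", "sqrt_dt"):
            raise ValueError("noise_scaling must be 'dt' or 'sqrt_dt'")


def random_kuramoto(
    seed: int | np.random.Generator = 0,
    coupling_sd: float = 0.5,
    max_delay_steps: int = 10,
) -> KuramotoSpec:
    """Random coupling (off-diagonal N(0, coupling_sd^2)) and integer delays.

    Delays are uniform on ``0..max_delay_steps`` steps; with the default
    ``dt = 1/100`` that spans lags up to 100 ms.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = rng.standard_normal((2, 2)) * coupling_sd
    np.fill_diagonal(a, 0.0)
    delays = rng.integers(0, max_delay_steps + 1, size=(2, 2))
    np.fill_diagonal(delays, 0)
    return KuramotoSpec(
        coupling=a, delays=delays, seed=int(rng.integers(2**31 - 1))
    )


def simulate_kuramoto(spec: KuramotoSpec, n_samples: int) -> TimeSeriesData:
    """Simulate two noisy delayed-coupled phase oscillators.

    Euler update (as written, the noise enters multiplied by ``dt``; set
    ``noise_scaling='sqrt_dt'`` for the diffusion-consistent alternative):

        theta(t+1, i) = theta(t, i) + dt * (omega + sigma*eta(t, i)
                        + sum_j a(i, j) sin(theta(t, i) - theta(t - tau(i,j), j)))

    Output is ``x(t, i) = sin(theta(t, i))``, bounded in [-1, 1]; with
    ``omega = 20*pi`` the spectrum peaks at 10 Hz.  Initial phases are
    uniform on [0, 2*pi) and the delay buffer is pre-filled with them.
    """
    rng = np.random.default_rng(spec.seed)
    n_ch = spec.coupling.shape[0]
    max_delay = int(spec.delays.max())
    theta = np.empty((n_samples + max_delay, n_ch))
    theta[: max_delay + 1] = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)[None, :]
    eta = rng.standard_normal((n_samples + max_delay, n_ch))
    noise_fac = spec.dt if spec.noise_scaling == "dt" else np.sqrt(spec.dt)
    dt, omega, sigma = spec.dt, spec.omega, spec.sigma
    a, tau = spec.coupling, spec.delays

    if n_ch == 2 and spec.noise_scaling == "dt":
        # scalar fast path for the canonical two-oscillator setup
        a01, a10 = a[0, 1], a[1, 0]
        t01, t10 = int(tau[0, 1]), int(tau[1, 0])
        th = theta  # local alias
        from math import sin

        for t in range(max_delay, n_samples + max_delay - 1):
            th0, th1 = th[t, 0], th[t, 1]
            th[t + 1, 0] = th0 + dt * (
                omega + sigma * eta[t, 0] + a01 * sin(th0 - th[t - t01, 1])
            )
            th[t + 1, 1] = th1 + dt * (
                omega + sigma * eta[t, 1] + a10 * sin(th1 - th[t - t10, 0])
            )
    else:
        for t in range(max_delay, n_samples + max_delay - 1):
            delayed = theta[t - tau, np.arange(n_ch)[None, :]]  # (i, j) -> theta(t - tau_ij, j)
            drive = (a * np.sin(theta[t][:, None] - delayed)).sum(axis=1)
            theta[t + 1] = theta[t] + dt * (omega + drive) + noise_fac * sigma * eta[t]
    x = np.sin(theta[max_delay:])
    return TimeSeriesData(values=x.T, sampling_rate=1.0 / spec.dt)
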