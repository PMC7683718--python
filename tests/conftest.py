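"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite",
        derandomize=True,
        max_examples=25,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


def circular_gaussian_pair(c: complex, n: int, rng: np.random.Generator):
    """Pair of unit-power circular Gaussians with prescribed coherency c.

    Independent oracle construction (z1 = u, z2 = c*.u + sqrt(1-|c|^2) v)
    used to probe estimators without going through the package's own
    mixing-matrix generator.
    """
    u = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    v = (rng.standard_normal(n) + 1j * rng.standard_normal(n)) / np.sqrt(2)
    z2 = np.conj(c) * u + np.sqrt(max(0.0, 1.0 - abs(c) ** 2)) * v
    return u, z2


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
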