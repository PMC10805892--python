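import numpy as np
import pytest

import allokaryo as ak


@pytest.fixture(scope="session")
def small_params() -> ak.SimulationParams:
    """Desk-scale genome shared by read-only tests: 4 pairs x 1.5 Mb."""
    return ak.SimulationParams(
        n_chromosome_pairs=4,
        chromosome_length=1_500_000,
        homoeologous_site_density=0.02,
        coverage_per_copy=5.0,
        seed=20_240_101,
    )


@pytest.fixture(scope="session")
def small_ref(small_params) -> ak.ReferenceModel:
    return ak.simulate_reference(small_params)


def brute_force_window_boundaries(is_masked: np.ndarray, content: int) -> list[int]:
    """Base-by-base prefix-sum oracle for the fixed-content segmentation."""
    bounds = []
    count = 0
    for i, masked in enumerate(is_masked):
        if not masked:
            count += 1
            if count == content:
                bounds.append(i + 1)
                count = 0
    return bounds


def brute_force_roh(a, b) -> tuple[float, int]:
    """Per-site chi-square oracle computed with explicit loops."""
    chi2 = 0.0
    df = 0
    for ai, bi in zip(a, b):
        tot = ai + bi
        if tot > 0:
            exp = tot / 2.0
            chi2 += (ai - exp) ** 2 / exp + (bi - exp) ** 2 / exp
            df += 1
    return chi2, df
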