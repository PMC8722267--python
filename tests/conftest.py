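import numpy as np
import pandas as pd
import pytest

from littervar.animal_model import ModelSpec, Pedigree, fit_mixed_model
from littervar.phenoprep import apply_edit_rules
from littervar.simdata import SimConfig, simulate_dataset


def tabular_a(sire, dam):
    """Dense numerator relationship matrix by the tabular method (oracle)."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


def random_pedigree(rng, n_min=4, n_max=12):
    """Random valid pedigree (parents precede offspring)."""
    n = int(rng.integers(n_min, n_max))
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(2, n):
        if rng.random() < 0.7:
            sire[i] = int(rng.integers(0, i))
            dam[i] = int(rng.integers(0, i))
            if sire[i] == dam[i]:
                dam[i] = -1
    return Pedigree(np.arange(1, n + 1), sire, dam)


@pytest.fixture(scope="session")
def trio_pedigree():
    """Unrelated sire and dam plus one offspring."""
    return Pedigree(np.array([1, 2, 3]), np.array([-1, -1, 0]), np.array([-1, -1, 1]))


@pytest.fixture(scope="session")
def small_dataset():
    """80-sow simulated dataset at the study's variance-component values."""
    cfg = SimConfig(
        n_sires=8,
        n_dams_per_sire=10,
        n_generations=1,
        litters_per_sow_range=(3, 6),
        n_snps=60,
        n_chromosomes=2,
        n_hys=6,
        seed=31,
    )
    ped, geno, records, truth = simulate_dataset(cfg)
    return cfg, ped, geno, apply_edit_rules(records), truth


@pytest.fixture(scope="session")
def small_mean_fit(small_dataset):
    """Homoscedastic TNB repeatability fit on the 80-sow dataset."""
    _, ped, _, records, _ = small_dataset
    spec = ModelSpec(
        response="tnb",
        fixed=["hys", "parity"],
        random=["additive", "permanent_env"],
        animal="sow",
    )
    return fit_mixed_model(spec, records, ped)


@pytest.fixture()
def toy_records():
    """Hand-sized record table exercising every edit rule."""
    return pd.DataFrame(
        {
            "sow": [1, 1, 2, 2, 2, 3, 3, 4, 4, 5],
            "parity": [1, 2, 1, 2, 12, 1, 2, 1, 2, 1],
            "hys": [1, 1, 2, 2, 2, 1, 2, 1, 1, 2],
            "tnb": [12, 14, 3, 15, 27, 2, 13, 11, 16, 13],
        }
    )
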