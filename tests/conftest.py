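import numpy as np
import pytest

from cpca import BiomarkerPanel, CohortConfig, simulate_cohort


def make_panel(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"T{j}" for j in range(values.shape[1])]
    mask = np.isnan(values)
    ids = np.array([f"S{i}" for i in range(values.shape[0])])
    return BiomarkerPanel(ids, names, values, mask)


@pytest.fixture(scope="session")
def small_cohort():
    """5-trait cohort with two disease-driving traits and two variants:
    one pleiotropic (A, B, C) and one single-trait (E)."""
    k = 5
    R = np.full((k, k), 0.2)
    np.fill_diagonal(R, 1.0)
    cfg = CohortConfig(
        n_samples=4000,
        trait_names=list("ABCDE"),
        trait_correlation=R,
        disease_weights={"A": -1.0, "B": -0.8},
        target_prevalence=0.1,
        n_variants=2,
        variant_mafs=[0.3, 0.25],
        genetic_effects={"rs00001": [("A", 0.2), ("B", 0.2), ("C", 0.15)],
                         "rs00002": [("E", 0.35)]},
        rng_seed=20240917,
    )
    return simulate_cohort(cfg)
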