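import numpy as np
import pytest

from twinace import (
    SimulationConfig,
    TraitSpec,
    TwinPairRecord,
    pairs_for_trait,
    simulate_cohort,
    split_by_zygosity,
)


def make_pairs(values, zygosity="MZ", ages=None, sexes=None):
    """Hand-build TwinPairRecords from a list of (v1, v2) tuples."""
    out = []
    for i, (v1, v2) in enumerate(values):
        out.append(
            TwinPairRecord(
                pair_id=f"p{i}",
                zygosity=zygosity,
                values=(float(v1), float(v2)),
                ages=ages[i] if ages else (50.0, 50.0),
                sexes=sexes[i] if sexes else ("F", "F"),
            )
        )
    return out


def simulated_pairs(a2, c2, n_pairs, seed, *, trait_kwargs=None):
    """Simulate one trait and return (mz_records, dz_records)."""
    kwargs = dict(total_sd=10.0, mean_intercept=100.0, beta_age=-0.3, beta_sex=5.0)
    if trait_kwargs:
        kwargs.update(trait_kwargs)
    spec = TraitSpec("y", a2=a2, c2=c2, **kwargs)
    cfg = SimulationConfig(
        traits=(spec,), n_mz_pairs=n_pairs, n_dz_pairs=n_pairs, n_triplet_sets=0, seed=seed
    )
    cohort = simulate_cohort(cfg)
    return split_by_zygosity(pairs_for_trait(cohort, "y"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A small mixed cohort with two triplet sets, usable across io tests."""
    spec = TraitSpec("vol", a2=0.8, total_sd=5.0, mean_intercept=50.0)
    cfg = SimulationConfig(traits=(spec,), n_mz_pairs=6, n_dz_pairs=4, n_triplet_sets=2, seed=7)
    return simulate_cohort(cfg)
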