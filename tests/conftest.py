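import numpy as np
import pandas as pd
import pytest

from invpopkit.core_io import GenotypeTable, PopulationPanel
from invpopkit.synthdata import SimConfig, simulate_haplotypes


@pytest.fixture(scope="session")
def trio_panel():
    """Panel with two complete trios (one CEU-like, one YRI-like) plus
    unrelated samples of both sexes."""
    rows = []
    for fam, pop, grp in (("fam1", "CEU", "EUR"), ("fam2", "YRI", "AFR")):
        rows += [
            {"sample_id": f"{fam}_f", "sex": "male", "population": pop,
             "group": grp, "family_role": "father", "family_id": fam},
            {"sample_id": f"{fam}_m", "sex": "female", "population": pop,
             "group": grp, "family_role": "mother", "family_id": fam},
            {"sample_id": f"{fam}_c", "sex": "female", "population": pop,
             "group": grp, "family_role": "child", "family_id": fam},
        ]
    for i in range(4):
        rows.append({"sample_id": f"u{i}", "sex": "male" if i % 2 else "female",
                     "population": "CHB", "group": "EAS",
                     "family_role": "unrelated", "family_id": None})
    return PopulationPanel(pd.DataFrame(rows))


def make_gt(panel, calls, chromosomes=None):
    df = pd.DataFrame(calls, index=pd.Index(panel.sample_ids, name="sample_id"))
    return GenotypeTable(df, panel, chromosomes or {})


@pytest.fixture(scope="session")
def unique_sim():
    """Well-separated unique-origin cohort (crossover suppression, no gene
    conversion): the canonical single-clade inversion."""
    cfg = SimConfig(n_samples=30, sequence_length=60_000, span=(20_000, 40_000),
                    target_frequency=0.3, origin="unique", age_generations=5_000,
                    mutation_rate=5e-7, derived_deme_size=300, seed=11)
    haps, vp, gt, truth = simulate_haplotypes(cfg)
    return cfg, haps, vp, gt, truth


@pytest.fixture(scope="session")
def recurrent_sim():
    """Three independent origins on distinct backgrounds."""
    cfg = SimConfig(n_samples=30, sequence_length=60_000, span=(20_000, 40_000),
                    target_frequency=0.4, origin="recurrent", k_events=3,
                    age_generations=5_000, mutation_rate=5e-7,
                    derived_deme_size=300, seed=13)
    haps, vp, gt, truth = simulate_haplotypes(cfg)
    return cfg, haps, vp, gt, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_926)
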