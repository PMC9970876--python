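import numpy as np
import pandas as pd
import pytest

from discoprofile import instrument_selection, synthetic_data
from discoprofile.synthetic_data import TraitSpec, TruthConfig


@pytest.fixture(scope="session")
def world_cfg() -> TruthConfig:
    return TruthConfig(seed=11, trait_panel=synthetic_data.default_trait_panel())


@pytest.fixture(scope="session")
def panel(world_cfg):
    return synthetic_data.simulate_reference_panel(world_cfg, n_individuals=2_000)


@pytest.fixture(scope="session")
def gwas_pair(world_cfg, panel):
    return synthetic_data.simulate_gwas_pair(world_cfg, panel)


@pytest.fixture(scope="session")
def profile(world_cfg, panel, gwas_pair):
    bmi, t2d, _ = gwas_pair
    return instrument_selection.select_instruments(bmi, t2d, panel)


@pytest.fixture(scope="session")
def scan(world_cfg, panel, profile):
    from discoprofile import phenome_scan

    tables, _ = synthetic_data.simulate_trait_panel(world_cfg, profile)
    return phenome_scan.harvest(profile, tables, panel=panel)


def make_sumstats(rows) -> pd.DataFrame:
    """Small canonical summary-statistics frame from dict rows."""
    defaults = dict(chrom="1", eaf=0.3, n=100_000.0)
    recs = []
    for r in rows:
        rec = {**defaults, **r}
        recs.append(rec)
    return pd.DataFrame(
        recs,
        columns=["snp_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"],
    )
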