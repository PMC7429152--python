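import numpy as np
import pandas as pd
import pytest

from copdprs import SimConfig, simulate_cohort
from copdprs.pipeline import run_pipeline, validate_config


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort with all downstream phenotypes."""
    cfg = SimConfig(n_individuals=3000, n_variants=200, seed=7)
    G, ph = simulate_cohort(cfg, prs_link=0.3)
    return G, ph


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """Full pipeline at the default study scale: training GWAS n=5000 with
    1000 variants in 10-variant blocks (rho=0.5, h2=0.4), 500-sample LD
    panel, 2000-sample tuning cohort, two 4000-sample test cohorts."""
    out = tmp_path_factory.mktemp("e2e")
    cfg = validate_config({"seed": 20, "out_dir": str(out)})
    return run_pipeline(cfg)
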