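import numpy as np
import pandas as pd
import pytest

from repqtl.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully featured cohort (all timepoints, cells, survival),
    with one planted cis, trans and k-mer effect."""
    cfg = SimConfig(
        n_individuals=40,
        n_variants=60,
        n_vgenes_alpha=8,
        n_vgenes_beta=10,
        clones_per_sample=150,
        cis_effects=[("var00000", "TRBV3", 0.8)],
        trans_effects=[("B*44", "TRBV7", 0.8)],
        kmer_effects=[("B*35:01", "TGDSNQP", 0.8)],
        maf_overrides={"var00000": 0.3},
        n_cells=600,
        n_sc_individuals=20,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def clone_frame():
    """Tiny hand-written clone table."""
    return pd.DataFrame(
        {
            "individual_id": ["I1", "I1", "I1", "I2", "I2", "I2"],
            "timepoint": ["C1"] * 6,
            "chain": ["beta"] * 6,
            "v_gene": ["TRBV28", "TRBV28", "TRBV19", "TRBV28", "TRBV19", "TRBV19"],
            "cdr3_aa": ["CASSA", "CASSB", "CASSC", "CASSA", "CASSC", "CASSC"],
            "count": [5, 3, 1, 2, 4, 6],
            "productive": [True] * 6,
        }
    )
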