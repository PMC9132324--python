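import numpy as np
import pandas as pd
import pytest

from isoratio import CohortConfig, IsoformCountMatrix, generate_cohort


def null_config(**overrides) -> CohortConfig:
    """A cohort with no planted effects and no technical distortions:
    perfectly pure samples, no 3' bias, no batch effects."""
    base = dict(
        frac_dir_genes=0.0,
        frac_de_genes=0.0,
        frac_infiltrate_samples=0.0,
        purity_beta_params=((1.0, 0.0), (1.0, 0.0)),
        bias_beta_params=((1.0, 0.0), (1.0, 0.0)),
        bias_strength=0.0,
        batch_sd=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_primary=12, n_metastatic=24, n_genes=40,
                       isoforms_per_gene_range=(1, 4), seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def toy_counts():
    """3 genes (2/2/1 isoforms), 6 samples, hand-set values."""
    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(1, 7)]
    iso = ["gA.i1", "gA.i2", "gB.i1", "gB.i2", "gC.i1"]
    genes = ["gA", "gA", "gB", "gB", "gC"]
    values = pd.DataFrame(rng.uniform(1, 50, (5, 6)), index=iso,
                          columns=samples)
    return IsoformCountMatrix(values, pd.Series(genes, index=iso))


@pytest.fixture
def toy_meta():
    samples = [f"s{i}" for i in range(1, 7)]
    return pd.DataFrame({
        "sample_type": ["primary"] * 3 + ["metastatic"] * 3,
        "batch": "b1",
        "purity": [0.9, 0.8, 0.95, 0.85, 0.75, 0.9],
        "bias_score": [0.1, 0.2, 0.3, 0.2, 0.4, 0.1],
        "subtype": "BRAF",
        "region": "x",
    }, index=pd.Index(samples, name="sample_id"))
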