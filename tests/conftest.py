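import pytest

from lupus_stratify.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study design: full cohort structure, fewer genes/controls."""
    return SimulationConfig(n_genes=800, module_size=25, n_hc=200, seed=11)


@pytest.fixture(scope="session")
def cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def matched(cohort):
    """Matched controls and per-gene z for the CNS patients of `cohort`."""
    from lupus_stratify import dysreg

    meta = cohort.meta
    patients = meta[meta["cohort"] == "CNS_LUPUS"]
    hc = meta[meta["cohort"] == "HC"]
    match = dysreg.match_controls(patients, hc, ratio=5)
    gz = dysreg.gene_z(cohort.expr, match.pooled, list(patients.index))
    return match, gz
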