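import pytest

import circprof as cp


@pytest.fixture(scope="session")
def small_design():
    """A scaled-down cohort (78 samples, ~66 circles) for fast tests."""
    return cp.SimulationDesign(
        n_class1=24, n_class2=36, n_class3=18,
        n_genes=40, n_circ_target=60, n_abundant_target=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    config, truth = cp.simulate_cohort(small_design, outdir)
    return config, truth, outdir


@pytest.fixture(scope="session")
def small_pipeline(small_cohort, tmp_path_factory):
    config, truth, _ = small_cohort
    outdir = tmp_path_factory.mktemp("pipeline_out")
    result = cp.run_pipeline(config, outdir)
    return result, truth, outdir
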