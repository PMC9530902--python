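import numpy as np
import pytest

from mutgrowth import RunConfig, default_media, run_pipeline, synthetic

#: Fixed seed for every deterministic fixture in the suite.
SEED = 12345


@pytest.fixture(scope="session")
def media():
    return {m.name: m for m in default_media()}


@pytest.fixture(scope="session")
def panel():
    """Default-size panel: 14 MDS + 10 KHK + 10 MG strains."""
    return synthetic.make_strain_panel({"MDS": 14, "KHK": 10, "MG": 10}, seed=SEED)


@pytest.fixture(scope="session")
def true_table(panel):
    """Noisy ground-truth rate table for the full panel in all media."""
    rates = synthetic.sample_true_rates(
        panel, default_media(), sigma_log10=0.2, seed=SEED
    )
    return synthetic.true_rate_table(panel, rates)


@pytest.fixture(scope="session")
def noiseless_table(panel):
    """Rates lying exactly on each medium's trade-off line."""
    rates = synthetic.sample_true_rates(
        panel, default_media(), sigma_log10=0.0, seed=SEED
    )
    return synthetic.true_rate_table(panel, rates)


@pytest.fixture(scope="session")
def small_run_config(tmp_path_factory):
    return RunConfig(
        n_mds=4,
        n_khk=3,
        n_mg=3,
        n_cultures=15,
        n_assay_replicates=2,
        n_wells=3,
        n_classifier_repeats=2,
        outdir=str(tmp_path_factory.mktemp("run")),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def small_report(small_run_config):
    return run_pipeline(small_run_config)
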