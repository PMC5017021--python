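import pytest

from metabotox import CellCountModel, EffectSpec, StudyDesign, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Two-dataset simulated study with default effects, reused read-only."""
    return simulate_study(
        StudyDesign(modes=("RP_pos", "RP_neg")),
        EffectSpec(),
        CellCountModel(),
        noise_cv=0.10,
        seed=42,
        n_features=300,
    )


@pytest.fixture()
def rp_pos(small_study):
    tables, meta, counts, truth = small_study
    return tables["RP_pos"], meta, counts, truth
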