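import pytest
from hypothesis import HealthCheck, settings

import linkagekit as lk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> lk.StudyConfig:
    return lk.load_caladium_config()


@pytest.fixture(scope="session")
def counts(config):
    """All bundled count tables, keyed by cross_id."""
    out = {}
    for name in (
        "background",
        "shape_background",
        "spotting_background",
        "vein_background",
        "rugosity_background",
        "four_locus",
    ):
        for table in lk.load_caladium_counts(name):
            out[table.cross_id] = table
    return out


@pytest.fixture(scope="session")
def lem_model(config) -> lk.TraitModel:
    return config.trait_models["LEM"]


@pytest.fixture(scope="session")
def four_locus_cross(config) -> lk.CrossSpec:
    """The pooled pseudo-testcross restricted to the four linked loci."""
    return config.cross("t7-01").restrict(("LEM", "V", "S", "RLF"))


def pairwise_analysis(config, table):
    """Independence test, phase and RF estimate for one two-locus table."""
    cross = config.cross(table.cross_id).restrict(table.loci)
    phase = lk.infer_phase(table, cross)
    est = lk.estimate_rf(table, cross, phase)
    return cross, phase, est
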