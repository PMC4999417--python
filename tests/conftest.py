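import pytest
from hypothesis import HealthCheck, settings

from finemapkit.pipeline import load_config
from finemapkit.synthetic_data import LocusDesign, write_fixture_locus

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic locus (seed 42, full sample sizes), built once."""
    out = tmp_path_factory.mktemp("locus") / "fixture42"
    write_fixture_locus(LocusDesign(), out)
    return out


@pytest.fixture(scope="session")
def fixture_config(fixture_dir):
    return load_config(fixture_dir / "config.json")


@pytest.fixture(scope="session")
def small_design():
    """Down-scaled locus design for fast structural tests."""
    return LocusDesign(
        n_cases=250,
        n_controls=500,
        n_background=10,
        n_haplotype_pool=4_000,
        n_expression_samples=120,
        fourc_n_reads=5_000,
        seed=7,
    )
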