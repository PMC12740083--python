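import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

import stratashift as ss


@pytest.fixture(scope="session")
def scale():
    return ss.StrataScale.default()


@pytest.fixture(scope="session")
def small_bundle():
    """A small seeded universe + biased DEG set exercising every stage."""
    cfg = ss.SyntheticConfig(universe_size=2000, n_deg=200, beta=0.5, seed=7)
    return ss.make_bundle(cfg)


@pytest.fixture(scope="session")
def small_universe(small_bundle):
    return small_bundle.gene_ages.universe()


@pytest.fixture()
def age_table(tmp_path, scale):
    """A 5-gene gene-age TSV on disk."""
    path = tmp_path / "ages.tsv"
    path.write_text(
        "gene\tstratum\n"
        "A\tPrimates\n"
        "B\tEukaryota\n"
        "C\tMetazoa\n"
        "d \tall living organisms\n"
        "E\t12\n"
    )
    return path
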