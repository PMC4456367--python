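import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome genome (1 with p+q, 13 q-only), 50 probes/arm."""
    from armcna.genome import default_genome
    return default_genome(probes_per_arm=50, chromosomes=["1", "13"])


@pytest.fixture(scope="session")
def full_genome():
    from armcna.genome import default_genome
    return default_genome(probes_per_arm=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_track(genome, ratio_a=1.0, ratio_b=1.0):
    """A ratio track at fixed levels over a genome's probe map."""
    probes = genome.probes
    return pd.DataFrame({
        "snp_id": probes["snp_id"].to_numpy(),
        "chrom": probes["chrom"].to_numpy(),
        "pos": probes["pos"].to_numpy(),
        "ratio_a": ratio_a,
        "ratio_b": ratio_b,
    })


@pytest.fixture()
def make_track(small_genome):
    def _make(ratio_a=1.0, ratio_b=1.0):
        return constant_track(small_genome, ratio_a, ratio_b)
    return _make
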