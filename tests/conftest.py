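import numpy as np
import pandas as pd
import pytest

from dnmlineage import SimConfig, simulate_study
from dnmlineage.genome import GenomeModel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_genome():
    """Two autosomes plus sex chromosomes, small enough to enumerate."""
    return GenomeModel(
        chromosomes=[("chr1", 100_000), ("chr2", 80_000),
                     ("chrX", 60_000), ("chrY", 30_000)],
        repeat_mask={"chr1": [(10_000, 12_000)]},
        excluded_ends={"chr1": [(0, 500), (99_500, 100_000)]},
    )


@pytest.fixture(scope="session")
def desk_genome():
    return GenomeModel.mouse_desk_scale()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_sibships=2, n_f2_per_sibship=4, n_founder_het=30,
                     n_shared_ancestral_snvs=5, n_controls=2, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One small simulated study shared by read-only tests."""
    return simulate_study(small_config)


def make_calls(rows):
    """Build a long-format call table from dict rows with defaults that
    pass every filter."""
    defaults = dict(sample_id="s1", chrom="chr1", pos=1000, ref="C",
                    alt="T", qual=50.0, total_depth=30, ref_depth=15,
                    alt_depth=15, mq_ref=55.0, mq_alt=55.0)
    full = []
    for row in rows:
        d = dict(defaults)
        d.update(row)
        d["ref_depth"] = d["total_depth"] - d["alt_depth"]
        full.append(d)
    return pd.DataFrame(full)
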