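import numpy as np
import pandas as pd
import pytest

from ndrquant.coverage import FragmentSet
from ndrquant.regions import TranscriptModel, WindowSpec
from ndrquant.simdata import SimConfig, simulate_reference, simulate_sample


@pytest.fixture
def plus_tx() -> TranscriptModel:
    # TSS 10000, exon1 ends 12000, three exons
    return TranscriptModel(
        "txp", "gp", "chr1", "+",
        exons=((10_000, 12_000), (12_700, 13_100), (13_800, 14_200)),
    )


@pytest.fixture
def minus_tx() -> TranscriptModel:
    # TSS 10000 (right end of exon 1), transcription right-to-left
    return TranscriptModel(
        "txm", "gm", "chr1", "-",
        exons=((8_500, 10_000), (7_200, 7_800), (6_000, 6_500)),
    )


@pytest.fixture
def window_spec() -> WindowSpec:
    return WindowSpec()


def make_fragments(records, sample_id="s"):
    return FragmentSet.from_records(sample_id, records)


@pytest.fixture
def random_fragments():
    """200 fragments scattered over a 10 kb locus around position 20000."""
    rng = np.random.default_rng(42)
    starts = rng.integers(15_000, 25_000, size=200)
    lengths = rng.integers(80, 250, size=200)
    return FragmentSet(
        "rand",
        np.full(200, "chr1", dtype=object),
        starts.astype(np.int64),
        (starts + lengths).astype(np.int64),
        np.full(200, 2, dtype=np.uint8),
    )


SMALL_SIM = SimConfig(
    n_tumor_genes=8,
    n_blood_genes=8,
    n_shared_genes=4,
    n_unexpressed_genes=4,
)


@pytest.fixture(scope="session")
def small_reference():
    return simulate_reference(SMALL_SIM, seed=11)


@pytest.fixture(scope="session")
def small_healthy_sample(small_reference):
    fr, _ = simulate_sample(small_reference, {"blood": 1.0}, depth=40.0, seed=12,
                            sample_id="H_small")
    return fr
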