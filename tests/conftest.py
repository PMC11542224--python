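import numpy as np
import pytest

from erosym.io_model import GeneRecord, Genome, Replicon


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_replicon_genome(rng):
    """A small hand-checkable genome: two replicons, three genes."""
    r1 = Replicon("chr1", random_dna(rng, 1000), topology="circular")
    r2 = Replicon("chr2", random_dna(rng, 400), topology="circular")
    genes = [
        GeneRecord("gA", "chr1", 101, 400, "+", False, cog_category="J"),
        GeneRecord("gB", "chr1", 501, 800, "-", True, product_label="polA"),
        GeneRecord("gC", "chr2", 51, 350, "+", False, cog_category="L"),
    ]
    return Genome("toy", [r1, r2], genes)
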