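import numpy as np
import pytest

from readkit.model import GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_interval(rng, chroms=("chr1", "chr2"), max_pos=1_000_000,
                    max_len=2_000, stranded=True, name=""):
    start = int(rng.integers(0, max_pos))
    length = int(rng.integers(1, max_len))
    strand = rng.choice(["+", "-", "."]) if stranded else "."
    return GenomicInterval(
        str(rng.choice(list(chroms))), start, start + length, str(strand),
        name=name,
    )


def random_spliced_interval(rng, chroms=("chr1",), max_pos=1_000_000,
                            name=""):
    """Multi-exon interval with 1-4 exons separated by >= 1 nt gaps."""
    n_exons = int(rng.integers(1, 5))
    pos = int(rng.integers(0, max_pos))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(1, 300))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(2, 500))
    strand = str(rng.choice(["+", "-"]))
    return GenomicInterval(
        str(rng.choice(list(chroms))), exons[0][0], exons[-1][1], strand,
        exons=exons if len(exons) > 1 else [], name=name,
    )
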