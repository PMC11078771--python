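import itertools

import pytest

from wgdkit import synthetic


@pytest.fixture(scope="session")
def small_genome():
    """Two chromosomes with one duplicated and one triplicated implant."""
    return synthetic.build_genome(
        2, 60,
        [
            synthetic.SegmentDuplication("chr1", 10, 12, copies=2, ks=1.0),
            synthetic.SegmentDuplication("chr2", 5, 10, copies=3, ks=0.5),
        ],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_genome_pairs(small_genome):
    return [
        p
        for members in small_genome.true_families.values()
        for p in itertools.combinations(sorted(members), 2)
    ]
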