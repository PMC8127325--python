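import numpy as np
import pytest

from introness.records import EssentialityLabel, GeneRecord, IntronRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(gene_id, seqs, category="essential", binary=None, strand="+"):
    """Toy GeneRecord from raw intron sequences."""
    binary = binary or ("essential" if category == "essential" else "nonessential")
    return GeneRecord(
        gene_id=gene_id,
        strand=strand,
        introns=[
            IntronRecord(gene_id, f"{gene_id}.t1", k, s)
            for k, s in enumerate(seqs, start=1)
        ],
        label=EssentialityLabel(category=category, binary=binary),
        essential_fraction=1.0 if binary == "essential" else 0.0,
    )
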