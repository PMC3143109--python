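import pytest

from hitdb import Alignment
from hitdb.synthgen import SyntheticDataset


def store_dataset(aln: Alignment, ds: SyntheticDataset) -> Alignment:
    """Load a synthetic dataset's single-end hits and pairs into a store."""
    for chrom, hits in sorted(ds.hits_by_chrom.items()):
        aln.append_single(chrom, hits)
    if len(ds.pairs):
        aln.append_paired(ds.pairs)
    return aln


@pytest.fixture
def make_alignment(tmp_path):
    def make(name="aln"):
        return Alignment(tmp_path / name, create=True)

    return make
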