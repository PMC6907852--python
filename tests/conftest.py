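import numpy as np
import pytest

from stagpipe.io_formats import MarkerTable
from stagpipe.marker_qc import MarkerLocus


def make_locus(
    allele_id="100001",
    ref_seq=None,
    snp_offset=24,
    ref_base="C",
    alt_base="T",
    calls=(0, 1, 2, -1),
    depth=80.0,
    tag_len=69,
    motif="TGCAG",
):
    """Construct a valid bi-allelic tag locus with a deterministic body."""
    if ref_seq is None:
        rng = np.random.default_rng(abs(hash(allele_id)) % 2**31)
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, tag_len - len(motif)))
        ref_seq = motif + body
        ref_seq = ref_seq[:snp_offset] + ref_base + ref_seq[snp_offset + 1 :]
    alt_seq = ref_seq[:snp_offset] + alt_base + ref_seq[snp_offset + 1 :]
    return MarkerLocus(
        allele_id=allele_id,
        allele_seqs=(ref_seq, alt_seq),
        snp_offset=snp_offset,
        calls=np.array(calls, dtype=np.int8),
        mean_read_depth=depth,
        restriction_motif_present=ref_seq.startswith(motif),
    )


@pytest.fixture
def tiny_table():
    """Three loci genotyped on four individuals."""
    loci = [
        make_locus("100001", calls=(0, 1, 2, -1)),
        make_locus("100002", calls=(0, 0, 0, 0), ref_base="A", alt_base="G"),
        make_locus("100003", calls=(1, 1, 2, 0), ref_base="G", alt_base="T"),
    ]
    return MarkerTable(loci=loci, individual_ids=["i1", "i2", "i3", "i4"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
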