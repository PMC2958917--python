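import pytest

from hapsurv.seqio import Alignment


@pytest.fixture
def make_fasta(tmp_path):
    """Write records to a temporary FASTA file and return its path."""

    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, seq in records:
                fh.write(f">{sid}\n{seq}\n")
        return path

    return _write


def simple_alignment(seqs, outgroup=None, coding=None, noncoding=None):
    """Alignment from a mapping id -> sequence (coding over all columns by
    default when coding is None and length is a multiple of 3)."""
    ids = tuple(seqs)
    sequences = tuple(seqs[i] for i in ids)
    L = len(sequences[0])
    if coding is None and L % 3 == 0:
        coding = ((0, L, 0),)
    return Alignment(
        ids=ids,
        seqs=sequences,
        coding_mask=tuple(coding or ()),
        noncoding_mask=tuple(noncoding or ()),
        outgroup_id=outgroup,
    )
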