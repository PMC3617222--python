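import numpy as np
import pytest

from aaclust.records import ProteinRecord

TOY_FLAT = """\
ID   TOY1_HUMAN              Reviewed;           4 AA.
AC   P00001;
SQ   SEQUENCE   4 AA;  440 MW;  0000000000000000 CRC64;
     ACDE
//
ID   TOY2_HUMAN              Reviewed;           3 AA.
AC   P00002;
SQ   SEQUENCE   3 AA;  330 MW;  0000000000000000 CRC64;
     KKK
//
"""


@pytest.fixture
def toy_flat_path(tmp_path):
    path = tmp_path / "toy.flat"
    path.write_text(TOY_FLAT)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_records(rng, n, length_range=(50, 300), alphabet="ACDEFGHIKLMNPQRSTVWY"):
    """Records with i.i.d. residues over the given alphabet."""
    letters = np.array(list(alphabet))
    records = []
    for i in range(n):
        length = int(rng.integers(*length_range))
        seq = "".join(rng.choice(letters, size=length))
        records.append(
            ProteinRecord(
                entry_name=f"R{i:03d}_TEST",
                accession="",
                declared_length=length,
                sequence=seq,
            )
        )
    return records
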