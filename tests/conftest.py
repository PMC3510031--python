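import numpy as np
import pytest

from mirtail import MiRNARefEntry, SmallRNARead


def make_read(seq, quals=None, read_id="r1"):
    if quals is None:
        quals = np.full(len(seq), 35, dtype=np.uint8)
    return SmallRNARead(
        read_id=read_id, sequence=seq, qualities=np.asarray(quals, dtype=np.uint8)
    )


@pytest.fixture(scope="session")
def toy_catalog():
    """Two dissimilar miRNAs; mir-a's flank starts G, mir-b's starts T."""
    return [
        MiRNARefEntry("mir-a", "ACGTACGGTCAATCGGACCTTG", "GTACCGGTAACT"),
        MiRNARefEntry("mir-b", "TTGACCATGGCGTTAGCACAGT", "TTAGCCGGATCA"),
    ]


@pytest.fixture(scope="session")
def tiny_catalog():
    """Short toy entries for exhaustive enumeration."""
    return [
        MiRNARefEntry("tiny-1", "ACGTTGCA", "GTACCGGTAA"),
        MiRNARefEntry("tiny-2", "TTGACC", "TACGTTGGCA"),
    ]
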