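import numpy as np
import pytest

import qtykit as q


@pytest.fixture
def worked_record():
    """The 10-residue worked example: TM helix at positions 3-8."""
    return q.attach_segments(
        q.ProteinRecord(id="toy", sequence="MKLLIVFAGW"),
        [q.TMSegment(3, 8)],
    )


@pytest.fixture
def bundle():
    """A deterministic 4-helix synthetic TM protein with CA-trace model."""
    return q.synthetic_tm_protein(
        n_helices=4, helix_len=20, loop_len=6, hydrophobic_bias=0.9, seed=11
    )


@pytest.fixture
def fixture_dir(tmp_path, bundle):
    """FASTA + TM TSV + PDB files for the bundle, written to disk."""
    return q.write_fixture(bundle, tmp_path)


def random_record(rng: np.random.Generator, max_len: int = 80) -> q.ProteinRecord:
    """A random annotated record with 1-3 non-overlapping TM segments."""
    n = int(rng.integers(10, max_len))
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    segments = []
    pos = 1
    for _ in range(int(rng.integers(1, 4))):
        if pos + 3 > n:
            break
        start = int(rng.integers(pos, pos + 3))
        end = min(int(start + rng.integers(3, 15)), n)
        if end < start:
            break
        segments.append(q.TMSegment(start, end))
        pos = end + 2
    if not segments:
        segments = [q.TMSegment(1, min(5, n))]
    return q.attach_segments(q.ProteinRecord(id="rnd", sequence=seq), segments)
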