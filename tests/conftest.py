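import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plasmidqc.seqcore import ReadPair, ReadSet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_pair(
    r1: str,
    r2: str | None = None,
    q1=None,
    q2=None,
    pair_id: str = "pair",
    provenance: str = "unknown",
) -> ReadPair:
    """Build a ReadPair with uniform Q40 qualities unless given."""
    r2 = r2 if r2 is not None else r1
    q1 = np.asarray(q1) if q1 is not None else np.full(len(r1), 40)
    q2 = np.asarray(q2) if q2 is not None else np.full(len(r2), 40)
    return ReadPair(id=pair_id, r1_seq=r1, r2_seq=r2, r1_qual=q1, r2_qual=q2,
                    provenance=provenance)


def make_readset(seqs: list[str], **kwargs) -> ReadSet:
    return ReadSet(
        pairs=[make_pair(s, pair_id=f"p{i}", **kwargs) for i, s in enumerate(seqs)],
        source_id="test",
    )


@pytest.fixture
def toy_plasmid() -> str:
    """8-base circular toy plasmid whose 4-mers are all distinct."""
    return "ATGGCGTA"


@pytest.fixture
def toy_reads(toy_plasmid) -> ReadSet:
    """The 8 circular 6-mers of the toy plasmid, one pair each."""
    doubled = toy_plasmid + toy_plasmid
    return make_readset([doubled[i : i + 6] for i in range(8)])
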