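import numpy as np
import pytest

from aavqc import SimConfig, make_genome
from aavqc.alignfeatures import AlignedRead, SupplementaryAlignment
from aavqc.refmodel import ReferenceModel


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(payload_length=3342, itr_length=145, seed=42)


@pytest.fixture(scope="session")
def model(sim_config):
    """Toy vector genome (L=3342, ITRs at both ends) plus contaminants."""
    return make_genome(sim_config)


@pytest.fixture
def vector_only_model():
    """Minimal hand-built model without sequences, for rule tests."""
    return ReferenceModel(
        references=(("vec", "", "vector"), ("hum", "", "human")),
        genome_start=0,
        genome_end=3342,
        itr_intervals=((0, 145), (3197, 3342)),
    )


def make_read(
    read_id="r1",
    read_length=3342,
    ref_name="vec",
    ref_start=0,
    ref_end=3342,
    strand="+",
    clip_left=0,
    clip_right=0,
    n_supp=0,
    supp_entries=None,
):
    """Build an AlignedRead with consistent CIGAR bookkeeping."""
    aligned = read_length - clip_left - clip_right
    if supp_entries is None:
        supp_entries = tuple(
            SupplementaryAlignment("vec", 100 * (i + 1), "+", f"{aligned}M")
            for i in range(n_supp)
        )
    return AlignedRead(
        read_id=read_id,
        read_length=read_length,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        clip_left=clip_left,
        clip_right=clip_right,
        aligned_bases=aligned,
        supplementary=tuple(supp_entries),
    )
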