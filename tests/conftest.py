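import numpy as np
import pytest

from paccmit.conservation import ConservationConfig
from paccmit.seqio import AlignedUTR, MiRNA, UTRRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def let7a():
    return MiRNA("hsa-let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def toy_alignment():
    """Three-species gapless alignment: chimp identical, mouse mutated at one column."""
    seq = "CTACCTCACTACCTCG"
    rows = {
        "human": seq,
        "chimp": seq,
        "mouse": seq[:3] + "G" + seq[4:],  # substitution at ref position 3
    }
    return UTRRecord("g1", seq), AlignedUTR(gene_id="g1", ref_species="human", rows=rows)


@pytest.fixture
def selected4():
    return ConservationConfig(mode="selected",
                              species_list=("human", "chimp", "rhesus", "mouse"))
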