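import numpy as np
import pytest

from uorfcatalog.annotation_io import GenomeSequence, TranscriptModel
from uorfcatalog.synthetic_data import SimulationConfig, simulate_study


def make_single_exon(seq: str, cds_start: int, tid: str = "t1",
                     strand: str = "+", gstart: int = 1) -> TranscriptModel:
    """Single-exon coding transcript over a sequence laid on the plus strand."""
    n = len(seq)
    return TranscriptModel(
        transcript_id=tid, gene_id="g1", contig="c", strand=strand,
        exons=((gstart, gstart + n - 1),), cds_start=cds_start, cds_end=n,
        biotype="coding",
    )


def random_coding_transcript(rng, max_utr: int = 300):
    """A random single-exon coding transcript and its sequence."""
    utr_len = int(rng.integers(0, max_utr + 1))
    cds_codons = int(rng.integers(2, 60))
    seq = "".join(rng.choice(list("ACGT"), utr_len + 3 * cds_codons))
    model = make_single_exon(seq, cds_start=utr_len + 1)
    return model, seq


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory):
    """A small synthetic study bundle shared across file-facing tests."""
    cfg = SimulationConfig(seed=3, n_transcripts=120)
    return simulate_study(cfg, tmp_path_factory.mktemp("bundle"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
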