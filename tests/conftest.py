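import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from bescreen.library_io import GuideRecord, TranscriptModel
from bescreen.synthetic_data import SimConfig, simulate_screen


@pytest.fixture(scope="session")
def toy_tx() -> TranscriptModel:
    """Single-exon coding transcript: 3-nt UTRs around MQLPDC* (21-nt CDS).

    sequence positions: 3 ATG | 6 CAA | 9 CTG | 12 CCA | 15 GAT | 18 TGC | 21 TAA
    """
    return TranscriptModel(
        transcript_id="toy_t1",
        gene="TOY",
        is_coding=True,
        sequence="AAA" + "ATGCAACTGCCAGATTGCTAA" + "TTT",
        exons=((0, 27),),
        cds_start=3,
        cds_end=24,
    )


@pytest.fixture(scope="session")
def toy_tx_intron() -> TranscriptModel:
    """Two-exon version of the same CDS with a GT...AG intron at positions 9-15."""
    return TranscriptModel(
        transcript_id="toy_t2",
        gene="TOY",
        is_coding=True,
        sequence="AAA" + "ATGCAA" + "GTCCAG" + "CTGCCAGATTGCTAA" + "TTT",
        exons=((0, 9), (15, 33)),
        cds_start=3,
        cds_end=30,
    )


@pytest.fixture(scope="session")
def toy_nc_tx() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="toy_nc",
        gene="TOY",
        is_coding=False,
        sequence="ACCACCACCACCACCACCACCACCACCACC",
        exons=((0, 30),),
    )


def make_guide(protospacer, placements=(), guide_id="g1", gene="TOY",
               control_class="targeting", pam="AGG", score=None):
    return GuideRecord(
        guide_id=guide_id, protospacer=protospacer, pam=pam, gene=gene,
        placements=tuple(placements), control_class=control_class,
        on_target_score=score,
    )


@pytest.fixture(scope="session")
def sim_screen():
    """One default simulated screen shared across tests (seed fixed)."""
    return simulate_screen(SimConfig(seed=11))
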