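"""Annotate base-editing guides on a hand-built transcript model.

Builds a 7-codon coding transcript, places two guides on it and prints the
collapsed consequence category of each.  The editing window is positions
13-18 from the PAM, i.e. 5'-based protospacer positions 3-8: every window
cytosine can deaminate to thymine, and a guide is labelled by the most
damaging outcome any subset of edits can produce in any isoform.
"""

from bescreen import TranscriptModel, classify_guide, editable_positions
from bescreen.library_io import GuideRecord, Placement

# 3-nt UTRs around the CDS ATG CAA CTG CCA GAT TGC TAA (protein MQLPDC*)
tx = TranscriptModel(
    transcript_id="demo_t1", gene="DEMO", is_coding=True,
    sequence="AAA" + "ATGCAACTGCCAGATTGCTAA" + "TTT",
    exons=((0, 27),), cds_start=3, cds_end=24,
)

# a guide whose window covers the CAA glutamine codon (C->T gives TAA, a stop)
stop_guide = GuideRecord(
    guide_id="stop_guide", protospacer=tx.sequence[2:22], pam="AGG",
    gene="DEMO", placements=(Placement("demo_t1", "sense", 2),),
    control_class="targeting", on_target_score=0.8,
)
# a guide with no cytosine in the window: nothing to edit
empty_guide = GuideRecord(
    guide_id="empty_guide", protospacer="CCTTATTGATTGATTGATTG", pam="TGG",
    gene="DEMO", placements=(Placement("demo_t1", "sense", 0),),
    control_class="targeting", on_target_score=0.5,
)

for guide in (stop_guide, empty_guide):
    positions = editable_positions(guide.protospacer)
    ann = classify_guide(guide, {"demo_t1": tx})
    print(f"{guide.guide_id}: window cytosines at {positions or 'none'} -> "
          f"category={ann.category}, worst change={ann.worst_protein_change}, "
          f"{ann.n_outcomes} outcome(s)")

# stop_guide collapses to 'nonsense' (Q2*) even though some partial edits
# are synonymous: the most damaging predicted outcome defines the guide.
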