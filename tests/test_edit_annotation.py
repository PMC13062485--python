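import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bescreen.edit_annotation import (
    EditingWindow,
    Substitution,
    assign_clinical_class,
    call_consequence,
    classify_guide,
    editable_positions,
    enumerate_outcomes,
    project_outcome,
)
from bescreen.library_io import ClinicalMap, Placement, TranscriptModel, ValidationError
from conftest import make_guide
from oracles import oracle_classify

# the printed safe-harbor protospacer used to validate window numbering
AAVS1_GUIDE = "GGGGCCACTAGGGACAGGAT"


class TestEditableWindow:
    def test_distance_from_pam_maps_to_5prime_positions(self):
        w = EditingWindow(13, 18)
        assert (w.p_min, w.p_max) == (3, 8)

    @pytest.mark.parametrize(
        "protospacer, expected",
        [
            (AAVS1_GUIDE, [5, 6, 8]),
            ("AAGGTTAAGGTTAAGGTTAA", []),
            ("C" * 20, [3, 4, 5, 6, 7, 8]),
        ],
    )
    def test_editable_positions(self, protospacer, expected):
        assert editable_positions(protospacer) == expected

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            EditingWindow(0, 18)


class TestEnumerateOutcomes:
    def test_aavs1_guide_yields_seven_outcomes(self):
        outcomes = enumerate_outcomes(AAVS1_GUIDE)
        assert len(outcomes) == 7
        # ordered by size then lexicographically
        assert outcomes[:3] == [(5,), (6,), (8,)]
        assert outcomes[-1] == (5, 6, 8)

    def test_no_editable_cytosine_gives_empty_list(self):
        assert enumerate_outcomes("AAGGTTAAGGTTAAGGTTAA") == []

    def test_cap_exceeded_raises(self):
        with pytest.raises(ValidationError, match="max_editable"):
            enumerate_outcomes("C" * 20, max_editable=5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    def test_outcome_count_is_2k_minus_1(self, protospacer):
        k = len(editable_positions(protospacer))
        assert len(enumerate_outcomes(protospacer)) == 2 ** k - 1


class TestProjectOutcome:
    def _tx(self, seq):
        return TranscriptModel("tx", "G", False, seq, ((0, len(seq)),))

    def test_sense_projection(self):
        seq = "A" * 14 + "C" + "A" * 20
        guide = make_guide("AAAAC" + "A" * 15,
                           [Placement("tx", "sense", 10)])
        subs = project_outcome(guide, (5,), self._tx(seq))
        assert subs == [Substitution(14, "C", "T")]

    def test_antisense_projection(self):
        seq = "A" * 25 + "G" + "A" * 10
        guide = make_guide("AAAAC" + "A" * 15,
                           [Placement("tx", "antisense", 10)])
        subs = project_outcome(guide, (5,), self._tx(seq))
        assert subs == [Substitution(25, "G", "A")]

    def test_reference_mismatch_is_error(self):
        seq = "A" * 40  # no C at the projected position
        guide = make_guide("AAAAC" + "A" * 15, [Placement("tx", "sense", 10)])
        with pytest.raises(ValidationError, match="inconsistency"):
            project_outcome(guide, (5,), self._tx(seq))


class TestCallConsequence:
    def test_stop_gain_is_nonsense_with_star_change(self, toy_tx):
        call = call_consequence([Substitution(6, "C", "T")], toy_tx)  # CAA->TAA
        assert call.category == "nonsense"
        assert call.protein_changes == ("Q2*",)

    def test_silent_codon_change_is_synonymous(self, toy_tx):
        call = call_consequence([Substitution(9, "C", "T")], toy_tx)  # CTG->TTG
        assert call.category == "synonymous"

    def test_amino_acid_change_is_missense(self, toy_tx):
        call = call_consequence([Substitution(12, "C", "T")], toy_tx)  # CCA->TCA
        assert call.category == "missense"
        assert call.protein_changes == ("P4S",)

    def test_donor_site_edit_is_splice(self, toy_tx_intron):
        # GT donor at positions 9-10; antisense G->A gives AT
        call = call_consequence([Substitution(9, "G", "A")], toy_tx_intron)
        assert call.category == "splice"

    def test_deep_intronic_edit_is_silent(self, toy_tx_intron):
        call = call_consequence([Substitution(11, "C", "T")], toy_tx_intron)
        assert call.category == "synonymous"

    def test_first_codon_edit_is_nonsense(self, toy_tx):
        # antisense G->A converts ATG (codon 1) to ATA
        call = call_consequence([Substitution(5, "G", "A")], toy_tx)
        assert call.category == "nonsense"

    def test_noncoding_transcript_always_non_coding(self, toy_nc_tx):
        call = call_consequence([Substitution(1, "C", "T")], toy_nc_tx)
        assert call.category == "non_coding"


class TestClassifyGuide:
    def test_most_damaging_category_wins(self, toy_tx):
        # window positions 3..8 of this placement cover transcript 4..9:
        # pos 6 (Q2* nonsense) and pos 9 (synonymous) are both editable
        guide = make_guide(toy_tx.sequence[2:22],
                           [Placement("toy_t1", "sense", 2)])
        assert guide.protospacer[4] == "C" and guide.protospacer[7] == "C"
        ann = classify_guide(guide, {"toy_t1": toy_tx})
        assert ann.category == "nonsense"
        assert ann.worst_protein_change == "Q2*"

    def test_noncoding_only_placement_is_non_coding(self, toy_nc_tx):
        guide = make_guide(toy_nc_tx.sequence[0:20],
                           [Placement("toy_nc", "sense", 0)])
        ann = classify_guide(guide, {"toy_nc": toy_nc_tx})
        assert ann.category == "non_coding"

    def test_coding_placement_takes_precedence(self, toy_tx, toy_nc_tx):
        guide = make_guide(toy_tx.sequence[2:22],
                           [Placement("toy_t1", "sense", 2),
                            Placement("toy_nc", "antisense", 3)])
        ann = classify_guide(guide, {"toy_t1": toy_tx, "toy_nc": toy_nc_tx})
        assert ann.category == "nonsense"

    def test_no_window_cytosine_is_empty_window(self, toy_tx):
        guide = make_guide("CCTTATTGATTGATTGATTG",
                           [Placement("toy_t1", "sense", 0)])
        ann = classify_guide(guide, {"toy_t1": toy_tx})
        assert ann.category == "empty_window" and ann.n_outcomes == 0

    def test_unplaced_targeting_guide_is_error(self):
        guide = make_guide("ACGTACGTACGTACGTACGT", [])
        with pytest.raises(ValidationError, match="no transcript placements"):
            classify_guide(guide, {})

    def test_severity_never_drops_when_partial_edits_added(self, sim_screen):
        """Collapsing over all subsets dominates the fully-edited outcome."""
        from bescreen.edit_annotation import SEVERITY

        tx = sim_screen.transcripts
        checked = 0
        for guide in sim_screen.guides[:80]:
            if not guide.placements:
                continue
            full = classify_guide(guide, tx, full_edit_only=True)
            subsets = classify_guide(guide, tx)
            if full.category is None:
                continue
            assert SEVERITY[subsets.category] >= SEVERITY[full.category]
            checked += 1
        assert checked >= 40


class TestClinicalClass:
    CMAP = ClinicalMap({("TOY", "Q2*"): "PLP", ("TOY", "P4S"): "BLB",
                        ("TOY", "P4L"): "VUS"})

    def test_equally_deleterious_ties_break_by_hierarchy(self):
        assert assign_clinical_class(["P4S", "P4L"], self.CMAP, "TOY") == "VUS"

    def test_single_most_deleterious_change_returns_its_class(self):
        assert assign_clinical_class(["Q2*"], self.CMAP, "TOY") == "PLP"

    def test_absent_changes_are_na(self):
        assert assign_clinical_class(["K9R"], self.CMAP, "TOY") == "NA"
        assert assign_clinical_class([], self.CMAP, "TOY") == "NA"

    def test_nonsense_change_outranks_missense_for_lookup(self, toy_tx):
        guide = make_guide(toy_tx.sequence[2:22],
                           [Placement("toy_t1", "sense", 2)])
        ann = classify_guide(guide, {"toy_t1": toy_tx}, clinical_map=self.CMAP)
        assert ann.clinical_class == "PLP"


class TestOracleAgreement:
    def test_brute_force_retranslation_agrees_on_simulated_guides(self, sim_screen):
        """Category matches a whole-protein re-translation oracle."""
        tx = sim_screen.transcripts
        rng = np.random.default_rng(5)
        placed = [g for g in sim_screen.guides if g.placements]
        picks = rng.choice(len(placed), size=60, replace=False)
        for i in picks:
            guide = placed[i]
            ours = classify_guide(guide, tx).category
            assert ours == oracle_classify(guide, tx), guide.guide_id

    def test_projected_reference_bases_match_transcript(self, sim_screen):
        tx = sim_screen.transcripts
        for guide in sim_screen.guides[:100]:
            for pl in guide.placements:
                model = tx[pl.transcript_id]
                positions = editable_positions(guide.protospacer)
                if positions:
                    # project_outcome raises on any ref-base mismatch
                    project_outcome(guide, tuple(positions), model)
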