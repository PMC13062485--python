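"""Predicted C-to-T edit outcomes and protein-level consequence calling.

A cytosine base editor deaminates cytosines within a fixed window of the
protospacer.  The window is specified in distance-from-PAM coordinates
(the nucleotide adjacent to the PAM has d = 1); BE3's six-nucleotide window
d in [13, 18] corresponds to 5'-based protospacer positions 3-8 via
p = 21 - d.  Because editing of individual cytosines is independent and
often partial, every non-empty subset of the editable cytosines is a
possible DNA outcome; each outcome is projected onto the transcript models
a guide is placed on, consequences are called per transcript, and the guide
is collapsed to the single most damaging category across outcomes and
isoforms.

Severity order (least to most damaging):
empty_window < synonymous < non_coding < missense < nonsense < splice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .library_io import (
    ClinicalMap,
    GuideRecord,
    Placement,
    TranscriptModel,
    ValidationError,
)

CATEGORIES = ("empty_window", "synonymous", "non_coding", "missense", "nonsense", "splice")
SEVERITY = {cat: rank for rank, cat in enumerate(CATEGORIES, start=1)}

#: clinical tie-break hierarchy, least to most relevant; None encodes
#: "absent from the clinical map" (NA)
CLINICAL_HIERARCHY: tuple[Optional[str], ...] = ("BLB", None, "VUS", "PLP")
_CLINICAL_RANK = {cls: i for i, cls in enumerate(CLINICAL_HIERARCHY)}

_CODON_CACHE: dict[str, str] = {}


def translate_codon(codon: str) -> str:
    """Standard nuclear genetic code, one codon to one amino acid ('*' = stop)."""
    aa = _CODON_CACHE.get(codon)
    if aa is None:
        aa = str(Seq(codon).translate())
        _CODON_CACHE[codon] = aa
    return aa


@dataclass(frozen=True)
class EditingWindow:
    """Editable span in distance-from-PAM coordinates (PAM-adjacent base d=1)."""

    d_min: int = 13
    d_max: int = 18

    def __post_init__(self) -> None:
        if not (1 <= self.d_min <= self.d_max <= 20):
            raise ValidationError(
                f"editing window must satisfy 1 <= d_min <= d_max <= 20, "
                f"got [{self.d_min}, {self.d_max}]"
            )

    @property
    def p_min(self) -> int:
        """Smallest 5'-based protospacer position in the window (p = 21 - d_max)."""
        return 21 - self.d_max

    @property
    def p_max(self) -> int:
        return 21 - self.d_min


@dataclass(frozen=True)
class Substitution:
    """One base substitution in transcript-forward coordinates."""

    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ConsequenceCall:
    transcript_id: str
    category: str
    protein_changes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown consequence category {self.category!r}")

    @property
    def severity(self) -> int:
        return SEVERITY[self.category]


@dataclass(frozen=True)
class GuideAnnotation:
    guide_id: str
    category: Optional[str]  # None for guides with no transcript placement
    k_editable: int
    n_outcomes: int
    worst_protein_change: Optional[str]
    clinical_class: str  # "BLB" | "NA" | "VUS" | "PLP"


def editable_positions(protospacer: str, window: EditingWindow = EditingWindow()) -> list[int]:
    """5'-based protospacer positions in the window that carry a cytosine."""
    return [p for p in range(window.p_min, window.p_max + 1) if protospacer[p - 1] == "C"]


def enumerate_outcomes(
    protospacer: str,
    window: EditingWindow = EditingWindow(),
    max_editable: int = 10,
) -> list[tuple[int, ...]]:
    """All 2^k - 1 non-empty subsets of the editable positions.

    Deterministic order: by subset size, then lexicographically.  Guides with
    more than ``max_editable`` editable cytosines are rejected to bound the
    enumeration; the cap can be raised by the caller.
    """
    positions = editable_positions(protospacer, window)
    k = len(positions)
    if k > max_editable:
        raise ValidationError(
            f"{k} editable positions exceeds cap {max_editable}; "
            f"raise max_editable to enumerate this guide"
        )
    out: list[tuple[int, ...]] = []
    for size in range(1, k + 1):
        out.extend(itertools.combinations(positions, size))
    return out


def _placement_on(guide: GuideRecord, tx: TranscriptModel) -> Placement:
    for pl in guide.placements:
        if pl.transcript_id == tx.transcript_id:
            return pl
    raise ValidationError(
        f"guide {guide.guide_id} has no placement on transcript {tx.transcript_id}"
    )


def project_outcome(
    guide: GuideRecord,
    subset: Sequence[int],
    tx: TranscriptModel,
) -> list[Substitution]:
    """Map edited protospacer positions onto transcript substitutions.

    Sense placements edit C->T at ``offset + (p - 1)``; antisense placements
    edit the complementary strand, observed on the transcript-forward strand
    as G->A at ``offset + (20 - p)``.  A reference-base mismatch means the
    library and transcript models disagree and is an error.
    """
    pl = _placement_on(guide, tx)
    subs = []
    for p in subset:
        if guide.protospacer[p - 1] != "C":
            raise ValidationError(
                f"guide {guide.guide_id}: position {p} is not a cytosine"
            )
        if pl.strand == "sense":
            pos, ref, alt = pl.offset + (p - 1), "C", "T"
        else:
            pos, ref, alt = pl.offset + (20 - p), "G", "A"
        if not (0 <= pos < len(tx.sequence)):
            raise ValidationError(
                f"guide {guide.guide_id}: edit at transcript position {pos} "
                f"outside {tx.transcript_id} (length {len(tx.sequence)})"
            )
        if tx.sequence[pos] != ref:
            raise ValidationError(
                f"guide {guide.guide_id}: expected {ref} at {tx.transcript_id}:{pos}, "
                f"found {tx.sequence[pos]} (library/model inconsistency)"
            )
        subs.append(Substitution(pos, ref, alt))
    return subs


@lru_cache(maxsize=2048)
def _tx_context(tx: TranscriptModel):
    """Cached per-transcript lookup structures for consequence calling."""
    cds_positions = tx.cds_positions()
    cds_index = {pos: i for i, pos in enumerate(cds_positions)}
    return cds_index, tx.spliced_cds(), tx.splice_site_positions()


def call_consequence(
    substitutions: Sequence[Substitution],
    tx: TranscriptModel,
) -> ConsequenceCall:
    """Call the consequence of a set of substitutions on one transcript.

    Non-coding transcripts always yield ``non_coding``.  Otherwise a
    substitution within the two intronic bases of any exon-intron junction is
    a splice event; coding substitutions are applied jointly to the spliced
    CDS and affected codons are re-translated — any stop gain (or any hit to
    the first codon) is nonsense, any other amino-acid change is missense,
    and an unchanged protein with no splice event is synonymous.  The call's
    category is the most severe event observed.
    """
    for sub in substitutions:
        if not (0 <= sub.position < len(tx.sequence)):
            raise ValidationError(
                f"substitution at {sub.position} outside transcript "
                f"{tx.transcript_id}"
            )
    if not tx.is_coding:
        return ConsequenceCall(tx.transcript_id, "non_coding")

    cds_index, ref_cds, splice_sites = _tx_context(tx)
    splice_hit = any(s.position in splice_sites for s in substitutions)
    mut = list(ref_cds)
    affected_codons: set[int] = set()
    for s in substitutions:
        i = cds_index.get(s.position)
        if i is None:
            continue
        mut[i] = s.alt
        affected_codons.add(i // 3)

    changes: list[str] = []
    stop_gain = False
    first_codon_hit = 0 in affected_codons
    n_codons = len(ref_cds) // 3
    for c in sorted(affected_codons):
        if c >= n_codons:  # trailing partial codon in a flagged model
            continue
        ref_codon = ref_cds[3 * c:3 * c + 3]
        alt_codon = "".join(mut[3 * c:3 * c + 3])
        aa_ref = translate_codon(ref_codon)
        aa_alt = translate_codon(alt_codon)
        if aa_ref == aa_alt:
            continue
        changes.append(f"{aa_ref}{c + 1}{aa_alt}")
        if aa_alt == "*" and aa_ref != "*":
            stop_gain = True

    if splice_hit:
        category = "splice"
    elif stop_gain or first_codon_hit:
        category = "nonsense"
    elif changes:
        category = "missense"
    else:
        category = "synonymous"
    return ConsequenceCall(tx.transcript_id, category, tuple(changes))


def _change_position(change: str) -> int:
    return int("".join(ch for ch in change if ch.isdigit()))


def assign_clinical_class(
    changes: Sequence[str],
    clinical_map: Optional[ClinicalMap],
    gene: Optional[str],
) -> str:
    """Collapse the worst-tier amino-acid changes to one clinical class.

    Each change is looked up in the map (missing -> NA); ties among equally
    deleterious changes break by the hierarchy BLB < NA < VUS < PLP.
    """
    if not changes:
        return "NA"
    classes = []
    for ch in changes:
        cls = clinical_map.lookup(gene, ch) if clinical_map is not None else None
        classes.append(cls)
    best = max(classes, key=lambda c: _CLINICAL_RANK[c])
    return best if best is not None else "NA"


def classify_guide(
    guide: GuideRecord,
    transcripts: Mapping[str, TranscriptModel],
    window: EditingWindow = EditingWindow(),
    clinical_map: Optional[ClinicalMap] = None,
    max_editable: int = 10,
    full_edit_only: bool = False,
) -> GuideAnnotation:
    """Collapse all outcomes x isoforms of one guide to a single annotation.

    Rules, in order: no editable cytosine -> ``empty_window``; placements on
    coding isoforms take precedence, and the guide's category is the maximum
    severity over all outcomes and coding isoforms; a guide placed only on
    non-coding isoforms is ``non_coding`` regardless of predicted effect.
    ``worst_protein_change`` is the most deleterious amino-acid change
    (nonsense over missense, then smallest residue number); the clinical
    class is assigned from the worst-tier changes.

    ``full_edit_only=True`` considers only the fully edited outcome instead
    of all partial-edit subsets.
    """
    positions = editable_positions(guide.protospacer, window)
    k = len(positions)

    if not guide.placements:
        if guide.control_class == "nontargeting_control":
            return GuideAnnotation(guide.guide_id, None, k, 0, None, "NA")
        raise ValidationError(
            f"guide {guide.guide_id} ({guide.control_class}) has no transcript placements"
        )

    if k == 0:
        return GuideAnnotation(guide.guide_id, "empty_window", 0, 0, None, "NA")

    if full_edit_only:
        outcomes: list[tuple[int, ...]] = [tuple(positions)]
    else:
        outcomes = enumerate_outcomes(guide.protospacer, window, max_editable)

    placed = []
    for pl in guide.placements:
        tx = transcripts.get(pl.transcript_id)
        if tx is None:
            raise ValidationError(
                f"guide {guide.guide_id}: unknown transcript {pl.transcript_id}"
            )
        placed.append(tx)
    coding = [tx for tx in placed if tx.is_coding]

    if not coding:
        return GuideAnnotation(guide.guide_id, "non_coding", k, len(outcomes), None, "NA")

    best_rank = SEVERITY["synonymous"]
    nonsense_changes: list[str] = []
    missense_changes: list[str] = []
    for tx in coding:
        for subset in outcomes:
            subs = project_outcome(guide, subset, tx)
            call = call_consequence(subs, tx)
            best_rank = max(best_rank, call.severity)
            for ch in call.protein_changes:
                if ch.endswith("*"):
                    nonsense_changes.append(ch)
                else:
                    missense_changes.append(ch)

    category = CATEGORIES[best_rank - 1]
    if nonsense_changes:
        worst_tier = sorted(set(nonsense_changes), key=lambda c: (_change_position(c), c))
    elif missense_changes:
        worst_tier = sorted(set(missense_changes), key=lambda c: (_change_position(c), c))
    else:
        worst_tier = []
    worst_change = worst_tier[0] if worst_tier else None
    clinical = assign_clinical_class(worst_tier, clinical_map, guide.gene)
    return GuideAnnotation(
        guide_id=guide.guide_id,
        category=category,
        k_editable=k,
        n_outcomes=len(outcomes),
        worst_protein_change=worst_change,
        clinical_class=clinical,
    )


def annotate_library(
    guides: Iterable[GuideRecord],
    transcripts: Mapping[str, TranscriptModel],
    window: EditingWindow = EditingWindow(),
    clinical_map: Optional[ClinicalMap] = None,
    max_editable: int = 10,
    full_edit_only: bool = False,
) -> list[GuideAnnotation]:
    """Annotate every guide in a library (see :func:`classify_guide`)."""
    return [
        classify_guide(g, transcripts, window, clinical_map, max_editable, full_edit_only)
        for g in guides
    ]


def annotations_to_frame(annotations: Sequence[GuideAnnotation]):
    """Tabulate annotations (category NA for unplaced non-targeting guides)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "guide_id": [a.guide_id for a in annotations],
            "category": [a.category if a.category is not None else "NA"
                         for a in annotations],
            "k_editable": [a.k_editable for a in annotations],
            "n_outcomes": [a.n_outcomes for a in annotations],
            "worst_protein_change": [a.worst_protein_change for a in annotations],
            "clinical_class": [a.clinical_class for a in annotations],
        }
    )
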