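"""Per-guide fitness scores and control-calibrated screen statistics.

The phenotypic score of guide *i* in replicate *r* is

    x_i = log2((R'_i + eps) / (C'_i + eps))

where R' and C' are the median-normalized endpoint and T0 counts and eps
(default 0.05) damps low-count noise; the guide's LFC is the mean of x_i
over replicate pairs.  Negative depletion indicates a fitness cost.

Calibration against negative controls provides (a) empirical control bounds
(5th/95th percentile of negative-control LFC), (b) a rank-based two-sided
empirical p-value per guide, and (c) hit tiers: a guide whose LFC falls
outside the bounds is low-priority at p < 0.05 and high-priority at
p < 0.01.  ROC/AUC contrasts between designed positive controls (iSTOP) and
the negative-control classes quantify screen separation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics

from .library_io import ValidationError
from .screen_counts import NormalizedCounts

logger = logging.getLogger(__name__)

TIERS = ("none", "low_priority", "high_priority")


@dataclass(frozen=True)
class ControlBounds:
    """q and 1-q quantiles of the negative-control LFC distribution."""

    lo: float
    hi: float
    q: float = 0.05

    def __post_init__(self) -> None:
        if not self.lo <= self.hi:
            raise ValidationError("control bounds must satisfy lo <= hi")

    def outside(self, lfc) -> np.ndarray:
        lfc = np.asarray(lfc, dtype=float)
        return (lfc < self.lo) | (lfc > self.hi)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


@dataclass
class EnrichmentTest:
    """One-sided Fisher test of category overrepresentation among depleted guides."""

    k_category_depleted: int
    n_category: int
    k_reference_depleted: int
    n_reference: int
    p_value: float


def compute_lfc(
    norm: NormalizedCounts,
    epsilon: float = 0.05,
) -> pd.DataFrame:
    """Per-replicate x_i and replicate-mean LFC for a single cell line.

    Samples must pair into (T0, TEND) by replicate number.  Returns a frame
    indexed by guide with one ``x_rep<r>`` column per replicate and an
    ``lfc`` column holding their arithmetic mean.
    """
    cell_lines = {s.cell_line for s in norm.samples}
    if len(cell_lines) != 1:
        raise ValidationError(
            f"compute_lfc expects a single cell line, got {sorted(cell_lines)}"
        )
    t0 = {s.replicate: s.sample_id for s in norm.samples if s.timepoint == "T0"}
    tend = {s.replicate: s.sample_id for s in norm.samples if s.timepoint == "TEND"}
    if set(t0) != set(tend) or not t0:
        raise ValidationError(
            f"replicates do not pair across timepoints: T0={sorted(t0)}, "
            f"TEND={sorted(tend)}"
        )
    out = pd.DataFrame(index=norm.values.index)
    xcols = []
    for r in sorted(t0):
        x = np.log2(
            (norm.values[tend[r]] + epsilon) / (norm.values[t0[r]] + epsilon)
        )
        col = f"x_rep{r}"
        out[col] = x
        xcols.append(col)
    out["lfc"] = out[xcols].mean(axis=1)
    return out


def control_bounds(
    lfc: pd.Series,
    negative_ids: Sequence[str],
    q: float = 0.05,
) -> ControlBounds:
    """Empirical q / (1-q) bounds of the negative-control LFC distribution.

    Uses the sorted-linear-interpolation quantile (numpy default, type 7).
    """
    neg = lfc.loc[lfc.index.intersection(negative_ids)].dropna()
    if len(neg) == 0:
        raise ValidationError("no negative-control LFC values for bounds")
    if len(neg) < 20:
        warnings.warn(
            f"only {len(neg)} negative controls: {q:.0%} tail bounds are unstable"
        )
    lo, hi = np.quantile(neg.values, [q, 1.0 - q])
    return ControlBounds(lo=float(lo), hi=float(hi), q=q)


def empirical_pvalues(
    lfc: pd.Series,
    negative_ids: Sequence[str],
) -> pd.Series:
    """Two-sided empirical p-value of each LFC against the negative controls.

    With n negative-control values, r_lo = #{negatives <= x} and
    r_hi = #{negatives >= x}:

        p = min(1, 2 * min(r_lo + 1, r_hi + 1) / (n + 1))

    The +1 terms make p strictly positive and conservative (a value below
    all of n = 99 negatives gets p = 2/100 = 0.02).
    """
    neg = np.sort(lfc.loc[lfc.index.intersection(negative_ids)].dropna().values)
    n = len(neg)
    if n == 0:
        raise ValidationError("no negative-control LFC values for p-values")
    x = lfc.values.astype(float)
    r_lo = np.searchsorted(neg, x, side="right")
    r_hi = n - np.searchsorted(neg, x, side="left")
    p = 2.0 * (np.minimum(r_lo, r_hi) + 1) / (n + 1)
    return pd.Series(np.minimum(p, 1.0), index=lfc.index, name="p_value")


def tier_hits(
    lfc: pd.Series,
    p_values: pd.Series,
    bounds: ControlBounds,
    p_low: float = 0.05,
    p_high: float = 0.01,
) -> pd.Series:
    """Hit tiers: outside control bounds and p<0.01 -> high_priority,
    p<0.05 -> low_priority, else none."""
    outside = bounds.outside(lfc)
    tier = np.where(
        outside & (p_values.values < p_high),
        "high_priority",
        np.where(outside & (p_values.values < p_low), "low_priority", "none"),
    )
    return pd.Series(tier, index=lfc.index, name="tier")


def score_guides(
    norm: NormalizedCounts,
    negative_ids: Sequence[str],
    epsilon: float = 0.05,
    q: float = 0.05,
) -> tuple[pd.DataFrame, ControlBounds]:
    """LFC + empirical p + tier for every guide of one cell-line screen."""
    fitness = compute_lfc(norm, epsilon=epsilon)
    bounds = control_bounds(fitness["lfc"], negative_ids, q=q)
    fitness["p_value"] = empirical_pvalues(fitness["lfc"], negative_ids)
    fitness["tier"] = tier_hits(fitness["lfc"], fitness["p_value"], bounds)
    return fitness, bounds


def roc_auc(
    positive_scores: Sequence[float],
    negative_scores: Sequence[float],
    score_direction: str = "higher_is_positive",
) -> RocResult:
    """ROC curve and AUC separating two score sets.

    ``score_direction='lower_is_positive'`` negates the scores first (used
    for depletion contrasts, where a more negative LFC is more positive).
    The AUC equals the Mann-Whitney pair statistic with midrank ties.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("ROC needs non-empty positive and negative sets")
    if score_direction == "lower_is_positive":
        pos, neg = -pos, -neg
    elif score_direction != "higher_is_positive":
        raise ValidationError(f"unknown score_direction {score_direction!r}")
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    scores = np.concatenate([pos, neg])
    fpr, tpr, thr = skmetrics.roc_curve(y, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return RocResult(
        thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
        n_positive=len(pos), n_negative=len(neg),
    )


def depletion_enrichment_test(
    lfc: pd.Series,
    category_ids: Sequence[str],
    reference_ids: Sequence[str],
    bounds: ControlBounds,
) -> EnrichmentTest:
    """One-sided Fisher exact test: is the category enriched below the lower
    control bound relative to the reference set?

    The 2x2 table crosses (category vs reference) with (lfc < lo vs not);
    the p-value is the hypergeometric upper tail of the observed overlap.
    """
    cat = lfc.loc[lfc.index.intersection(category_ids)].dropna()
    ref = lfc.loc[lfc.index.intersection(reference_ids)].dropna()
    k_cat = int((cat < bounds.lo).sum())
    k_ref = int((ref < bounds.lo).sum())
    table = [[k_cat, len(cat) - k_cat], [k_ref, len(ref) - k_ref]]
    if len(cat) == 0 or len(ref) == 0 or (k_cat + k_ref) == 0:
        warnings.warn("degenerate enrichment table; p set to 1")
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="greater")[1])
    return EnrichmentTest(
        k_category_depleted=k_cat,
        n_category=len(cat),
        k_reference_depleted=k_ref,
        n_reference=len(ref),
        p_value=p,
    )


LOF_CATEGORIES = ("nonsense", "splice")
NEUTRAL_CATEGORIES = ("synonymous", "empty_window")


def category_comparisons(
    fitness: pd.DataFrame,
    guide_meta: pd.DataFrame,
    essential_genes: Sequence[str],
    score_threshold: float = 0.5,
) -> dict[str, dict]:
    """The screen's standard control and category contrasts, as ROC AUCs.

    ``guide_meta`` is indexed by guide id with columns ``control_class``,
    ``category``, ``clinical_class``, ``gene``, ``on_target_score``.
    Depletion is the positive direction throughout (score = -LFC).
    Contrasts with an empty side are skipped with a warning.

    Returns a dict keyed by contrast name; each value carries the AUC and
    set sizes.
    """
    meta = guide_meta.loc[guide_meta.index.intersection(fitness.index)]
    lfc = fitness.loc[meta.index, "lfc"]
    essential = set(essential_genes)

    def ids(mask) -> pd.Index:
        return meta.index[mask]

    istop = ids(meta["control_class"] == "istop_control")
    aavs1 = ids(meta["control_class"] == "aavs1_control")
    ntc = ids(meta["control_class"] == "nontargeting_control")
    empty = ids(meta["control_class"] == "empty_window_control")
    high_score = meta["on_target_score"].fillna(-1.0) > score_threshold
    in_essential = meta["gene"].isin(essential)
    targeting = meta["control_class"] == "targeting"
    lof = ids(targeting & in_essential & meta["category"].isin(LOF_CATEGORIES))
    neutral = ids(targeting & in_essential & meta["category"].isin(NEUTRAL_CATEGORIES))
    plp = ids(targeting & in_essential & (meta["clinical_class"] == "PLP"))
    blb = ids(targeting & in_essential & (meta["clinical_class"] == "BLB"))

    contrasts = {
        "istop_vs_aavs1": (istop, aavs1),
        "istop_vs_aavs1_high_score": (istop[high_score.loc[istop]], aavs1),
        "istop_vs_empty_window": (istop, empty),
        "istop_vs_nontargeting": (istop, ntc),
        "lof_vs_neutral_essential": (lof, neutral),
        "lof_vs_neutral_essential_high_score": (
            lof[high_score.loc[lof]], neutral[high_score.loc[neutral]]),
        "plp_vs_blb_essential": (plp, blb),
    }
    report: dict[str, dict] = {}
    for name, (pos_ids, neg_ids) in contrasts.items():
        if len(pos_ids) == 0 or len(neg_ids) == 0:
            warnings.warn(f"contrast {name}: empty side, skipped")
            continue
        roc = roc_auc(lfc.loc[pos_ids], lfc.loc[neg_ids],
                      score_direction="lower_is_positive")
        report[name] = {
            "auc": roc.auc,
            "n_positive": roc.n_positive,
            "n_negative": roc.n_negative,
        }
    return report


def negative_control_ids(guide_meta: pd.DataFrame) -> pd.Index:
    """AAVS1-targeting plus non-targeting guides (the neutral calibration set)."""
    mask = guide_meta["control_class"].isin(["aavs1_control", "nontargeting_control"])
    return guide_meta.index[mask]
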