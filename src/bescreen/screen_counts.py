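"""Count-matrix hygiene and replicate-concordance QC.

Guides with a zero count in any sample are dropped before normalization;
each retained column is then divided by its median so that the per-sample
median of normalized counts is exactly 1.  Replicate concordance is the
Pearson correlation of log2(count + 1) values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedCounts:
    """Median-normalized counts, same shape and metadata as the source matrix."""

    values: pd.DataFrame
    samples: list
    genes: pd.Series


@dataclass(frozen=True)
class ReplicateCorrelation:
    sample_a: str
    sample_b: str
    r: float  # NaN when undefined (constant column)
    median_log2_a: float
    median_log2_b: float


def filter_zero_guides(cm: CountMatrix) -> CountMatrix:
    """Drop every guide with a zero count in at least one sample."""
    keep = (cm.counts > 0).all(axis=1)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("zero-count filtering removed every guide")
    logger.info(
        "zero-count filter: removed %d of %d guides", n_removed, len(cm.counts)
    )
    return CountMatrix(
        counts=cm.counts.loc[keep].copy(),
        samples=list(cm.samples),
        genes=cm.genes.loc[keep].copy(),
    )


def median_normalize(cm: CountMatrix) -> NormalizedCounts:
    """Divide each sample column by its median count over retained guides."""
    medians = cm.counts.median(axis=0)
    zero = medians[medians <= 0]
    if len(zero):
        raise ValidationError(
            f"zero median in samples {list(zero.index)}; filter zero-count guides first"
        )
    values = cm.counts / medians
    return NormalizedCounts(values=values, samples=list(cm.samples), genes=cm.genes)


def replicate_correlation(
    cm: CountMatrix,
    pairs: Sequence[tuple[str, str]],
) -> list[ReplicateCorrelation]:
    """Pearson r of log2(count + 1) for each replicate pair.

    Also reports each sample's median transformed count (the dashed-line
    statistic of the usual replicate scatter plot).  A constant column makes
    r undefined; it is reported as NaN with a warning.
    """
    log = np.log2(cm.counts + 1.0)
    out = []
    for a, b in pairs:
        xa, xb = log[a].values, log[b].values
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            warnings.warn(f"correlation undefined for constant column in ({a}, {b})")
            r = float("nan")
        else:
            r = float(stats.pearsonr(xa, xb).statistic)
        out.append(
            ReplicateCorrelation(
                sample_a=a,
                sample_b=b,
                r=r,
                median_log2_a=float(np.median(xa)),
                median_log2_b=float(np.median(xb)),
            )
        )
    return out


def default_replicate_pairs(cm: CountMatrix) -> list[tuple[str, str]]:
    """All within-timepoint replicate pairs, per cell line (T0_R1 vs T0_R2 etc.)."""
    pairs = []
    by_group: dict[tuple[str, str], list] = {}
    for s in cm.samples:
        by_group.setdefault((s.cell_line, s.timepoint), []).append(s)
    for group in by_group.values():
        group = sorted(group, key=lambda s: s.replicate)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                pairs.append((group[i].sample_id, group[j].sample_id))
    return pairs


def correlations_to_frame(corrs: Sequence[ReplicateCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_a": [c.sample_a for c in corrs],
            "sample_b": [c.sample_b for c in corrs],
            "pearson_r": [c.r for c in corrs],
            "median_log2_a": [c.median_log2_a for c in corrs],
            "median_log2_b": [c.median_log2_b for c in corrs],
        }
    )
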