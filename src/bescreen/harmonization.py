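"""Cross-cell-line harmonization: nLFC, significance selection, Ward
clustering and hypergeometric cluster enrichment.

The normalized LFC rescales each cell line's scores by its own control
dynamic range,

    nLFC_i = (x_i - mu_neg) / sigma_ctrl,

with mu_neg the mean LFC of the negative controls (AAVS1-targeting plus
non-targeting guides) and sigma_ctrl the sample standard deviation of the
pooled positive (iSTOP) and negative controls.  Guides with |nLFC| > 1 in
at least one cell line are considered significant, clustered in cell-line
space with Euclidean distance and Ward's linkage, and each cluster is
tested for overrepresentation of gene or clinical-class labels with a
hypergeometric upper-tail test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .library_io import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NlfcParams:
    mu_neg: float
    sigma_ctrl: float
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_ctrl) or self.sigma_ctrl <= 0:
            raise ValidationError("sigma_ctrl must be finite and > 0")


@dataclass
class NlfcMatrix:
    """Guide x cell-line nLFC values plus the |nLFC|>1 significance mask."""

    values: pd.DataFrame  # index guide, columns cell lines
    significant: pd.Series  # bool per guide
    params: dict[str, NlfcParams]  # per cell line


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: int
    label: str
    k: int  # label members inside the cluster
    K: int  # label members among all clustered guides
    n: int  # cluster size
    N: int  # all clustered guides
    p_value: float


def compute_nlfc(
    lfc: pd.Series,
    negative_ids: Sequence[str],
    positive_ids: Sequence[str],
    epsilon: float = 0.05,
) -> tuple[pd.Series, NlfcParams]:
    """Control-calibrated nLFC for one cell line.

    mu_neg is estimated from the negative controls alone; sigma_ctrl is the
    sample (n-1) standard deviation of the pooled positive and negative
    control LFCs, capturing the assay's full dynamic range.
    """
    neg = lfc.loc[lfc.index.intersection(negative_ids)].dropna()
    pos = lfc.loc[lfc.index.intersection(positive_ids)].dropna()
    if len(neg) == 0 or len(pos) == 0:
        raise ValidationError("nLFC needs non-empty negative and positive control sets")
    mu_neg = float(neg.mean())
    pooled = np.concatenate([neg.values, pos.values])
    sigma = float(np.std(pooled, ddof=1))
    params = NlfcParams(mu_neg=mu_neg, sigma_ctrl=sigma, epsilon=epsilon)
    return (lfc - mu_neg) / sigma, params


def assemble_nlfc_matrix(
    nlfc_by_cell_line: Mapping[str, pd.Series],
    params_by_cell_line: Optional[Mapping[str, NlfcParams]] = None,
    threshold: float = 1.0,
) -> NlfcMatrix:
    """Join per-cell-line nLFC series into a complete guide x cell-line matrix.

    Guides missing from any cell line (e.g. removed by that screen's
    zero-count filter) are excluded: Euclidean/Ward geometry is undefined on
    missing cells and imputation would invent signal.
    """
    if len(nlfc_by_cell_line) < 2:
        raise ValidationError("harmonization needs at least 2 cell lines")
    frame = pd.DataFrame(dict(nlfc_by_cell_line)).dropna()
    common = frame.index
    dropped = {cl: len(s) - len(common) for cl, s in nlfc_by_cell_line.items()}
    logger.info("nLFC matrix: %d shared guides (dropped per line: %s)",
                len(common), dropped)
    if len(common) == 0:
        raise ValidationError("no guides shared across all cell lines")
    sig = select_significant(frame, threshold=threshold)
    mask = pd.Series(frame.index.isin(sig), index=frame.index, name="significant")
    return NlfcMatrix(
        values=frame,
        significant=mask,
        params=dict(params_by_cell_line or {}),
    )


def select_significant(matrix: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Guides with |nLFC| strictly greater than the threshold in >= 1 cell line."""
    mask = (matrix.abs() > threshold).any(axis=1)
    return matrix.index[mask]


def ward_cluster(
    matrix: pd.DataFrame,
    k_clusters: int = 4,
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative Ward clustering in cell-line space, cut to k clusters.

    Merges minimize the Ward variance increase under Euclidean distance;
    ties break by scipy's deterministic ordering, so labels are reproducible
    given the input row order.  Cluster ids are renumbered 1..k by first
    appearance in the input order.
    """
    n = len(matrix)
    if k_clusters > n:
        raise ValidationError(f"k_clusters={k_clusters} exceeds {n} rows")
    Z = hierarchy.linkage(matrix.values, method="ward", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[i] = relabel[c]
    return pd.Series(labels, index=matrix.index, name="cluster"), Z


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cluster_enrichment(
    labels: pd.Series,
    categories: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each category in each cluster.

    For cluster of size n holding k of the K category members among all N
    clustered guides, p = sum_{j>=k} C(K,j) C(N-K,n-j) / C(N,n).  Raw
    p-values are reported (flagged at ``alpha``) together with a
    Benjamini-Hochberg adjusted column for convenience.
    """
    cats = categories.loc[labels.index]
    N = len(labels)
    rows = []
    for cluster_id in sorted(labels.unique()):
        in_cluster = labels == cluster_id
        n = int(in_cluster.sum())
        for label in sorted(cats.dropna().unique()):
            K = int((cats == label).sum())
            k = int((in_cluster & (cats == label)).sum())
            p = hypergeom_upper_tail(k, N, K, n)
            rows.append(
                EnrichmentResult(cluster_id=int(cluster_id), label=str(label),
                                 k=k, K=K, n=n, N=N, p_value=p)
            )
    df = pd.DataFrame(
        {
            "cluster": [r.cluster_id for r in rows],
            "label": [r.label for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    if len(df):
        df["significant"] = df["p_value"] < alpha
        df["p_adj_bh"] = multipletests(df["p_value"].values, method="fdr_bh")[1]
    return df


def harmonize(
    lfc_by_cell_line: Mapping[str, pd.Series],
    negative_ids: Sequence[str],
    positive_ids: Sequence[str],
    categories: Optional[pd.Series] = None,
    k_clusters: int = 4,
    threshold: float = 1.0,
) -> dict:
    """Full harmonization pass over >= 2 cell lines.

    Returns a dict with the complete nLFC matrix, the significant subset,
    cluster labels, the linkage matrix and (when ``categories`` is given)
    the per-cluster enrichment table.
    """
    nlfc: dict[str, pd.Series] = {}
    params: dict[str, NlfcParams] = {}
    for cell_line, lfc in lfc_by_cell_line.items():
        nlfc[cell_line], params[cell_line] = compute_nlfc(
            lfc, negative_ids, positive_ids
        )
    matrix = assemble_nlfc_matrix(nlfc, params, threshold=threshold)
    selected = matrix.values.loc[matrix.significant]
    if len(selected) < k_clusters:
        raise ValidationError(
            f"only {len(selected)} significant guides for k={k_clusters} clusters"
        )
    labels, linkage = ward_cluster(selected, k_clusters)
    result = {
        "nlfc": matrix,
        "selected": selected,
        "labels": labels,
        "linkage": linkage,
        "enrichment": None,
    }
    if categories is not None:
        cats = categories.reindex(labels.index)
        result["enrichment"] = cluster_enrichment(labels, cats)
    return result
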