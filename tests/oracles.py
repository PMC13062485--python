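"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own code paths: consequences are
called by mutating the full transcript string and re-translating the whole
protein; AUC is pairwise counting; hypergeometric and Fisher tails are
exact combinatorial sums; Ward clustering is a direct Lance-Williams
agglomeration over cluster means.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from Bio.Seq import Seq

SEVERITY_ORDER = ["empty_window", "synonymous", "non_coding", "missense",
                  "nonsense", "splice"]


def _apply_subs(sequence: str, substitutions) -> str:
    seq = list(sequence)
    for sub in substitutions:
        assert seq[sub.position] == sub.ref
        seq[sub.position] = sub.alt
    return "".join(seq)


def _spliced_cds(sequence: str, tx) -> str:
    out = []
    for start, end in tx.exons:
        lo, hi = max(start, tx.cds_start), min(end, tx.cds_end)
        if lo < hi:
            out.append(sequence[lo:hi])
    return "".join(out)


def oracle_call_consequence(substitutions, tx) -> str:
    """Whole-protein re-translation oracle for one outcome on one transcript."""
    if not tx.is_coding:
        return "non_coding"
    mutated = _apply_subs(tx.sequence, substitutions)
    # splice: any junction dinucleotide (donor GT / acceptor AG) changed
    for (_, e1), (s2, _) in zip(tx.exons, tx.exons[1:]):
        if mutated[e1:e1 + 2] != tx.sequence[e1:e1 + 2]:
            return "splice"
        if mutated[s2 - 2:s2] != tx.sequence[s2 - 2:s2]:
            return "splice"
    ref_cds = _spliced_cds(tx.sequence, tx)
    mut_cds = _spliced_cds(mutated, tx)
    if mut_cds[:3] != ref_cds[:3]:
        return "nonsense"  # first-codon rule
    n = len(ref_cds) - len(ref_cds) % 3
    p_ref = str(Seq(ref_cds[:n]).translate())
    p_mut = str(Seq(mut_cds[:n]).translate())
    if any(a != "*" and b == "*" for a, b in zip(p_ref, p_mut)):
        return "nonsense"
    if p_ref != p_mut:
        return "missense"
    return "synonymous"


def oracle_classify(guide, transcripts, p_min=3, p_max=8) -> str:
    """Guide-level oracle: enumerate subsets independently, collapse severity."""
    from bescreen.edit_annotation import Substitution

    positions = [p for p in range(p_min, p_max + 1) if guide.protospacer[p - 1] == "C"]
    if not positions:
        return "empty_window"
    placed = [transcripts[pl.transcript_id] for pl in guide.placements]
    coding = [(pl, tx) for pl, tx in zip(guide.placements, placed) if tx.is_coding]
    if not coding:
        return "non_coding"
    best = "synonymous"
    for size in range(1, len(positions) + 1):
        for subset in itertools.combinations(positions, size):
            for pl, tx in coding:
                subs = []
                for p in subset:
                    if pl.strand == "sense":
                        subs.append(Substitution(pl.offset + p - 1, "C", "T"))
                    else:
                        subs.append(Substitution(pl.offset + 20 - p, "G", "A"))
                cat = oracle_call_consequence(subs, tx)
                if SEVERITY_ORDER.index(cat) > SEVERITY_ORDER.index(best):
                    best = cat
    return best


def pairwise_auc(positive, negative) -> float:
    """AUC by direct pair counting with half-credit ties (higher = positive)."""
    wins = ties = 0
    for p in positive:
        for n in negative:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(positive) * len(negative))


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P(X >= k) by combinatorial summation."""
    total = comb(N, n)
    s = 0
    for j in range(k, min(K, n) + 1):
        s += comb(K, j) * comb(N - K, n - j)
    return s / total


def fisher_greater(table) -> float:
    """One-sided (enrichment) Fisher p by exhaustive table enumeration."""
    (a, b), (c, d) = table
    N, K, n = a + b + c + d, a + b, a + c
    return hypergeom_tail(a, N, K, n)


def brute_ward_partition(X: np.ndarray, k: int) -> list[set[int]]:
    """Direct Ward agglomeration; returns the k-cluster partition."""
    clusters = [{i} for i in range(len(X))]

    def ward_dist(A, B):
        ma = X[sorted(A)].mean(axis=0)
        mb = X[sorted(B)].mean(axis=0)
        return len(A) * len(B) / (len(A) + len(B)) * float(((ma - mb) ** 2).sum())

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = ward_dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return clusters


def longhand_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
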