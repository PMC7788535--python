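"""GSEA similarity baseline for MOA recovery.

The comparison method against which the classifier is benchmarked:

1. each signature column is turned into a gene ranking (most up-regulated
   first);
2. a compound's rankings are Borda-merged (mean rank, deterministic
   gene-id tie-break) into one "optimal signature" ranking;
3. the top/bottom m = 20 landmark genes of each compound are tested for
   enrichment in the other compound's ranking with an unweighted
   Kolmogorov-Smirnov running statistic, averaged symmetrically into a
   similarity in [-1, 1];
4. positive-positive compound pairs are true positives and
   positive-negative pairs false positives; ranking all pairs by
   similarity yields ROC/PRC curves and the benchmark AUROC/AP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .io import CompoundLabelSet, SignatureMatrix, SignatureMeta, ValidationError

__all__ = [
    "GeneRanking",
    "signature_to_ranking",
    "borda_merge",
    "set_enrichment",
    "pairwise_similarity",
    "benchmark",
]

DEFAULT_TOP_GENES = 20


@dataclass(frozen=True)
class GeneRanking:
    """Ordered gene list, most up-regulated (rank 1) first."""

    compound_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranking contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, m: int) -> set[str]:
        return set(self.genes[:m])

    def bottom(self, m: int) -> set[str]:
        return set(self.genes[-m:])


def signature_to_ranking(
    gene_ids: list[str], zscores: np.ndarray, compound_id: str = ""
) -> GeneRanking:
    """Rank genes by descending z-score; ties break to ascending gene id."""
    z = np.asarray(zscores, dtype=float)
    if not np.isfinite(z).all():
        raise ValidationError("z-scores contain non-finite values")
    order = sorted(range(len(gene_ids)), key=lambda i: (-z[i], gene_ids[i]))
    return GeneRanking(compound_id, tuple(gene_ids[i] for i in order))


def borda_merge(rankings: list[GeneRanking], compound_id: str | None = None) -> GeneRanking:
    """Merge rankings by mean rank (Borda), ties by ascending gene id."""
    if not rankings:
        raise ValidationError("no rankings to merge")
    universe = set(rankings[0].genes)
    for r in rankings[1:]:
        if set(r.genes) != universe:
            raise ValidationError("rankings cover different gene sets")
    mean_rank: dict[str, float] = {g: 0.0 for g in universe}
    for r in rankings:
        for pos, g in enumerate(r.genes, start=1):
            mean_rank[g] += pos
    k = len(rankings)
    merged = sorted(universe, key=lambda g: (mean_rank[g] / k, g))
    cid = compound_id if compound_id is not None else rankings[0].compound_id
    return GeneRanking(cid, tuple(merged))


def set_enrichment(gene_set: set[str], ranking: GeneRanking) -> float:
    """Signed maximum of the unweighted KS running statistic.

    Walking the ranking, the running sum steps +1/m at members of
    ``gene_set`` and -1/(G-m) at non-members; the return value is the
    deviation of largest magnitude (positive if the set concentrates at the
    top, negative at the bottom; 0 if the two excursions tie exactly).
    """
    G = len(ranking)
    m = len(gene_set)
    if m == 0 or m >= G:
        raise ValidationError("gene set must be a non-empty strict subset of the ranking")
    extra = gene_set - set(ranking.genes)
    if extra:
        raise ValidationError(f"genes not in ranking: {sorted(extra)[:5]}")
    member = np.fromiter((g in gene_set for g in ranking.genes), dtype=bool, count=G)
    steps = np.where(member, 1.0 / m, -1.0 / (G - m))
    running = np.cumsum(steps)
    a = float(running.max())  # largest excursion towards the top
    b = float(-running.min())  # largest excursion towards the bottom
    if a > b:
        return a
    if b > a:
        return -b
    return 0.0


def pairwise_similarity(a: GeneRanking, b: GeneRanking, m: int = DEFAULT_TOP_GENES) -> float:
    """Symmetric up/down enrichment similarity between two rankings.

    s(a, b) = [ES(up_a in b) - ES(down_a in b) + ES(up_b in a) - ES(down_b in a)] / 4,
    where up/down are the top/bottom m genes; s is symmetric and in [-1, 1].
    """
    if set(a.genes) != set(b.genes):
        raise ValidationError("rankings cover different gene universes")
    if 2 * m > len(a):
        raise ValidationError(f"m={m} too large for {len(a)} genes")
    s = (
        set_enrichment(a.top(m), b)
        - set_enrichment(a.bottom(m), b)
        + set_enrichment(b.top(m), a)
        - set_enrichment(b.bottom(m), a)
    )
    return float(s / 4.0)


def compound_rankings(
    matrix: SignatureMatrix, meta: SignatureMeta, compounds: set[str]
) -> dict[str, GeneRanking]:
    """Borda-merged ranking for each compound from all of its signatures."""
    idx = meta.indexed()
    out: dict[str, GeneRanking] = {}
    for comp in sorted(compounds):
        sigs = idx.index[idx["compound_id"] == comp].tolist()
        sigs = [s for s in sigs if s in set(matrix.sig_ids)]
        if not sigs:
            continue
        rankings = [
            signature_to_ranking(matrix.gene_ids, matrix.column(s), comp) for s in sigs
        ]
        out[comp] = borda_merge(rankings, compound_id=comp)
    return out


def benchmark(
    matrix: SignatureMatrix,
    meta: SignatureMeta,
    labels: CompoundLabelSet,
    m: int = DEFAULT_TOP_GENES,
) -> tuple[float, float, pd.DataFrame]:
    """Score MOA recovery of the GSEA similarity.

    Builds one merged ranking per labeled compound, computes pairwise
    similarities for all positive-positive and positive-negative compound
    pairs, and returns (AUROC, AP, pair table) with positive-positive pairs
    as true positives.
    """
    if len(labels.positives) < 2:
        raise ValidationError("benchmark needs at least 2 positive compounds")
    rankings = compound_rankings(matrix, meta, labels.positives | labels.negatives)
    pos = sorted(c for c in labels.positives if c in rankings)
    neg = sorted(c for c in labels.negatives if c in rankings)
    if len(pos) < 2:
        raise ValidationError("fewer than 2 positive compounds have signatures")
    rows = []
    for i, a in enumerate(pos):
        for b in pos[i + 1 :]:
            rows.append((a, b, pairwise_similarity(rankings[a], rankings[b], m), 1))
        for b in neg:
            rows.append((a, b, pairwise_similarity(rankings[a], rankings[b], m), 0))
    pairs = pd.DataFrame(rows, columns=["compound_a", "compound_b", "similarity", "label"])
    pairs["label_name"] = np.where(pairs["label"] == 1, "true_positive", "false_positive")
    auroc = metrics.auroc(pairs["similarity"], pairs["label"])
    ap = metrics.average_precision(pairs["similarity"], pairs["label"])
    return auroc, ap, pairs
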