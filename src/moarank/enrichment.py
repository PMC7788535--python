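"""Compound-level enrichment ranking of classifier scores.

A trained MOA classifier assigns each signature a positive-class
probability.  Because most compounds have several signatures, per-signature
probabilities are translated into one connectivity-map-style enrichment
score (ES) per compound: signatures are ranked by descending probability
(rank 1 = most positive-like) and a signed Kolmogorov-Smirnov maximum
deviation measures whether a compound's k signatures concentrate at the top
of the list of n scored signatures.  With the compound's sorted ranks
R(1) < ... < R(k),

    a = max_i [ i/k - R(i)/n ]        (greatest "hit" excess)
    b = max_i [ R(i)/n - (i-1)/k ]    (greatest "miss" deficit)

and ES = a if a > b, -b if b > a, 0 on a tie.  Significance comes from a
permutation null: k distinct ranks drawn uniformly from [1, n], 1000
repetitions by default, p = frequency of null ES >= observed ES.  Compounds
pass the final filter when p < 0.05 and they have more than 4 replicate
signatures; passing compounds are ranked by descending ES.

Two literal-reading modes are provided for comparison with the published
formulas: ``literal_eq2`` uses the printed miss-deviation denominator
(R(i)/k instead of R(i)/n, which can exceed 1), and ``literal_direction``
uses p = frequency of null ES < observed ES (which would assign large p to
strongly enriched compounds).  Neither is the default; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SignatureMeta, ValidationError

__all__ = [
    "RankVector",
    "EnrichmentResult",
    "ranks_from_scores",
    "enrichment_score",
    "permutation_pvalue",
    "rank_predictions",
    "passes_filter",
    "results_to_frame",
]

P_THRESHOLD = 0.05
MIN_REPLICATES = 5  # "more than 4" replicate signatures


def passes_filter(p_value: float, k: int) -> bool:
    """Final-list filter: permutation p below 0.05 AND at least 5 replicates."""
    return (p_value < P_THRESHOLD) and (k >= MIN_REPLICATES)


@dataclass(frozen=True)
class RankVector:
    """Ranks of one compound's signatures within the full scored list.

    Attributes
    ----------
    compound_id : str
    n : int
        Total number of scored signatures.
    R : tuple of int
        This compound's k ranks, strictly increasing, each in [1, n].
    """

    compound_id: str
    n: int
    R: tuple[int, ...]

    def __post_init__(self) -> None:
        R = tuple(int(r) for r in self.R)
        object.__setattr__(self, "R", R)
        if not 1 <= len(R) <= self.n:
            raise ValidationError(f"{self.compound_id}: need 1 <= k <= n")
        if any(r2 <= r1 for r1, r2 in zip(R, R[1:])):
            raise ValidationError(f"{self.compound_id}: ranks must be strictly increasing")
        if R[0] < 1 or R[-1] > self.n:
            raise ValidationError(f"{self.compound_id}: ranks must lie in [1, n]")

    @property
    def k(self) -> int:
        return len(self.R)


@dataclass
class EnrichmentResult:
    compound_id: str
    es: float
    p_value: float
    k: int
    passes_filter: bool
    rank: int | None  # None = unranked (failed filter)


def ranks_from_scores(
    score_table: dict[str, float] | pd.Series,
    meta: SignatureMeta,
    exclude_compounds: set[str] | None = None,
) -> list[RankVector]:
    """Rank scored signatures and group ranks by compound.

    Signatures are sorted by descending probability (rank 1 = highest), ties
    broken by ascending sig_id.  Signatures of ``exclude_compounds``
    (typically the training set) are removed before ranking, so ``n`` counts
    only the retained signatures.
    """
    if isinstance(score_table, dict):
        score_table = pd.Series(score_table)
    exclude = exclude_compounds or set()
    idx = meta.indexed()
    missing = [s for s in score_table.index if s not in idx.index]
    if missing:
        raise ValidationError(f"scored signatures without metadata: {missing[:5]}")
    compounds = idx.loc[score_table.index, "compound_id"]
    keep = ~compounds.isin(exclude)
    scores = score_table[keep]
    if scores.empty:
        raise ValidationError("no signatures remain after exclusion")
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    rank_of = {sig: i + 1 for i, sig in enumerate(order)}
    n = len(order)
    by_compound: dict[str, list[int]] = {}
    for sig in order:
        by_compound.setdefault(compounds[sig], []).append(rank_of[sig])
    return [
        RankVector(compound_id=c, n=n, R=tuple(sorted(r)))
        for c, r in sorted(by_compound.items())
    ]


def _es_from_ranks(R: np.ndarray, n: int, k: int, literal_eq2: bool = False) -> float:
    """ES for one sorted rank array; vectorized over i."""
    i = np.arange(1, k + 1)
    a = np.max(i / k - R / n)
    miss = (R / k if literal_eq2 else R / n) - (i - 1) / k
    b = np.max(miss)
    if a > b:
        return float(a)
    if b > a:
        return float(-b)
    return 0.0


def enrichment_score(rv: RankVector, literal_eq2: bool = False) -> float:
    """Signed KS-style enrichment score in [-1, 1] (default mode)."""
    return _es_from_ranks(np.asarray(rv.R, dtype=float), rv.n, rv.k, literal_eq2)


def permutation_pvalue(
    rv: RankVector,
    repetitions: int = 1000,
    seed: int | np.random.Generator = 0,
    literal_eq2: bool = False,
    literal_direction: bool = False,
) -> float:
    """Permutation p-value of a compound's enrichment score.

    Each repetition draws k distinct ranks uniformly from [1, n] and
    computes the null ES.  Default direction: p = frequency of null
    ES >= observed ES (no smoothing; p can be 0 at finite repetitions).
    """
    if repetitions < 1:
        raise ValidationError("repetitions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es_obs = enrichment_score(rv, literal_eq2=literal_eq2)
    n, k = rv.n, rv.k
    i = np.arange(1, k + 1, dtype=float)
    # all null rank sets at once: k distinct ranks per row via partial argsort
    u = rng.random((repetitions, n))
    draws = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1).astype(float) + 1.0
    a = np.max(i / k - draws / n, axis=1)
    miss = (draws / k if literal_eq2 else draws / n) - (i - 1.0) / k
    b = np.max(miss, axis=1)
    null = np.where(a > b, a, np.where(b > a, -b, 0.0))
    if literal_direction:
        return float(np.mean(null < es_obs))
    return float(np.mean(null >= es_obs))


def rank_predictions(
    rank_vectors: list[RankVector],
    repetitions: int = 1000,
    seed: int = 0,
    literal_eq2: bool = False,
    literal_direction: bool = False,
) -> list[EnrichmentResult]:
    """Score, test, filter and rank every compound.

    A compound passes the filter iff its permutation p-value is below 0.05
    and it has at least 5 replicate signatures; passing compounds are ranked
    by descending ES (ties by ascending compound id), the rest keep
    ``rank=None``.
    """
    if rank_vectors and len({rv.n for rv in rank_vectors}) != 1:
        raise ValidationError("all rank vectors must share the same n")
    rng = np.random.default_rng(seed)
    results = []
    for rv in rank_vectors:
        es = enrichment_score(rv, literal_eq2=literal_eq2)
        p = permutation_pvalue(
            rv,
            repetitions=repetitions,
            seed=rng,
            literal_eq2=literal_eq2,
            literal_direction=literal_direction,
        )
        passes = passes_filter(p, rv.k)
        results.append(
            EnrichmentResult(
                compound_id=rv.compound_id,
                es=es,
                p_value=p,
                k=rv.k,
                passes_filter=passes,
                rank=None,
            )
        )
    passing = sorted(
        (r for r in results if r.passes_filter), key=lambda r: (-r.es, r.compound_id)
    )
    for pos, r in enumerate(passing, start=1):
        r.rank = pos
    results.sort(
        key=lambda r: (r.rank is None, r.rank if r.rank is not None else 0, -r.es, r.compound_id)
    )
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results as the output CSV schema."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "es": r.es,
                "p_value": r.p_value,
                "k": r.k,
                "passes_filter": r.passes_filter,
                "rank": r.rank if r.rank is not None else "",
            }
            for r in results
        ]
    )
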