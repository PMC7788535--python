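"""Training-set assembly and drug-level fold planning.

The compendium is first reduced to one representative signature per
(compound, cell line) pair — the signature with the highest mean Pearson
correlation to the compound's other signatures in that cell line.  Labeled
signatures are then assembled into a binary training set, and folds are
planned at *drug* granularity so no compound contributes signatures to both
the train and test side of a split.  The fold count K follows the positive
drug number N: K = N for 2 <= N <= 4, K = 5 for 5 <= N <= 9, K = 10 for
N >= 10; for N = 1 the single positive compound's signatures themselves are
partitioned into K = (number of positive signatures) folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CompoundLabelSet, SignatureMatrix, SignatureMeta, ValidationError

__all__ = [
    "TrainingSet",
    "FoldPlan",
    "select_representative",
    "reduce_compendium",
    "assemble",
    "plan_folds",
]

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class TrainingSet:
    """Labeled signatures for one MOA.

    entries: list of (sig_id, compound_id, label); feature_gene_ids defines
    the model input space (matrix gene order at assembly time).
    """

    moa_name: str
    entries: list[tuple[str, str, str]]
    feature_gene_ids: list[str]

    def __post_init__(self) -> None:
        sigs = [e[0] for e in self.entries]
        if len(set(sigs)) != len(sigs):
            raise ValidationError("a sig_id appears more than once in the training set")
        comp_label: dict[str, str] = {}
        for _, comp, label in self.entries:
            if label not in (POSITIVE, NEGATIVE):
                raise ValidationError(f"unknown label {label!r}")
            if comp_label.setdefault(comp, label) != label:
                raise ValidationError(f"compound {comp} carries both labels")
        labels = set(comp_label.values())
        if labels != {POSITIVE, NEGATIVE}:
            raise ValidationError("training set must contain both classes")

    @property
    def sig_ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if e[2] == POSITIVE else 0 for e in self.entries])

    def compounds(self, label: str | None = None) -> list[str]:
        seen: dict[str, None] = {}
        for _, comp, lab in self.entries:
            if label is None or lab == label:
                seen.setdefault(comp, None)
        return list(seen)

    def signatures_of(self, compound_id: str) -> list[str]:
        return [s for s, c, _ in self.entries if c == compound_id]


@dataclass
class FoldPlan:
    """Drug-disjoint K-fold partition.

    ``assignment`` maps compound_id -> fold index in [0, K).  In the N = 1
    degenerate case the lone positive compound's signatures are split
    instead, recorded in ``signature_assignment`` (negative compounds still
    split by compound).
    """

    K: int
    assignment: dict[str, int]
    signature_assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValidationError("need at least 2 folds")
        for fold in list(self.assignment.values()) + list(self.signature_assignment.values()):
            if not 0 <= fold < self.K:
                raise ValidationError(f"fold index {fold} outside [0, {self.K})")

    def test_mask(self, training_set: TrainingSet, fold: int) -> np.ndarray:
        """Boolean mask over training-set entries held out in ``fold``."""
        mask = np.zeros(len(training_set.entries), dtype=bool)
        for i, (sig, comp, _) in enumerate(training_set.entries):
            if sig in self.signature_assignment:
                mask[i] = self.signature_assignment[sig] == fold
            else:
                mask[i] = self.assignment[comp] == fold
        return mask

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, f) for c, f in sorted(self.assignment.items())]
        return pd.DataFrame(rows, columns=["compound_id", "fold"])


# ---------------------------------------------------------------------------


def select_representative(matrix: SignatureMatrix, sig_ids: list[str]) -> str:
    """Most representative signature of one compound in one cell line.

    Returns the signature whose mean Pearson correlation with the other
    listed signatures is maximal; ties (including the 2-signature case,
    where both means are equal by symmetry) break to the lexicographically
    smallest sig_id.  A zero-variance column contributes correlation 0.
    """
    if not sig_ids:
        raise ValidationError("empty signature list")
    if len(sig_ids) == 1:
        return sig_ids[0]
    sub = matrix.subset_signatures(list(sig_ids)).values
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance signature column; correlations treated as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    mean_corr = corr.sum(axis=1) / (len(sig_ids) - 1)
    best = max(range(len(sig_ids)), key=lambda j: (mean_corr[j], ), default=0)
    # deterministic tie-break on sig_id
    best_val = mean_corr.max()
    tied = [sig_ids[j] for j in range(len(sig_ids)) if mean_corr[j] == best_val]
    return min(tied)


def reduce_compendium(
    matrix: SignatureMatrix, meta: SignatureMeta
) -> tuple[SignatureMatrix, SignatureMeta]:
    """Keep one representative signature per (compound, cell line) pair."""
    df = meta.table
    keep: list[str] = []
    for (_, _), group in df.groupby(["compound_id", "cell_line"], sort=False):
        sigs = group["sig_id"].tolist()
        keep.append(select_representative(matrix, sigs))
    keep_set = set(keep)
    ordered = [s for s in matrix.sig_ids if s in keep_set]
    return matrix.subset_signatures(ordered), meta.subset(ordered)


def assemble(
    matrix: SignatureMatrix,
    meta: SignatureMeta,
    labels: CompoundLabelSet,
    cell_lines: set[str] | None = None,
) -> TrainingSet:
    """Collect the labeled signatures into a training set.

    All signatures of each labeled compound enter with the compound's
    label, optionally restricted to ``cell_lines``.  Labeled compounds with
    no signatures are reported and skipped; it is an error if no positive
    signature remains.
    """
    df = meta.table
    if cell_lines is not None:
        df = df[df["cell_line"].isin(set(cell_lines))]
    in_matrix = set(matrix.sig_ids)
    df = df[df["sig_id"].isin(in_matrix)]
    entries: list[tuple[str, str, str]] = []
    present: set[str] = set()
    for sig, comp in zip(df["sig_id"], df["compound_id"]):
        if comp in labels.positives:
            entries.append((sig, comp, POSITIVE))
            present.add(comp)
        elif comp in labels.negatives:
            entries.append((sig, comp, NEGATIVE))
            present.add(comp)
    missing = (labels.positives | labels.negatives) - present
    if not (labels.positives & present):
        raise ValidationError(
            f"no positive signatures after filtering; missing compounds: "
            f"{sorted(labels.positives - present)}"
            + (f" (cell filter {sorted(cell_lines)})" if cell_lines else "")
        )
    if missing:
        warnings.warn(f"assemble: {len(missing)} labeled compound(s) have no signatures")
    order = {s: j for j, s in enumerate(matrix.sig_ids)}
    entries.sort(key=lambda e: order[e[0]])
    return TrainingSet(
        moa_name=labels.moa_name,
        entries=entries,
        feature_gene_ids=list(matrix.gene_ids),
    )


def fold_count(n_positive_drugs: int, n_positive_signatures: int | None = None) -> int:
    """The K rule: K=N for N in [2,4]; K=5 for N in [5,9]; K=10 for N>=10;
    for N=1, K = number of positive signatures."""
    n = n_positive_drugs
    if n < 1:
        raise ValidationError("need at least one positive drug")
    if n == 1:
        if not n_positive_signatures or n_positive_signatures < 2:
            raise ValidationError("N=1 requires >= 2 positive signatures")
        return n_positive_signatures
    if n <= 4:
        return n
    if n <= 9:
        return 5
    return 10


def _partition(items: list[str], K: int, rng: np.random.Generator) -> dict[str, int]:
    """Random partition into K near-equal groups (sizes differ by <= 1)."""
    items = list(items)
    perm = rng.permutation(len(items))
    out: dict[str, int] = {}
    for pos, idx in enumerate(perm):
        out[items[idx]] = pos % K
    return out


def plan_folds(training_set: TrainingSet, seed: int = 0) -> FoldPlan:
    """Stratified drug-level K-fold plan, reproducible under ``seed``.

    Positives and negatives are partitioned independently into K near-equal
    compound groups; fold i pairs positive group i with negative group i.
    """
    rng = np.random.default_rng(seed)
    positives = sorted(training_set.compounds(POSITIVE))
    negatives = sorted(training_set.compounds(NEGATIVE))
    n_pos = len(positives)
    if n_pos == 1:
        pos_sigs = sorted(training_set.signatures_of(positives[0]))
        K = fold_count(1, len(pos_sigs))
        sig_assignment = _partition(pos_sigs, K, rng)
        assignment = _partition(negatives, K, rng)
        return FoldPlan(K=K, assignment=assignment, signature_assignment=sig_assignment)
    K = fold_count(n_pos)
    assignment = _partition(positives, K, rng)
    assignment.update(_partition(negatives, K, rng))
    return FoldPlan(K=K, assignment=assignment)
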