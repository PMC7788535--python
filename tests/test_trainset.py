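import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from moarank.io import CompoundLabelSet, SignatureMatrix, SignatureMeta, ValidationError
from moarank.trainset import (
    FoldPlan,
    TrainingSet,
    assemble,
    fold_count,
    plan_folds,
    reduce_compendium,
    select_representative,
)


def matrix_from_columns(cols: dict[str, np.ndarray]) -> SignatureMatrix:
    sigs = list(cols)
    values = np.column_stack([cols[s] for s in sigs])
    return SignatureMatrix([f"g{i}" for i in range(values.shape[0])], sigs, values)


def correlated_triplet():
    """Three vectors with pairwise correlations ~ (0.8, 0.6, 0.2) between
    (s1,s2), (s1,s3), (s2,s3), built by Cholesky factorization, so s1 has
    the highest mean correlation (0.7 vs 0.5 vs 0.4)."""
    target = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.2], [0.6, 0.2, 1.0]])
    L = np.linalg.cholesky(target)
    rng = np.random.default_rng(7)
    z = rng.standard_normal((5000, 3))
    # orthonormal columns -> realized correlations equal the target exactly
    q, _ = np.linalg.qr(z - z.mean(axis=0))
    x = (L @ q.T) * 10.0
    return {"s1": x[0], "s2": x[1], "s3": x[2]}


class TestSelectRepresentative:
    def test_single_signature_identity(self, small_matrix):
        assert select_representative(small_matrix, ["s2"]) == "s2"

    def test_highest_mean_correlation_wins(self):
        cols = correlated_triplet()
        m = matrix_from_columns(cols)
        # oracle: brute-force mean pairwise Pearson correlation
        sigs = list(cols)
        corr = np.corrcoef(np.column_stack([cols[s] for s in sigs]).T)
        mean_corr = (corr.sum(axis=1) - 1.0) / (len(sigs) - 1)
        expected = sigs[int(np.argmax(mean_corr))]
        assert expected == "s1"  # mean 0.85 vs 0.5 vs 0.45 by construction
        assert select_representative(m, sigs) == expected

    def test_two_signatures_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(1)
        m = matrix_from_columns({"sb": rng.standard_normal(20), "sa": rng.standard_normal(20)})
        assert select_representative(m, ["sb", "sa"]) == "sa"

    def test_zero_variance_column_warns(self):
        m = matrix_from_columns(
            {"s1": np.zeros(10), "s2": np.arange(10.0), "s3": np.arange(10.0) + 0.5}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            rep = select_representative(m, ["s1", "s2", "s3"])
        assert rep in {"s2", "s3"}

    @settings(max_examples=25, deadline=None)
    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_oracle_equivalence_random_matrices(self, n_sigs, seed):
        rng = np.random.default_rng(seed)
        cols = {f"s{i:02d}": rng.standard_normal(30) for i in range(n_sigs)}
        m = matrix_from_columns(cols)
        sigs = sorted(cols)
        mean_corr = []
        for s in sigs:
            others = [
                float(np.corrcoef(cols[s], cols[o])[0, 1]) for o in sigs if o != s
            ]
            mean_corr.append(sum(others) / len(others))
        best = max(mean_corr)
        tied = [sigs[j] for j in range(n_sigs) if mean_corr[j] == best]
        assert select_representative(m, sigs) in tied
        if len(tied) == 1:
            assert select_representative(m, sigs) == tied[0]


class TestReduceCompendium:
    def build(self, spec, seed=0):
        """spec: list of (compound, cell, n_replicates)."""
        rng = np.random.default_rng(seed)
        rows, cols = [], {}
        for comp, cell, n in spec:
            for r in range(n):
                sig = f"{comp}:{cell}:r{r}"
                cols[sig] = rng.standard_normal(25)
                rows.append({"sig_id": sig, "compound_id": comp, "cell_line": cell})
        return matrix_from_columns(cols), SignatureMeta(pd.DataFrame(rows))

    def test_one_per_compound_cell(self):
        m, meta = self.build([("A", "X", 3), ("A", "Y", 2)])
        rm, rmeta = reduce_compendium(m, meta)
        assert rm.n_signatures == 2
        assert set(rmeta.table["cell_line"]) == {"X", "Y"}

    def test_counting_5x2x3(self):
        spec = [(f"c{i}", cell, 3) for i in range(5) for cell in ("X", "Y")]
        m, meta = self.build(spec)
        rm, _ = reduce_compendium(m, meta)
        assert rm.n_signatures == 10

    def test_idempotent_and_never_grows(self):
        m, meta = self.build([("A", "X", 4), ("B", "X", 1), ("B", "Y", 2)])
        rm1, rmeta1 = reduce_compendium(m, meta)
        rm2, rmeta2 = reduce_compendium(rm1, rmeta1)
        assert rm2.sig_ids == rm1.sig_ids
        assert rm1.n_signatures <= m.n_signatures


class TestAssemble:
    def test_counts_and_labels(self):
        helper = TestReduceCompendium()
        spec = [("p1", "X", 1), ("p1", "Y", 1), ("p2", "X", 1), ("p2", "Y", 1),
                ("n1", "X", 1), ("n2", "X", 1), ("n3", "X", 1)]
        m, meta = helper.build(spec)
        labels = CompoundLabelSet({"p1", "p2"}, {"n1", "n2", "n3"})
        tr = assemble(m, meta, labels)
        assert len(tr.entries) == 7
        assert int(tr.labels.sum()) == 4

    def test_cell_filter_without_positives_errors(self):
        helper = TestReduceCompendium()
        m, meta = helper.build([("p1", "PC3", 1), ("n1", "MCF7", 1)])
        labels = CompoundLabelSet({"p1"}, {"n1"})
        with pytest.raises(ValidationError, match="no positive"):
            assemble(m, meta, labels, cell_lines={"MCF7"})

    def test_missing_compounds_skipped_with_warning(self):
        helper = TestReduceCompendium()
        m, meta = helper.build([("p1", "X", 1), ("n1", "X", 1)])
        labels = CompoundLabelSet({"p1", "ghost"}, {"n1"})
        with pytest.warns(UserWarning, match="no signatures"):
            tr = assemble(m, meta, labels)
        assert len(tr.entries) == 2


class TestTrainingSetInvariants:
    def test_both_classes_required(self):
        with pytest.raises(ValidationError, match="both classes"):
            TrainingSet("m", [("s1", "c1", "positive")], ["g1"])

    def test_conflicting_compound_label(self):
        with pytest.raises(ValidationError, match="both labels"):
            TrainingSet(
                "m",
                [("s1", "c1", "positive"), ("s2", "c1", "negative")],
                ["g1"],
            )


def toy_training_set(n_pos, n_neg, sigs_per_compound=2):
    entries = []
    for i in range(n_pos):
        for s in range(sigs_per_compound):
            entries.append((f"p{i}_{s}", f"cp{i}", "positive"))
    for i in range(n_neg):
        for s in range(sigs_per_compound):
            entries.append((f"n{i}_{s}", f"cn{i}", "negative"))
    return TrainingSet("m", entries, ["g1"])


class TestPlanFolds:
    @pytest.mark.parametrize(
        "n_pos,expected_k",
        [(2, 2), (3, 3), (4, 4), (5, 5), (7, 5), (9, 5), (10, 10), (12, 10), (30, 10)],
    )
    def test_k_rule(self, n_pos, expected_k):
        plan = plan_folds(toy_training_set(n_pos, 20), seed=0)
        assert plan.K == expected_k

    def test_n1_splits_signatures(self):
        tr = toy_training_set(1, 5, sigs_per_compound=8)
        plan = plan_folds(tr, seed=0)
        assert plan.K == 8
        assert set(plan.signature_assignment) == set(tr.signatures_of("cp0"))
        assert sorted(set(plan.signature_assignment.values())) == list(range(8))

    def test_partition_and_balance(self):
        tr = toy_training_set(12, 33)
        plan = plan_folds(tr, seed=3)
        pos = tr.compounds("positive")
        counts = [sum(plan.assignment[c] == f for c in pos) for f in range(plan.K)]
        assert sum(counts) == 12
        assert max(counts) - min(counts) <= 1
        neg_counts = [
            sum(plan.assignment[c] == f for c in tr.compounds("negative"))
            for f in range(plan.K)
        ]
        assert max(neg_counts) - min(neg_counts) <= 1

    def test_seed_reproducibility(self):
        tr = toy_training_set(7, 15)
        assert plan_folds(tr, seed=5).assignment == plan_folds(tr, seed=5).assignment
        assert plan_folds(tr, seed=5).assignment != plan_folds(tr, seed=6).assignment

    def test_drug_disjoint(self):
        tr = toy_training_set(6, 10, sigs_per_compound=3)
        plan = plan_folds(tr, seed=0)
        for fold in range(plan.K):
            mask = plan.test_mask(tr, fold)
            test_compounds = {tr.entries[i][1] for i in np.flatnonzero(mask)}
            train_compounds = {tr.entries[i][1] for i in np.flatnonzero(~mask)}
            assert not (test_compounds & train_compounds)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(2, 25), st.integers(1, 30), st.integers(0, 10_000))
    def test_property_k_rule_and_partition(self, n_pos, n_neg, seed):
        tr = toy_training_set(n_pos, n_neg)
        plan = plan_folds(tr, seed=seed)
        assert plan.K == fold_count(n_pos)
        assert set(plan.assignment) == set(tr.compounds())
        pos_counts = [
            sum(plan.assignment[c] == f for c in tr.compounds("positive"))
            for f in range(plan.K)
        ]
        assert max(pos_counts) - min(pos_counts) <= 1
        assert min(pos_counts) >= 1  # every fold holds out >= 1 positive compound

    def test_zero_positives_errors(self):
        with pytest.raises(ValidationError):
            fold_count(0)
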