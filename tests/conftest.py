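import numpy as np
import pandas as pd
import pytest

from moarank.classifier import ModelConfig
from moarank.io import CompoundLabelSet, SignatureMatrix, SignatureMeta
from moarank.synthdata import generate, scenario
from moarank import trainset as ts


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    sigs = [f"s{i}" for i in range(4)]
    return SignatureMatrix(genes, sigs, rng.standard_normal((6, 4)))


@pytest.fixture
def small_meta():
    return SignatureMeta(
        pd.DataFrame(
            {
                "sig_id": ["s0", "s1", "s2", "s3"],
                "compound_id": ["cA", "cA", "cB", "cC"],
                "cell_line": ["MCF7", "MCF7", "PC3", "PC3"],
                "dose": ["10uM"] * 4,
                "time": ["24h"] * 4,
            }
        )
    )


@pytest.fixture
def desk_config():
    """Reduced-size model settings used throughout the suite."""
    return ModelConfig(hidden_layers=(64, 32), iterations=300, batch_size=64, seed=0)


@pytest.fixture(scope="session")
def strong_data():
    """Strong-consistent scenario compendium, reduced, with its training set."""
    matrix, meta, truth, labels = generate(scenario("strong_consistent", seed=0))
    red_m, red_meta = ts.reduce_compendium(matrix, meta)
    training = ts.assemble(red_m, red_meta, labels["moa1"])
    return {
        "matrix": matrix,
        "meta": meta,
        "truth": truth,
        "labels": labels["moa1"],
        "red_matrix": red_m,
        "red_meta": red_meta,
        "training": training,
    }


def separable_set(n_pos=20, n_neg=60, n_genes=100, shift=2.0, seed=0):
    """Linearly separable toy problem: positives shifted +`shift` z on the
    first 50 genes."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = rng.standard_normal((n_genes, n))
    X[:50, :n_pos] += shift
    genes = [f"g{i}" for i in range(n_genes)]
    sigs = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    matrix = SignatureMatrix(genes, sigs, X)
    meta = SignatureMeta(
        pd.DataFrame(
            {
                "sig_id": sigs,
                "compound_id": [f"cp{i // 2}" for i in range(n_pos)]
                + [f"cn{i // 2}" for i in range(n_neg)],
                "cell_line": ["MCF7"] * n,
            }
        )
    )
    labels = CompoundLabelSet(
        positives={f"cp{i}" for i in range(n_pos // 2)},
        negatives={f"cn{i}" for i in range(n_neg // 2)},
        moa_name="toy",
    )
    training = ts.assemble(matrix, meta, labels)
    return matrix, meta, labels, training
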