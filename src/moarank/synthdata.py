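"""Synthetic L1000-like compendia with known MOA structure.

Every stage of the pipeline is testable without downloads by generating a
compendium that mimics the structure of a large perturbational z-score
resource: 978 landmark genes, several cell lines, replicate signatures per
compound, a group of positive compounds sharing one mechanism of action,
and many inert negative compounds.

Generative model, per signature (gene vector of z-scores):

    signature = effect + batch + noise

* every MOA draws a prototype effect vector — ``amplitude`` x a random sign
  on ``effect_genes`` randomly chosen genes, zero elsewhere;
* each compound in the MOA perturbs the prototype with its own Gaussian
  jitter (sd ``compound_effect_jitter_sd`` on all genes), modeling
  compound-specific off-target expression that can mask the shared MOA
  genes; the compound effect is zeroed in cell lines outside the MOA's
  ``expressing_cells`` (target not expressed there);
* ``batch`` is a Gaussian offset (sd ``batch_sd``) shared by all signatures
  on the same simulated plate group, modeling batch interference;
* ``noise`` is i.i.d. Gaussian per gene (sd ``noise_sd``, default 1.0 so
  values live on the z-score scale);
* negative compounds have zero effect.

Named scenarios provide the presets used throughout the test-suite and the
benchmark comparisons: ``strong_consistent``, ``cell_dependent``,
``weak_signal`` and ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CompoundLabelSet, SignatureMatrix, SignatureMeta, ValidationError

__all__ = ["MoaSpec", "SyntheticConfig", "GroundTruth", "generate", "scenario", "SCENARIOS"]


@dataclass
class MoaSpec:
    """One simulated mechanism of action."""

    name: str
    n_compounds: int
    effect_genes: int = 60
    amplitude: float = 2.0
    expressing_cells: list[str] | None = None  # None = all cell lines


@dataclass
class SyntheticConfig:
    n_genes: int = 978
    cell_lines: list[str] = field(default_factory=lambda: ["A375", "A549", "MCF7", "PC3"])
    moas: list[MoaSpec] = field(default_factory=lambda: [MoaSpec("moa1", 10)])
    n_negative_compounds: int = 200
    replicates_per_cell: int = 3
    batch_sd: float = 0.8
    noise_sd: float = 1.0
    compound_effect_jitter_sd: float = 0.8
    n_batches: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.replicates_per_cell < 1 or not self.cell_lines:
            raise ValidationError("counts must be >= 1 and cell_lines non-empty")
        if self.n_negative_compounds < 0:
            raise ValidationError("n_negative_compounds must be >= 0")
        if min(self.batch_sd, self.noise_sd, self.compound_effect_jitter_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")
        for moa in self.moas:
            if moa.n_compounds < 1:
                raise ValidationError(f"{moa.name}: n_compounds must be >= 1")
            if not 0 <= moa.effect_genes <= self.n_genes:
                raise ValidationError(f"{moa.name}: effect_genes must be <= n_genes")
            if moa.amplitude < 0:
                raise ValidationError(f"{moa.name}: amplitude must be >= 0")
            if moa.expressing_cells is not None and not set(moa.expressing_cells) <= set(
                self.cell_lines
            ):
                raise ValidationError(f"{moa.name}: expressing_cells not in cell_lines")


@dataclass
class GroundTruth:
    """What the generator actually did, keyed consistently with the metadata."""

    compound_moa: dict[str, str | None]
    moa_effects: dict[str, np.ndarray]
    moa_expressing_cells: dict[str, list[str]]
    signature_batch: dict[str, int]
    compound_effects: dict[str, np.ndarray]


def generate(
    config: SyntheticConfig,
) -> tuple[SignatureMatrix, SignatureMeta, GroundTruth, dict[str, CompoundLabelSet]]:
    """Draw one compendium; bitwise reproducible under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(G)]

    compound_moa: dict[str, str | None] = {}
    moa_effects: dict[str, np.ndarray] = {}
    moa_cells: dict[str, list[str]] = {}
    compound_effects: dict[str, np.ndarray] = {}

    for moa in config.moas:
        proto = np.zeros(G)
        idx = rng.choice(G, size=moa.effect_genes, replace=False)
        proto[idx] = moa.amplitude * rng.choice([-1.0, 1.0], size=moa.effect_genes)
        moa_effects[moa.name] = proto
        cells = list(moa.expressing_cells) if moa.expressing_cells is not None else list(
            config.cell_lines
        )
        moa_cells[moa.name] = cells
        for c in range(moa.n_compounds):
            comp = f"{moa.name}_cpd{c:03d}"
            compound_moa[comp] = moa.name
            jitter = rng.normal(0.0, config.compound_effect_jitter_sd, size=G)
            compound_effects[comp] = proto + jitter
    for c in range(config.n_negative_compounds):
        comp = f"neg_cpd{c:04d}"
        compound_moa[comp] = None
        compound_effects[comp] = np.zeros(G)

    batch_offsets = rng.normal(0.0, config.batch_sd, size=(config.n_batches, G))

    sig_rows = []
    columns = []
    sig_batch: dict[str, int] = {}
    for comp in compound_moa:
        moa_name = compound_moa[comp]
        expressing = moa_cells[moa_name] if moa_name else []
        for cell in config.cell_lines:
            active = (moa_name is None) or (cell in expressing)
            effect = compound_effects[comp] if (moa_name and active) else np.zeros(G)
            for rep in range(config.replicates_per_cell):
                sig_id = f"{comp}:{cell}:r{rep}"
                batch = int(rng.integers(config.n_batches))
                col = effect + batch_offsets[batch] + rng.normal(0.0, config.noise_sd, G)
                columns.append(col)
                sig_rows.append(
                    {
                        "sig_id": sig_id,
                        "compound_id": comp,
                        "cell_line": cell,
                        "dose": "10uM",
                        "time": "24h",
                    }
                )
                sig_batch[sig_id] = batch

    values = np.column_stack(columns)
    matrix = SignatureMatrix(gene_ids, [r["sig_id"] for r in sig_rows], values)
    meta = SignatureMeta(pd.DataFrame(sig_rows))
    truth = GroundTruth(
        compound_moa=compound_moa,
        moa_effects=moa_effects,
        moa_expressing_cells=moa_cells,
        signature_batch=sig_batch,
        compound_effects=compound_effects,
    )
    negatives = {c for c, m in compound_moa.items() if m is None}
    label_sets = {
        moa.name: CompoundLabelSet(
            positives={c for c, m in compound_moa.items() if m == moa.name},
            negatives=set(negatives),
            moa_name=moa.name,
        )
        for moa in config.moas
    }
    return matrix, meta, truth, label_sets


SCENARIOS = ("strong_consistent", "cell_dependent", "weak_signal", "null")


def scenario(name: str, seed: int = 0) -> SyntheticConfig:
    """Documented presets.

    * ``strong_consistent`` — amplitude 2.0, effect in every cell line:
      reproducible signatures with strong signal.
    * ``cell_dependent`` — amplitude 2.0 but the MOA target is expressed in
      only half the cell lines; signatures elsewhere are pure noise.
    * ``weak_signal`` — amplitude 0.5: low transcript signal.
    * ``null`` — amplitude 0: no transcriptional MOA at all.
    """
    base = SyntheticConfig(seed=seed)
    if name == "strong_consistent":
        base.moas = [MoaSpec("moa1", 10, amplitude=2.0)]
    elif name == "cell_dependent":
        base.moas = [
            MoaSpec("moa1", 10, amplitude=2.0, expressing_cells=base.cell_lines[: len(base.cell_lines) // 2])
        ]
    elif name == "weak_signal":
        base.moas = [MoaSpec("moa1", 10, amplitude=0.5)]
    elif name == "null":
        base.moas = [MoaSpec("moa1", 10, amplitude=0.0)]
    else:
        raise ValidationError(f"unknown scenario {name!r}; valid: {', '.join(SCENARIOS)}")
    return base
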