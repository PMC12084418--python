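"""Synthetic compendium generator with planted disease clusters and outliers.

The generator emulates the structure of a large multi-disease tumor RNA-seq
compendium: several disease groups of varying size (including rare diseases
of 1–3 samples), within-disease correlation induced by per-disease per-gene
expression shifts, zero inflation, and a focus sample carrying a handful of
strongly overexpressed (planted) genes.  Values are drawn directly on the
log2(TPM+1) scale:

    x[g, s] = max(0, base[g] + effect[d(s), g] + eps[g, s]),
    then set to 0 with probability ``zero_inflation``

with base ~ N(baseline_mean, baseline_sd), effect ~ N(0, disease_effect_sd)
per (disease, gene), and eps ~ N(0, noise_sd) per (gene, sample).  The
focus sample is drawn from its disease's model; each planted outlier gene
gets ``outlier_delta`` added on top of the (never zero-inflated) model
value, so a planted outlier is overexpressed by construction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CareValidationError, ExpressionCompendium, FocusSample

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_compendium",
    "simulate_read_records",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic compendium.

    Defaults describe the generator's reference conditions: 5 diseases of
    30 samples over 2,000 genes, baseline 3.0 ± 1.5 log2(TPM+1), disease
    shifts of sd 1.0, residual noise sd 0.5, 20% zero inflation, and 40
    planted outlier genes shifted by +6 log2 units in the focus sample.
    """

    n_diseases: int = 5
    samples_per_disease: list[int] = field(default_factory=lambda: [30] * 5)
    n_genes: int = 2000
    baseline_mean: float = 3.0
    baseline_sd: float = 1.5
    disease_effect_sd: float = 1.0
    noise_sd: float = 0.5
    outlier_genes: int = 40
    outlier_delta: float = 6.0
    zero_inflation: float = 0.2
    focus_disease_index: int = 0
    n_prior_focus_samples: int = 0
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_diseases < 1 or self.n_genes < 1:
            raise CareValidationError("n_diseases and n_genes must be >= 1")
        if len(self.samples_per_disease) != self.n_diseases:
            raise CareValidationError(
                "samples_per_disease must list one count per disease"
            )
        if any(n < 1 for n in self.samples_per_disease):
            raise CareValidationError("every disease needs >= 1 sample")
        if min(self.baseline_sd, self.disease_effect_sd, self.noise_sd) < 0:
            raise CareValidationError("standard deviations must be >= 0")
        if not 0 <= self.zero_inflation < 1:
            raise CareValidationError("zero_inflation must be in [0, 1)")
        if not 0 <= self.outlier_genes <= self.n_genes:
            raise CareValidationError("outlier_genes must be in [0, n_genes]")
        if not 0 <= self.focus_disease_index < self.n_diseases:
            raise CareValidationError("focus_disease_index out of range")
        if self.n_prior_focus_samples < 0:
            raise CareValidationError("n_prior_focus_samples must be >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground truth of a simulated compendium, for evaluating the pipeline."""

    planted_outlier_genes: list[str]
    focus_disease: str
    disease_assignment: dict[str, str]


def _disease_label(i: int) -> str:
    return f"disease_{i:02d}"


def simulate_compendium(
    config: SimulationConfig,
) -> tuple[ExpressionCompendium, FocusSample, SimulationTruth]:
    """Generate a compendium, a focus sample and the planted ground truth.

    The focus sample is not part of the compendium matrix (matching the
    comparator contract); ``n_prior_focus_samples`` > 0 injects additional
    samples of the focus disease labelled as prior tumors of the same
    patient, reproducing the rare-disease topology where the only
    same-diagnosis samples in the compendium are the patient's own.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    base = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    effects = rng.normal(
        0.0, config.disease_effect_sd, (config.n_diseases, config.n_genes)
    )

    sample_ids: list[str] = []
    diseases: list[str] = []
    cols: list[np.ndarray] = []

    def draw_sample(d: int) -> np.ndarray:
        eps = rng.normal(0.0, config.noise_sd, config.n_genes)
        x = np.maximum(0.0, base + effects[d] + eps)
        if config.zero_inflation > 0:
            x[rng.random(config.n_genes) < config.zero_inflation] = 0.0
        return x

    for d in range(config.n_diseases):
        for j in range(config.samples_per_disease[d]):
            sample_ids.append(f"{_disease_label(d)}_s{j:03d}")
            diseases.append(_disease_label(d))
            cols.append(draw_sample(d))

    focus_d = config.focus_disease_index
    for j in range(config.n_prior_focus_samples):
        sample_ids.append(f"focus_prior_s{j:02d}")
        diseases.append(_disease_label(focus_d))
        cols.append(draw_sample(focus_d))

    planted_idx = rng.choice(config.n_genes, size=config.outlier_genes, replace=False)
    planted = sorted(genes[i] for i in planted_idx)

    # Focus sample: model value without zero inflation on planted genes,
    # outlier_delta added on top.
    eps = rng.normal(0.0, config.noise_sd, config.n_genes)
    focus_vals = np.maximum(0.0, base + effects[focus_d] + eps)
    if config.zero_inflation > 0:
        mask = rng.random(config.n_genes) < config.zero_inflation
        mask[planted_idx] = False
        focus_vals[mask] = 0.0
    focus_vals[planted_idx] += config.outlier_delta

    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    metadata = pd.DataFrame(
        {"disease": diseases}, index=pd.Index(sample_ids, name="sample_id")
    )
    compendium = ExpressionCompendium(values, metadata).validate()
    focus = FocusSample(
        sample_id="focus_s01",
        expression=pd.Series(focus_vals, index=values.index),
        diagnosis=_disease_label(focus_d),
    ).validate()
    truth = SimulationTruth(
        planted_outlier_genes=planted,
        focus_disease=_disease_label(focus_d),
        disease_assignment=dict(zip(sample_ids, diseases)),
    )
    return compendium, focus, truth


def simulate_read_records(
    n_reads: int,
    p_mapped: float,
    p_exonic_given_mapped: float,
    p_duplicate: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-read QC flags for the MEND counter.

    Each read independently draws (mapped, exonic, duplicate); ``exonic``
    is forced False for unmapped reads.  Returns a DataFrame with columns
    ``read_id, mapped, exonic, duplicate``.
    """
    for name, p in [
        ("p_mapped", p_mapped),
        ("p_exonic_given_mapped", p_exonic_given_mapped),
        ("p_duplicate", p_duplicate),
    ]:
        if not 0 <= p <= 1:
            raise CareValidationError(f"{name} must be in [0, 1]")
    if n_reads < 0:
        raise CareValidationError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    mapped = rng.random(n_reads) < p_mapped
    exonic = mapped & (rng.random(n_reads) < p_exonic_given_mapped)
    duplicate = rng.random(n_reads) < p_duplicate
    return pd.DataFrame(
        {
            "read_id": [f"r{i:07d}" for i in range(n_reads)],
            "mapped": mapped,
            "exonic": exonic,
            "duplicate": duplicate,
        }
    )
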