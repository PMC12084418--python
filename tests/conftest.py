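import numpy as np
import pandas as pd
import pytest

from carekit import ExpressionCompendium, FocusSample


def make_compendium(values: np.ndarray, diseases: list[str],
                    genes=None, samples=None) -> ExpressionCompendium:
    """Build a validated compendium from a raw genes x samples array."""
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i:04d}" for i in range(n_genes)]
    samples = samples or [f"s{i:03d}" for i in range(n_samples)]
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=samples)
    meta = pd.DataFrame({"disease": diseases},
                        index=pd.Index(samples, name="sample_id"))
    return ExpressionCompendium(vals, meta).validate()


def make_focus(expression, compendium, diagnosis="disease_a",
               sample_id="focus") -> FocusSample:
    return FocusSample(
        sample_id=sample_id,
        expression=pd.Series(np.asarray(expression, float),
                             index=compendium.genes),
        diagnosis=diagnosis,
    ).validate()


@pytest.fixture
def clustered_compendium():
    """Three well-separated disease clusters of 25 samples, 60 genes.

    Each disease has its own mean profile; within-cluster noise is small
    relative to between-cluster separation, so Spearman similarity cleanly
    separates the groups.
    """
    rng = np.random.default_rng(42)
    n_genes, per = 60, 25
    profiles = rng.normal(4.0, 2.0, (3, n_genes)).clip(min=0)
    cols, diseases = [], []
    for d in range(3):
        for _ in range(per):
            cols.append(np.clip(profiles[d] + rng.normal(0, 0.3, n_genes), 0, None))
            diseases.append(f"disease_{'abc'[d]}")
    comp = make_compendium(np.column_stack(cols), diseases)
    focus_expr = np.clip(profiles[0] + rng.normal(0, 0.3, n_genes), 0, None)
    focus = make_focus(focus_expr, comp, diagnosis="disease_a")
    return comp, focus
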