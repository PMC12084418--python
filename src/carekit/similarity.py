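"""Spearman similarity, the 95th-percentile neighbor threshold, and
first/second-degree neighbor sets.

Two tumors are molecularly similar when the Spearman correlation of their
expression profiles exceeds the 95th percentile of all pairwise
correlations within the compendium.  First-degree neighbors of the focus
sample are compendium samples above that threshold; second-degree
neighbors are samples similarly correlated with a first-degree neighbor
but not with the focus itself.

Conventions pinned here because they change neighbor membership: ranks use
mid-ranks (average over ties); "above the percentile" is a strict ``>``;
the percentile uses the linear-interpolation convention; the focus sample
does not participate in the pairwise percentile pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CareValidationError, ExpressionCompendium, FocusSample

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityResult",
    "spearman_rho",
    "pairwise_threshold",
    "neighbors",
    "top_correlated",
    "compute_similarity",
    "similarity_report",
]


@dataclass
class SimilarityResult:
    """Focus-to-compendium correlations, the neighbor threshold and neighbor sets."""

    focus_correlations: pd.Series  # sample -> Spearman rho with focus
    neighbor_threshold: float  # 95th percentile of within-compendium pairwise rhos
    first_degree: list[str]
    second_degree: list[str]
    top_k_samples: list[str]
    pairwise: pd.DataFrame | None = field(default=None, repr=False)
    subsampled: bool = False


def _rank_matrix(values: pd.DataFrame, gene_subset) -> np.ndarray:
    """Column-wise mid-ranks of the matrix restricted to gene_subset."""
    sub = values.loc[list(gene_subset)].to_numpy()
    if sub.shape[0] < 3:
        raise CareValidationError("need >= 3 genes for Spearman correlation")
    return rankdata(sub, axis=0, method="average")


def _corr_of_ranks(ranks: np.ndarray) -> np.ndarray:
    """Pearson correlation between rank columns; constant columns give NaN."""
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centered / safe
    corr = unit.T @ unit
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)  # NaN passes through


def spearman_rho(x, y, gene_subset=None) -> float:
    """Spearman rho of two expression vectors: Pearson correlation of mid-ranks.

    ``x`` and ``y`` are pandas Series over genes (aligned to ``gene_subset``
    when given) or plain arrays.  A vector with zero rank variance (all
    values tied) is not comparable; NaN is returned as the sentinel and the
    pair must be excluded from any percentile pool.
    """
    if gene_subset is not None:
        x = pd.Series(x).loc[list(gene_subset)]
        y = pd.Series(y).loc[list(gene_subset)]
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape or xa.size < 3:
        raise CareValidationError("vectors must be aligned and of length >= 3")
    ranks = rankdata(np.column_stack([xa, ya]), axis=0, method="average")
    return float(_corr_of_ranks(ranks)[0, 1])


def pairwise_rho_matrix(
    compendium: ExpressionCompendium, gene_subset=None
) -> pd.DataFrame:
    """All within-compendium pairwise Spearman rhos (samples × samples)."""
    if gene_subset is None:
        gene_subset = compendium.genes
    ranks = _rank_matrix(compendium.values, gene_subset)
    corr = _corr_of_ranks(ranks)
    return pd.DataFrame(corr, index=compendium.samples, columns=compendium.samples)


def pairwise_threshold(
    compendium: ExpressionCompendium,
    gene_subset=None,
    percentile: float = 0.95,
    max_pairs: int | None = None,
    seed: int = 0,
    pairwise: pd.DataFrame | None = None,
) -> tuple[float, bool]:
    """The ``percentile`` of all n(n-1)/2 pairwise rhos (linear interpolation).

    When ``max_pairs`` is set and the pool is larger, a seeded uniform
    subsample of pairs is used instead (the subsampling is logged).  Pairs
    involving a constant-rank sample are not comparable and are excluded.
    Returns (threshold, subsampled_flag).
    """
    if compendium.n_samples < 2:
        raise CareValidationError("need >= 2 samples for a pairwise threshold")
    if pairwise is None:
        pairwise = pairwise_rho_matrix(compendium, gene_subset)
    n = pairwise.shape[0]
    iu = np.triu_indices(n, k=1)
    pool = pairwise.to_numpy()[iu]
    subsampled = False
    if max_pairs is not None and pool.size > max_pairs:
        rng = np.random.default_rng(seed)
        pool = rng.choice(pool, size=max_pairs, replace=False)
        subsampled = True
        logger.info(
            "pairwise percentile pool subsampled to %d of %d pairs",
            max_pairs, n * (n - 1) // 2,
        )
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise CareValidationError("no comparable sample pairs in the compendium")
    return float(np.quantile(pool, percentile)), subsampled


def focus_correlations(
    focus: FocusSample, compendium: ExpressionCompendium, gene_subset=None
) -> pd.Series:
    """Spearman rho of the focus sample against every compendium sample."""
    if gene_subset is None:
        gene_subset = compendium.genes
    ranks = _rank_matrix(
        pd.concat([focus.expression.rename(focus.sample_id), compendium.values],
                  axis=1),
        gene_subset,
    )
    corr = _corr_of_ranks(ranks)
    return pd.Series(corr[0, 1:], index=compendium.samples, name="rho")


def neighbors(
    focus_rhos: pd.Series,
    pairwise: pd.DataFrame,
    neighbor_threshold: float,
) -> tuple[list[str], list[str]]:
    """First- and second-degree neighbor sets under a strict ``>`` rule.

    first_degree: samples whose rho with the focus exceeds the threshold.
    second_degree: samples outside first_degree whose rho with some
    first-degree member exceeds the threshold.  The sets are disjoint.
    """
    first = focus_rhos.index[focus_rhos > neighbor_threshold].tolist()
    first_set = set(first)
    second: list[str] = []
    if first:
        block = pairwise.loc[first]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            hits = (block > neighbor_threshold).any(axis=0)
        second = [s for s in pairwise.columns
                  if hits[s] and s not in first_set]
    return first, second


def top_correlated(focus_rhos: pd.Series, k: int = 6) -> list[str]:
    """The k samples most correlated with the focus; ties broken by sample id."""
    df = focus_rhos.dropna().rename("rho").reset_index()
    df.columns = ["sample_id", "rho"]
    df = df.sort_values(["rho", "sample_id"], ascending=[False, True],
                        kind="stable")
    if len(df) < k:
        warnings.warn(
            f"only {len(df)} samples available for top-{k} ranking", stacklevel=2
        )
    return df["sample_id"].head(k).tolist()


def compute_similarity(
    focus: FocusSample,
    compendium: ExpressionCompendium,
    gene_subset=None,
    percentile: float = 0.95,
    k: int = 6,
    max_pairs: int | None = None,
    seed: int = 0,
) -> SimilarityResult:
    """Run the full similarity stage and bundle the results."""
    pairwise = pairwise_rho_matrix(compendium, gene_subset)
    threshold, subsampled = pairwise_threshold(
        compendium, gene_subset, percentile, max_pairs, seed, pairwise=pairwise
    )
    rhos = focus_correlations(focus, compendium, gene_subset)
    first, second = neighbors(rhos, pairwise, threshold)
    top = top_correlated(rhos, k)
    return SimilarityResult(
        focus_correlations=rhos,
        neighbor_threshold=threshold,
        first_degree=first,
        second_degree=second,
        top_k_samples=top,
        pairwise=pairwise,
        subsampled=subsampled,
    )


def similarity_report(
    result: SimilarityResult, compendium: ExpressionCompendium
) -> pd.DataFrame:
    """TSV-ready table: sample, disease, rho, neighbor flags, rank by rho."""
    rhos = result.focus_correlations
    df = pd.DataFrame(
        {
            "disease": compendium.disease_labels(),
            "rho": rhos,
            "is_first_degree": rhos.index.isin(result.first_degree),
            "is_second_degree": rhos.index.isin(result.second_degree),
        }
    ).rename_axis("sample_id")
    df = df.sort_values(["rho", "sample_id"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df
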