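"""Per-cell gene-set enrichment scores and score comparisons.

Two single-sample scorers are provided:

* ``ssgsea`` (default) — per cell, genes are ranked by the log-normalized
  value (ties broken by gene name); the score is the signed maximum
  deviation between the weighted running sum over set members (weights
  ``|rank statistic|**tau``) and the uniform running sum over
  non-members. Scores are per-cell independent, so subsetting cells
  never changes them.
* ``gsva_gaussian`` — per gene, a Gaussian-kernel CDF statistic across
  cells (bandwidth = per-gene std / 4) replaces the expression value
  before the identical random-walk statistic. Scores then depend on the
  cell population, as in the kernel variant of GSVA.

Group comparisons use the two-sided Mann-Whitney U test (exact for small
samples) plus a rank-biserial effect size.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def _walk_scores(values: np.ndarray, in_set: np.ndarray, tau: float) -> np.ndarray:
    """Signed max-deviation running-sum statistic for each row of ``values``.

    ``values`` must have columns ordered so that a stable descending sort
    breaks ties the intended way (here: by gene name).
    """
    n_cells, n_genes = values.shape
    n_hit = int(in_set.sum())
    n_miss = n_genes - n_hit
    order = np.argsort(-values, axis=1, kind="stable")
    hit = in_set[order]  # (cells, genes) bool in rank order
    rank_stat = (n_genes - np.arange(n_genes, dtype=np.float64))[None, :]
    w = np.where(hit, np.abs(rank_stat) ** tau, 0.0)
    hit_cum = np.cumsum(w, axis=1)
    hit_tot = hit_cum[:, -1:]
    hit_cum = hit_cum / np.where(hit_tot > 0, hit_tot, 1.0)
    miss_cum = np.cumsum(np.where(hit, 0.0, 1.0), axis=1) / max(n_miss, 1)
    dev = hit_cum - miss_cum
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(n_cells), idx]


def _kernel_cdf_statistic(values: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel CDF of each cell's value across cells."""
    n_cells, n_genes = values.shape
    out = np.empty_like(values)
    for j in range(n_genes):
        x = values[:, j]
        h = x.std()
        h = h / 4.0 if h > 0 else 1e-9
        out[:, j] = stats.norm.cdf((x[:, None] - x[None, :]) / h).mean(axis=1)
    return out


def score_cells(
    adata: ad.AnnData,
    gene_sets: dict[str, list[str]],
    method: str = "ssgsea",
    tau: float = 0.25,
    chunk: int = 1024,
) -> pd.DataFrame:
    """Cells x gene-sets score matrix.

    Set genes absent from the matrix are dropped with a warning; a set
    left with fewer than 2 present genes is dropped entirely. All-zero
    cells still get a (tie-broken) score and are flagged in the log.
    """
    if method not in ("ssgsea", "gsva_gaussian"):
        raise ValueError(f"unknown scoring method {method!r}")
    name_order = np.argsort(adata.var_names.values, kind="stable")
    X = _dense(adata.X)[:, name_order]
    names = adata.var_names.values[name_order]
    name_index = {g: i for i, g in enumerate(names)}

    masks = {}
    for set_name, genes in gene_sets.items():
        present = [g for g in genes if g in name_index]
        absent = len(genes) - len(present)
        if absent:
            warnings.warn(f"gene set {set_name}: {absent} gene(s) absent from matrix")
        if len(present) < 2:
            warnings.warn(f"gene set {set_name} dropped (<2 genes present)")
            continue
        mask = np.zeros(len(names), dtype=bool)
        mask[[name_index[g] for g in present]] = True
        masks[set_name] = mask

    n_zero = int((X.sum(axis=1) == 0).sum())
    if n_zero:
        log.info("%d all-zero cell(s); scores rely on tie-broken ranks", n_zero)

    if method == "gsva_gaussian":
        X = _kernel_cdf_statistic(X)

    scores = {}
    for set_name, mask in masks.items():
        parts = [
            _walk_scores(X[i:i + chunk], mask, tau)
            for i in range(0, X.shape[0], chunk)
        ]
        scores[set_name] = np.concatenate(parts) if parts else np.array([])
    return pd.DataFrame(scores, index=adata.obs_names)


def compare_scores(
    scores_a: np.ndarray | pd.Series,
    scores_b: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney p-value and rank-biserial effect size.

    Uses the exact U distribution when both samples together hold at
    most 20 tie-free observations, the tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0, 0.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    u1, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    effect = 2.0 * float(u1) / (a.size * b.size) - 1.0
    return float(p), effect


def gene_correlations(
    adata: ad.AnnData,
    anchor_gene: str,
    target_genes: list[str],
    cell_subset: np.ndarray | pd.Index | None = None,
) -> pd.Series:
    """Pearson r between the anchor gene and each target on lognorm values.

    Returns NaN (with a warning) for targets — or an anchor — with zero
    variance in the subset.
    """
    sub = adata if cell_subset is None else adata[cell_subset]
    if sub.n_obs < 3:
        raise ValueError("need at least 3 cells for a correlation")
    for g in [anchor_gene, *target_genes]:
        if g not in sub.var_names:
            raise KeyError(f"gene {g} absent from matrix")
    x = _dense(sub[:, anchor_gene].X).ravel()
    out = {}
    if x.std() == 0:
        warnings.warn(f"anchor gene {anchor_gene} has zero variance")
        return pd.Series({g: np.nan for g in target_genes})
    for g in target_genes:
        y = _dense(sub[:, g].X).ravel()
        if y.std() == 0:
            warnings.warn(f"target gene {g} has zero variance")
            out[g] = np.nan
        else:
            out[g] = float(stats.pearsonr(x, y)[0])
    return pd.Series(out)
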