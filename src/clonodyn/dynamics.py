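"""Pre/post clonotype dynamics: per-clone Fisher tests and classification.

Each clonotype of a patient is tested with a two-sided Fisher's exact
test on the 2x2 table of (cells in clone, other keyed cells) at pre vs
post treatment. Clones with p < alpha are *expanded* (frequency rose) or
*contracted* (frequency fell); expanded clones absent at pre-treatment
carry the *novel* flag; everything else is *unchanged*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

CLASSES = ("novel", "expanded", "contracted", "unchanged")


@dataclass(frozen=True)
class CloneDynamicsResult:
    patient: str
    clonotype: str
    n_pre: int
    N_pre: int
    n_post: int
    N_post: int
    p_value: float
    dynamics_class: str  # expanded / contracted / unchanged
    novel: bool

    @property
    def freq_pre(self) -> float:
        return self.n_pre / self.N_pre

    @property
    def freq_post(self) -> float:
        return self.n_post / self.N_post


def clone_table(n_pre: int, N_pre: int, n_post: int, N_post: int) -> np.ndarray:
    """[[n_pre, N_pre-n_pre], [n_post, N_post-n_post]] with bounds checked."""
    if not (0 <= n_pre <= N_pre and 0 <= n_post <= N_post):
        raise ValueError("clone counts must satisfy 0 <= n <= N")
    if N_pre <= 0 or N_post <= 0:
        raise ValueError("phase totals must be positive")
    return np.array([[n_pre, N_pre - n_pre], [n_post, N_post - n_post]], dtype=np.int64)


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric point probabilities
    no larger than the observed one (within 1e-7 relative tolerance).

    A table with a zero margin carries no information; p = 1 by convention.
    """
    table = np.asarray(table)
    if (table < 0).any():
        raise ValueError("negative cell in 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.debug("zero margin in 2x2 table; p = 1 by convention")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_dynamics(
    table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
    post_timepoints: tuple[str, ...] = ("B", "C"),
) -> pd.DataFrame:
    """Classify every clonotype of every patient with both phases present.

    ``table`` is a keyed cell-clonotype table. Post-treatment counts pool
    the timepoints in ``post_timepoints``. Patients missing either phase
    are skipped with a warning. ``correction='BH'`` applies
    Benjamini-Hochberg within each patient before thresholding.

    Returns a DataFrame with one row per (patient, clonotype).
    """
    if correction not in ("none", "BH"):
        raise ValueError("correction must be 'none' or 'BH'")
    keyed = table.dropna(subset=["clonotype"])
    rows = []
    for patient, sub in keyed.groupby("patient"):
        pre = sub[sub["timepoint"] == "A"]
        post = sub[sub["timepoint"].isin(post_timepoints)]
        if pre.empty or post.empty:
            warnings.warn(f"patient {patient} lacks a phase; skipped")
            continue
        n_pre = pre.groupby("clonotype").size()
        n_post = post.groupby("clonotype").size()
        N_pre, N_post = int(n_pre.sum()), int(n_post.sum())
        clones = sorted(set(n_pre.index) | set(n_post.index))
        pvals = []
        for key in clones:
            a, b = int(n_pre.get(key, 0)), int(n_post.get(key, 0))
            pvals.append(fisher_exact_two_sided(clone_table(a, N_pre, b, N_post)))
        adj = (
            multipletests(pvals, method="fdr_bh")[1] if correction == "BH" and pvals
            else np.asarray(pvals)
        )
        for key, p_raw, p_use in zip(clones, pvals, adj):
            a, b = int(n_pre.get(key, 0)), int(n_post.get(key, 0))
            f_pre, f_post = a / N_pre, b / N_post
            if p_use < alpha and f_post > f_pre:
                cls, novel = "expanded", a == 0
            elif p_use < alpha and f_post < f_pre:
                cls, novel = "contracted", False
            else:
                cls, novel = "unchanged", False
            rows.append(
                dict(patient=patient, clonotype=key, n_pre=a, N_pre=N_pre,
                     n_post=b, N_post=N_post, freq_pre=f_pre, freq_post=f_post,
                     p_value=float(p_raw), p_adjusted=float(p_use),
                     dynamics_class=cls, novel=novel)
            )
    return pd.DataFrame(
        rows,
        columns=["patient", "clonotype", "n_pre", "N_pre", "n_post", "N_post",
                 "freq_pre", "freq_post", "p_value", "p_adjusted",
                 "dynamics_class", "novel"],
    )


def summarize_dynamics(
    results: pd.DataFrame,
    response_groups: pd.Series | dict,
    celltype_of_clone: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Counts of novel/expanded/contracted per response group (and cell type).

    ``response_groups`` maps patient -> group. ``celltype_of_clone``, if
    given, maps (patient, clonotype) -> a cell-type label (the phenotype
    of the cells carrying the clone, from the phenotype-link module).
    Also reports, per group, the fraction of expanded clones that are
    novel.
    """
    res = results.copy()
    groups = pd.Series(response_groups)
    res["response_group"] = res["patient"].map(groups)

    def _tally(frame: pd.DataFrame, by: str) -> pd.DataFrame:
        tall = []
        for val, sub in frame.groupby(by, dropna=False):
            exp = sub[sub["dynamics_class"] == "expanded"]
            tall.append(
                {
                    by: val,
                    "novel": int(exp["novel"].sum()),
                    "expanded": int(len(exp)),
                    "contracted": int((sub["dynamics_class"] == "contracted").sum()),
                    "unchanged": int((sub["dynamics_class"] == "unchanged").sum()),
                    "novel_fraction_of_expanded":
                        float(exp["novel"].mean()) if len(exp) else np.nan,
                }
            )
        return pd.DataFrame(tall)

    out = {"by_response_group": _tally(res, "response_group")}
    if celltype_of_clone is not None:
        res = res.set_index(["patient", "clonotype"])
        res["celltype"] = celltype_of_clone
        out["by_celltype"] = _tally(res.reset_index(), "celltype")
    return out
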