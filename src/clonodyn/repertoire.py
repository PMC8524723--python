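"""Clonotype abundance structure: clone sizes, sharing, Simpson clonality.

A repertoire here is the multiset of clone sizes of one grouping unit —
a patient x timepoint sample, a patient x phase pool, or the whole
cohort. Simpson clonality is sqrt(sum p_i^2), the usual immune-repertoire
convention: 1 for a monoclonal repertoire, sqrt(1/n) for n perfectly even
clones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPINGS = {
    "patient_timepoint": ["patient", "timepoint"],
    "patient_phase": ["patient", "phase"],
    "cohort": [],
}


@dataclass
class RepertoireSummary:
    unit: tuple
    n_cells_keyed: int
    n_clonotypes: int
    clone_sizes: dict[str, int]
    shared_fraction: float | None
    clonality: float | None
    top_clones: list[tuple[str, int, float]] = field(default_factory=list)


def simpson_clonality(clone_sizes) -> float:
    """sqrt(sum p_i^2) over clone frequencies p_i."""
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("empty repertoire has no clonality")
    p = sizes / sizes.sum()
    return float(np.sqrt(np.sum(p**2)))


def simpson_diversity(clone_sizes) -> float:
    """Simpson's D = sum p_i^2 (probability two cells share a clone)."""
    return simpson_clonality(clone_sizes) ** 2


def inverse_simpson(clone_sizes) -> float:
    """1 / D, the effective number of clones."""
    return 1.0 / simpson_diversity(clone_sizes)


def clone_size_table(table: pd.DataFrame, by: list[str]) -> pd.Series:
    keyed = table.dropna(subset=["clonotype"])
    cols = by + ["clonotype"] if by else ["clonotype"]
    return keyed.groupby(cols, observed=True).size()


def summarize_repertoire(
    table: pd.DataFrame, group_by: str = "patient_timepoint", top_n: int = 3
) -> list[RepertoireSummary]:
    """One :class:`RepertoireSummary` per group.

    Groups with zero keyed cells get n_clonotypes = 0 and missing (None)
    clonality and shared fraction rather than zeros.
    """
    if group_by not in GROUPINGS:
        raise ValueError(f"unknown grouping {group_by!r}")
    by = GROUPINGS[group_by]
    groups = table.groupby(by, observed=True) if by else [((), table)]
    out = []
    for unit, sub in groups:
        unit = unit if isinstance(unit, tuple) else (unit,)
        sizes = sub.dropna(subset=["clonotype"]).groupby("clonotype").size()
        if sizes.empty:
            out.append(RepertoireSummary(unit, 0, 0, {}, None, None, []))
            continue
        out.append(
            RepertoireSummary(
                unit=unit,
                n_cells_keyed=int(sizes.sum()),
                n_clonotypes=int(len(sizes)),
                clone_sizes=sizes.to_dict(),
                shared_fraction=float((sizes >= 2).sum() / len(sizes)),
                clonality=simpson_clonality(sizes.values),
                top_clones=_top(sizes, top_n),
            )
        )
    return out


def _top(sizes: pd.Series, n: int) -> list[tuple[str, int, float]]:
    total = sizes.sum()
    ranked = sizes.sort_index().sort_values(ascending=False, kind="stable")
    return [(k, int(s), float(s / total)) for k, s in ranked.head(n).items()]


def top_clonotypes(table: pd.DataFrame, group: dict, n: int = 3) -> list[tuple[str, int, float]]:
    """Top-``n`` clones of one group (e.g. {'patient': 'PT1', 'timepoint': 'A'}).

    Sorted by size descending; ties broken by clonotype key order.
    """
    sub = table
    for col, val in group.items():
        sub = sub[sub[col] == val]
    sizes = sub.dropna(subset=["clonotype"]).groupby("clonotype").size()
    if sizes.empty:
        raise ValueError(f"group {group} has no keyed cells")
    return _top(sizes, n)


def summaries_frame(summaries: list[RepertoireSummary], unit_names: list[str]) -> pd.DataFrame:
    """Tidy one-row-per-group CSV form of repertoire summaries."""
    rows = []
    for s in summaries:
        row = dict(zip(unit_names, s.unit))
        row.update(
            n_cells_keyed=s.n_cells_keyed,
            n_clonotypes=s.n_clonotypes,
            shared_fraction=s.shared_fraction,
            clonality=s.clonality,
            max_clone_size=max(s.clone_sizes.values()) if s.clone_sizes else 0,
        )
        rows.append(row)
    return pd.DataFrame(rows)
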