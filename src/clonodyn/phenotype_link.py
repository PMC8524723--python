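"""Clonotype-phenotype integration.

Joins clonotypes to cell phenotypes by barcode and derives:

* per-cell-type clonal dominance (distribution of each cell's clone size),
* the phenotype composition of the top-3 clonotypes of a sample,
* a lineage *sharing matrix* — the fraction of clonotypes of a primary
  cell type also seen in a secondary cell type within a phase,
* a pre/post *transition matrix* — the fraction of pre-treatment
  clonotypes of a cell type found post-treatment in each cell type,
* CD4:CD8 ratios.

Clonotype keys are patient-scoped, so all set arithmetic happens within
a patient; matrices are aggregated across patients either pooled
(summing numerators and denominators) or as an unweighted mean of
per-patient fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_LINEAGE_MAP = {
    "CD4 naive": "CD4", "CD4 Treg": "CD4", "CD4 TH1": "CD4", "CD4 TH17": "CD4",
    "CD4 CTL": "CD4", "CD4 NOS": "CD4",
    "CD8 naive": "CD8", "CD8 GZMK": "CD8", "CD8 STAT1": "CD8", "CD8 CTL": "CD8",
}


def clonotype_type_sets(table: pd.DataFrame, phase: str) -> dict[tuple[str, str], set[str]]:
    """(patient, clonotype) -> set of cell types carrying it in ``phase``."""
    keyed = table.dropna(subset=["clonotype"])
    sub = keyed[keyed["phase"] == phase]
    out: dict[tuple[str, str], set[str]] = {}
    for (patient, clone), grp in sub.groupby(["patient", "clonotype"]):
        out[(patient, clone)] = set(grp["celltype"])
    return out


def _per_patient_sets(table: pd.DataFrame, phase: str) -> dict[str, dict[str, set]]:
    """patient -> cell type -> set of clonotypes of that type in phase."""
    keyed = table.dropna(subset=["clonotype"])
    sub = keyed[keyed["phase"] == phase]
    out: dict[str, dict[str, set]] = {}
    for (patient, ct), grp in sub.groupby(["patient", "celltype"], observed=True):
        out.setdefault(patient, {})[ct] = set(grp["clonotype"])
    return out


def _aggregate(num: pd.DataFrame, den: pd.DataFrame, mode: str,
               per_patient: list[pd.DataFrame]) -> pd.DataFrame:
    if mode == "pooled":
        with np.errstate(invalid="ignore"):
            return num / den
    if mode == "mean":
        stack = np.dstack([f.values for f in per_patient])
        with np.errstate(invalid="ignore"):
            return pd.DataFrame(
                np.nanmean(stack, axis=2), index=num.index, columns=num.columns
            )
    raise ValueError(f"unknown aggregation mode {mode!r}")


def sharing_matrix(
    table: pd.DataFrame, phase: str, mode: str = "pooled"
) -> pd.DataFrame:
    """Fraction of primary-type clonotypes shared with each secondary type.

    Entry (i, j) = |clones of type i also seen in type j| / |clones of
    type i|, clone sets taken within patients in the given phase.
    ``pooled`` sums counts over patients (equivalent to weighting each
    patient's fraction by its row clonotype count); ``mean`` averages
    per-patient fractions unweighted.
    """
    per = _per_patient_sets(table, phase)
    types = sorted({ct for d in per.values() for ct in d})
    num = pd.DataFrame(0.0, index=types, columns=types)
    den = pd.DataFrame(0.0, index=types, columns=types)
    per_frames = []
    for d in per.values():
        f = pd.DataFrame(np.nan, index=types, columns=types)
        for i in d:
            for j in types:
                inter = len(d[i] & d.get(j, set()))
                num.loc[i, j] += inter
                den.loc[i, j] += len(d[i])
                f.loc[i, j] = inter / len(d[i])
        per_frames.append(f)
    return _aggregate(num, den, mode, per_frames)


def transition_matrix(table: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Entry (i, j) = fraction of pre clonotypes of type i found post in type j."""
    pre = _per_patient_sets(table, "pre")
    post = _per_patient_sets(table, "post")
    rows = sorted({ct for d in pre.values() for ct in d})
    cols = sorted({ct for d in post.values() for ct in d})
    num = pd.DataFrame(0.0, index=rows, columns=cols)
    den = pd.DataFrame(0.0, index=rows, columns=cols)
    per_frames = []
    for patient, d_pre in pre.items():
        d_post = post.get(patient, {})
        f = pd.DataFrame(np.nan, index=rows, columns=cols)
        for i in d_pre:
            for j in cols:
                inter = len(d_pre[i] & d_post.get(j, set()))
                num.loc[i, j] += inter
                den.loc[i, j] += len(d_pre[i])
                f.loc[i, j] = inter / len(d_pre[i])
        per_frames.append(f)
    return _aggregate(num, den, mode, per_frames)


def clonal_dominance_by_type(table: pd.DataFrame) -> pd.DataFrame:
    """Per cell type, summaries of the per-cell clone-size distribution.

    Each cell is annotated with the size of its clonotype within its
    sample (patient x timepoint); the per-type summary reports the median
    size and the fraction of cells in clones of size >= 2 and >= 10.
    """
    keyed = table.dropna(subset=["clonotype"]).copy()
    sizes = keyed.groupby(["patient", "timepoint", "clonotype"])["barcode"].transform("size")
    keyed["clone_size"] = sizes
    rows = []
    for ct, sub in keyed.groupby("celltype", observed=True):
        s = sub["clone_size"]
        rows.append(
            dict(celltype=ct, n_cells=len(s), median_clone_size=float(s.median()),
                 frac_in_shared=float((s >= 2).mean()),
                 frac_in_large=float((s >= 10).mean()))
        )
    return pd.DataFrame(rows)


def top3_composition(table: pd.DataFrame, patient: str, timepoint: str, n: int = 3) -> pd.DataFrame:
    """Cell-type composition of the top-``n`` clonotypes of one sample.

    Returns one row per (clonotype, celltype) with the fraction of the
    clone's cells of that type; ``top_fraction`` is the overall fraction
    of the sample's keyed cells in the top clones.
    """
    sub = table[(table["patient"] == patient) & (table["timepoint"] == timepoint)]
    keyed = sub.dropna(subset=["clonotype"])
    if keyed.empty:
        raise ValueError(f"{patient}/{timepoint} has no keyed cells")
    sizes = keyed.groupby("clonotype").size()
    ranked = sizes.sort_index().sort_values(ascending=False, kind="stable").head(n)
    total = sizes.sum()
    rows = []
    for key in ranked.index:
        cells = keyed[keyed["clonotype"] == key]
        comp = cells["celltype"].value_counts(normalize=True)
        for ct, frac in comp.items():
            rows.append(
                dict(patient=patient, timepoint=timepoint, clonotype=key,
                     clone_size=int(ranked[key]), celltype=ct, fraction=float(frac),
                     top_fraction=float(ranked.sum() / total))
            )
    return pd.DataFrame(rows)


def cd4_cd8_ratio(
    table: pd.DataFrame,
    stratum: dict | None = None,
    lineage_map: dict[str, str] | None = None,
) -> float | None:
    """CD4-lineage cells / CD8-lineage cells within a stratum.

    ``stratum`` filters the table by column values (e.g. {'phase': 'pre'}).
    Returns None (missing) when the stratum has no CD8 cells.
    """
    lineage_map = lineage_map or DEFAULT_LINEAGE_MAP
    sub = table
    for col, val in (stratum or {}).items():
        sub = sub[sub[col] == val]
    lineage = sub["celltype"].map(lineage_map)
    n_cd4 = int((lineage == "CD4").sum())
    n_cd8 = int((lineage == "CD8").sum())
    if n_cd8 == 0:
        return None
    return n_cd4 / n_cd8


def dominant_celltype_of_clone(table: pd.DataFrame, phase: str | None = "post") -> pd.Series:
    """(patient, clonotype) -> most frequent cell type among the clone's cells.

    Used to attribute dynamics classes to a cell type of origin. Ties
    break by cell-type name order.
    """
    keyed = table.dropna(subset=["clonotype"])
    if phase is not None:
        sub = keyed[keyed["phase"] == phase]
        # clones absent in the phase fall back to their other-phase cells
        rest = keyed[~keyed.set_index(["patient", "clonotype"]).index.isin(
            sub.set_index(["patient", "clonotype"]).index)]
        keyed = pd.concat([sub, rest])
    counts = (
        keyed.groupby(["patient", "clonotype", "celltype"], observed=True)
        .size().rename("n").reset_index()
        .sort_values(["n", "celltype"], ascending=[False, True], kind="stable")
    )
    best = counts.drop_duplicates(["patient", "clonotype"])
    return best.set_index(["patient", "clonotype"])["celltype"]
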