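"""Gene/cell quality filters and rule-based doublet flags.

The filters reproduce a conventional droplet-QC recipe: drop genes seen
in fewer than 3 cells, drop cells with fewer than 200 detected genes or
more than 15% mitochondrial transcripts; then flag (not remove) likely
doublets by three orthogonal rules — aberrant library complexity,
co-expression of mutually exclusive lineage markers, and TCR contigs in
cells annotated as a non-T lineage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

#: lineages whose cells legitimately carry a TCR
T_LINEAGES = frozenset({
    "CD4 naive", "CD4 Treg", "CD4 TH1", "CD4 TH17", "CD4 CTL", "CD4 NOS",
    "CD8 naive", "CD8 GZMK", "CD8 STAT1", "CD8 CTL",
    "MAIT GZMK", "MAIT CTL", "gd", "unconvT",
})

#: mutually exclusive lineage marker genes used by the hybrid-expression rule
DEFAULT_MARKER_CONFIG = {
    "T": ["CD3D", "CD3E"],
    "B": ["CD79A", "MS4A1"],
    "myeloid": ["LYZ", "CD14"],
}


class ConfigError(ValueError):
    pass


class EmptyResultError(ValueError):
    pass


@dataclass
class QCReport:
    n_genes_removed: int = 0
    n_cells_removed_low_complexity: int = 0
    n_cells_removed_mito: int = 0
    doublet_flags: dict[str, list[str]] = field(default_factory=dict)

    def flag(self, barcode: str, reason: str) -> None:
        self.doublet_flags.setdefault(barcode, [])
        if reason not in self.doublet_flags[barcode]:
            self.doublet_flags[barcode].append(reason)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_genes_removed": self.n_genes_removed,
            "n_cells_removed_low_complexity": self.n_cells_removed_low_complexity,
            "n_cells_removed_mito": self.n_cells_removed_mito,
            "n_doublet_flagged": len(self.doublet_flags),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def flags_frame(self) -> pd.DataFrame:
        rows = [
            (bc, ";".join(sorted(reasons)))
            for bc, reasons in sorted(self.doublet_flags.items())
        ]
        return pd.DataFrame(rows, columns=["barcode", "reasons"])


def _detected(counts) -> np.ndarray:
    """Per-cell number of detected genes."""
    if sp.issparse(counts):
        return np.asarray((counts > 0).sum(axis=1)).ravel()
    return (counts > 0).sum(axis=1)


def mito_fraction(adata: ad.AnnData, mito_prefix: str = "MT-") -> np.ndarray:
    counts = adata.layers["counts"]
    is_mito = adata.var_names.str.startswith(mito_prefix)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, np.asarray(is_mito)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    return frac


def filter_genes_cells(
    adata: ad.AnnData,
    min_cells: int = 3,
    min_genes: int = 200,
    max_mito: float = 0.15,
    mito_prefix: str = "MT-",
) -> tuple[ad.AnnData, QCReport]:
    """Apply the gene filter, then both cell filters.

    Genes detected in fewer than ``min_cells`` cells go first; cells with
    fewer than ``min_genes`` detected genes (after the gene filter) or a
    mitochondrial fraction strictly above ``max_mito`` go second.
    """
    report = QCReport()
    counts = adata.layers["counts"]
    cells_per_gene = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells
    report.n_genes_removed = int((~keep_genes).sum())
    adata = adata[:, keep_genes].copy()

    detected = _detected(adata.layers["counts"])
    frac = mito_fraction(adata, mito_prefix)
    low = detected < min_genes
    mito_bad = frac > max_mito
    report.n_cells_removed_low_complexity = int(low.sum())
    report.n_cells_removed_mito = int(mito_bad.sum())
    keep_cells = ~(low | mito_bad)
    if not keep_cells.any():
        raise EmptyResultError("quality filters removed every cell")
    adata = adata[keep_cells].copy()
    log.info(
        "QC: removed %d genes, %d low-complexity cells, %d high-mito cells",
        report.n_genes_removed, report.n_cells_removed_low_complexity,
        report.n_cells_removed_mito,
    )
    return adata, report


def flag_doublets(
    adata: ad.AnnData,
    celltypes: pd.Series,
    clonotype_table: pd.DataFrame | None = None,
    marker_config: dict[str, list[str]] | None = None,
    sample_key: pd.Series | None = None,
    iqr_k: float = 3.0,
    min_hybrid_markers: int = 2,
    t_lineages: frozenset[str] = T_LINEAGES,
) -> QCReport:
    """Flag likely doublets without removing them.

    * ``complexity_outlier`` — detected-gene count above the Tukey upper
      fence Q3 + ``iqr_k``*IQR, computed per sample;
    * ``hybrid_markers`` — at least ``min_hybrid_markers`` markers of each
      of two mutually exclusive lineages with count > 0;
    * ``tcr_in_non_t`` — a clonotype key on a barcode annotated outside
      the T lineages.
    """
    explicit = marker_config is not None
    marker_config = dict(marker_config or DEFAULT_MARKER_CONFIG)
    for lineage, genes in list(marker_config.items()):
        if not isinstance(genes, (list, tuple)) or not genes:
            raise ConfigError(f"marker_config lineage {lineage!r} has no genes")
        absent = [g for g in genes if g not in adata.var_names]
        if len(absent) == len(genes):
            if explicit:
                raise ConfigError(
                    f"no marker of lineage {lineage!r} is present in the matrix"
                )
            # default config on a reduced gene universe: skip the lineage
            log.info("lineage %s has no markers in the matrix; skipped", lineage)
            del marker_config[lineage]
    report = QCReport()
    barcodes = np.asarray(adata.obs_names)
    detected = _detected(adata.layers["counts"])

    groups = (
        pd.Series(np.asarray(sample_key), index=barcodes)
        if sample_key is not None
        else pd.Series("all", index=barcodes)
    )
    det = pd.Series(detected, index=barcodes)
    for _, idx in det.groupby(groups.values).groups.items():
        vals = det.loc[idx]
        q1, q3 = np.percentile(vals, [25, 75])
        fence = q3 + iqr_k * (q3 - q1)
        for bc in vals.index[vals > fence]:
            report.flag(bc, "complexity_outlier")

    counts = adata.layers["counts"]
    lineage_hits = {}
    for lineage, genes in marker_config.items():
        cols = [adata.var_names.get_loc(g) for g in genes if g in adata.var_names]
        sub = counts[:, cols]
        hits = np.asarray((sub > 0).sum(axis=1)).ravel()
        lineage_hits[lineage] = hits >= min_hybrid_markers
    lineages = list(lineage_hits)
    for i, a in enumerate(lineages):
        for b in lineages[i + 1:]:
            both = lineage_hits[a] & lineage_hits[b]
            for bc in barcodes[both]:
                report.flag(bc, "hybrid_markers")

    if clonotype_table is not None and "clonotype" in clonotype_table.columns:
        keyed = clonotype_table.dropna(subset=["clonotype"])
        ct = pd.Series(np.asarray(celltypes), index=barcodes)
        for bc in keyed["barcode"]:
            if bc in ct.index and ct.loc[bc] not in t_lineages:
                report.flag(bc, "tcr_in_non_t")
    return report
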