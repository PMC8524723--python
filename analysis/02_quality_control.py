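#!/usr/bin/env python
"""Apply the gene/cell quality filters and doublet flags to the cohort
and report how many planted artefacts each rule recovered."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import cell_table, cohort, outdir

from clonodyn import qc


def main():
    co = cohort()
    adata = co.to_anndata()
    out = outdir("02_qc")

    filtered, report = qc.filter_genes_cells(adata)
    meta = co.meta.set_index("barcode").loc[filtered.obs_names]
    flags = qc.flag_doublets(
        filtered,
        celltypes=meta["celltype"],
        clonotype_table=cell_table().dropna(subset=["clonotype"]),
        sample_key=meta["patient"] + "_" + meta["timepoint"],
    )
    report.doublet_flags = flags.doublet_flags
    report.to_json(out / "qc_report.json")
    report.flags_frame().to_csv(out / "doublet_flags.csv", index=False)

    truth = co.truth.cell_truth.set_index("barcode")
    lowq_removed = truth["lowq"].sum() - truth.loc[
        truth.index.intersection(filtered.obs_names), "lowq"].sum()
    flagged = set(report.doublet_flags)
    doub_in_matrix = truth.index.intersection(filtered.obs_names)
    doub_recall = truth.loc[doub_in_matrix, "doublet"] & pd.Series(
        [bc in flagged for bc in doub_in_matrix], index=doub_in_matrix
    )
    print(f"removed {report.n_genes_removed} genes, "
          f"{report.n_cells_removed_low_complexity} low-complexity and "
          f"{report.n_cells_removed_mito} high-mito cells "
          f"({int(lowq_removed)}/{int(truth['lowq'].sum())} planted low-quality)")
    n_doub = int(truth.loc[doub_in_matrix, "doublet"].sum())
    print(f"doublet flags: {len(flagged)} barcodes; recovered "
          f"{int(doub_recall.sum())}/{n_doub} planted doublets surviving filters")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
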