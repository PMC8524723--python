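#!/usr/bin/env python
"""Join clonotypes to T-cell phenotypes: clonal dominance by cell type,
top-3 clonotype composition, lineage sharing and pre/post transition
matrices, CD4:CD8 ratios."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import cell_table, outdir

from clonodyn import phenotype_link as pl


def main():
    table = cell_table()
    out = outdir("05_phenotypes")

    pl.clonal_dominance_by_type(table).to_csv(out / "dominance.csv", index=False)

    comps = []
    disease = table[table["response_group"] != "healthy"]
    for (patient, tp), _ in disease.groupby(["patient", "timepoint"]):
        comps.append(pl.top3_composition(table, patient, tp))
    pd.concat(comps, ignore_index=True).to_csv(out / "top3_composition.csv",
                                               index=False)

    for phase in ("pre", "post"):
        pl.sharing_matrix(table, phase).round(4).to_csv(
            out / f"sharing_{phase}.tsv", sep="\t")
    trans = pl.transition_matrix(table).round(4)
    trans.to_csv(out / "transition.tsv", sep="\t")

    ratios = {
        "healthy": pl.cd4_cd8_ratio(table[table["response_group"] == "healthy"]),
        "disease_pre": pl.cd4_cd8_ratio(disease, {"phase": "pre"}),
        "disease_post": pl.cd4_cd8_ratio(disease, {"phase": "post"}),
    }
    pd.Series(ratios).round(3).to_csv(out / "cd4_cd8_ratios.csv",
                                      header=["ratio"])
    gzmk_ctl = trans.loc["CD8 GZMK", "CD8 CTL"]
    print(f"GZMK->CTL transition fraction: {gzmk_ctl:.2f}")
    print("CD4:CD8 ratios:",
          {k: (round(v, 2) if v is not None else None) for k, v in ratios.items()})
    print(f"written to {out}")


if __name__ == "__main__":
    main()
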