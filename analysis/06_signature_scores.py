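#!/usr/bin/env python
"""Per-cell exhaustion/cytotoxicity scores, group comparisons, and the
GZMK-versus-cytotoxic-gene correlation structure in CD8 cells."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import cohort, outdir

from clonodyn import signatures


def main():
    co = cohort()
    adata = co.to_anndata()
    out = outdir("06_signatures")

    scores = signatures.score_cells(adata, co.gene_sets)
    meta = co.meta.set_index("barcode").loc[scores.index]
    by_group = (
        scores.groupby([meta["response_group"], meta["timepoint"],
                        meta["celltype"]])
        .agg(["mean", "std", "size"]).round(4)
    )
    by_group.to_csv(out / "score_summaries.csv")
    cd8 = meta["celltype"].str.startswith("CD8")
    rows = []
    exh = scores["EXHAUSTION"]
    pre_resp = exh[cd8 & (meta["response_group"] == "responder")
                   & (meta["timepoint"] == "A")]
    pre_nr = exh[cd8 & (meta["response_group"] == "NR")
                 & (meta["timepoint"] == "A")]
    p, eff = signatures.compare_scores(pre_resp, pre_nr)
    rows.append(("exhaustion_cd8_pre_responder_vs_nr", p, eff))
    post_resp = exh[cd8 & (meta["response_group"] == "responder")
                    & (meta["timepoint"] != "A")]
    p2, eff2 = signatures.compare_scores(pre_resp, post_resp)
    rows.append(("exhaustion_cd8_responder_pre_vs_post", p2, eff2))
    comp = pd.DataFrame(rows, columns=["comparison", "p", "rank_biserial"])
    comp.to_csv(out / "comparisons.csv", index=False)

    targets = ["GZMB", "GNLY", "PRF1", "NKG7"]
    corr = signatures.gene_correlations(
        adata, "GZMK", targets, cell_subset=np.asarray(cd8)
    )
    corr.round(4).to_csv(out / "gzmk_correlations.csv", header=["pearson_r"])

    print(comp.to_string(index=False))
    print("GZMK vs cytotoxic genes (CD8 cells):",
          corr.round(3).to_dict())
    print(f"written to {out}")


if __name__ == "__main__":
    main()
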