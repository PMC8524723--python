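#!/usr/bin/env python
"""Patient-level chromosome-7/7q-loss versus response association: the
synthetic cohort's 2x2 table, and the two published patient-count tables
recomputed (rates, Pearson chi-square, Fisher, odds ratio)."""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import cohort, outdir

from clonodyn import association, cnv
from clonodyn.association import Table2x2


def synthetic_table(co):
    adata = co.to_anndata()
    meta = co.meta.set_index("barcode").loc[adata.obs_names]
    ref = np.asarray(
        (meta["response_group"] == "healthy") & (meta["celltype"] == "Mono")
    )
    cnv.relative_expression(adata, ref)
    cnv.smooth_by_position(adata, window=100)
    calls = {}
    for patient in sorted(meta["patient"].unique()):
        if patient.startswith("HD"):
            continue
        mask = np.asarray(
            (meta["patient"] == patient) & (meta["celltype"] == "AML")
            & (meta["timepoint"] == "A")
        )
        calls[patient] = cnv.call_arm(adata, "7", cells=mask).sample_loss
    responses = (
        co.meta[co.meta["response_group"] != "healthy"]
        .drop_duplicates("patient").set_index("patient")["response_group"]
    )
    return association.build_marker_table(calls, responses)


def main():
    co = cohort()
    out = outdir("08_association")
    payload = {}

    t = synthetic_table(co)
    res = association.associate(t)
    payload["synthetic_cohort"] = association.result_to_dict(res) | {
        "table": [[t.a, t.b], [t.c, t.d]]
    }
    print(f"synthetic cohort: {t.a}/{t.a + t.b} responders with loss vs "
          f"{t.c}/{t.c + t.d} without (fisher p = {res.fisher_p:.3f})")

    for name, table in (
        ("icb_cohort", Table2x2(2, 17, 14, 24)),
        ("azacitidine_cohort", Table2x2(5, 9, 15, 70)),
    ):
        r = association.associate(table)
        payload[name] = association.result_to_dict(r)
        print(f"{name}: {r.rate_row1:.1f}% vs {r.rate_row2:.1f}% respond, "
              f"chi2 p = {r.chi2_p:.4f} (displayed {r.display_p()})")

    (out / "association.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    print(f"written to {out}")


if __name__ == "__main__":
    main()
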