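#!/usr/bin/env python
"""Classify every clonotype's pre-to-post change (Fisher's exact test at
alpha = 0.05), aggregate by response group, and score recovery of the
planted dynamics."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import cell_table, cohort, outdir

from clonodyn import dynamics, phenotype_link, synthetic


def main():
    co = cohort()
    table = cell_table()
    out = outdir("04_dynamics")

    results = dynamics.classify_dynamics(table)
    sig = results[results["dynamics_class"] != "unchanged"]
    sig.round(6).to_csv(out / "significant_clones.csv", index=False)
    groups = co.meta.drop_duplicates("patient").set_index("patient")["response_group"]
    celltype_of = phenotype_link.dominant_celltype_of_clone(table)
    summary = dynamics.summarize_dynamics(results, groups, celltype_of)
    summary["by_response_group"].to_csv(out / "by_response_group.csv", index=False)
    summary["by_celltype"].to_csv(out / "by_celltype.csv", index=False)

    recovery = synthetic.truth_eval(co.truth, dynamics_results=results)
    for task in ("dynamics_expanded", "dynamics_contracted", "novel"):
        r = recovery[task]
        print(f"{task}: sensitivity {r['sensitivity']:.2f}, "
              f"specificity {r['specificity']:.2f} "
              f"(tp={r['tp']} fp={r['fp']} fn={r['fn']})")
    for row in summary["by_response_group"].itertuples():
        print(f"{row.response_group}: {row.expanded} expanded "
              f"({row.novel} novel), {row.contracted} contracted")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
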