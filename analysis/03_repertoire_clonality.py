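#!/usr/bin/env python
"""Per-sample repertoire structure: clone sizes, shared-clonotype
fraction, Simpson clonality and top clones; healthy versus disease."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import cell_table, outdir

from clonodyn import repertoire as rep


def main():
    table = cell_table()
    out = outdir("03_repertoire")
    summaries = rep.summarize_repertoire(table, "patient_timepoint")
    frame = rep.summaries_frame(summaries, ["patient", "timepoint"])
    frame.to_csv(out / "per_sample_summaries.csv", index=False)

    healthy = frame[frame["patient"].str.startswith("HD")]
    disease = frame[~frame["patient"].str.startswith("HD")]
    print(f"{len(frame)} samples summarized")
    print(f"healthy: max clone {healthy['max_clone_size'].max()}, "
          f"median clonality {healthy['clonality'].median():.3f}, "
          f"shared fraction {healthy['shared_fraction'].median():.3f}")
    print(f"disease: max clone {disease['max_clone_size'].max()}, "
          f"median clonality {disease['clonality'].median():.3f}, "
          f"shared fraction {disease['shared_fraction'].median():.3f}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
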