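"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same seeded synthetic cohort (generation is
deterministic and takes seconds), derives the keyed cell table through
the pipeline's own clonotype-calling path, and writes its tables under
results/. Heavyweight raw artifacts belong under scratch/, not results/.
"""

from pathlib import Path

from clonodyn import experiments, synthetic

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

_cache = {}


def cohort():
    if "cohort" not in _cache:
        _cache["cohort"] = synthetic.generate_cohort(seed=SEED)
    return _cache["cohort"]


def cell_table():
    if "table" not in _cache:
        _cache["table"] = experiments.cohort_cell_table(cohort())
    return _cache["table"]


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
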