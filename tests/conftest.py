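import numpy as np
import pandas as pd
import pytest

from clonodyn import io_formats, synthetic


def records_from_frame(frame: pd.DataFrame) -> list:
    """Contig DataFrame (generator dialect) -> ContigRecord list."""
    return [
        io_formats.ContigRecord(
            barcode=r.barcode, chain=r.chain, cdr3_nt=r.cdr3_nt,
            cdr3_aa=r.cdr3, v_gene=r.v_gene, j_gene=r.j_gene,
            productive=str(r.productive).lower() == "true", umis=int(r.umis),
        )
        for r in frame.itertuples()
    ]


def keyed_table(cohort: synthetic.Cohort) -> pd.DataFrame:
    """Cell metadata joined with pipeline-derived clonotype keys."""
    from clonodyn.experiments import cohort_cell_table

    return cohort_cell_table(cohort)


@pytest.fixture(scope="session")
def small_config() -> synthetic.SimConfig:
    return synthetic.SimConfig(
        n_responders=1, n_sd=1, n_nr=1, n_healthy=1, cells_per_sample=300
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> synthetic.Cohort:
    return synthetic.generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cohort) -> pd.DataFrame:
    return keyed_table(small_cohort)


@pytest.fixture(scope="session")
def small_adata(small_cohort):
    return small_cohort.to_anndata()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
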