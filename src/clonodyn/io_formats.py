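"""Readers, writers and the canonical cell-level data model.

Everything downstream of this module works on two containers:

* a *cell–clonotype table* — a :class:`pandas.DataFrame` with one row per
  cell, carrying the cell metadata (patient, timepoint, phase, response
  group, phenotype label) and, where the cell has a productive TCR, a
  patient-scoped clonotype key;
* an :class:`anndata.AnnData` expression matrix with raw counts in
  ``layers["counts"]``, the library-size-normalized log layer in ``X``,
  and optional per-gene genomic positions in ``var``.

Clonotype keys are built from the retained productive TRA/TRB chains of a
cell and are only ever compared within a patient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

#: timepoint -> treatment phase. A is the pre-treatment aspirate; B and C
#: are on-treatment follow-ups.
PHASE_OF_TIMEPOINT = {"A": "pre", "B": "post", "C": "post"}

_TRUTHY = {"true", "t", "1", "yes"}

CONTIG_REQUIRED_COLUMNS = ("barcode", "chain", "cdr3_nt", "productive", "umis")


class FormatError(ValueError):
    """A malformed input file (missing column, inconsistent dimensions...)."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig of one cell."""

    barcode: str
    chain: str  # "TRA", "TRB" or "other"
    cdr3_nt: str
    cdr3_aa: str = ""
    v_gene: str = ""
    j_gene: str = ""
    productive: bool = False
    umis: int = 0
    raw_clonotype_id: str | None = None

    def __post_init__(self) -> None:
        if self.umis < 0:
            raise FormatError(f"negative umis for barcode {self.barcode}")
        if self.productive and not self.cdr3_nt:
            raise FormatError(
                f"productive contig without cdr3_nt for barcode {self.barcode}"
            )


def _parse_chain(raw: str) -> str:
    raw = (raw or "").strip().upper()
    return raw if raw in ("TRA", "TRB") else "other"


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Read a 10x-style ``filtered_contig_annotations`` CSV.

    Accepts both the native 10x header (``cdr3_nt``/``cdr3``) and any file
    providing at least barcode, chain, cdr3_nt, productive and umis.
    Extra columns are ignored.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in CONTIG_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig file {path} is missing column(s): {', '.join(missing)}")
    if df.empty:
        warnings.warn(f"contig file {path} contains no rows")
        return []
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ContigRecord(
                barcode=d["barcode"],
                chain=_parse_chain(d["chain"]),
                cdr3_nt=d["cdr3_nt"],
                cdr3_aa=d.get("cdr3", d.get("cdr3_aa", "")),
                v_gene=d.get("v_gene", ""),
                j_gene=d.get("j_gene", ""),
                productive=d["productive"].strip().lower() in _TRUTHY,
                umis=int(d["umis"]) if d["umis"] != "" else 0,
                raw_clonotype_id=d.get("raw_clonotype_id") or None,
            )
        )
    return records


def build_clonotypes(
    contigs: list[ContigRecord],
    patient: str,
    use_raw_ids: bool = False,
    amino_acid: bool = False,
) -> pd.DataFrame:
    """Derive one clonotype key per barcode from productive TRA/TRB chains.

    Per barcode, productive TRA and TRB contigs are retained; if more than
    one productive contig of the same chain exists, the highest-UMI one is
    kept (ties broken by lexicographically smallest CDR3). The key is the
    canonical, order-independent concatenation of (chain, cdr3) pairs,
    prefixed with the patient so keys are never comparable across patients.

    Returns a DataFrame (barcode, clonotype) with one row per keyed
    barcode; barcodes without a productive TRA/TRB chain are absent.
    """
    seq_of = (lambda c: c.cdr3_aa or c.cdr3_nt) if amino_acid else (lambda c: c.cdr3_nt)
    best: dict[str, dict[str, ContigRecord]] = {}
    raw_ids: dict[str, str] = {}
    n_unkeyed = 0
    barcodes = {c.barcode for c in contigs}
    for c in contigs:
        if not c.productive or c.chain not in ("TRA", "TRB"):
            continue
        slot = best.setdefault(c.barcode, {})
        prev = slot.get(c.chain)
        if prev is None or (c.umis, _neg_lex(seq_of(c))) > (prev.umis, _neg_lex(seq_of(prev))):
            slot[c.chain] = c
        if c.raw_clonotype_id:
            raw_ids[c.barcode] = c.raw_clonotype_id
    rows = []
    for barcode, chains in sorted(best.items()):
        if use_raw_ids and barcode in raw_ids:
            key = f"{patient}|{raw_ids[barcode]}"
        else:
            sig = ";".join(
                f"{chain}:{seq_of(rec)}" for chain, rec in sorted(chains.items())
            )
            key = f"{patient}|{sig}"
        rows.append((barcode, key))
    n_unkeyed = len(barcodes) - len(rows)
    if n_unkeyed:
        log.info("%s: %d barcode(s) without productive TRA/TRB chains left unkeyed",
                 patient, n_unkeyed)
    return pd.DataFrame(rows, columns=["barcode", "clonotype"])


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smallest string."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read the cell metadata CSV and derive the treatment phase."""
    meta = pd.read_csv(path, dtype={"barcode": str, "patient": str})
    required = {"barcode", "patient", "timepoint", "response_group", "celltype"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata {path} is missing column(s): {sorted(missing)}")
    meta["phase"] = meta["timepoint"].map(PHASE_OF_TIMEPOINT)
    if meta["phase"].isna().any():
        bad = sorted(meta.loc[meta["phase"].isna(), "timepoint"].unique())
        raise FormatError(f"unknown timepoint(s) {bad}; expected A/B/C")
    if "mito_fraction" in meta.columns:
        frac = meta["mito_fraction"].astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise FormatError("mito_fraction outside [0, 1]")
    return meta


def attach_clonotypes(meta: pd.DataFrame, keys: pd.DataFrame) -> pd.DataFrame:
    """Join clonotype keys onto cell metadata by barcode.

    Keys whose barcode is absent from the metadata are dropped with a
    warning (cells that failed expression QC keep no repertoire record).
    """
    dup = keys["barcode"].duplicated()
    if dup.any():
        raise FormatError("more than one clonotype key for a barcode")
    orphans = ~keys["barcode"].isin(meta["barcode"])
    if orphans.any():
        warnings.warn(f"{int(orphans.sum())} clonotype key(s) without metadata dropped")
        keys = keys[~orphans]
    return meta.merge(keys, on="barcode", how="left")


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"barcode": str, "patient": str})
    if "clonotype" in table.columns:
        table["clonotype"] = table["clonotype"].astype("object")
    return table


# ---------------------------------------------------------------------------
# expression


def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Set ``X`` to log1p(count * scale / cell_total) from ``layers['counts']``."""
    counts = adata.layers["counts"]
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    if sp.issparse(counts):
        norm = counts.multiply(scale / totals[:, None]).tocsr()
        norm.data = np.log1p(norm.data)
        adata.X = norm
    else:
        adata.X = np.log1p(counts * (scale / totals[:, None]))
    adata.uns["lognorm_scale"] = scale
    return adata


def read_expression(
    mtx_dir: str | Path,
    scale: float = 1e4,
    gene_positions: str | Path | None = None,
) -> ad.AnnData:
    """Read an MTX triplet (matrix.mtx, genes.tsv, barcodes.tsv) as AnnData.

    The matrix file is genes x cells (the 10x convention); the returned
    AnnData is cells x genes with counts in ``layers['counts']`` and the
    log-normalized layer in ``X``.
    """
    mtx_dir = Path(mtx_dir)
    matrix = sp.csr_matrix(scipy.io.mmread(mtx_dir / "matrix.mtx").T)
    if (matrix.data < 0).any():
        raise FormatError("negative counts in matrix.mtx")
    genes = pd.read_csv(mtx_dir / "genes.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(mtx_dir / "barcodes.tsv", sep="\t", header=None, dtype=str)
    if barcodes.empty:
        raise FormatError("empty barcodes file")
    gene_names = genes.iloc[:, -1] if genes.shape[1] > 1 else genes.iloc[:, 0]
    if matrix.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"dimension mismatch: matrix {matrix.shape[::-1]} vs "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    adata = ad.AnnData(
        X=matrix.astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(barcodes.iloc[:, 0], name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_names.values, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    lognormalize(adata, scale=scale)
    log.info("read %d cells x %d genes from %s", adata.n_obs, adata.n_vars, mtx_dir)
    if gene_positions is not None:
        attach_gene_positions(adata, read_gene_positions(gene_positions))
    return adata


def read_gene_sets(gmt_path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(gmt_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            seen: dict[str, None] = {}
            for g in parts[2:]:
                if g:
                    seen.setdefault(g)
            if not seen:
                raise FormatError(f"gene set {parts[0]} is empty")
            sets[parts[0]] = list(seen)
    return sets


def read_gene_positions(bed_path: str | Path) -> pd.DataFrame:
    """Read a BED-like 5-column file: chrom, start, end, gene, arm (0-based)."""
    pos = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene", "arm"], dtype={"chrom": str},
    )
    if pos[["start", "end"]].isna().any().any():
        raise FormatError(f"malformed gene-position file {bed_path}")
    return pos


def attach_gene_positions(adata: ad.AnnData, pos: pd.DataFrame) -> ad.AnnData:
    pos = pos.drop_duplicates("gene").set_index("gene")
    for col in ("chrom", "start", "end", "arm"):
        adata.var[col] = pos[col].reindex(adata.var_names)
    covered = adata.var["chrom"].notna().sum()
    log.info("gene positions cover %d/%d genes", covered, adata.n_vars)
    return adata


def write_expression(adata: ad.AnnData, mtx_dir: str | Path) -> None:
    """Write the counts layer back out as an MTX triplet."""
    mtx_dir = Path(mtx_dir)
    mtx_dir.mkdir(parents=True, exist_ok=True)
    counts = adata.layers["counts"]
    scipy.io.mmwrite(str(mtx_dir / "matrix.mtx"), sp.coo_matrix(counts.T))
    pd.DataFrame({"gene": adata.var_names, "name": adata.var_names}).to_csv(
        mtx_dir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        mtx_dir / "barcodes.tsv", sep="\t", header=False, index=False
    )
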