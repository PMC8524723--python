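"""Synthetic paired scRNA + scTCR cohorts with planted ground truth.

The generator emulates the statistical structure of a small pre/post
checkpoint-blockade AML cohort so that every pipeline stage has a
parameter-recovery test without any controlled-access download:

* 8 patients in three response groups (3 responders, 2 stable disease,
  3 non-responders) sampled at timepoints A (pre) and B/C (post), plus
  healthy donors;
* heavy-tailed clone-size distributions — near-singleton repertoires in
  healthy marrow (max clone size 16 by default) versus strongly
  dominated repertoires in disease;
* a per-group expansion plan: responder repertoires gain expanded and
  novel clones after treatment, non-responders mostly contract, with
  expansions concentrated in cytotoxic CD8 phenotypes and a planted
  CD8 GZMK -> CD8 CTL phenotype transition for a subset of persistent
  clones;
* phenotype-specific marker programs on named marker genes (naive /
  GZMK / CTL axes, lineage markers, an exhaustion program);
* 2,000 genes laid out on 10 pseudo-chromosomes of 200 genes, with a
  planted chr7q expression down-shift in the malignant cells of the
  non-responder patients (multiplicative on counts, factor 2**-shift);
* injected doublets (summed two-cell profiles; half are T x B pairs
  whose barcode keeps the T partner's TCR but the B partner's label)
  and low-quality cells (scaled-down counts, high mitochondrial load).

Counts are negative-binomial (gamma-Poisson) with configurable
dispersion. A fixed seed makes the whole cohort byte-for-byte
reproducible, outputs included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats

T_TYPES = [
    "CD4 naive", "CD4 Treg", "CD8 naive", "CD8 GZMK", "CD8 STAT1",
    "CD8 CTL", "MAIT GZMK", "MAIT CTL", "gd", "unconvT",
]
NON_T_TYPES = ["AML", "B", "Mono", "NK"]

#: T-phenotype frequencies per (response group, phase); normalized at use.
#: Anchored to the reported group-level patterns: CD4-heavy responders and
#: non-responders at pre-treatment, CD8-heavy stable disease, a post-treatment
#: CD8/MAIT/gd rise in responders, GZMK-dominated responder CD8 compartments
#: versus CTL-dominated non-responder ones.
PHENOTYPE_FREQS = {
    ("responder", "pre"):  {"CD4 naive": .45, "CD4 Treg": .19, "CD8 naive": .05,
                            "CD8 GZMK": .14, "CD8 STAT1": .03, "CD8 CTL": .04,
                            "MAIT GZMK": .015, "MAIT CTL": .005, "gd": .023, "unconvT": .07},
    ("responder", "post"): {"CD4 naive": .20, "CD4 Treg": .08, "CD8 naive": .04,
                            "CD8 GZMK": .12, "CD8 STAT1": .04, "CD8 CTL": .16,
                            "MAIT GZMK": .06, "MAIT CTL": .10, "gd": .09, "unconvT": .09},
    ("SD", "pre"):         {"CD4 naive": .25, "CD4 Treg": .08, "CD8 naive": .08,
                            "CD8 GZMK": .15, "CD8 STAT1": .07, "CD8 CTL": .24,
                            "MAIT GZMK": .01, "MAIT CTL": .01, "gd": .02, "unconvT": .07},
    ("SD", "post"):        {"CD4 naive": .18, "CD4 Treg": .06, "CD8 naive": .06,
                            "CD8 GZMK": .14, "CD8 STAT1": .08, "CD8 CTL": .30,
                            "MAIT GZMK": .03, "MAIT CTL": .03, "gd": .05, "unconvT": .08},
    ("NR", "pre"):         {"CD4 naive": .30, "CD4 Treg": .125, "CD8 naive": .05,
                            "CD8 GZMK": .07, "CD8 STAT1": .04, "CD8 CTL": .22,
                            "MAIT GZMK": .01, "MAIT CTL": .01, "gd": .02, "unconvT": .07},
    ("NR", "post"):        {"CD4 naive": .38, "CD4 Treg": .15, "CD8 naive": .04,
                            "CD8 GZMK": .05, "CD8 STAT1": .03, "CD8 CTL": .15,
                            "MAIT GZMK": .02, "MAIT CTL": .02, "gd": .05, "unconvT": .08},
    ("healthy", "pre"):    {"CD4 naive": .40, "CD4 Treg": .10, "CD8 naive": .10,
                            "CD8 GZMK": .09, "CD8 STAT1": .03, "CD8 CTL": .05,
                            "MAIT GZMK": .02, "MAIT CTL": .01, "gd": .03, "unconvT": .05},
}

#: fraction of each sample by compartment (T is subdivided by PHENOTYPE_FREQS)
COMPARTMENTS = {
    "disease": {"T": .48, "AML": .35, "Mono": .06, "B": .05, "NK": .06},
    "healthy": {"T": .63, "AML": .0, "Mono": .15, "B": .12, "NK": .10},
}

#: marker genes with an elevated mean in the carrying cell types
MARKER_PROGRAMS = {
    "CD3D": T_TYPES, "CD3E": T_TYPES,
    "CD4": ["CD4 naive", "CD4 Treg"], "IL7R": ["CD4 naive", "CD4 Treg"],
    "CD8A": ["CD8 naive", "CD8 GZMK", "CD8 STAT1", "CD8 CTL"],
    "CD8B": ["CD8 naive", "CD8 GZMK", "CD8 STAT1", "CD8 CTL"],
    "CCR7": ["CD4 naive", "CD8 naive"], "SELL": ["CD4 naive", "CD8 naive"],
    "TCF7": ["CD4 naive", "CD8 naive", "CD8 GZMK", "MAIT GZMK"],
    "FOXP3": ["CD4 Treg"], "CTLA4": ["CD4 Treg"],
    "STAT1": ["CD8 STAT1"],
    "GZMK": ["CD8 GZMK", "MAIT GZMK"], "CD27": ["CD8 GZMK", "MAIT GZMK"],
    "LTB": ["CD8 GZMK", "MAIT GZMK"], "EOMES": ["CD8 GZMK", "MAIT GZMK"],
    "GZMB": ["CD8 CTL", "MAIT CTL", "NK"], "GNLY": ["CD8 CTL", "MAIT CTL", "NK"],
    "PRF1": ["CD8 CTL", "MAIT CTL", "NK"], "NKG7": ["CD8 CTL", "MAIT CTL", "NK"],
    "KLRD1": ["NK"],
    "CD79A": ["B"], "MS4A1": ["B"], "CD19": ["B"],
    "LYZ": ["Mono"], "CD14": ["Mono"],
    "CD34": ["AML"], "KIT": ["AML"],
}
EXHAUSTION_GENES = ["PDCD1", "LAG3", "HAVCR2", "TIGIT", "CTLA4"]
CYTOTOXICITY_GENES = ["GZMB", "PRF1", "GNLY", "NKG7"]
MITO_GENES = ["MT-ND1", "MT-CO1", "MT-CYB"]

#: exhaustion-program count shift (log2 units) applied to conventional T
#: cells per (group, phase): responders start low and rise post-treatment.
EXHAUSTION_PLAN = {
    ("responder", "pre"): 0.0, ("responder", "post"): 0.8,
    ("SD", "pre"): 0.6, ("SD", "post"): 0.6,
    ("NR", "pre"): 0.8, ("NR", "post"): 0.3,
    ("healthy", "pre"): 0.0,
}


class SimConfigError(ValueError):
    pass


@dataclass
class ExpansionPlan:
    """Per-response-group pre -> post repertoire modification.

    Dominant clones move by the gentler ``top_fold`` (responders' most
    abundant clonotypes expand, non-responders' contract); mid-rank
    clones move by the stronger ``fold_expand`` / ``fold_contract``;
    ``n_novel`` clones absent at pre-treatment enter at ``novel_freq``
    each. Keeping the added and removed probability mass moderate stops
    renormalization from masquerading as expansion or contraction of
    untouched clones.
    """

    n_expanded: int
    n_novel: int
    n_contracted: int
    n_top_expanded: int = 0
    n_top_contracted: int = 0
    fold_expand: float = 10.0
    fold_contract: float = 10.0
    top_fold: float = 2.5
    novel_freq: float = 0.02  # post-phase frequency target per novel clone

    def __post_init__(self) -> None:
        if min(self.fold_expand, self.fold_contract, self.top_fold) <= 0:
            raise SimConfigError("folds must be positive")


DEFAULT_PLANS = {
    "responder": ExpansionPlan(n_expanded=8, n_novel=8, n_contracted=2,
                               n_top_expanded=2),
    "SD": ExpansionPlan(n_expanded=4, n_novel=4, n_contracted=4,
                        n_top_expanded=1),
    "NR": ExpansionPlan(n_expanded=0, n_novel=1, n_contracted=12,
                        n_top_contracted=2, novel_freq=0.015),
}


@dataclass
class SimConfig:
    n_responders: int = 3
    n_sd: int = 2
    n_nr: int = 3
    n_healthy: int = 2
    timepoints: tuple[str, ...] = ("A", "B", "C")
    cells_per_sample: int = 800
    # clone-size law
    healthy_alpha: float = 3.5
    healthy_max_clone: int = 16
    disease_alpha: float = 1.0
    disease_max_clone: int = 1200
    n_base_clones: int = 300
    tcr_capture_rate: float = 0.9
    phenotype_fidelity: float = 0.85
    n_transitions: int = 10  # planted GZMK->CTL clones per disease patient
    plans: dict = field(default_factory=lambda: dict(DEFAULT_PLANS))
    # expression
    n_genes: int = 2000
    n_chromosomes: int = 10
    base_mean: float = 1.2
    nb_dispersion: float = 0.3
    marker_shift: float = 1.5   # log2 count shift on marker genes in carriers
    marker_off_scale: float = 0.08  # marker expression outside carrier types
    mito_scale: float = 30.0
    arm_loss_arm: str = "7"  # whole-chromosome loss (monosomy 7)
    arm_loss_shift: float = 0.5  # log2; counts scaled by 2**-shift
    arm_loss_groups: tuple[str, ...] = ("NR",)
    # artefacts
    doublet_rate: float = 0.03
    lowq_rate: float = 0.02
    lowq_scale: float = 0.06

    def __post_init__(self) -> None:
        for rate in (self.tcr_capture_rate, self.phenotype_fidelity,
                     self.doublet_rate, self.lowq_rate):
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError("rates must lie in [0, 1]")
        for group, plan in self.plans.items():
            budget = self.cells_per_sample
            if plan.n_novel > budget:
                raise SimConfigError(
                    f"{group}: {plan.n_novel} forced novel clones exceed the "
                    f"cell budget of {budget}"
                )

    def patients(self) -> list[tuple[str, str]]:
        out = []
        idx = 1
        for group, n in (("responder", self.n_responders), ("SD", self.n_sd),
                         ("NR", self.n_nr)):
            for _ in range(n):
                out.append((f"PT{idx}", group))
                idx += 1
        for h in range(1, self.n_healthy + 1):
            out.append((f"HD{h}", "healthy"))
        return out


@dataclass
class GroundTruth:
    clone_truth: pd.DataFrame    # patient, clonotype, class, novel, transition
    cell_truth: pd.DataFrame     # barcode, true celltype, doublet, lowq
    patient_truth: pd.DataFrame  # patient, arm, loss
    exhaustion_plan: dict


@dataclass
class Cohort:
    config: SimConfig
    seed: int
    meta: pd.DataFrame
    contigs: dict[str, pd.DataFrame]   # "{patient}_{timepoint}" -> contig table
    counts: np.ndarray                 # cells x genes (int)
    gene_names: list[str]
    gene_positions: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: GroundTruth

    def to_anndata(self):
        import anndata as ad
        import scipy.sparse as sp

        adata = ad.AnnData(
            X=sp.csr_matrix(self.counts.astype(np.float64)),
            obs=self.meta.set_index("barcode"),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.layers["counts"] = adata.X.copy()
        io_formats.lognormalize(adata)
        io_formats.attach_gene_positions(adata, self.gene_positions)
        return adata

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "contigs").mkdir(parents=True, exist_ok=True)
        (outdir / "expression").mkdir(exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        for sample, frame in self.contigs.items():
            frame.to_csv(outdir / "contigs" / f"{sample}_contigs.csv", index=False)
        self.meta.to_csv(outdir / "cells.csv", index=False)
        self.to_anndata()  # validates shapes
        _write_mtx(self.counts, self.gene_names, self.meta["barcode"],
                   outdir / "expression")
        self.gene_positions.to_csv(
            outdir / "genes.bed", sep="\t", header=False, index=False
        )
        with open(outdir / "signatures.gmt", "w") as fh:
            for name, genes in self.gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")
        self.truth.clone_truth.to_csv(outdir / "truth" / "clones.csv", index=False)
        self.truth.cell_truth.to_csv(outdir / "truth" / "cells.csv", index=False)
        self.truth.patient_truth.to_csv(outdir / "truth" / "patients.csv", index=False)
        (outdir / "truth" / "run.json").write_text(
            json.dumps({"seed": self.seed}, sort_keys=True) + "\n"
        )


def _write_mtx(counts, gene_names, barcodes, mtx_dir: Path) -> None:
    import scipy.io
    import scipy.sparse as sp

    scipy.io.mmwrite(str(mtx_dir / "matrix.mtx"), sp.coo_matrix(counts.T))
    pd.DataFrame({"gene": gene_names, "name": gene_names}).to_csv(
        mtx_dir / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(np.asarray(barcodes)).to_csv(
        mtx_dir / "barcodes.tsv", sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# repertoire layer


def draw_clone_sizes(rng: np.random.Generator, n_cells: int, alpha: float,
                     max_size: int) -> np.ndarray:
    """Clone sizes from a truncated discrete power law until the budget fills.

    The last clone is truncated to the remaining budget, so the configured
    maximum is a hard bound on every emitted size.
    """
    support = np.arange(1, max_size + 1)
    p = support.astype(float) ** (-alpha)
    p /= p.sum()
    sizes = []
    remaining = n_cells
    while remaining > 0:
        s = int(rng.choice(support, p=p))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return np.asarray(sizes)


def base_clone_weights(rng: np.random.Generator, n_clones: int, alpha: float) -> np.ndarray:
    """Zipf-like base frequencies, shuffled so rank is not identity."""
    w = np.arange(1, n_clones + 1, dtype=float) ** (-alpha)
    return w / w.sum()


def _random_cdr3(rng: np.random.Generator, length_range=(30, 45)) -> str:
    n = int(rng.integers(*length_range))
    return "".join(rng.choice(list("ACGT"), size=n))


@dataclass
class _PatientRepertoire:
    keys: list[str]              # clonotype keys, index-aligned with weights
    cdr3: dict[str, tuple[str, str]]
    p_pre: np.ndarray
    p_post: np.ndarray
    clone_class: dict[str, str]
    clone_novel: dict[str, bool]
    transition: dict[str, bool]
    home_pre: dict[str, str]
    home_post: dict[str, str]


def _plan_patient_repertoire(
    cfg: SimConfig, rng: np.random.Generator, patient: str, group: str
) -> _PatientRepertoire:
    n = cfg.n_base_clones
    weights = base_clone_weights(rng, n, cfg.disease_alpha)
    cdr3 = {}
    keys = []
    for i in range(n):
        a, b = _random_cdr3(rng), _random_cdr3(rng)
        key = f"{patient}|TRA:{a};TRB:{b}"
        keys.append(key)
        cdr3[key] = (a, b)
    plan = cfg.plans[group]
    mid = np.arange(20, min(80, n))  # mid-rank clones: present but not dominant
    picks = rng.choice(mid, size=min(len(mid), plan.n_expanded + plan.n_contracted
                                     + cfg.n_transitions), replace=False)
    expanded_idx = list(picks[:plan.n_expanded])
    contracted_idx = list(picks[plan.n_expanded:plan.n_expanded + plan.n_contracted])
    transition_idx = picks[plan.n_expanded + plan.n_contracted:]

    w_post = weights.copy()
    w_post[picks[:plan.n_expanded]] *= plan.fold_expand
    w_post[picks[plan.n_expanded:plan.n_expanded + plan.n_contracted]] /= plan.fold_contract
    # dominant clones move gently: ranks 0.. for expansion, then contraction
    top_exp = list(range(plan.n_top_expanded))
    top_con = list(range(plan.n_top_expanded,
                         plan.n_top_expanded + plan.n_top_contracted))
    w_post[top_exp] *= plan.top_fold
    w_post[top_con] /= plan.top_fold
    expanded_idx += top_exp
    contracted_idx += top_con

    clone_class = {k: "unchanged" for k in keys}
    clone_novel = {k: False for k in keys}
    transition = {k: False for k in keys}
    home_pre: dict[str, str] = {}
    home_post: dict[str, str] = {}

    pre_freqs = PHENOTYPE_FREQS[(group, "pre")]
    t_names = list(pre_freqs)
    t_probs = np.array([pre_freqs[t] for t in t_names])
    t_probs = t_probs / t_probs.sum()
    cytotoxic_bias = {"CD8 GZMK": .35, "CD8 CTL": .35, "MAIT CTL": .15, "CD8 STAT1": .15}

    for i, key in enumerate(keys):
        home = str(rng.choice(t_names, p=t_probs))
        home_pre[key] = home
        home_post[key] = home
    for i in expanded_idx:
        key = keys[i]
        clone_class[key] = "expanded"
        home = str(rng.choice(list(cytotoxic_bias), p=list(cytotoxic_bias.values())))
        home_pre[key] = home
        home_post[key] = home
    for i in contracted_idx:
        clone_class[keys[i]] = "contracted"
    for i in transition_idx:
        key = keys[i]
        transition[key] = True
        home_pre[key] = "CD8 GZMK"
        home_post[key] = "CD8 CTL"

    # novel clones exist only in the post-phase law
    p_pre = np.concatenate([weights, np.zeros(plan.n_novel)])
    novel_w = plan.novel_freq * w_post.sum() / max(1e-12, 1 - plan.novel_freq * plan.n_novel)
    w_post = np.concatenate([w_post, np.full(plan.n_novel, novel_w)])
    for j in range(plan.n_novel):
        a, b = _random_cdr3(rng), _random_cdr3(rng)
        key = f"{patient}|TRA:{a};TRB:{b}"
        keys.append(key)
        cdr3[key] = (a, b)
        clone_class[key] = "expanded"
        clone_novel[key] = True
        transition[key] = False
        home = str(rng.choice(list(cytotoxic_bias), p=list(cytotoxic_bias.values())))
        home_pre[key] = home
        home_post[key] = home
    return _PatientRepertoire(
        keys=keys, cdr3=cdr3,
        p_pre=p_pre / p_pre.sum(), p_post=w_post / w_post.sum(),
        clone_class=clone_class, clone_novel=clone_novel, transition=transition,
        home_pre=home_pre, home_post=home_post,
    )


# ---------------------------------------------------------------------------
# expression layer


def build_gene_universe(cfg: SimConfig) -> tuple[list[str], pd.DataFrame]:
    """Gene names and BED-like positions over pseudo-chromosomes.

    Named marker/mito genes sit at the start of chromosome 1 so the
    planted chr7 loss never touches them; the rest are synthetic names.
    40% of each chromosome is the p arm, the remainder q.
    """
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    named = list(MARKER_PROGRAMS) + EXHAUSTION_GENES[:3] + MITO_GENES
    # CTLA4 and TIGIT/PDCD1/LAG3/HAVCR2 overlap handling: dedupe, keep order
    named = list(dict.fromkeys(list(MARKER_PROGRAMS) + EXHAUSTION_GENES + MITO_GENES))
    names, rows = [], []
    k = 0
    for c in range(1, cfg.n_chromosomes + 1):
        for i in range(per_chrom):
            if c == 1 and i < len(named):
                g = named[i]
            else:
                g = f"G{c:02d}_{i:03d}"
            start = i * 10_000
            arm = "p" if i < int(0.4 * per_chrom) else "q"
            names.append(g)
            rows.append((f"chr{c}", start, start + 1_000, g, f"{c}{arm}"))
            k += 1
    pos = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "arm"])
    return names, pos


def celltype_means(cfg: SimConfig, base_mu: np.ndarray, gene_index: dict[str, int]
                   ) -> dict[str, np.ndarray]:
    """Per-celltype NB mean vectors: marker genes are near-silent outside
    their carrier types and boosted by ``2**marker_shift`` inside them."""
    mult = {}
    factor = 2.0 ** cfg.marker_shift
    for ct in T_TYPES + NON_T_TYPES:
        m = base_mu.copy()
        for gene, carriers in MARKER_PROGRAMS.items():
            if gene not in gene_index:
                continue
            if ct in carriers:
                m[gene_index[gene]] *= factor
            else:
                m[gene_index[gene]] *= cfg.marker_off_scale
        mult[ct] = m
    return mult


_celltype_means = celltype_means


def nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float,
              n_cells: int) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts, cells x genes."""
    if dispersion <= 0:
        return rng.poisson(np.broadcast_to(mu, (n_cells, mu.size)))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.broadcast_to(mu * dispersion, (n_cells, mu.size)))
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: SimConfig | None = None, seed: int = 0) -> Cohort:
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    gene_names, gene_pos = build_gene_universe(cfg)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    base_mu = cfg.base_mean * np.exp(rng.normal(0.0, 0.5, len(gene_names)))
    for g in MITO_GENES:
        base_mu[gene_index[g]] = cfg.base_mean * cfg.mito_scale
    ct_means = _celltype_means(cfg, base_mu, gene_index)
    exh_cols = [gene_index[g] for g in EXHAUSTION_GENES]
    arm_mask = _arm_gene_mask(gene_pos, cfg.arm_loss_arm, gene_names)

    meta_rows, contigs, count_blocks = [], {}, []
    clone_rows, cell_rows, patient_rows = [], [], []

    for patient, group in cfg.patients():
        is_healthy = group == "healthy"
        has_loss = group in cfg.arm_loss_groups
        patient_rows.append(dict(patient=patient, arm=cfg.arm_loss_arm,
                                 loss=bool(has_loss)))
        rep = None
        if not is_healthy:
            rep = _plan_patient_repertoire(cfg, rng, patient, group)
            for key in rep.keys:
                clone_rows.append(dict(
                    patient=patient, clonotype=key,
                    dynamics_class=rep.clone_class[key],
                    novel=rep.clone_novel[key], transition=rep.transition[key],
                ))
        timepoints = ("A",) if is_healthy else cfg.timepoints
        for tp in timepoints:
            phase = io_formats.PHASE_OF_TIMEPOINT[tp]
            sample = f"{patient}_{tp}"
            block, rows, contig_frame = _make_sample(
                cfg, rng, patient, group, tp, phase, rep, ct_means, gene_names,
                gene_index, exh_cols, arm_mask, has_loss, cell_rows,
            )
            meta_rows.extend(rows)
            contigs[sample] = contig_frame
            count_blocks.append(block)

    counts = np.vstack(count_blocks)
    meta = pd.DataFrame(meta_rows)
    gene_sets = {
        "EXHAUSTION": list(EXHAUSTION_GENES),
        "CYTOTOXICITY": list(CYTOTOXICITY_GENES),
        "NAIVE": ["CCR7", "SELL", "TCF7"],
    }
    truth = GroundTruth(
        clone_truth=pd.DataFrame(clone_rows),
        cell_truth=pd.DataFrame(cell_rows),
        patient_truth=pd.DataFrame(patient_rows),
        exhaustion_plan={f"{g}|{p}": s for (g, p), s in EXHAUSTION_PLAN.items()},
    )
    return Cohort(config=cfg, seed=seed, meta=meta, contigs=contigs,
                  counts=counts, gene_names=gene_names, gene_positions=gene_pos,
                  gene_sets=gene_sets, truth=truth)


def _arm_gene_mask(gene_pos: pd.DataFrame, arm: str, gene_names) -> np.ndarray:
    token = arm.removeprefix("chr")
    if token and token[-1] in ("p", "q"):
        sel = gene_pos["arm"] == token
    else:
        sel = gene_pos["chrom"] == f"chr{token}"
    lost = set(gene_pos.loc[sel, "gene"])
    return np.array([g in lost for g in gene_names])


def _make_sample(cfg, rng, patient, group, tp, phase, rep, ct_means, gene_names,
                 gene_index, exh_cols, arm_mask, has_loss, cell_rows):
    n = cfg.cells_per_sample
    comp = COMPARTMENTS["healthy" if group == "healthy" else "disease"]
    n_t = int(round(comp["T"] * n))
    non_t = {ct: int(round(comp[ct] * n)) for ct in ("AML", "B", "Mono", "NK")}
    n_t += n - (n_t + sum(non_t.values()))  # absorb rounding into T

    # --- T-cell clonotypes and phenotypes
    freqs = PHENOTYPE_FREQS[(group, phase)]
    t_names = list(freqs)
    t_probs = np.array([freqs[t] for t in t_names])
    t_probs = t_probs / t_probs.sum()

    celltypes, clonotypes = [], []
    if group == "healthy":
        sizes = draw_clone_sizes(rng, n_t, cfg.healthy_alpha, cfg.healthy_max_clone)
        for ci, size in enumerate(sizes):
            a, b = _random_cdr3(rng), _random_cdr3(rng)
            key = f"{patient}|TRA:{a};TRB:{b}"
            home = str(rng.choice(t_names, p=t_probs))
            for _ in range(size):
                celltypes.append(_draw_phenotype(rng, cfg, home, t_names, t_probs))
                clonotypes.append(key)
    else:
        p = rep.p_pre if phase == "pre" else rep.p_post
        draws = rng.multinomial(n_t, p)
        homes = rep.home_pre if phase == "pre" else rep.home_post
        for ci, size in enumerate(draws):
            if size == 0:
                continue
            key = rep.keys[ci]
            for _ in range(int(size)):
                celltypes.append(_draw_phenotype(rng, cfg, homes[key], t_names, t_probs))
                clonotypes.append(key)

    for ct, n_ct in non_t.items():
        celltypes.extend([ct] * n_ct)
        clonotypes.extend([None] * n_ct)

    order = rng.permutation(len(celltypes))
    celltypes = [celltypes[i] for i in order]
    clonotypes = [clonotypes[i] for i in order]
    barcodes = [f"{patient}_{tp}_c{i:05d}-1" for i in range(len(celltypes))]

    # --- expression
    exh_shift = EXHAUSTION_PLAN.get((group, phase), 0.0)
    blocks = np.zeros((len(celltypes), len(gene_names)), dtype=np.int32)
    ct_arr = np.asarray(celltypes)
    for ct in dict.fromkeys(celltypes):
        idx = np.flatnonzero(ct_arr == ct)
        mu = ct_means[ct].copy()
        if ct.startswith(("CD8", "CD4")) and exh_shift:
            scale = 2.0 ** (exh_shift if ct.startswith("CD8") else exh_shift / 2)
            mu[exh_cols] *= scale
        if has_loss and ct == "AML":
            mu = mu.copy()
            mu[arm_mask] *= 2.0 ** (-cfg.arm_loss_shift)
        blocks[idx] = nb_counts(rng, mu, cfg.nb_dispersion, len(idx))

    rows = []
    for bc, ct, key in zip(barcodes, celltypes, clonotypes):
        rows.append(dict(barcode=bc, patient=patient, timepoint=tp,
                         response_group=group, celltype=ct))
        cell_rows.append(dict(barcode=bc, true_celltype=ct, doublet=False,
                              lowq=False))

    # --- TCR contigs (captured keyed T cells only)
    contig_rows = []
    for bc, key in zip(barcodes, clonotypes):
        if key is None or rng.random() > cfg.tcr_capture_rate:
            continue
        a, b = key.split("|", 1)[1].split(";")
        cdr3_a, cdr3_b = a.split(":", 1)[1], b.split(":", 1)[1]
        for chain, cdr3 in (("TRA", cdr3_a), ("TRB", cdr3_b)):
            contig_rows.append(dict(
                barcode=bc, is_cell=True, chain=chain,
                v_gene=f"{chain}V1-1", j_gene=f"{chain}J1-1",
                cdr3="C" + cdr3[:8], cdr3_nt=cdr3, productive="True",
                umis=int(rng.integers(2, 50)), reads=int(rng.integers(50, 500)),
                raw_clonotype_id="",
            ))
        if rng.random() < 0.05:  # occasional non-productive extra chain
            contig_rows.append(dict(
                barcode=bc, is_cell=True, chain="TRB", v_gene="TRBV2-1",
                j_gene="TRBJ2-1", cdr3="", cdr3_nt=_random_cdr3(rng),
                productive="False", umis=1, reads=int(rng.integers(5, 50)),
                raw_clonotype_id="",
            ))

    # --- doublets: summed profiles; at least half forced T x B
    n_doub = int(round(cfg.doublet_rate * n))
    t_keyed = [i for i, k in enumerate(clonotypes) if k is not None]
    b_cells = [i for i, c in enumerate(celltypes) if c == "B"]
    doub_blocks = []
    for j in range(n_doub):
        if j < (n_doub + 1) // 2 and t_keyed and b_cells:
            i1 = int(rng.choice(t_keyed))
            i2 = int(rng.choice(b_cells))
            label = "B"
        else:
            i1, i2 = (int(x) for x in rng.choice(len(celltypes), 2, replace=False))
            label = celltypes[i2]
        bc = f"{patient}_{tp}_d{j:04d}-1"
        doub_blocks.append(blocks[i1] + blocks[i2])
        rows.append(dict(barcode=bc, patient=patient, timepoint=tp,
                         response_group=group, celltype=label))
        cell_rows.append(dict(barcode=bc, true_celltype=label, doublet=True,
                              lowq=False))
        if clonotypes[i1] is not None:
            key = clonotypes[i1]
            a, b = key.split("|", 1)[1].split(";")
            for chain, cdr3 in (("TRA", a.split(":", 1)[1]), ("TRB", b.split(":", 1)[1])):
                contig_rows.append(dict(
                    barcode=bc, is_cell=True, chain=chain,
                    v_gene=f"{chain}V1-1", j_gene=f"{chain}J1-1",
                    cdr3="C" + cdr3[:8], cdr3_nt=cdr3, productive="True",
                    umis=int(rng.integers(2, 50)), reads=int(rng.integers(50, 500)),
                    raw_clonotype_id="",
                ))

    # --- low-quality cells: shrunken library, dominant mitochondrial load
    n_lowq = int(round(cfg.lowq_rate * n))
    lowq_blocks = []
    mito_cols = [gene_index[g] for g in MITO_GENES]
    for j in range(n_lowq):
        ct = str(rng.choice(list(dict.fromkeys(celltypes))))
        prof = nb_counts(rng, ct_means[ct] * cfg.lowq_scale, cfg.nb_dispersion, 1)[0]
        prof[mito_cols] = nb_counts(
            rng, ct_means[ct][mito_cols], cfg.nb_dispersion, 1)[0]
        bc = f"{patient}_{tp}_q{j:04d}-1"
        lowq_blocks.append(prof)
        rows.append(dict(barcode=bc, patient=patient, timepoint=tp,
                         response_group=group, celltype=ct))
        cell_rows.append(dict(barcode=bc, true_celltype=ct, doublet=False,
                              lowq=True))

    all_blocks = [blocks] + ([np.vstack(doub_blocks)] if doub_blocks else []) \
        + ([np.vstack(lowq_blocks)] if lowq_blocks else [])
    block = np.vstack(all_blocks)

    contig_frame = pd.DataFrame(
        contig_rows,
        columns=["barcode", "is_cell", "chain", "v_gene", "j_gene", "cdr3",
                 "cdr3_nt", "productive", "umis", "reads", "raw_clonotype_id"],
    )
    return block, rows, contig_frame


def _draw_phenotype(rng, cfg, home, t_names, t_probs) -> str:
    if rng.random() < cfg.phenotype_fidelity:
        return home
    return str(rng.choice(t_names, p=t_probs))


# ---------------------------------------------------------------------------
# recovery evaluation


def _confusion(pred: pd.Series, true: pd.Series) -> dict:
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    tn = int((~pred & ~true).sum())
    return dict(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=tp / (tp + fn) if tp + fn else np.nan,
        specificity=tn / (tn + fp) if tn + fp else np.nan,
    )


def truth_eval(
    truth: GroundTruth,
    dynamics_results: pd.DataFrame | None = None,
    doublet_flags: pd.DataFrame | None = None,
    arm_calls: dict[str, bool] | None = None,
    scores: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Confusion summaries of pipeline outputs against the planted truth."""
    report: dict = {}
    if dynamics_results is not None:
        merged = dynamics_results.merge(
            truth.clone_truth, on=["patient", "clonotype"], how="left",
            suffixes=("", "_true"),
        )
        if merged["dynamics_class_true"].isna().any():
            raise ValueError("dynamics results contain clonotypes unknown to the truth")
        for cls in ("expanded", "contracted"):
            report[f"dynamics_{cls}"] = _confusion(
                merged["dynamics_class"] == cls,
                merged["dynamics_class_true"] == cls,
            )
        report["novel"] = _confusion(
            merged["novel"].astype(bool), merged["novel_true"].astype(bool)
        )
    if doublet_flags is not None:
        flagged = set(doublet_flags["barcode"])
        ct = truth.cell_truth
        report["doublets"] = _confusion(
            ct["barcode"].isin(flagged), ct["doublet"].astype(bool)
        )
        planted_txb = ct[ct["doublet"]]
        report["doublets"]["n_planted"] = int(len(planted_txb))
    if arm_calls is not None:
        pt = truth.patient_truth.set_index("patient")
        unknown = set(arm_calls) - set(pt.index)
        if unknown:
            raise ValueError(f"arm calls for unknown patients: {sorted(unknown)}")
        pred = pd.Series({p: bool(v) for p, v in arm_calls.items()})
        true = pt.loc[pred.index, "loss"].astype(bool)
        report["arm_loss"] = _confusion(pred, true)
    if scores is not None and meta is not None:
        from .signatures import compare_scores
        exh = scores["EXHAUSTION"]
        m = meta.set_index("barcode").loc[exh.index]
        hi = exh[(m["response_group"] == "NR") & (m["celltype"].str.startswith("CD8"))]
        lo = exh[(m["response_group"] == "responder")
                 & (m["timepoint"] == "A") & (m["celltype"].str.startswith("CD8"))]
        if len(hi) and len(lo):
            p, eff = compare_scores(hi, lo)
            report["exhaustion_separation"] = dict(p=p, rank_biserial=eff)
    return report
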