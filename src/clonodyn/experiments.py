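"""Calibration and recovery experiments on synthetic cohorts.

These drivers quantify how well each pipeline stage recovers planted
truth under the generator's study conditions: type-I error and power of
the clone-dynamics classifier, sensitivity/specificity of arm-level CNV
calls, the healthy-versus-disease clonality ordering, and the
response-group direction of detected clonotype dynamics.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import cnv, dynamics, io_formats
from .repertoire import simpson_clonality
from .synthetic import (
    SimConfig,
    base_clone_weights,
    build_gene_universe,
    celltype_means,
    draw_clone_sizes,
    generate_cohort,
    nb_counts,
)


def _counts_table(n_pre: np.ndarray, n_post: np.ndarray, patient="PT1") -> pd.DataFrame:
    """Cell-level table from per-clone pre/post counts (vectorized)."""
    frames = []
    for tp, phase, counts in (("A", "pre", n_pre), ("B", "post", n_post)):
        keys = np.repeat(
            [f"{patient}|k{i:05d}" for i in range(len(counts))], counts
        )
        frames.append(pd.DataFrame({
            "barcode": [f"{patient}_{tp}_{i}" for i in range(len(keys))],
            "patient": patient, "timepoint": tp, "phase": phase,
            "response_group": "responder", "celltype": "CD8 CTL",
            "clonotype": keys,
        }))
    return pd.concat(frames, ignore_index=True)


def null_dynamics_fp_rate(
    n_clones: int = 700,
    n_cells: int = 1500,
    alpha: float = 0.05,
    law_exponent: float = 0.5,
    seed: int = 0,
) -> dict:
    """Fraction of clones called expanded or contracted when pre and post
    are multinomial resamples of the same clone-frequency law.

    The law is a shallow power law so that most clones are actually
    observed and contribute a test.
    """
    rng = np.random.default_rng(seed)
    p = base_clone_weights(rng, n_clones, alpha=law_exponent)
    n_pre = rng.multinomial(n_cells, p)
    n_post = rng.multinomial(n_cells, p)
    res = dynamics.classify_dynamics(_counts_table(n_pre, n_post), alpha=alpha)
    called = (res["dynamics_class"] != "unchanged").sum()
    return {
        "n_clones_tested": int(len(res)),
        "fp_rate": float(called / len(res)),
    }


def expansion_power(
    n_reps: int = 20,
    n_planted: int = 10,
    baseline_freq: float = 0.005,
    fold: float = 10.0,
    n_cells: int = 1000,
    n_background: int = 200,
    seed: int = 0,
) -> dict:
    """Detection rate of planted ``fold``-times frequency increases from
    ``baseline_freq``, with pre and post sampled at ``n_cells`` each."""
    detected = total = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        bg = base_clone_weights(rng, n_background, alpha=1.0)
        planted_pre = np.full(n_planted, baseline_freq)
        planted_post = planted_pre * fold
        p_pre = np.concatenate([planted_pre, bg * (1 - planted_pre.sum())])
        p_post = np.concatenate([planted_post, bg * (1 - planted_post.sum())])
        n_pre = rng.multinomial(n_cells, p_pre)
        n_post = rng.multinomial(n_cells, p_post)
        res = dynamics.classify_dynamics(_counts_table(n_pre, n_post))
        res = res.set_index("clonotype")
        for i in range(n_planted):
            key = f"PT1|k{i:05d}"
            total += 1
            if key in res.index:
                detected += res.loc[key, "dynamics_class"] == "expanded"
    return {"n_planted": total, "detection_rate": float(detected / total)}


def cnv_recovery(
    n_loss: int = 25,
    n_neutral: int = 25,
    cells_per_patient: int = 100,
    n_reference: int = 150,
    shift: float | None = None,
    arm: str | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict:
    """Sample-level sensitivity/specificity of planted arm-loss calls.

    Builds a panel of synthetic patients directly on the generator's gene
    universe and count model: half carry the configured multiplicative
    arm down-shift on their cells, half are copy-neutral; healthy
    monocyte-like cells serve as the centering reference.
    """
    cfg = config or SimConfig()
    shift = cfg.arm_loss_shift if shift is None else shift
    arm = cfg.arm_loss_arm if arm is None else arm
    rng = np.random.default_rng(seed)
    gene_names, gene_pos = build_gene_universe(cfg)
    gene_index = {g: i for i, g in enumerate(gene_names)}
    base_mu = cfg.base_mean * np.exp(rng.normal(0.0, 0.5, len(gene_names)))
    ct_means = celltype_means(cfg, base_mu, gene_index)
    mono_mu = ct_means["Mono"]
    aml_mu = ct_means["AML"]
    token = arm.removeprefix("chr")
    if token[-1:] in ("p", "q"):
        lost = gene_pos["arm"] == token
    else:
        lost = gene_pos["chrom"] == f"chr{token}"
    lost_mask = lost.values

    blocks = [nb_counts(rng, mono_mu, cfg.nb_dispersion, n_reference)]
    obs = [("ref", i) for i in range(n_reference)]
    labels = {}
    order = ["loss"] * n_loss + ["neutral"] * n_neutral
    for pi, status in enumerate(order):
        mu = aml_mu.copy()
        if status == "loss":
            mu[lost_mask] *= 2.0 ** (-shift)
        blocks.append(nb_counts(rng, mu, cfg.nb_dispersion, cells_per_patient))
        patient = f"SP{pi:03d}"
        labels[patient] = status == "loss"
        obs.extend((patient, i) for i in range(cells_per_patient))
    counts = np.vstack(blocks)
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.float64)),
        obs=pd.DataFrame(
            {"patient": [p for p, _ in obs]},
            index=[f"{p}_{i}" for p, i in obs],
        ),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    io_formats.lognormalize(adata)
    io_formats.attach_gene_positions(adata, gene_pos)

    ref_mask = (adata.obs["patient"] == "ref").values
    cnv.relative_expression(adata, ref_mask)
    cnv.smooth_by_position(adata, window=100)
    tp = fp = fn = tn = 0
    for patient, true_loss in labels.items():
        res = cnv.call_arm(
            adata, arm, cells=(adata.obs["patient"] == patient).values
        )
        if true_loss:
            tp += res.sample_loss
            fn += not res.sample_loss
        else:
            fp += res.sample_loss
            tn += not res.sample_loss
    return {
        "n_patients": len(labels), "shift": float(shift),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def clonality_direction(
    n_seeds: int = 40,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict:
    """Fraction of seeds where the disease repertoire's Simpson clonality
    exceeds the healthy repertoire's, at matched keyed-cell yields."""
    cfg = config or SimConfig()
    n_keyed = int(cfg.cells_per_sample * 0.48 * cfg.tcr_capture_rate)
    n_keyed_h = int(cfg.cells_per_sample * 0.63 * cfg.tcr_capture_rate)
    wins = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        healthy_sizes = draw_clone_sizes(
            rng, n_keyed_h, cfg.healthy_alpha, cfg.healthy_max_clone
        )
        p = base_clone_weights(rng, cfg.n_base_clones, cfg.disease_alpha)
        disease_sizes = rng.multinomial(n_keyed, p)
        disease_sizes = disease_sizes[disease_sizes > 0]
        wins += simpson_clonality(disease_sizes) > simpson_clonality(healthy_sizes)
    return {"n_seeds": n_seeds, "fraction_disease_gt_healthy": wins / n_seeds}


def dynamics_direction_counts(
    n_seeds: int = 3,
    seed: int = 0,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """One row per (seed, response group) with detected dynamics counts."""
    rows = []
    for s in range(n_seeds):
        cohort = generate_cohort(config, seed=seed + s)
        table = cohort_cell_table(cohort)
        res = dynamics.classify_dynamics(table)
        groups = cohort.meta.drop_duplicates("patient").set_index("patient")[
            "response_group"]
        summary = dynamics.summarize_dynamics(res, groups)["by_response_group"]
        summary.insert(0, "seed", seed + s)
        rows.append(summary)
    return pd.concat(rows, ignore_index=True)


def cohort_cell_table(cohort) -> pd.DataFrame:
    """Keyed cell table derived from a cohort's contig tables through the
    same clonotype-calling path the pipeline uses."""
    keys = []
    for sample, frame in cohort.contigs.items():
        patient = sample.split("_")[0]
        recs = [
            io_formats.ContigRecord(
                barcode=r.barcode, chain=r.chain, cdr3_nt=r.cdr3_nt,
                cdr3_aa=r.cdr3, productive=str(r.productive).lower() == "true",
                umis=int(r.umis),
            )
            for r in frame.itertuples()
        ]
        if recs:
            keys.append(io_formats.build_clonotypes(recs, patient))
    key_frame = (
        pd.concat(keys, ignore_index=True) if keys
        else pd.DataFrame(columns=["barcode", "clonotype"])
    )
    meta = cohort.meta.copy()
    meta["phase"] = meta["timepoint"].map(io_formats.PHASE_OF_TIMEPOINT)
    return io_formats.attach_clonotypes(meta, key_frame)
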