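"""Expression-based arm-level copy-number inference.

Large chromosomal gains and losses leave a coherent shift in the
expression of the genes they cover. The procedure: center each gene's
log-normalized expression on a diploid reference population (healthy
monocytes by default), clip extreme residuals, order genes by genomic
position, smooth with a moving average of ~100 genes strictly within
each chromosome, and call an arm lost (gained) in a cell when the mean
smoothed residual over the arm's genes falls below -t_loss (above
+t_gain). A sample carries the loss when at least half its evaluated
cells do.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ArmCallResult:
    arm: str
    per_cell: pd.DataFrame  # barcode, mean_smoothed, call
    loss_fraction: float
    sample_loss: bool


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X)


def relative_expression(
    adata: ad.AnnData,
    reference_cells,
    clip: float = 3.0,
) -> ad.AnnData:
    """Center lognorm values on the per-gene reference mean; clip to +-clip.

    Writes the result to ``layers['relative']`` and returns the AnnData.
    """
    ref = adata[reference_cells]
    if ref.n_obs == 0:
        raise ValueError("empty reference cell set")
    if ref.n_obs < 20:
        warnings.warn(f"only {ref.n_obs} reference cells; centering will be noisy")
    ref_mean = _dense(ref.X).mean(axis=0)
    rel = _dense(adata.X) - ref_mean[None, :]
    np.clip(rel, -clip, clip, out=rel)
    adata.layers["relative"] = rel
    adata.uns["cnv_clip"] = clip
    return adata


def smooth_by_position(
    adata: ad.AnnData,
    window: int = 100,
    mode: str = "centered",
) -> ad.AnnData:
    """Moving average of the relative layer along genomic gene order.

    Genes are sorted by start coordinate within each chromosome; the
    window never crosses a chromosome boundary and is truncated at
    chromosome ends. ``centered`` takes floor(window/2) genes on each
    side of the focal gene; ``trailing`` takes the ``window`` genes
    ending at the focal gene. Genes without positions get NaN.
    """
    if "relative" not in adata.layers:
        raise ValueError("run relative_expression first")
    rel = np.asarray(adata.layers["relative"], dtype=np.float64)
    smoothed = np.full_like(rel, np.nan)
    var = adata.var
    missing = var["chrom"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} gene(s) without positions excluded from smoothing")
    for chrom, genes in var[~missing].groupby("chrom", observed=True, sort=False).groups.items():
        cols = [adata.var_names.get_loc(g) for g in
                var.loc[genes].sort_values("start", kind="stable").index]
        if len(cols) < 2:
            warnings.warn(f"chromosome {chrom} has <2 positioned genes; passthrough")
            smoothed[:, cols] = rel[:, cols]
            continue
        block = rel[:, cols]
        csum = np.concatenate(
            [np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1
        )
        n = len(cols)
        idx = np.arange(n)
        if mode == "centered":
            half = window // 2
            lo = np.maximum(idx - half, 0)
            hi = np.minimum(idx + half, n - 1)
        elif mode == "trailing":
            lo = np.maximum(idx - window + 1, 0)
            hi = idx
        else:
            raise ValueError(f"unknown smoothing mode {mode!r}")
        means = (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)[None, :]
        smoothed[:, cols] = means
    adata.layers["smoothed"] = smoothed
    adata.uns["cnv_window"] = window
    return adata


def _arm_columns(adata: ad.AnnData, arm: str) -> np.ndarray:
    var = adata.var
    arm_label = var["arm"].astype(str)
    chrom = var["chrom"].astype(str)
    token = arm.removeprefix("chr")
    if token and token[-1] in ("p", "q"):
        mask = (chrom.str.removeprefix("chr") == token[:-1]) & (arm_label == token[-1])
        # also accept arm columns that carry the full label (e.g. "7q")
        mask |= arm_label == token
    else:
        mask = chrom.str.removeprefix("chr") == token
    cols = np.flatnonzero(mask.values & var["chrom"].notna().values)
    if cols.size == 0:
        raise ValueError(f"arm {arm!r} not present in gene positions")
    if cols.size < 10:
        warnings.warn(f"arm {arm}: only {cols.size} positioned genes")
    return cols


def call_arm(
    adata: ad.AnnData,
    arm: str,
    t_loss: float = 0.15,
    t_gain: float = 0.15,
    sample_fraction: float = 0.5,
    cells=None,
) -> ArmCallResult:
    """Per-cell and sample-level loss/neutral/gain calls for one arm.

    ``arm`` may be an arm label ("7q") or a whole chromosome ("7" or
    "chr7"). Calls use strict inequalities, so a mean exactly at a
    threshold stays neutral.
    """
    if "smoothed" not in adata.layers:
        raise ValueError("run smooth_by_position first")
    sub = adata if cells is None else adata[cells]
    cols = _arm_columns(adata, arm)
    means = np.asarray(sub.layers["smoothed"])[:, cols].mean(axis=1)
    call = np.where(means < -t_loss, "loss", np.where(means > t_gain, "gain", "neutral"))
    per_cell = pd.DataFrame(
        {"barcode": np.asarray(sub.obs_names), "arm": arm,
         "mean_smoothed": means, "call": call}
    )
    loss_fraction = float((call == "loss").mean())
    return ArmCallResult(
        arm=arm, per_cell=per_cell, loss_fraction=loss_fraction,
        sample_loss=bool(loss_fraction >= sample_fraction),
    )
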