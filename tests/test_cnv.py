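import anndata as ad
import numpy as np
import pandas as pd
import pytest

from clonodyn import cnv


def positioned_adata(X, chroms, starts=None, arms=None, barcodes=None):
    X = np.asarray(X, dtype=float)
    n_genes = X.shape[1]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    starts = starts if starts is not None else np.arange(n_genes) * 1000
    arms = arms or ["q"] * n_genes
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=barcodes or [f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": np.asarray(starts) + 100,
             "arm": [f"{str(c).removeprefix('chr')}{a}" for c, a in zip(chroms, arms)]},
            index=genes,
        ),
    )
    return adata


class TestRelativeExpression:
    def test_reference_cells_center_to_zero(self, rng):
        X = rng.random((30, 8))
        adata = positioned_adata(X, ["chr1"] * 8)
        ref = np.arange(30) < 25
        cnv.relative_expression(adata, ref)
        rel = adata.layers["relative"][ref]
        np.testing.assert_allclose(rel.mean(axis=0), 0.0, atol=1e-12)

    def test_cell_matching_reference_profile_is_zero(self):
        X = np.vstack([np.full(6, 2.0)] * 25)
        adata = positioned_adata(X, ["chr1"] * 6)
        cnv.relative_expression(adata, np.ones(25, dtype=bool))
        np.testing.assert_allclose(adata.layers["relative"], 0.0)

    def test_clipping(self):
        X = np.zeros((25, 4))
        X[0] = 10.0
        adata = positioned_adata(X, ["chr1"] * 4)
        cnv.relative_expression(adata, np.arange(25) >= 1, clip=3.0)
        assert adata.layers["relative"].max() == pytest.approx(3.0)

    def test_empty_reference_rejected(self):
        adata = positioned_adata(np.ones((5, 3)), ["chr1"] * 3)
        with pytest.raises(ValueError):
            cnv.relative_expression(adata, np.zeros(5, dtype=bool))


class TestSmoothing:
    def _smoothed(self, rel, chroms, window, **kw):
        adata = positioned_adata(np.zeros_like(rel), chroms, **kw)
        adata.layers["relative"] = np.asarray(rel, dtype=float)
        cnv.smooth_by_position(adata, window=window)
        return adata.layers["smoothed"]

    def test_constant_profile_unchanged(self):
        rel = np.full((3, 20), -0.5)
        sm = self._smoothed(rel, ["chr1"] * 20, window=7)
        np.testing.assert_allclose(sm, -0.5)

    def test_impulse_window_three(self):
        rel = np.zeros((1, 6))
        rel[0, 2] = 3.0
        sm = self._smoothed(rel, ["chr1"] * 6, window=3)
        np.testing.assert_allclose(sm[0], [0, 1, 1, 1, 0, 0])

    def test_no_bleed_across_chromosomes(self):
        rel = np.concatenate([np.full((1, 10), -1.0), np.full((1, 10), 1.0)], axis=1)
        chroms = ["chr1"] * 10 + ["chr2"] * 10
        sm = self._smoothed(rel, chroms, window=100,
                            starts=list(range(10)) * 2)
        np.testing.assert_allclose(sm[0, :10], -1.0)
        np.testing.assert_allclose(sm[0, 10:], 1.0)

    def test_linearity(self, rng):
        rel = rng.normal(0, 1, (4, 30))
        sm1 = self._smoothed(rel, ["chr1"] * 30, window=9)
        sm2 = self._smoothed(2.5 * rel, ["chr1"] * 30, window=9)
        np.testing.assert_allclose(sm2, 2.5 * sm1, atol=1e-12)

    def test_genes_sorted_by_position_not_input_order(self):
        # positions reversed relative to column order
        rel = np.array([[0.0, 0.0, 3.0, 0.0, 0.0, 0.0]])
        sm = self._smoothed(rel, ["chr1"] * 6, window=3,
                            starts=[5000, 4000, 3000, 2000, 1000, 0])
        # in position order the impulse sits at index 3: neighbours smoothed
        assert sm[0, 1] == pytest.approx(1.0)  # column 1 is position-adjacent
        assert sm[0, 2] == pytest.approx(1.0)
        assert sm[0, 3] == pytest.approx(1.0)
        assert sm[0, 0] == pytest.approx(0.0)


class TestCallArm:
    def _adata(self, smoothed, chroms, arms=None):
        adata = positioned_adata(np.zeros_like(smoothed), chroms, arms=arms)
        adata.layers["relative"] = np.zeros_like(np.asarray(smoothed, float))
        adata.layers["smoothed"] = np.asarray(smoothed, dtype=float)
        return adata

    def test_all_zero_is_neutral(self):
        adata = self._adata(np.zeros((5, 12)), ["chr7"] * 12)
        res = cnv.call_arm(adata, "7")
        assert (res.per_cell["call"] == "neutral").all()
        assert not res.sample_loss

    def test_threshold_is_strict(self):
        sm = np.full((4, 12), -0.15)  # exactly at -t_loss: neutral
        adata = self._adata(sm, ["chr7"] * 12)
        res = cnv.call_arm(adata, "7", t_loss=0.15)
        assert (res.per_cell["call"] == "neutral").all()

    def test_loss_and_gain_calls(self):
        sm = np.vstack([np.full(12, -0.4), np.full(12, 0.4), np.zeros(12)])
        adata = self._adata(sm, ["chr7"] * 12)
        res = cnv.call_arm(adata, "7", sample_fraction=0.5)
        assert list(res.per_cell["call"]) == ["loss", "gain", "neutral"]
        assert res.loss_fraction == pytest.approx(1 / 3)
        assert not res.sample_loss

    def test_arm_selection_by_label(self):
        sm = np.hstack([np.full((3, 6), -0.4), np.zeros((3, 6))])
        adata = self._adata(sm, ["chr7"] * 12, arms=["q"] * 6 + ["p"] * 6)
        res_q = cnv.call_arm(adata, "7q")
        assert (res_q.per_cell["call"] == "loss").all()
        res_p = cnv.call_arm(adata, "7p")
        assert (res_p.per_cell["call"] == "neutral").all()

    def test_missing_arm_rejected(self):
        adata = self._adata(np.zeros((2, 4)), ["chr1"] * 4)
        with pytest.raises(ValueError):
            cnv.call_arm(adata, "7q")

    def test_cell_order_invariance(self, rng):
        sm = rng.normal(0, 0.3, (10, 12))
        adata = self._adata(sm, ["chr7"] * 12)
        full = cnv.call_arm(adata, "7").per_cell.set_index("barcode")
        perm = rng.permutation(10)
        shuffled = adata[perm].copy()
        out = cnv.call_arm(shuffled, "7").per_cell.set_index("barcode")
        pd.testing.assert_frame_equal(
            out.sort_index(), full.sort_index(), check_like=True
        )


class TestEndToEndRecovery:
    def test_planted_loss_recovered_on_cohort(self, small_cohort, small_adata):
        """The NR patient's planted chr7 loss is called; others stay neutral."""
        meta = small_cohort.meta.set_index("barcode").loc[small_adata.obs_names]
        ref = np.asarray(
            (meta["response_group"] == "healthy") & (meta["celltype"] == "Mono")
        )
        adata = small_adata.copy()
        cnv.relative_expression(adata, ref)
        cnv.smooth_by_position(adata, window=100)
        truth = small_cohort.truth.patient_truth.set_index("patient")
        for patient in truth.index:
            if patient.startswith("HD"):
                continue
            mask = np.asarray(
                (meta["patient"] == patient) & (meta["celltype"] == "AML")
                & (meta["timepoint"] == "A")
            )
            res = cnv.call_arm(adata, "7", cells=mask)
            assert res.sample_loss == bool(truth.loc[patient, "loss"])
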