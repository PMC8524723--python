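import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonodyn import synthetic
from clonodyn.synthetic import SimConfig, SimConfigError, ExpansionPlan

from conftest import keyed_table


TINY = dict(n_responders=1, n_sd=0, n_nr=1, n_healthy=1, cells_per_sample=80)


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        cfg = SimConfig(**TINY)
        c1 = synthetic.generate_cohort(cfg, seed=5)
        c2 = synthetic.generate_cohort(SimConfig(**TINY), seed=5)
        pd.testing.assert_frame_equal(c1.meta, c2.meta)
        np.testing.assert_array_equal(c1.counts, c2.counts)
        for sample in c1.contigs:
            pd.testing.assert_frame_equal(c1.contigs[sample], c2.contigs[sample])

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(**TINY)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthetic.generate_cohort(cfg, seed=5).write(d1)
        synthetic.generate_cohort(SimConfig(**TINY), seed=5).write(d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_different_seeds_differ(self):
        cfg = SimConfig(**TINY)
        c1 = synthetic.generate_cohort(cfg, seed=5)
        c2 = synthetic.generate_cohort(SimConfig(**TINY), seed=6)
        assert not np.array_equal(c1.counts, c2.counts)


class TestRepertoireLaw:
    def test_healthy_max_clone_bounded(self):
        cfg = SimConfig(n_responders=0, n_sd=0, n_nr=0, n_healthy=3,
                        cells_per_sample=400)
        cohort = synthetic.generate_cohort(cfg, seed=2)
        table = keyed_table(cohort)
        sizes = table.dropna(subset=["clonotype"]).groupby(
            ["patient", "clonotype"]).size()
        assert sizes.max() <= cfg.healthy_max_clone

    def test_clone_size_marginals_match_law(self, rng):
        """KS distance between drawn healthy clone sizes and the configured
        truncated power law stays small at >= 2000 clones."""
        alpha, max_size = 3.5, 16
        sizes = []
        while len(sizes) < 2000:
            sizes.extend(
                synthetic.draw_clone_sizes(rng, 500, alpha, max_size).tolist()
            )
        support = np.arange(1, max_size + 1)
        p = support.astype(float) ** (-alpha)
        p /= p.sum()
        law_cdf = np.cumsum(p)
        emp_cdf = np.array([(np.asarray(sizes) <= s).mean() for s in support])
        assert np.abs(emp_cdf - law_cdf).max() <= 0.05

    def test_neutral_plan_all_unchanged(self):
        cfg = SimConfig(**TINY)
        cfg.plans = {g: ExpansionPlan(0, 0, 0) for g in ("responder", "SD", "NR")}
        cohort = synthetic.generate_cohort(cfg, seed=1)
        assert (cohort.truth.clone_truth["dynamics_class"] == "unchanged").all()

    def test_novel_clones_absent_pre(self, small_cohort, small_table):
        truth = small_cohort.truth.clone_truth
        novel = truth[truth["novel"]]
        pre = small_table[(small_table["phase"] == "pre")]
        pre_keys = set(zip(pre["patient"], pre["clonotype"].dropna()))
        for patient, key in zip(novel["patient"], novel["clonotype"]):
            assert (patient, key) not in pre_keys


class TestConfigValidation:
    def test_novel_budget_error(self):
        with pytest.raises(SimConfigError):
            SimConfig(cells_per_sample=5,
                      plans={"responder": ExpansionPlan(0, 10, 0),
                             "SD": ExpansionPlan(0, 0, 0),
                             "NR": ExpansionPlan(0, 0, 0)})

    def test_invalid_rate_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(doublet_rate=1.5)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(SimConfigError):
            ExpansionPlan(1, 1, 1, fold_expand=0.0)


class TestPlantedStructure:
    def test_doublet_and_lowq_rates(self, small_cohort):
        truth = small_cohort.truth.cell_truth
        cfg = small_cohort.config
        n_samples = len(small_cohort.contigs)
        expected_doub = n_samples * round(cfg.doublet_rate * cfg.cells_per_sample)
        assert truth["doublet"].sum() == expected_doub
        assert truth["lowq"].sum() == n_samples * round(
            cfg.lowq_rate * cfg.cells_per_sample
        )

    def test_zero_doublet_rate_means_no_planted_positives(self):
        cfg = SimConfig(**{**TINY, "doublet_rate": 0.0})
        cohort = synthetic.generate_cohort(cfg, seed=4)
        assert not cohort.truth.cell_truth["doublet"].any()

    def test_arm_loss_depresses_arm_counts(self, small_cohort):
        truth = small_cohort.truth.patient_truth.set_index("patient")
        meta = small_cohort.meta
        arm_mask = synthetic._arm_gene_mask(
            small_cohort.gene_positions, small_cohort.config.arm_loss_arm,
            small_cohort.gene_names,
        )
        aml = meta["celltype"] == "AML"
        lost_p = truth[truth["loss"]].index
        lost = meta.index[aml & meta["patient"].isin(lost_p)]
        kept = meta.index[aml & ~meta["patient"].isin(lost_p)]
        mean_lost = small_cohort.counts[lost][:, arm_mask].mean()
        mean_kept = small_cohort.counts[kept][:, arm_mask].mean()
        assert mean_lost < mean_kept * 0.85

    def test_truth_eval_reports_dynamics_recovery(self, small_cohort, small_table):
        from clonodyn import dynamics

        res = dynamics.classify_dynamics(small_table)
        report = synthetic.truth_eval(small_cohort.truth, dynamics_results=res)
        assert 0.0 <= report["dynamics_expanded"]["sensitivity"] <= 1.0
        assert report["dynamics_expanded"]["tp"] > 0

    def test_truth_eval_rejects_unknown_patients(self, small_cohort):
        with pytest.raises(ValueError):
            synthetic.truth_eval(small_cohort.truth, arm_calls={"NOPE": True})


class TestScoreSeparation:
    def test_exhaustion_program_separates_groups(self, small_cohort, small_adata):
        """NR CD8 cells carry the planted exhaustion program; responder
        pre-treatment CD8 cells do not."""
        from clonodyn import signatures

        scores = signatures.score_cells(small_adata, small_cohort.gene_sets)
        report = synthetic.truth_eval(
            small_cohort.truth, scores=scores, meta=small_cohort.meta
        )
        assert report["exhaustion_separation"]["p"] < 0.01
        assert report["exhaustion_separation"]["rank_biserial"] > 0
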