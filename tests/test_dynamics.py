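import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonodyn import dynamics
from clonodyn.dynamics import clone_table, fisher_exact_two_sided


def fisher_enumeration(table) -> float:
    """Independent oracle: full hypergeometric enumeration of all 2x2
    tables with the observed margins, summing point probabilities no
    larger than the observed one (1e-7 relative tolerance)."""
    (a, b), (c, d) = np.asarray(table)
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestCloneTable:
    def test_layout(self):
        assert clone_table(0, 100, 10, 100).tolist() == [[0, 100], [10, 90]]
        assert clone_table(5, 10, 5, 10).tolist() == [[5, 5], [5, 5]]
        assert clone_table(3, 3, 0, 7).tolist() == [[3, 0], [0, 7]]

    @pytest.mark.parametrize("args", [(-1, 5, 0, 5), (6, 5, 0, 5), (0, 0, 1, 5)])
    def test_bounds_enforced(self, args):
        with pytest.raises(ValueError):
            clone_table(*args)


class TestFisherTwoSided:
    def test_identical_proportions(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_small_table_against_hand_enumeration(self):
        # margins (5,5)/(4,6): P(a=0) + P(a=4) = (6 + 6)/252
        p = fisher_exact_two_sided([[0, 5], [4, 1]])
        assert p == pytest.approx(12 / 252, rel=1e-9)
        assert p == pytest.approx(0.047619, abs=1e-6)

    def test_row_swap_symmetry(self, rng):
        for _ in range(20):
            t = rng.integers(0, 15, size=(2, 2))
            assert fisher_exact_two_sided(t) == pytest.approx(
                fisher_exact_two_sided(t[::-1]), rel=1e-12
            )

    def test_zero_margin_convention(self):
        assert fisher_exact_two_sided([[0, 0], [3, 7]]) == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            t = rng.integers(0, 16, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_two_sided(t) == pytest.approx(
                fisher_enumeration(t), abs=1e-9
            )


def make_table(clone_counts_pre, clone_counts_post, patient="PT1"):
    """Build a cell table from {clone: count} dicts per phase."""
    rows = []
    for tp, phase, counts in (("A", "pre", clone_counts_pre),
                              ("B", "post", clone_counts_post)):
        i = 0
        for key, n in counts.items():
            for _ in range(n):
                rows.append(dict(
                    barcode=f"{patient}_{tp}_{i}", patient=patient,
                    timepoint=tp, phase=phase, response_group="responder",
                    celltype="CD8 CTL", clonotype=f"{patient}|{key}",
                ))
                i += 1
    return pd.DataFrame(rows)


class TestClassifyDynamics:
    def test_novel_expansion(self):
        pre = {"bg": 1000}
        post = {"bg": 985, "nov": 15}
        res = dynamics.classify_dynamics(make_table(pre, post))
        row = res[res["clonotype"] == "PT1|nov"].iloc[0]
        assert row["dynamics_class"] == "expanded" and bool(row["novel"])
        assert row["p_value"] < 0.05

    def test_equal_frequencies_unchanged(self):
        pre = {"k": 1, "bg": 999}
        post = {"k": 1, "bg": 999}
        res = dynamics.classify_dynamics(make_table(pre, post))
        row = res[res["clonotype"] == "PT1|k"].iloc[0]
        assert row["dynamics_class"] == "unchanged"
        assert row["p_value"] == 1.0

    def test_contraction(self):
        pre = {"k": 30, "bg": 470}
        post = {"k": 2, "bg": 498}
        res = dynamics.classify_dynamics(make_table(pre, post))
        row = res[res["clonotype"] == "PT1|k"].iloc[0]
        assert row["dynamics_class"] == "contracted"
        assert not bool(row["novel"])

    def test_patient_missing_phase_skipped(self):
        table = make_table({"k": 5}, {"k": 5})
        table = table[table["timepoint"] == "A"]
        with pytest.warns(UserWarning, match="lacks a phase"):
            res = dynamics.classify_dynamics(table)
        assert res.empty

    def test_order_invariance(self):
        pre = {"a": 20, "b": 5, "bg": 475}
        post = {"a": 2, "b": 50, "bg": 448}
        table = make_table(pre, post)
        res1 = dynamics.classify_dynamics(table)
        res2 = dynamics.classify_dynamics(
            table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        )
        merged = res1.merge(res2, on="clonotype", suffixes=("_1", "_2"))
        assert (merged["dynamics_class_1"] == merged["dynamics_class_2"]).all()

    def test_bh_correction_is_more_conservative(self):
        pre = {f"k{i}": 8 for i in range(20)} | {"bg": 340}
        post = {f"k{i}": (16 if i < 3 else 8) for i in range(20)} | {"bg": 316}
        table = make_table(pre, post)
        raw = dynamics.classify_dynamics(table, correction="none")
        bh = dynamics.classify_dynamics(table, correction="BH")
        n_raw = (raw["dynamics_class"] != "unchanged").sum()
        n_bh = (bh["dynamics_class"] != "unchanged").sum()
        assert n_bh <= n_raw


class TestSummarizeDynamics:
    def test_all_unchanged_cohort(self):
        res = dynamics.classify_dynamics(
            make_table({"a": 5, "b": 5}, {"a": 5, "b": 5})
        )
        out = dynamics.summarize_dynamics(res, {"PT1": "responder"})
        row = out["by_response_group"].iloc[0]
        assert row["expanded"] == row["contracted"] == row["novel"] == 0

    def test_group_counts_partition_cohort(self):
        t1 = make_table({"k": 30, "bg": 470}, {"k": 2, "bg": 498}, patient="PT1")
        t2 = make_table({"bg": 500}, {"bg": 485, "nov": 15}, patient="PT2")
        res = dynamics.classify_dynamics(pd.concat([t1, t2], ignore_index=True))
        out = dynamics.summarize_dynamics(
            res, {"PT1": "NR", "PT2": "responder"}
        )["by_response_group"]
        total = out[["expanded", "contracted", "unchanged"]].sum().sum()
        assert total == len(res)

    def test_novel_flag_semantics_on_cohort(self, small_cohort, small_table):
        """Novel means significantly expanded AND unobserved pre-treatment;
        planted novel clones that reach significance must carry the flag."""
        res = dynamics.classify_dynamics(small_table)
        detected_novel = res[res["novel"]]
        assert len(detected_novel) > 0
        assert (detected_novel["n_pre"] == 0).all()
        assert (detected_novel["dynamics_class"] == "expanded").all()
        truth = small_cohort.truth.clone_truth
        planted = truth[truth["novel"]].set_index(["patient", "clonotype"])
        merged = res.set_index(["patient", "clonotype"])
        planted_detected = merged.loc[
            merged.index.intersection(planted.index)
        ]
        expanded = planted_detected[planted_detected["dynamics_class"] == "expanded"]
        assert len(expanded) > 0
        assert expanded["novel"].all()
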