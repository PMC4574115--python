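"""DMP calling: ANOVA correctness, BH behaviour, thresholds, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

import senesig as sg
from senesig.dmp import TINY_P

from conftest import make_annotation, make_beta


def two_group_labels(n_a=3, n_b=3):
    return {f"s{j}": ("A" if j < n_a else "B") for j in range(n_a + n_b)}


def anova_oracle(a, b):
    """Brute-force one-way ANOVA via the explicit sum-of-squares formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ssb == 0:
        return 0.0, 1.0
    F = (ssb / df1) / (ssw / df2)
    # regularized incomplete beta form of the F tail
    p = special.betainc(df2 / 2, df1 / 2, df2 / (df2 + df1 * F))
    return F, p


class TestFTest:
    def test_no_variance_gives_null_result(self):
        bm = make_beta([[0.2] * 6])
        t = sg.f_test(bm, two_group_labels())
        assert t["F"].iloc[0] == 0.0 and t["p"].iloc[0] == 1.0

    def test_equal_group_means_give_null_result(self):
        bm = make_beta([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]])
        t = sg.f_test(bm, two_group_labels())
        assert t["F"].iloc[0] == 0.0 and t["p"].iloc[0] == 1.0

    def test_hand_computed_case(self):
        bm = make_beta([[0.1, 0.2, 0.3, 0.6, 0.7, 0.8]])
        t = sg.f_test(bm, two_group_labels(), order=("A", "B"))
        assert t["F"].iloc[0] == pytest.approx(37.5, rel=1e-12)
        assert t["delta"].iloc[0] == pytest.approx(0.5, abs=1e-12)
        assert t["p"].iloc[0] == pytest.approx(anova_oracle(
            [0.1, 0.2, 0.3], [0.6, 0.7, 0.8])[1], rel=1e-10)

    def test_zero_within_variance_unequal_means_is_degenerate(self):
        bm = make_beta([[0.2, 0.2, 0.2, 0.8, 0.8, 0.8]])
        t = sg.f_test(bm, two_group_labels())
        assert t["p"].iloc[0] == TINY_P
        assert bool(t["degenerate"].iloc[0])

    def test_matches_sum_of_squares_oracle_on_random_probes(self):
        rng = np.random.default_rng(123)
        X = rng.random((100, 6))
        bm = make_beta(X)
        t = sg.f_test(bm, two_group_labels(), order=("A", "B"))
        for i, pid in enumerate(bm.probe_ids):
            F, p = anova_oracle(X[i, :3], X[i, 3:])
            assert abs(t.at[pid, "p"] - p) < 1e-10
            assert abs(t.at[pid, "F"] - F) < 1e-8

    def test_missing_policy_drops_underpowered_probes(self):
        X = np.full((2, 6), 0.4)
        X[0, :2] = np.nan  # group A keeps only one value for probe 0
        X[1, 0] = np.nan   # probe 1 keeps 2 + 3
        bm = make_beta(X)
        t = sg.f_test(bm, two_group_labels())
        assert list(t.index) == ["p1"]


class TestBH:
    def test_hand_example(self):
        assert np.allclose(sg.bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identity_cases(self):
        assert np.allclose(sg.bh_qvalues([1.0, 1.0]), [1.0, 1.0])
        assert np.allclose(sg.bh_qvalues([0.04]), [0.04])
        assert sg.bh_qvalues([]).size == 0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_permutation_invariant_and_dominates_p(self, pvals):
        p = np.array(pvals)
        q = sg.bh_qvalues(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0 + 1e-12).all()
        perm = np.argsort(p, kind="stable")[::-1]
        q_perm = sg.bh_qvalues(p[perm])
        assert np.allclose(np.sort(q_perm), np.sort(q))


class TestCallDmps:
    @pytest.fixture
    def samples(self):
        rows = [
            {"group": "EP", "experiment": "exp1", "replicate": r,
             "age": np.nan, "paired_with": ""} for r in (1, 2, 3)
        ] + [
            {"group": "DS", "experiment": "exp1", "replicate": r,
             "age": np.nan, "paired_with": ""} for r in (1, 2, 3)
        ]
        return sg.SampleTable(
            pd.DataFrame(rows, index=pd.Index(
                [f"s{j}" for j in range(6)], name="sample_id"))
        )

    def test_strict_thresholds_at_the_boundary(self, samples):
        # both probes have zero within-group variance, so q is far below
        # 0.01; only the probe with |delta| strictly above 0.3 is called
        bm = make_beta(
            [
                [0.20, 0.20, 0.20, 0.51, 0.51, 0.51],  # delta = 0.31
                [0.20, 0.20, 0.20, 0.50, 0.50, 0.50],  # delta = 0.30 exactly
            ]
        )
        records = sg.call_dmps(bm, samples, "EP", "DS")
        assert [r.probe_id for r in records] == ["p0"]
        assert records[0].direction == "hyper"

    def test_relaxing_thresholds_is_monotone(self, two_experiment_sim):
        s = two_experiment_sim
        strict = {
            r.probe_id
            for r in sg.call_dmps(s["beta"], s["samples"], "EP", "DS",
                                  experiment="exp1")
        }
        relaxed = {
            r.probe_id
            for r in sg.call_dmps(s["beta"], s["samples"], "EP", "DS",
                                  experiment="exp1", q_thresh=0.05,
                                  delta_thresh=0.2)
        }
        assert strict <= relaxed

    def test_sorted_by_abs_delta_then_probe_id(self, two_experiment_sim):
        s = two_experiment_sim
        recs = s["calls"]["exp1"]
        keys = [(-abs(r.delta), r.probe_id) for r in recs]
        assert keys == sorted(keys)

    def test_small_group_is_an_error(self, samples):
        bm = make_beta(np.full((3, 6), 0.4))
        with pytest.raises(ValueError, match=">=2 samples"):
            sg.call_dmps(bm, samples, "EP", "normal")

    def test_recovers_planted_sites_from_truth(self, two_experiment_sim):
        """Sensitivity and observed false-discovery proportion vs the oracle."""
        s = two_experiment_sim
        truth = s["truth"]
        called = {r.probe_id for r in s["calls"]["exp1"]}
        plantable = {
            p for p, d in truth.planted("exp1").items()
            if abs(truth.probes.at[p, "delta_exp1"]) > 0.3
        }
        tp = len(called & plantable)
        sensitivity = tp / len(plantable)
        # anything with a truly nonzero delta is not a false discovery
        truly_null = called - set(truth.planted("exp1"))
        fdp = len(truly_null) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert fdp <= 0.05


class TestFilterProbes:
    def test_drops_sex_chromosome_probes(self):
        rows = [(f"p{i}", "chr1", 100 * i, "", "intergenic", ()) for i in range(8)]
        rows += [
            ("px", "chrX", 50, "", "intergenic", ("sex_chromosome",)),
            ("py", "chrY", 60, "", "intergenic", ("sex_chromosome",)),
        ]
        ann = make_annotation(rows)
        bm = make_beta(np.full((10, 2), 0.5), probes=[r[0] for r in rows])
        out = sg.filter_probes(bm, ann)
        assert out.probe_ids == [f"p{i}" for i in range(8)]

    def test_identity_when_nothing_flagged(self):
        rows = [(f"p{i}", "chr1", 100 * i, "", "promoter", ()) for i in range(4)]
        ann = make_annotation(rows)
        bm = make_beta(np.full((4, 2), 0.5), probes=[r[0] for r in rows])
        policy = sg.FilterPolicy(drop_sex_chromosomes=False)
        assert sg.filter_probes(bm, ann, policy).probe_ids == bm.probe_ids

    def test_probe_with_two_reasons_removed_once(self):
        rows = [
            ("pa", "chrY", 10, "", "intergenic", ("multimapping",)),
            ("pb", "chr2", 20, "", "intergenic", ()),
        ]
        ann = make_annotation(rows)
        bm = make_beta(np.full((2, 2), 0.5), probes=["pa", "pb"])
        out = sg.filter_probes(bm, ann)
        assert out.probe_ids == ["pb"]

    def test_unannotated_probe_is_an_error(self):
        ann = make_annotation([("pa", "chr1", 10, "", "intergenic", ())])
        bm = make_beta(np.full((2, 2), 0.5), probes=["pa", "pz"])
        with pytest.raises(ValueError, match="pz"):
            sg.filter_probes(bm, ann)
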