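"""Signature groups, DS-discordance partition, enrichment, co-methylation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import senesig as sg
from senesig.dmp import DMPRecord

from conftest import make_annotation


def rec(pid, delta):
    return DMPRecord(pid, F=50.0, p=1e-6, q=1e-5, delta=delta,
                     direction="hyper" if delta > 0 else "hypo")


class TestClassifySignatureGroups:
    def test_trivial_assignments(self):
        dmps1 = [rec("a", 0.40), rec("b", 0.40), rec("c", 0.40)]
        dmps2 = [rec("b", 0.35), rec("c", -0.35)]
        delta1 = {"a": 0.40, "b": 0.40, "c": 0.40}
        delta2 = {"a": 0.05, "b": 0.35, "c": -0.35}
        g = sg.classify_signature_groups(dmps1, dmps2, delta1, delta2)
        assert g.exp1_only == {"a": "hyper"}
        assert g.agree == {"b": "hyper"}
        assert g.disagree == {"c": "hyper"}
        assert g.unclassified == set()

    def test_large_minor_delta_without_call_is_unclassified(self):
        g = sg.classify_signature_groups(
            [rec("a", 0.4)], [], {"a": 0.4}, {"a": 0.2}
        )
        assert g.unclassified == {"a"}
        assert not g.exp1_only

    def test_missing_delta_map_entry_is_an_error(self):
        with pytest.raises(ValueError, match="delta map"):
            sg.classify_signature_groups([rec("a", 0.4)], [], {"a": 0.4}, {})

    def test_matches_brute_force_set_algebra(self):
        """Exact agreement with an independent reimplementation, 1000 probes."""
        rng = np.random.default_rng(77)
        probes = [f"cg{i:05d}" for i in range(1000)]
        delta1 = {p: float(rng.uniform(-0.6, 0.6)) for p in probes}
        delta2 = {p: float(rng.uniform(-0.6, 0.6)) for p in probes}
        called1 = [p for p in probes if abs(delta1[p]) > 0.3 and rng.random() < 0.8]
        called2 = [p for p in probes if abs(delta2[p]) > 0.3 and rng.random() < 0.8]
        dmps1 = [rec(p, delta1[p]) for p in called1]
        dmps2 = [rec(p, delta2[p]) for p in called2]
        g = sg.classify_signature_groups(dmps1, dmps2, delta1, delta2)

        # independent brute force over the union of calls
        exp1_only, exp2_only, agree, disagree, unclassified = {}, {}, {}, {}, set()
        s1, s2 = set(called1), set(called2)
        for p in s1 | s2:
            dir1 = "hyper" if delta1[p] > 0 else "hypo"
            dir2 = "hyper" if delta2[p] > 0 else "hypo"
            if p in s1 and p in s2:
                (agree if dir1 == dir2 else disagree)[p] = dir1
            elif p in s1:
                if abs(delta2[p]) < 0.1:
                    exp1_only[p] = dir1
                else:
                    unclassified.add(p)
            else:
                if abs(delta1[p]) < 0.1:
                    exp2_only[p] = dir2
                else:
                    unclassified.add(p)
        assert g.exp1_only == exp1_only
        assert g.exp2_only == exp2_only
        assert g.agree == agree
        assert g.disagree == disagree
        assert g.unclassified == unclassified

    def test_signature_extraction_splits_directions(self):
        g = sg.classify_signature_groups(
            [rec("a", 0.4), rec("b", -0.4)], [rec("a", 0.4), rec("b", -0.4)],
            {"a": 0.4, "b": -0.4}, {"a": 0.4, "b": -0.4},
        )
        sig = g.signature("agree")
        assert sig.hyper_probes == ("a",) and sig.hypo_probes == ("b",)


class TestClassifyDsDifferences:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [
            (0.05, 0.02, "batch_effect"),
            (0.40, 0.05, "unique_change"),
            (0.40, 0.30, "common_same_direction"),
            (0.40, -0.30, "common_opposite_direction"),
            (0.10, 0.10, "common_same_direction"),  # boundary goes to "change"
        ],
    )
    def test_category_rules(self, d1, d2, expected):
        out = sg.classify_ds_differences(["p"], {"p": d1}, {"p": d2})
        assert out["p"] == expected

    def test_partition_is_exhaustive_and_exact(self):
        rng = np.random.default_rng(5)
        probes = [f"p{i}" for i in range(1000)]
        delta1 = {p: float(rng.uniform(-0.5, 0.5)) for p in probes}
        delta2 = {p: float(rng.uniform(-0.5, 0.5)) for p in probes}
        out = sg.classify_ds_differences(probes, delta1, delta2)
        assert len(out) == len(probes)
        counts = pd.Series(out).value_counts()
        assert counts.sum() == len(probes)
        for p in probes:
            big1, big2 = abs(delta1[p]) >= 0.1, abs(delta2[p]) >= 0.1
            if not big1 and not big2:
                assert out[p] == "batch_effect"
            elif big1 != big2:
                assert out[p] == "unique_change"
            elif np.sign(delta1[p]) == np.sign(delta2[p]):
                assert out[p] == "common_same_direction"
            else:
                assert out[p] == "common_opposite_direction"


class TestOverlapEnrichment:
    def test_identical_sets_spanning_universe(self):
        uni = [f"x{i}" for i in range(50)]
        enr = sg.overlap_enrichment(uni, uni, uni, n_resamples=100, seed=1)
        assert enr.fold_analytic == 1.0
        assert enr.fold_empirical == 1.0
        assert enr.empirical_p == 1.0

    def test_disjoint_sets_in_large_universe(self):
        uni = [f"x{i}" for i in range(2000)]
        enr = sg.overlap_enrichment(uni[:20], uni[20:40], uni,
                                    n_resamples=200, seed=2)
        assert enr.fold_analytic == 0.0
        assert enr.empirical_p == 1.0

    def test_known_fold_with_resampled_background(self):
        uni = [f"x{i}" for i in range(1000)]
        a, b = uni[:100], uni[60:110]  # overlap 40
        enr = sg.overlap_enrichment(a, b, uni, n_resamples=1000, seed=3)
        assert enr.fold_analytic == pytest.approx(8.0)
        assert 7.2 <= enr.fold_empirical <= 8.8

    def test_empty_set_reports_missing(self):
        uni = [f"x{i}" for i in range(10)]
        enr = sg.overlap_enrichment([], uni[:5], uni, n_resamples=10, seed=4)
        assert np.isnan(enr.fold_analytic) and enr.message

    def test_empirical_fold_converges_to_analytic(self):
        uni = [f"x{i}" for i in range(1000)]
        a, b = uni[:100], uni[60:110]
        enr = sg.overlap_enrichment(a, b, uni, n_resamples=50_000, seed=5)
        assert abs(enr.fold_empirical - enr.fold_analytic) / enr.fold_analytic < 0.05
        assert 1 / 50_001 <= enr.empirical_p <= 1.0


class TestComethylation:
    def test_nearest_probe_selection_and_distance_cap(self):
        ann = make_annotation(
            [
                ("i", "chr1", 1000, "", "intergenic", ()),
                ("n1", "chr1", 1100, "", "intergenic", ()),
                ("n2", "chr1", 2000, "", "intergenic", ()),
                ("far", "chr2", 5000, "", "intergenic", ()),
                ("far2", "chr2", 5600, "", "intergenic", ()),
            ]
        )
        deltas = {"i": 0.4, "n1": 0.35, "n2": 0.0, "far": 0.4, "far2": 0.1}
        prof = sg.comethylation_profile(
            ["i", "far"], ann, deltas, max_dist=500, n_resamples=10, seed=1
        )
        # "i" pairs with its 100-bp neighbor; "far"'s nearest is 600 bp away
        assert list(prof.pairs["index_probe"]) == ["i"]
        assert prof.pairs["neighbor_probe"].iloc[0] == "n1"
        assert prof.pairs["distance"].iloc[0] == 100
        assert prof.excluded == ["far"]

    def test_index_probes_kept_as_neighbors(self):
        ann = make_annotation(
            [
                ("a", "chr1", 1000, "", "intergenic", ()),
                ("b", "chr1", 1200, "", "intergenic", ()),
            ]
        )
        prof = sg.comethylation_profile(
            ["a", "b"], ann, {"a": 0.4, "b": 0.38}, n_resamples=5, seed=1
        )
        # both index probes are each other's neighbor and both are retained
        assert len(prof.pairs) == 2

    def test_nearest_neighbors_match_all_pairs_scan(self):
        rng = np.random.default_rng(11)
        n = 300
        rows = []
        for i in range(n):
            rows.append(
                (f"p{i:03d}", f"chr{rng.integers(1, 4)}",
                 int(rng.integers(0, 50_000)), "", "intergenic", ())
            )
        ann = make_annotation(rows)
        nn = sg.nearest_neighbors(ann)
        t = ann.table
        for pid in t.index:
            same = t[(t["chrom"] == t.at[pid, "chrom"]) & (t.index != pid)]
            if same.empty:
                assert pid not in nn.index
                continue
            dist = (same["pos"] - t.at[pid, "pos"]).abs()
            best = dist.min()
            assert nn.at[pid, "distance"] == best
            # the chosen neighbor is among the distance-minimizers
            assert nn.at[pid, "neighbor"] in set(dist.index[dist == best])

    def test_recovered_rho_matches_monte_carlo_oracle(self):
        """Planted neighbor deltas = index deltas + Gaussian noise."""
        params = sg.SimParams(
            n_probes=8000, nu=500.0, neighbor_fraction=0.6,
            neighbor_noise_sd=0.1, seed=21,
        )
        beta, samples, ann, truth = sg.simulate_two_experiment_senescence(params)
        recs = sg.call_dmps(beta, samples, "EP", "DS", experiment="exp1")
        ep = samples.samples_in("EP", "exp1")
        ds = samples.samples_in("DS", "exp1")
        delta = beta.values[ds].mean(axis=1) - beta.values[ep].mean(axis=1)
        prof = sg.comethylation_profile(recs, ann, delta, n_resamples=20, seed=1)
        assert len(prof.pairs) > 150

        rng = np.random.default_rng(0)
        planted = truth.probes.loc[
            truth.probes["delta_exp1"].abs() > 0.29, "delta_exp1"
        ].to_numpy()
        d = rng.choice(planted, 100_000)
        implied = stats.spearmanr(d, d + rng.normal(0, 0.1, d.size))[0]
        assert prof.rho == pytest.approx(implied, abs=0.1)
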