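"""Footprint post-processing, memory sites, co-binding, performance sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonemem import footprints, simulate
from clonemem._rng import stream
from clonemem.footprints import (
    MemorySiteSet,
    _normalize_log2_or,
    _odds_ratio,
    call_memory_sites,
    cobinding_score,
    collapse_overlapping_sites,
    filter_low_bins,
    footprint_vs_binding_performance,
    quantile_transform_scores,
    site_distances,
)


def make_table(control, case, conditions=("control", "recovered")):
    rows = []
    for cond, scores in zip(conditions, (control, case)):
        for (peak, b), s in scores.items():
            rows.append((peak, b, cond, s))
    return pd.DataFrame(rows, columns=["peak", "bin_start", "condition", "score"])


class TestFilterAndTransform:
    def test_low_max_bins_excluded(self):
        tbl = make_table({("p1", 0): 0.1, ("p1", 10): 0.15},
                         {("p1", 0): 0.19, ("p1", 10): 0.3})
        out = filter_low_bins(tbl)
        assert set(out["bin_start"]) == {10}

    def test_strictly_increasing_maps_to_grid(self):
        vals = np.arange(11.0)
        tbl = pd.DataFrame({"peak": "p", "bin_start": np.arange(11) * 10,
                            "condition": "c", "score": vals})
        out = quantile_transform_scores(tbl)
        assert np.allclose(sorted(out["score"]), np.linspace(0, 1, 11))

    def test_rank_preserving(self):
        rng = stream(40, "qt")
        vals = rng.normal(size=200)
        tbl = pd.DataFrame({"peak": "p", "bin_start": np.arange(200) * 10,
                            "condition": "c", "score": vals})
        out = quantile_transform_scores(tbl)
        tau = stats.kendalltau(vals, out["score"]).statistic
        assert tau == pytest.approx(1.0)

    def test_rank_equivalent_conditions_transform_identically(self):
        rng = stream(41, "qt2")
        vals = rng.normal(size=100)
        tbl = pd.concat(
            [
                pd.DataFrame({"peak": "p", "bin_start": np.arange(100) * 10,
                              "condition": "a", "score": vals}),
                pd.DataFrame({"peak": "p", "bin_start": np.arange(100) * 10,
                              "condition": "b", "score": 100 + 3 * vals}),
            ]
        )
        out = quantile_transform_scores(tbl)
        a = out[out["condition"] == "a"]["score"].to_numpy()
        b = out[out["condition"] == "b"]["score"].to_numpy()
        assert np.allclose(a, b)


class TestMemorySites:
    FAM = pd.DataFrame({"family": "f", "peak": ["p1", "p1"], "bin_start": [0, 10]})

    def test_identical_conditions_empty(self):
        tbl = make_table({("p1", 0): 0.5, ("p1", 10): 0.5},
                         {("p1", 0): 0.5, ("p1", 10): 0.5})
        mem = call_memory_sites(tbl, "recovered", "control", self.FAM)
        assert len(mem["f"]) == 0

    def test_delta_exactly_at_threshold_included(self):
        tbl = make_table({("p1", 0): 0.3, ("p1", 10): 0.3},
                         {("p1", 0): 0.5, ("p1", 10): 0.49})
        mem = call_memory_sites(tbl, "recovered", "control", self.FAM, delta_min=0.2)
        assert set(mem["f"].sites["bin_start"]) == {0}

    def test_loss_calling_with_negative_sign(self):
        tbl = make_table({("p1", 0): 0.6, ("p1", 10): 0.6},
                         {("p1", 0): 0.35, ("p1", 10): 0.55})
        mem = call_memory_sites(tbl, "recovered", "control", self.FAM, sign=-1)
        assert set(mem["f"].sites["bin_start"]) == {0}

    def test_planted_gains_recovered_exactly(self):
        cfg = simulate.SimulationConfig(seed=50)
        fs = simulate.simulate_footprints(cfg, delta=0.3)
        filt = filter_low_bins(fs.table)
        mem = call_memory_sites(filt, fs.truth["case"], fs.truth["control"],
                                fs.family_sites)
        for fam, planted in fs.truth["planted_sites"].items():
            got = set(zip(mem[fam].sites["peak"], mem[fam].sites["bin_start"]))
            assert got == planted


class TestCobinding:
    def _mem(self, fam, peaks):
        df = pd.DataFrame({"peak": list(peaks), "bin_start": 0,
                           "delta": 0.3, "midpoint": 5.0})
        return MemorySiteSet(family=fam, sites=df)

    def test_printed_contingency_fixture(self):
        # both=10, first=5, second=5, neither=80 -> OR = 10*80/(5*5) = 32
        assert _odds_ratio(10, 5, 5, 80) == pytest.approx(32.0)
        assert np.log2(_odds_ratio(10, 5, 5, 80)) == pytest.approx(5.0)

    def test_haldane_correction_keeps_or_finite(self):
        assert np.isfinite(_odds_ratio(10, 0, 5, 80))
        assert np.isfinite(_odds_ratio(0, 0, 0, 0))

    def test_recovered_table_from_memberships(self):
        universe = [f"p{i}" for i in range(100)]
        a = self._mem("A", universe[:15])   # both = 10, first-only = 5
        b = self._mem("B", universe[:10] + universe[15:20])
        out = cobinding_score({"A": a, "B": b}, pd.Index(universe))
        row = out.iloc[0]
        assert (row["both"], row["first_only"], row["second_only"], row["neither"]) \
            == (10, 5, 5, 80)
        assert row["odds_ratio"] == pytest.approx(32.0)
        assert row["log2_or"] == pytest.approx(5.0)

    def test_independent_memberships_log2_or_near_zero(self):
        rng = stream(42, "cb-null")
        universe = pd.Index([f"p{i}" for i in range(400)])
        log2s = []
        for rep in range(30):
            in_a = rng.random(400) < 0.3
            in_b = rng.random(400) < 0.3
            a = self._mem("A", universe[in_a])
            b = self._mem("B", universe[in_b])
            out = cobinding_score({"A": a, "B": b}, universe)
            log2s.append(out["log2_or"].iloc[0])
        m = np.mean(log2s)
        se = np.std(log2s, ddof=1) / np.sqrt(len(log2s))
        assert abs(m) <= 3 * se + 1e-9

    def test_degenerate_normalization_maps_to_one(self):
        out = _normalize_log2_or(np.array([5.0, 5.0, 5.0]))
        assert np.allclose(out, 1.0)
        out = _normalize_log2_or(np.array([-2.0, -2.0]))
        assert np.allclose(out, -1.0)

    def test_scores_bounded_and_sign_matched(self):
        vals = np.array([3.0, 1.0, 0.5, -0.5, -4.0, 0.0])
        out = _normalize_log2_or(vals)
        assert ((out >= -1) & (out <= 1)).all()
        # no sign flips (magnitudes below the 10th percentile clip to 0)
        assert (out * vals >= 0).all()
        # monotone in log2_or within each sign class
        assert out[0] >= out[1] >= out[2]
        assert out[3] >= out[4]

    def test_empty_family_reported_missing(self):
        universe = pd.Index(["p0", "p1"])
        a = self._mem("A", ["p0"])
        b = MemorySiteSet("B", a.sites.iloc[:0])
        out = cobinding_score({"A": a, "B": b}, universe)
        assert np.isnan(out["odds_ratio"].iloc[0])


class TestDistances:
    def test_different_peaks_no_distance(self):
        a = MemorySiteSet("A", pd.DataFrame(
            {"peak": ["p1"], "bin_start": [100], "delta": [0.3], "midpoint": [105.0]}))
        b = MemorySiteSet("B", pd.DataFrame(
            {"peak": ["p2"], "bin_start": [100], "delta": [0.3], "midpoint": [105.0]}))
        assert site_distances(a, b).size == 0

    def test_midpoint_arithmetic(self):
        a = MemorySiteSet("A", pd.DataFrame(
            {"peak": ["p1"], "bin_start": [95], "delta": [0.3], "midpoint": [100.0]}))
        b = MemorySiteSet("B", pd.DataFrame(
            {"peak": ["p1"], "bin_start": [110], "delta": [0.3], "midpoint": [115.0]}))
        assert site_distances(a, b).tolist() == [15.0]

    def test_planted_spacing_mode(self):
        cfg = simulate.SimulationConfig(seed=51)
        fs = simulate.simulate_footprints(cfg, pair_distance=15)
        mem = call_memory_sites(filter_low_bins(fs.table), fs.truth["case"],
                                fs.truth["control"], fs.family_sites)
        d = site_distances(mem["famA"], mem["famB"])
        mode = pd.Series(d).mode().iloc[0]
        assert abs(mode - 15) <= 10  # bin resolution


class TestPerformanceSweep:
    def test_perfect_ranking_reaches_corner(self):
        deltas = pd.DataFrame({"peak": [f"p{i}" for i in range(8)],
                               "delta": [0.9, 0.8, 0.7, 0.6, 0.1, 0.05, 0.0, -0.1]})
        labels = pd.Series([True] * 4 + [False] * 4,
                           index=[f"p{i}" for i in range(8)])
        curve = footprint_vs_binding_performance(deltas, labels)
        assert ((curve["sensitivity"] == 1) & (curve["specificity"] == 1)).any()

    def test_lowest_threshold_boundary(self):
        deltas = pd.DataFrame({"peak": ["a", "b"], "delta": [0.2, 0.5]})
        labels = pd.Series([False, True], index=["a", "b"])
        curve = footprint_vs_binding_performance(deltas, labels)
        first = curve.iloc[0]
        assert first["sensitivity"] == 1.0 and first["specificity"] == 0.0

    def test_random_labels_auc_near_half(self):
        rng = stream(43, "roc")
        n = 500
        deltas = pd.DataFrame({"peak": [f"p{i}" for i in range(n)],
                               "delta": rng.normal(size=n)})
        labels = pd.Series(rng.random(n) < 0.5, index=deltas["peak"])
        curve = footprint_vs_binding_performance(deltas, labels)
        fpr = 1 - curve["specificity"].to_numpy()
        tpr = curve["sensitivity"].to_numpy()
        order = np.argsort(fpr)
        auc = np.trapezoid(tpr[order], fpr[order])
        assert abs(auc - 0.5) < 0.1

    def test_overlapping_sites_collapse(self):
        sites = pd.DataFrame(
            {"peak": ["p1", "p1", "p1"], "start": [0, 5, 30],
             "end": [10, 15, 40], "delta": [0.2, -0.5, 0.1]}
        )
        out = collapse_overlapping_sites(sites)
        assert len(out) == 2
        assert out.iloc[0]["delta"] == -0.5  # largest magnitude wins the merge
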