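"""Deviation scoring, motif bagging, sample stats, programs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from clonemem import scoring, simulate
from clonemem._rng import stream
from clonemem.scoring import (
    AnnotationSet,
    activated_fraction,
    bag_motif_families,
    deviation_scores,
    fit_gene_programs,
    heterogeneity_test,
    per_sample_stats,
    program_gene_lists,
)


@pytest.fixture(scope="module")
def counts_sim():
    cfg = simulate.SimulationConfig(
        seed=101, n_cells=600, n_features=500, n_clones=10, frac_high_subpop=0.1
    )
    return simulate.simulate_counts_and_annotations(
        cfg, n_families=5, family_size=50, high_fold=2.0
    )


class TestDeviationScores:
    def test_all_features_set_has_zero_raw_deviation(self, counts_sim):
        full = AnnotationSet(name="all", members=np.arange(500))
        sm = deviation_scores(counts_sim.counts, [full], n_background=50,
                              seed=1, n_bins=10)
        assert np.allclose(sm.raw["all"], 0.0, atol=1e-12)
        assert sm.scores["all"].abs().mean() < 0.5

    def test_permuted_annotations_centered_at_zero(self, counts_sim):
        rng = stream(2, "perm-sets")
        sets = [
            AnnotationSet(name=f"perm{i}", members=rng.choice(500, 50, replace=False))
            for i in range(5)
        ]
        sm = deviation_scores(counts_sim.counts, sets, n_background=100,
                              seed=3, n_bins=10)
        m = sm.scores.mean()
        se = sm.scores.std() / np.sqrt(len(sm.scores))
        assert (m.abs() <= 3 * se).all()

    def test_planted_fold_detected_in_case_condition(self, counts_sim):
        sm = deviation_scores(counts_sim.counts, counts_sim.annotation_sets,
                              n_background=100, seed=4, n_bins=10,
                              cell_index=counts_sim.cells)
        target = counts_sim.truth["target_family"]
        cond = counts_sim.cell_conditions
        case = counts_sim.truth["case_condition"]
        a = sm.scores.loc[cond == case, target]
        b = sm.scores.loc[cond != case, target]
        p = stats.ttest_ind(a, b, alternative="greater").pvalue
        assert p < 0.01

    def test_depth_invariance_under_null(self, counts_sim):
        rng = stream(5, "depth")
        sets = [AnnotationSet(name="n", members=rng.choice(500, 50, replace=False))]
        sm = deviation_scores(counts_sim.counts, sets, n_background=100,
                              seed=6, n_bins=10)
        depth = np.asarray(counts_sim.counts.sum(axis=1)).ravel()
        r = np.corrcoef(depth, sm.scores["n"])[0, 1]
        assert abs(r) < 0.08

    def test_seed_stability(self, counts_sim):
        sets = counts_sim.annotation_sets[:2]
        a = deviation_scores(counts_sim.counts, sets, n_background=50, seed=7)
        b = deviation_scores(counts_sim.counts, sets, n_background=50, seed=7)
        pd.testing.assert_frame_equal(a.scores, b.scores)


class TestBagging:
    def _scores(self, variabilities):
        rng = stream(8, "bag")
        data = {m: rng.normal(0, v, 200) for m, v in variabilities.items()}
        return pd.DataFrame(data)

    def test_all_dissimilar_every_motif_own_family(self):
        sc = self._scores({"A": 3, "B": 2, "C": 1})
        q = pd.DataFrame(1.0, index=list("ABC"), columns=list("ABC"))
        bags = bag_motif_families(q, sc)
        assert sorted(b.leader for b in bags) == ["A", "B", "C"]
        assert all(b.members == {b.leader} for b in bags)

    def test_greedy_hand_traced(self):
        # var A>B>C; q(A,B)=0.01, q(A,C)=0.9, q(B,C)=0.01 -> {A,B}, {C}
        sc = self._scores({"A": 3, "B": 2, "C": 1})
        q = pd.DataFrame(1.0, index=list("ABC"), columns=list("ABC"))
        q.loc["A", "B"] = q.loc["B", "A"] = 0.01
        q.loc["A", "C"] = q.loc["C", "A"] = 0.9
        q.loc["B", "C"] = q.loc["C", "B"] = 0.01
        bags = bag_motif_families(q, sc)
        by_leader = {b.leader: b.members for b in bags}
        assert by_leader == {"A": {"A", "B"}, "C": {"C"}}

    @pytest.mark.parametrize("qv,merged", [(0.049, True), (0.05, True), (0.051, False)])
    def test_threshold_boundary(self, qv, merged):
        sc = self._scores({"A": 2, "B": 1})
        q = pd.DataFrame(1.0, index=list("AB"), columns=list("AB"))
        q.loc["A", "B"] = q.loc["B", "A"] = qv
        bags = bag_motif_families(q, sc)
        assert (len(bags) == 1) == merged

    def test_bagging_is_partition(self):
        rng = stream(9, "part")
        motifs = [f"m{i}" for i in range(20)]
        sc = pd.DataFrame(rng.normal(size=(100, 20)), columns=motifs)
        qvals = pd.DataFrame(rng.uniform(0, 1, size=(20, 20)),
                             index=motifs, columns=motifs)
        bags = bag_motif_families(qvals, sc)
        seen = [m for b in bags for m in b.members]
        assert sorted(seen) == sorted(motifs)  # disjoint and covering


class TestPerSampleStats:
    def _toy(self, shift=0.0, seed=10, n_samples=5, cells_per=300):
        rng = stream(seed, "pss")
        rows, cell_sample = [], {}
        conditions = {}
        i = 0
        for cond in ("control", "treated"):
            for s in range(n_samples):
                name = f"{cond}{s}"
                conditions[name] = cond
                mu = shift if cond == "treated" else 0.0
                for _ in range(cells_per):
                    rows.append((f"c{i}", name, rng.normal(mu, 1.0)))
                    i += 1
        df = pd.DataFrame(rows, columns=["cell", "sample", "fam"]).set_index("cell")
        scores = df[["fam"]]
        return scores, df["sample"], pd.Series(conditions)

    def test_control_changes_average_zero(self):
        scores, samp, cond = self._toy()
        out = per_sample_stats(scores, samp, cond, control_condition="control",
                               min_cells=1)
        ctrl = cond.index[cond == "control"]
        assert out["change"].loc[ctrl, "fam"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_planted_shift_significant(self):
        scores, samp, cond = self._toy(shift=1.0)
        out = per_sample_stats(scores, samp, cond, control_condition="control",
                               min_cells=1)
        q = out["tests"].set_index("family").loc["fam", "q"]
        assert q < 0.05

    def test_low_cell_samples_flagged(self):
        scores, samp, cond = self._toy(cells_per=50)
        out = per_sample_stats(scores, samp, cond, control_condition="control",
                               min_cells=200)
        assert set(out["low_cell_samples"]) == set(cond.index)


class TestActivatedFraction:
    def test_simple_fraction(self):
        scores = pd.Series([2.0, 1.0, 1.6, -0.5], index=list("abcd"))
        samples = pd.Series("s1", index=list("abcd"))
        assert activated_fraction(scores, samples)["s1"] == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        scores = pd.Series([1.5, 1.5000001], index=list("ab"))
        samples = pd.Series("s1", index=list("ab"))
        assert activated_fraction(scores, samples)["s1"] == pytest.approx(0.5)

    def test_normal_tail_rate(self):
        rng = stream(11, "tail")
        n = 1000
        scores = pd.Series(rng.normal(size=n))
        samples = pd.Series("s", index=scores.index)
        frac = activated_fraction(scores, samples)["s"]
        expect = stats.norm.sf(1.5)  # ~0.0668
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < 4 * se


class TestHeterogeneity:
    def test_identical_distributions_p_one(self):
        rng = stream(12, "het")
        vals = rng.normal(size=300)
        scores = pd.DataFrame({"f": np.concatenate([vals, vals])})
        labels = pd.Series(["a"] * 300 + ["b"] * 300)
        out = heterogeneity_test(scores, labels, ("a", "b"), n_downsample=500)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert bool(out["undersized"].iloc[0])

    def test_shifted_subpopulation_detected(self):
        # a 10% subpopulation at +3 SD is detectable well above the 5% null
        # rate of the two-sample KS at n=500 per condition
        rng = stream(13, "het2")
        hits = 0
        reps = 15
        for rep in range(reps):
            a = rng.normal(size=800)
            b = rng.normal(size=800)
            b[:80] += 3.0
            scores = pd.DataFrame({"f": np.concatenate([a, b])})
            labels = pd.Series(["ctl"] * 800 + ["rec"] * 800)
            out = heterogeneity_test(scores, labels, ("ctl", "rec"),
                                     n_downsample=500, seed=rep)
            hits += out["p"].iloc[0] < 0.05
        assert hits / reps >= 0.6


@pytest.fixture(scope="module")
def planted_lda():
    rng = stream(14, "lda")
    n_topics, n_genes, n_cells = 5, 100, 300
    topic_gene = rng.dirichlet(np.full(n_genes, 0.05), size=n_topics)
    cell_topic = rng.dirichlet(np.full(n_topics, 0.2), size=n_cells)
    rates = cell_topic @ topic_gene
    depth = rng.integers(300, 600, size=n_cells)
    X = np.vstack([rng.multinomial(d, r) for d, r in zip(depth, rates)])
    return topic_gene, pd.DataFrame(X)


class TestGenePrograms:
    def test_rows_are_distributions(self, planted_lda):
        _, X = planted_lda
        model = fit_gene_programs(X, [3, 5], seed=0, max_iter=15)
        assert np.allclose(model.topic_gene.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(model.cell_topic.sum(axis=1), 1.0, atol=1e-6)

    def test_planted_topics_recovered(self, planted_lda):
        truth, X = planted_lda
        model = fit_gene_programs(X, [3, 5, 8], seed=0, max_iter=30)
        assert model.n_topics == 5
        est = model.topic_gene.to_numpy()
        sim = (truth / np.linalg.norm(truth, axis=1, keepdims=True)) @ (
            est / np.linalg.norm(est, axis=1, keepdims=True)
        ).T
        ri, ci = linear_sum_assignment(-sim)
        assert sim[ri, ci].mean() >= 0.8

    def test_all_zero_cells_dropped_with_warning(self):
        X = pd.DataFrame(np.ones((10, 5)))
        X.iloc[0] = 0
        with pytest.warns(UserWarning):
            model = fit_gene_programs(X, [2], seed=0, max_iter=5)
        assert len(model.cell_topic) == 9


class TestProgramGeneLists:
    def test_top_weights_selected(self):
        w = pd.Series([0.5, 0.3, 0.2], index=["g0", "g1", "g2"])
        assert list(program_gene_lists(w, top_n=2)) == ["g0", "g1"]

    def test_clamped_when_top_n_exceeds_genes(self):
        w = pd.Series([0.5, 0.5], index=["g0", "g1"])
        assert len(program_gene_lists(w, top_n=150)) == 2

    def test_matches_sort_oracle(self):
        rng = stream(15, "pgl")
        for _ in range(50):
            w = rng.random(30)
            got = program_gene_lists(w, top_n=10)
            oracle = sorted(range(30), key=lambda i: (-w[i], i))[:10]
            assert list(got) == oracle
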