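"""Permutation tests against brute force and reference implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from aerosource import inference, synth
from aerosource.containers import CountTable, Habitat, SampleInfo, ValidationError


def euclidean_dm(values):
    values = np.asarray(values, float).reshape(-1, 1)
    ids = [f"s{i}" for i in range(len(values))]
    return DistanceMatrix(squareform(pdist(values)), ids)


def exact_anosim_p(dm, labels):
    """Brute-force reference: enumerate every distinct label assignment."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    condensed = dm.condensed_form()
    ranks = stats.rankdata(condensed)
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)

    obs = r_stat(labels)
    perms = {tuple(p) for p in itertools.permutations(labels)}
    hits = sum(r_stat(np.asarray(p, dtype=object)) >= obs - 1e-12 for p in perms)
    return obs, hits / len(perms)


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        dm = euclidean_dm([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        res = inference.anosim(dm, ["a"] * 3 + ["b"] * 3, 999, seed=1)
        assert res.R == pytest.approx(1.0)
        assert res.p_value >= 1 / 1000

    def test_no_separation_gives_r_zero(self):
        # identical points: every rank ties, so within and between rank
        # means coincide
        dm = euclidean_dm([2.0, 2.0, 2.0, 2.0])
        res = inference.anosim(dm, ["a", "a", "b", "b"], 99, seed=0)
        assert res.R == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        values = np.concatenate([rng.normal(0, 1, 3), rng.normal(1.5, 1, 3)])
        dm = euclidean_dm(values)
        labels = ["a"] * 3 + ["b"] * 3
        obs, p_exact = exact_anosim_p(dm, labels)
        res = inference.anosim(dm, labels, 999, seed=5)
        assert res.R == pytest.approx(obs)
        assert abs(res.p_value - p_exact) <= 0.02

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(9)])
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        mine = inference.anosim(dm, labels, 99, seed=0)
        ref = skbio_anosim(dm, labels, permutations=99)
        assert mine.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        labels = ["a"] * 4 + ["b"] * 4
        r1 = inference.anosim(DistanceMatrix(d, [f"s{i}" for i in range(8)]),
                              labels, 9, seed=0).R
        r2 = inference.anosim(DistanceMatrix(np.sqrt(d), [f"s{i}" for i in range(8)]),
                              labels, 9, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_small_group_rejected(self):
        dm = euclidean_dm([0, 1, 2])
        with pytest.raises(ValidationError):
            inference.anosim(dm, ["a", "a", "b"])


class TestPermanova:
    def test_equals_classical_anova_on_euclidean_distances(self):
        values = np.array([0.0, 0.0, 1.0, 10.0, 10.0, 11.0])
        labels = ["g1"] * 3 + ["g2"] * 3
        res = inference.permanova(euclidean_dm(values), labels, 99, seed=0)
        f_classical = stats.f_oneway(values[:3], values[3:]).statistic
        assert res.pseudo_F == pytest.approx(f_classical, abs=1e-9)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 5))
        dm = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(10)])
        labels = ["a"] * 5 + ["b"] * 5
        mine = inference.permanova(dm, labels, 99, seed=0)
        ref = skbio_permanova(dm, labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_null_labels_give_small_r2_and_large_p(self):
        rng = np.random.default_rng(9)
        r2s, ps = [], []
        for seed in range(20):
            values = rng.normal(size=10)
            labels = ["a"] * 5 + ["b"] * 5
            res = inference.permanova(euclidean_dm(values), labels, 99, seed=seed)
            r2s.append(res.R2)
            ps.append(res.p_value)
        assert np.mean(r2s) < 0.25
        assert np.mean(ps) > 0.3

    def test_exhaustive_p_matches_monte_carlo(self):
        rng = np.random.default_rng(11)
        values = np.concatenate([rng.normal(0, 1, 3), rng.normal(2, 1, 3)])
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        dm = euclidean_dm(values)
        d2 = dm.data ** 2
        obs, _ = inference._permanova_stats(d2, labels)
        perms = {tuple(p) for p in itertools.permutations(labels)}
        hits = sum(
            inference._permanova_stats(d2, np.asarray(p, object))[0] >= obs - 1e-12
            for p in perms
        )
        p_exact = hits / len(perms)
        res = inference.permanova(dm, labels, 999, seed=2)
        assert abs(res.p_value - p_exact) <= 0.02

    def test_single_level_rejected(self):
        with pytest.raises(ValidationError):
            inference.permanova(euclidean_dm([0, 1, 2]), ["a", "a", "a"])


class TestAlphaGroupTest:
    def test_identical_groups_give_p_one(self):
        vals = [1, 2, 3, 4, 1, 2, 3, 4]
        groups = ["a"] * 4 + ["b"] * 4
        out = inference.alpha_group_test(vals, groups)
        assert out["p_adjusted"].iloc[0] == 1.0

    def test_complete_separation_exact_p(self):
        # all of A below all of B at sizes 5/5: exact two-sided p = 2/252
        vals = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
        groups = ["a"] * 5 + ["b"] * 5
        out = inference.alpha_group_test(vals, groups)
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 252, abs=1e-12)

    def test_three_groups_bonferroni_factor(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        out = inference.alpha_group_test(vals, groups)
        assert len(out) == 3
        expected = np.minimum(1.0, out["p_raw"] * 3)
        np.testing.assert_allclose(out["p_adjusted"], expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            inference.alpha_group_test([1.0], ["a"])


def site_meta(site, suffix=""):
    return [
        SampleInfo(f"P{suffix}", Habitat.PLANT, site),
        SampleInfo(f"U{suffix}", Habitat.UPWIND, site),
        SampleInfo(f"D{suffix}", Habitat.DOWNWIND, site),
    ]


class TestEnrichmentRegression:
    def make_table(self, plant, upwind, downwind):
        df = pd.DataFrame({"P": plant, "U": upwind, "D": downwind},
                          index=[f"O{i}" for i in range(len(plant))])
        return CountTable(df)

    def test_identical_air_columns_give_zero_slope_p_one(self):
        t = self.make_table([500, 300, 200], [400, 300, 300], [400, 300, 300])
        res = inference.enrichment_regression(t, site_meta("L01"))
        assert res.slope == 0.0 and res.slope_p_value == 1.0

    def test_plant_abundance_filter_boundary(self):
        # one OTU at exactly 0.1% of plant reads, one at 0.05%
        plant = [1000 - 1, 1] + [0] * 0  # 0.1% boundary
        t = self.make_table([998, 1, 1], [300, 300, 400], [250, 350, 400])
        res = inference.enrichment_regression(t, site_meta("L01"),
                                              min_plant_prop=0.001)
        assert set(res.points["otu_id"]) == {"O0", "O1", "O2"}
        t2 = self.make_table([1997, 1, 2], [300, 300, 400], [250, 350, 400])
        res2 = inference.enrichment_regression(t2, site_meta("L01"),
                                               min_plant_prop=0.001)
        # O1 at 0.05% of the plant library is excluded, O2 at 0.1% included
        assert set(res2.points["otu_id"]) == {"O0", "O2"}

    def test_site_without_all_habitats_excluded(self):
        t = CountTable(pd.DataFrame(
            {"P": [800, 200], "U": [500, 500], "D": [400, 600], "P2": [500, 500]},
            index=["O0", "O1"]))
        meta = site_meta("L01") + [SampleInfo("P2", Habitat.PLANT, "L02")]
        res = inference.enrichment_regression(t, meta)
        assert res.excluded_sites == ["L02"]

    def test_synthetic_mixture_yields_positive_slope(self):
        cfg = synth.SynthConfig(n_sites=6, n_otus=120, n_plant_otus=24,
                                n_contam_otus=12, mixing_m=0.4,
                                library_size=8000, seed=5)
        table, meta, _ = synth.generate_study(cfg)
        res = inference.enrichment_regression(table, meta)
        assert res.slope > 0
        assert res.slope_p_value < 0.01

    def test_no_qualifying_otu_errors(self):
        t = self.make_table([0, 0], [5, 5], [5, 5])
        with pytest.raises(ValidationError):
            inference.enrichment_regression(t, site_meta("L01"))
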