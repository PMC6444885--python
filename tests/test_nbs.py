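"""Network-based statistic: edge t values, components, permutation FWE."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import hallnet as hn

from conftest import connectome


def full_mask(n):
    return hn.GroupMask(matrix=~np.eye(n, dtype=bool), method="consistency")


def cohort_from_edge_values(values_per_edge, n_nodes):
    """Subjects whose (i,j) weights are given per subject."""
    n_subj = len(next(iter(values_per_edge.values())))
    mats = [np.zeros((n_nodes, n_nodes)) for _ in range(n_subj)]
    for (i, j), vals in values_per_edge.items():
        for s, v in enumerate(vals):
            mats[s][i, j] = mats[s][j, i] = v
    return [connectome(m, f"s{s}") for s, m in enumerate(mats)]


class TestEdgeStatistics:
    def test_constant_edge_gives_zero(self):
        cohort = cohort_from_edge_values({(0, 1): [0.5] * 6}, 3)
        t = hn.edge_statistics(cohort, full_mask(3), np.arange(6.0))
        assert t[0, 1] == 0.0

    def test_perfect_negative_association_capped(self):
        g = np.arange(6.0)
        cohort = cohort_from_edge_values({(0, 1): list(0.9 - 0.1 * g)}, 3)
        t = hn.edge_statistics(cohort, full_mask(3), g, direction="negative")
        assert t[0, 1] == pytest.approx(1e6)

    def test_hand_computed_six_subject_fixture(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        w = [0.81, 0.74, 0.69, 0.60, 0.55, 0.43]
        cohort = cohort_from_edge_values({(0, 1): w}, 3)
        t = hn.edge_statistics(cohort, full_mask(3), g, direction="negative")
        r = stats.pearsonr(w, g).statistic
        expected = -(r * math.sqrt(4 / (1 - r**2)))  # df = n-2, sign flipped
        assert t[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_covariate_partial_correlation(self):
        # edge depends only on the covariate; partialling it out kills the t
        rng = np.random.default_rng(0)
        n = 20
        cov = rng.standard_normal(n)
        g = rng.standard_normal(n)
        w = 0.5 + 0.1 * cov
        cohort = cohort_from_edge_values({(0, 1): list(w)}, 3)
        t_raw = hn.edge_statistics(cohort, full_mask(3), cov, direction="positive")
        t_part = hn.edge_statistics(cohort, full_mask(3), g, covariate=cov,
                                    direction="positive")
        assert abs(t_raw[0, 1]) > 100  # near-perfect raw association
        assert abs(t_part[0, 1]) < 3

    def test_partial_t_matches_pingouin_style_oracle(self):
        # independent oracle: residualize with numpy polyfit, t from scipy
        rng = np.random.default_rng(5)
        n = 15
        g = rng.standard_normal(n)
        cov = 0.4 * g + rng.standard_normal(n)
        w = 0.5 - 0.05 * g + 0.03 * cov + 0.02 * rng.standard_normal(n)
        cohort = cohort_from_edge_values({(0, 1): list(w)}, 3)
        t = hn.edge_statistics(cohort, full_mask(3), g, covariate=cov,
                               direction="negative")
        res_w = w - np.polyval(np.polyfit(cov, w, 1), cov)
        res_g = g - np.polyval(np.polyfit(cov, g, 1), cov)
        r = stats.pearsonr(res_w, res_g).statistic
        expected = -(r * math.sqrt((n - 3) / (1 - r**2)))
        assert t[0, 1] == pytest.approx(expected, abs=1e-8)

    def test_constant_regressor_rejected(self):
        cohort = cohort_from_edge_values({(0, 1): [0.1, 0.2, 0.3, 0.4, 0.5]}, 3)
        with pytest.raises(ValueError, match="variance"):
            hn.edge_statistics(cohort, full_mask(3), np.ones(5))

    def test_constant_covariate_rejected(self):
        cohort = cohort_from_edge_values({(0, 1): [0.1, 0.2, 0.3, 0.4, 0.5]}, 3)
        with pytest.raises(ValueError, match="covariate"):
            hn.edge_statistics(cohort, full_mask(3), np.arange(5.0),
                               covariate=np.ones(5))


class TestSuprathresholdComponents:
    def _tmat(self, edges, n):
        m = np.zeros((n, n))
        for (i, j), v in edges.items():
            m[i, j] = m[j, i] = v
        return m

    def test_no_suprathreshold_edges(self):
        comps = hn.suprathreshold_components(self._tmat({(0, 1): 1.0}, 4), 1.7)
        assert comps == []

    def test_path_plus_isolated_edge(self):
        t = self._tmat({(0, 1): 2.0, (1, 2): 2.5, (3, 4): 3.0}, 5)
        comps = hn.suprathreshold_components(t, 1.7)
        assert [c.n_edges for c in comps] == [2, 1]
        assert set(comps[0].nodes) == {0, 1, 2}
        assert set(comps[1].nodes) == {3, 4}

    def test_fully_suprathreshold_is_one_component(self):
        n = 5
        t = np.full((n, n), 2.0)
        np.fill_diagonal(t, 0)
        comps = hn.suprathreshold_components(t, 1.7)
        assert len(comps) == 1
        assert comps[0].n_edges == n * (n - 1) // 2

    def test_component_edges_disjoint(self, small_cohort):
        _, manifest, cohort, _, _ = small_cohort
        mask = hn.consistency_mask(cohort, 0.5)
        hss = hn.compute_hss(manifest)["hss"].to_numpy()
        t = hn.edge_statistics(cohort, mask, hss)
        comps = hn.suprathreshold_components(t, 1.7)
        pairs = [p for c in comps for p in c.edges.pairs]
        assert len(pairs) == len(set(pairs))

    def test_raising_threshold_never_grows_components(self, small_cohort):
        _, manifest, cohort, _, _ = small_cohort
        mask = hn.consistency_mask(cohort, 0.5)
        hss = hn.compute_hss(manifest)["hss"].to_numpy()
        t = hn.edge_statistics(cohort, mask, hss)
        sizes = []
        for thr in (1.0, 1.7, 2.5, 3.5):
            comps = hn.suprathreshold_components(t, thr)
            sizes.append(sum(c.n_edges for c in comps))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestNbsTest:
    def test_exact_enumeration_matches_brute_force(self):
        # n=5 subjects: permutation p must equal enumeration over all 120
        # orderings computed by an independent scipy-based oracle
        rng = np.random.default_rng(2)
        n_nodes, n_subj = 6, 5
        mats = []
        for _ in range(n_subj):
            m = np.triu(rng.random((n_nodes, n_nodes)) * 0.5 + 0.2, 1)
            mats.append(m + m.T)
        cohort = [connectome(m, f"s{i}") for i, m in enumerate(mats)]
        g = rng.standard_normal(n_subj)
        cfg = hn.NBSConfig(t_threshold=1.0, n_permutations=200, seed=0)
        res = hn.nbs_test(cohort, full_mask(n_nodes), g, config=cfg)
        assert res.exact

        def max_comp(gperm):
            t = hn.edge_statistics(cohort, full_mask(n_nodes), np.asarray(gperm),
                                   direction="negative")
            comps = hn.suprathreshold_components(t, 1.0)
            return comps[0].n_edges if comps else 0

        null = [max_comp(g[list(p)]) for p in
                itertools.permutations(range(n_subj))]
        assert sorted(null) == sorted(res.max_component_size_null.tolist())
        for comp in res.components:
            expected_p = sum(v >= comp.n_edges for v in null) / len(null)
            assert comp.p_fwe == pytest.approx(expected_p, abs=1e-12)

    def test_recovers_planted_subnetwork_at_strong_effect(self):
        cfg = hn.SimulationConfig(effect_beta=0.3, subject_noise_sd=0.03,
                                  presence_jitter=0.05, seed=21)
        manifest, cohort, _, truth = hn.generate_cohort(cfg)
        mask = hn.consistency_mask(cohort, 0.5)
        hss = hn.compute_hss(manifest)["hss"].to_numpy()
        res = hn.nbs_test(cohort, mask, hss,
                          config=hn.NBSConfig(n_permutations=200, seed=3))
        planted = truth.planted_edge_set.pairs
        sig = res.significant_edges.pairs
        recall = len(planted & sig) / len(planted)
        assert recall >= 0.9
        jaccard = len(planted & sig) / len(planted | sig)
        assert jaccard > 0.2  # effect spills into correlated neighbours

    def test_p_invariant_to_regressor_shift(self, null_cohort):
        _, manifest, cohort, _, _ = null_cohort
        mask = hn.consistency_mask(cohort, 0.5)
        hss = hn.compute_hss(manifest)["hss"].to_numpy()
        cfg = hn.NBSConfig(n_permutations=300, seed=9)
        base = hn.nbs_test(cohort, mask, hss, config=cfg)
        shifted = hn.nbs_test(cohort, mask, hss + 100.0, config=cfg)
        assert sorted(c.p_fwe for c in shifted.components) == sorted(
            c.p_fwe for c in base.components)

    def test_p_invariant_to_subject_order_under_exact_null(self):
        # with n=5 the null is the full permutation orbit, so reordering
        # subjects cannot change any p-value
        rng = np.random.default_rng(8)
        mats = []
        for _ in range(5):
            m = np.triu(rng.random((6, 6)) * 0.5 + 0.2, 1)
            mats.append(m + m.T)
        cohort = [connectome(m, f"s{i}") for i, m in enumerate(mats)]
        g = rng.standard_normal(5)
        cfg = hn.NBSConfig(t_threshold=1.0, n_permutations=200, seed=0)
        base = hn.nbs_test(cohort, full_mask(6), g, config=cfg)
        order = [3, 1, 4, 0, 2]
        reordered = hn.nbs_test([cohort[i] for i in order], full_mask(6),
                                g[order], config=cfg)
        assert sorted(c.p_fwe for c in base.components) == sorted(
            c.p_fwe for c in reordered.components)

    def test_p_values_in_valid_range(self, null_cohort):
        _, manifest, cohort, _, _ = null_cohort
        mask = hn.consistency_mask(cohort, 0.5)
        hss = hn.compute_hss(manifest)["hss"].to_numpy()
        res = hn.nbs_test(cohort, mask, hss,
                          config=hn.NBSConfig(n_permutations=300, seed=4))
        for c in res.components:
            assert 1 / 301 <= c.p_fwe <= 1.0

    def test_deterministic_given_seed(self, null_cohort):
        _, manifest, cohort, _, _ = null_cohort
        mask = hn.consistency_mask(cohort, 0.5)
        hss = hn.compute_hss(manifest)["hss"].to_numpy()
        cfg = hn.NBSConfig(n_permutations=200, seed=11)
        r1 = hn.nbs_test(cohort, mask, hss, config=cfg)
        r2 = hn.nbs_test(cohort, mask, hss, config=cfg)
        assert np.array_equal(r1.max_component_size_null,
                              r2.max_component_size_null)

    def test_power_monotone_in_effect_size(self):
        min_p = []
        for beta in (0.0, 0.15, 0.4):
            cfg = hn.SimulationConfig(n_subjects=20, n_nodes=40, n_modules=4,
                                      effect_beta=beta, seed=33)
            manifest, cohort, _, _ = hn.generate_cohort(cfg)
            mask = hn.consistency_mask(cohort, 0.5)
            hss = hn.compute_hss(manifest)["hss"].to_numpy()
            res = hn.nbs_test(cohort, mask, hss,
                              config=hn.NBSConfig(n_permutations=200, seed=5))
            min_p.append(min((c.p_fwe for c in res.components), default=1.0))
        assert min_p[2] <= min_p[1] <= min_p[0] + 0.05
        assert min_p[2] < 0.05
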