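"""Overlap, contrast, enrichment and nodewise-screen permutation tests."""

import numpy as np
import pytest
from scipy import stats

import hallnet as hn
from hallnet.severity import DegenerateInputError


class TestRsnOverlap:
    def test_saturated_subnetwork_is_neither(self):
        labels = np.repeat(["visual", "DMN"], 10)
        out = hn.rsn_overlap_test(np.arange(20), labels, n_iterations=500, seed=0)
        assert (out["percent_in_subnetwork"] == 100.0).all()
        assert (out["verdict"] == "neither").all()

    def test_single_label_subnetwork_targeted(self):
        labels = np.array(["visual"] * 10 + ["DMN"] * 60)
        out = hn.rsn_overlap_test(np.arange(10), labels, n_iterations=2000,
                                  seed=1)
        row = out.set_index("rsn_label")
        assert row.loc["visual", "percent_in_subnetwork"] == 100.0
        assert row.loc["visual", "verdict"] == "targeted"

    def test_absent_label_spared_in_half_connectome(self):
        # a label entirely outside a half-sized subnetwork is spared with
        # high probability; check across simulations
        rng = np.random.default_rng(2)
        labels = np.array(["visual"] * 12 + ["DMN"] * 48)
        spared = 0
        n_sim = 20
        for k in range(n_sim):
            sub = rng.choice(np.arange(12, 60), size=30, replace=False)
            out = hn.rsn_overlap_test(sub, labels, n_iterations=500, seed=k)
            row = out.set_index("rsn_label")
            if row.loc["visual", "verdict"] == "spared":
                spared += 1
        assert spared >= 15

    def test_empty_subnetwork_all_zero(self):
        labels = np.repeat(["visual", "DMN", "limbic"], 10)
        out = hn.rsn_overlap_test(np.array([], dtype=int), labels,
                                  n_iterations=200, seed=3)
        assert (out["percent_in_subnetwork"] == 0.0).all()
        assert not (out["verdict"] == "targeted").any()

    def test_targeted_rate_near_2p5_percent_under_random_subnetworks(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([f"{lab}" for lab in
                            ("visual", "somatomotor", "DMN", "limbic")], 15)
        n_sim = 150
        hits = 0
        for k in range(n_sim):
            sub = rng.choice(60, size=20, replace=False)
            out = hn.rsn_overlap_test(sub, labels, n_iterations=400, seed=k)
            hits += int((out["verdict"] == "targeted").sum())
        rate = hits / (n_sim * 4)
        se = np.sqrt(0.025 * 0.975 / (n_sim * 4))
        assert rate <= 0.025 + 3 * se  # discreteness makes the test conservative


class TestGroupContrast:
    def test_identical_values_p_one(self):
        lab = np.array([True] * 5 + [False] * 5)
        out = hn.group_metric_contrast(np.ones(10), lab, n_iterations=500, seed=0)
        assert out["p"] == 1.0
        assert out["difference"] == 0.0

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(100)
        lab = np.zeros(100, bool)
        lab[:40] = True
        v[lab] += 1.0
        out = hn.group_metric_contrast(v, lab, n_iterations=2000, seed=2)
        assert out["p"] <= 0.001
        assert out["mean_in"] > out["mean_out"]

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            hn.group_metric_contrast(np.ones(5), np.ones(5, bool))


class TestClubEnrichment:
    def test_disjoint_club_p_near_one(self):
        count, p = hn.club_enrichment_test(np.arange(5), np.arange(20, 40), 60,
                                           n_iterations=500, seed=0)
        assert count == 0
        assert p > 0.5

    def test_club_inside_small_subnetwork_significant(self):
        count, p = hn.club_enrichment_test(np.arange(5), np.arange(8), 100,
                                           n_iterations=5000, seed=1)
        assert count == 5
        assert p < 0.001

    def test_matches_hypergeometric_tail(self):
        # 30 nodes, 12-node subnetwork, 6-node club, 4 inside
        club = np.arange(6)
        sub = np.concatenate([np.arange(4), np.arange(10, 18)])
        count, p = hn.club_enrichment_test(club, sub, 30, n_iterations=20000,
                                           seed=2)
        assert count == 4
        expected = stats.hypergeom.sf(count - 1, 30, len(sub), len(club))
        assert p == pytest.approx(expected, abs=0.01)

    def test_saturated_subnetwork_p_one(self):
        _, p = hn.club_enrichment_test(np.arange(5), np.arange(30), 30,
                                       n_iterations=300, seed=3)
        assert p == 1.0


class TestNodewiseScreen:
    def test_perfect_monotone_node_flagged_with_rho_one(self):
        rng = np.random.default_rng(0)
        n_subj, n_nodes = 20, 30
        M = rng.standard_normal((n_subj, n_nodes))
        hss = rng.standard_normal(n_subj)
        M[:, 7] = np.exp(hss)  # exact monotone function of severity
        res = hn.nodewise_screen(M, hss, n_iterations=1000, seed=1)
        assert res.rho[7] == pytest.approx(1.0, abs=1e-12)
        assert res.flagged[7]

    def test_flags_invariant_to_monotone_metric_transform(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((15, 20))
        hss = rng.standard_normal(15)
        r1 = hn.nodewise_screen(M, hss, n_iterations=500, seed=3)
        r2 = hn.nodewise_screen(np.exp(M), hss, n_iterations=500, seed=3)
        assert np.allclose(r1.rho, r2.rho, atol=1e-12)
        assert np.array_equal(r1.flagged, r2.flagged)

    def test_constant_node_gets_zero_rho(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((12, 5))
        M[:, 2] = 4.2
        res = hn.nodewise_screen(M, rng.standard_normal(12),
                                 n_iterations=300, seed=4)
        assert res.rho[2] == 0.0

    def test_rho_matches_scipy_spearman(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((18, 6))
        hss = rng.standard_normal(18)
        res = hn.nodewise_screen(M, hss, n_iterations=200, seed=6)
        for j in range(6):
            assert res.rho[j] == pytest.approx(
                stats.spearmanr(M[:, j], hss).statistic, abs=1e-10)

    def test_partial_screen_removes_covariate_driven_association(self):
        rng = np.random.default_rng(7)
        n = 40
        cov = rng.standard_normal(n)
        hss = 0.9 * cov + 0.2 * rng.standard_normal(n)
        M = rng.standard_normal((n, 10))
        M[:, 0] = cov + 0.1 * rng.standard_normal(n)  # covariate-driven node
        raw = hn.nodewise_screen(M, hss, n_iterations=500, seed=8)
        part = hn.nodewise_screen(M, hss, covariate=cov, n_iterations=500,
                                  seed=8)
        assert abs(raw.rho[0]) > 0.7
        assert abs(part.rho[0]) < 0.4

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(9)
        n_sim, fp = 100, 0
        for k in range(n_sim):
            M = rng.standard_normal((15, 25))
            hss = rng.standard_normal(15)
            res = hn.nodewise_screen(M, hss, n_iterations=300, alpha=0.05,
                                     seed=k)
            fp += int(res.flagged.any())
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert fp / n_sim <= 0.05 + 2 * se
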