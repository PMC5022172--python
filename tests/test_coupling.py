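import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from cfcausal import (
    ConnectivityGraph,
    build_fcg,
    generate_trial,
    morlet_phase,
    nm_plv,
    plv,
    rayleigh_significance,
    subgraph_strength,
)
from cfcausal import ALPHA2_BAND, DEFAULT_MONTAGE, THETA_BAND


def brute_force_plv(a, b):
    """Independent oracle: direct complex sum, no vectorization."""
    import cmath

    total = 0j
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    count = 0
    for s in range(a.shape[0]):
        for t in range(a.shape[1]):
            total += cmath.exp(1j * (a[s, t] - b[s, t]))
            count += 1
    return abs(total / count)


class TestPlv:
    def test_identical_phases_give_one(self, rng):
        a = rng.uniform(-np.pi, np.pi, 300)
        assert plv(a, a) == pytest.approx(1.0)

    def test_constant_offset_gives_one(self, rng):
        a = rng.uniform(-np.pi, np.pi, 300)
        assert plv(a, a - np.pi / 3) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = rng.uniform(-np.pi, np.pi, 200)
        b = rng.uniform(-np.pi, np.pi, 200)
        assert plv(a, b) == pytest.approx(plv(b, a), abs=1e-12)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            plv(rng.uniform(size=10), rng.uniform(size=11))

    def test_matches_brute_force(self, rng):
        a = rng.uniform(-np.pi, np.pi, (3, 200))
        b = rng.uniform(-np.pi, np.pi, (3, 200))
        assert plv(a, b) == pytest.approx(brute_force_plv(a, b), abs=1e-12)

    def test_uniform_phases_rayleigh_nonsignificant(self, rng):
        # type-II sanity of the null: independent phases rarely significant
        n, w = 500, 1000
        hits = 0
        for _ in range(n):
            a = rng.uniform(-np.pi, np.pi, w)
            b = rng.uniform(-np.pi, np.pi, w)
            if rayleigh_significance(plv(a, b), w) <= 0.05:
                hits += 1
        assert (n - hits) / n >= 0.94


class TestNmPlv:
    def test_exact_two_to_one_locking(self, rng):
        theta = np.unwrap(rng.uniform(-np.pi, np.pi, 400))
        assert nm_plv(theta, 2 * theta) == pytest.approx(1.0)

    def test_constant_offset_invariance(self, rng):
        theta = np.unwrap(rng.uniform(-np.pi, np.pi, 400))
        assert nm_plv(theta, 2 * theta + 1.234) == pytest.approx(1.0)

    def test_role_order_is_kept(self, rng):
        # nm_plv is not symmetric in its arguments' roles
        a = rng.uniform(-np.pi, np.pi, 500)
        b = 2 * a + 0.1 * rng.standard_normal(500)
        assert nm_plv(a, b) > 0.9
        assert nm_plv(b, a) < 0.5

    def test_independent_phases_nonsignificant(self, rng):
        n, w = 500, 1000
        hits = 0
        for _ in range(n):
            a = rng.uniform(-np.pi, np.pi, w)
            b = rng.uniform(-np.pi, np.pi, w)
            if rayleigh_significance(nm_plv(a, b), w) <= 0.05:
                hits += 1
        assert (n - hits) / n >= 0.94

    def test_matches_brute_force(self, rng):
        import cmath

        a = rng.uniform(-np.pi, np.pi, 300)
        b = rng.uniform(-np.pi, np.pi, 300)
        total = sum(cmath.exp(1j * (2 * ai - bi)) for ai, bi in zip(a, b))
        assert nm_plv(a, b) == pytest.approx(abs(total / 300), abs=1e-12)


class TestRayleigh:
    def test_perfect_locking_tiny_p(self):
        assert rayleigh_significance(1.0, 100) < 1e-10

    def test_zero_plv_p_one(self):
        assert rayleigh_significance(0.0, 1000) == 1.0

    def test_monotone_in_plv(self):
        ps = [rayleigh_significance(v, 200) for v in (0.05, 0.1, 0.2, 0.4)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_small_n_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert rayleigh_significance(0.9, 4) == 1.0

    def test_type_one_error_calibrated(self, rng):
        n_eff, reps = 200, 2000
        z = rng.uniform(-np.pi, np.pi, (reps, n_eff))
        r = np.abs(np.mean(np.exp(1j * z), axis=1))
        pvals = np.array([rayleigh_significance(v, n_eff) for v in r])
        rate = float((pvals <= 0.05).mean())
        assert 0.04 <= rate <= 0.06


class TestBuildFcg:
    @pytest.fixture(scope="class")
    def trial_and_graph(self, small_config):
        trial, _ = generate_trial(
            small_config, 3, "correct", np.random.default_rng(5)
        )
        return trial, build_fcg(trial, small_config.montage)

    def test_symmetric_for_undirected_estimators(self, trial_and_graph):
        _, g = trial_and_graph
        np.testing.assert_allclose(g.weights, g.weights.T)
        assert not g.directed

    def test_cross_block_uses_cross_frequency_plv(self, small_config):
        # reconstruct the F x PO block by hand from the wavelet phases
        trial, _ = generate_trial(
            small_config, 3, "correct", np.random.default_rng(5)
        )
        mont = small_config.montage
        th = morlet_phase(trial, THETA_BAND)
        al = morlet_phase(trial, ALPHA2_BAND)
        v = th.valid & al.valid
        g = build_fcg(trial, mont, theta_rep=th, alpha_rep=al)
        i = mont.f_indices[0]
        j = mont.po_indices[0]
        expected = nm_plv(th.phase[i][:, v], al.phase[j][:, v])
        assert g.weights[i, j] == pytest.approx(expected, abs=1e-12)
        within = plv(th.phase[i][:, v], th.phase[j][:, v])
        assert g.weights[i, j] != pytest.approx(within, abs=1e-6)

    def test_locking_contrast_raises_cross_strength(self, small_config):
        # paired comparison over seeds: strong 2:1 locking vs none
        from scipy.stats import binomtest

        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng1 = np.random.default_rng(seed)
            rng2 = np.random.default_rng(seed)
            hi_cfg = dataclasses.replace(small_config, nm_phase_locking=0.9)
            lo_cfg = dataclasses.replace(small_config, nm_phase_locking=0.0)
            t_hi, _ = generate_trial(hi_cfg, 3, "correct", rng1)
            t_lo, _ = generate_trial(lo_cfg, 3, "correct", rng2)
            m = small_config.montage
            s_hi = subgraph_strength(build_fcg(t_hi, m), m, "FxPO").strength
            s_lo = subgraph_strength(build_fcg(t_lo, m), m, "FxPO").strength
            wins += s_hi > s_lo
        assert binomtest(wins, n_seeds, alternative="greater").pvalue < 0.01


def test_nm_plv_monotone_in_locking_parameter(small_config):
    # long trials: the 2:1 phase difference of uncoupled rhythms drifts at
    # only ~0.5 Hz, so short trials inflate the lambda=0 baseline
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    mont = small_config.montage
    means = []
    for lam in grid:
        cfg = dataclasses.replace(
            small_config, nm_phase_locking=lam,
            duration_base_ms=12000.0, duration_step_ms=0.0,
        )
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(8):
            trial, _ = generate_trial(cfg, 3, "correct", rng)
            th = morlet_phase(trial, THETA_BAND)
            al = morlet_phase(trial, ALPHA2_BAND)
            v = th.valid & al.valid
            i = mont.f_indices[0]
            j = mont.index("O2")
            vals.append(nm_plv(th.phase[i][:, v], al.phase[j][:, v]))
        means.append(np.mean(vals))
    assert spearmanr(grid, means).statistic > 0.9


class TestSubgraphStrength:
    def make_graph(self, weights, mask=None):
        weights = np.asarray(weights, dtype=float)
        if mask is None:
            mask = np.ones_like(weights, dtype=bool)
        return ConnectivityGraph(
            weights=weights, mask=mask, estimator="plv_fcg",
            directed=False, labels=DEFAULT_MONTAGE.labels,
        )

    def test_zero_graph_zero_strength(self):
        g = self.make_graph(np.zeros((25, 25)))
        for region in ("F", "PO", "FxPO"):
            assert subgraph_strength(g, DEFAULT_MONTAGE, region).strength == 0.0

    def test_all_ones_frontal_block_counts_each_edge_once(self):
        g = self.make_graph(np.ones((25, 25)))
        # 13 frontal sensors, no self-edges, undirected: 13 * 12 / 2 = 78
        assert subgraph_strength(g, DEFAULT_MONTAGE, "F").strength == 78.0
        assert subgraph_strength(g, DEFAULT_MONTAGE, "PO").strength == 66.0
        assert subgraph_strength(g, DEFAULT_MONTAGE, "FxPO").strength == 13 * 12

    def test_fully_masked_graph_zero(self):
        g = self.make_graph(np.ones((25, 25)), mask=np.zeros((25, 25), bool))
        assert subgraph_strength(g, DEFAULT_MONTAGE, "F").strength == 0.0

    def test_unknown_region_raises(self):
        g = self.make_graph(np.ones((25, 25)))
        with pytest.raises(ValueError, match="unknown region"):
            subgraph_strength(g, DEFAULT_MONTAGE, "occipital")


def test_fcg_per_graph_fdr_mask_is_subset(small_config):
    """The FDR-corrected mask never keeps an edge the per-edge mask drops."""
    trial, _ = generate_trial(small_config, 3, "correct", np.random.default_rng(8))
    mont = small_config.montage
    per_edge = build_fcg(trial, mont, mask_correction="per_edge")
    per_graph = build_fcg(trial, mont, mask_correction="fdr_per_graph")
    np.testing.assert_allclose(per_edge.weights, per_graph.weights)
    # FDR across ~45 edges at q=0.05 rejects a subset of p<0.05 edges
    assert not np.any(per_graph.mask & ~per_edge.mask)
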