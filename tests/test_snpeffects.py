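"""Back-solving, re-weighting and window-variance partitioning."""

import numpy as np
import pandas as pd
import pytest

from liabilityscan import (RelationshipMatrix, backsolve_effects, blend_G,
                           build_G, initial_weights, iterate_reweighting,
                           top_windows, update_weights, window_variance)
from liabilityscan.simdata import simulate_founder_genotypes
from liabilityscan.snpeffects import SnpEffectSet

from conftest import panel_from_genotypes


def hwe_panel(n, m, seed, chrom=None):
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.15, 0.5, size=m)
    geno = simulate_founder_genotypes(n, freqs, rng)
    panel = panel_from_genotypes(geno, chrom=chrom)
    # centre at the generating frequencies: sample-frequency centering
    # leaves G with the all-ones null vector (every column of Z sums to 0)
    panel.allele_freqs = freqs
    return panel


def solve_round1(panel, a_g, alpha=0.0):
    w = initial_weights(panel)
    G = build_G(panel, w)
    if alpha > 0:
        A22 = RelationshipMatrix(np.eye(panel.n_individuals),
                                 panel.ids.copy(), kind="A22")
        G = blend_G(G, A22, alpha)
    return backsolve_effects(panel, w, G, a_g)


class TestBacksolve:
    def test_zero_breeding_values_zero_effects(self):
        panel = hwe_panel(15, 60, seed=1)
        eff = solve_round1(panel, np.zeros(15), alpha=0.05)
        assert np.allclose(eff.u, 0.0)

    def test_unblended_full_rank_reproduces_a_g(self):
        panel = hwe_panel(12, 80, seed=2)
        rng = np.random.default_rng(3)
        a_g = rng.normal(size=12)
        eff = solve_round1(panel, a_g, alpha=0.0)
        from liabilityscan.relmat import centered_Z
        Z = centered_Z(panel)
        assert np.abs(Z @ eff.u - a_g).max() < 1e-8

    def test_duplicated_markers_equal_effects(self):
        rng = np.random.default_rng(4)
        geno = simulate_founder_genotypes(10, rng.uniform(0.2, 0.5, 30), rng)
        geno[:, 7] = geno[:, 3]
        panel = panel_from_genotypes(geno)
        eff = solve_round1(panel, rng.normal(size=10), alpha=0.05)
        assert eff.u[7] == pytest.approx(eff.u[3], rel=1e-10)

    def test_dense_kkt_oracle_small(self):
        # u = D Z' G^-1 a_g solves: minimize u' D^-1 u  s.t.  Z u = a_g;
        # compare against the dense KKT system of that program
        panel = hwe_panel(6, 18, seed=5)
        rng = np.random.default_rng(6)
        a_g = rng.normal(size=6)
        w = initial_weights(panel)
        eff = solve_round1(panel, a_g, alpha=0.0)
        from liabilityscan.relmat import centered_Z
        Z = centered_Z(panel)
        m = panel.n_markers
        kkt = np.block([
            [np.diag(1.0 / w.d), Z.T],
            [Z, np.zeros((6, 6))],
        ])
        rhs = np.concatenate([np.zeros(m), a_g])
        u_oracle = np.linalg.solve(kkt, rhs)[:m]
        assert np.abs(eff.u - u_oracle).max() < 1e-8

    def test_scale_equivariance(self):
        panel = hwe_panel(10, 40, seed=7)
        rng = np.random.default_rng(8)
        a_g = rng.normal(size=10)
        e1 = solve_round1(panel, a_g, alpha=0.05)
        e2 = solve_round1(panel, 3.0 * a_g, alpha=0.05)
        assert np.allclose(e2.u, 3.0 * e1.u)
        w1 = window_variance(e1, panel)
        w2 = window_variance(e2, panel)
        assert np.allclose(w1.variance_share, w2.variance_share)

    def test_dimension_mismatch(self):
        panel = hwe_panel(5, 20, seed=9)
        with pytest.raises(ValueError):
            solve_round1(panel, np.zeros(7))


class TestReweighting:
    def test_equal_effects_equal_freqs_noop(self):
        # equal u and equal p: realized re-weighting reproduces the
        # expected-variance weights after rescaling
        geno = np.tile(np.array([[0], [1], [2], [1]]), (1, 20)).astype(np.int8)
        panel = panel_from_genotypes(geno)
        w0 = initial_weights(panel)
        eff = SnpEffectSet(u=np.full(20, 0.3), weights=w0,
                           a_g=np.zeros(4), ids=panel.ids)
        w1 = update_weights(eff, panel)
        assert np.allclose(w1.d, w0.d)

    def test_single_dominant_marker(self):
        panel = hwe_panel(8, 25, seed=10)
        w0 = initial_weights(panel)
        u = np.zeros(25)
        u[11] = 2.0
        u += 1e-9  # avoid the all-zero guard for the other markers
        eff = SnpEffectSet(u=u, weights=w0, a_g=np.zeros(8), ids=panel.ids)
        w1 = update_weights(eff, panel, floor=1e-8)
        p = panel.allele_freqs
        share = w1.d * 2 * p * (1 - p)
        assert share[11] > 0.999
        assert share.sum() == pytest.approx(1.0, abs=1e-10)

    def test_normalization_holds_each_round(self):
        panel = hwe_panel(20, 60, seed=11)
        rng = np.random.default_rng(12)
        rounds = iterate_reweighting(panel, rng.normal(size=20), n_rounds=4)
        p = panel.allele_freqs
        for eff in rounds:
            total = np.sum(eff.weights.d * 2 * p * (1 - p))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_effects_rejected(self):
        panel = hwe_panel(5, 10, seed=13)
        eff = SnpEffectSet(u=np.zeros(10), weights=initial_weights(panel),
                           a_g=np.zeros(5), ids=panel.ids)
        with pytest.raises(ValueError):
            update_weights(eff, panel)

    def test_round_counts(self):
        panel = hwe_panel(10, 30, seed=14)
        rng = np.random.default_rng(15)
        a_g = rng.normal(size=10)
        one = iterate_reweighting(panel, a_g, n_rounds=1, alpha=0.05)
        assert len(one) == 1
        base = solve_round1(panel, a_g, alpha=0.05)
        assert np.allclose(one[0].u, base.u)
        four = iterate_reweighting(panel, a_g)  # default rounds
        assert len(four) == 4
        assert [e.iteration for e in four] == [1, 2, 3, 4]


class TestWindows:
    def test_hundred_snps_ten_windows(self):
        panel = hwe_panel(30, 100, seed=16)
        rng = np.random.default_rng(17)
        eff = solve_round1(panel, rng.normal(size=30), alpha=0.05)
        tab = window_variance(eff, panel, window_size=10)
        assert len(tab) == 10
        assert tab.variance_share.sum() == pytest.approx(1.0, abs=1e-10)
        assert (tab.n_snps == 10).all()

    def test_partial_final_window(self):
        panel = hwe_panel(10, 25, seed=18)
        rng = np.random.default_rng(19)
        eff = solve_round1(panel, rng.normal(size=10), alpha=0.05)
        tab = window_variance(eff, panel, window_size=10)
        assert list(tab.n_snps) == [10, 10, 5]
        assert tab.start_bp.iloc[0] == panel.marker_map.bp.iloc[0]
        assert tab.stop_bp.iloc[2] == panel.marker_map.bp.iloc[24]

    def test_windows_never_span_chromosomes(self):
        chrom = np.repeat([1, 2], [15, 15])
        panel = hwe_panel(10, 30, seed=20, chrom=chrom)
        rng = np.random.default_rng(21)
        eff = solve_round1(panel, rng.normal(size=10), alpha=0.05)
        tab = window_variance(eff, panel, window_size=10)
        assert list(tab.n_snps) == [10, 5, 10, 5]
        assert list(tab.chrom) == [1, 1, 2, 2]

    def test_all_variance_on_one_snp(self):
        panel = hwe_panel(5, 30, seed=22)
        u = np.zeros(30)
        u[17] = 1.0
        eff = SnpEffectSet(u=u, weights=initial_weights(panel),
                           a_g=np.zeros(5), ids=panel.ids)
        tab = window_variance(eff, panel, window_size=10)
        assert tab.variance_share.iloc[1] == pytest.approx(1.0)
        assert tab.variance_share.drop(index=1).abs().max() == 0.0

    def test_variance_conservation(self):
        panel = hwe_panel(12, 50, seed=23)
        rng = np.random.default_rng(24)
        eff = solve_round1(panel, rng.normal(size=12), alpha=0.05)
        tab = window_variance(eff, panel, window_size=10)
        total = eff.realized_variance.sum()
        assert tab.variance_share.to_numpy().sum() * total == \
            pytest.approx(total, rel=1e-12)

    def test_unsorted_map_rejected(self):
        panel = hwe_panel(5, 20, seed=25)
        panel.marker_map.loc[3, "bp"] = 10 ** 9
        eff = SnpEffectSet(u=np.ones(20), weights=initial_weights(panel),
                           a_g=np.zeros(5), ids=panel.ids)
        with pytest.raises(ValueError, match="not sorted"):
            window_variance(eff, panel)


class TestTopWindows:
    def _table(self, shares, chrom=None):
        k = len(shares)
        return pd.DataFrame({
            "window_id": np.arange(1, k + 1),
            "chrom": chrom if chrom is not None else np.ones(k, dtype=int),
            "start_bp": np.arange(k) * 1000 + 1,
            "stop_bp": np.arange(k) * 1000 + 900,
            "n_snps": 10,
            "variance_share": shares,
        })

    def test_descending_selection(self):
        top = top_windows(self._table([0.5, 0.3, 0.2]), n=2)
        assert list(top.window_id) == [1, 2]
        assert list(top.variance_share) == [0.5, 0.3]

    def test_tie_breaks_by_chromosome(self):
        tab = self._table([0.4, 0.4, 0.2], chrom=np.array([5, 2, 1]))
        top = top_windows(tab, n=2)
        assert list(top.chrom) == [2, 5]

    def test_monotone_shares_on_synthetic_genome(self):
        chrom = np.repeat(np.arange(1, 6), 30)
        panel = hwe_panel(40, 150, seed=26, chrom=chrom)
        rng = np.random.default_rng(27)
        eff = solve_round1(panel, rng.normal(size=40), alpha=0.05)
        tab = window_variance(eff, panel)
        top = top_windows(tab, n=10)
        assert len(top) == 10
        assert (np.diff(top.variance_share) <= 1e-15).all()

    def test_oversized_request_warns(self):
        with pytest.warns(UserWarning):
            top = top_windows(self._table([0.6, 0.4]), n=10)
        assert len(top) == 2


class TestShareProperties:
    """Property checks over randomly sized genomes and effect vectors."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(m=st.integers(min_value=11, max_value=80),
           seed=st.integers(min_value=0, max_value=2 ** 20))
    def test_shares_normalized_and_conserved(self, m, seed):
        panel = hwe_panel(6, m, seed=seed)
        rng = np.random.default_rng(seed + 1)
        u = rng.normal(size=m)
        eff = SnpEffectSet(u=u, weights=initial_weights(panel),
                           a_g=np.zeros(6), ids=panel.ids)
        tab = window_variance(eff, panel, window_size=10)
        assert (tab.variance_share >= 0).all()
        assert tab.variance_share.sum() == pytest.approx(1.0, abs=1e-10)
        # windows tile the marker list without overlap
        assert tab.n_snps.sum() == m

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2 ** 20))
    def test_reweighting_preserves_normalization(self, seed):
        panel = hwe_panel(8, 24, seed=seed)
        rng = np.random.default_rng(seed + 1)
        u = rng.normal(size=24)
        eff = SnpEffectSet(u=u, weights=initial_weights(panel),
                           a_g=np.zeros(8), ids=panel.ids)
        w = update_weights(eff, panel)
        p = panel.allele_freqs
        assert np.sum(w.d * 2 * p * (1 - p)) == pytest.approx(1.0, abs=1e-10)
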