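"""The adapted co-methylation linkage statistic D' and pair machinery."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

from ncats_eval.linkage import (
    LinkagePair,
    compute_D,
    compute_Dmax,
    compute_Dprime,
    decay_analysis,
    linkage_matrix,
    pair_counts,
    score_pairs,
)
from ncats_eval.meth_calls import SiteCall
from ncats_eval.sim import simulate_methylation_calls, simulate_read_layout

from _oracles import pairwise_tally
from conftest import make_sim_config


class TestDStatistics:
    def test_independence_gives_zero(self):
        assert compute_D(0.25, 0.25, 0.5, 0.5) == pytest.approx(0.0)

    def test_fully_methylated_pair_gives_zero(self):
        assert compute_D(1.0, 0.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_hand_evaluated_positive_excess(self):
        assert compute_D(0.4, 0.4, 0.5, 0.5) == pytest.approx(0.3)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_D(1.2, 0.0, 0.5, 0.5)

    def test_literal_normalizer_hand_value(self):
        # p_MM = p_UU = 0.4: D = 0.3, literal D_max = 1 - 0.8 = 0.2
        assert compute_Dmax(0.3, 0.4, 0.4, 0.5, 0.5, "literal") == pytest.approx(0.2)

    def test_bounded_normalizer_hand_value(self):
        # expected concordance e = 0.5, D > 0 -> D_max = 1 - e = 0.5
        assert compute_Dmax(0.3, 0.4, 0.4, 0.5, 0.5, "bounded") == pytest.approx(0.5)

    def test_negative_branch_literal(self):
        assert compute_Dmax(-0.1, 0.1, 0.1, 0.5, 0.5, "literal") == pytest.approx(0.2)

    def test_dprime_values(self):
        assert compute_Dprime(0.0, 1.0) == 0.0
        assert compute_Dprime(0.3, 0.5) == pytest.approx(0.6)
        # the published normalizer can exceed 1 on legitimate inputs
        assert compute_Dprime(0.3, 0.2) == pytest.approx(1.5)

    def test_degenerate_zero_normalizer_flagged(self):
        assert compute_Dprime(0.0, 0.0) == 0.0
        assert math.isnan(compute_Dprime(0.2, 0.0))


def _joint_tables(max_n):
    """All joint count tables (n_MM, n_MU, n_UM, n_UU) with 1 <= total <= max_n."""
    for n in range(1, max_n + 1):
        for n_mm in range(n + 1):
            for n_mu in range(n + 1 - n_mm):
                for n_um in range(n + 1 - n_mm - n_mu):
                    yield n_mm, n_mu, n_um, n - n_mm - n_mu - n_um


def _stats_from_counts(n_mm, n_mu, n_um, n_uu, mode):
    n = n_mm + n_mu + n_um + n_uu
    p_mm, p_mu, p_um, p_uu = (x / n for x in (n_mm, n_mu, n_um, n_uu))
    p1, p2 = p_mm + p_mu, p_mm + p_um
    D = compute_D(p_mm, p_uu, p1, p2)
    D_max = compute_Dmax(D, p_mm, p_uu, p1, p2, mode)
    return D, D_max, compute_Dprime(D, D_max)


joint_table = st.tuples(
    st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
).filter(lambda t: sum(t) > 0)


class TestInvariances:
    @given(joint_table)
    def test_label_swap_invariance(self, table):
        n_mm, n_mu, n_um, n_uu = table
        for mode in ("literal", "bounded"):
            d1, _, dp1 = _stats_from_counts(n_mm, n_mu, n_um, n_uu, mode)
            d2, _, dp2 = _stats_from_counts(n_mm, n_um, n_mu, n_uu, mode)
            assert d1 == pytest.approx(d2)
            if not (math.isnan(dp1) or math.isnan(dp2)):
                assert dp1 == pytest.approx(dp2)
            else:
                assert math.isnan(dp1) and math.isnan(dp2)

    @given(joint_table)
    def test_global_state_relabel_invariance(self, table):
        n_mm, n_mu, n_um, n_uu = table
        d1, _, _ = _stats_from_counts(n_mm, n_mu, n_um, n_uu, "bounded")
        d2, _, _ = _stats_from_counts(n_uu, n_um, n_mu, n_mm, "bounded")
        assert d1 == pytest.approx(d2)

    def test_bounded_mode_in_unit_interval_exhaustive(self):
        for table in _joint_tables(12):
            _, _, dp = _stats_from_counts(*table, "bounded")
            if not math.isnan(dp):
                assert 0.0 <= dp <= 1.0 + 1e-12


def _calls(rows):
    """rows: (read, pos, state) on one chrom."""
    return [SiteCall(r, "s1", "chr1", p, s) for r, p, s in rows]


class TestPairCounts:
    def test_all_mm_reads(self):
        spec = [(f"r{i}", p, True) for i in range(10) for p in (100, 200)]
        (pair,) = pair_counts(_calls(spec), min_shared_reads=10)
        assert pair.n_reads == 10
        assert pair.p_MM == 1.0
        assert pair.p_MU == pair.p_UM == pair.p_UU == 0.0

    def test_below_threshold_excluded(self):
        spec = [(f"r{i}", p, True) for i in range(9) for p in (100, 200)]
        assert pair_counts(_calls(spec), min_shared_reads=10) == []

    def test_matches_per_read_tally_oracle(self):
        import random

        rng = random.Random(29)
        sites = [100, 180, 260, 400]
        spec = []
        for i in range(40):
            for p in sites:
                if rng.random() < 0.8:  # some missing calls per read
                    spec.append((f"r{i}", p, rng.random() < 0.5))
        calls = _calls(spec)
        pairs = pair_counts(calls, min_shared_reads=5)
        oracle = pairwise_tally(calls)
        by_key = {("chr1", p.pos1, p.pos2): p for p in pairs}
        for key, tally in oracle.items():
            n = sum(tally.values())
            if n < 5:
                assert key not in by_key
                continue
            pair = by_key.pop(key)
            assert pair.n_reads == n
            assert pair.p_MM == pytest.approx(tally["MM"] / n)
            assert pair.p_MU == pytest.approx(tally["MU"] / n)
            assert pair.p_UM == pytest.approx(tally["UM"] / n)
            assert pair.p_UU == pytest.approx(tally["UU"] / n)
        assert not by_key  # no extra pairs

    def test_pooled_across_samples(self):
        spec1 = [(f"a{i}", p, True) for i in range(6) for p in (100, 200)]
        calls = _calls(spec1) + [
            SiteCall(f"b{i}", "s2", "chr1", p, False)
            for i in range(6)
            for p in (100, 200)
        ]
        (pair,) = pair_counts(calls, min_shared_reads=10)
        assert pair.n_reads == 12
        assert pair.p_MM == pytest.approx(0.5)
        assert pair.p_UU == pytest.approx(0.5)


class TestMatrix:
    def test_two_sites_symmetric(self):
        pair = LinkagePair("chr1", 100, 200, 10, 0.4, 0.1, 0.1, 0.4)
        score_pairs([pair], "bounded")
        mat, frame = linkage_matrix([pair], [100, 200])
        assert mat[0, 1] == mat[1, 0] == pytest.approx(pair.D_prime)
        assert mat[0, 0] == mat[1, 1] == 1.0

    def test_missing_pairs_flagged(self):
        mat, _ = linkage_matrix([], [100, 200, 300])
        off_diag = mat[~np.eye(3, dtype=bool)]
        assert np.isnan(off_diag).all()

    def test_unknown_site_rejected(self):
        pair = LinkagePair("chr1", 100, 999, 10, 0.25, 0.25, 0.25, 0.25)
        with pytest.raises(ValueError, match="999"):
            linkage_matrix([pair], [100, 200])

    def test_random_pairs_matrix_equals_transpose(self):
        rng = np.random.default_rng(3)
        sites = [100, 200, 300, 400]
        pairs = []
        for i, p1 in enumerate(sites):
            for p2 in sites[i + 1 :]:
                raw = rng.dirichlet(np.ones(4))
                pairs.append(LinkagePair("chr1", p1, p2, 20, *raw))
        score_pairs(pairs, "bounded")
        mat, _ = linkage_matrix(pairs, sites)
        assert np.array_equal(mat, mat.T, equal_nan=True)


class TestDecayAndRecovery:
    def _simulated_pairs(self, coupling, seed, n_reads=800, mode="bounded"):
        config = make_sim_config(
            seed=seed, n_reads=n_reads, truth=0.5, n_cpgs=6, cpg_spacing=150,
            coupling=coupling,
        )
        reads = simulate_read_layout(config)
        calls = simulate_methylation_calls(reads, config)
        site_calls = calls.rename(
            columns={"read_name": "read_id", "start": "position"}
        )[["read_id", "sample_id", "chromosome", "position", "true_state"]].rename(
            columns={"chromosome": "chrom", "true_state": "state"}
        )
        site_calls["state"] = site_calls["state"].astype(bool)
        return score_pairs(pair_counts(site_calls, 10), mode)

    def test_single_distance_single_bin(self):
        pair = LinkagePair("chr1", 100, 200, 10, 0.4, 0.1, 0.1, 0.4)
        score_pairs([pair], "bounded")
        table = decay_analysis([pair])
        assert len(table) == 1
        assert table.loc[0, "n_pairs"] == 1

    def test_uncoupled_simulation_shows_no_distance_trend(self):
        pairs = self._simulated_pairs({}, seed=31)
        assert len(pairs) >= 10
        distances = np.array([p.distance for p in pairs], dtype=float)
        dprimes = np.array([p.D_prime for p in pairs], dtype=float)
        ok = np.isfinite(dprimes)
        rho = spearmanr(distances[ok], dprimes[ok]).statistic
        # permutation oracle for the null scale of |rho|
        rng = np.random.default_rng(777)
        null = [
            abs(spearmanr(rng.permutation(distances[ok]), dprimes[ok]).statistic)
            for _ in range(500)
        ]
        assert abs(rho) <= np.quantile(null, 0.99)

    def test_constructed_decaying_coupling_decays(self):
        sites = list(range(41_000, 41_900, 150))
        coupling = {}
        for i, p1 in enumerate(sites):
            for p2 in sites[i + 1 :]:
                coupling[("chrT", p1, p2)] = max(0.0, 0.9 - 0.002 * (p2 - p1))
        pairs = self._simulated_pairs(coupling, seed=37, n_reads=1500)
        table = decay_analysis(pairs, n_bins=4)
        medians = table["median_D_prime"].to_numpy()
        assert medians[0] > medians[-1]

    def test_zero_coupling_d_centered_at_zero(self):
        pairs = self._simulated_pairs({}, seed=41, n_reads=1200)
        ds = np.array([p.D for p in pairs])
        se = ds.std(ddof=1) / math.sqrt(len(ds))
        assert abs(ds.mean()) <= 4 * se + 0.01

    def test_mean_bounded_dprime_increases_with_coupling(self):
        means = []
        for excess in (0.0, 0.5, 0.9):
            coupling = {("chrT", 41_000, 41_150): excess}
            pairs = self._simulated_pairs(coupling, seed=43, n_reads=900)
            target = [p for p in pairs if (p.pos1, p.pos2) == (41_000, 41_150)]
            assert len(target) == 1
            means.append(target[0].D_prime)
        assert means == sorted(means)
        assert means[-1] > means[0] + 0.3
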