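"""Simulator: read layout, call emission, array betas, determinism."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import norm

from ncats_eval import sim
from ncats_eval.genome import GenomicInterval, Guide, TargetRegion
from ncats_eval.meth_calls import site_calls_frame, threshold_calls
from ncats_eval.pipeline import _calls_to_records
from ncats_eval.sim import (
    LlrModel,
    SimConfig,
    SimulationError,
    simulate_array_betas,
    simulate_methylation_calls,
    simulate_read_layout,
    study_config,
)

from conftest import make_sim_config


def _overlap_fraction(reads, regions) -> float:
    n = sum(
        1
        for r in reads
        if any(r.interval.overlap(iv) >= 1 for iv in regions)
    )
    return n / len(reads)


class TestReadLayout:
    def test_all_off_target_matches_chance_overlap(self):
        config = make_sim_config(seed=3, n_reads=4000, on_target_fraction=0.0)
        reads = simulate_read_layout(config)
        regions = [t.interval for t in config.target_regions]
        frac = _overlap_fraction(reads, regions)
        chance = _expected_chance_overlap(config)
        se = math.sqrt(chance * (1 - chance) / len(reads))
        assert abs(frac - chance) <= 3 * se

    def test_all_on_target_anchored_at_guides(self):
        region = GenomicInterval("chrT", 40_000, 60_000, "t")
        config = make_sim_config(seed=1, n_reads=300, on_target_fraction=1.0)
        # single forward guide
        config.target_regions = [TargetRegion(region, (Guide(41_000, "+"),))]
        reads = simulate_read_layout(config)
        for r in reads:
            assert abs(r.interval.start - 41_000) <= 5  # cut jitter
            assert r.strand == "+"
            assert r.mapq == 60

    def test_on_target_fraction_within_binomial_error(self):
        config = make_sim_config(seed=7, n_reads=10_000, on_target_fraction=0.2)
        reads = simulate_read_layout(config)
        regions = [t.interval for t in config.target_regions]
        frac = _overlap_fraction(reads, regions)
        chance = _expected_chance_overlap(config)
        expected = 0.2 + 0.8 * chance
        se = math.sqrt(expected * (1 - expected) / len(reads))
        assert abs(frac - expected) <= 3 * se

    def test_empty_chromosomes_rejected(self):
        with pytest.raises(SimulationError):
            make_sim_config().__class__(
                **{**make_sim_config().__dict__, "chromosomes": []}
            )

    def test_bad_on_target_fraction_rejected(self):
        with pytest.raises(SimulationError):
            make_sim_config(on_target_fraction=1.5)


def _expected_chance_overlap(config: SimConfig) -> float:
    """Brute-force expected overlap probability for an off-target read."""
    rng = np.random.default_rng(987654)  # independent of the simulator streams
    lengths = config.read_length_model.draw(rng, 20_000)
    sizes = {name: size for name, size in config.chromosomes}
    total = sum(sizes.values())
    prob = 0.0
    for chrom, size in sizes.items():
        regions = [
            t.interval for t in config.target_regions if t.interval.chrom == chrom
        ]
        if not regions:
            continue
        per_len = []
        for L in lengths:
            count = 0
            for iv in regions:
                lo = max(0, iv.start - int(L) + 1)
                hi = min(size - 1, iv.end - 1)
                count += max(0, hi - lo + 1)
            per_len.append(count / size)
        prob += (size / total) * float(np.mean(per_len))
    return prob


class TestMethylationCalls:
    def test_degenerate_truth_all_methylated(self):
        config = make_sim_config(seed=2, n_reads=50, truth=1.0)
        calls = simulate_methylation_calls(simulate_read_layout(config), config)
        assert len(calls) > 0
        assert (calls["true_state"] == 1).all()

    def test_zero_coupling_matches_independence(self):
        cpgs = [41_000, 41_100]
        config = make_sim_config(
            seed=5,
            n_reads=4000,
            truth=0.5,
            n_cpgs=2,
            coupling={("chrT", cpgs[0], cpgs[1]): 0.0},
        )
        calls = simulate_methylation_calls(simulate_read_layout(config), config)
        both = calls.pivot_table(
            index="read_name", columns="start", values="true_state"
        ).dropna()
        concordance = float((both[cpgs[0]] == both[cpgs[1]]).mean())
        # independence oracle: product of marginals
        p1, p2 = float(both[cpgs[0]].mean()), float(both[cpgs[1]].mean())
        expected = p1 * p2 + (1 - p1) * (1 - p2)
        se = math.sqrt(expected * (1 - expected) / len(both))
        assert abs(concordance - expected) <= 3 * se

    def test_coupling_monotone_in_excess(self):
        cpgs = [41_000, 41_100]
        concordances = []
        for excess in (0.0, 0.4, 0.9):
            config = make_sim_config(
                seed=11,
                n_reads=3000,
                truth=0.5,
                n_cpgs=2,
                coupling={("chrT", cpgs[0], cpgs[1]): excess},
            )
            calls = simulate_methylation_calls(simulate_read_layout(config), config)
            both = calls.pivot_table(
                index="read_name", columns="start", values="true_state"
            ).dropna()
            concordances.append(float((both[cpgs[0]] == both[cpgs[1]]).mean()))
        assert concordances == sorted(concordances)

    def test_coupling_unknown_site_rejected(self):
        with pytest.raises(SimulationError):
            make_sim_config(coupling={("chrT", 1, 2): 0.5})

    def test_wide_llr_separation_recovers_states(self):
        config = make_sim_config(
            seed=9,
            n_reads=100,
            truth=0.5,
            llr_model=LlrModel(10.0, -10.0, 1.0),
        )
        calls = simulate_methylation_calls(simulate_read_layout(config), config)
        calls = calls.iloc[:1000]
        site_calls = site_calls_frame(
            threshold_calls(_calls_to_records(calls.assign(sample_id="s1"), "s1"), 2.0)
        )
        merged = site_calls.merge(
            calls.rename(columns={"read_name": "read_id", "start": "position"})[
                ["read_id", "position", "true_state"]
            ],
            on=["read_id", "position"],
        )
        recovered = (merged["state"].astype(int) == merged["true_state"]).mean()
        # misclassification mass of N(+/-10, 1) against cutoff 2 is ~Phi(-8)
        assert norm.cdf(-8) < 1e-4
        assert len(merged) >= 0.99 * len(calls)  # few calls discarded
        assert recovered >= 0.99

    def test_truth_convergence_at_depth(self):
        config = make_sim_config(seed=13, n_reads=400, truth=0.3, n_cpgs=5)
        calls = simulate_methylation_calls(simulate_read_layout(config), config)
        for _, group in calls.groupby(["sample_id", "start"]):
            freq = group["true_state"].mean()
            d = len(group)
            assert abs(freq - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / d) + 1e-12


class TestArrayBetas:
    def test_zero_noise_zero_compression_identity(self):
        config = make_sim_config(truth=0.37)
        betas = simulate_array_betas(config, {"chrT": [41_000, 41_100]})
        for sample in config.samples:
            assert np.allclose(betas[f"beta_{sample}"], 0.37)

    def test_compression_pulls_extremes_inward(self):
        config = make_sim_config(truth=0.0, array_edge_compression=0.1)
        betas = simulate_array_betas(config, {"chrT": [41_000]})
        assert (betas["beta_s1"] > 0).all()

    def test_unknown_probe_position_named_in_error(self):
        config = make_sim_config()
        with pytest.raises(SimulationError, match="chrT:99"):
            simulate_array_betas(config, {"chrT": [99]})

    def test_rmse_matches_noise_sd(self):
        positions = list(range(41_000, 41_000 + 100 * 100, 100))
        truth = {p: 0.5 for p in positions}
        config = make_sim_config(
            seed=21, truth=truth, n_cpgs=100, array_noise_sd=0.05
        )
        betas = simulate_array_betas(config, {"chrT": positions})
        resid = betas["beta_s1"].to_numpy() - 0.5
        rmse = float(np.sqrt(np.mean(resid**2)))
        # Monte-Carlo oracle: independent replicates of the same estimator
        oracle_rng = np.random.default_rng(5555)
        replicate_rmses = [
            float(np.sqrt(np.mean(oracle_rng.normal(0, 0.05, 100) ** 2)))
            for _ in range(400)
        ]
        se = float(np.std(replicate_rmses))
        assert abs(rmse - 0.05) <= 3 * se


class TestDeterminism:
    def test_identical_seed_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            config = study_config(seed=42, n_reads=400)
            reads = simulate_read_layout(config)
            calls = simulate_methylation_calls(reads, config)
            betas = simulate_array_betas(config, config.probe_positions)
            out = tmp_path / sub
            out.mkdir()
            sim.write_alignments_tsv(reads, out / "alignments.tsv")
            sim.write_nanopolish_calls(calls, out / "calls.tsv", "smoker")
            sim.write_array_csv(betas, out / "betas.csv")
        for name in ("alignments.tsv", "calls.tsv", "betas.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        r1 = simulate_read_layout(make_sim_config(seed=1))
        r2 = simulate_read_layout(make_sim_config(seed=2))
        assert any(
            a.interval.start != b.interval.start for a, b in zip(r1, r2)
        )
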