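"""End-to-end orchestration: simulate (or load) -> QC -> aggregate -> compare
-> differential methylation -> linkage, with a machine-readable run summary.

The pipeline has no hidden state: each stage calls the public module
functions on explicit intermediates, so composing the stages here yields
exactly what direct module invocation yields. Outputs are byte-stable for a
fixed configuration (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from . import compare_platforms, coverage, diff_meth, linkage, meth_calls, sim
from .genome import GenomicInterval, read_bed
from .meth_calls import PerReadCall

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "read_config_file"]


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Input paths may be the literal string ``"simulate"`` to draw that input
    from the built-in study emulation (seeded by ``seed``).
    """

    outdir: str = "ncats_run"
    seed: int = 1
    alignments: str = "simulate"
    calls_sample1: str = "simulate"  # sample 1 = case (smoker)
    calls_sample2: str = "simulate"
    array: str = "simulate"
    ewas: str = ""
    states_bed: str = ""
    regions_bed: str = ""
    sample1: str = "smoker"
    sample2: str = "nonsmoker"
    # stage toggles
    do_simulate: bool = True
    do_coverage: bool = True
    do_aggregate: bool = True
    do_compare: bool = True
    do_diffmeth: bool = True
    do_linkage: bool = True
    # stage parameters
    min_mapq: int = coverage.DEFAULT_MIN_MAPQ
    llr_cutoff: float = meth_calls.DEFAULT_LLR_CUTOFF
    min_depth: int = meth_calls.DEFAULT_MIN_DEPTH
    cluster_max_gap: int = 100
    alpha: float = 0.05
    depth_rule_inclusive: bool = True
    min_shared_reads: int = linkage.DEFAULT_MIN_SHARED_READS
    linkage_mode: str = "literal"
    # simulator knobs (used only when inputs are "simulate")
    n_reads: int = 20_000
    on_target_fraction: float = 0.032
    array_noise_sd: float = 0.08
    array_edge_compression: float = 0.15
    dmp_effect: float = -0.5

    def validate(self) -> None:
        if self.linkage_mode not in ("literal", "bounded"):
            raise ValueError("linkage_mode must be 'literal' or 'bounded'")
        for name in ("alignments", "calls_sample1", "calls_sample2", "array"):
            value = getattr(self, name)
            if value and value != "simulate" and not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value}")
        for name in ("ewas", "states_bed", "regions_bed"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value}")


def read_config_file(path: str | Path) -> PipelineConfig:
    """Parse a flat ``key = value`` configuration file."""
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict[str, Any] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown option '{key}'")
            ftype = fields[key].type
            if ftype == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif ftype == "int":
                kwargs[key] = int(value)
            elif ftype == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return PipelineConfig(**kwargs)


def _calls_to_records(calls: pd.DataFrame, sample_id: str) -> list[PerReadCall]:
    sub = calls[calls["sample_id"] == sample_id]
    return [
        PerReadCall(
            read_id=r.read_name,
            sample_id=sample_id,
            chrom=r.chromosome,
            group_start=int(r.start),
            group_end=int(r.end),
            llr=float(r.log_lik_ratio),
            num_motifs=int(r.num_motifs),
            sequence=r.sequence,
        )
        for r in sub.itertuples()
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write outputs + summary to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "warnings": [],
    }

    sim_cfg = None
    alignments = None
    calls = None
    betas_long = None
    regions: list[GenomicInterval] = []
    chromosomes: list[tuple[str, int]] = []

    needs_sim = config.do_simulate and "simulate" in (
        config.alignments, config.calls_sample1, config.calls_sample2, config.array
    )
    if needs_sim:
        sim_cfg = sim.study_config(
            seed=config.seed,
            n_reads=config.n_reads,
            on_target_fraction=config.on_target_fraction,
            array_noise_sd=config.array_noise_sd,
            array_edge_compression=config.array_edge_compression,
            dmp_effect=config.dmp_effect,
        )
        chromosomes = sim_cfg.chromosomes
        regions = [r.interval for r in sim_cfg.target_regions]
        alignments = sim.simulate_read_layout(sim_cfg)
        calls = sim.simulate_methylation_calls(alignments, sim_cfg)
        betas = sim.simulate_array_betas(sim_cfg, sim_cfg.probe_positions or {})
        betas_long = compare_platforms.melt_array_betas(betas)
        sim.write_alignments_tsv(alignments, outdir / "alignments.tsv")
        sim.write_sam(alignments, chromosomes, outdir / "alignments.sam")
        for sample in sim_cfg.samples:
            sim.write_nanopolish_calls(calls, outdir / f"calls_{sample}.tsv", sample)
        sim.write_array_csv(betas, outdir / "array_betas.csv")
        sim.write_truth_table(sim_cfg, outdir / "truth.tsv")
        summary["sim"] = {
            "n_reads": len(alignments),
            "n_call_records": len(calls),
            "samples": list(sim_cfg.samples),
        }

    if config.alignments not in ("", "simulate"):
        path = Path(config.alignments)
        if path.suffix in (".sam", ".bam"):
            alignments = coverage.read_sam(path)
        else:
            alignments = coverage.read_alignments_tsv(path)
    if config.regions_bed:
        regions = read_bed(config.regions_bed)

    filtered = alignments
    if alignments is not None:
        filtered, retention = coverage.filter_alignments(
            alignments, min_mapq=config.min_mapq
        )
        summary["filtering"] = {
            "n_input": len(alignments),
            "n_retained": len(filtered),
            "retention_pct": retention,
        }

    if config.do_coverage and filtered is not None and regions:
        on_target = coverage.count_on_target(filtered, regions)
        table = coverage.region_summary_table(filtered, regions)
        table.to_csv(outdir / "region_summary.tsv", sep="\t", index=False)
        cov_summary: dict[str, Any] = {"on_target": on_target}
        if chromosomes:
            mean_depth, sd_depth = coverage.genome_depth_stats(filtered, chromosomes)
            cov_summary["genome_mean_depth"] = mean_depth
            cov_summary["genome_sd_depth"] = sd_depth
        cov_summary["regions"] = table.to_dict(orient="records")
        summary["coverage"] = cov_summary

    frequencies: dict[str, pd.DataFrame] = {}
    site_call_frames: list[pd.DataFrame] = []
    if config.do_aggregate:
        surviving_reads = (
            {a.read_id for a in filtered} if filtered is not None else None
        )
        for sample, source in (
            (config.sample1, config.calls_sample1),
            (config.sample2, config.calls_sample2),
        ):
            if source == "simulate":
                if calls is None:
                    continue
                records = _calls_to_records(calls, sample)
            elif source:
                records = list(meth_calls.parse_methylation_calls(source, sample))
            else:
                continue
            if surviving_reads is not None:
                records = [r for r in records if r.read_id in surviving_reads]
            site_calls = meth_calls.site_calls_frame(
                meth_calls.threshold_calls(records, config.llr_cutoff)
            )
            site_call_frames.append(site_calls)
            freq = meth_calls.aggregate_frequencies(site_calls, config.min_depth)
            frequencies[sample] = freq
            meth_calls.write_frequency_tsv(freq, outdir / f"frequency_{sample}.tsv")
        if frequencies:
            all_sites = sorted(
                set().union(
                    *(
                        set(zip(f["chrom"], f["position"]))
                        for f in frequencies.values()
                    )
                )
            )
            n_clusters = 0
            sites_by_chrom: dict[str, list[int]] = {}
            for chrom, pos in all_sites:
                sites_by_chrom.setdefault(chrom, []).append(pos)
            for chrom, positions in sites_by_chrom.items():
                n_clusters += len(
                    meth_calls.cluster_sites(sorted(positions), config.cluster_max_gap)
                )
            summary["aggregate"] = {
                "n_sites_union": len(all_sites),
                "n_clusters": n_clusters,
                "per_sample_sites": {s: len(f) for s, f in frequencies.items()},
            }

    if config.do_compare and frequencies:
        if config.array == "simulate":
            probes = betas_long
        elif config.array:
            probes = compare_platforms.read_array_csv(config.array)
        else:
            probes = None
        if probes is not None:
            pooled = pd.concat(frequencies.values(), ignore_index=True)
            pairs = compare_platforms.match_sites(pooled, probes)
            pairs.to_csv(outdir / "platform_pairs.csv", index=False)
            overall = compare_platforms.concordance(pairs)
            summary["compare"] = {
                "n_pairs": overall.n,
                "pearson_r": overall.pearson_r,
                "rmse": overall.rmse,
                "per_sample": {
                    s: dataclasses.asdict(c)
                    for s, c in compare_platforms.per_sample_concordance(pairs).items()
                },
            }

    results = []
    if config.do_diffmeth and len(frequencies) == 2:
        results, n_tested = diff_meth.run_differential(
            frequencies[config.sample1],
            frequencies[config.sample2],
            min_depth_each=config.min_depth,
            alpha=config.alpha,
            inclusive=config.depth_rule_inclusive,
        )
        if config.states_bed:
            diff_meth.annotate_states(results, read_bed(config.states_bed))
        res_df = diff_meth.results_frame(results)
        res_df.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        significant = res_df[res_df["significant"]] if n_tested else res_df
        summary["diffmeth"] = {
            "n_tested": n_tested,
            "bonferroni_threshold": config.alpha / n_tested if n_tested else None,
            "n_significant": int(significant.shape[0]) if n_tested else 0,
            "mean_diff_significant": (
                float(significant["diff"].mean()) if len(significant) else None
            ),
        }
        if config.ewas:
            ewas = diff_meth.read_ewas_tsv(config.ewas)
            comp = diff_meth.compare_to_ewas(results, ewas)
            comp["depth_vs_logp"].to_csv(outdir / "ewas_depth_vs_logp.csv", index=False)
            summary["ewas"] = {
                "n_joined": comp["n"],
                "sign_agreement": comp["sign_agreement"],
                "overlap": (
                    comp["overlap"].to_dict() if comp["overlap"] is not None else None
                ),
            }

    if config.do_linkage and site_call_frames:
        pooled_calls = pd.concat(site_call_frames, ignore_index=True)
        pairs_list = linkage.pair_counts(pooled_calls, config.min_shared_reads)
        linkage.score_pairs(pairs_list, config.linkage_mode)
        table = linkage.pairs_frame(pairs_list)
        table.to_csv(outdir / "linkage_pairs.tsv", sep="\t", index=False)
        decay = linkage.decay_analysis(pairs_list)
        decay.to_csv(outdir / "linkage_decay.tsv", sep="\t", index=False)
        defined = table[table["D_prime"].notna()] if len(table) else table
        summary["linkage"] = {
            "n_pairs": len(table),
            "mode": config.linkage_mode,
            "mean_D": float(table["D"].mean()) if len(table) else None,
            "mean_D_prime": float(defined["D_prime"].mean()) if len(defined) else None,
            "median_D_prime": float(defined["D_prime"].median()) if len(defined) else None,
        }

    write_report(summary, outdir)
    return summary


def _json_default(obj: Any):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)


def write_report(summary: dict, outdir: str | Path) -> tuple[Path, Path]:
    """Write the machine-readable JSON summary and a human-readable report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "summary.json"
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default, sort_keys=True)
        fh.write("\n")

    lines = [f"ncats-eval run report (version {summary.get('version', '?')})", ""]
    params = summary.get("parameters", {})
    if params:
        lines.append("parameters:")
        lines.extend(f"  {k} = {v}" for k, v in sorted(params.items()))
        lines.append("")
    if "filtering" in summary:
        f = summary["filtering"]
        lines.append(
            f"filtering: retained {f['n_retained']} / {f['n_input']} "
            f"alignments ({f['retention_pct']}%)"
        )
    if "coverage" in summary:
        on = summary["coverage"]["on_target"]
        lines.append(
            f"on-target: {on['on_target_reads']} / {on['total_reads']} reads "
            f"({on['on_target_pct']}%)"
        )
    if "aggregate" in summary:
        a = summary["aggregate"]
        lines.append(
            f"aggregation: {a['n_sites_union']} CpGs in {a['n_clusters']} clusters"
        )
    if "compare" in summary:
        c = summary["compare"]
        lines.append(
            f"platform concordance: n={c['n_pairs']}, r={c['pearson_r']:.3f}, "
            f"RMSE={c['rmse']:.3f}"
        )
    if "diffmeth" in summary:
        d = summary["diffmeth"]
        thr = d["bonferroni_threshold"]
        lines.append(
            f"differential methylation: {d['n_significant']} significant of "
            f"{d['n_tested']} tested (Bonferroni threshold "
            f"{thr if thr is None else format(thr, '.3g')})"
        )
    if "linkage" in summary:
        li = summary["linkage"]
        lines.append(
            f"linkage: {li['n_pairs']} pairs ({li['mode']} mode), "
            f"median D' = {li['median_D_prime']}"
        )
    n_warn = len(summary.get("warnings", []))
    lines.append(f"warnings: {n_warn}")
    text_path = outdir / "report.txt"
    text_path.write_text("\n".join(lines) + "\n")
    return json_path, text_path
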