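"""Alignment filtering and enrichment / coverage QC for targeted sequencing.

Summarizes how well Cas9-guided enrichment worked: retention after quality
filtering, per-region on-target read counts and percentages, per-base depth
profiles, and read-length statistics per target region.

Conventions: a read counts toward a region if it overlaps by at least 1 bp
(half-open intervals, so a read ending exactly at a region start does not
overlap); percentages use round-half-away-from-zero at the printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import GenomicInterval, ReadAlignment

__all__ = [
    "RegionCoverageSummary",
    "percent",
    "round_half_away",
    "filter_alignments",
    "count_on_target",
    "depth_profile",
    "genome_depth_stats",
    "read_length_stats",
    "region_length_kb",
    "region_summary_table",
    "read_sam",
    "read_alignments_tsv",
    "write_bedgraph",
    "DEFAULT_MIN_MAPQ",
]

DEFAULT_MIN_MAPQ = 20


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (the convention of printed summaries)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """Percentage with round-half-away-from-zero at ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    return round_half_away(100.0 * numerator / denominator, ndigits)


@dataclass
class RegionCoverageSummary:
    """Table-1-style summary of one targeted region.

    Statistics are ``None`` (undefined, not zero) when no reads overlap the
    region.
    """

    region: GenomicInterval
    n_reads: int
    pct_reads: float | None
    mean_coverage: float | None
    mean_read_length: float | None
    n_reads_gt: int
    frac_spanning: float | None
    mean_region_fraction: float | None


def filter_alignments(
    alignments: Sequence[ReadAlignment],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    primary_only: bool = True,
) -> tuple[list[ReadAlignment], float | None]:
    """Keep high-quality (primary) alignments; return them with the retention %.

    Retention is reported rounded to the nearest integer percent, or ``None``
    for empty input (undefined).
    """
    kept = [
        a
        for a in alignments
        if a.mapq >= min_mapq and (a.is_primary or not primary_only)
    ]
    retention = percent(len(kept), len(alignments)) if alignments else None
    return kept, retention


def count_on_target(
    alignments: Sequence[ReadAlignment], regions: Sequence[GenomicInterval]
) -> dict:
    """Per-region and total on-target read counts with percentages (2 decimals).

    Regions must not overlap each other: a read may contribute to at most one
    region's count. Overlap means >= 1 bp under half-open coordinates.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for region in regions:
        by_chrom.setdefault(region.chrom, []).append(region)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda r: r.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"target regions overlap on {chrom}: "
                    f"{a.name or a.start}-{a.end} and {b.name or b.start}-{b.end}"
                )
    total = len(alignments)
    counts = {region.name or f"{region.chrom}:{region.start}": 0 for region in regions}
    n_on = 0
    for read in alignments:
        for region in by_chrom.get(read.interval.chrom, ()):
            if read.interval.overlap(region) >= 1:
                counts[region.name or f"{region.chrom}:{region.start}"] += 1
                n_on += 1
                break
    out = {
        "total_reads": total,
        "on_target_reads": n_on,
        "on_target_pct": percent(n_on, total, 2) if total else None,
        "regions": {
            name: {
                "n_reads": n,
                "pct_reads": percent(n, total, 2) if total else None,
            }
            for name, n in counts.items()
        },
    }
    return out


def depth_profile(
    alignments: Sequence[ReadAlignment],
    interval: GenomicInterval,
    bin_size: int = 1,
) -> tuple[np.ndarray, float, float]:
    """Read depth across an interval: per-base (or binned mean) profile, mean, SD.

    Depth at position p counts reads whose interval contains p. SD is the
    population standard deviation over the interval's bases.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    length = interval.length
    delta = np.zeros(length + 1, dtype=np.int64)
    for read in alignments:
        if read.interval.chrom != interval.chrom:
            continue
        lo = max(read.interval.start, interval.start) - interval.start
        hi = min(read.interval.end, interval.end) - interval.start
        if hi > lo:
            delta[lo] += 1
            delta[hi] -= 1
    depth = np.cumsum(delta[:-1])
    mean = float(depth.mean())
    sd = float(depth.std(ddof=0))
    if bin_size > 1:
        n_bins = math.ceil(length / bin_size)
        pad = n_bins * bin_size - length
        binned = np.pad(depth.astype(float), (0, pad), constant_values=np.nan)
        depth = np.nanmean(binned.reshape(n_bins, bin_size), axis=1)
    return depth, mean, sd


def genome_depth_stats(
    alignments: Sequence[ReadAlignment],
    chromosomes: Sequence[tuple[str, int]],
    bin_size: int = 10_000,
) -> tuple[float, float]:
    """Genome-wide mean and SD of depth over fixed-size bins."""
    bins: list[np.ndarray] = []
    for chrom, size in chromosomes:
        profile, _, _ = depth_profile(
            alignments, GenomicInterval(chrom, 0, size), bin_size=bin_size
        )
        bins.append(profile)
    allbins = np.concatenate(bins)
    return float(allbins.mean()), float(allbins.std(ddof=0))


def read_length_stats(
    alignments: Sequence[ReadAlignment],
    region: GenomicInterval,
    length_threshold: int = 10_000,
    span_fraction: float = 0.9,
) -> RegionCoverageSummary:
    """Length and span statistics for the reads overlapping one region."""
    hits = [a for a in alignments if a.interval.overlap(region) >= 1]
    n = len(hits)
    if n == 0:
        return RegionCoverageSummary(region, 0, None, None, None, 0, None, None)
    lengths = np.array([a.length for a in hits], dtype=float)
    overlaps = np.array([a.interval.overlap(region) for a in hits], dtype=float)
    _, mean_cov, _ = depth_profile(hits, region)
    spanning = overlaps >= span_fraction * region.length
    return RegionCoverageSummary(
        region=region,
        n_reads=n,
        pct_reads=None,  # filled by region_summary_table against the global total
        mean_coverage=mean_cov,
        mean_read_length=float(lengths.mean()),
        n_reads_gt=int((lengths > length_threshold).sum()),
        frac_spanning=float(spanning.mean()),
        mean_region_fraction=float((overlaps / region.length).mean()),
    )


def region_length_kb(interval: GenomicInterval) -> float:
    """Region size in kb to 1 decimal, as printed for a 1-based inclusive range.

    ``interval`` is the usual 0-based half-open representation, whose length
    equals (end - start + 1) of the printed 1-based inclusive range.
    """
    if interval.length <= 0:
        raise ValueError("interval must have positive length")
    return round_half_away(interval.length / 1000.0, 1)


def region_summary_table(
    alignments: Sequence[ReadAlignment],
    regions: Sequence[GenomicInterval],
    length_threshold: int = 10_000,
    span_fraction: float = 0.9,
) -> pd.DataFrame:
    """Per-region enrichment summary in the layout of the study's Table 1."""
    total = len(alignments)
    rows = []
    for region in regions:
        s = read_length_stats(alignments, region, length_threshold, span_fraction)
        rows.append(
            {
                "region": region.name or f"{region.chrom}:{region.start}",
                "chrom": region.chrom,
                "start_1based": region.start + 1,
                "end_1based": region.end,
                "size_kb": region_length_kb(region),
                "n_reads": s.n_reads,
                "pct_reads": percent(s.n_reads, total, 2) if total else None,
                "mean_coverage": s.mean_coverage,
                "mean_read_length": s.mean_read_length,
                "n_reads_gt_threshold": s.n_reads_gt,
                "frac_spanning": s.frac_spanning,
                "mean_region_fraction": s.mean_region_fraction,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_sam(path: str | Path) -> list[ReadAlignment]:
    """Read SAM/BAM alignments (sample id taken from the RG tag when present)."""
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            out.append(
                ReadAlignment(
                    read_id=seg.query_name,
                    interval=GenomicInterval(
                        seg.reference_name, seg.reference_start, seg.reference_end
                    ),
                    strand="-" if seg.is_reverse else "+",
                    mapq=seg.mapping_quality,
                    is_primary=not (seg.is_secondary or seg.is_supplementary),
                    sample_id=seg.get_tag("RG") if seg.has_tag("RG") else "",
                )
            )
    return out


def read_alignments_tsv(path: str | Path) -> list[ReadAlignment]:
    """Read the tabular alignment fallback written by the simulator."""
    df = pd.read_csv(path, sep="\t")
    return [
        ReadAlignment(
            read_id=str(r.read_id),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            strand=str(r.strand),
            mapq=int(r.mapq),
            is_primary=bool(r.primary_flag),
            sample_id=str(r.sample_id),
        )
        for r in df.itertuples()
    ]


def write_bedgraph(
    depth: np.ndarray, interval: GenomicInterval, path: str | Path
) -> None:
    """Write a per-base depth profile as bedGraph, merging equal-depth runs."""
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        run_start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[run_start]:
                fh.write(
                    f"{interval.chrom}\t{interval.start + run_start}\t"
                    f"{interval.start + i}\t{depth[run_start]:g}\n"
                )
                run_start = i
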