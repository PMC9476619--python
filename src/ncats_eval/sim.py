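"""Synthetic data generator for Cas9-targeted nanopore methylation studies.

Emulates the inputs of a two-sample nCATS (nanopore Cas9-targeted sequencing)
experiment: guide-anchored read layouts on a reduced genome, per-read CpG
methylation calls with state-conditional log-likelihood-ratio emissions, and
microarray beta values with edge compression and Gaussian noise. Every stage
is seeded and reproducible: identical configuration gives byte-identical
output files.

The generative model, per read:

* on-target reads start at a guide cut site (uniform jitter of +/-5 bp) and
  extend downstream on the guide's strand with log-normal lengths; off-target
  reads are placed uniformly over the genome;
* at each CpG the read covers, a binary methylation state is drawn from the
  sample's true proportion at that site; optional pairwise coupling copies the
  upstream partner's state with a configured excess probability;
* the caller emission is a Gaussian log-likelihood ratio whose location and
  scale depend on the true state (methylated location > 0 > unmethylated).

Array betas are the true proportions compressed toward the interior at the
extremes (the array loses sensitivity near 0 and 1), plus Gaussian noise,
clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .genome import GenomicInterval, Guide, ReadAlignment, TargetRegion

__all__ = [
    "ReadLengthModel",
    "LlrModel",
    "SimConfig",
    "SimulationError",
    "simulate_read_layout",
    "simulate_methylation_calls",
    "simulate_array_betas",
    "study_config",
    "write_sam",
    "write_alignments_tsv",
    "write_nanopolish_calls",
    "write_array_csv",
    "write_truth_table",
]

NANOPOLISH_COLUMNS = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
]

# fixed 11-mer context with a single CG at offset 5, used for singleton calls
_CONTEXT = "ATCTACGTCTA"
_CUT_JITTER_BP = 5

# stable sub-stream indices so adding a stage never reshuffles earlier ones
_STAGE_KEYS = {"layout": 0, "calls": 1, "array": 2, "map": 3}


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class ReadLengthModel:
    """Truncated log-normal read-length distribution (lengths in bp)."""

    mean_log: float
    sd_log: float
    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if self.min_bp >= self.max_bp:
            raise SimulationError("read length truncation requires min < max")
        if self.sd_log < 0:
            raise SimulationError("sd_log must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lengths = rng.lognormal(self.mean_log, self.sd_log, size=n)
        return np.clip(np.round(lengths), self.min_bp, self.max_bp).astype(np.int64)


@dataclass(frozen=True)
class LlrModel:
    """State-conditional Gaussian emissions for the caller's log-likelihood ratio."""

    loc_methylated: float = 5.0
    loc_unmethylated: float = -5.0
    scale: float = 2.0

    def __post_init__(self) -> None:
        if not (self.loc_methylated > 0.0 > self.loc_unmethylated):
            raise SimulationError(
                "llr model must separate states: methylated location > 0 > "
                "unmethylated location"
            )
        if self.scale <= 0:
            raise SimulationError("llr scale must be > 0")


@dataclass
class SimConfig:
    """Full generative specification for one synthetic two-sample experiment.

    ``true_methylation`` maps sample -> chromosome -> per-CpG proportion array
    aligned with ``cpg_positions``. ``dmp_effects`` are signed differences
    added to the *second* sample's proportions at designated positions (the
    smoker in the default study emulation, hypomethylated by ~0.5).
    ``coupling`` maps (chrom, pos1, pos2) to the excess probability with which
    a read copies the pos1 state to pos2.
    """

    seed: int
    chromosomes: list[tuple[str, int]]
    target_regions: list[TargetRegion]
    n_reads: int
    on_target_fraction: float
    read_length_model: ReadLengthModel
    cpg_positions: dict[str, np.ndarray]
    true_methylation: dict[str, dict[str, np.ndarray]]
    dmp_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    llr_model: LlrModel = field(default_factory=LlrModel)
    coupling: dict[tuple[str, int, int], float] = field(default_factory=dict)
    array_noise_sd: float = 0.0
    array_edge_compression: float = 0.0
    probe_positions: dict[str, list[int]] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if not self.chromosomes:
            raise SimulationError("at least one chromosome is required")
        if not 0.0 <= self.on_target_fraction <= 1.0:
            raise SimulationError("on_target_fraction must be in [0, 1]")
        if self.on_target_fraction > 0 and not self.target_regions:
            raise SimulationError(
                "on_target_fraction > 0 requires at least one target region"
            )
        if self.n_reads < 0:
            raise SimulationError("n_reads must be >= 0")
        if not 0.0 <= self.array_edge_compression <= 1.0:
            raise SimulationError("array_edge_compression must be in [0, 1]")
        if self.array_noise_sd < 0:
            raise SimulationError("array_noise_sd must be >= 0")
        if len(self.true_methylation) < 1:
            raise SimulationError("at least one sample is required")
        chrom_names = {name for name, _ in self.chromosomes}
        for chrom, positions in self.cpg_positions.items():
            if chrom not in chrom_names:
                raise SimulationError(f"CpG positions on unknown chromosome {chrom}")
            arr = np.asarray(positions)
            if arr.size and np.any(np.diff(arr) <= 0):
                raise SimulationError(
                    f"cpg_positions on {chrom} must be strictly increasing"
                )
        for sample, per_chrom in self.true_methylation.items():
            for chrom, props in per_chrom.items():
                arr = np.asarray(props, dtype=float)
                if arr.shape != np.asarray(self.cpg_positions[chrom]).shape:
                    raise SimulationError(
                        f"truth for {sample}/{chrom} does not match cpg_positions"
                    )
                if np.any((arr < 0) | (arr > 1)):
                    raise SimulationError(f"truth for {sample}/{chrom} outside [0, 1]")
        for (chrom, p1, p2), excess in self.coupling.items():
            positions = np.asarray(self.cpg_positions.get(chrom, ()))
            for p in (p1, p2):
                if p not in positions:
                    raise SimulationError(
                        f"coupling references CpG {chrom}:{p} absent from cpg_positions"
                    )
            if not 0.0 <= excess <= 1.0:
                raise SimulationError("coupling excess must be in [0, 1]")
        for chrom, props in self.resolved_truth(self.samples[-1]).items():
            if np.any((props < 0) | (props > 1)):
                raise SimulationError(
                    "dmp_effects push a sample-2 proportion outside [0, 1] on "
                    f"{chrom}"
                )

    # -- derived views ----------------------------------------------------

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.true_methylation)

    def rng(self, stage: str) -> np.random.Generator:
        """Independent deterministic RNG stream for one simulation stage."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGE_KEYS[stage],))
        return np.random.default_rng(ss)

    def resolved_truth(self, sample_id: str) -> dict[str, np.ndarray]:
        """Per-chromosome truth with DMP effects applied to the second sample."""
        base = {
            chrom: np.asarray(props, dtype=float).copy()
            for chrom, props in self.true_methylation[sample_id].items()
        }
        if sample_id == self.samples[-1] and len(self.samples) > 1:
            for (chrom, pos), effect in self.dmp_effects.items():
                idx = int(np.searchsorted(self.cpg_positions[chrom], pos))
                positions = np.asarray(self.cpg_positions[chrom])
                if idx >= positions.size or positions[idx] != pos:
                    raise SimulationError(
                        f"dmp effect at {chrom}:{pos} is not a configured CpG"
                    )
                base[chrom][idx] += effect
        return base


# ---------------------------------------------------------------------------
# read layout


def simulate_read_layout(config: SimConfig) -> list[ReadAlignment]:
    """Place reads on the genome: guide-anchored on-target, uniform off-target.

    On-target reads start within +/-5 bp of a uniformly chosen guide cut and
    extend downstream on the guide's strand with mapq 60; off-target reads are
    uniform over the genome with mapq drawn uniformly from 0..60, so mapping-
    quality filtering is exercised downstream. Each read is assigned to one of
    the configured samples with equal probability.
    """
    rng = config.rng("layout")
    n = config.n_reads
    chrom_names = [name for name, _ in config.chromosomes]
    chrom_sizes = {name: size for name, size in config.chromosomes}
    sizes = np.array([size for _, size in config.chromosomes], dtype=float)

    is_on_target = rng.random(n) < config.on_target_fraction
    lengths = config.read_length_model.draw(rng, n)
    sample_idx = rng.integers(0, len(config.samples), size=n)
    samples = config.samples

    guides: list[tuple[str, Guide]] = [
        (region.interval.chrom, g)
        for region in config.target_regions
        for g in region.guides
    ]
    if config.on_target_fraction > 0 and not guides:
        raise SimulationError("on-target reads requested but no guides configured")

    guide_choice = rng.integers(0, max(len(guides), 1), size=n)
    jitter = rng.integers(-_CUT_JITTER_BP, _CUT_JITTER_BP + 1, size=n)
    off_chrom = rng.choice(len(chrom_names), size=n, p=sizes / sizes.sum())
    off_pos = rng.random(n)
    off_strand = rng.integers(0, 2, size=n)
    off_mapq = rng.integers(0, 61, size=n)

    reads: list[ReadAlignment] = []
    for i in range(n):
        length = int(lengths[i])
        if is_on_target[i]:
            chrom, guide = guides[int(guide_choice[i])]
            anchor = guide.cut_position + int(jitter[i])
            if guide.strand == "+":
                start, end = anchor, anchor + length
            else:
                start, end = anchor - length, anchor
            strand, mapq = guide.strand, 60
        else:
            chrom = chrom_names[int(off_chrom[i])]
            start = int(off_pos[i] * chrom_sizes[chrom])
            end = start + length
            strand = "+" if off_strand[i] == 0 else "-"
            mapq = int(off_mapq[i])
        size = chrom_sizes[chrom]
        start, end = max(0, start), min(size, end)
        if end - start < 1:  # read fell off the chromosome edge
            start, end = max(0, min(start, size - 1)), max(1, min(end, size))
        reads.append(
            ReadAlignment(
                read_id=f"read{i:06d}",
                interval=GenomicInterval(chrom, start, end),
                strand=strand,
                mapq=mapq,
                is_primary=True,
                sample_id=samples[int(sample_idx[i])],
            )
        )
    return reads


# ---------------------------------------------------------------------------
# methylation calls


def simulate_methylation_calls(
    alignments: Sequence[ReadAlignment], config: SimConfig
) -> pd.DataFrame:
    """Emit one caller record per (read, covered CpG) with a state-conditional LLR.

    Returns a table in the Nanopolish call dialect plus ``sample_id`` and the
    latent ``true_state`` (1 = methylated) retained for oracles. Pairwise
    coupling is applied read-wise: for each configured (pos1, pos2) pair the
    pos2 state is replaced by the pos1 state with the configured excess
    probability.
    """
    rng = config.rng("calls")
    truth = {s: config.resolved_truth(s) for s in config.samples}
    positions = {c: np.asarray(p) for c, p in config.cpg_positions.items()}
    coupling_by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for (chrom, p1, p2), excess in sorted(config.coupling.items()):
        coupling_by_chrom.setdefault(chrom, []).append((p1, p2, excess))

    llr = config.llr_model
    rows: dict[str, list] = {key: [] for key in (
        "chromosome", "strand", "start", "end", "read_name", "log_lik_ratio",
        "sample_id", "true_state",
    )}

    for read in alignments:
        chrom = read.interval.chrom
        pos = positions.get(chrom)
        if pos is None or pos.size == 0:
            continue
        lo = int(np.searchsorted(pos, read.interval.start, side="left"))
        hi = int(np.searchsorted(pos, read.interval.end, side="left"))
        if hi <= lo:
            continue
        covered = pos[lo:hi]
        props = truth[read.sample_id][chrom][lo:hi]
        states = (rng.random(hi - lo) < props).astype(np.int8)
        for p1, p2, excess in coupling_by_chrom.get(chrom, ()):
            i1 = int(np.searchsorted(covered, p1))
            i2 = int(np.searchsorted(covered, p2))
            if (
                i1 < covered.size and covered[i1] == p1
                and i2 < covered.size and covered[i2] == p2
                and rng.random() < excess
            ):
                states[i2] = states[i1]
        locs = np.where(states == 1, llr.loc_methylated, llr.loc_unmethylated)
        emissions = rng.normal(locs, llr.scale)
        k = hi - lo
        rows["chromosome"].extend([chrom] * k)
        rows["strand"].extend([read.strand] * k)
        rows["start"].extend(covered.tolist())
        rows["end"].extend(covered.tolist())
        rows["read_name"].extend([read.read_id] * k)
        rows["log_lik_ratio"].extend(np.round(emissions, 3).tolist())
        rows["sample_id"].extend([read.sample_id] * k)
        rows["true_state"].extend(states.tolist())

    calls = pd.DataFrame(rows)
    calls["log_lik_unmethylated"] = -85.0
    calls["log_lik_methylated"] = np.round(-85.0 + calls["log_lik_ratio"], 3)
    calls["num_calling_strands"] = 1
    calls["num_motifs"] = 1
    calls["sequence"] = _CONTEXT
    return calls[NANOPOLISH_COLUMNS + ["sample_id", "true_state"]]


# ---------------------------------------------------------------------------
# array betas


def simulate_array_betas(
    config: SimConfig, probe_positions: Mapping[str, Sequence[int]]
) -> pd.DataFrame:
    """Array beta values at probe positions: edge-compressed truth plus noise.

    Compression maps a true proportion t to gamma + t * (1 - 2 * gamma) with
    gamma = ``array_edge_compression``, pulling the extremes toward the
    interior while leaving 0.5 fixed; Gaussian noise (``array_noise_sd``) is
    then added and the result clipped to [0, 1]. Returns a wide table with one
    beta column per sample.
    """
    rng = config.rng("array")
    gamma = config.array_edge_compression
    records: list[dict] = []
    probe_no = 0
    for chrom in sorted(probe_positions):
        cpgs = np.asarray(config.cpg_positions.get(chrom, ()))
        for p in sorted(probe_positions[chrom]):
            idx = int(np.searchsorted(cpgs, p))
            if idx >= cpgs.size or cpgs[idx] != p:
                raise SimulationError(
                    f"probe position {chrom}:{p} has no true methylation value"
                )
            rec = {"probe_id": f"cg{probe_no:08d}", "chrom": chrom, "position": int(p)}
            for sample in config.samples:
                t = config.resolved_truth(sample)[chrom][idx]
                compressed = gamma + t * (1.0 - 2.0 * gamma)
                beta = compressed + rng.normal(0.0, config.array_noise_sd)
                rec[f"beta_{sample}"] = float(np.clip(beta, 0.0, 1.0))
            records.append(rec)
            probe_no += 1
    return pd.DataFrame.from_records(
        records, columns=["probe_id", "chrom", "position"]
        + [f"beta_{s}" for s in config.samples]
    )


# ---------------------------------------------------------------------------
# default study emulation


def study_config(
    seed: int,
    n_reads: int = 20_000,
    on_target_fraction: float = 0.032,
    array_noise_sd: float = 0.08,
    array_edge_compression: float = 0.15,
    dmp_effect: float = -0.5,
    coupling: Mapping[tuple[str, int, int], float] | None = None,
) -> SimConfig:
    """Scaled-down two-sample smoking study: three targeted regions on a 60 Mb genome.

    Mirrors the study design: a ~140.5 kb region tiled with 10 guides
    ("AHRR"), an 8.3 kb intergenic region and a 17.6 kb region ("GFI1") with
    guides at both ends; two samples (non-smoker, smoker) with 12 designated
    DMPs hypomethylated in the smoker by ``dmp_effect`` (default -0.5: ten in
    the large region, six of them clustered within 400 bp, and two ~1 kb apart
    in the intergenic region). Read counts and the on-target fraction are
    chosen so the absolute number of on-target reads (~640) and per-region
    coverage match the study while the off-target background is scaled to the
    reduced genome.
    """
    map_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_KEYS["map"],))
    )
    chromosomes = [("chr5", 20_000_000), ("chr2", 20_000_000), ("chr1", 20_000_000)]

    def tiled_guides(iv: GenomicInterval, n_tiled: int) -> tuple[Guide, ...]:
        # two inward guides at each end, the rest tiled across the interior
        cuts = [iv.start + 10, iv.start + 60, iv.end - 60, iv.end - 10]
        strands = ["+", "+", "-", "-"]
        if n_tiled > 0:
            interior = np.linspace(iv.start, iv.end, n_tiled + 2)[1:-1]
            for k, c in enumerate(interior):
                cuts.append(int(c))
                strands.append("+" if k % 2 == 0 else "-")
        order = np.argsort(cuts)
        return tuple(Guide(int(cuts[i]), strands[i]) for i in order)

    iv_ahrr = GenomicInterval.from_1based("chr5", 300_325, 440_842, "AHRR")
    iv_chr2 = GenomicInterval.from_1based("chr2", 10_000_000, 10_008_337, "chr2_intergenic")
    iv_gfi1 = GenomicInterval.from_1based("chr1", 10_000_000, 10_017_647, "GFI1")
    regions = [
        TargetRegion(iv_ahrr, tiled_guides(iv_ahrr, 6)),
        TargetRegion(iv_chr2, tiled_guides(iv_chr2, 0)),
        TargetRegion(iv_gfi1, tiled_guides(iv_gfi1, 0)),
    ]

    # CpG map: dense inside targets (median gap ~35 bp), sparse background
    cpg_positions: dict[str, np.ndarray] = {}
    for chrom, size in chromosomes:
        background = np.sort(
            map_rng.choice(size, size=size // 3000, replace=False)
        ).astype(np.int64)
        dense = []
        for region in regions:
            if region.interval.chrom != chrom:
                continue
            gaps = map_rng.lognormal(math.log(35.0), 1.0, size=region.interval.length // 30)
            pos = region.interval.start + np.cumsum(np.maximum(2, np.round(gaps)))
            dense.append(pos[pos < region.interval.end].astype(np.int64))
        merged = np.unique(np.concatenate([background] + dense))
        cpg_positions[chrom] = merged

    # bimodal base truth shared by both samples
    base: dict[str, np.ndarray] = {}
    for chrom, pos in cpg_positions.items():
        low = map_rng.beta(1.0, 8.0, size=pos.size)
        high = map_rng.beta(8.0, 1.5, size=pos.size)
        base[chrom] = np.where(map_rng.random(pos.size) < 0.3, low, high)

    # 12 DMPs: 10 in AHRR (6 clustered within 400 bp), 2 in chr2 ~1 kb apart
    def nearest_cpg(chrom: str, target: int) -> int:
        pos = cpg_positions[chrom]
        return int(pos[np.argmin(np.abs(pos - target))])

    # DMPs sit just downstream of forward guides, at the acute coverage peaks
    # where detection is best powered (significant sites are high-depth sites)
    ahrr_fwd_cuts = sorted(
        g.cut_position for g in regions[0].guides if g.strand == "+"
    )
    dmp_positions: list[tuple[str, int]] = []
    cluster_anchor = ahrr_fwd_cuts[2] + 300
    for offset in (0, 70, 140, 220, 300, 390):
        dmp_positions.append(("chr5", nearest_cpg("chr5", cluster_anchor + offset)))
    for cut in (ahrr_fwd_cuts[0], ahrr_fwd_cuts[1], ahrr_fwd_cuts[3], ahrr_fwd_cuts[4]):
        dmp_positions.append(("chr5", nearest_cpg("chr5", cut + 500)))
    dmp_positions.append(("chr2", nearest_cpg("chr2", iv_chr2.start + 3_000)))
    dmp_positions.append(("chr2", nearest_cpg("chr2", iv_chr2.start + 4_000)))
    dmp_positions = list(dict.fromkeys(dmp_positions))

    dmp_effects: dict[tuple[str, int], float] = {}
    for chrom, p in dmp_positions:
        idx = int(np.searchsorted(cpg_positions[chrom], p))
        base[chrom][idx] = 0.85  # smoker ends at 0.35 with the default effect
        dmp_effects[(chrom, p)] = dmp_effect

    true_methylation = {
        "nonsmoker": {c: v.copy() for c, v in base.items()},
        "smoker": {c: v.copy() for c, v in base.items()},
    }

    # EPIC-like probe panel: sparse subset of in-target CpGs
    probe_positions: dict[str, list[int]] = {}
    for region, n_probes in zip(regions, (159, 25, 45)):
        chrom = region.interval.chrom
        pos = cpg_positions[chrom]
        inside = pos[(pos >= region.interval.start) & (pos < region.interval.end)]
        take = map_rng.choice(inside.size, size=min(n_probes, inside.size), replace=False)
        probe_positions.setdefault(chrom, []).extend(int(p) for p in np.sort(inside[take]))

    config = SimConfig(
        seed=seed,
        chromosomes=chromosomes,
        target_regions=regions,
        n_reads=n_reads,
        on_target_fraction=on_target_fraction,
        read_length_model=ReadLengthModel(math.log(5000.0), 0.85, 200, 60_000),
        cpg_positions=cpg_positions,
        true_methylation=true_methylation,
        dmp_effects=dmp_effects,
        llr_model=LlrModel(),
        coupling=dict(coupling) if coupling else {},
        array_noise_sd=array_noise_sd,
        array_edge_compression=array_edge_compression,
        probe_positions=probe_positions,
    )
    return config


# ---------------------------------------------------------------------------
# writers


def write_sam(
    alignments: Sequence[ReadAlignment],
    chromosomes: Sequence[tuple[str, int]],
    path: str | Path,
) -> None:
    """Write alignments as a plain-text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": size} for name, size in chromosomes],
    }
    order = sorted(
        range(len(alignments)),
        key=lambda i: (alignments[i].interval.chrom, alignments[i].interval.start),
    )
    tid = {name: k for k, (name, _) in enumerate(chromosomes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in order:
            read = alignments[i]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.flag = (0 if read.strand == "+" else 16) | (0 if read.is_primary else 256)
            seg.reference_id = tid[read.interval.chrom]
            seg.reference_start = read.interval.start
            seg.mapping_quality = read.mapq
            seg.cigartuples = [(0, read.interval.length)]
            seg.set_tag("RG", read.sample_id or "unknown")
            out.write(seg)


def write_alignments_tsv(alignments: Sequence[ReadAlignment], path: str | Path) -> None:
    """Tabular fallback for the alignment records."""
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\tmapq\tprimary_flag\tsample_id\n")
        for read in alignments:
            fh.write(
                f"{read.read_id}\t{read.interval.chrom}\t{read.interval.start}\t"
                f"{read.interval.end}\t{read.strand}\t{read.mapq}\t"
                f"{int(read.is_primary)}\t{read.sample_id}\n"
            )


def write_nanopolish_calls(calls: pd.DataFrame, path: str | Path, sample_id: str) -> None:
    """Write one sample's calls in the Nanopolish methylation-call dialect."""
    sub = calls.loc[calls["sample_id"] == sample_id, NANOPOLISH_COLUMNS]
    sub.to_csv(path, sep="\t", index=False)


def write_array_csv(betas: pd.DataFrame, path: str | Path) -> None:
    betas.to_csv(path, index=False)


def write_truth_table(config: SimConfig, path: str | Path) -> None:
    """Per-sample true proportions at every CpG, for test oracles."""
    frames = []
    for sample in config.samples:
        truth = config.resolved_truth(sample)
        for chrom in sorted(truth):
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "position": np.asarray(config.cpg_positions[chrom]),
                        "sample_id": sample,
                        "true_proportion": truth[chrom],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
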