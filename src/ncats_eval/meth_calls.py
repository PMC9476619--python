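"""Per-read methylation calls: parsing, LLR thresholding, site aggregation.

Follows the conventions of the Nanopolish companion frequency script: calls
with |log-likelihood ratio| below the cutoff (default 2.0) are discarded;
CpG-group calls (``num_motifs`` > 1) are split into one record per
constituent CpG, each inheriting the group's state, with constituent
positions located by scanning the local sequence context for CG
dinucleotides. Positions are 0-based forward-strand C coordinates; calls on
either strand collapse to the forward-strand C.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "PerReadCall",
    "SiteCall",
    "CallFormatError",
    "parse_methylation_calls",
    "threshold_calls",
    "aggregate_frequencies",
    "cluster_sites",
    "site_calls_frame",
    "write_frequency_tsv",
    "read_frequency_tsv",
    "DEFAULT_LLR_CUTOFF",
    "DEFAULT_MIN_DEPTH",
]

DEFAULT_LLR_CUTOFF = 2.0
DEFAULT_MIN_DEPTH = 10

_REQUIRED_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "num_motifs",
    "sequence",
)


class CallFormatError(ValueError):
    """Raised when a call file does not follow the expected dialect."""


@dataclass(frozen=True)
class PerReadCall:
    """One caller emission: one read at one CpG group."""

    read_id: str
    sample_id: str
    chrom: str
    group_start: int
    group_end: int
    llr: float
    num_motifs: int = 1
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.group_start > self.group_end:
            raise ValueError("group_start must be <= group_end")
        if self.num_motifs < 1:
            raise ValueError("num_motifs must be >= 1")


@dataclass(frozen=True)
class SiteCall:
    """Binary methylation state of one read at one CpG."""

    read_id: str
    sample_id: str
    chrom: str
    position: int
    state: bool  # True = methylated


@dataclass(frozen=True)
class SiteMethylation:
    """Per-sample read counts and methylated frequency at one CpG."""

    chrom: str
    position: int
    sample_id: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_meth <= self.n_total:
            raise ValueError("need 0 <= n_meth <= n_total")

    @property
    def frequency(self) -> float:
        return self.n_meth / self.n_total


def parse_methylation_calls(path: str | Path, sample_id: str) -> Iterator[PerReadCall]:
    """Stream PerReadCall records from a Nanopolish-dialect call TSV.

    Raises :class:`CallFormatError` naming the column if a required column is
    missing; malformed rows raise with their line number.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise CallFormatError(f"{path}: missing required column '{col}'")
        for lineno, row in enumerate(reader, start=2):
            try:
                yield PerReadCall(
                    read_id=row["read_name"],
                    sample_id=sample_id,
                    chrom=row["chromosome"],
                    group_start=int(row["start"]),
                    group_end=int(row["end"]),
                    llr=float(row["log_lik_ratio"]),
                    num_motifs=int(row["num_motifs"]),
                    sequence=row["sequence"],
                )
            except (TypeError, ValueError) as exc:
                raise CallFormatError(f"{path}:{lineno}: malformed row ({exc})") from exc


def _cg_offsets(sequence: str) -> list[int]:
    return [i for i in range(len(sequence) - 1) if sequence[i : i + 2] == "CG"]


def split_group_positions(call: PerReadCall) -> list[int]:
    """Genomic C positions of the CpGs in a group call.

    The first CG in the context anchors at ``group_start``; the rest are
    offset by their spacing within the context string.
    """
    if call.num_motifs == 1:
        return [call.group_start]
    offsets = _cg_offsets(call.sequence)
    if len(offsets) < call.num_motifs:
        raise CallFormatError(
            f"group at {call.chrom}:{call.group_start} declares "
            f"{call.num_motifs} motifs but context has {len(offsets)} CG sites"
        )
    anchor = offsets[0]
    return [call.group_start + (off - anchor) for off in offsets[: call.num_motifs]]


def threshold_calls(
    calls: Iterable[PerReadCall], llr_cutoff: float = DEFAULT_LLR_CUTOFF
) -> Iterator[SiteCall]:
    """Binarize calls at |LLR| >= cutoff and split CpG groups into site calls.

    Calls with |llr| < cutoff are discarded (ambiguous); positive surviving
    LLRs are methylated, negative unmethylated. Group calls yield one
    :class:`SiteCall` per constituent CpG, all inheriting the group state.
    """
    if llr_cutoff <= 0:
        raise ValueError("llr_cutoff must be > 0")
    for call in calls:
        if abs(call.llr) < llr_cutoff:
            continue
        state = call.llr > 0
        for position in split_group_positions(call):
            yield SiteCall(call.read_id, call.sample_id, call.chrom, position, state)


def site_calls_frame(site_calls: Iterable[SiteCall]) -> pd.DataFrame:
    """Materialize site calls into a columnar table."""
    return pd.DataFrame(
        [(c.read_id, c.sample_id, c.chrom, c.position, c.state) for c in site_calls],
        columns=["read_id", "sample_id", "chrom", "position", "state"],
    )


def aggregate_frequencies(
    site_calls: Iterable[SiteCall] | pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Aggregate read-level states into per-site methylated frequencies.

    Returns one row per (sample, site) with ``n_meth``, ``n_total`` and
    ``frequency``, dropping sites below ``min_depth`` and sorting by
    chromosome then position. Duplicate (read, site) records raise: a read
    must not be counted twice at one CpG.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    df = site_calls if isinstance(site_calls, pd.DataFrame) else site_calls_frame(site_calls)
    if df.empty:
        return pd.DataFrame(
            columns=["chrom", "position", "sample_id", "n_meth", "n_total", "frequency"]
        )
    dup = df.duplicated(subset=["read_id", "sample_id", "chrom", "position"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (read, position) call: read "
            f"{first['read_id']} at {first['chrom']}:{first['position']}"
        )
    grouped = (
        df.groupby(["chrom", "position", "sample_id"], sort=True)["state"]
        .agg(n_meth="sum", n_total="size")
        .reset_index()
    )
    grouped = grouped[grouped["n_total"] >= min_depth].reset_index(drop=True)
    grouped["n_meth"] = grouped["n_meth"].astype(int)
    grouped["frequency"] = grouped["n_meth"] / grouped["n_total"]
    return grouped


def cluster_sites(positions: Sequence[int], max_gap: int) -> list[list[int]]:
    """Partition sorted positions into maximal runs with inter-site gap <= max_gap."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    positions = list(positions)
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be sorted ascending")
    clusters: list[list[int]] = []
    for p in positions:
        if clusters and p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def write_frequency_tsv(frequencies: pd.DataFrame, path: str | Path) -> None:
    """Write per-site frequencies in the companion frequency-script layout."""
    out = pd.DataFrame(
        {
            "chromosome": frequencies["chrom"],
            "start": frequencies["position"],
            "end": frequencies["position"],
            "called_sites": frequencies["n_total"],
            "called_sites_methylated": frequencies["n_meth"],
            "methylated_frequency": frequencies["frequency"].round(6),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_frequency_tsv(path: str | Path, sample_id: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "chrom": raw["chromosome"],
            "position": raw["start"],
            "sample_id": sample_id,
            "n_meth": raw["called_sites_methylated"],
            "n_total": raw["called_sites"],
            "frequency": raw["called_sites_methylated"] / raw["called_sites"],
        }
    )
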