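"""Concordance between sequencing-derived methylation and array beta values.

Matches per-site sequencing frequencies to array probes by genomic position
and computes Pearson correlation and RMSE over the matched pairs, pooling
both samples into one comparison (per-sample statistics are also provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "match_sites",
    "concordance",
    "melt_array_betas",
    "read_array_csv",
]


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    pearson_r: float  # NaN when undefined (zero variance on either axis)
    rmse: float


def melt_array_betas(betas: pd.DataFrame) -> pd.DataFrame:
    """Wide array table (one beta_<sample> column per sample) to long form."""
    beta_cols = [c for c in betas.columns if c.startswith("beta_")]
    long = betas.melt(
        id_vars=["probe_id", "chrom", "position"],
        value_vars=beta_cols,
        var_name="sample_id",
        value_name="beta",
    )
    long["sample_id"] = long["sample_id"].str.removeprefix("beta_")
    return long


def read_array_csv(path: str | Path) -> pd.DataFrame:
    """Read a wide array beta CSV (probe_id, chrom, position, beta per sample)."""
    return melt_array_betas(pd.read_csv(path))


def match_sites(
    ont_sites: pd.DataFrame, probes: pd.DataFrame, tolerance_bp: int = 0
) -> pd.DataFrame:
    """Pair sequencing sites with array probes within ``tolerance_bp``.

    ``ont_sites`` is an aggregated frequency table (chrom, position,
    sample_id, frequency); ``probes`` is a long beta table (probe_id, chrom,
    position, sample_id, beta). Each site takes at most one probe; ties are
    broken by smallest distance, then lowest probe id. Duplicate probe
    positions are an error.
    """
    probe_pos = probes[["probe_id", "chrom", "position"]].drop_duplicates()
    dup = probe_pos.duplicated(subset=["chrom", "position"], keep=False)
    if dup.any():
        dupes = probe_pos[dup].sort_values(["chrom", "position"])
        listing = ", ".join(
            f"{r.chrom}:{r.position}({r.probe_id})" for r in dupes.itertuples()
        )
        raise ValueError(f"duplicated probe positions: {listing}")

    pairs = []
    for chrom, site_group in ont_sites.groupby("chrom"):
        chrom_probes = probe_pos[probe_pos["chrom"] == chrom].sort_values(
            ["position", "probe_id"]
        )
        if chrom_probes.empty:
            continue
        ppos = chrom_probes["position"].to_numpy()
        pids = chrom_probes["probe_id"].to_numpy()
        for site in site_group.itertuples():
            idx = np.searchsorted(ppos, site.position)
            best: tuple[int, str] | None = None
            for j in (idx - 1, idx):
                if 0 <= j < len(ppos):
                    d = abs(int(ppos[j]) - int(site.position))
                    if d <= tolerance_bp and (
                        best is None
                        or d < best[0]
                        or (d == best[0] and pids[j] < best[1])
                    ):
                        best = (d, pids[j])
            if best is not None:
                pairs.append(
                    {
                        "chrom": chrom,
                        "position": site.position,
                        "sample_id": site.sample_id,
                        "ont_frequency": site.frequency,
                        "probe_id": best[1],
                        "distance_bp": best[0],
                    }
                )
    if not pairs:
        return pd.DataFrame(
            columns=[
                "chrom", "position", "sample_id", "ont_frequency",
                "probe_id", "distance_bp", "array_beta",
            ]
        )
    out = pd.DataFrame(pairs).merge(
        probes[["probe_id", "sample_id", "beta"]].rename(columns={"beta": "array_beta"}),
        on=["probe_id", "sample_id"],
        how="inner",
    )
    return out.sort_values(["chrom", "position", "sample_id"]).reset_index(drop=True)


def concordance(pairs: pd.DataFrame) -> ConcordanceResult:
    """Pearson r and RMSE between sequencing frequency and array beta.

    Pairs are pooled over samples. r is NaN (undefined) when either axis has
    zero variance; RMSE is always computed.
    """
    x = pairs["ont_frequency"].to_numpy(dtype=float)
    y = pairs["array_beta"].to_numpy(dtype=float)
    n = len(x)
    if n == 0:
        return ConcordanceResult(0, float("nan"), float("nan"))
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return ConcordanceResult(n, r, rmse)


def per_sample_concordance(pairs: pd.DataFrame) -> dict[str, ConcordanceResult]:
    return {
        sample: concordance(group) for sample, group in pairs.groupby("sample_id")
    }
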