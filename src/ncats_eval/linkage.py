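"""Read-phased co-methylation linkage: the adapted D' statistic.

Long reads phase methylation states of CpG pairs on the same molecule. For a
pair of sites (1, 2) with joint read proportions p_MM, p_MU, p_UM, p_UU and
marginals p1, p2, the concordance excess is

    D = p_MM + p_UU - (p1 * p2 + (1 - p1) * (1 - p2))

i.e. the observed fraction of reads with the same state at both sites minus
the fraction expected under independence. D is standardized to D' = |D| /
D_max. Two normalizers are provided:

* ``literal`` —  D_max = p_MM + p_UU if D < 0, else 1 - p_MM - p_UU (the
  published form). This normalizer can be exceeded: for p_MM = p_UU = 0.4,
  p1 = p2 = 0.5 it gives D = 0.3, D_max = 0.2, D' = 1.5, and it degenerates
  to 0/0 for perfectly concordant pairs.
* ``bounded`` — replaces the observed concordance with the expected
  concordance e = p1 * p2 + (1 - p1) * (1 - p2): D_max = e if D < 0, else
  1 - e. Since D = (p_MM + p_UU) - e and p_MM + p_UU is in [0, 1], this
  guarantees D' in [0, 1].

Both are shipped; every output records which mode produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .meth_calls import SiteCall, site_calls_frame

__all__ = [
    "LinkagePair",
    "compute_D",
    "compute_Dmax",
    "compute_Dprime",
    "pair_counts",
    "score_pairs",
    "linkage_table",
    "pairs_frame",
    "decay_analysis",
    "linkage_matrix",
    "DEFAULT_MIN_SHARED_READS",
]

DEFAULT_MIN_SHARED_READS = 10


@dataclass
class LinkagePair:
    """Joint methylation proportions and linkage statistics for one CpG pair."""

    chrom: str
    pos1: int
    pos2: int
    n_reads: int
    p_MM: float
    p_MU: float
    p_UM: float
    p_UU: float
    D: float = math.nan
    D_max: float = math.nan
    D_prime: float = math.nan  # NaN = undefined (flagged, never raised)
    mode: str = ""

    def __post_init__(self) -> None:
        if self.pos1 >= self.pos2:
            raise ValueError("pos1 must be < pos2")

    @property
    def distance(self) -> int:
        return self.pos2 - self.pos1

    @property
    def p1(self) -> float:
        return self.p_MM + self.p_MU

    @property
    def p2(self) -> float:
        return self.p_MM + self.p_UM


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


def compute_D(p_MM: float, p_UU: float, p1: float, p2: float) -> float:
    """Concordance excess: observed same-state fraction minus independence."""
    for name, v in (("p_MM", p_MM), ("p_UU", p_UU), ("p1", p1), ("p2", p2)):
        _check_unit(name, v)
    expected = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    return p_MM + p_UU - expected


def compute_Dmax(
    D: float, p_MM: float, p_UU: float, p1: float, p2: float, mode: str = "literal"
) -> float:
    """Normalizer for D' under the chosen mode.

    ``literal`` uses the observed concordance p_MM + p_UU as printed;
    ``bounded`` uses the expected concordance e = p1*p2 + (1-p1)*(1-p2),
    which guarantees D' <= 1. When D = 0 the normalizer is defined as 1 so
    that D' = 0.
    """
    if mode not in ("literal", "bounded"):
        raise ValueError(f"unknown mode {mode!r}")
    if D == 0:
        return 1.0
    if mode == "literal":
        concordance = p_MM + p_UU
    else:
        concordance = p1 * p2 + (1.0 - p1) * (1.0 - p2)
    return concordance if D < 0 else 1.0 - concordance


def compute_Dprime(D: float, D_max: float) -> float:
    """Standardized linkage |D| / D_max; NaN (flagged) when 0/0-degenerate."""
    if D_max == 0:
        return 0.0 if D == 0 else math.nan
    return abs(D) / D_max


def pair_counts(
    site_calls: Iterable[SiteCall] | pd.DataFrame,
    min_shared_reads: int = DEFAULT_MIN_SHARED_READS,
) -> list[LinkagePair]:
    """Joint methylation proportions for every CpG pair sharing enough reads.

    Reads are pooled across samples; a read is informative for a pair only if
    it carries a surviving (post-threshold) call at both sites. Pairs seen on
    fewer than ``min_shared_reads`` reads are excluded.

    Counting is done per chromosome with read-by-site indicator matrices:
    with coverage matrix A (reads x sites) and methylation matrix S,
    A'A gives shared-read counts and S'S the both-methylated counts, from
    which all four joint proportions follow.
    """
    if min_shared_reads < 1:
        raise ValueError("min_shared_reads must be >= 1")
    df = site_calls if isinstance(site_calls, pd.DataFrame) else site_calls_frame(site_calls)
    pairs: list[LinkagePair] = []
    if df.empty:
        return pairs
    for chrom, sub in df.groupby("chrom", sort=True):
        # drop sites that cannot reach the threshold to keep matrices small
        depth = sub.groupby("position")["read_id"].size()
        keep = depth[depth >= min_shared_reads].index
        sub = sub[sub["position"].isin(keep)]
        if sub.empty:
            continue
        positions = np.sort(sub["position"].unique())
        pos_index = {int(p): i for i, p in enumerate(positions)}
        read_ids, read_codes = np.unique(sub["read_id"], return_inverse=True)
        site_codes = sub["position"].map(pos_index).to_numpy()
        n_reads, n_sites = len(read_ids), len(positions)
        A = np.zeros((n_reads, n_sites), dtype=np.float32)
        S = np.zeros((n_reads, n_sites), dtype=np.float32)
        A[read_codes, site_codes] = 1.0
        S[read_codes, site_codes] = sub["state"].to_numpy(dtype=np.float32)
        shared = A.T @ A
        mm = S.T @ S
        m_any = S.T @ A  # reads methylated at row site and covered at col site
        upper = np.triu(shared >= min_shared_reads, k=1)
        for i, j in np.argwhere(upper):
            n = int(round(shared[i, j]))
            n_mm = int(round(mm[i, j]))
            n_mu = int(round(m_any[i, j])) - n_mm  # meth at i, unmeth at j
            n_um = int(round(m_any[j, i])) - n_mm
            n_uu = n - n_mm - n_mu - n_um
            pairs.append(
                LinkagePair(
                    chrom=chrom,
                    pos1=int(positions[i]),
                    pos2=int(positions[j]),
                    n_reads=n,
                    p_MM=n_mm / n,
                    p_MU=n_mu / n,
                    p_UM=n_um / n,
                    p_UU=n_uu / n,
                )
            )
    return pairs


def score_pairs(pairs: list[LinkagePair], mode: str = "literal") -> list[LinkagePair]:
    """Fill D, D_max and D' on counted pairs (in place) under one mode."""
    for pair in pairs:
        pair.D = compute_D(pair.p_MM, pair.p_UU, pair.p1, pair.p2)
        pair.D_max = compute_Dmax(pair.D, pair.p_MM, pair.p_UU, pair.p1, pair.p2, mode)
        pair.D_prime = compute_Dprime(pair.D, pair.D_max)
        pair.mode = mode
    return pairs


def linkage_table(
    site_calls: Iterable[SiteCall] | pd.DataFrame,
    min_shared_reads: int = DEFAULT_MIN_SHARED_READS,
    mode: str = "literal",
) -> pd.DataFrame:
    """Count, score and tabulate all pairs in one step."""
    return pairs_frame(score_pairs(pair_counts(site_calls, min_shared_reads), mode))


def pairs_frame(pairs: list[LinkagePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "pos1": p.pos1,
                "pos2": p.pos2,
                "distance": p.distance,
                "n_reads": p.n_reads,
                "p_MM": p.p_MM,
                "p_MU": p.p_MU,
                "p_UM": p.p_UM,
                "p_UU": p.p_UU,
                "D": p.D,
                "D_max": p.D_max,
                "D_prime": p.D_prime,
                "mode": p.mode,
            }
            for p in pairs
        ]
    )


def decay_analysis(pairs: list[LinkagePair], n_bins: int = 10) -> pd.DataFrame:
    """Distance-binned medians of D' to assess decay with inter-site distance.

    Returns one row per occupied distance bin with the bin midpoint, the
    median D' and the pair count. Pairs with undefined D' are dropped.
    """
    points = pairs_frame(pairs)
    if points.empty:
        return pd.DataFrame(columns=["bin_mid", "median_D_prime", "n_pairs"])
    points = points[np.isfinite(points["D_prime"])]
    if points.empty:
        return pd.DataFrame(columns=["bin_mid", "median_D_prime", "n_pairs"])
    if points["distance"].nunique() == 1:
        return pd.DataFrame(
            {
                "bin_mid": [float(points["distance"].iloc[0])],
                "median_D_prime": [float(points["D_prime"].median())],
                "n_pairs": [len(points)],
            }
        )
    bins = pd.cut(points["distance"], bins=n_bins)
    grouped = points.groupby(bins, observed=True)["D_prime"].agg(["median", "size"])
    return pd.DataFrame(
        {
            "bin_mid": [iv.mid for iv in grouped.index],
            "median_D_prime": grouped["median"].to_numpy(),
            "n_pairs": grouped["size"].to_numpy(),
        }
    )


def linkage_matrix(
    pairs: list[LinkagePair], site_order: list[int]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Symmetric D' matrix over ``site_order`` (diagonal 1, missing pairs NaN).

    Returns the matrix and a labeled DataFrame view for heatmap export.
    """
    index = {int(p): i for i, p in enumerate(site_order)}
    n = len(site_order)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for pair in pairs:
        if pair.pos1 not in index or pair.pos2 not in index:
            raise ValueError(
                f"pair {pair.pos1}-{pair.pos2} references a site missing from site_order"
            )
        i, j = index[pair.pos1], index[pair.pos2]
        mat[i, j] = mat[j, i] = pair.D_prime
    frame = pd.DataFrame(mat, index=site_order, columns=site_order)
    return mat, frame
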