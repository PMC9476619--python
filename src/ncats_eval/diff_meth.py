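"""Two-sample differential methylation by Fisher's exact test.

At each CpG with sufficient depth in both samples, the methylated /
unmethylated read counts form a 2x2 table tested with a two-sided Fisher
exact test; family-wise error is controlled with Bonferroni over the number
of sites actually tested. The effect size is the frequency difference
sample1 - sample2, so with the smoker as sample 1 a negative difference
means hypomethylation in the smoker.

Also provides the comparison against an external EWAS summary table (sign
agreement of effects, significance overlap, depth vs. EWAS p-value export)
and chromatin-state annotation of sites from a ChromHMM-style BED track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genome import GenomicInterval
from .meth_calls import SiteMethylation

__all__ = [
    "FisherResult",
    "fisher_p_value",
    "fisher_site",
    "run_differential",
    "results_frame",
    "compare_to_ewas",
    "annotate_states",
    "read_ewas_tsv",
]

# relative tie tolerance when summing tables as extreme as the observed one;
# same convention as the standard two-sided implementations
_TIE_EPS = 1e-7


@dataclass
class FisherResult:
    """Fisher exact test of one CpG's 2x2 methylated/unmethylated table.

    Counts: a/b = sample-1 methylated/unmethylated reads, c/d = sample-2.
    """

    chrom: str
    position: int
    a: int
    b: int
    c: int
    d: int
    p_value: float
    diff: float
    combined_depth: int
    significant: bool = False
    state: str | None = None


def fisher_p_value(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Computed by summing hypergeometric probabilities of all tables with the
    observed margins that are no more probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _TIE_EPS)].sum()))


def fisher_site(site1: SiteMethylation, site2: SiteMethylation) -> FisherResult:
    """Test one CpG's methylated-read proportions between two samples."""
    if (site1.chrom, site1.position) != (site2.chrom, site2.position):
        raise ValueError(
            f"site mismatch: {site1.chrom}:{site1.position} vs "
            f"{site2.chrom}:{site2.position}"
        )
    if site1.n_total == 0 or site2.n_total == 0:
        raise ValueError("both sites must have positive depth")
    a, b = site1.n_meth, site1.n_total - site1.n_meth
    c, d = site2.n_meth, site2.n_total - site2.n_meth
    return FisherResult(
        chrom=site1.chrom,
        position=site1.position,
        a=a,
        b=b,
        c=c,
        d=d,
        p_value=fisher_p_value(a, b, c, d),
        diff=site1.frequency - site2.frequency,
        combined_depth=site1.n_total + site2.n_total,
    )


def run_differential(
    sites1: pd.DataFrame,
    sites2: pd.DataFrame,
    min_depth_each: int = 10,
    alpha: float = 0.05,
    inclusive: bool = True,
) -> tuple[list[FisherResult], int]:
    """Fisher-test every site with sufficient depth in both samples.

    ``sites1``/``sites2`` are aggregated frequency tables (one sample each).
    The depth rule is ``n_total >= min_depth_each`` in both samples
    (``inclusive=False`` switches to strictly greater). Significance is
    Bonferroni-corrected: p <= alpha / n_tested.
    """
    merged = sites1.merge(
        sites2, on=["chrom", "position"], suffixes=("_1", "_2"), how="inner"
    )
    if inclusive:
        ok = (merged["n_total_1"] >= min_depth_each) & (merged["n_total_2"] >= min_depth_each)
    else:
        ok = (merged["n_total_1"] > min_depth_each) & (merged["n_total_2"] > min_depth_each)
    merged = merged[ok]
    n_tested = len(merged)
    if n_tested == 0:
        warnings.warn("no sites passed the depth rule in both samples; nothing tested")
        return [], 0
    results = []
    for row in merged.itertuples():
        s1 = SiteMethylation(row.chrom, row.position, "sample1", int(row.n_meth_1), int(row.n_total_1))
        s2 = SiteMethylation(row.chrom, row.position, "sample2", int(row.n_meth_2), int(row.n_total_2))
        results.append(fisher_site(s1, s2))
    threshold = alpha / n_tested
    for res in results:
        res.significant = res.p_value <= threshold
    results.sort(key=lambda r: (r.chrom, r.position))
    return results, n_tested


_RESULT_COLUMNS = [
    "chrom", "position", "meth_1", "unmeth_1", "meth_2", "unmeth_2",
    "p_value", "significant", "diff", "combined_depth", "state",
]


def results_frame(results: list[FisherResult]) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=_RESULT_COLUMNS)
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "position": r.position,
                "meth_1": r.a,
                "unmeth_1": r.b,
                "meth_2": r.c,
                "unmeth_2": r.d,
                "p_value": r.p_value,
                "significant": r.significant,
                "diff": r.diff,
                "combined_depth": r.combined_depth,
                "state": r.state,
            }
            for r in results
        ]
    )


def read_ewas_tsv(path: str | Path) -> pd.DataFrame:
    """Read an external EWAS summary (probe_id, chrom, position, effect, p_value)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"probe_id", "chrom", "position", "effect", "p_value"} - set(df.columns)
    if missing:
        raise ValueError(f"EWAS summary missing columns: {sorted(missing)}")
    return df


def compare_to_ewas(
    results: list[FisherResult], ewas: pd.DataFrame, ewas_alpha: float = 9e-8
) -> dict:
    """Compare the sequencing-based tests with an external array EWAS.

    Joins on (chrom, position) and reports the sign-agreement fraction of the
    effect estimates, the 2x2 significance overlap, and per-site
    (combined_depth, -log10 EWAS p) pairs for the depth-vs-power export.
    Effects with either side exactly zero are excluded from sign agreement.
    """
    res = results_frame(results)
    if res.empty or ewas.empty:
        return {"n": 0, "sign_agreement": None, "overlap": None, "depth_vs_logp": pd.DataFrame()}
    joined = res.merge(ewas, on=["chrom", "position"], how="inner")
    n = len(joined)
    if n == 0:
        return {"n": 0, "sign_agreement": None, "overlap": None, "depth_vs_logp": pd.DataFrame()}
    signs = np.sign(joined["diff"]) * np.sign(joined["effect"])
    informative = signs != 0
    agreement = float((signs[informative] > 0).mean()) if informative.any() else None
    ewas_sig = joined["p_value_y"] <= ewas_alpha
    overlap = pd.crosstab(
        joined["significant"].rename("ont_significant"),
        ewas_sig.rename("ewas_significant"),
        dropna=False,
    )
    depth_vs_logp = joined[["chrom", "position", "combined_depth"]].assign(
        neg_log10_ewas_p=-np.log10(joined["p_value_y"]),
        ont_significant=joined["significant"],
        ewas_significant=ewas_sig,
    )
    return {
        "n": n,
        "sign_agreement": agreement,
        "overlap": overlap,
        "depth_vs_logp": depth_vs_logp,
    }


def annotate_states(
    results: list[FisherResult], states: list[GenomicInterval]
) -> list[FisherResult]:
    """Label each site with the chromatin-state interval containing it.

    Sites outside every interval stay unlabeled. If intervals overlap, the
    first containing interval in sort order wins and a warning is emitted.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in states:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda r: (r.start, r.end))
        if any(a.end > b.start for a, b in zip(ivs, ivs[1:])):
            warnings.warn(f"overlapping state intervals on {chrom}; first match wins")
    for res in results:
        res.state = None
        for iv in by_chrom.get(res.chrom, ()):
            if iv.contains(res.position):
                res.state = iv.name
                break
    return results
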