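"""Proteome-level aggregation and two-proteome statistical comparisons.

The headline metrics mirror a comparative disorder survey: per-proteome mean
disorder content, fraction of proteins carrying at least one LDR/DBR, mean
region counts and lengths, and content bins.  Two-proteome comparisons use
the Pearson chi-square on 2x2 count tables (pooled residues, or proteins
with/without an LDR) and the two-sided Wilcoxon rank-sum test for per-protein
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .enrichment import chi_square_2x2
from .segmentation import ProteinDisorderSummary

#: R prints p-values below this as "< 2.2e-16"; we follow for display only.
P_DISPLAY_FLOOR = 2.2e-16

#: exact Wilcoxon enumeration is used up to this pooled sample size
_EXACT_MAX_TOTAL = 18


@dataclass
class ProteomeSummary:
    """Table-style aggregate of per-protein disorder metrics for one group."""

    genus: str
    n_proteins: int
    mean_pct_disordered: float
    pct_proteins_with_ldr: float
    mean_pct_in_ldr: float
    mean_n_ldr: float
    mean_ldr_length: float
    mean_ldr_length_defined: bool
    pct_proteins_with_dbr: float
    mean_n_dbr: float
    mean_pct_in_dbr: float
    pct_half_disordered: float   # proteins with >= 50% disordered residues
    pct_extreme: float           # >= 70%
    pct_low: float               # <= 30%


@dataclass
class ComparisonResult:
    metric: str
    test: str  # "chi_square" | "wilcoxon_rank_sum"
    statistic: float
    p_value: float
    direction: str  # label of the group with the higher value


def format_pvalue(p: float, floor: float = P_DISPLAY_FLOOR) -> str:
    """R-style display convention: values below the floor print as '< floor'."""
    return f"< {floor:g}" if p < floor else f"{p:.6g}"


def summarize_proteome(
    summaries: Sequence[ProteinDisorderSummary],
    genus: str,
    pooled: bool = False,
) -> ProteomeSummary:
    """Aggregate per-protein summaries for one group.

    ``mean_pct_disordered`` is the unweighted mean of per-protein percentages
    by default; ``pooled=True`` reports the residue-pooled fraction instead
    (total disordered residues / total residues).  ``mean_ldr_length``
    averages over all LDRs in the proteome; when no protein has an LDR it is
    reported as 0 with ``mean_ldr_length_defined=False``.
    """
    if not summaries:
        raise ValueError("empty proteome: no protein summaries")
    n = len(summaries)
    if pooled:
        mean_pct = 100.0 * sum(s.n_disordered for s in summaries) / sum(s.length for s in summaries)
    else:
        mean_pct = float(np.mean([s.pct_disordered for s in summaries]))
    ldr_lengths = [r.length for s in summaries for r in s.ldrs]
    return ProteomeSummary(
        genus=genus,
        n_proteins=n,
        mean_pct_disordered=mean_pct,
        pct_proteins_with_ldr=100.0 * sum(s.has_ldr for s in summaries) / n,
        mean_pct_in_ldr=float(np.mean([s.pct_in_ldr for s in summaries])),
        mean_n_ldr=float(np.mean([s.n_ldr for s in summaries])),
        mean_ldr_length=float(np.mean(ldr_lengths)) if ldr_lengths else 0.0,
        mean_ldr_length_defined=bool(ldr_lengths),
        pct_proteins_with_dbr=100.0 * sum(s.has_dbr for s in summaries) / n,
        mean_n_dbr=float(np.mean([s.n_dbr for s in summaries])),
        mean_pct_in_dbr=float(np.mean([s.pct_in_dbr for s in summaries])),
        pct_half_disordered=100.0 * sum(s.pct_disordered >= 50.0 for s in summaries) / n,
        pct_extreme=100.0 * sum(s.pct_disordered >= 70.0 for s in summaries) / n,
        pct_low=100.0 * sum(s.pct_disordered <= 30.0 for s in summaries) / n,
    )


def bin_by_content(
    summaries: Sequence[ProteinDisorderSummary],
    edges: Sequence[float] | None = None,
    field: str = "pct_disordered",
) -> pd.DataFrame:
    """Histogram of protein counts by disorder (or DBR) content.

    Bins are left-closed/right-open except the last, which is closed so that
    100% falls in it.  *edges* must be strictly increasing and span [0, 100];
    default deciles.  Returns a DataFrame with columns ``low``, ``high``,
    ``count``.
    """
    if field not in ("pct_disordered", "pct_in_dbr"):
        raise ValueError(f"unsupported binning field {field!r}")
    edges = np.asarray(edges if edges is not None else np.linspace(0, 100, 11), dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    if edges[0] != 0.0 or edges[-1] != 100.0:
        raise ValueError("edges must span [0, 100]")
    values = np.array([getattr(s, field) for s in summaries], dtype=float)
    # np.histogram has exactly this closed-last-bin convention
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({"low": edges[:-1], "high": edges[1:], "count": counts})


def _chi2_comparison(
    metric: str, x1: int, n1: int, x2: int, n2: int, labels: tuple[str, str], yates: bool
) -> ComparisonResult:
    table = np.array([[x1, x2], [n1 - x1, n2 - x2]], dtype=np.int64)
    stat, p, _ = chi_square_2x2(table, yates=yates)
    direction = labels[0] if x1 / n1 >= x2 / n2 else labels[1]
    return ComparisonResult(metric, "chi_square", stat, p, direction)


def compare_residue_disorder(
    summariesA: Sequence[ProteinDisorderSummary],
    summariesB: Sequence[ProteinDisorderSummary],
    labels: tuple[str, str] = ("A", "B"),
    yates: bool = False,
) -> ComparisonResult:
    """Pearson chi-square on pooled {disordered, ordered} x {group} residue counts."""
    x1 = sum(s.n_disordered for s in summariesA)
    n1 = sum(s.length for s in summariesA)
    x2 = sum(s.n_disordered for s in summariesB)
    n2 = sum(s.length for s in summariesB)
    return _chi2_comparison("residue_disorder", x1, n1, x2, n2, labels, yates)


def compare_ldr_proteins(
    summariesA: Sequence[ProteinDisorderSummary],
    summariesB: Sequence[ProteinDisorderSummary],
    labels: tuple[str, str] = ("A", "B"),
    yates: bool = False,
) -> ComparisonResult:
    """Pearson chi-square on {has LDR, no LDR} x {group} protein counts."""
    x1 = sum(s.has_ldr for s in summariesA)
    x2 = sum(s.has_ldr for s in summariesB)
    return _chi2_comparison(
        "proteins_with_ldr", x1, len(summariesA), x2, len(summariesB), labels, yates
    )


def _rank_sum_u(ranks: np.ndarray, idx: tuple[int, ...], n: int) -> float:
    return float(ranks[list(idx)].sum()) - n * (n + 1) / 2.0


def wilcoxon_rank_sum(
    valuesA: Sequence[float],
    valuesB: Sequence[float],
    metric: str = "",
    labels: tuple[str, str] = ("A", "B"),
    method: str = "auto",
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``method='exact'`` enumerates the full permutation distribution of U over
    all C(n+m, n) group assignments (ties handled through midranks); the
    two-sided p-value is P(|U' - nm/2| >= |U - nm/2|).  ``'asymptotic'`` uses
    the tie-corrected normal approximation without continuity correction, so
    identical samples give p = 1.  ``'auto'`` picks exact when n+m <= 18.
    """
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    if method == "auto":
        method = "exact" if n + m <= _EXACT_MAX_TOTAL else "asymptotic"

    if method == "exact":
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        u_obs = _rank_sum_u(ranks, tuple(range(n)), n)
        center = n * m / 2.0
        dev_obs = abs(u_obs - center)
        total = comb(n + m, n)
        hits = sum(
            abs(_rank_sum_u(ranks, idx, n) - center) >= dev_obs - 1e-9
            for idx in combinations(range(n + m), n)
        )
        u, p = u_obs, hits / total
    elif method == "asymptotic":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        u, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")

    direction = labels[0] if np.mean(a) >= np.mean(b) else labels[1]
    return ComparisonResult(metric or "rank_sum", "wilcoxon_rank_sum", u, min(p, 1.0), direction)


def write_proteome_summary_tsv(
    summaries: Sequence[ProteomeSummary], path: str | Path, header: str = ""
) -> None:
    frame = pd.DataFrame([vars(s) for s in summaries])
    with open(path, "w") as out:
        if header:
            out.write(header)
        frame.to_csv(out, sep="\t", index=False, float_format="%.4f")


def write_comparisons_tsv(
    results: Sequence[ComparisonResult], path: str | Path, header: str = ""
) -> None:
    with open(path, "w") as out:
        if header:
            out.write(header)
        out.write("metric\ttest\tstatistic\tp_value\tp_display\tdirection\n")
        for r in results:
            out.write(
                f"{r.metric}\t{r.test}\t{r.statistic:.6g}\t{r.p_value:.6g}"
                f"\t{format_pvalue(r.p_value)}\t{r.direction}\n"
            )
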