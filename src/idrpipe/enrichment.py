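"""Per-GO-term contingency-table enrichment of disordered proteins.

A protein counts as *disordered* when it carries at least one LDR.  Two
analyses are provided:

* within one group: per term, a 2x2 table of disorder status x annotation
  status over the whole proteome (chi-square, with an automatic Fisher exact
  fallback when any expected count is below 5);
* between two groups: per term common to both, a 2x2 table of disorder
  status x group, restricted to the proteins annotated with that term.
  Pearson chi-square; a term's *excess* is the observed minus expected
  disordered count in the focal (first) group, and only terms with positive
  excess count as enriched in the focal group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Set

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GOAnnotation
from .segmentation import ProteinDisorderSummary

logger = logging.getLogger(__name__)


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero marginal; the chi-square test is undefined."""


@dataclass
class ContingencyTable:
    """2x2 counts: rows disordered/not-disordered, columns the two groups."""

    go_id: str
    a: int  # disordered, group 1
    b: int  # disordered, group 2
    c: int  # not disordered, group 1
    d: int  # not disordered, group 2
    row_labels: tuple[str, str] = ("disordered", "not_disordered")
    col_labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        for count in (self.a, self.b, self.c, self.d):
            if count < 0 or int(count) != count:
                raise ValueError(f"counts must be non-negative integers, got {count}")

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class EnrichmentResult:
    go_id: str
    table: ContingencyTable
    chi2: float
    p_value: float
    excess: float                 # observed - expected disordered, focal group
    direction_positive: bool      # excess > 0
    mean_disordered_per_group: tuple[float, float]
    df: int = 1
    test: str = "chi_square"      # "fisher_exact" when the fallback fired
    adjusted_p: float | None = None


def chi_square_2x2(
    table: ContingencyTable | np.ndarray, yates: bool = False
) -> tuple[float, float, np.ndarray]:
    """Pearson chi-square for a 2x2 table, df = 1.

    The statistic is the textbook closed form: expected counts are products
    of marginals over the grand total and the statistic sums
    (observed - expected)^2 / expected over the four cells.  With
    ``yates=True`` the absolute deviations are shrunk by 0.5 (capped at the
    deviation itself).  Returns ``(statistic, p_value, expected)``.

    Raises :class:`DegenerateTableError` when any marginal is zero.
    """
    obs = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a non-negative 2x2 table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("degenerate table: a marginal is zero")
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p, expected


def flag_disordered_proteins(summaries: Iterable[ProteinDisorderSummary]) -> set[str]:
    """Ids of proteins with at least one LDR (the disordered-protein rule)."""
    return {s.protein_id for s in summaries if s.has_ldr}


def _terms_by_ontology(annotations: Iterable[GOAnnotation], ontology: str | None) -> set[str]:
    return {a.go_id for a in annotations if ontology is None or a.ontology == ontology}


def common_terms(
    annotationsA: Iterable[GOAnnotation],
    annotationsB: Iterable[GOAnnotation],
    ontology: str | None = "BP",
) -> set[str]:
    """GO terms annotated (post-PPV-filter) in both groups, one ontology."""
    return _terms_by_ontology(annotationsA, ontology) & _terms_by_ontology(annotationsB, ontology)


def _proteins_by_term(annotations: Iterable[GOAnnotation]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for ann in annotations:
        out.setdefault(ann.go_id, set()).add(ann.protein_id)
    return out


def build_between_table(
    go_id: str,
    annotationsA: Iterable[GOAnnotation] | dict[str, Set[str]],
    annotationsB: Iterable[GOAnnotation] | dict[str, Set[str]],
    disorderedA: Set[str],
    disorderedB: Set[str],
    labels: tuple[str, str] = ("group1", "group2"),
) -> ContingencyTable:
    """2x2 table of disorder status x group for one term.

    The population is the proteins annotated with *go_id* in each group (not
    the whole proteome).  Annotations may be pre-indexed as a
    ``{go_id: set of protein ids}`` mapping to avoid re-indexing in batch use.
    """
    byA = annotationsA if isinstance(annotationsA, dict) else _proteins_by_term(annotationsA)
    byB = annotationsB if isinstance(annotationsB, dict) else _proteins_by_term(annotationsB)
    if go_id not in byA or go_id not in byB:
        raise KeyError(f"{go_id} is not annotated in both groups")
    annA, annB = byA[go_id], byB[go_id]
    a = len(annA & disorderedA)
    b = len(annB & disorderedB)
    return ContingencyTable(
        go_id, a=a, b=b, c=len(annA) - a, d=len(annB) - b, col_labels=labels
    )


def _result_from_table(
    table: ContingencyTable, yates: bool
) -> EnrichmentResult | None:
    """Chi-square a between-groups table; None when the test is undefined."""
    if table.a + table.b == 0:
        logger.info("skipping %s: no disordered proteins in either group", table.go_id)
        return None
    try:
        stat, p, expected = chi_square_2x2(table, yates=yates)
    except DegenerateTableError:
        logger.info("skipping %s: degenerate table %s", table.go_id, table.as_array().tolist())
        return None
    excess = float(table.a - expected[0, 0])
    return EnrichmentResult(
        go_id=table.go_id,
        table=table,
        chi2=stat,
        p_value=p,
        excess=excess,
        direction_positive=excess > 0,
        mean_disordered_per_group=(float(table.a), float(table.b)),
    )


def enrich_between(
    annotationsA: Iterable[GOAnnotation],
    annotationsB: Iterable[GOAnnotation],
    disorderedA: Set[str],
    disorderedB: Set[str],
    ontology: str | None = "BP",
    yates: bool = False,
    adjust: str = "none",
    labels: tuple[str, str] = ("group1", "group2"),
) -> list[EnrichmentResult]:
    """Between-groups enrichment over all common terms, sorted by p-value.

    One result per common term (smaller p = stronger departure from equal
    disorder fractions).  Callers wanting the focal group's enriched list
    filter on ``direction_positive``; terms whose table is degenerate or has
    no disordered protein in either group are skipped with a logged notice.
    """
    annotationsA, annotationsB = list(annotationsA), list(annotationsB)
    terms = common_terms(annotationsA, annotationsB, ontology)
    if not terms:
        raise ValueError("no common terms between the two groups")
    byA = _proteins_by_term(a for a in annotationsA if ontology is None or a.ontology == ontology)
    byB = _proteins_by_term(a for a in annotationsB if ontology is None or a.ontology == ontology)
    results = []
    for go_id in sorted(terms):
        table = build_between_table(go_id, byA, byB, disorderedA, disorderedB, labels)
        res = _result_from_table(table, yates)
        if res is not None:
            results.append(res)
    results.sort(key=lambda r: (r.p_value, r.go_id))
    if adjust != "none":
        results = adjust_pvalues(results, adjust)
    return results


def enrich_within(
    annotations: Iterable[GOAnnotation],
    disordered_set: Set[str],
    all_protein_ids: Set[str],
    ontology: str | None = "BP",
    yates: bool = False,
    adjust: str = "none",
    min_expected_for_chi2: float = 5.0,
) -> list[EnrichmentResult]:
    """Within-group enrichment of disordered proteins per GO term.

    Per term: 2x2 table with rows disordered / not-disordered and columns
    annotated / not-annotated, over the whole proteome as background.
    Pearson chi-square by default; when any expected cell falls below
    *min_expected_for_chi2* the two-sided Fisher exact test is substituted
    (the approximation breaks down on small classes).  ``excess`` is the
    observed minus expected count of disordered annotated proteins.
    """
    annotations = [a for a in annotations if ontology is None or a.ontology == ontology]
    by_term = _proteins_by_term(annotations)
    if not by_term:
        raise ValueError("no annotations in the requested ontology")
    n_total = len(all_protein_ids)
    n_dis = len(disordered_set & all_protein_ids)
    results = []
    for go_id in sorted(by_term):
        annotated = by_term[go_id] & all_protein_ids
        if not annotated:
            raise ValueError(f"term {go_id} annotates no known protein")
        a = len(annotated & disordered_set)           # disordered, annotated
        b = n_dis - a                                 # disordered, not annotated
        c = len(annotated) - a                        # ordered, annotated
        d = (n_total - n_dis) - c
        table = ContingencyTable(go_id, a, b, c, d,
                                 col_labels=("annotated", "not_annotated"))
        try:
            stat, p, expected = chi_square_2x2(table, yates=yates)
            test = "chi_square"
            if np.any(expected < min_expected_for_chi2):
                _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
                p, test = float(p), "fisher_exact"
        except DegenerateTableError:
            logger.info("skipping %s: degenerate within-group table", go_id)
            continue
        excess = float(a - expected[0, 0])
        results.append(EnrichmentResult(
            go_id=go_id, table=table, chi2=stat, p_value=p, excess=excess,
            direction_positive=excess > 0,
            mean_disordered_per_group=(float(a), float(b)),
            test=test,
        ))
    results.sort(key=lambda r: (r.p_value, r.go_id))
    if adjust != "none":
        results = adjust_pvalues(results, adjust)
    return results


def adjust_pvalues(
    results: Sequence[EnrichmentResult], method: str = "benjamini_hochberg"
) -> list[EnrichmentResult]:
    """Attach multiple-testing adjusted p-values (Benjamini-Hochberg step-up)."""
    results = list(results)
    if method == "none":
        for r in results:
            r.adjusted_p = None
        return results
    if method != "benjamini_hochberg":
        raise ValueError(f"unknown adjustment method {method!r}")
    if results:
        _, adjusted, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, ap in zip(results, adjusted):
            r.adjusted_p = float(ap)
    return results


def mean_disordered_per_class(results: Sequence[EnrichmentResult]) -> "pd.DataFrame":
    """Per term, the disordered-protein count in each group, raw and per annotated protein."""
    import pandas as pd

    rows = []
    for r in results:
        nA, nB = r.table.col_totals
        rows.append({
            "go_id": r.go_id,
            "disordered_group1": r.table.a,
            "disordered_group2": r.table.b,
            "annotated_group1": nA,
            "annotated_group2": nB,
            "disordered_frac_group1": r.table.a / nA if nA else float("nan"),
            "disordered_frac_group2": r.table.b / nB if nB else float("nan"),
        })
    return pd.DataFrame(rows)


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], path: str | Path, header: str = ""
) -> None:
    with open(path, "w") as out:
        if header:
            out.write(header)
        out.write(
            "go_id\ta\tb\tc\td\ttest\tchi2\tp_value\tadjusted_p\texcess\tdirection"
            "\tdisordered_count_group1\tdisordered_count_group2\n"
        )
        for r in results:
            adj = f"{r.adjusted_p:.6g}" if r.adjusted_p is not None else "NA"
            direction = "positive" if r.direction_positive else "non_positive"
            out.write(
                f"{r.go_id}\t{r.table.a}\t{r.table.b}\t{r.table.c}\t{r.table.d}"
                f"\t{r.test}\t{r.chi2:.6g}\t{r.p_value:.6g}\t{adj}\t{r.excess:.4f}"
                f"\t{direction}\t{r.table.a}\t{r.table.b}\n"
            )
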