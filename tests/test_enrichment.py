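"""Per-GO-term contingency tables, chi-square, and the two enrichment analyses."""

import numpy as np
import pytest
from scipy import stats as sps

from idrpipe.enrichment import (
    ContingencyTable,
    DegenerateTableError,
    adjust_pvalues,
    build_between_table,
    chi_square_2x2,
    common_terms,
    enrich_between,
    enrich_within,
    flag_disordered_proteins,
    mean_disordered_per_class,
)
from idrpipe.io import GOAnnotation
from tests.test_proteome_stats import make_summary


# --- disordered-protein flag -------------------------------------------------

def test_flag_disordered_requires_at_least_one_ldr():
    summaries = [
        make_summary("a", 100, 0),
        make_summary("b", 100, 40, ldr_lengths=(40,)),
        make_summary("c", 300, 150, ldr_lengths=(40, 50, 60)),
    ]
    assert flag_disordered_proteins(summaries) == {"b", "c"}


def test_flag_disordered_empty_proteome():
    assert flag_disordered_proteins([]) == set()


# --- common terms ---------------------------------------------------------------

def _ann(pid, go, onto="BP"):
    return GOAnnotation(pid, go, onto, 0.9)


def test_common_terms_intersection():
    a = [_ann("p1", "GO:0000001"), _ann("p2", "GO:0000002")]
    b = [_ann("q1", "GO:0000002"), _ann("q2", "GO:0000003")]
    assert common_terms(a, b) == {"GO:0000002"}


def test_common_terms_disjoint_and_ontology_restriction():
    a = [_ann("p1", "GO:0000001"), _ann("p1", "GO:0000009", "MF")]
    b = [_ann("q1", "GO:0000002"), _ann("q1", "GO:0000009", "MF")]
    assert common_terms(a, b, "BP") == set()
    assert common_terms(a, b, "MF") == {"GO:0000009"}
    assert common_terms(a, b, None) == {"GO:0000009"}


# --- between-groups table -------------------------------------------------------

def test_worked_example_table_cells_and_marginals(worked_example):
    we = worked_example
    table = build_between_table(
        we.go_id, we.annotationsA, we.annotationsB,
        we.disorderedA, we.disorderedB, we.labels,
    )
    assert (table.a, table.b, table.c, table.d) == (111, 2, 211, 209)
    assert table.row_totals == (113, 420)
    assert table.col_totals == (322, 211)
    assert table.total == 533


def test_between_table_single_protein_per_group():
    a = [_ann("p1", "GO:0000005")]
    b = [_ann("q1", "GO:0000005")]
    table = build_between_table("GO:0000005", a, b, {"p1"}, {"q1"})
    assert table.as_array().tolist() == [[1, 1], [0, 0]]


def test_between_table_missing_term_errors():
    a = [_ann("p1", "GO:0000001")]
    b = [_ann("q1", "GO:0000002")]
    with pytest.raises(KeyError):
        build_between_table("GO:0000001", a, b, set(), set())


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable("GO:0000001", -1, 0, 0, 0)


# --- chi-square --------------------------------------------------------------

def test_no_association_gives_zero_statistic():
    stat, p, expected = chi_square_2x2(np.array([[10, 10], [10, 10]]))
    assert stat == pytest.approx(0.0, abs=1e-14)
    assert p == pytest.approx(1.0)
    np.testing.assert_allclose(expected, [[10, 10], [10, 10]])


def test_worked_example_statistic_matches_closed_form(worked_example):
    we = worked_example
    table = build_between_table(
        we.go_id, we.annotationsA, we.annotationsB, we.disorderedA, we.disorderedB
    )
    stat, p, _ = chi_square_2x2(table)
    # hand-derived Pearson closed form from the printed cells
    obs = np.array([[111.0, 2.0], [211.0, 209.0]])
    expected = np.outer([113, 420], [322, 211]) / 533.0
    by_hand = ((obs - expected) ** 2 / expected).sum()
    assert stat == pytest.approx(by_hand, abs=1e-10)
    assert p < 2.2e-16


def test_random_tables_match_scipy_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        table = rng.integers(1, 200, size=(2, 2))
        stat, p, expected = chi_square_2x2(table)
        ref_stat, ref_p, _, ref_exp = sps.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(ref_stat, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)
        np.testing.assert_allclose(expected, ref_exp, atol=1e-10)


def test_yates_correction_matches_scipy():
    rng = np.random.default_rng(12)
    for _ in range(50):
        table = rng.integers(1, 60, size=(2, 2))
        stat, p, _ = chi_square_2x2(table, yates=True)
        ref_stat, ref_p, _, _ = sps.chi2_contingency(table, correction=True)
        assert stat == pytest.approx(ref_stat, abs=1e-10)
        assert p == pytest.approx(ref_p, abs=1e-10)


def test_zero_marginal_is_degenerate():
    with pytest.raises(DegenerateTableError, match="degenerate"):
        chi_square_2x2(np.array([[0, 0], [5, 7]]))


def test_column_swap_keeps_statistic_flips_direction():
    a = [_ann(f"p{i}", "GO:0000001") for i in range(40)]
    b = [_ann(f"q{i}", "GO:0000001") for i in range(40)]
    dis_a = {f"p{i}" for i in range(30)}
    dis_b = {f"q{i}" for i in range(10)}
    fwd = enrich_between(a, b, dis_a, dis_b)[0]
    rev = enrich_between(b, a, dis_b, dis_a)[0]
    assert fwd.chi2 == pytest.approx(rev.chi2, abs=1e-12)
    assert fwd.direction_positive and not rev.direction_positive
    assert fwd.excess == pytest.approx(-rev.excess, abs=1e-12)


# --- enrichment analyses -----------------------------------------------------

def test_enrich_between_skips_degenerate_and_all_ordered_terms():
    # GO:0000001 has mixed disorder statuses -> testable table;
    # GO:0000002 has no disordered protein in either group -> skipped.
    anns_a = [_ann("p1", "GO:0000001"), _ann("p2", "GO:0000001"), _ann("p3", "GO:0000002")]
    anns_b = [_ann("q1", "GO:0000001"), _ann("q2", "GO:0000001"), _ann("q3", "GO:0000002")]
    results = enrich_between(anns_a, anns_b, {"p1"}, {"q1"})
    assert [r.go_id for r in results] == ["GO:0000001"]


def test_enrich_between_no_common_terms_errors():
    with pytest.raises(ValueError, match="common"):
        enrich_between([_ann("p", "GO:0000001")], [_ann("q", "GO:0000002")], set(), set())


def test_enrich_between_sorted_by_p():
    rng = np.random.default_rng(13)
    anns_a, anns_b = [], []
    dis_a, dis_b = set(), set()
    for t in range(1, 6):
        go = f"GO:{t:07d}"
        for i in range(30):
            pid, qid = f"p{t}_{i}", f"q{t}_{i}"
            anns_a.append(_ann(pid, go))
            anns_b.append(_ann(qid, go))
            if rng.random() < 0.3 + 0.1 * t:
                dis_a.add(pid)
            if rng.random() < 0.3:
                dis_b.add(qid)
    results = enrich_between(anns_a, anns_b, dis_a, dis_b)
    ps = [r.p_value for r in results]
    assert ps == sorted(ps)


def test_enrich_within_all_annotated_disordered_is_positive():
    # term annotated to 10 proteins, all disordered; background 50% disordered
    all_ids = {f"p{i}" for i in range(100)}
    disordered = {f"p{i}" for i in range(50)}
    anns = [_ann(f"p{i}", "GO:0000007") for i in range(10)]
    (res,) = enrich_within(anns, disordered, all_ids)
    assert res.direction_positive
    assert res.p_value < 0.05
    # independent check: one-sided hypergeometric tail doubled bounds the
    # two-sided Fisher p from above
    hyper = sps.hypergeom(100, 50, 10).sf(9)  # P(all 10 drawn disordered)
    assert res.p_value <= 2 * hyper + 1e-12


def test_enrich_within_uses_fisher_on_small_expected():
    all_ids = {f"p{i}" for i in range(100)}
    disordered = {f"p{i}" for i in range(50)}
    anns = [_ann(f"p{i}", "GO:0000007") for i in range(6)]
    (res,) = enrich_within(anns, disordered, all_ids)
    assert res.test == "fisher_exact"
    ref = sps.fisher_exact(res.table.as_array(), alternative="two-sided")[1]
    assert res.p_value == pytest.approx(ref, abs=1e-12)


def test_enrich_within_large_classes_use_chi_square():
    all_ids = {f"p{i}" for i in range(400)}
    disordered = {f"p{i}" for i in range(200)}
    anns = [_ann(f"p{i}", "GO:0000008") for i in range(120, 220)]
    (res,) = enrich_within(anns, disordered, all_ids)
    assert res.test == "chi_square"


def test_enrich_within_empty_ontology_errors():
    with pytest.raises(ValueError, match="ontology"):
        enrich_within([_ann("p", "GO:0000001", "MF")], set(), {"p"}, ontology="BP")


# --- p-value adjustment --------------------------------------------------------

def _fake_results(ps):
    from idrpipe.enrichment import EnrichmentResult

    return [
        EnrichmentResult(
            go_id=f"GO:{i + 1:07d}",
            table=ContingencyTable(f"GO:{i + 1:07d}", 5, 5, 5, 5),
            chi2=0.0, p_value=p, excess=0.0, direction_positive=False,
            mean_disordered_per_group=(5.0, 5.0),
        )
        for i, p in enumerate(ps)
    ]


def test_bh_adjustment_is_monotone_and_bounded():
    ps = [0.001, 0.02, 0.02, 0.5, 0.9]
    results = adjust_pvalues(_fake_results(ps))
    adjusted = [r.adjusted_p for r in results]
    assert all(a >= p for a, p in zip(adjusted, ps))
    assert all(0 <= a <= 1 for a in adjusted)
    order = np.argsort(ps)
    ranked = [adjusted[i] for i in order]
    assert ranked == sorted(ranked)


def test_bh_matches_hand_stepup():
    ps = [0.01, 0.04, 0.03, 0.005]
    results = adjust_pvalues(_fake_results(ps))
    m = len(ps)
    order = np.argsort(ps)
    stepped = np.minimum.accumulate(
        [min(1.0, ps[i] * m / (rank + 1)) for rank, i in enumerate(order)][::-1]
    )[::-1]
    expected = np.empty(m)
    expected[order] = stepped
    np.testing.assert_allclose([r.adjusted_p for r in results], expected, atol=1e-12)


def test_adjust_none_clears_field():
    results = adjust_pvalues(_fake_results([0.2, 0.4]), method="none")
    assert all(r.adjusted_p is None for r in results)


def test_unknown_adjustment_errors():
    with pytest.raises(ValueError, match="method"):
        adjust_pvalues(_fake_results([0.5]), method="bonferroni_typo")


# --- per-class means -------------------------------------------------------------

def test_mean_disordered_per_class_counts(worked_example):
    we = worked_example
    results = enrich_between(
        we.annotationsA, we.annotationsB, we.disorderedA, we.disorderedB,
        labels=we.labels,
    )
    frame = mean_disordered_per_class(results)
    row = frame.iloc[0]
    assert row["go_id"] == we.go_id
    assert (row["disordered_group1"], row["disordered_group2"]) == (111, 2)
    assert row["disordered_frac_group1"] == pytest.approx(111 / 322)
    assert row["disordered_frac_group2"] == pytest.approx(2 / 211)
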