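from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lincscout import characterize
from lincscout.io_formats import reverse_complement
from lincscout.types import GeneAnnotation, TranscriptModel

from ._oracles import hypergeom_upper_tail_exact, nearest_gene_all_pairs


def _linc(tid, span, scaffold="s1", length=None):
    s, e = span
    seq = "A" * (e - s)
    return TranscriptModel(tid, scaffold, [span], spliced_sequence=seq, strand="+")


def _gene(gid, span, scaffold="s1"):
    return GeneAnnotation(gid, scaffold, "+", span, [span])


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def test_gc_trivial_values():
    series, mean = characterize.gc_content({"a": "ATGC", "b": "GGCC"})
    assert series["a"] == 0.5 and series["b"] == 1.0 and mean == 0.75


def test_gc_excludes_ambiguous_bases_and_flags_all_n():
    series, mean = characterize.gc_content({"a": "GGNNAA", "b": "NNNN"})
    assert series["a"] == 0.5
    assert np.isnan(series["b"])
    assert mean == 0.5


@given(st.text(alphabet="ACGTN", min_size=4, max_size=100).filter(lambda s: set(s) != {"N"}))
def test_gc_is_complement_invariant(seq):
    s1, _ = characterize.gc_content({"x": seq})
    s2, _ = characterize.gc_content({"x": reverse_complement(seq)})
    assert s1["x"] == pytest.approx(s2["x"])


# ---------------------------------------------------------------------------
# Scaffold summaries and survey worked example
# ---------------------------------------------------------------------------

def test_scaffold_summary_exact_statistics():
    catalog = [
        _linc("l1", (0, 100)), _linc("l2", (500, 700)), _linc("l3", (2000, 2300)),
    ]
    genes = [_gene("g1", (5000, 6000)), _gene("g2", (8000, 9000))]
    (row,) = characterize.scaffold_summary(catalog, genes)
    assert row.n_known_genes == 2 and row.n_lincrna == 3
    assert row.lincrna_length_range == (100, 300)
    assert row.lincrna_mean_length == 200.0


def test_scaffold_summary_counts_sum_to_catalog_size(small_identification, small_sim):
    summaries = characterize.scaffold_summary(
        small_identification.catalog, small_sim["genes"]
    )
    assert sum(s.n_lincrna for s in summaries) == len(small_identification.catalog)


def test_published_survey_reproduces_printed_tallies():
    summaries = characterize.load_scaffold_survey()
    assert characterize.count_lincrna_rich_scaffolds(summaries, min_lincrna=20) == 18
    top = max(summaries, key=lambda s: s.n_lincrna)
    assert top.n_lincrna == 40 and top.scaffold_id == "Scaffold_51"


# ---------------------------------------------------------------------------
# Scaffold count correlation
# ---------------------------------------------------------------------------

def test_perfect_linear_relation():
    summaries = [
        characterize.ScaffoldSummary(f"s{i}", i, 2 * i, (100, 200), 150.0)
        for i in range(1, 6)
    ]
    slope, intercept, r2, p = characterize.correlate_scaffold_counts(summaries)
    assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)


def test_constant_response_gives_zero_r_squared():
    summaries = [
        characterize.ScaffoldSummary(f"s{i}", i, 7, (100, 200), 150.0) for i in range(5)
    ]
    *_, r2, _ = characterize.correlate_scaffold_counts(summaries)
    assert r2 == pytest.approx(0.0)


def test_zero_variance_predictor_is_an_error():
    summaries = [
        characterize.ScaffoldSummary(f"s{i}", 3, i, (100, 200), 150.0) for i in range(5)
    ]
    with pytest.raises(ValueError):
        characterize.correlate_scaffold_counts(summaries)
    with pytest.raises(ValueError):
        characterize.correlate_scaffold_counts(summaries[:2])


def test_r_squared_sampling_distribution_at_known_correlation():
    rng = np.random.default_rng(15)
    rho, n = 0.9, 200
    inside = 0
    runs = 40
    for _ in range(runs):
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        summaries = [
            characterize.ScaffoldSummary(f"s{i}", xi, yi, (1, 2), 1.5)
            for i, (xi, yi) in enumerate(zip((50 + 10 * x), (50 + 10 * y)))
        ]
        *_, r2, _ = characterize.correlate_scaffold_counts(summaries)
        inside += 0.73 <= r2 <= 0.88
    assert inside / runs >= 0.85


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------

def test_nearest_gene_and_side():
    linc = _linc("l", (2000, 2500))
    genes = [_gene("up", (1000, 1500)), _gene("down", (3200, 4000))]
    (hit,) = characterize.nearest_neighbor([linc], genes)
    assert hit.gene_id == "up" and hit.distance == 500 and hit.side == "upstream"
    assert not hit.tie


def test_equidistant_genes_tie_to_smaller_start():
    linc = _linc("l", (2000, 2500))
    genes = [_gene("b", (3000, 3500)), _gene("a", (1000, 1500))]
    (hit,) = characterize.nearest_neighbor([linc], genes)
    assert hit.gene_id == "a" and hit.tie


def test_lincrna_without_same_scaffold_gene_is_omitted():
    hits = characterize.nearest_neighbor([_linc("l", (0, 100), scaffold="sX")], [_gene("g", (0, 10))])
    assert hits == []


def test_nearest_neighbor_matches_all_pairs_oracle():
    rng = np.random.default_rng(23)
    for _ in range(500):
        n_genes = int(rng.integers(1, 10))
        genes = []
        spans = []
        for i in range(n_genes):
            s = int(rng.integers(0, 100_000))
            span = (s, s + int(rng.integers(100, 3000)))
            genes.append(_gene(f"g{i}", span))
            spans.append(span)
        ls = int(rng.integers(0, 100_000))
        linc = _linc("l", (ls, ls + int(rng.integers(100, 2000))))
        (hit,) = characterize.nearest_neighbor([linc], genes)
        idx, gap = nearest_gene_all_pairs(linc.span, spans)
        assert hit.distance == gap
        # the oracle's tie rule is also smaller-start
        assert genes[idx].span[0] == [g for g in genes if g.gene_id == hit.gene_id][0].span[0]


# ---------------------------------------------------------------------------
# Neighbor expression comparison
# ---------------------------------------------------------------------------

def test_identical_distributions_rarely_significant():
    rng = np.random.default_rng(31)
    significant = 0
    for _ in range(20):
        a = rng.lognormal(2, 1, 100)
        b = rng.lognormal(2, 1, 100)
        significant += characterize.neighbor_expression_compare(a, b)["p_value"] < 0.05
    assert significant <= 2


def test_tenfold_shift_detected():
    rng = np.random.default_rng(32)
    a = rng.lognormal(2, 1, 100) * 10
    b = rng.lognormal(2, 1, 100)
    out = characterize.neighbor_expression_compare(a, b)
    assert out["p_value"] < 0.01
    assert out["lincrna_median"] == pytest.approx(float(np.sort(a)[49:51].mean()))


def test_empty_sets_are_an_error():
    with pytest.raises(ValueError):
        characterize.neighbor_expression_compare([], [1.0])


# ---------------------------------------------------------------------------
# Pre-miRNA search
# ---------------------------------------------------------------------------

def test_verbatim_embed_found_with_full_identity():
    rng = np.random.default_rng(40)
    pre = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
    host = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
    linc = TranscriptModel("l", "s1", [(0, 580)], spliced_sequence=host[:250] + pre + host[250:], strand="+")
    (hit,) = characterize.mirna_precursor_search({"m": pre}, [linc])
    assert hit.strand == "+" and hit.identity == 1.0 and hit.coverage == 1.0


def test_reverse_complement_embed_found_on_minus_strand():
    rng = np.random.default_rng(41)
    pre = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
    host = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    seq = host[:200] + reverse_complement(pre) + host[200:]
    linc = TranscriptModel("l", "s1", [(0, len(seq))], spliced_sequence=seq, strand="+")
    (hit,) = characterize.mirna_precursor_search({"m": pre}, [linc])
    assert hit.strand == "-" and hit.identity == 1.0


def test_unrelated_sequences_produce_no_hits():
    rng = np.random.default_rng(42)
    pre = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
    linc = TranscriptModel(
        "l", "s1", [(0, 2000)],
        spliced_sequence="".join("ACGT"[i] for i in rng.integers(0, 4, 2000)),
        strand="+",
    )
    assert characterize.mirna_precursor_search({"m": pre}, [linc]) == []


def test_precursor_length_bounds_enforced():
    with pytest.raises(ValueError):
        characterize.mirna_precursor_search({"m": "ACGT"}, [])


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

def test_universal_term_has_unit_p():
    bg = {f"g{i}" for i in range(20)}
    fg = {f"g{i}" for i in range(5)}
    term_map = {g: {"everywhere"} for g in bg}
    (res,) = characterize.term_enrichment(fg, bg, term_map)
    assert res.p_value == pytest.approx(1.0)


def test_enrichment_p_matches_exact_tail_sum():
    bg = {f"g{i}" for i in range(100)}
    fg = {f"g{i}" for i in range(10)}
    term_map = {f"g{i}": {"t"} for i in list(range(5)) + list(range(50, 55))}
    (res,) = characterize.term_enrichment(fg, bg, term_map)
    assert res.k == 5 and res.n == 10 and res.K == 10 and res.N == 100
    assert res.p_value == pytest.approx(hypergeom_upper_tail_exact(5, 10, 10, 100), rel=1e-9)


def test_enrichment_matches_oracle_on_small_instances():
    rng = np.random.default_rng(50)
    for _ in range(50):
        N = int(rng.integers(5, 31))
        n = int(rng.integers(1, N + 1))
        K = int(rng.integers(1, N + 1))
        k_max = min(n, K)
        k_min = max(0, n + K - N)
        k = int(rng.integers(k_min, k_max + 1))
        assert characterize.hypergeometric_upper_tail(k, n, K, N) == pytest.approx(
            hypergeom_upper_tail_exact(k, n, K, N), rel=1e-9
        )


def test_permuting_gene_labels_preserves_p_multiset():
    bg = [f"g{i}" for i in range(30)]
    fg = bg[:8]
    rng = np.random.default_rng(51)
    term_map = {g: {f"T{int(rng.integers(0, 4))}"} for g in bg}
    res1 = characterize.term_enrichment(fg, bg, term_map)
    perm = dict(zip(bg, rng.permutation(bg)))
    term_map2 = {perm[g]: t for g, t in term_map.items()}
    fg2 = {perm[g] for g in fg}
    res2 = characterize.term_enrichment(fg2, bg, term_map2)
    # consistent relabeling is an isomorphism: the p multiset is unchanged
    assert sorted(r.p_value for r in res1) == pytest.approx(sorted(r.p_value for r in res2))


def test_foreground_must_be_subset_of_background():
    with pytest.raises(ValueError):
        characterize.term_enrichment({"x"}, {"y"}, {"y": {"t"}})
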