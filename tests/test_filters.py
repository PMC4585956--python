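from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from lincscout.lincrna_identify import (
    CodingModel,
    collapse_duplicates,
    filter_coding_potential,
    filter_distance,
    filter_expression,
    filter_known_overlap,
    filter_orf,
    run_identification,
    train_hexamer_tables,
)
from lincscout.types import (
    CountMatrix,
    GeneAnnotation,
    LibraryInfo,
    PipelineError,
    TranscriptModel,
)


def _cand(tid, exons, seq=None, scaffold="s1"):
    if seq is None:
        seq = "A" * sum(e - s for s, e in exons)
    return TranscriptModel(tid, scaffold, exons, spliced_sequence=seq, strand="+")


def _gene(gid, span, scaffold="s1", biotype="protein_coding"):
    return GeneAnnotation(gid, scaffold, "+", span, [span], biotype=biotype)


# ---------------------------------------------------------------------------
# overlap filter
# ---------------------------------------------------------------------------

def test_overlapping_exon_removed():
    assert filter_known_overlap([_cand("t", [(150, 250)])], [_gene("g", (0, 200))]) == []


def test_candidate_inside_intron_removed():
    # gene span (0, 1000) with exons only at the ends: overlap is against
    # the whole span, so an intron-contained candidate is removed
    gene = GeneAnnotation("g", "s1", "+", (0, 1000), [(0, 100), (900, 1000)])
    assert filter_known_overlap([_cand("t", [(400, 500)])], [gene]) == []


def test_abutting_candidate_is_not_overlap():
    survivors = filter_known_overlap([_cand("t", [(500, 600)])], [_gene("g", (0, 500))])
    assert [t.transcript_id for t in survivors] == ["t"]


def test_unknown_scaffold_kept_with_warning(caplog):
    with caplog.at_level("WARNING"):
        survivors = filter_known_overlap(
            [_cand("t", [(0, 100)], scaffold="sX")], [_gene("g", (0, 200))]
        )
    assert len(survivors) == 1
    assert any("no annotations" in m for m in caplog.messages)


def test_non_coding_annotations_do_not_trigger_overlap():
    genes = [_gene("g", (0, 200), biotype="lincRNA")]
    assert len(filter_known_overlap([_cand("t", [(150, 250)])], genes)) == 1


# ---------------------------------------------------------------------------
# distance filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gene_span,kept",
    [((0, 1999), True), ((0, 2000), False), ((5000, 6000), False), ((5001, 6000), True)],
)
def test_distance_boundary_arithmetic(gene_span, kept):
    survivors = filter_distance([_cand("t", [(3000, 4000)])], [_gene("g", gene_span)])
    assert bool(survivors) is kept


def test_candidate_alone_on_scaffold_kept():
    assert len(filter_distance([_cand("t", [(0, 100)])], [])) == 1


# ---------------------------------------------------------------------------
# ORF filter
# ---------------------------------------------------------------------------

def _orf_seq(n_aa: int) -> str:
    return "ATG" + "AAA" * (n_aa - 1) + "TGA"


def test_orf_filter_is_strictly_above_threshold():
    at_limit = _cand("a", [(0, 3 * 100 + 3)], seq=_orf_seq(100))
    above = _cand("b", [(0, 3 * 101 + 3)], seq=_orf_seq(101))
    from lincscout.lincrna_identify import find_longest_orf

    assert find_longest_orf(at_limit.sequence()).aa_length == 100
    survivors = filter_orf([at_limit, above], max_aa=100)
    assert [t.transcript_id for t in survivors] == ["a"]


def test_generator_lincrna_truths_all_pass_orf_filter(small_sim):
    truth = small_sim["truth"]
    linc_ids = set(truth.ids("lincRNA"))
    lincs = [c for c in small_sim["candidates"] if c.transcript_id in linc_ids]
    assert len(filter_orf(lincs)) == len(lincs)


# ---------------------------------------------------------------------------
# coding-potential filter
# ---------------------------------------------------------------------------

def _fixed_probability_model(p: float) -> CodingModel:
    return CodingModel(
        mean=np.zeros(4), scale=np.ones(4), coef=np.zeros(4),
        intercept=math.log(p / (1 - p)),
    )


def test_coding_probability_boundary_is_inclusive():
    tables = train_hexamer_tables(["ATGGCTGCTTAA"], ["ACGTACGTAC"])
    cand = _cand("t", [(0, 30)], seq="ACGTACGTACGTACGTACGTACGTACGTAC")
    assert filter_coding_potential([cand], _fixed_probability_model(0.2999), tables) != []
    assert filter_coding_potential([cand], _fixed_probability_model(0.3000001), tables) == []


def test_decoys_rejected_by_trained_model(small_sim):
    tables = train_hexamer_tables(small_sim["train_coding"], small_sim["train_noncoding"])
    from lincscout.lincrna_identify import compute_coding_features, train_coding_model

    cod = [compute_coding_features(s, tables) for s in small_sim["train_coding"]]
    non = [compute_coding_features(s, tables) for s in small_sim["train_noncoding"]]
    model = train_coding_model(cod, non)
    decoy_ids = set(small_sim["truth"].ids("coding_decoy"))
    decoys = [c for c in small_sim["candidates"] if c.transcript_id in decoy_ids]
    survivors = filter_coding_potential(decoys, model, tables)
    assert len(survivors) <= 0.1 * len(decoys)


# ---------------------------------------------------------------------------
# expression filter
# ---------------------------------------------------------------------------

def _matrix(rows: dict[str, list[int]]) -> CountMatrix:
    n_lib = len(next(iter(rows.values())))
    libs = [LibraryInfo(f"lib{i}", "g", 10_000) for i in range(n_lib)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[l.library_id for l in libs])
    return CountMatrix(df, libs)


@pytest.mark.parametrize(
    "counts,kept",
    [
        ([10, 10, 10, 0, 0, 0, 0, 0], False),  # 10 is not *more than* 10
        ([11, 11, 11, 0, 0, 0, 0, 0], True),
        ([11, 11, 0, 0, 0, 0, 0, 0], False),  # only two qualifying libraries
    ],
)
def test_expression_rule_strictness(counts, kept):
    matrix = _matrix({"t": counts})
    survivors = filter_expression([_cand("t", [(0, 8)])], matrix)
    assert bool(survivors) is kept


def test_expression_filter_names_missing_candidate():
    matrix = _matrix({"other": [0] * 8})
    with pytest.raises(PipelineError, match="t_missing"):
        filter_expression([_cand("t_missing", [(0, 8)])], matrix)


# ---------------------------------------------------------------------------
# duplicate collapse
# ---------------------------------------------------------------------------

def test_identical_sequences_collapse_to_smallest_id():
    a = _cand("b_dup", [(0, 100)], seq="ACGT" * 25)
    b = _cand("a_dup", [(5000, 5100)], seq="ACGT" * 25)
    out = collapse_duplicates([a, b])
    assert [t.transcript_id for t in out] == ["a_dup"]


def test_overlapping_spans_keep_longest():
    a = _cand("a", [(0, 500)])
    b = _cand("b", [(400, 1000)], seq="C" * 600)
    out = collapse_duplicates([a, b])
    assert [t.transcript_id for t in out] == ["b"]


def test_equal_length_overlap_ties_to_smallest_id():
    a = _cand("b_tie", [(0, 500)])
    b = _cand("a_tie", [(400, 900)], seq="C" * 500)
    out = collapse_duplicates([a, b])
    assert [t.transcript_id for t in out] == ["a_tie"]


def test_collapse_is_idempotent_on_random_layouts():
    rng = np.random.default_rng(7)
    for _ in range(200):
        cands = []
        for i in range(int(rng.integers(1, 15))):
            start = int(rng.integers(0, 5000))
            length = int(rng.integers(50, 400))
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, length))
            cands.append(
                _cand(f"t{i:02d}", [(start, start + length)], seq=seq,
                      scaffold=f"s{int(rng.integers(0, 3))}")
            )
        once = collapse_duplicates(cands)
        twice = collapse_duplicates(once)
        assert [t.transcript_id for t in once] == [t.transcript_id for t in twice]
        # survivors never overlap on a scaffold
        by_scaffold: dict[str, list] = {}
        for t in once:
            by_scaffold.setdefault(t.scaffold_id, []).append(t.span)
        for spans in by_scaffold.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


# ---------------------------------------------------------------------------
# orchestrated run
# ---------------------------------------------------------------------------

def test_empty_candidate_set_yields_empty_catalog(small_sim):
    result = run_identification(
        [], small_sim["genes"], small_sim["counts"],
        small_sim["train_coding"], small_sim["train_noncoding"],
    )
    assert result.catalog == []
    assert all(n_in == n_out == 0 for _, n_in, n_out in result.report.stages)


def test_stage_counts_weakly_decreasing_and_chained(small_identification):
    stages = small_identification.report.stages
    assert len(stages) == 6
    for (_, n_in, n_out), (_, next_in, _) in zip(stages, stages[1:]):
        assert n_out <= n_in
        assert next_in == n_out


def test_identification_is_deterministic(small_sim):
    kwargs = dict(
        candidates=small_sim["candidates"], annotations=small_sim["genes"],
        counts=small_sim["counts"], coding_training=small_sim["train_coding"],
        noncoding_training=small_sim["train_noncoding"],
    )
    r1 = run_identification(**kwargs)
    r2 = run_identification(**kwargs)
    assert [t.transcript_id for t in r1.catalog] == [t.transcript_id for t in r2.catalog]
    assert [t.sequence() for t in r1.catalog] == [t.sequence() for t in r2.catalog]
    assert r1.report.stages == r2.report.stages
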