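"""Catalog characterization.

GC content, per-scaffold summaries and the gene-count correlation,
nearest-neighbor gene assignment with an expression comparison, local
alignment search for embedded pre-miRNA sequences, and generic
hypergeometric term enrichment over a user-supplied gene-to-term map.

A packaged survey table (``data/px_lincrna_scaffold_survey.tsv``) holds
the published per-scaffold tallies of lincRNA-rich scaffolds in the
*Plutella xylostella* genome assembly v2, used as a worked example.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import reverse_complement
from .types import (
    EnrichmentResult,
    GeneAnnotation,
    NeighborAssignment,
    ScaffoldSummary,
    TranscriptModel,
    interval_gap,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(sequences: Mapping[str, str]) -> tuple[pd.Series, float]:
    """Per-sequence GC fraction and the set mean.

    ``GC = (#G + #C) / (#A + #C + #G + #T)``; N and other ambiguity codes
    are excluded from numerator and denominator. A sequence without any
    unambiguous base is reported as missing (NaN) and excluded from the
    mean.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    values = {}
    for sid, seq in sequences.items():
        s = seq.upper()
        gc = s.count("G") + s.count("C")
        at = s.count("A") + s.count("T")
        if gc + at == 0:
            log.warning("sequence %s has no unambiguous bases; GC undefined", sid)
            values[sid] = np.nan
        else:
            values[sid] = gc / (gc + at)
    series = pd.Series(values, name="gc_fraction")
    return series, float(series.mean())


# ---------------------------------------------------------------------------
# Scaffold summaries
# ---------------------------------------------------------------------------

def scaffold_summary(
    catalog: Sequence[TranscriptModel], annotations: Sequence[GeneAnnotation]
) -> list[ScaffoldSummary]:
    """One summary row per scaffold carrying at least one catalogued lincRNA."""
    genes_per_scaffold: dict[str, int] = {}
    for g in annotations:
        if g.biotype == "protein_coding":
            genes_per_scaffold[g.scaffold_id] = genes_per_scaffold.get(g.scaffold_id, 0) + 1
    lincs: dict[str, list[int]] = {}
    for t in catalog:
        lincs.setdefault(t.scaffold_id, []).append(t.length)
    out = []
    for sid in sorted(lincs):
        lengths = lincs[sid]
        out.append(
            ScaffoldSummary(
                scaffold_id=sid,
                n_known_genes=genes_per_scaffold.get(sid, 0),
                n_lincrna=len(lengths),
                lincrna_length_range=(min(lengths), max(lengths)),
                lincrna_mean_length=float(np.mean(lengths)),
            )
        )
    out.sort(key=lambda s: (-s.n_lincrna, s.scaffold_id))
    return out


def load_scaffold_survey(path=None) -> list[ScaffoldSummary]:
    """Load a per-scaffold survey TSV (defaults to the packaged table)."""
    if path is None:
        source = resources.files("lincscout.data").joinpath("px_lincrna_scaffold_survey.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        ScaffoldSummary(
            scaffold_id=str(r.scaffold_id),
            n_known_genes=int(r.n_known_genes),
            n_lincrna=int(r.n_lincrna),
            lincrna_length_range=(int(r.min_length_bp), int(r.max_length_bp)),
            lincrna_mean_length=float(r.mean_length_bp),
        )
        for r in df.itertuples()
    ]


def count_lincrna_rich_scaffolds(
    summaries: Sequence[ScaffoldSummary], min_lincrna: int = 20
) -> int:
    """Scaffolds carrying at least ``min_lincrna`` catalogued lincRNAs."""
    return sum(1 for s in summaries if s.n_lincrna >= min_lincrna)


def correlate_scaffold_counts(
    summaries: Sequence[ScaffoldSummary],
) -> tuple[float, float, float, float]:
    """OLS of lincRNA count on known-gene count across scaffolds.

    Returns ``(slope, intercept, r_squared, p_value)`` with the p-value
    from the slope t-test.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 scaffolds")
    x = np.array([s.n_known_genes for s in summaries], dtype=float)
    y = np.array([s.n_lincrna for s in summaries], dtype=float)
    if np.var(x) == 0:
        raise ValueError("zero variance in known-gene counts; correlation undefined")
    if np.var(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), float(fit.pvalue)


def summaries_frame(summaries: Sequence[ScaffoldSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold_id": [s.scaffold_id for s in summaries],
            "n_known_genes": [s.n_known_genes for s in summaries],
            "n_lincrna": [s.n_lincrna for s in summaries],
            "min_length_bp": [s.lincrna_length_range[0] for s in summaries],
            "max_length_bp": [s.lincrna_length_range[1] for s in summaries],
            "mean_length_bp": [s.lincrna_mean_length for s in summaries],
        }
    )


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------

def nearest_neighbor(
    catalog: Sequence[TranscriptModel], annotations: Sequence[GeneAnnotation]
) -> list[NeighborAssignment]:
    """Nearest protein-coding gene per lincRNA by span gap distance.

    Ties go to the gene with the smaller start (``tie`` flagged); lincRNAs
    on scaffolds without genes are omitted with a logged note. ``side`` is
    relative to scaffold coordinates: ``upstream`` means the gene starts
    before the lincRNA.
    """
    genes: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        if g.biotype == "protein_coding":
            genes.setdefault(g.scaffold_id, []).append(g)
    for glist in genes.values():
        glist.sort(key=lambda g: (g.span, g.gene_id))
    out: list[NeighborAssignment] = []
    for t in catalog:
        glist = genes.get(t.scaffold_id)
        if not glist:
            log.info("lincRNA %s: no protein-coding gene on scaffold %s", t.transcript_id, t.scaffold_id)
            continue
        gaps = np.array([interval_gap(t.span, g.span) for g in glist])
        best = int(gaps.argmin())
        tie = bool((gaps == gaps[best]).sum() > 1)
        gene = glist[best]  # sorted by start => smaller start wins ties
        side = "upstream" if gene.span[0] < t.span[0] else "downstream"
        out.append(
            NeighborAssignment(
                lincrna_id=t.transcript_id,
                gene_id=gene.gene_id,
                distance=int(gaps[best]),
                side=side,
                tie=tie,
            )
        )
    return out


def neighbor_expression_compare(
    lincrna_rpkm: Sequence[float], neighbor_rpkm: Sequence[float]
) -> dict[str, float]:
    """Distribution summaries plus a two-sided Wilcoxon rank-sum p-value."""
    a = np.asarray(lincrna_rpkm, dtype=float)
    b = np.asarray(neighbor_rpkm, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both expression sets must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "lincrna_median": float(np.median(a)),
        "lincrna_mean": float(a.mean()),
        "neighbor_median": float(np.median(b)),
        "neighbor_mean": float(b.mean()),
        "statistic": float(stat),
        "p_value": float(p),
        "n_lincrna": int(a.size),
        "n_neighbor": int(b.size),
    }


# ---------------------------------------------------------------------------
# Pre-miRNA embedding search
# ---------------------------------------------------------------------------

@dataclass
class MirnaHit:
    lincrna_id: str
    precursor_id: str
    strand: str
    identity: float
    coverage: float
    score: float


def mirna_precursor_search(
    precursors: Mapping[str, str],
    catalog: Sequence[TranscriptModel],
    min_identity: float = 0.90,
    min_coverage: float = 0.80,
) -> list[MirnaHit]:
    """Local-alignment search for pre-miRNA precursors inside lincRNAs.

    Each precursor (and its reverse complement) is aligned locally against
    each lincRNA with match +1, mismatch -2, gap -2. A hit requires
    identity >= ``min_identity`` over >= ``min_coverage`` of the precursor
    length. Precursor lengths outside 50-200 nt are rejected.
    """
    for pid, seq in precursors.items():
        if not 50 <= len(seq) <= 200:
            raise ValueError(f"precursor {pid} has length {len(seq)}; expected 50-200 nt")
    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2,
        open_gap_score=-2, extend_gap_score=-2,
    )
    hits: list[MirnaHit] = []
    for t in catalog:
        target = t.sequence().upper()
        for pid, pre in precursors.items():
            pre = pre.upper()
            # a qualifying hit scores at least ~0.5 * coverage * length
            floor = 0.4 * len(pre)
            best = None
            for strand, query in (("+", pre), ("-", reverse_complement(pre))):
                score = aligner.score(target, query)
                if score < floor:
                    continue
                aln = aligner.align(target, query)[0]
                counts = aln.counts()
                cols = counts.identities + counts.mismatches + counts.gaps
                identity = counts.identities / cols if cols else 0.0
                q_aligned = sum(e - s for s, e in aln.aligned[1])
                coverage = q_aligned / len(pre)
                if identity >= min_identity and coverage >= min_coverage:
                    cand = MirnaHit(t.transcript_id, pid, strand, identity, coverage, float(score))
                    if best is None or cand.score > best.score:
                        best = cand
            if best is not None:
                hits.append(best)
    hits.sort(key=lambda h: (h.lincrna_id, h.precursor_id))
    return hits


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def term_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of terms in the foreground.

    ``term_map`` maps gene id to its terms. Terms absent from the
    background are skipped; q-values are Benjamini-Hochberg over the
    tested terms; results sorted by p then term.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    genes_per_term: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene in bg:
            for term in terms:
                genes_per_term.setdefault(term, set()).add(gene)
    if not any(g & fg for g in genes_per_term.values()):
        raise ValueError("term map covers no foreground gene")
    N, n = len(bg), len(fg)
    raw = []
    for term in sorted(genes_per_term):
        members = genes_per_term[term]
        K = len(members)
        k = len(members & fg)
        raw.append((term, k, K, hypergeometric_upper_tail(k, n, K, N)))
    qs = multipletests([p for *_, p in raw], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term=term, k=k, n=n, K=K, N=N, p_value=p, q_value=float(q))
        for (term, k, K, p), q in zip(raw, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
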