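"""The lincRNA identification cascade.

From candidate transcript models to a lincRNA catalog, applying in order:

1. discard candidates whose exons overlap known protein-coding genes
   (exons *and* introns count, strand-agnostic);
2. discard candidates within 1 kb of any protein-coding gene span;
3. discard candidates whose longest ORF (all six frames) exceeds 100 aa;
4. discard candidates the four-feature logistic model calls coding
   (probability >= 0.3; features: ORF size, ORF coverage, Fickett
   TESTCODE, hexamer usage bias);
5. keep candidates with more than 10 reads in at least 3 libraries;
6. collapse identical and genomically overlapping survivors.

Every filter returns a subset of its input and the per-stage counts are
recorded in a :class:`StageReport`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .fickett import fickett_score
from .io_formats import reverse_complement
from .types import (
    CodingPotential,
    CountMatrix,
    FEATURE_NAMES,
    GeneAnnotation,
    OrfResult,
    PipelineError,
    StageReport,
    TrainingError,
    TranscriptModel,
    interval_gap,
    intervals_overlap,
)

log = logging.getLogger(__name__)

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_FRAME_ORDER = ("+1", "+2", "+3", "-1", "-2", "-3")


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

def find_longest_orf(sequence: str) -> OrfResult:
    """Longest ORF over all six reading frames.

    An ORF starts at ATG and runs to the first in-frame stop (TAA/TAG/TGA),
    or is open-ended at the sequence end (``has_stop=False``). Ties are
    broken by frame order ``+1,+2,+3,-1,-2,-3`` then smaller ``start_nt``.
    A sequence without any ATG yields ``aa_length == 0``.
    """
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    rc = reverse_complement(seq)
    best = OrfResult("+1", 0, 0, False)
    strands = {"+": seq, "-": rc}
    for frame in _FRAME_ORDER:
        s = strands[frame[0]]
        offset = int(frame[1]) - 1
        n = len(s)
        open_start: Optional[int] = None
        j = offset
        while j + 3 <= n:
            codon = s[j : j + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = j
            elif codon in _STOP_CODONS:
                aa = (j - open_start) // 3
                if aa > best.aa_length:
                    best = OrfResult(frame, open_start, aa, True)
                open_start = None
            j += 3
        if open_start is not None:
            aa = (j - open_start) // 3
            if aa > best.aa_length:
                best = OrfResult(frame, open_start, aa, False)
    return best


def orf_nucleotides(sequence: str, orf: OrfResult) -> str:
    """The coding region of ``orf`` (ATG through last codon, stop excluded)."""
    s = sequence.upper() if orf.frame.startswith("+") else reverse_complement(sequence.upper())
    return s[orf.start_nt : orf.start_nt + 3 * orf.aa_length]


# ---------------------------------------------------------------------------
# Hexamer usage bias
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _hexamer_index(seq: str, pos: int) -> Optional[int]:
    idx = 0
    for k in range(6):
        code = _BASE_CODE.get(seq[pos + k])
        if code is None:
            return None
        idx = idx * 4 + code
    return idx


def _count_hexamers(sequences: Iterable[str], step: int) -> np.ndarray:
    counts = np.zeros(4096, dtype=float)
    for seq in sequences:
        seq = seq.upper()
        for pos in range(0, len(seq) - 5, step):
            idx = _hexamer_index(seq, pos)
            if idx is not None:
                counts[idx] += 1
    return counts


@dataclass
class HexamerTables:
    """In-frame coding vs sliding noncoding hexamer frequency tables."""

    f_coding: np.ndarray
    f_noncoding: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        for name, f in (("f_coding", self.f_coding), ("f_noncoding", self.f_noncoding)):
            if f.shape != (4096,):
                raise ValueError(f"{name} must have 4096 entries")
            if (f <= 0).any():
                raise ValueError(f"{name} entries must all be positive")
            if not math.isclose(float(f.sum()), 1.0, rel_tol=1e-9):
                raise ValueError(f"{name} must sum to 1")

    @property
    def log_ratio(self) -> np.ndarray:
        return np.log(self.f_coding / self.f_noncoding)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pseudocount={self.pseudocount}\n")
            fh.write("hexamer_index\tf_coding\tf_noncoding\n")
            for i in range(4096):
                fh.write(f"{i}\t{self.f_coding[i]:.12e}\t{self.f_noncoding[i]:.12e}\n")

    @classmethod
    def load(cls, path) -> "HexamerTables":
        with open(path) as fh:
            header = fh.readline()
            pseudocount = float(header.strip().split("=", 1)[1])
            fh.readline()
            fc = np.empty(4096)
            fn = np.empty(4096)
            for line in fh:
                i, a, b = line.split("\t")
                fc[int(i)] = float(a)
                fn[int(i)] = float(b)
        return cls(fc, fn, pseudocount)


def train_hexamer_tables(
    coding: Sequence[str], noncoding: Sequence[str], pseudocount: float = 1.0
) -> HexamerTables:
    """Hexamer tables: in-frame (step 3) over coding ORFs, sliding (step 1)
    over noncoding sequences, with additive pseudocount."""
    if not coding or not noncoding:
        raise TrainingError("both coding and noncoding training sets must be non-empty")
    fc = _count_hexamers(coding, step=3) + pseudocount
    fn = _count_hexamers(noncoding, step=1) + pseudocount
    return HexamerTables(fc / fc.sum(), fn / fn.sum(), pseudocount)


def hexamer_score(sequence: str, tables: HexamerTables) -> float:
    """Mean log(f_coding/f_noncoding) over in-frame hexamers of the longest
    ORF; falls back to the full sequence when there is no usable ORF."""
    orf = find_longest_orf(sequence)
    region = orf_nucleotides(sequence, orf) if 3 * orf.aa_length >= 6 else sequence.upper()
    lr = tables.log_ratio
    values = []
    for pos in range(0, len(region) - 5, 3):
        idx = _hexamer_index(region, pos)
        if idx is not None:
            values.append(lr[idx])
    if not values:
        return 0.0
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Coding-potential model
# ---------------------------------------------------------------------------

def compute_coding_features(sequence: str, tables: HexamerTables) -> CodingPotential:
    """The four coding-potential features of one spliced sequence."""
    orf = find_longest_orf(sequence)
    orf_size = 3 * orf.aa_length + (3 if orf.has_stop and orf.aa_length > 0 else 0)
    return CodingPotential(
        orf_size_nt=orf_size,
        orf_coverage=orf_size / len(sequence),
        fickett=fickett_score(sequence),
        hexamer_bias=hexamer_score(sequence, tables),
    )


@dataclass
class CodingModel:
    """Standardized four-feature logistic regression (class 1 = coding)."""

    mean: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float

    def predict_proba(self, features) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        z = ((X - self.mean) / self.scale) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def coding_probability(self, cp: CodingPotential) -> float:
        return float(self.predict_proba(cp.as_vector())[0])

    def save(self, path) -> None:
        payload = {
            "features": list(FEATURE_NAMES),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "CodingModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            mean=np.array(payload["mean"]),
            scale=np.array(payload["scale"]),
            coef=np.array(payload["coef"]),
            intercept=float(payload["intercept"]),
        )


def train_coding_model(
    coding_features: Sequence[CodingPotential],
    noncoding_features: Sequence[CodingPotential],
) -> CodingModel:
    """Fit the logistic model on labelled feature sets (>= 20 per class).

    Features are standardized internally; a small ridge penalty keeps the
    fit finite under perfect separation (a note is logged in that case).
    """
    if len(coding_features) < 20 or len(noncoding_features) < 20:
        raise TrainingError("need at least 20 training examples per class")
    X = np.vstack([cp.as_vector() for cp in list(coding_features) + list(noncoding_features)])
    if not np.isfinite(X).all():
        raise TrainingError("non-finite feature values in training data")
    y = np.array([1] * len(coding_features) + [0] * len(noncoding_features))
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000, tol=1e-10)
    clf.fit(Xs, y)
    margins = (Xs @ clf.coef_[0] + clf.intercept_[0]) * (2 * y - 1)
    if (margins > 0).all():
        log.info("training classes are perfectly separated; ridge penalty bounds the fit")
    return CodingModel(mean=mean, scale=scale, coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]))


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _genes_by_scaffold(
    annotations: Iterable[GeneAnnotation], biotype: str = "protein_coding"
) -> dict[str, list[GeneAnnotation]]:
    out: dict[str, list[GeneAnnotation]] = {}
    for g in annotations:
        if g.biotype == biotype:
            out.setdefault(g.scaffold_id, []).append(g)
    return out


def filter_known_overlap(
    candidates: Sequence[TranscriptModel], annotations: Sequence[GeneAnnotation]
) -> list[TranscriptModel]:
    """Remove candidates with any exon overlapping (>= 1 bp) the span of a
    known protein-coding gene, on either strand. Introns count: overlap is
    tested against the whole gene span."""
    genes = _genes_by_scaffold(annotations)
    survivors = []
    for cand in candidates:
        spans = genes.get(cand.scaffold_id)
        if spans is None:
            log.warning(
                "candidate %s on scaffold %s with no annotations; kept",
                cand.transcript_id, cand.scaffold_id,
            )
            survivors.append(cand)
            continue
        hit = any(
            intervals_overlap(exon, g.span) for exon in cand.exons for g in spans
        )
        if not hit:
            survivors.append(cand)
    return survivors


def filter_distance(
    candidates: Sequence[TranscriptModel],
    annotations: Sequence[GeneAnnotation],
    min_gap_bp: int = 1000,
) -> list[TranscriptModel]:
    """Keep candidates strictly more than ``min_gap_bp`` away from every
    protein-coding gene span on the same scaffold."""
    genes = _genes_by_scaffold(annotations)
    survivors = []
    for cand in candidates:
        spans = genes.get(cand.scaffold_id, [])
        if all(interval_gap(cand.span, g.span) > min_gap_bp for g in spans):
            survivors.append(cand)
    return survivors


def filter_orf(
    candidates: Sequence[TranscriptModel], max_aa: int = 100
) -> list[TranscriptModel]:
    """Remove candidates whose longest ORF is strictly above ``max_aa``
    amino acids; open-ended ORFs count with their current length."""
    return [
        c for c in candidates if find_longest_orf(c.sequence()).aa_length <= max_aa
    ]


def filter_coding_potential(
    candidates: Sequence[TranscriptModel],
    model: CodingModel,
    tables: HexamerTables,
    threshold: float = 0.3,
    features_out: Optional[dict] = None,
) -> list[TranscriptModel]:
    """Remove candidates with coding probability at or above ``threshold``.

    Each removal is logged with its four feature values. Computed
    :class:`CodingPotential` records are stored in ``features_out`` when a
    dict is supplied (for survivors and casualties alike).
    """
    survivors = []
    for cand in candidates:
        cp = compute_coding_features(cand.sequence(), tables)
        cp.coding_probability = model.coding_probability(cp)
        if features_out is not None:
            features_out[cand.transcript_id] = cp
        if cp.coding_probability >= threshold:
            log.info(
                "discarding %s as putative coding (p=%.3f; orf_size=%d, coverage=%.3f, "
                "fickett=%.3f, hexamer=%.3f)",
                cand.transcript_id, cp.coding_probability, cp.orf_size_nt,
                cp.orf_coverage, cp.fickett, cp.hexamer_bias,
            )
        else:
            survivors.append(cand)
    return survivors


def filter_expression(
    candidates: Sequence[TranscriptModel],
    counts: CountMatrix,
    min_reads: int = 10,
    min_libraries: int = 3,
) -> list[TranscriptModel]:
    """Keep candidates with strictly more than ``min_reads`` reads in at
    least ``min_libraries`` libraries."""
    survivors = []
    for cand in candidates:
        try:
            row = counts.row(cand.transcript_id)
        except KeyError as exc:
            raise PipelineError(
                f"expression filter: candidate {cand.transcript_id} has no count row"
            ) from exc
        if int((row > min_reads).sum()) >= min_libraries:
            survivors.append(cand)
    return survivors


def collapse_duplicates(candidates: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Collapse identical spliced sequences (keep lexicographically smallest
    id), then collapse genomically overlapping survivors per scaffold (keep
    the longest; ties to the smallest id). Idempotent."""
    by_seq: dict[str, TranscriptModel] = {}
    for cand in candidates:
        seq = cand.sequence()
        kept = by_seq.get(seq)
        if kept is None or cand.transcript_id < kept.transcript_id:
            by_seq[seq] = cand
    unique = list(by_seq.values())

    by_scaffold: dict[str, list[TranscriptModel]] = {}
    for cand in unique:
        by_scaffold.setdefault(cand.scaffold_id, []).append(cand)
    result: list[TranscriptModel] = []
    for scaffold in by_scaffold:
        members = sorted(by_scaffold[scaffold], key=lambda t: (t.span, t.transcript_id))
        component: list[TranscriptModel] = []
        comp_end = -1
        for cand in members:
            s, e = cand.span
            if component and s >= comp_end:
                result.append(_pick_longest(component))
                component = []
                comp_end = -1
            component.append(cand)
            comp_end = max(comp_end, e)
        if component:
            result.append(_pick_longest(component))
    result.sort(key=lambda t: (t.scaffold_id, t.span, t.transcript_id))
    return result


def _pick_longest(component: list[TranscriptModel]) -> TranscriptModel:
    return min(component, key=lambda t: (-t.length, t.transcript_id))


# ---------------------------------------------------------------------------
# Orchestrated run
# ---------------------------------------------------------------------------

@dataclass
class IdentifyConfig:
    """Thresholds of the filtering cascade (defaults are the published ones)."""

    min_gap_bp: int = 1000
    max_orf_aa: int = 100
    coding_prob_threshold: float = 0.3
    min_reads: int = 10
    min_libraries: int = 3
    hexamer_pseudocount: float = 1.0


@dataclass
class IdentificationResult:
    catalog: list[TranscriptModel]
    report: StageReport
    features: dict[str, CodingPotential]
    tables: HexamerTables
    model: CodingModel


def run_identification(
    candidates: Sequence[TranscriptModel],
    annotations: Sequence[GeneAnnotation],
    counts: CountMatrix,
    coding_training: Sequence[str],
    noncoding_training: Sequence[str],
    config: IdentifyConfig = IdentifyConfig(),
) -> IdentificationResult:
    """Run the full cascade and record per-stage survivor counts.

    ``coding_training`` / ``noncoding_training`` are spliced sequences used
    to fit the hexamer tables and the four-feature logistic model.
    """
    try:
        tables = train_hexamer_tables(
            coding_training, noncoding_training, config.hexamer_pseudocount
        )
        coding_feats = [compute_coding_features(s, tables) for s in coding_training]
        noncoding_feats = [compute_coding_features(s, tables) for s in noncoding_training]
        model = train_coding_model(coding_feats, noncoding_feats)
    except Exception as exc:
        raise PipelineError(f"stage model_training failed: {exc}") from exc

    report = StageReport()
    features: dict[str, CodingPotential] = {}
    current = list(candidates)

    stages = (
        ("known_gene_overlap", lambda c: filter_known_overlap(c, annotations)),
        ("distance_gt_min_gap", lambda c: filter_distance(c, annotations, config.min_gap_bp)),
        ("orf_length", lambda c: filter_orf(c, config.max_orf_aa)),
        (
            "coding_potential",
            lambda c: filter_coding_potential(
                c, model, tables, config.coding_prob_threshold, features_out=features
            ),
        ),
        (
            "expression",
            lambda c: filter_expression(c, counts, config.min_reads, config.min_libraries),
        ),
        ("collapse_duplicates", collapse_duplicates),
    )
    for name, fn in stages:
        n_in = len(current)
        try:
            current = fn(current)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        report.add(name, n_in, len(current))

    return IdentificationResult(current, report, features, tables, model)
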