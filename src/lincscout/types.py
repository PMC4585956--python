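"""Core domain containers shared across the pipeline.

All genomic intervals are 0-based half-open ``(start, end)`` tuples.
Conversion to the 1-based closed convention of GFF3 happens only at the
I/O boundary (:mod:`lincscout.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class ConfigurationError(ValueError):
    """A configuration value or combination is infeasible."""


class TrainingError(ValueError):
    """Classifier or table training received unusable input."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def check_interval(iv: Interval, label: str = "interval") -> None:
    start, end = iv
    if not (0 <= start < end):
        raise ValueError(f"{label} must satisfy 0 <= start < end, got {iv!r}")


def check_exons(exons: Sequence[Interval], label: str = "feature") -> None:
    """Exons must be sorted by start and pairwise disjoint."""
    for iv in exons:
        check_interval(iv, f"{label} exon")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValueError(f"{label}: exons {((s1, e1), (s2, e2))} overlap or are unsorted")


def interval_gap(a: Interval, b: Interval) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap or abut."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class GenomeSequence:
    """One scaffold of the genome assembly."""

    scaffold_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A known gene with exon/intron structure on one scaffold."""

    gene_id: str
    scaffold_id: str
    strand: str
    span: Interval
    exons: list[Interval]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        check_interval(self.span, self.gene_id)
        if not self.exons:
            self.exons = [self.span]
        check_exons(self.exons, self.gene_id)
        s, e = self.span
        for xs, xe in self.exons:
            if xs < s or xe > e:
                raise ValueError(f"{self.gene_id}: exon ({xs},{xe}) outside span {self.span}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass
class TranscriptModel:
    """A candidate transcript: genomic exons plus its spliced sequence.

    ``spliced_sequence`` may be ``None`` when the transcript was read from
    annotation alone; operations that need sequence raise in that case.
    Strand ``"."`` means unknown; the ORF scanner covers both strands
    regardless.
    """

    transcript_id: str
    scaffold_id: str
    exons: list[Interval]
    spliced_sequence: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        check_exons(self.exons, self.transcript_id)
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if self.spliced_sequence is not None:
            total = sum(e - s for s, e in self.exons)
            if len(self.spliced_sequence) != total:
                raise ValueError(
                    f"{self.transcript_id}: spliced sequence length "
                    f"{len(self.spliced_sequence)} != exon total {total}"
                )

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sequence(self) -> str:
        if self.spliced_sequence is None:
            raise ValueError(f"{self.transcript_id}: spliced sequence not available")
        return self.spliced_sequence


@dataclass(frozen=True)
class LibraryInfo:
    """One RNA-seq library: its group label and sequencing depth."""

    library_id: str
    group: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError(f"{self.library_id}: total_mapped_reads must be > 0")


class CountMatrix:
    """Transcripts x libraries integer read counts with library metadata.

    Wraps a :class:`pandas.DataFrame` whose index is transcript ids and whose
    columns follow the order of ``libraries``.
    """

    def __init__(self, counts: pd.DataFrame, libraries: Sequence[LibraryInfo]):
        libraries = list(libraries)
        lib_ids = [lib.library_id for lib in libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise ValueError("duplicate library ids")
        if list(counts.columns) != lib_ids:
            raise ValueError("count matrix columns must match library metadata order")
        if counts.index.has_duplicates:
            raise ValueError("duplicate transcript ids in count matrix")
        arr = counts.to_numpy()
        if arr.size and arr.dtype.kind not in "iu":
            raise FormatError("counts must be integers")
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = arr.sum(axis=0) if arr.size else np.zeros(len(libraries))
        for lib, cs in zip(libraries, colsums):
            if lib.total_mapped_reads < cs:
                raise ValueError(
                    f"{lib.library_id}: total_mapped_reads {lib.total_mapped_reads} "
                    f"< column sum {cs}"
                )
        self.counts = counts
        self.libraries = libraries

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return [lib.library_id for lib in self.libraries]

    @property
    def totals(self) -> np.ndarray:
        return np.array([lib.total_mapped_reads for lib in self.libraries], dtype=float)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for lib in self.libraries:
            if lib.group not in seen:
                seen.append(lib.group)
        return seen

    def columns_for_group(self, group: str) -> list[str]:
        cols = [lib.library_id for lib in self.libraries if lib.group == group]
        if not cols:
            raise KeyError(f"no libraries in group {group!r}")
        return cols

    def totals_for_group(self, group: str) -> np.ndarray:
        return np.array(
            [lib.total_mapped_reads for lib in self.libraries if lib.group == group],
            dtype=float,
        )

    def row(self, transcript_id: str) -> np.ndarray:
        if transcript_id not in self.counts.index:
            raise KeyError(f"transcript {transcript_id!r} missing from count matrix")
        return self.counts.loc[transcript_id].to_numpy()

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame of a spliced sequence.

    ``start_nt`` is the 0-based offset within the scanned strand: the
    sequence itself for frames +1/+2/+3, its reverse complement for
    -1/-2/-3. ``aa_length`` counts codons from the ATG (Met included) up to
    but excluding the stop.
    """

    frame: str
    start_nt: int
    aa_length: int
    has_stop: bool


@dataclass
class CodingPotential:
    """The four coding-potential features plus the combined probability."""

    orf_size_nt: int
    orf_coverage: float
    fickett: float
    hexamer_bias: float
    coding_probability: float = float("nan")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.orf_size_nt, self.orf_coverage, self.fickett, self.hexamer_bias],
            dtype=float,
        )


FEATURE_NAMES = ("orf_size_nt", "orf_coverage", "fickett", "hexamer_bias")


@dataclass
class StageReport:
    """Per-stage survivor counts of the identification cascade.

    External-evidence stages of the published workflow that rely on outside
    databases (Pfam domain search, BLASTx protein homology, the CPC SVM with
    its "score above -1 means coding" cutoff) are listed in
    ``skipped_stages`` but never executed here.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    skipped_stages: tuple[str, ...] = (
        "protein_domain_search (Pfam; external database)",
        "protein_homology_search (BLASTx vs nr/Swiss-Prot, E<1e-5; external)",
        "svm_coding_potential (CPC, score > -1 called coding; external)",
    )

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: surviving {n_out} exceeds input {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(
                f"stage {name}: input {n_in} does not chain from previous "
                f"surviving count {self.stages[-1][2]}"
            )
        self.stages.append((name, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_input", "n_surviving"])


@dataclass
class DEResult:
    """Differential-expression call for one transcript in one contrast."""

    transcript_id: str
    contrast: tuple[str, str]
    mean_rpkm_a: float
    mean_rpkm_b: float
    fold_change: float
    direction: str
    statistic: float
    p_value: float
    passes_reads_rule: bool
    is_de: bool
    q_value: float = float("nan")


@dataclass
class ScaffoldSummary:
    """Per-scaffold tally of known genes and catalogued lincRNAs."""

    scaffold_id: str
    n_known_genes: int
    n_lincrna: int
    lincrna_length_range: tuple[int, int]
    lincrna_mean_length: float


@dataclass
class NeighborAssignment:
    """Nearest protein-coding gene of one lincRNA, with gap distance in bp."""

    lincrna_id: str
    gene_id: str
    distance: int
    side: str
    tie: bool = False


@dataclass
class EnrichmentResult:
    """One term of a hypergeometric enrichment scan."""

    term: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float


def sequences_by_id(records: Iterable) -> dict[str, str]:
    """Map record id -> sequence for GenomeSequence / TranscriptModel mixes."""
    out: dict[str, str] = {}
    for rec in records:
        if isinstance(rec, GenomeSequence):
            out[rec.scaffold_id] = rec.sequence
        elif isinstance(rec, TranscriptModel):
            out[rec.transcript_id] = rec.sequence()
        else:
            rid, seq = rec
            out[rid] = seq
    return out
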