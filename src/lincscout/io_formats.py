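"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: everything in memory is 0-based half-open. GFF3 on
disk is 1-based closed (``internal (s, e) <-> GFF3 (s+1, e)``); BED is
0-based half-open and written verbatim. FASTA parsing goes through
Biopython, GFF3 parsing through gffutils; writing is plain text emitted
here so the round-trip conventions stay explicit.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .types import (
    CountMatrix,
    FormatError,
    GeneAnnotation,
    GenomeSequence,
    LibraryInfo,
    TranscriptModel,
)

log = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    Sequences are uppercased; IUPAC ambiguity characters other than N are
    normalized to N with a logged warning. Empty files and duplicate ids are
    format errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned, n = _NON_ACGTN.subn("N", seq)
        n_mapped += n
        records.append(GenomeSequence(rec.id, cleaned))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if n_mapped:
        log.warning("%s: %d non-ACGTN characters normalized to N", path, n_mapped)
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records (GenomeSequence / TranscriptModel / (id, seq) pairs / mapping)."""
    if isinstance(records, Mapping):
        pairs = list(records.items())
    else:
        pairs = []
        for rec in records:
            if isinstance(rec, GenomeSequence):
                pairs.append((rec.scaffold_id, rec.sequence))
            elif isinstance(rec, TranscriptModel):
                pairs.append((rec.transcript_id, rec.sequence()))
            else:
                pairs.append(tuple(rec))
    with open(path, "w") as fh:
        for rid, seq in pairs:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff3_feature_lines(
    fid: str,
    ftype: str,
    scaffold: str,
    strand: str,
    span,
    exons,
    extra_attrs: str = "",
) -> list[str]:
    s, e = span
    attrs = f"ID={fid}" + extra_attrs
    lines = [f"{scaffold}\tlincscout\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"]
    for i, (xs, xe) in enumerate(exons, 1):
        lines.append(
            f"{scaffold}\tlincscout\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t"
            f"ID={fid}.exon{i};Parent={fid}"
        )
    return lines


def write_gff3(genes: Sequence[GeneAnnotation], transcripts: Sequence[TranscriptModel], path) -> None:
    """Write genes (type ``gene``) and candidate transcripts (type ``transcript``)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            for line in _gff3_feature_lines(
                g.gene_id, "gene", g.scaffold_id, g.strand, g.span, g.exons,
                extra_attrs=f";biotype={g.biotype}",
            ):
                fh.write(line + "\n")
        for t in transcripts:
            strand = t.strand if t.strand in {"+", "-"} else "."
            for line in _gff3_feature_lines(
                t.transcript_id, "transcript", t.scaffold_id, strand, t.span, t.exons
            ):
                fh.write(line + "\n")


def read_gff3(
    path,
    genome: Optional[Mapping[str, str]] = None,
    biotype_filter: Optional[set] = None,
) -> tuple[list[GeneAnnotation], list[TranscriptModel]]:
    """Read a GFF3 file with a gene/transcript -> exon hierarchy.

    1-based closed coordinates are converted to internal 0-based half-open;
    exons are sorted by start. If ``genome`` (scaffold id -> sequence) is
    given, transcript spliced sequences are extracted (reverse-complemented
    for minus-strand models). An exon outside its parent span is a format
    error naming the feature.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##gff-version"):
        raise FormatError(f"{path}: missing ##gff-version directive")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    transcripts: list[TranscriptModel] = []
    for ftype in ("gene", "transcript", "mRNA"):
        for feat in db.features_of_type(ftype):
            span = (feat.start - 1, feat.end)
            exons = sorted(
                (ex.start - 1, ex.end) for ex in db.children(feat, featuretype="exon")
            )
            if not exons:
                exons = [span]
            for xs, xe in exons:
                if xs < span[0] or xe > span[1]:
                    raise FormatError(
                        f"{path}: exon ({xs + 1},{xe}) outside span of feature {feat.id}"
                    )
            if ftype == "gene":
                biotype = feat.attributes.get("biotype", ["protein_coding"])[0]
                if biotype_filter is not None and biotype not in biotype_filter:
                    continue
                genes.append(
                    GeneAnnotation(
                        gene_id=feat.id,
                        scaffold_id=feat.seqid,
                        strand=feat.strand if feat.strand in "+-" else "+",
                        span=span,
                        exons=list(exons),
                        biotype=biotype,
                    )
                )
            else:
                spliced = None
                if genome is not None:
                    if feat.seqid not in genome:
                        raise FormatError(
                            f"{path}: transcript {feat.id} on unknown scaffold {feat.seqid}"
                        )
                    scaffold_seq = genome[feat.seqid]
                    spliced = "".join(scaffold_seq[s:e] for s, e in exons)
                    if feat.strand == "-":
                        spliced = reverse_complement(spliced)
                transcripts.append(
                    TranscriptModel(
                        transcript_id=feat.id,
                        scaffold_id=feat.seqid,
                        exons=list(exons),
                        spliced_sequence=spliced,
                        strand=feat.strand if feat.strand in "+-" else ".",
                    )
                )
    return genes, transcripts


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def read_count_table(counts_path, library_meta_path) -> CountMatrix:
    """Read a transcripts x libraries TSV plus per-library metadata.

    The metadata TSV needs columns ``library_id``, ``group`` and
    ``total_mapped_reads``. Non-integer count cells and libraries missing
    from the metadata are format errors.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in df.columns:
        if df[col].dtype.kind not in "iu":
            raise FormatError(f"{counts_path}: column {col!r} has non-integer values")
    meta = pd.read_csv(library_meta_path, sep="\t", dtype={"library_id": str, "group": str})
    required = {"library_id", "group", "total_mapped_reads"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{library_meta_path}: metadata needs columns {sorted(required)}"
        )
    meta = meta.set_index("library_id")
    libraries = []
    for col in df.columns:
        if col not in meta.index:
            raise FormatError(f"library {col!r} in counts is missing from metadata")
        row = meta.loc[col]
        libraries.append(LibraryInfo(col, str(row["group"]), int(row["total_mapped_reads"])))
    df.index = df.index.astype(str)
    return CountMatrix(df, libraries)


def write_count_table(matrix: CountMatrix, counts_path, library_meta_path) -> None:
    df = matrix.counts.copy()
    df.index.name = "transcript_id"
    df.to_csv(counts_path, sep="\t")
    meta = pd.DataFrame(
        {
            "library_id": [lib.library_id for lib in matrix.libraries],
            "group": [lib.group for lib in matrix.libraries],
            "total_mapped_reads": [lib.total_mapped_reads for lib in matrix.libraries],
        }
    )
    meta.to_csv(library_meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Catalog export
# ---------------------------------------------------------------------------

def write_catalog(catalog: Sequence[TranscriptModel], path, format: str) -> None:
    """Write a lincRNA catalog as BED6, GFF3 or FASTA of spliced sequences."""
    fmt = format.upper()
    if fmt == "BED":
        with open(path, "w") as fh:
            for t in catalog:
                s, e = t.span
                strand = t.strand if t.strand in {"+", "-"} else "."
                fh.write(f"{t.scaffold_id}\t{s}\t{e}\t{t.transcript_id}\t0\t{strand}\n")
    elif fmt == "GFF3":
        write_gff3([], list(catalog), path)
    elif fmt == "FASTA":
        write_fasta(catalog, path)
    else:
        raise ValueError(f"unknown catalog format {format!r} (use BED, GFF3 or FASTA)")
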