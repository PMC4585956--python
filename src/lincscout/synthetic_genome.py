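"""Synthetic genome, annotation and count-matrix generator.

Emulates the study conditions the pipeline assumes: a multi-scaffold
genome carrying protein-coding genes whose CDS comes from a first-order
codon chain (strong hexamer/positional bias), intergenic noncoding loci
(GC below the coding average, longest ORF < 100 aa by construction, some
with embedded pre-miRNA copies), intergenic coding decoys, candidates
overlapping known genes, and an eight-library count matrix with two-group
structure, planted fold changes and negative-binomial overdispersion.
Everything is deterministic given the seed, and a ground-truth table makes
planted-truth recovery measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lincrna_identify import find_longest_orf
from .io_formats import reverse_complement
from .types import (
    ConfigurationError,
    CountMatrix,
    GeneAnnotation,
    GenomeSequence,
    LibraryInfo,
    TranscriptModel,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_LIBRARIES: tuple[tuple[str, int], ...] = (
    ("susceptible", 1_800_000),
    ("susceptible", 2_050_000),
    ("susceptible", 1_950_000),
    ("susceptible", 2_200_000),
    ("resistant", 1_900_000),
    ("resistant", 2_100_000),
    ("resistant", 2_000_000),
    ("resistant", 2_150_000),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the study conditions under test.

    ``gc_coding``/``gc_noncoding`` follow the reported GC averages of
    protein-coding genes (42.0%) and lincRNAs (36.9%). Eight libraries in
    two groups of four mirror the susceptible-vs-resistant design the
    expression filter ("three out of eight libraries") and the count test
    assume.
    """

    seed: int = 0
    n_scaffolds: int = 30
    scaffold_length: int = 400_000
    n_coding_genes: int = 300
    n_noncoding_loci: int = 200
    n_decoy_coding_transcripts: int = 100
    n_gene_overlap_candidates: int = 50
    gc_coding: float = 0.42
    gc_noncoding: float = 0.369
    noncoding_length_range: tuple[int, int] = (250, 3000)
    libraries: tuple[tuple[str, int], ...] = DEFAULT_LIBRARIES
    reference_group: str = "susceptible"
    de_fraction: float = 0.30
    planted_log2_fc: float = 3.0
    dispersion: float = 0.05
    n_mirna_embeds: int = 10
    baseline_mean_count: float = 80.0
    baseline_log_sigma: float = 0.6
    min_intergenic_gap: int = 1200
    n_training_per_class: int = 300

    def __post_init__(self) -> None:
        for name in ("gc_coding", "gc_noncoding", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        lo, hi = self.noncoding_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("noncoding_length_range must be positive and ordered")
        if self.scaffold_length <= 0 or self.n_scaffolds <= 0:
            raise ConfigurationError("scaffold dimensions must be positive")
        if self.n_mirna_embeds > self.n_noncoding_loci:
            raise ConfigurationError("n_mirna_embeds cannot exceed n_noncoding_loci")
        if self.n_gene_overlap_candidates > self.n_coding_genes:
            raise ConfigurationError("need at least one gene per gene-overlap candidate")
        groups: dict[str, int] = {}
        for grp, total in self.libraries:
            if total <= 0:
                raise ConfigurationError("library totals must be > 0")
            groups[grp] = groups.get(grp, 0) + 1
        if any(n < 2 for n in groups.values()):
            raise ConfigurationError("at least 2 libraries per group are required")
        if self.reference_group not in groups:
            raise ConfigurationError(f"reference_group {self.reference_group!r} has no libraries")


@dataclass
class TruthTable:
    """Ground truth for every generated candidate, plus the pre-miRNA set.

    ``table`` columns: transcript_id, truth_class ({lincRNA, coding_decoy,
    known_gene}), planted_de, true_log2_fc, embedded_mirna_id.
    """

    table: pd.DataFrame
    mirna_precursors: dict[str, str] = field(default_factory=dict)

    def ids(self, truth_class: Optional[str] = None) -> list[str]:
        t = self.table
        if truth_class is not None:
            t = t[t["truth_class"] == truth_class]
        return list(t["transcript_id"])

    def planted_de_ids(self) -> list[str]:
        t = self.table
        return list(t.loc[t["planted_de"], "transcript_id"])

    def embedded_pairs(self) -> set[tuple[str, str]]:
        t = self.table
        rows = t[t["embedded_mirna_id"].notna() & (t["embedded_mirna_id"] != "")]
        return {(r.transcript_id, r.embedded_mirna_id) for r in rows.itertuples()}


# ---------------------------------------------------------------------------
# Codon model (built-in usage vector + first-order chain)
# ---------------------------------------------------------------------------

_POS_WEIGHTS = (
    {"A": 0.35, "C": 0.18, "G": 0.28, "T": 0.19},
    {"A": 0.30, "C": 0.20, "G": 0.12, "T": 0.38},
    {"A": 0.12, "C": 0.25, "G": 0.30, "T": 0.33},
)
# mild preference for keeping/avoiding certain junction dinucleotides gives
# the chain genuine first-order (dicodon) structure
_JUNCTION_BOOST = {
    ("A", "A"): 1.6, ("T", "T"): 1.6, ("G", "C"): 1.4, ("C", "G"): 0.6,
}


def _codon_model() -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sense codons, stationary weights, and per-previous-last-base kernels."""
    stops = {"TAA", "TAG", "TGA"}
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in stops]
    w = np.array(
        [_POS_WEIGHTS[0][c[0]] * _POS_WEIGHTS[1][c[1]] * _POS_WEIGHTS[2][c[2]] for c in codons]
    )
    w /= w.sum()
    kernels = np.empty((4, len(codons)))
    for bi, prev_last in enumerate("ACGT"):
        boost = np.array([_JUNCTION_BOOST.get((prev_last, c[0]), 1.0) for c in codons])
        k = w * boost
        kernels[bi] = k / k.sum()
    return codons, w, kernels


_CODONS, _CODON_W, _CODON_KERNELS = _codon_model()
_BASE_TO_I = {"A": 0, "C": 1, "G": 2, "T": 3}


def _sample_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) codons from the first-order chain + a stop codon.

    The encoded peptide is exactly ``n_aa`` residues.
    """
    parts = ["ATG"]
    prev_last = "G"
    for _ in range(n_aa - 1):
        kernel = _CODON_KERNELS[_BASE_TO_I[prev_last]]
        codon = _CODONS[rng.choice(len(_CODONS), p=kernel)]
        parts.append(codon)
        prev_last = codon[-1]
    parts.append(["TAA", "TAG", "TGA"][rng.choice(3, p=[0.45, 0.25, 0.30])])
    return "".join(parts)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _noncoding_seq(
    rng: np.random.Generator, length: int, gc: float, max_aa: int = 99
) -> str:
    """Random sequence with longest ORF strictly below 100 aa (rejection)."""
    for _ in range(200):
        seq = _random_seq(rng, length, gc)
        if find_longest_orf(seq).aa_length <= max_aa:
            return seq
    raise ConfigurationError(
        f"could not sample a {length} nt noncoding sequence with ORF <= {max_aa} aa"
    )


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _split_into_exons(
    rng: np.random.Generator, spliced: str, start: int, n_exons: int, strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, str]]]:
    """Assign ``spliced`` to ``n_exons`` genomic exons beginning at ``start``.

    Returns (exon intervals, [(genomic offset, genomic exon sequence)]).
    For minus-strand features the genomic exon k (coordinate order) carries
    the reverse complement of spliced piece n-1-k.
    """
    n = len(spliced)
    if n_exons == 1:
        pieces = [spliced]
    else:
        cuts = sorted(rng.choice(np.arange(60, n - 60), size=n_exons - 1, replace=False))
        pieces = [spliced[a:b] for a, b in zip([0] + cuts, cuts + [n])]
    intervals: list[tuple[int, int]] = []
    paint: list[tuple[int, str]] = []
    pos = start
    genomic_pieces = (
        pieces if strand == "+" else [reverse_complement(p) for p in reversed(pieces)]
    )
    for i, gp in enumerate(genomic_pieces):
        intervals.append((pos, pos + len(gp)))
        paint.append((pos, gp))
        pos += len(gp)
        if i < len(genomic_pieces) - 1:
            pos += int(rng.integers(100, 400))
    return intervals, paint


def build_genome(
    config: SimulationConfig,
) -> tuple[list[GenomeSequence], list[GeneAnnotation], list[TranscriptModel], TruthTable]:
    """Generate the genome, gene annotation, candidate transcripts and truth.

    Noncoding truth loci are intergenic with more than 1 kb of clearance
    from every gene, GC near ``gc_noncoding`` and longest ORF < 100 aa;
    decoys are intergenic but coding-like with ORFs well above 100 aa;
    gene-overlap candidates straddle a known gene boundary. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 11])

    # --- plan features ----------------------------------------------------
    features: list[dict] = []
    for i in range(config.n_coding_genes):
        n_aa = int(rng.integers(120, 400))
        cds = _sample_cds(rng, n_aa)
        utr5 = _random_seq(rng, int(rng.integers(60, 200)), config.gc_coding)
        utr3 = _random_seq(rng, int(rng.integers(60, 250)), config.gc_coding)
        features.append(
            dict(kind="gene", name=f"gene_{i:04d}", spliced=utr5 + cds + utr3,
                 n_exons=int(rng.integers(1, 4)), strand="+" if rng.random() < 0.5 else "-")
        )
    lo, hi = config.noncoding_length_range
    mirna_targets = set(
        rng.choice(config.n_noncoding_loci, size=config.n_mirna_embeds, replace=False).tolist()
    )
    mirna_precursors: dict[str, str] = {}
    for i in range(config.n_noncoding_loci):
        length = int(rng.integers(max(lo, 200), hi + 1))
        seq = _noncoding_seq(rng, length, config.gc_noncoding)
        mirna_id = ""
        if i in mirna_targets:
            for _ in range(50):
                pre_len = int(rng.integers(70, 91))
                pre = _random_seq(rng, pre_len, 0.45)
                insert = pre if rng.random() < 0.5 else reverse_complement(pre)
                off = int(rng.integers(0, length - pre_len + 1))
                trial = seq[:off] + insert + seq[off + pre_len:]
                if find_longest_orf(trial).aa_length <= 99:
                    mirna_id = f"pre_mir_{len(mirna_precursors):03d}"
                    mirna_precursors[mirna_id] = pre
                    seq = trial
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise ConfigurationError("failed to embed pre-miRNA without creating a long ORF")
        features.append(
            dict(kind="lincRNA", name=f"linc_{i:04d}", spliced=seq,
                 n_exons=1 if rng.random() < 0.7 else 2,
                 strand="+" if rng.random() < 0.5 else "-", mirna_id=mirna_id)
        )
    for i in range(config.n_decoy_coding_transcripts):
        n_aa = int(rng.integers(105, 260))
        cds = _sample_cds(rng, n_aa)
        utr5 = _random_seq(rng, int(rng.integers(40, 120)), config.gc_coding)
        utr3 = _random_seq(rng, int(rng.integers(40, 120)), config.gc_coding)
        features.append(
            dict(kind="coding_decoy", name=f"decoy_{i:04d}", spliced=utr5 + cds + utr3,
                 n_exons=1, strand="+" if rng.random() < 0.5 else "-")
        )

    # --- assign features to scaffolds (shared propensities -> the gene /
    # lincRNA per-scaffold counts correlate, as in real assemblies) --------
    scaffold_ids = [f"scaffold_{i:03d}" for i in range(config.n_scaffolds)]
    weights = rng.dirichlet(np.full(config.n_scaffolds, 3.0))
    order = rng.permutation(len(features))
    per_scaffold: dict[str, list[dict]] = {sid: [] for sid in scaffold_ids}
    for fi in order:
        sid = scaffold_ids[int(rng.choice(config.n_scaffolds, p=weights))]
        per_scaffold[sid].append(features[fi])

    # --- place and paint --------------------------------------------------
    genomes: list[GenomeSequence] = []
    genes: list[GeneAnnotation] = []
    candidates: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    genes_for_overlap: list[tuple[GeneAnnotation, str]] = []

    for sid in scaffold_ids:
        arr = np.frombuffer(
            _random_seq(rng, config.scaffold_length, config.gc_noncoding).encode(), dtype=np.uint8
        ).copy()
        pos = 0
        for feat in per_scaffold[sid]:
            pos += int(rng.integers(config.min_intergenic_gap, config.min_intergenic_gap + 800))
            intervals, paint = _split_into_exons(
                rng, feat["spliced"], pos, feat["n_exons"], feat["strand"]
            )
            end = intervals[-1][1]
            if end > config.scaffold_length:
                raise ConfigurationError(
                    f"features do not fit on {sid} with the required intergenic gaps; "
                    "increase scaffold_length or n_scaffolds"
                )
            for off, piece in paint:
                arr[off : off + len(piece)] = np.frombuffer(piece.encode(), dtype=np.uint8)
            pos = end
            if feat["kind"] == "gene":
                gene = GeneAnnotation(
                    gene_id=feat["name"], scaffold_id=sid, strand=feat["strand"],
                    span=(intervals[0][0], intervals[-1][1]), exons=intervals,
                    biotype="protein_coding",
                )
                genes.append(gene)
                genes_for_overlap.append((gene, sid))
            else:
                candidates.append(
                    TranscriptModel(
                        transcript_id=feat["name"], scaffold_id=sid, exons=intervals,
                        spliced_sequence=feat["spliced"], strand=feat["strand"],
                    )
                )
                truth_rows.append(
                    dict(
                        transcript_id=feat["name"],
                        truth_class=feat["kind"],
                        planted_de=False,
                        true_log2_fc=0.0,
                        embedded_mirna_id=feat.get("mirna_id", ""),
                    )
                )
        genomes.append(GenomeSequence(sid, arr.tobytes().decode()))

    # minus-strand single/multi-exon candidates: spliced sequence must equal
    # the reverse complement of the concatenated genomic exons, which is how
    # they were painted; rebuild from the genome to keep the contract exact.
    genome_map = {g.scaffold_id: g.sequence for g in genomes}
    for i, cand in enumerate(candidates):
        concat = "".join(genome_map[cand.scaffold_id][s:e] for s, e in cand.exons)
        spliced = reverse_complement(concat) if cand.strand == "-" else concat
        candidates[i] = replace_spliced(cand, spliced)

    # --- gene-overlap candidates ------------------------------------------
    chosen = rng.choice(len(genes_for_overlap), size=config.n_gene_overlap_candidates, replace=False)
    for j, gi in enumerate(sorted(int(x) for x in chosen)):
        gene, sid = genes_for_overlap[gi]
        gs, ge = gene.span
        left = int(rng.integers(100, 301))
        right = int(rng.integers(100, 301))
        ex = (max(0, gs - left), min(ge, gs + right))
        seq = genome_map[sid][ex[0] : ex[1]]
        name = f"ovl_{j:04d}"
        candidates.append(
            TranscriptModel(transcript_id=name, scaffold_id=sid, exons=[ex],
                            spliced_sequence=seq, strand="+")
        )
        truth_rows.append(
            dict(transcript_id=name, truth_class="known_gene", planted_de=False,
                 true_log2_fc=0.0, embedded_mirna_id="")
        )

    # --- anonymize candidate ids so class labels cannot leak downstream ---
    perm = rng.permutation(len(candidates))
    renames = {}
    for new_i, old_i in enumerate(perm):
        renames[candidates[int(old_i)].transcript_id] = f"cand_{new_i:05d}"
    candidates = [replace_id(c, renames[c.transcript_id]) for c in candidates]
    for row in truth_rows:
        row["transcript_id"] = renames[row["transcript_id"]]

    truth_df = pd.DataFrame(truth_rows).sort_values("transcript_id").reset_index(drop=True)

    # --- plant differential expression on lincRNA truths ------------------
    linc_ids = list(truth_df.loc[truth_df["truth_class"] == "lincRNA", "transcript_id"])
    n_de = int(round(config.de_fraction * len(linc_ids)))
    if n_de:
        de_ids = set(
            np.array(linc_ids)[rng.choice(len(linc_ids), size=n_de, replace=False)].tolist()
        )
        signs = {tid: (1.0 if rng.random() < 0.5 else -1.0) for tid in sorted(de_ids)}
        truth_df["planted_de"] = truth_df["transcript_id"].isin(de_ids)
        truth_df["true_log2_fc"] = [
            signs[tid] * config.planted_log2_fc if tid in signs else 0.0
            for tid in truth_df["transcript_id"]
        ]

    candidates.sort(key=lambda t: t.transcript_id)
    truth = TruthTable(truth_df, mirna_precursors)
    return genomes, genes, candidates, truth


def replace_spliced(t: TranscriptModel, spliced: str) -> TranscriptModel:
    return TranscriptModel(t.transcript_id, t.scaffold_id, list(t.exons), spliced, t.strand)


def replace_id(t: TranscriptModel, new_id: str) -> TranscriptModel:
    return TranscriptModel(new_id, t.scaffold_id, list(t.exons), t.spliced_sequence, t.strand)


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def simulate_counts(config: SimulationConfig, truth: TruthTable) -> CountMatrix:
    """Negative-binomial library counts around group means.

    Per-locus baseline abundance is lognormal (median
    ``baseline_mean_count`` reads at average depth); non-reference groups
    of planted loci differ by ``2**true_log2_fc``; library means scale
    with recorded depth. Counts are gamma-Poisson draws with
    ``Var = mu + dispersion * mu**2``. Deterministic given the seed.
    """
    if config.dispersion <= 0:
        raise ConfigurationError("dispersion must be > 0")
    rng = np.random.default_rng([config.seed, 7919])
    ids = list(truth.table["transcript_id"])
    lfc = truth.table["true_log2_fc"].to_numpy(dtype=float)
    m = len(ids)
    totals = np.array([t for _, t in config.libraries], dtype=float)
    groups = [g for g, _ in config.libraries]
    depth = totals / totals.mean()
    baseline = rng.lognormal(math.log(config.baseline_mean_count), config.baseline_log_sigma, m)
    effect = np.where(
        np.array([g != config.reference_group for g in groups])[None, :],
        2.0 ** lfc[:, None],
        1.0,
    )
    mu = baseline[:, None] * depth[None, :] * effect
    phi = config.dispersion
    lam = rng.gamma(1.0 / phi, phi * mu)
    counts = rng.poisson(lam).astype(np.int64)
    lib_counts: dict[str, int] = {}
    libraries = []
    colsums = counts.sum(axis=0)
    for j, (grp, total) in enumerate(config.libraries):
        k = lib_counts.get(grp, 0)
        lib_counts[grp] = k + 1
        libraries.append(LibraryInfo(f"{grp}_{k + 1}", grp, int(max(total, colsums[j]))))
    df = pd.DataFrame(counts, index=ids, columns=[lib.library_id for lib in libraries])
    df.index.name = "transcript_id"
    return CountMatrix(df, libraries)


def null_truth_table(n_loci: int) -> TruthTable:
    """A truth table of unplanted lincRNA loci, for calibration studies."""
    df = pd.DataFrame(
        {
            "transcript_id": [f"null_{i:05d}" for i in range(n_loci)],
            "truth_class": "lincRNA",
            "planted_de": False,
            "true_log2_fc": 0.0,
            "embedded_mirna_id": "",
        }
    )
    return TruthTable(df)


# ---------------------------------------------------------------------------
# Classifier training material
# ---------------------------------------------------------------------------

def generate_coding_training_set(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Held-out (coding, noncoding) training sequences for the classifier.

    Drawn from the same codon chain and noncoding composition as the
    genome but from an independent random stream, so training never leaks
    candidate loci.
    """
    rng = np.random.default_rng([config.seed, 104729])
    n = config.n_training_per_class
    coding = []
    for i in range(n):
        n_aa = int(rng.integers(110, 380))
        cds = _sample_cds(rng, n_aa)
        utr5 = _random_seq(rng, int(rng.integers(40, 150)), config.gc_coding)
        utr3 = _random_seq(rng, int(rng.integers(40, 150)), config.gc_coding)
        coding.append((f"train_cod_{i:04d}", utr5 + cds + utr3))
    lo, hi = config.noncoding_length_range
    noncoding = [
        (
            f"train_non_{i:04d}",
            _noncoding_seq(rng, int(rng.integers(max(lo, 200), hi + 1)), config.gc_noncoding),
        )
        for i in range(n)
    ]
    return coding, noncoding
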