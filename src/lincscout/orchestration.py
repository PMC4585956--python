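"""End-to-end orchestration: simulate -> identify -> de -> characterize.

A run is driven by a flat key=value config file whose defaults are the
published thresholds of the workflow (1 kb distance, 100 aa ORF cap, 0.3
coding probability, >10 reads in >=3 libraries, fold change 4, alpha
0.05). Every run writes a machine-readable manifest with SHA-256 digests
of all outputs; identical config and seed reproduce identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, characterize, expression_de, io_formats, synthetic_genome
from .lincrna_identify import IdentifyConfig, run_identification
from .synthetic_genome import SimulationConfig
from .types import ConfigurationError, FormatError, sequences_by_id

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEConfig:
    fc_threshold: float = 4.0
    alpha: float = 0.05
    min_reads: int = 10
    pseudocount: float = 0.1


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    identify: IdentifyConfig = dataclasses.field(default_factory=IdentifyConfig)
    de: DEConfig = dataclasses.field(default_factory=DEConfig)


_TEMPLATE_NOTES = {
    "min_gap_bp": "candidates must lie strictly more than this many bp from any known gene",
    "max_orf_aa": "candidates with a longest ORF above this many amino acids are discarded",
    "coding_prob_threshold": "coding probability at or above this value is called coding",
    "min_reads": "expression filter: a library counts when it has strictly more reads than this",
    "min_libraries": "expression filter: minimum number of qualifying libraries",
    "fc_threshold": "differential expression requires fold change strictly above this",
    "alpha": "differential expression requires a raw p-value below this",
    "de_min_reads": "DE reads rule: at least one library in either group at or above this count",
}


def _libraries_to_str(libraries) -> str:
    return ",".join(f"{g}:{t}" for g, t in libraries)


def _libraries_from_str(text: str):
    pairs = []
    for item in text.split(","):
        group, total = item.strip().rsplit(":", 1)
        pairs.append((group, int(total)))
    return tuple(pairs)


def write_config_template(path, config: Optional[RunConfig] = None) -> None:
    """Write a commented flat key=value config with the default thresholds."""
    cfg = config or RunConfig()
    lines = ["# lincscout run configuration (flat key = value)"]
    lines.append("\n# --- simulation ---")
    for f in dataclasses.fields(SimulationConfig):
        value = getattr(cfg.simulation, f.name)
        if f.name == "libraries":
            value = _libraries_to_str(value)
        elif f.name == "noncoding_length_range":
            value = f"{value[0]}:{value[1]}"
        lines.append(f"{f.name} = {value}")
    lines.append("\n# --- identification thresholds ---")
    for f in dataclasses.fields(IdentifyConfig):
        note = _TEMPLATE_NOTES.get(f.name)
        if note:
            lines.append(f"# {note}")
        lines.append(f"{f.name} = {getattr(cfg.identify, f.name)}")
    lines.append("\n# --- differential expression ---")
    for f in dataclasses.fields(DEConfig):
        key = "de_min_reads" if f.name == "min_reads" else f.name
        note = _TEMPLATE_NOTES.get(key)
        if note:
            lines.append(f"# {note}")
        lines.append(f"{key} = {getattr(cfg.de, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_config(path) -> RunConfig:
    """Parse a flat key=value config file into a :class:`RunConfig`."""
    values: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}: cannot parse line {raw!r}")
        key, val = line.split("=", 1)
        values[key.strip()] = val.strip()
    return config_from_mapping(values, source=str(path))


def config_from_mapping(values: dict, source: str = "<config>") -> RunConfig:
    sim_kwargs = {}
    for f in dataclasses.fields(SimulationConfig):
        if f.name not in values:
            continue
        raw = values.pop(f.name)
        if f.name == "libraries":
            sim_kwargs[f.name] = _libraries_from_str(raw)
        elif f.name == "noncoding_length_range":
            lo, hi = raw.split(":")
            sim_kwargs[f.name] = (int(lo), int(hi))
        elif f.type in ("int", int):
            sim_kwargs[f.name] = int(raw)
        elif f.type in ("float", float):
            sim_kwargs[f.name] = float(raw)
        else:
            sim_kwargs[f.name] = raw
    id_kwargs = {}
    for f in dataclasses.fields(IdentifyConfig):
        if f.name in values:
            raw = values.pop(f.name)
            id_kwargs[f.name] = float(raw) if "." in raw or "e" in raw else int(raw)
    de_kwargs = {}
    for f in dataclasses.fields(DEConfig):
        key = "de_min_reads" if f.name == "min_reads" else f.name
        if key in values:
            raw = values.pop(key)
            de_kwargs[f.name] = float(raw) if f.type in ("float", float) else int(raw)
    if values:
        raise ConfigurationError(f"{source}: unknown config keys {sorted(values)}")
    return RunConfig(
        simulation=SimulationConfig(**sim_kwargs),
        identify=IdentifyConfig(**id_kwargs),
        de=DEConfig(**de_kwargs),
    )


# ---------------------------------------------------------------------------
# Stage runners (each writes fixed-name outputs under out_dir)
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    sim = config.simulation
    genomes, genes, candidates, truth = synthetic_genome.build_genome(sim)
    counts = synthetic_genome.simulate_counts(sim, truth)
    coding_train, noncoding_train = synthetic_genome.generate_coding_training_set(sim)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome.fasta": lambda p: io_formats.write_fasta(genomes, p),
        "annotation.gff3": lambda p: io_formats.write_gff3(genes, [], p),
        "candidates.gff3": lambda p: io_formats.write_gff3([], candidates, p),
        "counts.tsv": None,
        "library_meta.tsv": None,
        "truth.tsv": lambda p: truth.table.to_csv(p, sep="\t", index=False),
        "premirna.fasta": lambda p: io_formats.write_fasta(truth.mirna_precursors, p),
        "train_coding.fasta": lambda p: io_formats.write_fasta(coding_train, p),
        "train_noncoding.fasta": lambda p: io_formats.write_fasta(noncoding_train, p),
    }
    io_formats.write_count_table(
        counts, out_dir / "counts.tsv", out_dir / "library_meta.tsv"
    )
    for name, writer in paths.items():
        if writer is not None:
            writer(out_dir / name)
    return [out_dir / name for name in paths]


def run_identify(config: RunConfig, out_dir: Path) -> list[Path]:
    genome = sequences_by_id(io_formats.read_fasta(out_dir / "genome.fasta"))
    genes, _ = io_formats.read_gff3(out_dir / "annotation.gff3")
    _, candidates = io_formats.read_gff3(out_dir / "candidates.gff3", genome=genome)
    counts = io_formats.read_count_table(out_dir / "counts.tsv", out_dir / "library_meta.tsv")
    coding_train = [r.sequence for r in io_formats.read_fasta(out_dir / "train_coding.fasta")]
    noncoding_train = [r.sequence for r in io_formats.read_fasta(out_dir / "train_noncoding.fasta")]
    result = run_identification(
        candidates, genes, counts, coding_train, noncoding_train, config.identify
    )
    outputs = []
    for fmt, name in (("BED", "catalog.bed"), ("GFF3", "catalog.gff3"), ("FASTA", "catalog.fasta")):
        io_formats.write_catalog(result.catalog, out_dir / name, fmt)
        outputs.append(out_dir / name)
    feats = pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "orf_size_nt": cp.orf_size_nt,
                "orf_coverage": cp.orf_coverage,
                "fickett": cp.fickett,
                "hexamer_bias": cp.hexamer_bias,
                "coding_probability": cp.coding_probability,
            }
            for tid, cp in sorted(result.features.items())
        ]
    )
    feats.to_csv(out_dir / "features.tsv", sep="\t", index=False)
    result.report.to_frame().to_csv(out_dir / "stage_report.tsv", sep="\t", index=False)
    result.model.save(out_dir / "coding_model.json")
    outputs += [out_dir / "features.tsv", out_dir / "stage_report.tsv", out_dir / "coding_model.json"]
    return outputs


def run_de(config: RunConfig, out_dir: Path) -> list[Path]:
    counts = io_formats.read_count_table(out_dir / "counts.tsv", out_dir / "library_meta.tsv")
    genome = sequences_by_id(io_formats.read_fasta(out_dir / "genome.fasta"))
    _, catalog = io_formats.read_gff3(out_dir / "catalog.gff3", genome=genome)
    rpkm = expression_de.compute_rpkm(counts, _all_lengths(counts, catalog))
    catalog_ids = [t.transcript_id for t in catalog]
    reference = config.simulation.reference_group
    others = [g for g in counts.groups if g != reference]
    frames = []
    results_by_contrast = {}
    for group in others:
        res = expression_de.call_de(
            catalog_ids, counts, rpkm, (reference, group),
            fc_threshold=config.de.fc_threshold, alpha=config.de.alpha,
            min_reads=config.de.min_reads, pseudocount=config.de.pseudocount,
        )
        results_by_contrast[group] = res
        frames.append(expression_de.de_results_frame(res))
    de_frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    de_frame.to_csv(out_dir / "de_results.tsv", sep="\t", index=False)
    summary = expression_de.summarize_overlaps(results_by_contrast)
    with open(out_dir / "overlaps.tsv", "w") as fh:
        fh.write("set\tn_de\tn_up\tn_down\n")
        for name, (n_de, n_up, n_down) in summary.per_contrast.items():
            fh.write(f"{name}\t{n_de}\t{n_up}\t{n_down}\n")
        for (a, b), n in summary.pairwise.items():
            fh.write(f"{a}&{b}\t{n}\t\t\n")
        if len(summary.per_contrast) > 1:
            fh.write(f"all\t{summary.all_way}\t\t\n")
    rpkm_out = rpkm.loc[catalog_ids]
    rpkm_out.index.name = "transcript_id"
    rpkm_out.to_csv(out_dir / "rpkm.tsv", sep="\t")
    return [out_dir / "de_results.tsv", out_dir / "overlaps.tsv", out_dir / "rpkm.tsv"]


def _all_lengths(counts, catalog) -> dict[str, int]:
    # every transcript in the count table needs a length; candidates absent
    # from the catalog never enter RPKM reporting, so any positive length is
    # inert for them -- but the catalog lengths must be exact.
    lengths = {t: 1 for t in counts.transcript_ids}
    lengths.update(expression_de.catalog_lengths(catalog))
    return lengths


def run_characterize(config: RunConfig, out_dir: Path) -> list[Path]:
    genome = sequences_by_id(io_formats.read_fasta(out_dir / "genome.fasta"))
    genes, _ = io_formats.read_gff3(out_dir / "annotation.gff3")
    _, catalog = io_formats.read_gff3(out_dir / "catalog.gff3", genome=genome)
    rpkm = pd.read_csv(out_dir / "rpkm.tsv", sep="\t", index_col=0)

    gc_series, gc_mean = characterize.gc_content(sequences_by_id(catalog))
    gc_df = gc_series.rename_axis("transcript_id").reset_index()
    gc_df.to_csv(out_dir / "gc.tsv", sep="\t", index=False)

    lengths = pd.DataFrame(
        {"transcript_id": [t.transcript_id for t in catalog],
         "length_bp": [t.length for t in catalog]}
    )
    lengths.to_csv(out_dir / "lengths.tsv", sep="\t", index=False)

    summaries = characterize.scaffold_summary(catalog, genes)
    characterize.summaries_frame(summaries).to_csv(
        out_dir / "scaffold_summary.tsv", sep="\t", index=False
    )

    neighbors = characterize.nearest_neighbor(catalog, genes)
    pd.DataFrame(
        {
            "lincrna_id": [n.lincrna_id for n in neighbors],
            "gene_id": [n.gene_id for n in neighbors],
            "distance_bp": [n.distance for n in neighbors],
            "side": [n.side for n in neighbors],
            "tie": [n.tie for n in neighbors],
        }
    ).to_csv(out_dir / "neighbors.tsv", sep="\t", index=False)

    outputs = [out_dir / "gc.tsv", out_dir / "lengths.tsv",
               out_dir / "scaffold_summary.tsv", out_dir / "neighbors.tsv"]

    premirna_path = out_dir / "premirna.fasta"
    if premirna_path.exists() and premirna_path.stat().st_size > 0:
        precursors = sequences_by_id(io_formats.read_fasta(premirna_path))
        hits = characterize.mirna_precursor_search(precursors, catalog)
        pd.DataFrame(
            {
                "lincrna_id": [h.lincrna_id for h in hits],
                "precursor_id": [h.precursor_id for h in hits],
                "strand": [h.strand for h in hits],
                "identity": [h.identity for h in hits],
                "coverage": [h.coverage for h in hits],
                "score": [h.score for h in hits],
            }
        ).to_csv(out_dir / "mirna_hits.tsv", sep="\t", index=False)
        outputs.append(out_dir / "mirna_hits.tsv")
    return outputs


# ---------------------------------------------------------------------------
# run_all + validation
# ---------------------------------------------------------------------------

_STAGES = (
    ("simulate", run_simulate),
    ("identify", run_identify),
    ("de", run_de),
    ("characterize", run_characterize),
)


def run_all(config: RunConfig, out_dir, seed: Optional[int] = None) -> tuple[int, dict]:
    """Run all stages in order; returns (exit_status, manifest).

    The manifest is written to ``out_dir/manifest.json`` regardless of
    failure and records per-stage output digests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config = RunConfig(
            simulation=dataclasses.replace(config.simulation, seed=seed),
            identify=config.identify,
            de=config.de,
        )
    config_text = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    manifest = {
        "tool": "lincscout",
        "version": __version__,
        "seed": config.simulation.seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "stages": [],
    }
    status = 0
    for name, runner in _STAGES:
        entry = {"name": name, "status": "skipped", "outputs": {}}
        try:
            outputs = runner(config, out_dir)
        except Exception as exc:  # noqa: BLE001 - stage failures are reported, not raised
            entry["status"] = "failed"
            entry["error"] = str(exc)
            manifest["stages"].append(entry)
            log.error("stage %s failed: %s", name, exc)
            status = 1
            break
        entry["status"] = "completed"
        entry["outputs"] = {p.name: _sha256(p) for p in outputs}
        manifest["stages"].append(entry)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return status, manifest


def validate_inputs(
    genome_path=None, annotation_path=None, candidates_path=None,
    counts_path=None, library_meta_path=None,
) -> list[str]:
    """Cross-check input files; returns a (possibly empty) problem list.

    Never mutates inputs; each problem is one human-readable line.
    """
    problems: list[str] = []
    genome = None
    if genome_path is not None:
        try:
            genome = sequences_by_id(io_formats.read_fasta(genome_path))
        except (FormatError, OSError) as exc:
            problems.append(f"genome: {exc}")
    annotations = []
    if annotation_path is not None:
        try:
            annotations, _ = io_formats.read_gff3(annotation_path)
            if genome is not None:
                for g in annotations:
                    if g.scaffold_id not in genome:
                        problems.append(f"annotation: gene {g.gene_id} on unknown scaffold {g.scaffold_id}")
                    elif g.span[1] > len(genome[g.scaffold_id]):
                        problems.append(f"annotation: gene {g.gene_id} extends past scaffold end")
        except (FormatError, OSError, ValueError) as exc:
            problems.append(f"annotation: {exc}")
    candidates = []
    if candidates_path is not None:
        try:
            _, candidates = io_formats.read_gff3(candidates_path)
            if genome is not None:
                for t in candidates:
                    if t.scaffold_id not in genome:
                        problems.append(
                            f"candidates: transcript {t.transcript_id} on unknown scaffold {t.scaffold_id}"
                        )
        except (FormatError, OSError, ValueError) as exc:
            problems.append(f"candidates: {exc}")
    if counts_path is not None and library_meta_path is not None:
        try:
            counts = io_formats.read_count_table(counts_path, library_meta_path)
            if candidates:
                known = set(counts.transcript_ids)
                cand_ids = {t.transcript_id for t in candidates}
                for tid in sorted(known - cand_ids):
                    problems.append(f"counts: transcript {tid} not among candidates")
                for t in sorted(cand_ids - known):
                    problems.append(f"counts: candidate {t} has no count row")
        except (FormatError, OSError, ValueError) as exc:
            problems.append(f"counts: {exc}")
    return problems
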