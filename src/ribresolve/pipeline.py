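"""End-to-end run orchestration: genomes in, resolvability reports out.

Per-genome work (gene extraction and in-silico PCR) is independent, so it
can be dispatched to a worker pool; results are assembled in genome order
and the outputs are byte-identical for any worker count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alleles import (
    build_allele_matrix,
    dereplicate,
    fmt_pct,
    species_overlap,
    write_reports,
)
from .errors import EmptyResultError, InputFormatError
from .genes import (
    UNSPECIFIED,
    GenomeRecord,
    genes_by_anchoring,
    genes_from_gff,
    length_filter,
    parse_organism,
)
from .io import read_fasta, read_gff3, read_metadata
from .ispcr import (
    BUILTIN_PRIMERS,
    Amplicon,
    MatchTolerance,
    PrimerPair,
    amplify,
    load_primer_pairs,
)

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = (".fa", ".fasta", ".fna")


@dataclass
class RunConfig:
    """Every effective parameter of a run; echoed verbatim into summary.json."""

    genomes_dir: str
    out_dir: str
    gff_dir: str | None = None
    metadata: str | None = None
    primers: str = "V3V4"  # builtin name or path to a 3-column TSV
    tolerance: MatchTolerance = field(default_factory=MatchTolerance)
    min_fraction: float = 0.9
    reference_length: int = 1550
    min_product: int = 50
    max_product: int = 3000
    anchor_min: int = 1200
    anchor_max: int = 2000
    trim_primers: bool = False
    allow_empty: bool = False
    workers: int = 1
    make_plots: bool = False
    seed: int = 0
    log_level: str = "INFO"


def resolve_primers(selection: str) -> PrimerPair:
    """Map a --primers value to a pair: builtin name or first row of a TSV."""
    if selection in BUILTIN_PRIMERS:
        return BUILTIN_PRIMERS[selection]
    path = Path(selection)
    if not path.exists():
        raise InputFormatError(
            f"--primers must be one of {sorted(BUILTIN_PRIMERS)} or an "
            f"existing TSV file, got {selection!r}"
        )
    pairs = load_primer_pairs(path)
    if len(pairs) > 1:
        logger.info("primer file has %d pairs; using the first (%s)",
                    len(pairs), pairs[0].name)
    return pairs[0]


def _discover_genomes(genomes_dir: Path) -> list[Path]:
    files = sorted(
        p for p in genomes_dir.iterdir()
        if p.suffix.lower() in _FASTA_SUFFIXES and p.is_file()
    )
    return files


def _load_genome(path: Path, metadata: dict[str, str] | None) -> GenomeRecord:
    genome_id = path.stem
    records = read_fasta(path)
    contigs = {rid: seq for rid, _desc, seq in records}
    organism = None
    if metadata and genome_id in metadata:
        organism = metadata[genome_id]
    else:
        desc = records[0][1]
        if desc.strip():
            organism = desc
    if organism:
        genus, species = parse_organism(organism)
    else:
        logger.warning("genome %s: no organism name; treating as unclassified",
                       genome_id)
        genus, species = "NA", UNSPECIFIED
    return GenomeRecord(genome_id, genus, species, contigs)


def _gff_for(genome_id: str, gff_dir: Path | None) -> Path | None:
    if gff_dir is None:
        return None
    for suffix in (".gff", ".gff3"):
        p = gff_dir / f"{genome_id}{suffix}"
        if p.exists():
            return p
    return None


def _process_genome(args: tuple) -> tuple[str, int, list[Amplicon]]:
    """Extract genes and amplify for one genome (worker entry point)."""
    fasta_path, gff_path, metadata, cfg_dict = args
    config = RunConfig(**{**cfg_dict, "tolerance": MatchTolerance(*cfg_dict["tolerance"])})
    genome = _load_genome(Path(fasta_path), metadata)
    if gff_path is not None:
        genes = genes_from_gff(genome, read_gff3(gff_path))
    else:
        genes = genes_by_anchoring(
            genome, tol=config.tolerance,
            min_len=config.anchor_min, max_len=config.anchor_max,
        )
    genes = length_filter(genes, config.min_fraction, config.reference_length)
    pair = resolve_primers(config.primers)
    amplicons: list[Amplicon] = []
    for gene in genes:
        amplicons.extend(
            amplify(
                gene.sequence, pair, config.tolerance,
                max_len=config.max_product, min_len=config.min_product,
                trim_primers=config.trim_primers,
                genome_id=genome.genome_id,
                contig_id=f"{gene.contig_id}|{gene.start}-{gene.end}{gene.strand}",
            )
        )
    return genome.genome_id, len(genes), amplicons


def run_pipeline(config: RunConfig) -> dict:
    """Execute extraction -> PCR -> dereplication -> reports; return the summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    genomes_dir = Path(config.genomes_dir)
    if not genomes_dir.is_dir():
        raise InputFormatError(f"genomes directory not found: {genomes_dir}")
    fasta_files = _discover_genomes(genomes_dir)
    if not fasta_files:
        raise InputFormatError(f"no FASTA genomes (*.fa/*.fasta/*.fna) in {genomes_dir}")
    metadata = read_metadata(config.metadata) if config.metadata else None
    gff_dir = Path(config.gff_dir) if config.gff_dir else None
    resolve_primers(config.primers)  # fail fast on a bad selection

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["tolerance"] = (
        config.tolerance.max_mismatch,
        config.tolerance.max_insertion,
        config.tolerance.max_deletion,
    )
    jobs = [
        (str(p), _gff_for(p.stem, gff_dir) and str(_gff_for(p.stem, gff_dir)),
         metadata, cfg_dict)
        for p in fasta_files
    ]

    if config.workers > 1:
        from multiprocessing import Pool

        with Pool(config.workers) as pool:
            results = pool.map(_process_genome, jobs)
    else:
        results = [_process_genome(job) for job in jobs]

    genomes = [_load_genome(p, metadata) for p in fasta_files]
    per_genome: dict[str, dict[str, int]] = {}
    amplicons: list[Amplicon] = []
    for (gid, n_genes, amps), genome in zip(results, genomes):
        per_genome[gid] = {"genes": n_genes, "amplicons": len(amps)}
        logger.info("genome %s: %d genes, %d amplicons", gid, n_genes, len(amps))
        if not amps:
            logger.warning("genome %s yielded zero amplicons; kept as empty row", gid)
        amplicons.extend(amps)
    amplicons.sort(key=lambda a: (a.genome_id, a.contig_id, a.start, a.end, a.strand))

    if not amplicons and not config.allow_empty:
        raise EmptyResultError(
            "no amplicons produced from any genome (use --allow-empty to "
            "write empty reports instead)"
        )

    clusters = dereplicate(amplicons)
    matrix = build_allele_matrix(clusters, genomes)
    report = species_overlap(matrix)
    out_dir = Path(config.out_dir)
    write_reports(matrix, report, out_dir, clusters=clusters,
                  make_plots=config.make_plots)

    summary = {
        "version": __version__,
        "config": cfg_dict,
        "n_genomes": len(genomes),
        "n_named_species": report.n_named_species,
        "per_genome": per_genome,
        "n_amplicons": len(amplicons),
        "n_alleles": len(clusters),
        "multiplicity_pct": report.multiplicity_pct,
        "multiplicity_pct_2dp": fmt_pct(report.multiplicity_pct),
        "overlap_pct": report.overlap_pct,
        "overlap_pct_2dp": fmt_pct(report.overlap_pct),
        "indistinguishable_groups": [sorted(g) for g in report.indistinguishable_groups],
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
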