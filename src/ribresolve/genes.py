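"""Obtain candidate 16S rRNA genes per genome and apply the length filter.

Two extraction routes are supported: ingesting rRNA annotations from a
GFF3 file (Barrnap/NCBI dialect — features of type ``rRNA`` whose Name or
product attribute mentions "16S"), or anchoring directly on the genome
with the near-full-length V1V9 primer pair when no annotation is
available.  Genes shorter than 90% of a configurable reference full
length (default 1550 nt, the canonical 16S size) are discarded before
amplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputFormatError
from .io import GffFeature, read_gff3
from .ispcr import (
    BUILTIN_PRIMERS,
    MatchTolerance,
    PrimerPair,
    amplify,
    normalize_sequence,
    reverse_complement,
)

#: Sentinel species label for genomes classified only to genus ("sp.").
UNSPECIFIED = "unclassified"


@dataclass
class GenomeRecord:
    """One genome assembly: identifier, taxonomy labels and contigs."""

    genome_id: str
    genus: str
    species: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contigs = {
            cid: normalize_sequence(seq) for cid, seq in self.contigs.items()
        }
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(
                    f"contig {cid!r} of genome {self.genome_id!r} is empty"
                )


@dataclass(frozen=True)
class RrnaGene:
    """One candidate 16S gene, sequence in gene (5'->3') orientation."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    source: str  # "gff" or "anchored"

    @property
    def length(self) -> int:
        return self.end - self.start


def parse_organism(header_or_name: str) -> tuple[str, str]:
    """Split an organism name into (genus, species).

    The genus is the first whitespace token; the species epithet is the
    second, unless it is a placeholder ("sp.", "sp", "bacterium") or
    absent, in which case the UNSPECIFIED sentinel is returned.  Strain
    and subspecies tokens are ignored.
    """
    if not header_or_name or not header_or_name.strip():
        raise ValueError("empty organism name")
    tokens = header_or_name.split()
    genus = tokens[0]
    if len(tokens) < 2:
        return genus, UNSPECIFIED
    epithet = tokens[1]
    if epithet.lower().rstrip(".") in {"sp", "bacterium"}:
        return genus, UNSPECIFIED
    return genus, epithet


def genes_from_gff(genome: GenomeRecord, gff) -> list[RrnaGene]:
    """Extract 16S genes from GFF3 annotations of ``genome``.

    ``gff`` may be a list of ``GffFeature`` objects or raw GFF3 lines.
    1-based inclusive coordinates become 0-based half-open; "-"-strand
    features are reverse-complemented into gene orientation.
    """
    if gff and not isinstance(gff[0], GffFeature):
        gff = read_gff3(list(gff), label=f"<gff:{genome.genome_id}>")
    genes: list[RrnaGene] = []
    for feat in gff:
        if feat.type.lower() != "rrna":
            continue
        blob = (feat.attributes.get("Name", "") + " " +
                feat.attributes.get("product", "")).lower()
        if "16s" not in blob:
            continue
        if feat.seqid not in genome.contigs:
            raise InputFormatError(
                f"GFF feature at line {feat.line_no}: contig {feat.seqid!r} "
                f"not present in genome {genome.genome_id!r}"
            )
        contig = genome.contigs[feat.seqid]
        if feat.end > len(contig):
            raise InputFormatError(
                f"GFF feature at line {feat.line_no} ({feat.seqid}:"
                f"{feat.start}-{feat.end}) exceeds contig length {len(contig)}"
            )
        start, end = feat.start - 1, feat.end
        seq = contig[start:end]
        if feat.strand == "-":
            seq = reverse_complement(seq)
        genes.append(
            RrnaGene(genome.genome_id, feat.seqid, start, end,
                     feat.strand if feat.strand in "+-" else "+", seq, "gff")
        )
    return genes


def genes_by_anchoring(
    genome: GenomeRecord,
    v1v9: PrimerPair | None = None,
    tol: MatchTolerance | None = None,
    min_len: int = 1200,
    max_len: int = 2000,
) -> list[RrnaGene]:
    """Find 16S genes by amplifying whole contigs with the V1V9 pair.

    The product window [1200, 2000] nt brackets plausible near-full-length
    16S genes and excludes run-on products spanning neighbouring copies.
    """
    v1v9 = v1v9 or BUILTIN_PRIMERS["V1V9"]
    tol = tol or MatchTolerance()
    genes: list[RrnaGene] = []
    for contig_id, seq in genome.contigs.items():
        for amp in amplify(
            seq, v1v9, tol, max_len=max_len, min_len=min_len,
            genome_id=genome.genome_id, contig_id=contig_id,
        ):
            genes.append(
                RrnaGene(genome.genome_id, contig_id, amp.start, amp.end,
                         amp.strand, amp.sequence, "anchored")
            )
    return genes


def length_filter(
    genes: list[RrnaGene],
    min_fraction: float = 0.9,
    reference_length: int = 1550,
) -> list[RrnaGene]:
    """Keep genes at least ``min_fraction`` of the reference full length.

    The boundary is inclusive and input order is preserved; applying the
    filter twice changes nothing.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    threshold = min_fraction * reference_length
    return [g for g in genes if g.length >= threshold]
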