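"""Dereplicate amplicons into alleles and score species resolvability.

An "allele" is one 100%-identity cluster of amplicons — the theoretical
limit of an amplicon sequence variant (ASV).  Identity is exact string
equality after uppercase/U->T normalization; sequences differing only in
terminal length are distinct alleles (the strictest reading of the ASV
concept), and ambiguity codes are compared literally.

From the genome x allele count matrix the module derives the two headline
statistics of a resolvability screen:

* allele multiplicity — the percentage of genomes carrying more than one
  distinct allele (such genomes inflate ASV richness on their own), and
* species overlap — the percentage of named species sharing at least one
  identical allele with another named species (such species are
  indistinguishable by this amplicon).

Genomes classified only to genus level (the UNSPECIFIED sentinel) appear
in the genome confusion matrix and pair listing but never enter the
species-overlap percentage, whose denominator counts named species only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genes import UNSPECIFIED, GenomeRecord
from .ispcr import Amplicon, normalize_sequence, reverse_complement
from .io import write_fasta

logger = logging.getLogger(__name__)


def fmt_pct(value: float | None) -> str:
    """Format a percentage with 2 decimals, rounding half-up; None -> 'NA'."""
    if value is None:
        return "NA"
    return str(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize_orientation(seq: str, mode: str = "as_is") -> str:
    """Orientation-normalize a sequence prior to dereplication.

    PCR products already start with the forward primer, so ``as_is`` is
    the default.  ``lexicographic`` maps externally supplied sequences to
    min(seq, reverse_complement(seq)) so that a sequence and its reverse
    complement dereplicate together.
    """
    seq = normalize_sequence(seq)
    if mode == "as_is":
        return seq
    if mode == "lexicographic":
        return min(seq, reverse_complement(seq))
    raise ValueError(f"unknown orientation mode {mode!r}")


@dataclass(frozen=True)
class AlleleCluster:
    """One 100%-identity cluster; members carry amplicon provenance."""

    allele_id: int
    sequence: str
    members: tuple[tuple[str, str, int, int, str], ...]  # genome, contig, start, end, strand

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AlleleMatrix:
    """Genome x allele copy-count table plus species labels per genome."""

    counts: pd.DataFrame  # index: genome_id, columns: allele_id (int)
    species_of: dict[str, str]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def allele_ids(self) -> list[int]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class OverlapReport:
    """Resolvability summary: multiplicity, overlap, confusion, groups."""

    multiplicity_flags: pd.Series
    multiplicity_pct: float
    flagged_species: set[str]
    overlap_pct: float | None  # None when there are no named species
    n_named_species: int
    genome_confusion: pd.DataFrame
    species_pairs: list[tuple[str, str, tuple[int, ...]]]
    indistinguishable_groups: list[frozenset[str]]


def dereplicate(
    amplicons: Sequence[Amplicon],
    orientation: str = "as_is",
) -> list[AlleleCluster]:
    """Cluster amplicons at 100% identity into alleles.

    Two amplicons share a cluster iff their orientation-normalized
    sequences are byte-identical.  Allele ids are assigned by descending
    cluster size, ties broken by first appearance in the input, so the
    numbering is deterministic under the pipeline's canonical amplicon
    sort (genome_id, contig_id, start).
    """
    order: dict[str, int] = {}
    groups: dict[str, list[Amplicon]] = {}
    for amp in amplicons:
        key = normalize_orientation(amp.sequence, orientation)
        if key not in groups:
            order[key] = len(order)
            groups[key] = []
        groups[key].append(amp)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), order[kv[0]]))
    clusters = []
    for allele_id, (seq, members) in enumerate(ranked, start=1):
        clusters.append(
            AlleleCluster(
                allele_id,
                seq,
                tuple((m.genome_id, m.contig_id, m.start, m.end, m.strand)
                      for m in members),
            )
        )
    return clusters


def build_allele_matrix(
    clusters: Sequence[AlleleCluster],
    genomes: Sequence[GenomeRecord],
) -> AlleleMatrix:
    """Tabulate allele copy counts across genomes.

    Every genome appears as a row even with zero amplicons; an unknown
    member genome_id is an error.
    """
    genome_ids = [g.genome_id for g in genomes]
    species_of = {g.genome_id: g.species for g in genomes}
    known = set(genome_ids)
    allele_ids = [c.allele_id for c in clusters]
    counts = pd.DataFrame(
        0, index=pd.Index(genome_ids, name="genome_id"), columns=allele_ids,
        dtype=int,
    )
    for c in clusters:
        for gid, *_ in c.members:
            if gid not in known:
                raise ValueError(f"amplicon references unknown genome {gid!r}")
            counts.loc[gid, c.allele_id] += 1
    return AlleleMatrix(counts=counts, species_of=species_of)


def matrix_from_counts(
    counts: Mapping[str, Mapping[str, int]],
    species_of: Mapping[str, str],
) -> AlleleMatrix:
    """Build an AlleleMatrix from nested {genome: {sequence: count}} maps.

    Used for truth tables and report re-rendering; allele ids follow the
    same size-major numbering as ``dereplicate``.
    """
    first_seen: dict[str, int] = {}
    totals: dict[str, int] = {}
    for gid in counts:
        for seq, n in counts[gid].items():
            if seq not in first_seen:
                first_seen[seq] = len(first_seen)
            totals[seq] = totals.get(seq, 0) + n
    ranked = sorted(totals, key=lambda s: (-totals[s], first_seen[s]))
    seq_id = {seq: i + 1 for i, seq in enumerate(ranked)}
    genome_ids = list(counts)
    mat = pd.DataFrame(
        0, index=pd.Index(genome_ids, name="genome_id"),
        columns=[seq_id[s] for s in ranked], dtype=int,
    )
    for gid in counts:
        for seq, n in counts[gid].items():
            mat.loc[gid, seq_id[seq]] += n
    return AlleleMatrix(counts=mat, species_of=dict(species_of))


def allele_multiplicity(matrix: AlleleMatrix) -> tuple[pd.Series, float]:
    """Flag genomes with more than one distinct allele; return flags and %."""
    if len(matrix.genome_ids) == 0:
        raise ValueError("allele multiplicity undefined for zero genomes")
    flags = (matrix.counts > 0).sum(axis=1) >= 2
    pct = 100.0 * int(flags.sum()) / len(flags)
    return flags, pct


def species_overlap(matrix: AlleleMatrix) -> OverlapReport:
    """Compute the full resolvability report from an allele matrix."""
    flags, mult_pct = allele_multiplicity(matrix)
    counts = matrix.counts
    genome_ids = matrix.genome_ids
    present = counts.to_numpy() > 0

    conf = present.astype(int) @ present.astype(int).T > 0
    np.fill_diagonal(conf, True)
    genome_confusion = pd.DataFrame(conf, index=genome_ids, columns=genome_ids)

    species_of = matrix.species_of
    named = sorted({s for s in species_of.values() if s != UNSPECIFIED})

    # Label sets per allele column (labels include UNSPECIFIED for the
    # confusion/pair listing; overlap flags use named labels only).
    pair_alleles: dict[frozenset[str], set[int]] = {}
    flagged: set[str] = set()
    edges: set[frozenset[str]] = set()
    for col_idx, allele_id in enumerate(matrix.allele_ids):
        labels = {species_of[genome_ids[i]]
                  for i in np.nonzero(present[:, col_idx])[0]}
        for a in labels:
            for b in labels:
                if a < b:
                    pair_alleles.setdefault(frozenset((a, b)), set()).add(allele_id)
        named_here = labels - {UNSPECIFIED}
        if len(named_here) >= 2:
            flagged |= named_here
            for a in named_here:
                for b in named_here:
                    if a < b:
                        edges.add(frozenset((a, b)))

    overlap_pct = 100.0 * len(flagged) / len(named) if named else None

    # Connected components of the named species-sharing graph (union-find).
    parent = {s: s for s in named}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for edge in edges:
        a, b = sorted(edge)
        parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for s in named:
        comps.setdefault(find(s), set()).add(s)
    groups = sorted(
        (frozenset(c) for c in comps.values() if len(c) >= 2),
        key=lambda c: sorted(c),
    )

    species_pairs = sorted(
        (tuple(sorted(pair)) + (tuple(sorted(ids)),)
         for pair, ids in pair_alleles.items()),
        key=lambda t: (t[0], t[1]),
    )

    return OverlapReport(
        multiplicity_flags=flags,
        multiplicity_pct=mult_pct,
        flagged_species=flagged,
        overlap_pct=overlap_pct,
        n_named_species=len(named),
        genome_confusion=genome_confusion,
        species_pairs=list(species_pairs),
        indistinguishable_groups=list(groups),
    )


def ward_order(matrix: AlleleMatrix, axis: str = "rows") -> list[int]:
    """Leaf order of a Ward-linkage dendrogram on allele count vectors.

    Euclidean distances on raw counts, deterministic given the matrix;
    display ordering only — it never changes any statistic.
    """
    if axis == "rows":
        data = matrix.counts.to_numpy(dtype=float)
    elif axis == "cols":
        data = matrix.counts.to_numpy(dtype=float).T
    else:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    n = data.shape[0]
    if n < 2:
        return list(range(n))
    linkage = hierarchy.linkage(data, method="ward")
    return [int(i) for i in hierarchy.leaves_list(linkage)]


def write_reports(
    matrix: AlleleMatrix,
    report: OverlapReport,
    out_dir: str | Path,
    clusters: Sequence[AlleleCluster] | None = None,
    make_plots: bool = False,
) -> list[Path]:
    """Write the TSV/FASTA/text report set (and optional heatmaps).

    Emits the allele matrix, dereplicated allele FASTA (when clusters are
    given), genome confusion matrix, plain-text overlap report and a
    one-row summary TSV.  Degenerate inputs (zero alleles) still produce
    the full file set, with a WARNING logged.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if matrix.total == 0:
        logger.warning("no amplicons: reports will contain zero data rows")

    p = out_dir / "allele_matrix.tsv"
    matrix.counts.to_csv(p, sep="\t", lineterminator="\n")
    written.append(p)

    if clusters is not None:
        p = out_dir / "alleles.fasta"
        write_fasta(
            p, [(f"allele_{c.allele_id};size={c.size}", c.sequence) for c in clusters]
        )
        written.append(p)

    p = out_dir / "genome_confusion.tsv"
    report.genome_confusion.astype(int).to_csv(p, sep="\t", lineterminator="\n")
    written.append(p)

    p = out_dir / "overlap_report.txt"
    with open(p, "w") as fh:
        fh.write("# Species resolvability report\n")
        fh.write(f"genomes\t{len(matrix.genome_ids)}\n")
        fh.write(f"named_species\t{report.n_named_species}\n")
        fh.write(f"alleles\t{len(matrix.allele_ids)}\n")
        fh.write(f"allele_multiplicity_pct\t{fmt_pct(report.multiplicity_pct)}\n")
        if report.overlap_pct is None:
            fh.write("species_overlap_pct\tundefined (no named species)\n")
        else:
            fh.write(f"species_overlap_pct\t{fmt_pct(report.overlap_pct)}\n")
        fh.write("\n## Indistinguishable species groups (shared alleles)\n")
        if not report.indistinguishable_groups:
            fh.write("none\n")
        for i, group in enumerate(report.indistinguishable_groups, start=1):
            fh.write(f"group_{i}\t{', '.join(sorted(group))}\n")
        fh.write("\n## Species pairs sharing alleles (incl. unclassified genomes)\n")
        if not report.species_pairs:
            fh.write("none\n")
        for a, b, ids in report.species_pairs:
            fh.write(f"{a}\t{b}\talleles: {', '.join(map(str, ids))}\n")
        fh.write("\n## Per-genome allele multiplicity (>1 distinct allele)\n")
        for gid in matrix.genome_ids:
            n_alleles = int((matrix.counts.loc[gid] > 0).sum())
            flag = "multiple" if report.multiplicity_flags[gid] else "single"
            fh.write(f"{gid}\t{matrix.species_of[gid]}\t{n_alleles}\t{flag}\n")
    written.append(p)

    p = out_dir / "summary.tsv"
    with open(p, "w") as fh:
        fh.write("genomes\tnamed_species\talleles\tmultiplicity_pct\toverlap_pct\n")
        fh.write(
            f"{len(matrix.genome_ids)}\t{report.n_named_species}\t"
            f"{len(matrix.allele_ids)}\t{fmt_pct(report.multiplicity_pct)}\t"
            f"{fmt_pct(report.overlap_pct)}\n"
        )
    written.append(p)

    if make_plots:
        written.extend(_write_heatmaps(matrix, report, out_dir))
    return written


def _write_heatmaps(matrix: AlleleMatrix, report: OverlapReport, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    counts = matrix.counts
    if counts.size > 0:
        row_order = ward_order(matrix, "rows")
        col_order = ward_order(matrix, "cols")
        data = counts.to_numpy()[np.ix_(row_order, col_order)]
        fig, ax = plt.subplots(figsize=(max(4, 0.3 * counts.shape[1] + 2),
                                        max(3, 0.3 * counts.shape[0] + 1)))
        im = ax.imshow(data, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(col_order)))
        ax.set_xticklabels([counts.columns[i] for i in col_order], rotation=90, fontsize=6)
        ax.set_yticks(range(len(row_order)))
        ax.set_yticklabels(
            [f"{counts.index[i]} ({matrix.species_of[counts.index[i]]})"
             for i in row_order], fontsize=6,
        )
        ax.set_xlabel("allele")
        fig.colorbar(im, ax=ax, label="copies")
        fig.tight_layout()
        p = out_dir / "heatmap_alleles.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)

        conf = report.genome_confusion.astype(int).to_numpy()[np.ix_(row_order, row_order)]
        fig, ax = plt.subplots(figsize=(max(3, 0.3 * len(row_order) + 1),) * 2)
        ax.imshow(conf, cmap="Greys", vmin=0, vmax=1)
        ax.set_xticks(range(len(row_order)))
        ax.set_xticklabels([counts.index[i] for i in row_order], rotation=90, fontsize=6)
        ax.set_yticks(range(len(row_order)))
        ax.set_yticklabels([counts.index[i] for i in row_order], fontsize=6)
        fig.tight_layout()
        p = out_dir / "heatmap_confusion.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
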