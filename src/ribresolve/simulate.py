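"""Synthetic genera with planted 16S alleles and exactly known truth.

Real resolvability screens depend on whichever genomes a database holds
on a given day, so the test bed here is a generator that builds genera to
order: a pool of ~1550 nt allele sequences carrying exact V1V9 primer
sites at their termini and exact V3V4 sites at fixed internal offsets,
planted in random-background genomes with 1-10 rrn copies, random
strands, within-genome variants, alleles deliberately shared across
species, and "sp." genomes classified only to genus.  Every quantity the
pipeline computes — allele matrix, multiplicity, overlap, groups — is
known by construction, so truth recovery can be asserted exactly.

To keep that guarantee for any seed, backgrounds and junctions are
screened with an independent near-match scanner and redrawn whenever a
primer-like site (within the default matching tolerance) appears anywhere
except the planted footprints.  The screen covers the default tolerance
of one mismatch plus one insertion; synthetic truth claims do not extend
to runs with larger tolerances.

Randomness: one seed per design.  Stream order is fixed — child stream 0
draws the allele pool (base sequence, then mutated positions, then
substituted bases), child stream 1 draws genomes in order (for each
genome: copy number, copy distribution, placement gaps, strands,
background bases, redraws on screening failure).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alleles import (
    AlleleMatrix,
    build_allele_matrix,
    dereplicate,
    matrix_from_counts,
    species_overlap,
)
from .genes import (
    UNSPECIFIED,
    GenomeRecord,
    RrnaGene,
    genes_by_anchoring,
    genes_from_gff,
    length_filter,
)
from .ispcr import (
    BUILTIN_PRIMERS,
    MatchTolerance,
    _encode,
    amplify,
    expand_iupac,
    reverse_complement,
)

GENE_LENGTH = 1550

_V3V4 = BUILTIN_PRIMERS["V3V4"]
_V1V9 = BUILTIN_PRIMERS["V1V9"]


def _realize(primer: str) -> str:
    """One concrete ACGT realization of a degenerate primer (first base of
    each expansion, alphabetically) — the exact site planted in alleles."""
    return "".join(sorted(expand_iupac(c))[0] for c in primer)


_F19 = _realize(_V1V9.forward)                       # at [0, 20)
_R19RC = reverse_complement(_realize(_V1V9.reverse))  # at [1531, 1550)
_F34 = _realize(_V3V4.forward)                       # at [340, 357)
_R34RC = reverse_complement(_realize(_V3V4.reverse))  # at [779, 800)

V34_START = 340
V34_END = 800  # V3V4 product (primers included) = allele[340:800], 460 nt
_IN_WINDOW = np.arange(V34_START + len(_F34), V34_END - len(_R34RC))  # [357, 779)
_OUT_WINDOW = np.concatenate(
    [np.arange(len(_F19), V34_START),                    # [20, 340)
     np.arange(V34_END, GENE_LENGTH - len(_R19RC))]      # [800, 1531)
)

#: The eight degenerate queries any synthetic sequence is screened against.
_SCREEN_QUERIES: dict[str, str] = {
    "V3V4.fwd": _V3V4.forward,
    "V3V4.fwd.rc": reverse_complement(_V3V4.forward),
    "V3V4.rev": _V3V4.reverse,
    "V3V4.rev.rc": reverse_complement(_V3V4.reverse),
    "V1V9.fwd": _V1V9.forward,
    "V1V9.fwd.rc": reverse_complement(_V1V9.forward),
    "V1V9.rev": _V1V9.reverse,
    "V1V9.rev.rc": reverse_complement(_V1V9.reverse),
}

# Expected footprint offsets (relative to gene start) per query, by strand
# of the planted copy.  A "+" copy is the allele itself; a "-" copy is its
# reverse complement, which maps allele interval [x, y) to
# [L - y, L - x) and swaps each query with its reverse complement.
_PLUS_OFFSETS = {
    "V1V9.fwd": 0,
    "V1V9.rev.rc": GENE_LENGTH - len(_R19RC),
    "V3V4.fwd": V34_START,
    "V3V4.rev.rc": V34_END - len(_R34RC),
}
_MINUS_OFFSETS = {
    "V1V9.fwd.rc": GENE_LENGTH - len(_F19),
    "V1V9.rev": 0,
    "V3V4.fwd.rc": GENE_LENGTH - V34_START - len(_F34),
    "V3V4.rev": GENE_LENGTH - V34_END,
}

_SCREEN_MM = 2  # near-match mismatch budget: superset of tolerance (1,1,0)
_SCREEN_SLOP = 2  # positional slack around an expected footprint start


def _near_hits(text: str, query: str, max_mm: int = _SCREEN_MM) -> list[int]:
    """Start positions where ``query`` nearly matches ``text``.

    Considers gapless alignments and alignments with a single extra
    template base at any interior slot, with at most ``max_mm``
    IUPAC-incompatible columns.  Independent of the production matcher.
    """
    t = _encode(text, "screen text")
    q = _encode(query, "screen query")
    L, N = len(q), len(t)
    hits: set[int] = set()
    if N < L:
        return []
    inc = ((q[:, None] & t[None, :]) == 0).astype(np.int16)

    nv = N - L + 1
    m = np.zeros(nv, dtype=np.int16)
    for j in range(L):
        m += inc[j, j:j + nv]
    hits.update(np.nonzero(m <= max_mm)[0].tolist())

    if N >= L + 1:
        nv = N - L
        suffixes: list[np.ndarray | None] = [None] * (L + 1)
        suffixes[L] = np.zeros(nv, dtype=np.int16)
        for p in range(L - 1, 0, -1):
            suffixes[p] = suffixes[p + 1] + inc[p, p + 1:p + 1 + nv]
        pre = np.zeros(nv, dtype=np.int16)
        for p in range(1, L):
            pre = pre + inc[p - 1, p - 1:p - 1 + nv]
            hits.update(np.nonzero(pre + suffixes[p] <= max_mm)[0].tolist())
    return sorted(hits)


def _screen_clean(text: str, expected: Mapping[str, Sequence[int]]) -> bool:
    """True iff every near-hit sits at (or within slop of) a planted site."""
    for name, query in _SCREEN_QUERIES.items():
        allowed = expected.get(name, ())
        for h in _near_hits(text, query):
            if not any(abs(h - pos) <= _SCREEN_SLOP for pos in allowed):
                return False
    return True


@dataclass(frozen=True)
class GenusDesign:
    """Specification of a synthetic genus.

    ``shared_allele_plan`` lists sets of species indices (0-based) that
    must share one identical allele; ``v3v4_twin_pairs`` lists pool-index
    pairs (i, j) where allele j copies allele i's V3V4 window but differs
    elsewhere — the full-length-resolves-what-short-reads-cannot motif.
    """

    n_species: int = 3
    genomes_per_species: int = 2
    rrn_copies: tuple[int, int] = (4, 7)
    allele_pool_size: int = 8
    within_genome_variants: int = 1
    shared_allele_plan: tuple[tuple[int, ...], ...] = ()
    v3v4_twin_pairs: tuple[tuple[int, int], ...] = ()
    n_unspecified: int = 0
    background_length: int = 20000
    mutation_distance: int = 3
    seed: int = 0
    genus: str = "Synthomonas"

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.genomes_per_species < 1:
            raise ValueError("need at least one species and one genome each")
        lo, hi = self.rrn_copies
        if not 1 <= lo <= hi:
            raise ValueError("rrn_copies must be an increasing range from >= 1")
        if self.within_genome_variants < 1:
            raise ValueError("within_genome_variants must be >= 1")
        if self.allele_pool_size < self.within_genome_variants:
            raise ValueError("allele_pool_size must cover within_genome_variants")
        if self.mutation_distance < 1:
            raise ValueError("mutation_distance must be >= 1")
        n_plans = len(self.shared_allele_plan)
        plan_ids = set(range(self.allele_pool_size - n_plans, self.allele_pool_size))
        for plan in self.shared_allele_plan:
            if len(set(plan)) < 2:
                raise ValueError("each shared-allele plan needs >= 2 species")
            if any(not 0 <= s < self.n_species for s in plan):
                raise ValueError("shared-allele plan references unknown species")
        twins_j = [j for _, j in self.v3v4_twin_pairs]
        if len(set(twins_j)) != len(twins_j):
            raise ValueError("v3v4_twin_pairs: duplicate derived allele")
        for i, j in self.v3v4_twin_pairs:
            if i == j:
                raise ValueError("v3v4_twin_pairs: identical indices")
            for k in (i, j):
                if not 0 <= k < self.allele_pool_size:
                    raise ValueError("v3v4_twin_pairs: index outside pool")
            if j in plan_ids or i in twins_j:
                raise ValueError("v3v4_twin_pairs: invalid chaining with plan/twin alleles")


@dataclass
class GenusTruth:
    """Ground truth for one generated genus.

    ``matrices`` maps region ("V3V4"/"V1V9") to {genome_id: {amplicon
    sequence: copy count}}; statistics are recomputed from those tables
    with the same formulas the analysis module uses, so truth and
    observation are directly comparable.
    """

    genome_ids: list[str]
    species_of: dict[str, str]
    planted: list[tuple[str, str, int, int, str, int]]  # genome, contig, start, end, strand, allele idx
    matrices: dict[str, dict[str, dict[str, int]]]
    multiplicity_pct: dict[str, float]
    overlap_pct: dict[str, float | None]
    groups: dict[str, list[frozenset[str]]]
    allele_pool: list[str]

    def matrix(self, region: str) -> AlleleMatrix:
        return matrix_from_counts(self.matrices[region], self.species_of)


def _assign_alleles(design: GenusDesign) -> list[list[int]]:
    """Deterministically map species to pool allele indices.

    Shared-plan alleles occupy the top of the pool (plan i -> index
    P-1-i); private alleles are drawn from the bottom in order.  Each
    species carries max(within_genome_variants, its plan count) alleles.
    """
    P = design.allele_pool_size
    plans = list(design.shared_allele_plan)
    plan_allele = {i: P - 1 - i for i in range(len(plans))}
    private_limit = P - len(plans)
    cursor = 0
    assignment: list[list[int]] = []
    for s in range(design.n_species):
        mine = [plan_allele[i] for i, plan in enumerate(plans) if s in plan]
        target = max(design.within_genome_variants, len(mine))
        while len(mine) < target:
            if cursor >= private_limit:
                raise ValueError(
                    "allele_pool_size too small for this design; increase it"
                )
            mine.append(cursor)
            cursor += 1
        assignment.append(sorted(mine))
    return assignment


def _rng_for(design: GenusDesign, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, n, dtype=np.uint8)
    ]).decode("ascii")


_ALLELE_EXPECTED = {name: (pos,) for name, pos in _PLUS_OFFSETS.items()}


def make_allele_pool(design: GenusDesign) -> list[str]:
    """Generate the genus allele pool: deterministic per seed.

    Every allele shares exact primer footprints; distinct alleles carry
    ``mutation_distance`` private substitutions inside the V3V4 window
    (so both V3V4 and V1V9 amplicons are pairwise distinct), except twin
    alleles whose V3V4 window is copied from their partner and whose
    substitutions fall outside it.
    """
    rng = _rng_for(design, 0)
    P = design.allele_pool_size
    d = design.mutation_distance
    twin_of = {j: i for i, j in design.v3v4_twin_pairs}
    normal = [k for k in range(P) if k not in twin_of]
    need_in = d * len(normal)
    if need_in > len(_IN_WINDOW):
        raise ValueError(
            f"cannot keep {len(normal)} alleles >= {d} substitutions apart "
            f"inside the {len(_IN_WINDOW)} nt V3V4 window; reduce "
            "allele_pool_size or mutation_distance"
        )
    need_out = d * len(twin_of)
    if need_out > len(_OUT_WINDOW):
        raise ValueError("too many twin alleles for the regions outside V3V4")

    for _attempt in range(100):
        base = bytearray(_random_bases(rng, GENE_LENGTH), "ascii")
        for site, pos in ((_F19, 0), (_F34, V34_START),
                          (_R34RC, V34_END - len(_R34RC)),
                          (_R19RC, GENE_LENGTH - len(_R19RC))):
            base[pos:pos + len(site)] = site.encode("ascii")

        pos_in = rng.choice(_IN_WINDOW, size=need_in, replace=False)
        pos_out = rng.choice(_OUT_WINDOW, size=need_out, replace=False)

        def mutate(buf: bytearray, positions: Iterable[int]) -> None:
            for p in positions:
                old = chr(buf[p])
                choices = [b for b in "ACGT" if b != old]
                buf[p] = ord(choices[int(rng.integers(0, 3))])

        pool: list[str | None] = [None] * P
        for idx, k in enumerate(normal):
            buf = bytearray(base)
            mutate(buf, pos_in[idx * d:(idx + 1) * d])
            pool[k] = buf.decode("ascii")
        for idx, (j, i) in enumerate(sorted(twin_of.items())):
            buf = bytearray(base)
            mutate(buf, pos_out[idx * d:(idx + 1) * d])
            buf[V34_START:V34_END] = pool[i].encode("ascii")[V34_START:V34_END]
            pool[j] = buf.decode("ascii")

        if all(_screen_clean(seq, _ALLELE_EXPECTED) for seq in pool):
            return list(pool)  # type: ignore[arg-type]
    raise RuntimeError(
        "could not generate a primer-clean allele pool after 100 attempts; "
        "try a different seed"
    )


def _expected_hits_for_copies(
    copies: Sequence[tuple[int, str]],
) -> dict[str, list[int]]:
    expected: dict[str, list[int]] = {name: [] for name in _SCREEN_QUERIES}
    for pos, strand in copies:
        offsets = _PLUS_OFFSETS if strand == "+" else _MINUS_OFFSETS
        for name, off in offsets.items():
            expected[name].append(pos + off)
    return expected


def build_genus(
    design: GenusDesign,
) -> tuple[list[GenomeRecord], dict[str, list[str]], GenusTruth]:
    """Generate the genomes, their GFF3 annotations and the truth record."""
    pool = make_allele_pool(design)
    assignment = _assign_alleles(design)
    rng = _rng_for(design, 1)
    lo, hi = design.rrn_copies
    min_gap = 100

    roster: list[tuple[int, str]] = []  # (species index, label)
    for s in range(design.n_species):
        for _ in range(design.genomes_per_species):
            roster.append((s, f"sp{s + 1:02d}"))
    for _ in range(design.n_unspecified):
        mimic = int(rng.integers(0, design.n_species))
        roster.append((mimic, UNSPECIFIED))

    genomes: list[GenomeRecord] = []
    gffs: dict[str, list[str]] = {}
    planted: list[tuple[str, str, int, int, str, int]] = []
    truth_counts = {"V3V4": {}, "V1V9": {}}

    for g_idx, (sidx, label) in enumerate(roster, start=1):
        gid = f"SYN{g_idx:03d}"
        alleles = assignment[sidx]
        copies = max(int(rng.integers(lo, hi + 1)), len(alleles))
        per_allele = [1] * len(alleles)
        for _ in range(copies - len(alleles)):
            per_allele[int(rng.integers(0, len(alleles)))] += 1
        copy_alleles = [a for a, n in zip(alleles, per_allele) for _ in range(n)]
        copy_alleles = [copy_alleles[i] for i in rng.permutation(len(copy_alleles))]

        free = (design.background_length - copies * GENE_LENGTH
                - (copies - 1) * min_gap)
        if free < 0:
            raise ValueError(
                f"{copies} planted genes do not fit in background_length="
                f"{design.background_length}"
            )

        text = None
        for _attempt in range(100):
            gaps = rng.multinomial(free, [1.0 / (copies + 1)] * (copies + 1))
            strands = ["+" if b else "-" for b in rng.integers(0, 2, copies)]
            buf = bytearray(_random_bases(rng, design.background_length), "ascii")
            positions = []
            cursor = 0
            for c in range(copies):
                cursor += int(gaps[c]) + (min_gap if c else 0)
                positions.append(cursor)
                allele_seq = pool[copy_alleles[c]]
                if strands[c] == "-":
                    allele_seq = reverse_complement(allele_seq)
                buf[cursor:cursor + GENE_LENGTH] = allele_seq.encode("ascii")
                cursor += GENE_LENGTH
            candidate = buf.decode("ascii")
            expected = _expected_hits_for_copies(list(zip(positions, strands)))
            if _screen_clean(candidate, expected):
                text = candidate
                break
        if text is None:
            raise RuntimeError(
                f"could not place primer-clean background for {gid} "
                "after 100 attempts; try a different seed"
            )

        genomes.append(GenomeRecord(gid, design.genus, label, {"chr": text}))
        lines = ["##gff-version 3"]
        for c in range(copies):
            start, end = positions[c], positions[c] + GENE_LENGTH
            lines.append(
                f"chr\tribresolve_sim\trRNA\t{start + 1}\t{end}\t.\t"
                f"{strands[c]}\t.\tName=16S_ribosomal_RNA;"
                "product=16S ribosomal RNA"
            )
            planted.append((gid, "chr", start, end, strands[c], copy_alleles[c]))
        gffs[gid] = lines

        v19 = {}
        v34 = {}
        for c in range(copies):
            a = pool[copy_alleles[c]]
            v19[a] = v19.get(a, 0) + 1
            w = a[V34_START:V34_END]
            v34[w] = v34.get(w, 0) + 1
        truth_counts["V1V9"][gid] = v19
        truth_counts["V3V4"][gid] = v34

    species_of = {g.genome_id: g.species for g in genomes}
    mult, over, groups = {}, {}, {}
    for region in ("V3V4", "V1V9"):
        rep = species_overlap(matrix_from_counts(truth_counts[region], species_of))
        mult[region] = rep.multiplicity_pct
        over[region] = rep.overlap_pct
        groups[region] = list(rep.indistinguishable_groups)

    truth = GenusTruth(
        genome_ids=[g.genome_id for g in genomes],
        species_of=species_of,
        planted=planted,
        matrices=truth_counts,
        multiplicity_pct=mult,
        overlap_pct=over,
        groups=groups,
        allele_pool=pool,
    )
    return genomes, gffs, truth


@dataclass
class CheckResult:
    """Outcome of an end-to-end truth-recovery run; mismatches listed, not raised."""

    ok: bool
    mismatches: list[str]
    observed_stats: dict[str, dict[str, object]]
    refinement_ok: bool


def _pipeline_counts(
    genomes: Sequence[GenomeRecord],
    genes_per_genome: Mapping[str, Sequence[RrnaGene]],
    pair,
    tol: MatchTolerance,
) -> tuple[dict[str, dict[str, int]], list]:
    """Amplify extracted genes and tabulate sequences per genome."""
    amplicons = []
    for genome in genomes:
        for gene in genes_per_genome[genome.genome_id]:
            amplicons.extend(
                amplify(
                    gene.sequence, pair, tol,
                    genome_id=genome.genome_id,
                    contig_id=f"{gene.contig_id}|{gene.start}-{gene.end}{gene.strand}",
                )
            )
    amplicons.sort(key=lambda a: (a.genome_id, a.contig_id, a.start, a.end, a.strand))
    counts: dict[str, dict[str, int]] = {g.genome_id: {} for g in genomes}
    for a in amplicons:
        counts[a.genome_id][a.sequence] = counts[a.genome_id].get(a.sequence, 0) + 1
    return counts, amplicons


def end_to_end_check(design: GenusDesign) -> CheckResult:
    """Run generation -> extraction -> PCR -> dereplication -> statistics
    through both extraction routes and compare everything to truth."""
    genomes, gffs, truth = build_genus(design)
    tol = MatchTolerance()
    mismatches: list[str] = []
    observed_stats: dict[str, dict[str, object]] = {}

    genes_by_path: dict[str, dict[str, list[RrnaGene]]] = {}
    for path in ("gff", "anchored"):
        per_genome: dict[str, list[RrnaGene]] = {}
        for genome in genomes:
            if path == "gff":
                genes = genes_from_gff(genome, gffs[genome.genome_id])
            else:
                genes = genes_by_anchoring(genome, tol=tol)
            per_genome[genome.genome_id] = length_filter(genes)
        genes_by_path[path] = per_genome

    pair_products: dict[str, dict[str, dict[str, int]]] = {}
    per_gene_regions: dict[tuple[str, str], dict[str, str]] = {}

    for path in ("gff", "anchored"):
        for region, pair in (("V3V4", _V3V4), ("V1V9", _V1V9)):
            counts, amplicons = _pipeline_counts(
                genomes, genes_by_path[path], pair, tol
            )
            if counts != truth.matrices[region]:
                mismatches.append(f"{path}/{region}: allele matrix differs from truth")
            clusters = dereplicate(amplicons)
            matrix = build_allele_matrix(clusters, genomes)
            rep = species_overlap(matrix)
            key = f"{path}/{region}"
            observed_stats[key] = {
                "n_alleles": len(clusters),
                "multiplicity_pct": rep.multiplicity_pct,
                "overlap_pct": rep.overlap_pct,
                "groups": set(rep.indistinguishable_groups),
            }
            if rep.multiplicity_pct != truth.multiplicity_pct[region]:
                mismatches.append(f"{key}: multiplicity_pct differs from truth")
            if rep.overlap_pct != truth.overlap_pct[region]:
                mismatches.append(f"{key}: overlap_pct differs from truth")
            if set(rep.indistinguishable_groups) != set(truth.groups[region]):
                mismatches.append(f"{key}: indistinguishable groups differ from truth")
            if path == "gff":
                pair_products[region] = counts
            for genome in genomes:
                for gene in genes_by_path[path][genome.genome_id]:
                    amps = [a for a in amplicons
                            if a.genome_id == genome.genome_id and
                            a.contig_id ==
                            f"{gene.contig_id}|{gene.start}-{gene.end}{gene.strand}"]
                    if path == "gff" and len(amps) == 1:
                        per_gene_regions.setdefault(
                            (genome.genome_id, gene.contig_id + f":{gene.start}"),
                            {},
                        )[region] = amps[0].sequence

    # The two extraction routes must agree on amplicon multisets.
    for region, pair in (("V3V4", _V3V4), ("V1V9", _V1V9)):
        c_gff, _ = _pipeline_counts(genomes, genes_by_path["gff"], pair, tol)
        c_anc, _ = _pipeline_counts(genomes, genes_by_path["anchored"], pair, tol)
        if c_gff != c_anc:
            mismatches.append(f"{region}: GFF and anchoring routes disagree")

    # Refinement: copies identical over V1V9 are identical over V3V4, and
    # full-length overlap never exceeds short-read overlap.
    refinement_ok = True
    v19_to_v34: dict[str, set[str]] = {}
    for regions in per_gene_regions.values():
        if "V1V9" in regions and "V3V4" in regions:
            v19_to_v34.setdefault(regions["V1V9"], set()).add(regions["V3V4"])
    if any(len(v) != 1 for v in v19_to_v34.values()):
        refinement_ok = False
    o34 = observed_stats.get("gff/V3V4", {}).get("overlap_pct")
    o19 = observed_stats.get("gff/V1V9", {}).get("overlap_pct")
    if o34 is not None and o19 is not None and o19 > o34:
        refinement_ok = False
    if not refinement_ok:
        mismatches.append("V1V9 partition does not refine V3V4")

    return CheckResult(
        ok=not mismatches,
        mismatches=mismatches,
        observed_stats=observed_stats,
        refinement_ok=refinement_ok,
    )


def write_genus(
    out_dir: str | Path,
    genomes: Sequence[GenomeRecord],
    gffs: Mapping[str, Sequence[str]],
    truth: GenusTruth,
    design: GenusDesign,
) -> dict[str, Path]:
    """Write a generated genus to disk: FASTA + GFF3 per genome, a metadata
    TSV and a truth JSON with the design echo."""
    from .io import write_fasta  # local import to keep module deps one-way

    out_dir = Path(out_dir)
    genomes_dir = out_dir / "genomes"
    gff_dir = out_dir / "gff"
    genomes_dir.mkdir(parents=True, exist_ok=True)
    gff_dir.mkdir(parents=True, exist_ok=True)

    metadata_rows = ["genome_id\torganism_name"]
    for genome in genomes:
        gid = genome.genome_id
        if genome.species == UNSPECIFIED:
            organism = f"{genome.genus} sp. {gid}"
        else:
            organism = f"{genome.genus} {genome.species} strain {gid}"
        metadata_rows.append(f"{gid}\t{organism}")
        write_fasta(
            genomes_dir / f"{gid}.fasta",
            [(f"{cid} {organism}", seq) for cid, seq in genome.contigs.items()],
        )
        with open(gff_dir / f"{gid}.gff", "w") as fh:
            fh.write("\n".join(gffs[gid]) + "\n")

    metadata_path = out_dir / "metadata.tsv"
    metadata_path.write_text("\n".join(metadata_rows) + "\n")

    truth_path = out_dir / "truth.json"
    payload = {
        "design": {**asdict(design),
                   "shared_allele_plan": [list(p) for p in design.shared_allele_plan],
                   "v3v4_twin_pairs": [list(p) for p in design.v3v4_twin_pairs]},
        "genome_ids": truth.genome_ids,
        "species_of": truth.species_of,
        "planted": [list(p) for p in truth.planted],
        "matrices": truth.matrices,
        "n_alleles": {r: len({s for g in truth.matrices[r].values() for s in g})
                      for r in truth.matrices},
        "n_amplicons": {r: sum(n for g in truth.matrices[r].values()
                               for n in g.values())
                        for r in truth.matrices},
        "multiplicity_pct": truth.multiplicity_pct,
        "overlap_pct": truth.overlap_pct,
        "groups": {r: [sorted(g) for g in truth.groups[r]] for r in truth.groups},
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"genomes": genomes_dir, "gff": gff_dir,
            "metadata": metadata_path, "truth": truth_path}


def sample_design(seed: int) -> GenusDesign:
    """One random genus design, cycling through the problematic scenarios:

    0 — distinct species (baseline, sometimes with a V3V4 twin pair),
    1 — one allele shared identically across several species,
    2 — multi-variant genomes without sharing,
    3 — multi-variant genomes whose variants are individually shared.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    scenario = seed % 4
    n_species = int(rng.integers(2, 5))
    gps = int(rng.integers(1, 3))
    n_unspec = int(rng.integers(0, 3))
    variants = 1
    plans: tuple[tuple[int, ...], ...] = ()
    twins: tuple[tuple[int, int], ...] = ()

    if scenario == 1:
        k = min(int(rng.integers(2, 4)), n_species)
        plans = (tuple(range(k)),)
    elif scenario == 2:
        variants = int(rng.integers(2, 4))
    elif scenario == 3:
        n_species = max(n_species, 3)
        variants = 2
        plans = ((0, 1), (0, 2))

    pool_size = n_species * max(variants, 2) + len(plans) + 2
    base = GenusDesign(
        n_species=n_species,
        genomes_per_species=gps,
        rrn_copies=(max(2, variants), max(2, variants) + 3),
        allele_pool_size=pool_size,
        within_genome_variants=variants,
        shared_allele_plan=plans,
        n_unspecified=n_unspec,
        mutation_distance=3,
        seed=seed,
    )
    if scenario in (0, 2) and n_species >= 2 and rng.random() < 0.5:
        # twin the first private alleles of two species: shared V3V4
        # window, distinct full-length sequences
        assignment = _assign_alleles(base)
        i, j = assignment[0][0], assignment[1][0]
        if i != j:
            twins = ((i, j),)
            base = replace(base, v3v4_twin_pairs=twins)
    return base
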