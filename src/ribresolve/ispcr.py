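"""In-silico PCR against IUPAC-degenerate primers.

The matcher locates approximate primer binding sites on a nucleotide
template under independent budgets for

* mismatches — a non-gap alignment column whose IUPAC expansions do not
  intersect,
* insertions — extra template bases inside the primer footprint (gaps in
  the primer), which lengthen the footprint,
* deletions — primer positions aligned to a gap in the template, which
  shorten the footprint (off by default).

Amplicons are then extracted between a forward site and the nearest
downstream reverse-complemented reverse-primer site on the same strand,
mirroring what a PCR would produce from that template.  The default
tolerance of one mismatch plus one insertion matches common in-silico PCR
practice for 16S rRNA primers.

``oracle_find_sites`` is an intentionally naive exhaustive enumeration over
all start positions and gap placements.  It exists so the production
matcher can be checked against an independent implementation on small
instances; it is not meant for genome-scale templates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputFormatError

# 4-bit presence masks over the ACGT alphabet; U is an alias for T.
_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
_BASES = "ACGT"
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in _BITS.items():
    _ENCODE_LUT[ord(_c)] = _b
    _ENCODE_LUT[ord(_c.lower())] = _b


def expand_iupac(code: str) -> set[str]:
    """Expand one IUPAC nucleotide code to its set of concrete bases.

    Case-insensitive; U is treated as T.  Raises ``ValueError`` naming the
    offending character for anything outside the 15-letter alphabet.
    """
    if not isinstance(code, str) or len(code) != 1:
        raise ValueError(f"expected a single character, got {code!r}")
    bits = _BITS.get(code.upper())
    if bits is None:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}")
    return {b for i, b in enumerate(_BASES) if bits >> i & 1}


def bases_compatible(primer_code: str, template_code: str) -> bool:
    """True iff the IUPAC expansions of the two codes intersect."""
    pb = _BITS.get(primer_code.upper()) if len(primer_code) == 1 else None
    tb = _BITS.get(template_code.upper()) if len(template_code) == 1 else None
    if pb is None:
        raise ValueError(f"invalid IUPAC nucleotide code: {primer_code!r}")
    if tb is None:
        raise ValueError(f"invalid IUPAC nucleotide code: {template_code!r}")
    return bool(pb & tb)


def _check_alphabet(seq: str, what: str) -> None:
    for ch in set(seq):
        if ch.upper() not in _BITS:
            raise ValueError(f"invalid IUPAC character in {what}: {ch!r}")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, N->N)."""
    _check_alphabet(seq, "sequence")
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T; rejects non-IUPAC characters."""
    _check_alphabet(seq, "sequence")
    return seq.upper().replace("U", "T")


def _encode(seq: str, what: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _ENCODE_LUT[arr]
    if (masks == 0).any():
        bad = seq[int(np.nonzero(masks == 0)[0][0])]
        raise ValueError(f"invalid IUPAC character in {what}: {bad!r}")
    return masks


@dataclass(frozen=True)
class PrimerPair:
    """A published primer pair; both strings 5'->3', reverse on the opposite strand."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{label} primer of {self.name!r} is empty")
            _check_alphabet(seq, f"{label} primer of {self.name!r}")
            if len(seq) < 10:
                raise ValueError(
                    f"{label} primer of {self.name!r} is shorter than 10 nt"
                )


#: Built-in pairs: the short-read standard V3V4 amplicon (~460 nt) and the
#: near-full-length V1V9 amplicon (~1.5 kb).
BUILTIN_PRIMERS: dict[str, PrimerPair] = {
    "V3V4": PrimerPair("V3V4", "CCTACGGGNGGCNGCAG", "GACTACNNGGGTATCTAATCC"),
    "V1V9": PrimerPair("V1V9", "AGRGTTYGATYMTGGCTCAG", "RGYTACCTTGTTACGACTT"),
}


def load_primer_pairs(path: str | Path) -> list[PrimerPair]:
    """Read primer pairs from a 3-column TSV: name, forward, reverse."""
    path = Path(path)
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise InputFormatError(
                    f"{path}:{ln}: expected 3 tab-separated fields, got {len(fields)}"
                )
            try:
                pairs.append(PrimerPair(fields[0], fields[1], fields[2]))
            except ValueError as exc:
                raise InputFormatError(f"{path}:{ln}: {exc}") from exc
    if not pairs:
        raise InputFormatError(f"{path}: no primer pairs found")
    return pairs


@dataclass(frozen=True)
class MatchTolerance:
    """Edit budgets for primer matching (defaults: 1 mismatch, 1 insertion)."""

    max_mismatch: int = 1
    max_insertion: int = 1
    max_deletion: int = 0

    def __post_init__(self) -> None:
        for name in ("max_mismatch", "max_insertion", "max_deletion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PrimerSite:
    """One matched primer footprint, 0-based half-open on the template."""

    template_id: str
    start: int
    end: int
    strand: str
    n_mismatch: int
    n_insertion: int
    n_deletion: int

    @property
    def total_edits(self) -> int:
        return self.n_mismatch + self.n_insertion + self.n_deletion

    @property
    def footprint(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Amplicon:
    """One in-silico PCR product with provenance.

    ``sequence`` is oriented so the forward primer is at its 5' end; for
    "-"-strand products it is the reverse complement of the template slice
    [start, end).  With ``primers_included`` the footprints are part of the
    product (the default, as wet-lab amplicons carry their primers).
    """

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    primers_included: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


def _site_order_key(site: tuple[int, int, int, int, int]):
    s, e, nm, ni, nd = site
    return (nm + ni + nd, s, e - s, nd, ni)


def _select_per_locus(raw: list[tuple[int, int, int, int, int]]):
    """Collapse overlapping candidate sites to one site per locus.

    Candidates whose footprints overlap (transitively) describe the same
    binding locus; the winner has the fewest total edits, then the leftmost
    start, then the shortest footprint, then fewest deletions/insertions.
    """
    if not raw:
        return []
    raw = sorted(raw, key=lambda r: (r[0], r[1]))
    out = []
    group: list[tuple[int, int, int, int, int]] = []
    group_end = -1
    for site in raw:
        if group and site[0] >= group_end:
            out.append(min(group, key=_site_order_key))
            group = []
            group_end = -1
        group.append(site)
        group_end = max(group_end, site[1])
    out.append(min(group, key=_site_order_key))
    return sorted(out, key=lambda r: r[0])


def _placements(length: int, tol: MatchTolerance):
    """Yield (deleted primer positions, insertion slots) within the budgets.

    Insertion slots are interior (between primer positions 1..L-1) so an
    "insertion" is always an extra template base inside the footprint;
    duplicated slots mean several extra bases at the same point.
    """
    for nd in range(tol.max_deletion + 1):
        for dels in itertools.combinations(range(length), nd):
            for ni in range(tol.max_insertion + 1):
                for ins in itertools.combinations_with_replacement(
                    range(1, length), ni
                ):
                    yield dels, ins


def find_primer_sites(
    template: str,
    primer: str,
    tol: MatchTolerance | None = None,
    strand: str = "+",
    template_id: str = "",
) -> list[PrimerSite]:
    """Locate all loci where ``primer`` binds ``template`` within tolerance.

    For strand "-" the primer is reverse-complemented before scanning, so
    the returned coordinates always refer to the given template.  Exactly
    one site is reported per locus (see ``_select_per_locus``); sites are
    sorted by start.
    """
    tol = tol or MatchTolerance()
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not template:
        raise ValueError("template must be non-empty")
    if not primer:
        raise ValueError("primer must be non-empty")
    T = normalize_sequence(template)
    q = normalize_sequence(primer)
    if strand == "-":
        q = reverse_complement(q)
    L, N = len(q), len(T)
    for name in ("max_mismatch", "max_insertion", "max_deletion"):
        if getattr(tol, name) > L:
            raise ValueError(f"{name} exceeds primer length {L}")
    if L > N:
        return []
    tmask = _encode(T, "template")
    qmask = _encode(q, "primer")
    # Per-primer-position incompatibility profile across the template.
    inc = ((qmask[:, None] & tmask[None, :]) == 0).astype(np.int16)

    cands: dict[tuple[int, int, int, int], int] = {}
    for dels, ins in _placements(L, tol):
        nd, ni = len(dels), len(ins)
        foot = L - nd + ni
        if foot < 1 or foot > N:
            continue
        nv = N - foot + 1
        mism = np.zeros(nv, dtype=np.int16)
        for j in range(L):
            if j in dels:
                continue
            off = j - sum(d < j for d in dels) + sum(k <= j for k in ins)
            mism += inc[j, off:off + nv]
        for s in np.nonzero(mism <= tol.max_mismatch)[0]:
            key = (int(s), int(s) + foot, ni, nd)
            nm = int(mism[s])
            if nm < cands.get(key, 1 << 30):
                cands[key] = nm

    raw = [(s, e, nm, ni, nd) for (s, e, ni, nd), nm in cands.items()]
    return [
        PrimerSite(template_id, s, e, strand, nm, ni, nd)
        for (s, e, nm, ni, nd) in _select_per_locus(raw)
    ]


def oracle_find_sites(
    template: str,
    primer: str,
    tol: MatchTolerance | None = None,
    strand: str = "+",
    template_id: str = "",
) -> list[PrimerSite]:
    """Exhaustive reference matcher: enumerate every start and gap placement.

    Test-scale only (template up to a few hundred nt); independent of
    ``find_primer_sites`` except for the shared site-selection contract.
    """
    tol = tol or MatchTolerance()
    if len(template) > 10_000:
        raise ValueError("oracle_find_sites is for test-scale templates only")
    T = normalize_sequence(template)
    q = normalize_sequence(primer)
    if strand == "-":
        q = reverse_complement(q)
    L, N = len(q), len(T)
    if L > N:
        return []

    best: dict[tuple[int, int, int, int], int] = {}
    for s in range(N):
        for dels, ins in _placements(L, tol):
            nd, ni = len(dels), len(ins)
            foot = L - nd + ni
            if foot < 1 or s + foot > N:
                continue
            t = s
            nm = 0
            ok = True
            for j in range(L):
                t += ins.count(j)
                if j in dels:
                    continue
                if not bases_compatible(q[j], T[t]):
                    nm += 1
                    if nm > tol.max_mismatch:
                        ok = False
                        break
                t += 1
            if not ok:
                continue
            key = (s, s + foot, ni, nd)
            if nm < best.get(key, 1 << 30):
                best[key] = nm

    # Independent copy of the per-locus selection sweep.
    sites = sorted(
        [(s, e, nm, ni, nd) for (s, e, ni, nd), nm in best.items()],
        key=lambda r: (r[0], r[1]),
    )
    chosen = []
    bucket: list[tuple[int, int, int, int, int]] = []
    reach = -1
    for site in sites:
        if bucket and site[0] >= reach:
            chosen.append(
                min(
                    bucket,
                    key=lambda r: (r[2] + r[3] + r[4], r[0], r[1] - r[0], r[4], r[3]),
                )
            )
            bucket = []
            reach = -1
        bucket.append(site)
        reach = max(reach, site[1])
    if bucket:
        chosen.append(
            min(
                bucket,
                key=lambda r: (r[2] + r[3] + r[4], r[0], r[1] - r[0], r[4], r[3]),
            )
        )
    chosen.sort(key=lambda r: r[0])
    return [
        PrimerSite(template_id, s, e, strand, nm, ni, nd)
        for (s, e, nm, ni, nd) in chosen
    ]


def amplify(
    template: str,
    pair: PrimerPair,
    tol: MatchTolerance | None = None,
    max_len: int = 3000,
    min_len: int = 50,
    trim_primers: bool = False,
    genome_id: str = "",
    contig_id: str = "",
) -> list[Amplicon]:
    """Extract every in-silico PCR product of ``pair`` from ``template``.

    Both strands are scanned.  Each forward site pairs with the nearest
    downstream reverse site whose product length falls in
    [``min_len``, ``max_len``]; no nested multi-products per forward site.
    "-"-strand products are reported reverse-complemented so every amplicon
    starts with the forward-primer footprint.  The length window always
    refers to the footprint-inclusive product, even when trimming.
    """
    tol = tol or MatchTolerance()
    if min_len >= max_len:
        raise ValueError("min_len must be smaller than max_len")
    T = normalize_sequence(template)
    tid = contig_id

    f_plus = find_primer_sites(T, pair.forward, tol, "+", tid)
    r_minus = find_primer_sites(T, pair.reverse, tol, "-", tid)
    f_minus = find_primer_sites(T, pair.forward, tol, "-", tid)
    r_plus = find_primer_sites(T, pair.reverse, tol, "+", tid)

    amps: list[Amplicon] = []

    for f in f_plus:  # products read left-to-right on the template
        for r in r_minus:
            if r.start < f.end:
                continue
            plen = r.end - f.start
            if plen > max_len:
                break
            if plen < min_len:
                continue
            if trim_primers:
                start, end = f.end, r.start
                seq = T[start:end]
            else:
                start, end = f.start, r.end
                seq = T[start:end]
            amps.append(
                Amplicon(genome_id, contig_id, start, end, "+", seq, f, r,
                         primers_included=not trim_primers)
            )
            break

    for f in f_minus:  # products read right-to-left; report reverse-complemented
        for r in reversed(r_plus):
            if r.end > f.start:
                continue
            plen = f.end - r.start
            if plen > max_len:
                break
            if plen < min_len:
                continue
            if trim_primers:
                start, end = r.end, f.start
                seq = reverse_complement(T[start:end]) if end > start else ""
            else:
                start, end = r.start, f.end
                seq = reverse_complement(T[start:end])
            amps.append(
                Amplicon(genome_id, contig_id, start, end, "-", seq, f, r,
                         primers_included=not trim_primers)
            )
            break

    amps.sort(key=lambda a: (a.start, a.end, a.strand))
    return amps
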