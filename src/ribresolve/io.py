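"""Readers and writers for the plain-text formats the pipeline touches.

The readers enforce a strict contract: malformed records are rejected with
the file name and line number, duplicate identifiers are errors, sequences
are uppercase-normalized with U mapped to T.  GFF3 coordinates are kept
1-based inclusive here and converted to 0-based half-open at the point of
use (gene extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import InputFormatError
from .ispcr import IUPAC_CODES


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse a FASTA file into (id, description, sequence) triples.

    Tolerates wrapped lines, CRLF endings, lowercase and RNA (U) input.
    The id is the first whitespace token of the header; the description is
    the remainder.  Duplicate ids, characters outside the IUPAC alphabet,
    records without sequence and files without records are all rejected
    with a line-numbered message.
    """
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_chunks)
        if not seq:
            raise InputFormatError(
                f"{path}:{header_line}: record {cur_id!r} has no sequence"
            )
        records.append((cur_id, cur_desc, seq))

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise InputFormatError(f"{path}:{ln}: empty FASTA header")
                cur_id = header.split()[0]
                cur_desc = header[len(cur_id):].strip()
                if cur_id in seen:
                    raise InputFormatError(
                        f"{path}:{ln}: duplicate FASTA id {cur_id!r}"
                    )
                seen.add(cur_id)
                cur_chunks = []
                header_line = ln
            elif not line.strip():
                continue
            else:
                if cur_id is None:
                    raise InputFormatError(
                        f"{path}:{ln}: sequence data before first '>' header"
                    )
                chunk = line.strip().upper().replace("U", "T")
                bad = set(chunk) - IUPAC_CODES
                if bad:
                    raise InputFormatError(
                        f"{path}:{ln}: invalid sequence character {sorted(bad)[0]!r}"
                    )
                cur_chunks.append(chunk)
    flush()
    if not records:
        raise InputFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], wrap: int = 60) -> None:
    """Write (header, sequence) pairs, wrapping sequence lines at ``wrap``."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 feature line; start/end are 1-based inclusive as in the file."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str] = field(default_factory=dict)
    line_no: int = 0


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3(source: str | Path | Iterable[str], label: str = "<gff>") -> list[GffFeature]:
    """Parse GFF3 from a path or an iterable of lines.

    Only structural validation is done here (9 tab-separated columns,
    integer 1-based coordinates with start <= end); semantic checks against
    a genome happen in gene extraction.
    """
    if isinstance(source, (str, Path)):
        label = str(source)
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)

    feats: list[GffFeature] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise InputFormatError(
                f"{label}:{ln}: expected 9 tab-separated columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise InputFormatError(f"{label}:{ln}: non-integer coordinates") from exc
        if start < 1 or end < start:
            raise InputFormatError(
                f"{label}:{ln}: invalid coordinate range {start}..{end}"
            )
        if fields[6] not in ("+", "-", ".", "?"):
            raise InputFormatError(f"{label}:{ln}: invalid strand {fields[6]!r}")
        feats.append(
            GffFeature(
                seqid=fields[0], source=fields[1], type=fields[2],
                start=start, end=end, score=fields[5], strand=fields[6],
                phase=fields[7], attributes=_parse_attributes(fields[8]),
                line_no=ln,
            )
        )
    return feats


def read_metadata(path: str | Path) -> dict[str, str]:
    """Read a genome metadata TSV mapping genome_id -> organism name.

    A header line starting with 'genome_id' is skipped; duplicate ids are
    rejected.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if ln == 1 and fields[0].strip().lower() == "genome_id":
                continue
            if len(fields) < 2:
                raise InputFormatError(
                    f"{path}:{ln}: expected at least 2 tab-separated fields"
                )
            gid, organism = fields[0].strip(), fields[1].strip()
            if not gid or not organism:
                raise InputFormatError(f"{path}:{ln}: empty genome_id or organism")
            if gid in mapping:
                raise InputFormatError(f"{path}:{ln}: duplicate genome_id {gid!r}")
            mapping[gid] = organism
    if not mapping:
        raise InputFormatError(f"{path}: no metadata rows found")
    return mapping
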