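"""FASTA input and the four hit output formats.

Internally all coordinates are 0-based half-open.  The FASTA-style, compact
and GFF3 writers render 1-based inclusive coordinates; BED renders 0-based
half-open.  Reverse-strand hits are written with descending coordinates in
the FASTA-style header (``>id:[end,start]``) and with ascending coordinates
plus a strand column everywhere else (GFF3 and BED forbid descending
coordinates).  If the input used RNA letters, matched texts are echoed with
U restored.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, List, Union
from urllib.parse import quote

from Bio import SeqIO

from .alphabet import Molecule, canonicalize_sequence
from .errors import FastaFormatError, InvalidResidueError
from .match_engine import FORWARD, Match

GFF_SOURCE = "patscan"


@dataclass
class SequenceRecord:
    id: str
    description: str
    residues: str
    rna_flag: bool = False
    molecule: Molecule = Molecule.NUCLEOTIDE


@dataclass
class HitReport:
    """Ordered matches plus the records they came from."""

    matches: List[Match]
    records: Dict[str, SequenceRecord] = field(default_factory=dict)

    def __post_init__(self):
        for m in self.matches:
            rec = self.records.get(m.seq_id)
            if rec is None:
                raise FastaFormatError(f"match on unknown sequence {m.seq_id}")
            if not (0 <= m.start <= m.end <= len(rec.residues)):
                raise FastaFormatError(
                    f"match span [{m.start},{m.end}) outside sequence "
                    f"{m.seq_id} bounds"
                )


def read_fasta(
    source: Union[str, os.PathLike, io.TextIOBase],
    molecule: Molecule = Molecule.NUCLEOTIDE,
) -> List[SequenceRecord]:
    """Read FASTA: one record per '>' header, multi-line sequences folded.

    Rejects input whose first non-blank line is not a header, duplicate ids,
    empty sequences, and residues outside the alphabet.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()
    stripped = text.lstrip()
    if not stripped:
        raise FastaFormatError("empty FASTA input")
    if not stripped.startswith(">"):
        raise FastaFormatError(
            "not FASTA: first non-blank line must start with '>'"
        )
    records: List[SequenceRecord] = []
    seen: Dict[str, int] = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        raw = str(rec.seq)
        if not raw:
            raise FastaFormatError(f"sequence {rec.id!r} is empty")
        try:
            residues, rna_flag = canonicalize_sequence(raw, molecule)
        except InvalidResidueError as exc:
            raise InvalidResidueError(
                exc.char, exc.position, context=f"sequence {rec.id!r}"
            ) from None
        description = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(rec.id, description, residues, rna_flag,
                           Molecule(molecule))
        )
        seen[rec.id] = seen.get(rec.id, 0) + 1
    duplicates = sorted(k for k, v in seen.items() if v > 1)
    if duplicates:
        raise FastaFormatError(f"duplicate ids: {', '.join(duplicates)}")
    return records


def _echo(text: str, rna_flag: bool) -> str:
    return text.replace("T", "U") if rna_flag else text


def _unit_texts(match: Match, rna_flag: bool) -> List[str]:
    # zero-length spans (a range that matched empty) are dropped from the
    # space-joined body but kept in the GFF3 sub-span attribute
    return [_echo(sp.text, rna_flag) for sp in match.unit_spans if sp.text]


def write_hits_fasta(report: HitReport) -> str:
    """FASTA-style hits: ``>id:[start,end]`` (1-based inclusive; reverse
    hits with the larger coordinate first) then the unit texts, space-joined.
    """
    out = []
    for m in report.matches:
        rec = report.records[m.seq_id]
        lo, hi = m.start + 1, m.end
        if m.strand == FORWARD:
            header = f">{m.seq_id}:[{lo},{hi}]"
        else:
            header = f">{m.seq_id}:[{hi},{lo}]"
        out.append(header)
        out.append(" ".join(_unit_texts(m, rec.rna_flag)))
    return "".join(line + "\n" for line in out)


def write_hits_compact(report: HitReport) -> str:
    """One TSV line per hit: id, start, end (1-based inclusive), strand,
    match text with unit boundaries marked by spaces."""
    out = []
    for m in report.matches:
        rec = report.records[m.seq_id]
        body = " ".join(_unit_texts(m, rec.rna_flag))
        out.append(
            f"{m.seq_id}\t{m.start + 1}\t{m.end}\t{m.strand}\t{body}"
        )
    return "".join(line + "\n" for line in out)


def _fmt_score(score) -> str:
    if score is None:
        return "."
    return str(int(score)) if float(score) == int(score) else f"{score:g}"


def write_hits_gff3(report: HitReport, pattern_text: str) -> str:
    """GFF3 hit lines with the pattern (percent-encoded) and per-unit
    sub-spans carried in the attributes column."""
    lines = ["##gff-version 3"]
    for i, m in enumerate(report.matches, start=1):
        rec = report.records[m.seq_id]
        ftype = (
            "nucleotide_motif"
            if rec.molecule is Molecule.NUCLEOTIDE
            else "polypeptide_motif"
        )
        subspans = "|".join(
            f"{sp.name}:{sp.start + 1}-{sp.end}" for sp in m.unit_spans
        )
        attrs = (
            f"ID={GFF_SOURCE}_hit_{i}"
            f";pattern={quote(pattern_text, safe='')}"
            f";unit_spans={subspans}"
        )
        lines.append(
            "\t".join(
                [
                    m.seq_id,
                    GFF_SOURCE,
                    ftype,
                    str(m.start + 1),
                    str(m.end),
                    _fmt_score(m.score),
                    m.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "".join(line + "\n" for line in lines)


def _bed_score(score) -> int:
    if score is None:
        return 0
    return max(0, min(1000, round(score)))


def write_hits_bed(report: HitReport) -> str:
    """BED6: chrom, 0-based half-open span, name, score 0-1000, strand."""
    out = []
    for i, m in enumerate(report.matches, start=1):
        out.append(
            f"{m.seq_id}\t{m.start}\t{m.end}\t{GFF_SOURCE}_{i}"
            f"\t{_bed_score(m.score)}\t{m.strand}"
        )
    return "".join(line + "\n" for line in out)


WRITERS = {
    "fasta": lambda report, pattern_text: write_hits_fasta(report),
    "compact": lambda report, pattern_text: write_hits_compact(report),
    "gff3": write_hits_gff3,
    "bed": lambda report, pattern_text: write_hits_bed(report),
}


def write_hits(report: HitReport, fmt: str, pattern_text: str = "") -> str:
    try:
        writer = WRITERS[fmt]
    except KeyError:
        raise ValueError(f"unknown output format {fmt!r}") from None
    return writer(report, pattern_text)
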