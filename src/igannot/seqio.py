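"""Sequence I/O: FASTA in, annotated FASTA + BED out, frame handling.

Nucleotide input follows the six-frame protocol: every read is
translated in all six frames, frames containing a stop codon are
removed, the survivors are annotated, and (by default) only the
best-scoring annotated frame of each original read is kept.  All
coordinates written to BED are 0-based half-open per the UCSC
convention.
"""

from __future__ import annotations

import gzip
import logging
import os
import sys
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .annotator import AnnotationResult
from .errors import AlignmentFormatError, IgannotError
from .imgt import REGION_ORDER

log = logging.getLogger("igannot")

_NT = set("ACGTUN")
_IUPAC_NT = set("ACGTUNRYSWKMBDHV")

FRAME_TAGS = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass
class SeqRecord:
    """One FASTA record with a detected or forced molecule type."""

    id: str
    description: str
    sequence: str
    molecule: str = "amino-acid"  # or "nucleotide"


def detect_molecule(sequence: str) -> str:
    """Nucleotide when >= 90% of characters are ACGTUN."""
    seq = sequence.upper()
    if not seq:
        return "amino-acid"
    nt = sum(1 for ch in seq if ch in _NT)
    return "nucleotide" if nt / len(seq) >= 0.9 else "amino-acid"


def _open_text(path: str | os.PathLike) -> IO[str]:
    if str(path) == "-":
        return sys.stdin
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p, "rt")


def read_fasta(
    path: str | os.PathLike, molecule: Optional[str] = None
) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file (or '-' for standard input).

    The id is the first whitespace-delimited header token; the molecule
    type is auto-detected per record unless forced.
    """
    handle = _open_text(path)
    try:
        lines = iter(handle)
        first = None
        lineno = 0
        for line in lines:
            lineno += 1
            if line.strip():
                first = line
                break
        if first is None:
            return
        if not first.startswith(">"):
            raise AlignmentFormatError(
                f"{path}: line {lineno}: sequence data before first "
                "FASTA header"
            )
        import itertools

        for header, seq in SimpleFastaParser(
                itertools.chain([first], lines)):
            seq = "".join(seq.split()).upper()
            if not seq:
                continue
            tokens = header.split(None, 1)
            rec_id = tokens[0] if tokens else ""
            desc = tokens[1] if len(tokens) > 1 else ""
            mol = molecule or detect_molecule(seq)
            yield SeqRecord(rec_id, desc, seq, mol)
    finally:
        if handle is not sys.stdin:
            handle.close()


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike,
                width: int = 60) -> None:
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else \
                f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for k in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[k:k + width] + "\n")
    tmp.replace(path)


def six_frame_translate(rec: SeqRecord) -> list[SeqRecord]:
    """Translate a nucleotide record in all six reading frames.

    Frames +1/+2/+3 read the sequence at offsets 0/1/2; -1/-2/-3 read
    the reverse complement likewise.  Trailing partial codons are
    dropped, stops render as '*', N-containing codons as 'X'.  Record
    ids get '/frame+1' ... '/frame-3' suffixes.

    Raises
    ------
    IgannotError
        If the sequence contains a non-IUPAC nucleotide character.
    """
    if rec.molecule != "nucleotide":
        raise IgannotError(f"{rec.id}: six-frame translation needs "
                           "nucleotide input")
    seq = rec.sequence.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in _IUPAC_NT:
            raise IgannotError(
                f"{rec.id}: invalid_nucleotide {ch!r} at position {i}")
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    out = []
    for tag in FRAME_TAGS:
        strand, off = tag[0], int(tag[1]) - 1
        src = fwd if strand == "+" else rev
        sub = src[off:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(sub.translate())
        out.append(SeqRecord(
            id=f"{rec.id}/frame{tag}",
            description=rec.description,
            sequence=aa,
            molecule="amino-acid",
        ))
    return out


def filter_stops(records: Iterable[SeqRecord]) -> list[SeqRecord]:
    """Drop every record whose sequence contains a stop ('*')."""
    kept, dropped = [], 0
    for rec in records:
        if "*" in rec.sequence:
            dropped += 1
        else:
            kept.append(rec)
    if dropped:
        level = logging.WARNING if not kept else logging.INFO
        log.log(level, "removed %d record(s) containing stop codons",
                dropped)
    return kept


def split_frame_id(record_id: str) -> tuple[str, Optional[str]]:
    """('read7', '-2') from 'read7/frame-2'; (id, None) if unsuffixed."""
    if "/frame" in record_id:
        base, tag = record_id.rsplit("/frame", 1)
        if tag in FRAME_TAGS:
            return base, tag
    return record_id, None


def select_best_frames(
    results: Sequence[AnnotationResult]
) -> list[AnnotationResult]:
    """Keep, per original read, only the best-scoring annotated frame.

    Reverse frames of a real antibody do not always contain a stop
    codon, so several frames of one read can survive filtering and even
    annotate; reporting them all would fabricate extra domains.  Results
    whose ids carry no frame suffix pass through untouched.  Rejected
    frames of a read that has an annotated frame are dropped; if no
    frame annotated, the best-rejected one is kept so the read still
    appears (once) in the summary.
    """
    order: list[str] = []
    groups: dict[str, list[AnnotationResult]] = {}
    passthrough: list[AnnotationResult] = []
    for res in results:
        base, tag = split_frame_id(res.query_id)
        if tag is None:
            passthrough.append(res)
            continue
        if base not in groups:
            groups[base] = []
            order.append(base)
        groups[base].append(res)
    out = list(passthrough)
    for base in order:
        group = groups[base]
        annotated = [r for r in group if r.annotated]
        if annotated:
            out.append(max(annotated, key=lambda r: r.bit_score))
        else:
            out.append(group[0])
    return out


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def bed_lines(results: Iterable[AnnotationResult]) -> Iterator[str]:
    """BED6 lines, grouped by query, regions in FR1..FR4 order."""
    for res in results:
        if not res.annotated:
            continue
        score = max(0, min(1000, int(round(res.bit_score))))
        rid, tag = split_frame_id(res.query_id)
        strand = "-" if tag and tag.startswith("-") else "+"
        name = res.query_id if not tag else rid
        for region in res.regions:
            yield (f"{name}\t{region.start}\t{region.end}\t"
                   f"{region.region}\t{score}\t{strand}")


def write_bed(results: Iterable[AnnotationResult],
              path: str | os.PathLike) -> None:
    """Write region coordinates as BED6 (atomically; no partial files)."""
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        for line in bed_lines(results):
            fh.write(line + "\n")
    tmp.replace(path)


def write_fasta_regions(
    results: Iterable[AnnotationResult],
    path: str | os.PathLike,
    which: Iterable[str] = ("full",),
    width: int = 60,
) -> None:
    """Write selected region subsequences as FASTA.

    ``which`` is a subset of FR1..FR4, CDR1..CDR3 and ``full`` (the
    whole spanned domain).  Headers are ``id|region|start-end|model``.
    """
    selectors = list(which)
    valid = set(REGION_ORDER) | {"full"}
    for s in selectors:
        if s not in valid:
            raise ValueError(f"unknown region selector {s!r}")
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        for res in results:
            if not res.annotated:
                continue
            chosen = []
            for s in selectors:
                if s == "full":
                    start, end = res.numbering.query_span
                    chosen.append(("full", start, end, _span_sequence(res)))
                else:
                    reg = res.region(s)
                    if reg is not None:
                        chosen.append((s, reg.start, reg.end, reg.sequence))
            for name, start, end, seq in chosen:
                fh.write(f">{res.query_id}|{name}|{start}-{end}|"
                         f"{res.model_name}\n")
                for k in range(0, len(seq), width):
                    fh.write(seq[k:k + width] + "\n")
    tmp.replace(path)


def _span_sequence(res: AnnotationResult) -> str:
    return "".join(r.sequence for r in res.regions)


def write_summary_tsv(results: Iterable[AnnotationResult],
                      path: str | os.PathLike) -> None:
    """Per-read machine-readable report (one row per query)."""
    cols = ["query_id", "status", "model", "bit_score",
            *(f"len_{r}" for r in REGION_ORDER), "reject_reasons"]
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        fh.write("# igannot summary v1\n")
        fh.write("\t".join(cols) + "\n")
        for res in results:
            lengths = {r.region: r.end - r.start for r in res.regions}
            fh.write("\t".join([
                res.query_id,
                res.status,
                res.model_name or ".",
                f"{res.bit_score:.1f}",
                *(str(lengths.get(r, 0)) for r in REGION_ORDER),
                ",".join(res.reject_reasons) or ".",
            ]) + "\n")
    tmp.replace(path)
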