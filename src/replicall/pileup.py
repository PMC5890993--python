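"""Pileup and panel input.

Per-replicate allele evidence enters as samtools mpileup text (one line per
covered position, 6 columns when a single BAM was piled up). The parser
produces strand-split, base-quality-filtered allele counts; everything
downstream (matrix construction, the enrichment test) works from these
counts, never from the raw text.

Coordinate conventions: pileup positions and :class:`PanelRegion` are
1-based inclusive; BED input is 0-based half-open and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

log = logging.getLogger(__name__)

DEFAULT_MIN_BASE_QUALITY = 30
DEFAULT_QUALITY_OFFSET = 33

_BASES = set("ACGTN")


class PileupParseError(ValueError):
    """Malformed mpileup input; message carries the 1-based line number."""


@dataclass(frozen=True)
class PanelRegion:
    """A target region, 1-based inclusive on both ends."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end


@dataclass
class AlleleCounts:
    """Quality-filtered allele evidence at one position of one replicate.

    ``fwd``/``rev`` map allele tokens to read counts on each strand.
    Tokens are single upper-case bases for SNVs, ``+SEQ`` for insertions
    (inserted sequence, upper case) and ``-n`` for deletions (deleted
    length), anchored at the base before the event as in mpileup.
    Reference-supporting reads are not listed; they are recoverable as
    ``depth - sum(non-indel alt counts)`` per strand. Indel tokens ride on
    an anchor read that is already included in depth, so they add no depth
    of their own.
    """

    contig: str
    pos: int
    ref: str
    fwd: dict[str, int] = field(default_factory=dict)
    rev: dict[str, int] = field(default_factory=dict)
    depth_fwd: int = 0
    depth_rev: int = 0

    @property
    def depth(self) -> int:
        return self.depth_fwd + self.depth_rev


def read_panel(stream: Iterable[str]) -> list[PanelRegion]:
    """Read a BED stream into sorted, merged 1-based inclusive regions.

    Abutting and overlapping records are merged; ``track``/``browser``/
    comment lines are skipped. Raises ``ValueError`` on records with
    end <= start.
    """
    raw: list[PanelRegion] = []
    for i, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"BED line {i}: expected >=3 columns")
        contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
        if end0 <= start0:
            raise ValueError(f"BED line {i}: end {end0} <= start {start0}")
        raw.append(PanelRegion(contig, start0 + 1, end0))
    raw.sort(key=lambda r: (r.contig, r.start, r.end))
    merged: list[PanelRegion] = []
    for reg in raw:
        if merged and merged[-1].contig == reg.contig and reg.start <= merged[-1].end + 1:
            prev = merged.pop()
            reg = PanelRegion(prev.contig, prev.start, max(prev.end, reg.end))
        merged.append(reg)
    return merged


def panel_length(panel: Iterable[PanelRegion]) -> int:
    """Total number of targeted base pairs."""
    return sum(len(r) for r in panel)


def write_panel(panel: Iterable[PanelRegion], stream: TextIO) -> None:
    for r in panel:
        stream.write(f"{r.contig}\t{r.start - 1}\t{r.end}\n")


def in_panel(panel: Iterable[PanelRegion], contig: str, pos: int) -> bool:
    return any(r.contains(contig, pos) for r in panel)


def _decode_read_bases(bases: str, line_no: int) -> list[tuple[str, bool, str | None]]:
    """Decode an mpileup read-base string.

    Returns one entry per read symbol that consumes a base-quality
    character: (allele token, is_forward, indel token attached to this
    read or None). Indel tokens follow their anchor symbol in the string
    and do not consume quality characters.
    """
    out: list[tuple[str, bool, str | None]] = []
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError(f"line {line_no}: dangling '^'")
            i += 2  # caret + mapping quality char, no base consumed
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            # indel attached to the previous read symbol
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {line_no}: indel without length at col {i}")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) != length:
                raise PileupParseError(f"line {line_no}: truncated indel sequence")
            if not out:
                raise PileupParseError(f"line {line_no}: indel with no anchor read")
            token = f"+{seq.upper()}" if c == "+" else f"-{length}"
            allele, is_fwd, prev = out[-1]
            if prev is not None:
                raise PileupParseError(f"line {line_no}: two indels on one anchor")
            out[-1] = (allele, is_fwd, token)
            i = j + length
            continue
        if c == ".":
            out.append(("REF", True, None))
        elif c == ",":
            out.append(("REF", False, None))
        elif c == "*":
            out.append(("DEL_SPAN", True, None))
        elif c == "#":
            out.append(("DEL_SPAN", False, None))
        elif c.upper() in _BASES:
            out.append((c.upper(), c.isupper(), None))
        else:
            raise PileupParseError(f"line {line_no}: unknown pileup symbol {c!r}")
        i += 1
    return out


def parse_mpileup_line(
    line: str,
    line_no: int,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    quality_encoding_offset: int = DEFAULT_QUALITY_OFFSET,
) -> AlleleCounts:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated input
        fields = line.split()
    if len(fields) != 6:
        raise PileupParseError(
            f"line {line_no}: expected 6 columns, got {len(fields)}"
        )
    contig, pos_s, ref, _depth_s, bases, quals = fields
    symbols = _decode_read_bases(bases, line_no)
    if len(symbols) != len(quals):
        raise PileupParseError(
            f"line {line_no}: {len(symbols)} read symbols but "
            f"{len(quals)} quality characters"
        )
    ac = AlleleCounts(contig=contig, pos=int(pos_s), ref=ref.upper())
    for (allele, is_fwd, indel), qchar in zip(symbols, quals):
        q = ord(qchar) - quality_encoding_offset
        if q < min_base_quality:
            continue  # fails quality: excluded from counts and depth
        if is_fwd:
            ac.depth_fwd += 1
        else:
            ac.depth_rev += 1
        side = ac.fwd if is_fwd else ac.rev
        if allele not in ("REF", "DEL_SPAN") and allele != ac.ref and allele != "N":
            side[allele] = side.get(allele, 0) + 1
        # deletion-spanning '*' counts toward depth only: the event was
        # already registered at its anchor position
        if indel is not None:
            side[indel] = side.get(indel, 0) + 1
    return ac


def parse_mpileup(
    stream: Iterable[str],
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    quality_encoding_offset: int = DEFAULT_QUALITY_OFFSET,
) -> Iterator[AlleleCounts]:
    """Parse an mpileup text stream into per-position AlleleCounts."""
    if quality_encoding_offset not in (33, 64):
        raise ValueError("quality_encoding_offset must be 33 or 64")
    for i, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        yield parse_mpileup_line(
            line, i, min_base_quality, quality_encoding_offset
        )


def restrict_to_panel(
    counts: Iterable[AlleleCounts], panel: list[PanelRegion]
) -> list[AlleleCounts]:
    """Drop positions outside the panel, logging how many were dropped."""
    kept, dropped = [], 0
    for ac in counts:
        if in_panel(panel, ac.contig, ac.pos):
            kept.append(ac)
        else:
            dropped += 1
    if dropped:
        log.info("dropped %d pileup positions outside the panel", dropped)
    return kept


def read_counts_tsv(stream: Iterable[str]) -> list[AlleleCounts]:
    """Read the alternative TSV allele-count format.

    Header columns: contig, pos, ref, allele, strand (+/-), count, depth.
    Rows with allele '.' carry only that strand's depth. The per-strand
    depth must be consistent across rows of one (position, strand).
    """
    by_pos: dict[tuple[str, int], AlleleCounts] = {}
    header: list[str] | None = None
    for i, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.lower() for f in fields]
            expected = ["contig", "pos", "ref", "allele", "strand", "count", "depth"]
            if header != expected:
                raise ValueError(f"counts TSV header must be {expected}")
            continue
        contig, pos_s, ref, allele, strand, count_s, depth_s = fields
        pos, count, depth = int(pos_s), int(count_s), int(depth_s)
        if strand not in "+-":
            raise ValueError(f"counts TSV line {i}: strand must be + or -")
        key = (contig, pos)
        ac = by_pos.setdefault(key, AlleleCounts(contig=contig, pos=pos, ref=ref.upper()))
        if strand == "+":
            if ac.depth_fwd and ac.depth_fwd != depth:
                raise ValueError(f"counts TSV line {i}: inconsistent fwd depth")
            ac.depth_fwd = depth
            side = ac.fwd
        else:
            if ac.depth_rev and ac.depth_rev != depth:
                raise ValueError(f"counts TSV line {i}: inconsistent rev depth")
            ac.depth_rev = depth
            side = ac.rev
        if allele != ".":
            side[allele.upper() if not allele.startswith("-") else allele] = count
    return sorted(by_pos.values(), key=lambda a: (a.contig, a.pos))
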