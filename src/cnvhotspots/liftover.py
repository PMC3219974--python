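"""Coordinate mapping between genomes through a block-level orthology map.

The map is a list of gapless alignment blocks (source interval -> target
chromosome/start, orientation + or -), the essential content of a UCSC chain
file flattened to one block per row.  An interval maps when at least
``min_mapped_fraction`` of its bases project through blocks AND every
projected base lands on one target chromosome in one orientation; the mapped
interval is the coordinate span of the projected bases.  Failures are
classified ``unmapped`` (no base projects), ``split`` (bases project to
multiple chromosomes or mixed orientations), or ``low_coverage``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import ParameterError


@dataclass(frozen=True)
class Block:
    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    orient: str  # "+" | "-"

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    @property
    def tgt_end(self) -> int:
        return self.tgt_start + self.length


@dataclass
class MapResult:
    ok: bool
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    reason: Optional[str] = None  # unmapped | split | low_coverage
    mapped_bases: int = 0

    @property
    def interval(self) -> tuple[str, int, int]:
        if not self.ok:
            raise ValueError(f"mapping failed: {self.reason}")
        return (self.chrom, self.start, self.end)


class AlignmentBlockMap:
    """Non-overlapping source blocks with equal-length target projections."""

    def __init__(self, blocks: Sequence[Block],
                 source_genome: str = "source", target_genome: str = "target"):
        self.source_genome = source_genome
        self.target_genome = target_genome
        by_chrom: dict[str, list[Block]] = {}
        for b in blocks:
            if b.src_start >= b.src_end:
                raise ParameterError(f"empty block on {b.src_chrom}:{b.src_start}-{b.src_end}")
            if b.orient not in ("+", "-"):
                raise ParameterError(f"block orientation must be + or -, got {b.orient!r}")
            by_chrom.setdefault(b.src_chrom, []).append(b)
        for chrom, bl in by_chrom.items():
            bl.sort(key=lambda b: b.src_start)
            for prev, nxt in zip(bl, bl[1:]):
                if nxt.src_start < prev.src_end:
                    raise ParameterError(
                        f"overlapping source blocks on {chrom} at {nxt.src_start}")
        self.by_chrom = by_chrom
        self._starts = {c: [b.src_start for b in bl] for c, bl in by_chrom.items()}

    def __len__(self) -> int:
        return sum(len(bl) for bl in self.by_chrom.values())

    def blocks(self) -> list[Block]:
        return [b for bl in self.by_chrom.values() for b in bl]

    def inverse(self) -> "AlignmentBlockMap":
        """The target->source map (negative blocks stay negative)."""
        inv = []
        for b in self.blocks():
            if b.orient == "+":
                inv.append(Block(b.tgt_chrom, b.tgt_start, b.tgt_end,
                                 b.src_chrom, b.src_start, "+"))
            else:
                inv.append(Block(b.tgt_chrom, b.tgt_start, b.tgt_end,
                                 b.src_chrom, b.src_start, "-"))
        return AlignmentBlockMap(inv, self.target_genome, self.source_genome)

    def overlapping_blocks(self, chrom: str, start: int, end: int) -> list[Block]:
        bl = self.by_chrom.get(chrom, [])
        if not bl:
            return []
        i = bisect_right(self._starts[chrom], start) - 1
        if i < 0:
            i = 0
        out = []
        while i < len(bl) and bl[i].src_start < end:
            if bl[i].src_end > start:
                out.append(bl[i])
            i += 1
        return out


def _project_piece(b: Block, s: int, e: int) -> tuple[int, int]:
    """Target coordinates of source sub-interval [s, e) inside block b."""
    if b.orient == "+":
        return (b.tgt_start + (s - b.src_start), b.tgt_start + (e - b.src_start))
    # minus strand: source left end maps to target right end
    return (b.tgt_start + (b.src_end - e), b.tgt_start + (b.src_end - s))


def map_interval(block_map: AlignmentBlockMap, interval: tuple[str, int, int],
                 min_mapped_fraction: float = 0.95) -> MapResult:
    """Project one (chrom, start, end) interval through the block map.

    Succeeds iff mapped bases / interval length >= ``min_mapped_fraction`` and
    all mapped bases fall on one target chromosome with one orientation; the
    result interval is the span of the projected bases.
    """
    chrom, start, end = interval
    if start >= end or start < 0:
        raise ParameterError(f"invalid interval {chrom}:{start}-{end}")
    hits = block_map.overlapping_blocks(chrom, start, end)
    if not hits:
        return MapResult(ok=False, reason="unmapped")
    mapped = 0
    tgt_chrom = None
    orient = None
    span_start, span_end = None, None
    for b in hits:
        s, e = max(start, b.src_start), min(end, b.src_end)
        mapped += e - s
        if tgt_chrom is None:
            tgt_chrom, orient = b.tgt_chrom, b.orient
        elif b.tgt_chrom != tgt_chrom or b.orient != orient:
            return MapResult(ok=False, reason="split", mapped_bases=mapped)
        ts, te = _project_piece(b, s, e)
        span_start = ts if span_start is None else min(span_start, ts)
        span_end = te if span_end is None else max(span_end, te)
    if mapped / (end - start) < min_mapped_fraction:
        return MapResult(ok=False, reason="low_coverage", mapped_bases=mapped)
    return MapResult(ok=True, chrom=tgt_chrom, start=span_start, end=span_end,
                     mapped_bases=mapped)


def map_cnv_set(block_map: AlignmentBlockMap, cnvs: Sequence,
                min_mapped_fraction: float = 0.95):
    """Map a list of CNV-like objects (needs .chrom/.start/.end, mutated copies returned).

    Returns ``(mapped_cnvs, mapped_fraction, failure_tally)``.  Input order is
    preserved among successes; an empty input reports fraction 1.0 by
    convention (with count 0 in the tally).
    """
    from dataclasses import replace

    mapped = []
    tally = {"mapped": 0, "unmapped": 0, "split": 0, "low_coverage": 0, "total": len(cnvs)}
    for c in cnvs:
        res = map_interval(block_map, (c.chrom, c.start, c.end), min_mapped_fraction)
        if res.ok:
            mapped.append(replace(c, chrom=res.chrom, start=res.start, end=res.end))
            tally["mapped"] += 1
        else:
            tally[res.reason] += 1
    fraction = tally["mapped"] / len(cnvs) if cnvs else 1.0
    return mapped, fraction, tally
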