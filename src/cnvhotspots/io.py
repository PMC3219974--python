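"""On-disk formats: BED, bedGraph, BED12 genes, chrom.sizes, block maps, plain TSVs.

Coordinates on disk follow BED conventions (0-based, half-open).  Every file
written by the pipeline starts with a ``#`` header naming the producing
version and the configuration hash, which all readers here skip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .core import CnvInterval, GeneModel, GenomeModel, ParameterError
from .liftover import AlignmentBlockMap, Block


class BedParseError(ParameterError):
    """A malformed line, reported with its 1-based line number."""


def _header(config_hash: Optional[str]) -> str:
    tag = f" config={config_hash}" if config_hash else ""
    return f"# cnvhotspots v{__version__}{tag}\n"


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> list[CnvInterval]:
    """Read BED3/BED6+ into CnvIntervals.

    Extra columns beyond strand are interpreted as species, sample, state.
    Malformed lines raise :class:`BedParseError` naming the line.
    """
    out: list[CnvInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise BedParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] else f"iv_{lineno}"
            species = fields[6] if len(fields) > 6 else "human"
            sample = fields[7] if len(fields) > 7 and fields[7] not in ("", ".") else None
            state = fields[8] if len(fields) > 8 else "unknown"
            out.append(CnvInterval(id=name, chrom=chrom, start=start, end=end,
                                   species=species, state=state, sample=sample))
    return out


def write_bed(cnvs: Sequence[CnvInterval], path, config_hash: Optional[str] = None
              ) -> None:
    """Write CnvIntervals as BED6+ (extra columns: species, sample, state)."""
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        for c in cnvs:
            fh.write("\t".join([c.chrom, str(c.start), str(c.end), c.id, "0", ".",
                                c.species, c.sample or ".", c.state]) + "\n")


# ---------------------------------------------------------------------------
# bedGraph score tracks
# ---------------------------------------------------------------------------

def read_score_track(path) -> pd.DataFrame:
    """Read bedGraph (chrom, start, end, score) and verify non-overlap per chromosome."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad bedGraph record") from exc
            if rows[-1][1] >= rows[-1][2]:
                raise BedParseError(f"{path}:{lineno}: start >= end")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise BedParseError(f"{path}: overlapping records on {chrom}")
    return df


def write_score_track(frame: pd.DataFrame, path, config_hash: Optional[str] = None
                      ) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        for r in frame.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.score:.6g}\n")


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeModel, sizes_path, gaps_path,
                 config_hash: Optional[str] = None) -> None:
    with open(sizes_path, "w") as fh:
        fh.write(_header(config_hash))
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with open(gaps_path, "w") as fh:
        fh.write(_header(config_hash))
        for chrom, ivs in genome.gaps.items():
            for s, e in ivs:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_genome(sizes_path, gaps_path=None) -> GenomeModel:
    chroms = []
    with open(sizes_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            chroms.append((name, int(length)))
    gaps: dict[str, list[tuple[int, int]]] = {}
    if gaps_path is not None and Path(gaps_path).exists():
        with open(gaps_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, s, e = line.split("\t")[:3]
                gaps.setdefault(chrom, []).append((int(s), int(e)))
    return GenomeModel(chromosomes=chroms, gaps=gaps)


# ---------------------------------------------------------------------------
# plain TSVs (probes, samples, tables) ride on pandas
# ---------------------------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, config_hash: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# orthology block maps
# ---------------------------------------------------------------------------

def write_block_map(block_map: AlignmentBlockMap, path,
                    config_hash: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        fh.write("src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\torient\n")
        for b in sorted(block_map.blocks(), key=lambda b: (b.src_chrom, b.src_start)):
            fh.write(f"{b.src_chrom}\t{b.src_start}\t{b.src_end}"
                     f"\t{b.tgt_chrom}\t{b.tgt_start}\t{b.orient}\n")


def read_block_map(path) -> AlignmentBlockMap:
    df = read_tsv(path)
    blocks = [Block(str(r.src_chrom), int(r.src_start), int(r.src_end),
                    str(r.tgt_chrom), int(r.tgt_start), str(r.orient))
              for r in df.itertuples(index=False)]
    return AlignmentBlockMap(blocks)


def read_chain_file(path) -> AlignmentBlockMap:
    """Optional adapter: flatten a UCSC chain file into gapless blocks.

    Supports the standard ``chain`` header + alignment-data lines.  Negative
    target strands are converted to explicit minus-orientation blocks with
    plus-strand target coordinates.
    """
    blocks: list[Block] = []
    with open(path) as fh:
        header = None
        s_pos = t_pos = 0
        for raw in fh:
            line = raw.strip()
            if not line:
                header = None
                continue
            if line.startswith("chain"):
                f = line.split()
                # chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id
                header = {"s_chrom": f[2], "s_size": int(f[3]), "s_strand": f[4],
                          "s_start": int(f[5]),
                          "t_chrom": f[7], "t_size": int(f[8]), "t_strand": f[9],
                          "t_start": int(f[10])}
                if header["s_strand"] != "+":
                    raise ParameterError("chain source strand must be +")
                s_pos, t_pos = header["s_start"], header["t_start"]
                continue
            if header is None:
                continue
            f = [int(x) for x in line.split()]
            size = f[0]
            if header["t_strand"] == "+":
                blocks.append(Block(header["s_chrom"], s_pos, s_pos + size,
                                    header["t_chrom"], t_pos, "+"))
            else:
                tgt_start = header["t_size"] - (t_pos + size)
                blocks.append(Block(header["s_chrom"], s_pos, s_pos + size,
                                    header["t_chrom"], tgt_start, "-"))
            if len(f) == 3:
                s_pos += size + f[1]
                t_pos += size + f[2]
            else:
                header = None
    return AlignmentBlockMap(blocks)


# ---------------------------------------------------------------------------
# BED12 gene models
# ---------------------------------------------------------------------------

def write_genes_bed12(genes: Sequence[GeneModel], path,
                      config_hash: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config_hash))
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write("\t".join([g.chrom, str(g.start), str(g.end), g.gene_id, "0",
                                g.strand, str(g.start), str(g.end), "0",
                                str(len(g.exons)), sizes, starts]) + "\n")


def read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(gene_id=f[3], chrom=chrom, strand=f[5],
                                   start=start, end=end, exons=exons))
    return genes


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
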