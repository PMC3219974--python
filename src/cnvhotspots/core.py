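"""Shared domain types for the comparative CNV-hotspot pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` base pairs,
matching BED conventions on disk.  Intervals never span chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SPECIES = ("human", "chimp", "macaque")
STATES = ("gain", "loss", "multiallelic", "unknown")


class ParameterError(ValueError):
    """A parameter is outside its documented range."""


class PlacementError(RuntimeError):
    """An interval could not be placed on the genome (too large, or retries exhausted)."""


@dataclass
class GenomeModel:
    """A genome as an ordered list of chromosomes plus an unmappable gap mask.

    Parameters
    ----------
    chromosomes : list of (name, length)
        Chromosome names and lengths in bp, in genome order.
    gaps : dict chrom -> list of (start, end)
        Half-open unmappable intervals (assembly gaps).  Normalised (sorted,
        merged, clipped to chromosome bounds) on construction.
    """

    chromosomes: list[tuple[str, int]]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise ParameterError(f"chromosome {name} has non-positive length {length}")
        lengths = self.lengths()
        norm: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in self.gaps.items():
            if chrom not in lengths:
                raise ParameterError(f"gap on unknown chromosome {chrom!r}")
            clipped = []
            for s, e in ivs:
                s, e = max(0, int(s)), min(lengths[chrom], int(e))
                if e > s:
                    clipped.append((s, e))
            clipped.sort()
            merged: list[tuple[int, int]] = []
            for s, e in clipped:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            norm[chrom] = merged
        self.gaps = norm

    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def total_gap_length(self) -> int:
        return sum(e - s for ivs in self.gaps.values() for s, e in ivs)

    def segments(self, extra_mask: Optional[dict[str, list[tuple[int, int]]]] = None
                 ) -> list[tuple[str, int, int]]:
        """Maximal non-gap (mappable) intervals, optionally minus an extra mask."""
        out: list[tuple[str, int, int]] = []
        for chrom, length in self.chromosomes:
            blocked = list(self.gaps.get(chrom, []))
            if extra_mask:
                blocked += [(max(0, s), min(length, e))
                            for s, e in extra_mask.get(chrom, []) if e > s]
            blocked.sort()
            pos = 0
            for s, e in blocked:
                if s > pos:
                    out.append((chrom, pos, s))
                pos = max(pos, e)
            if pos < length:
                out.append((chrom, pos, length))
        return out


@dataclass
class ProbeLayout:
    """Ordered aCGH probe positions on a genome."""

    probes: pd.DataFrame  # columns: chrom, pos (sorted within chromosome)
    mean_spacing: float

    def __post_init__(self) -> None:
        cols = list(self.probes.columns)
        if cols[:2] != ["chrom", "pos"]:
            raise ParameterError(f"probe table needs columns (chrom, pos), got {cols}")

    def __len__(self) -> int:
        return len(self.probes)


@dataclass
class AcghSample:
    """One individual's aCGH profile: probe positions with log2 test/reference ratios."""

    sample_id: str
    data: pd.DataFrame  # columns: chrom, pos, log2

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CnvInterval:
    """A CNV as a half-open genomic interval with species, state and provenance."""

    id: str
    chrom: str
    start: int
    end: int
    species: str = "human"
    state: str = "unknown"
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParameterError(f"CNV {self.id}: start {self.start} >= end {self.end}")
        if self.species not in SPECIES:
            raise ParameterError(f"CNV {self.id}: unknown species {self.species!r}")
        if self.state not in STATES:
            raise ParameterError(f"CNV {self.id}: unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnvCall:
    """A per-sample CNV call: a run of consecutive significantly deviating probes."""

    chrom: str
    start: int
    end: int
    sample_id: str
    direction: str  # gain | loss
    n_probes: int
    mean_log2: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnvLocus:
    """Calls merged across samples into one locus with an allelic state."""

    chrom: str
    start: int
    end: int
    members: list[CnvCall]
    state: str
    carriers: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OverlapCriteria:
    """Cross-species overlap thresholds.

    ``pairwise_fraction`` governs two-species (HC / HR) membership;
    ``three_way_pair_fraction`` and ``three_way_total_fraction`` govern the
    three-species (HCR) rule: every pairwise overlap, measured as a fraction of
    the shorter interval of the pair, must reach ``three_way_pair_fraction``,
    and the common three-way intersection must cover
    ``three_way_total_fraction`` of the shortest of the three intervals.
    ``anchor`` selects whether the pairwise fraction is measured on the human
    (anchor) interval or reciprocally on the shorter of the two.
    """

    pairwise_fraction: float = 0.5
    three_way_pair_fraction: float = 0.2
    three_way_total_fraction: float = 0.5
    anchor: str = "human"  # "human" | "reciprocal"

    def __post_init__(self) -> None:
        for name in ("pairwise_fraction", "three_way_pair_fraction", "three_way_total_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ParameterError(f"{name} must be in (0, 1], got {v}")
        if self.anchor not in ("human", "reciprocal"):
            raise ParameterError(f"anchor must be 'human' or 'reciprocal', got {self.anchor!r}")


@dataclass
class HotspotRegion:
    """A merged region of three-species (HCR) CNVs."""

    chrom: str
    start: int
    end: int
    member_ids: list[str]
    species_counts: dict[str, int]
    complex: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NullDistribution:
    """Values of a statistic over N permutation iterations, with provenance."""

    name: str
    values: np.ndarray
    n_iter: int
    seed: int
    mask_description: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_iter < 1 or len(self.values) != self.n_iter:
            raise ParameterError(
                f"null distribution length {len(self.values)} != n_iter {self.n_iter}")


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    fold: float
    p_empirical: float
    z: Optional[float]

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_empirical": self.p_empirical,
            "z": self.z,
        }


@dataclass
class TestResult:
    """A named test statistic (KS D or Yates-corrected chi-square) with its p-value."""

    name: str  # "KS_D" | "chi2_yates"
    value: float
    p_value: float
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "value": self.value, "p_value": self.p_value,
                **self.detail}


@dataclass
class GeneModel:
    """A gene: strand, transcript span and exons; TSS at the strand-appropriate end."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ParameterError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ParameterError(f"gene {self.gene_id}: exon ({s},{e}) outside span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class TruthTable:
    """Ground truth for synthetic data: planted hotspots, CNVs and per-sample events."""

    hotspots: pd.DataFrame  # hotspot_id, chrom, start, end
    cnvs: pd.DataFrame      # id, species, chrom, start, end, state, hotspot_id (or "")
    events: pd.DataFrame    # sample, chrom, start, end, state, log2_shift, cnv_id


def intervals_to_frame(cnvs: Sequence[CnvInterval]) -> pd.DataFrame:
    """Tabulate CnvIntervals (one row per CNV, BED-like column order)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in cnvs],
            "start": [c.start for c in cnvs],
            "end": [c.end for c in cnvs],
            "id": [c.id for c in cnvs],
            "species": [c.species for c in cnvs],
            "state": [c.state for c in cnvs],
            "sample": [c.sample if c.sample is not None else "" for c in cnvs],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[CnvInterval]:
    out = []
    for row in df.itertuples(index=False):
        out.append(CnvInterval(
            id=str(row.id), chrom=str(row.chrom), start=int(row.start), end=int(row.end),
            species=str(getattr(row, "species", "human")),
            state=str(getattr(row, "state", "unknown")),
            sample=(str(row.sample) or None) if hasattr(row, "sample") else None,
        ))
    return out
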