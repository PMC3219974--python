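"""Cross-species CNV overlap: HC/HR/HCR identification, complex CNVs, hotspot collapsing.

Definitions
-----------
HC / HR : human CNVs that overlap at least one chimpanzee / macaque CNV under a
    50% pairwise criterion (fraction of the human interval by default).
HCR : human CNVs with a chimpanzee and a macaque partner such that every
    pairwise overlap reaches 20% of the shorter interval of the pair and the
    three-way intersection covers 50% of the shortest of the three.
Complex CNV : one that overlaps another CNV of the same set with reciprocal
    overlap below 50% (different breakpoints at one locus).

All membership thresholds are inclusive (>=) so boundary cases are
deterministic.  The heavy lifting runs on sorted numpy arrays; dataclass-level
wrappers preserve ids, partners and ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import CnvInterval, HotspotRegion, OverlapCriteria


def overlap_bp(a: tuple, b: tuple) -> int:
    """Overlap in bp between two (chrom, start, end) tuples (0 across chromosomes)."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """min(overlap/len(a), overlap/len(b)); symmetric in its arguments."""
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))


# ---------------------------------------------------------------------------
# vectorised pair machinery on global (chromosome-offset) coordinates
# ---------------------------------------------------------------------------

class GlobalCoords:
    """Maps (chrom, start, end) to a single integer axis with disjoint chromosome slots."""

    def __init__(self, chrom_names: Sequence[str], chrom_lengths: Sequence[int]):
        self.offset: dict[str, int] = {}
        pos = 0
        for name, length in zip(chrom_names, chrom_lengths):
            self.offset[name] = pos
            pos += int(length) + 1  # +1 spacer: abutting ends never cross chromosomes
        self.total = pos

    def encode(self, chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
        off = np.array([self.offset[c] for c in chroms], dtype=np.int64)
        return off + np.asarray(starts, dtype=np.int64), off + np.asarray(ends, dtype=np.int64)

    @classmethod
    def for_intervals(cls, *sets: Sequence[CnvInterval]) -> "GlobalCoords":
        chroms: dict[str, int] = {}
        for cnvs in sets:
            for c in cnvs:
                chroms[c.chrom] = max(chroms.get(c.chrom, 0), c.end)
        names = sorted(chroms)
        return cls(names, [chroms[n] for n in names])


def candidate_pairs(a_start: np.ndarray, a_end: np.ndarray,
                    b_start: np.ndarray, b_end: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All index pairs (i, j) with a[i] and b[j] overlapping by >= 1 bp.

    Coordinates must be global (see :class:`GlobalCoords`).  Returns
    ``(i_idx, j_idx, overlap_bp)`` arrays.  b need not be sorted.
    """
    a_start = np.asarray(a_start, dtype=np.int64)
    a_end = np.asarray(a_end, dtype=np.int64)
    if len(a_start) == 0 or len(b_start) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z
    order = np.argsort(b_start, kind="stable")
    bs = np.asarray(b_start, dtype=np.int64)[order]
    be = np.asarray(b_end, dtype=np.int64)[order]
    cummax_end = np.maximum.accumulate(be)
    lo = np.searchsorted(cummax_end, a_start, side="right")
    hi = np.searchsorted(bs, a_end, side="left")
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    if total == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z
    i_idx = np.repeat(np.arange(len(a_start)), counts)
    starts_of_run = np.repeat(np.cumsum(counts) - counts, counts)
    j_sorted = np.arange(total) - starts_of_run + np.repeat(lo, counts)
    ov = np.minimum(a_end[i_idx], be[j_sorted]) - np.maximum(a_start[i_idx], bs[j_sorted])
    keep = ov > 0
    return i_idx[keep], order[j_sorted[keep]], ov[keep]


def count_anchor_overlaps(a_start, a_end, b_start, b_end,
                          fraction: float, mode: str = "human") -> np.ndarray:
    """Boolean mask over anchors a: some single b interval satisfies the pairwise rule.

    mode "human": overlap / len(anchor) >= fraction.
    mode "reciprocal": min(overlap/len(a), overlap/len(b)) >= fraction.
    """
    i_idx, j_idx, ov = candidate_pairs(a_start, a_end, b_start, b_end)
    qualifies = np.zeros(len(a_start), dtype=bool)
    if len(i_idx) == 0:
        return qualifies
    len_a = (np.asarray(a_end) - np.asarray(a_start))[i_idx]
    if mode == "human":
        frac = ov / len_a
    else:
        len_b = (np.asarray(b_end) - np.asarray(b_start))[j_idx]
        frac = np.minimum(ov / len_a, ov / len_b)
    hits = i_idx[frac >= fraction]
    qualifies[hits] = True
    return qualifies


# ---------------------------------------------------------------------------
# public, id-preserving API
# ---------------------------------------------------------------------------

@dataclass
class OverlapAnnotation:
    """A qualifying anchor CNV with its partner ids."""

    cnv: CnvInterval
    partners: list[str] = field(default_factory=list)


def _arrays(gc: GlobalCoords, cnvs: Sequence[CnvInterval]) -> tuple[np.ndarray, np.ndarray]:
    return gc.encode([c.chrom for c in cnvs],
                     np.array([c.start for c in cnvs], dtype=np.int64),
                     np.array([c.end for c in cnvs], dtype=np.int64)) \
        if cnvs else (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))


def find_two_species_overlaps(anchor_set: Sequence[CnvInterval],
                              other_set: Sequence[CnvInterval],
                              criteria: OverlapCriteria = OverlapCriteria(),
                              ) -> list[OverlapAnnotation]:
    """Human CNVs overlapping at least one other-species CNV (HC or HR sets).

    In anchor mode a human CNV qualifies when a *single* partner covers at
    least ``criteria.pairwise_fraction`` of its length; in reciprocal mode the
    reciprocal overlap must reach the threshold.  Partner ids are recorded for
    every partner individually satisfying the rule.
    """
    if not anchor_set or not other_set:
        return []
    gc = GlobalCoords.for_intervals(anchor_set, other_set)
    a_s, a_e = _arrays(gc, anchor_set)
    b_s, b_e = _arrays(gc, other_set)
    i_idx, j_idx, ov = candidate_pairs(a_s, a_e, b_s, b_e)
    if len(i_idx) == 0:
        return []
    len_a = (a_e - a_s)[i_idx]
    if criteria.anchor == "human":
        frac = ov / len_a
    else:
        len_b = (b_e - b_s)[j_idx]
        frac = np.minimum(ov / len_a, ov / len_b)
    ok = frac >= criteria.pairwise_fraction
    partners: dict[int, list[str]] = {}
    for i, j in zip(i_idx[ok], j_idx[ok]):
        partners.setdefault(int(i), []).append(other_set[int(j)].id)
    return [OverlapAnnotation(anchor_set[i], partners[i]) for i in sorted(partners)]


@dataclass
class ThreeWayAnnotation:
    """An HCR human CNV with its chosen chimp and macaque partner ids."""

    cnv: CnvInterval
    chimp_partner: str
    macaque_partner: str
    intersection: tuple[int, int]  # on the human chromosome of cnv


def find_three_species_overlaps(human: Sequence[CnvInterval],
                                chimp: Sequence[CnvInterval],
                                macaque: Sequence[CnvInterval],
                                criteria: OverlapCriteria = OverlapCriteria(),
                                ) -> list[ThreeWayAnnotation]:
    """Human CNVs with a chimp and a macaque partner meeting the three-way rule.

    Each of the three pairwise overlaps (h-c, h-r, c-r), measured as a
    fraction of the shorter interval of the pair, must reach
    ``three_way_pair_fraction``, and the common intersection of all three must
    cover ``three_way_total_fraction`` of the shortest interval.  When several
    partner pairs qualify, the pair with the largest three-way intersection is
    kept (ties broken by leftmost partner coordinates).
    """
    if not human or not chimp or not macaque:
        return []
    gc = GlobalCoords.for_intervals(human, chimp, macaque)
    h_s, h_e = _arrays(gc, human)
    c_s, c_e = _arrays(gc, chimp)
    r_s, r_e = _arrays(gc, macaque)

    def pair_candidates(b_s, b_e):
        i_idx, j_idx, ov = candidate_pairs(h_s, h_e, b_s, b_e)
        if len(i_idx) == 0:
            return {}
        shorter = np.minimum((h_e - h_s)[i_idx], (b_e - b_s)[j_idx])
        ok = ov / shorter >= criteria.three_way_pair_fraction
        cand: dict[int, list[int]] = {}
        for i, j in zip(i_idx[ok], j_idx[ok]):
            cand.setdefault(int(i), []).append(int(j))
        return cand

    c_cand = pair_candidates(c_s, c_e)
    r_cand = pair_candidates(r_s, r_e)

    out: list[ThreeWayAnnotation] = []
    for hi in sorted(set(c_cand) & set(r_cand)):
        best = None
        for cj in c_cand[hi]:
            for rj in r_cand[hi]:
                ov_cr = min(c_e[cj], r_e[rj]) - max(c_s[cj], r_s[rj])
                if ov_cr <= 0:
                    continue
                shorter_cr = min(c_e[cj] - c_s[cj], r_e[rj] - r_s[rj])
                if ov_cr / shorter_cr < criteria.three_way_pair_fraction:
                    continue
                tri_s = max(h_s[hi], c_s[cj], r_s[rj])
                tri_e = min(h_e[hi], c_e[cj], r_e[rj])
                tri = tri_e - tri_s
                if tri <= 0:
                    continue
                shortest = min(h_e[hi] - h_s[hi], c_e[cj] - c_s[cj], r_e[rj] - r_s[rj])
                if tri / shortest < criteria.three_way_total_fraction:
                    continue
                key = (-tri, c_s[cj], r_s[rj])
                if best is None or key < best[0]:
                    best = (key, cj, rj, (int(tri_s), int(tri_e)))
        if best is not None:
            _, cj, rj, (ts, te) = best
            h = human[hi]
            off = gc.offset[h.chrom]
            out.append(ThreeWayAnnotation(h, chimp[cj].id, macaque[rj].id,
                                          (ts - off, te - off)))
    return out


def count_three_species_overlaps(h_s, h_e, c_s, c_e, r_s, r_e,
                                 criteria: OverlapCriteria) -> int:
    """Fast HCR count on pre-encoded global coordinate arrays (for permutation nulls)."""
    ic, jc, ovc = candidate_pairs(h_s, h_e, c_s, c_e)
    ir, jr, ovr = candidate_pairs(h_s, h_e, r_s, r_e)
    if len(ic) == 0 or len(ir) == 0:
        return 0
    okc = ovc / np.minimum((h_e - h_s)[ic], (c_e - c_s)[jc]) >= criteria.three_way_pair_fraction
    okr = ovr / np.minimum((h_e - h_s)[ir], (r_e - r_s)[jr]) >= criteria.three_way_pair_fraction
    c_cand: dict[int, list[int]] = {}
    for i, j in zip(ic[okc], jc[okc]):
        c_cand.setdefault(int(i), []).append(int(j))
    r_cand: dict[int, list[int]] = {}
    for i, j in zip(ir[okr], jr[okr]):
        r_cand.setdefault(int(i), []).append(int(j))
    n = 0
    for hi in set(c_cand) & set(r_cand):
        hs, he = h_s[hi], h_e[hi]
        found = False
        for cj in c_cand[hi]:
            for rj in r_cand[hi]:
                ov_cr = min(c_e[cj], r_e[rj]) - max(c_s[cj], r_s[rj])
                if ov_cr <= 0:
                    continue
                if ov_cr / min(c_e[cj] - c_s[cj], r_e[rj] - r_s[rj]) \
                        < criteria.three_way_pair_fraction:
                    continue
                tri = min(he, c_e[cj], r_e[rj]) - max(hs, c_s[cj], r_s[rj])
                if tri <= 0:
                    continue
                shortest = min(he - hs, c_e[cj] - c_s[cj], r_e[rj] - r_s[rj])
                if tri / shortest >= criteria.three_way_total_fraction:
                    found = True
                    break
            if found:
                break
        if found:
            n += 1
    return n


def classify_complex(cnvs: Sequence[CnvInterval],
                     reciprocal_threshold: float = 0.5) -> list[bool]:
    """Flag each CNV as complex: it overlaps another CNV in the same set with
    reciprocal overlap below the threshold (default 50%)."""
    flags = [False] * len(cnvs)
    if len(cnvs) < 2:
        return flags
    gc = GlobalCoords.for_intervals(cnvs)
    s, e = _arrays(gc, cnvs)
    i_idx, j_idx, ov = candidate_pairs(s, e, s, e)
    self_pair = i_idx == j_idx
    i_idx, j_idx, ov = i_idx[~self_pair], j_idx[~self_pair], ov[~self_pair]
    if len(i_idx) == 0:
        return flags
    rec = np.minimum(ov / (e - s)[i_idx], ov / (e - s)[j_idx])
    for i in i_idx[rec < reciprocal_threshold]:
        flags[int(i)] = True
    return flags


def collapse_hotspots(hcr: Sequence[ThreeWayAnnotation],
                      merge_gap: int = 0,
                      partner_intervals: Optional[dict[str, tuple[str, int, int]]] = None,
                      complex_flags: Optional[dict[str, bool]] = None,
                      ) -> list[HotspotRegion]:
    """Single-linkage merge of HCR CNVs (plus partner projections) into hotspot regions.

    Members whose gap is <= ``merge_gap`` bp are merged; the region interval is
    the union span.  ``partner_intervals`` maps partner CNV ids to their human
    coordinates so the chimp/macaque extents widen the region; the region's
    member list holds human HCR CNV ids only.  ``complex_flags`` (by human CNV
    id) sets the region's complex flag to "any member complex".  Output is
    ordered by coordinate.
    """
    if not hcr:
        return []
    pieces: list[tuple[str, int, int, str, str]] = []  # chrom,start,end,human_id,species
    for ann in hcr:
        pieces.append((ann.cnv.chrom, ann.cnv.start, ann.cnv.end, ann.cnv.id, "human"))
        if partner_intervals:
            for pid, sp in ((ann.chimp_partner, "chimp"), (ann.macaque_partner, "macaque")):
                if pid in partner_intervals:
                    chrom, s, e = partner_intervals[pid]
                    pieces.append((chrom, s, e, ann.cnv.id, sp))
    pieces.sort(key=lambda p: (p[0], p[1], p[2]))
    regions: list[HotspotRegion] = []
    cur: Optional[dict] = None
    for chrom, s, e, hid, sp in pieces:
        if cur is not None and chrom == cur["chrom"] and s - cur["end"] <= merge_gap:
            cur["end"] = max(cur["end"], e)
            cur["ids"].add(hid)
            cur["species"][sp] = cur["species"].get(sp, 0) + 1
        else:
            if cur is not None:
                regions.append(_finish_region(cur, complex_flags))
            cur = {"chrom": chrom, "start": s, "end": e, "ids": {hid},
                   "species": {sp: 1}}
    if cur is not None:
        regions.append(_finish_region(cur, complex_flags))
    return regions


def _finish_region(cur: dict, complex_flags: Optional[dict[str, bool]]) -> HotspotRegion:
    ids = sorted(cur["ids"])
    is_complex = any(complex_flags.get(i, False) for i in ids) if complex_flags else False
    return HotspotRegion(chrom=cur["chrom"], start=int(cur["start"]), end=int(cur["end"]),
                         member_ids=ids, species_counts=dict(cur["species"]),
                         complex=is_complex)


def hotspot_summary(regions: Sequence[HotspotRegion],
                    gene_intervals: Sequence[tuple[str, int, int]] = (),
                    ) -> dict:
    """Per-region length/genic/complexity table plus class-wise mean lengths.

    A region is "functional" when it overlaps any provided gene interval by at
    least 1 bp.  Returns a dict with a per-region record list and mean lengths
    of the functional and non-functional classes.
    """
    if not regions:
        return {"regions": [], "n": 0,
                "mean_length_functional": None, "mean_length_nonfunctional": None,
                "n_noncomplex": 0}
    genes_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in gene_intervals:
        genes_by_chrom.setdefault(chrom, []).append((s, e))
    records = []
    for r in regions:
        genic = any(min(r.end, e) - max(r.start, s) > 0
                    for s, e in genes_by_chrom.get(r.chrom, []))
        records.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                        "length": r.length, "genic": genic, "complex": r.complex,
                        "n_members": len(r.member_ids)})
    func = [rec["length"] for rec in records if rec["genic"]]
    nonf = [rec["length"] for rec in records if not rec["genic"]]
    return {
        "regions": records,
        "n": len(records),
        "mean_length_functional": float(np.mean(func)) if func else None,
        "mean_length_nonfunctional": float(np.mean(nonf)) if nonf else None,
        "n_noncomplex": sum(1 for rec in records if not rec["complex"]),
    }
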