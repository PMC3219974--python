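"""Size-matched permutation nulls, fold enrichment, and the pipeline's test statistics.

The null model keeps the exact multiset of observed interval sizes and
re-places each interval uniformly over all valid start positions on the
non-gap genome (chromosome chosen with probability proportional to its number
of valid starts for that size).  Placed intervals may overlap each other;
none may intersect the mask.  Each permutation iteration draws from an
independent substream spawned from the top-level seed, so results are
reproducible and order-independent.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .core import (CnvInterval, EnrichmentResult, GenomeModel, NullDistribution,
                   ParameterError, PlacementError, TestResult)
from .overlap import (GlobalCoords, OverlapCriteria, candidate_pairs,
                      count_anchor_overlaps, count_three_species_overlaps)

MaskType = Optional[dict[str, list[tuple[int, int]]]]


class IntervalPlacer:
    """Uniform placement of fixed-size intervals on the mappable genome.

    Precomputes the maximal non-gap segments once; each :meth:`place` call is
    fully vectorised over the requested sizes.
    """

    def __init__(self, genome: GenomeModel, mask: MaskType = None):
        segs = genome.segments(extra_mask=mask)
        if not segs:
            raise PlacementError("genome has no mappable sequence")
        self.seg_chrom = [s[0] for s in segs]
        self.seg_start = np.array([s[1] for s in segs], dtype=np.int64)
        self.seg_len = np.array([s[2] - s[1] for s in segs], dtype=np.int64)
        self.max_size = int(self.seg_len.max())
        names = [c for c, _ in genome.chromosomes]
        lengths = [l for _, l in genome.chromosomes]
        self.gc = GlobalCoords(names, lengths)
        self.seg_gstart = np.array(
            [self.gc.offset[c] for c in self.seg_chrom], dtype=np.int64) + self.seg_start

    def place(self, sizes: np.ndarray, rng: np.random.Generator,
              ) -> tuple[np.ndarray, np.ndarray]:
        """Place each size uniformly; returns (global_start, global_end) arrays.

        Raises :class:`PlacementError` naming the first unplaceable size.
        """
        sizes = np.asarray(sizes, dtype=np.int64)
        if len(sizes) == 0:
            return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
        if sizes.min() < 1:
            raise ParameterError("interval sizes must be >= 1 bp")
        # valid starts per (interval, segment)
        counts = np.maximum(self.seg_len[None, :] - sizes[:, None] + 1, 0)
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            bad = int(sizes[totals == 0][0])
            raise PlacementError(f"no segment can hold an interval of size {bad}")
        draw = rng.integers(0, totals)  # uniform over all valid starts genome-wide
        cum = np.cumsum(counts, axis=1)
        seg_idx = (draw[:, None] >= cum).sum(axis=1)
        prev = cum[np.arange(len(sizes)), seg_idx] - counts[np.arange(len(sizes)), seg_idx]
        offset = draw - prev
        gstart = self.seg_gstart[seg_idx] + offset
        return gstart, gstart + sizes

    def decode(self, gstart: np.ndarray, gend: np.ndarray
               ) -> list[tuple[str, int, int]]:
        """Convert global coordinates back to (chrom, start, end) tuples."""
        names = list(self.gc.offset)
        offs = np.array([self.gc.offset[n] for n in names], dtype=np.int64)
        order = np.argsort(offs)
        offs_sorted = offs[order]
        idx = np.searchsorted(offs_sorted, gstart, side="right") - 1
        out = []
        for k, i in enumerate(idx):
            off = offs_sorted[i]
            out.append((names[order[i]], int(gstart[k] - off), int(gend[k] - off)))
        return out


def randomize_intervals(sizes: Sequence[int], genome: GenomeModel,
                        mask: MaskType = None, seed: int = 0,
                        ) -> list[tuple[str, int, int]]:
    """Place the exact multiset of sizes uniformly on the non-gap genome."""
    placer = IntervalPlacer(genome, mask)
    gs, ge = placer.place(np.asarray(sizes, dtype=np.int64),
                          np.random.default_rng(seed))
    return placer.decode(gs, ge)


def _encode_set(gc: GlobalCoords, cnvs: Sequence[CnvInterval]
                ) -> tuple[np.ndarray, np.ndarray]:
    if not cnvs:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    return gc.encode([c.chrom for c in cnvs],
                     np.array([c.start for c in cnvs], dtype=np.int64),
                     np.array([c.end for c in cnvs], dtype=np.int64))


def null_overlap_distribution(sizes: Sequence[int],
                              target_sets: Sequence[Sequence[CnvInterval]],
                              criteria: OverlapCriteria = OverlapCriteria(),
                              n_iter: int = 1000,
                              genome: GenomeModel = None,
                              mask: MaskType = None,
                              seed: int = 0) -> NullDistribution:
    """Null distribution of the cross-species overlap count for size-matched random sets.

    With one target set the statistic is the number of placed intervals
    qualifying under the pairwise (HC/HR) rule; with two target sets it is the
    three-species (HCR) count.  Every iteration preserves the size multiset
    exactly and draws from its own RNG substream.
    """
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    if genome is None:
        raise ParameterError("genome is required")
    if len(target_sets) not in (1, 2):
        raise ParameterError("target_sets must hold one (HC/HR) or two (HCR) CNV sets")
    placer = IntervalPlacer(genome, mask)
    targets = [_encode_set(placer.gc, t) for t in target_sets]
    sizes = np.asarray(sizes, dtype=np.int64)
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    values = np.zeros(n_iter)
    for it in range(n_iter):
        rng = np.random.default_rng(streams[it])
        gs, ge = placer.place(sizes, rng)
        if len(target_sets) == 1:
            b_s, b_e = targets[0]
            mode = "human" if criteria.anchor == "human" else "reciprocal"
            values[it] = int(count_anchor_overlaps(
                gs, ge, b_s, b_e, criteria.pairwise_fraction, mode).sum())
        else:
            (c_s, c_e), (r_s, r_e) = targets
            values[it] = count_three_species_overlaps(gs, ge, c_s, c_e, r_s, r_e, criteria)
    name = "two_species_overlap_count" if len(target_sets) == 1 else "three_species_overlap_count"
    return NullDistribution(name=name, values=values, n_iter=n_iter, seed=seed,
                            mask_description="assembly gaps" + (" + extra mask" if mask else ""))


def enrichment_test(observed: float, null: NullDistribution) -> EnrichmentResult:
    """Fold enrichment and one-sided empirical p of an observed count against a null.

    fold = observed / mean(null) (+inf when the null mean is 0 and observed > 0);
    p = (1 + #{null_i >= observed}) / (N + 1); z = (observed - mean) / sd when
    the null is non-degenerate, else None.
    """
    vals = null.values
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    if mean == 0:
        fold = float("inf") if observed > 0 else 1.0
    else:
        fold = observed / mean
    p = (1 + int((vals >= observed).sum())) / (len(vals) + 1)
    z = (observed - mean) / sd if sd > 0 else None
    return EnrichmentResult(observed=float(observed), null_mean=mean, null_sd=sd,
                            fold=float(fold), p_empirical=float(p), z=z)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the p-value
    uses the asymptotic two-sample formula (one-sample K-S distribution at the
    effective sample size round(nm/(n+m))).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ParameterError("ks_two_sample requires non-empty samples")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n
    cdf_y = np.searchsorted(y, grid, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    en = round(n * m / (n + m))
    p = float(stats.distributions.kstwo.sf(d, max(en, 1)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TestResult(name="KS_D", value=d, p_value=p, detail={"n": n, "m": m})


def chi_square_yates(table: Sequence[Sequence[int]]) -> TestResult:
    """Yates-continuity-corrected chi-square for a 2x2 table.

    chi2 = N (|ad - bc| - N/2)^2 / (m1 m2 n1 n2), clamped at 0 when
    |ad - bc| <= N/2; p from the chi-square distribution with 1 df.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("chi_square_yates requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ParameterError("table must hold non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ParameterError("chi_square_yates: zero margin in table")
    delta = abs(a * d - b * c)
    if delta <= n / 2:
        chi2 = 0.0
    else:
        chi2 = n * (delta - n / 2) ** 2 / np.prod([float(m) for m in margins])
    p = float(special.chdtrc(1, chi2))
    return TestResult(name="chi2_yates", value=float(chi2), p_value=p, detail={"df": 1})


def recurrence_overlap_test(query_regions: Sequence[CnvInterval],
                            reference_sets: Sequence[Sequence[CnvInterval]],
                            genome: GenomeModel,
                            mask: MaskType = None,
                            n_iter: int = 1000,
                            seed: int = 0) -> EnrichmentResult:
    """Do query regions co-locate with a reference CNV set more than size-matched chance?

    The observed statistic is the number of query regions overlapping (>= 1 bp)
    any interval of the pooled reference sets; the null re-places intervals
    mimicking the query size distribution (exact multiset) uniformly on the
    mappable genome.
    """
    reference = [c for s in reference_sets for c in s]
    placer = IntervalPlacer(genome, mask)
    ref_s, ref_e = _encode_set(placer.gc, reference)

    def count_any_overlap(q_s, q_e) -> int:
        if len(ref_s) == 0 or len(q_s) == 0:
            return 0
        i_idx, _, _ = candidate_pairs(q_s, q_e, ref_s, ref_e)
        return len(np.unique(i_idx))

    q_s, q_e = _encode_set(placer.gc, query_regions)
    observed = count_any_overlap(q_s, q_e)
    sizes = np.array([c.length for c in query_regions], dtype=np.int64)
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    values = np.zeros(n_iter)
    for it in range(n_iter):
        gs, ge = placer.place(sizes, np.random.default_rng(streams[it]))
        values[it] = count_any_overlap(gs, ge)
    null = NullDistribution(name="recurrence_overlap_count", values=values,
                            n_iter=n_iter, seed=seed,
                            mask_description="assembly gaps" + (" + extra mask" if mask else ""))
    return enrichment_test(observed, null)
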