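"""Genic context, selection (K), conservation, and expression divergence of CNV sets.

Genic context uses the precedence exonic > intronic > promoter > intergenic,
with "any part overlaps" semantics and 2-kb promoters immediately upstream of
the TSS.  Selection is summarised by the per-gene K statistic (0 <= K <= 1;
lower = stronger evidence of positive selection); conservation by
length-weighted mean phastCons-like scores; expression divergence by
categorical proportions compared with Yates-corrected chi-square tests.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import (CnvInterval, EnrichmentResult, GeneModel, GenomeModel,
                   NullDistribution, ParameterError, TestResult)
from .permutation import IntervalPlacer, enrichment_test, chi_square_yates, ks_two_sample

CONTEXT_PRECEDENCE = ("exonic", "intronic", "promoter", "intergenic")


class GeneIndex:
    """Interval trees over exons, gene spans and promoter windows, per chromosome."""

    def __init__(self, genes: Sequence[GeneModel], promoter_bp: int = 2000):
        self.genes = list(genes)
        self.promoter_bp = promoter_bp
        self.exons: dict[str, IntervalTree] = {}
        self.spans: dict[str, IntervalTree] = {}
        self.promoters: dict[str, IntervalTree] = {}
        for g in genes:
            for s, e in g.exons:
                self.exons.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
            self.spans.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
            if g.strand == "+":
                ps, pe = g.tss - promoter_bp, g.tss
            else:
                ps, pe = g.tss, g.tss + promoter_bp
            if pe > ps and pe > 0:
                self.promoters.setdefault(g.chrom, IntervalTree()).addi(
                    max(0, ps), pe, g.gene_id)

    def _hits(self, trees: dict[str, IntervalTree], chrom: str, s: int, e: int):
        tree = trees.get(chrom)
        return tree.overlap(s, e) if tree is not None else set()

    def overlapping_genes(self, chrom: str, s: int, e: int) -> list[str]:
        return sorted({iv.data for iv in self._hits(self.spans, chrom, s, e)})


def classify_genic_context(interval: tuple[str, int, int], index: GeneIndex
                           ) -> str:
    """One label per interval: exonic > intronic > promoter > intergenic.

    An interval is exonic if any part overlaps any exon; intronic if it
    overlaps a gene body without touching an exon; promoter if it overlaps
    the 2-kb window immediately upstream of a TSS; intergenic otherwise.
    The interval inherits the highest-precedence context across all genes.
    """
    chrom, s, e = interval
    if index._hits(index.exons, chrom, s, e):
        return "exonic"
    if index._hits(index.spans, chrom, s, e):
        return "intronic"
    if index._hits(index.promoters, chrom, s, e):
        return "promoter"
    return "intergenic"


def genic_context_table(cnvs: Sequence[CnvInterval], genes: Sequence[GeneModel],
                        promoter_bp: int = 2000) -> pd.DataFrame:
    index = GeneIndex(genes, promoter_bp)
    rows = [{"id": c.id,
             "context": classify_genic_context((c.chrom, c.start, c.end), index)}
            for c in cnvs]
    return pd.DataFrame(rows, columns=["id", "context"])


def genic_enrichment(cnvs: Sequence[CnvInterval], genes: Sequence[GeneModel],
                     genome: GenomeModel, mask=None, n_iter: int = 1000,
                     seed: int = 0, feature: str = "exon") -> EnrichmentResult:
    """Are more CNVs genic than size-matched random intervals would be?

    The observed statistic counts CNVs overlapping any exon (``feature="exon"``)
    or any gene span (``feature="gene"``); the null re-places the exact size
    multiset uniformly on the mappable genome.
    """
    if feature not in ("exon", "gene"):
        raise ParameterError("feature must be 'exon' or 'gene'")
    index = GeneIndex(genes)
    trees = index.exons if feature == "exon" else index.spans

    def count(intervals: Sequence[tuple[str, int, int]]) -> int:
        return sum(1 for chrom, s, e in intervals
                   if index._hits(trees, chrom, s, e))

    observed = count([(c.chrom, c.start, c.end) for c in cnvs])
    placer = IntervalPlacer(genome, mask)
    sizes = np.array([c.length for c in cnvs], dtype=np.int64)
    streams = np.random.SeedSequence(seed).spawn(n_iter)
    values = np.zeros(n_iter)
    for it in range(n_iter):
        gs, ge = placer.place(sizes, np.random.default_rng(streams[it]))
        values[it] = count(placer.decode(gs, ge))
    null = NullDistribution(name=f"{feature}_overlap_count", values=values,
                            n_iter=n_iter, seed=seed, mask_description="assembly gaps")
    return enrichment_test(observed, null)


def positive_selection_fraction(gene_ids: Sequence[str], k_table: pd.DataFrame,
                                k_threshold: float = 0.05) -> dict:
    """Fraction of genes with K <= threshold (lower K = positive selection).

    Genes missing from the K table are excluded and tallied.  An empty join
    reports fraction None.
    """
    if not (0 < k_threshold < 1):
        raise ParameterError("k_threshold must be in (0, 1)")
    if len(gene_ids) == 0:
        return {"fraction": None, "n_selected": 0, "n_scored": 0, "n_missing": 0}
    k_map = dict(zip(k_table["gene_id"], k_table["K"]))
    scored = [k_map[g] for g in gene_ids if g in k_map]
    missing = len(gene_ids) - len(scored)
    if not scored:
        return {"fraction": None, "n_selected": 0, "n_scored": 0, "n_missing": missing}
    n_sel = sum(1 for k in scored if k <= k_threshold)
    return {"fraction": n_sel / len(scored), "n_selected": n_sel,
            "n_scored": len(scored), "n_missing": missing}


def calibrate_k_threshold(background_gene_ids: Sequence[str], k_table: pd.DataFrame,
                          target_fraction: float) -> float:
    """The K cutoff at which the background set's selected fraction matches a target."""
    k_map = dict(zip(k_table["gene_id"], k_table["K"]))
    ks = np.sort([k_map[g] for g in background_gene_ids if g in k_map])
    if len(ks) == 0:
        raise ParameterError("no background genes found in K table")
    idx = max(0, int(np.ceil(target_fraction * len(ks))) - 1)
    return float(ks[idx])


def compare_k_distributions(genes_a: Sequence[str], genes_b: Sequence[str],
                            k_table: pd.DataFrame) -> TestResult:
    """Two-sample KS on the K values of two gene sets; direction = median(a) - median(b)."""
    k_map = dict(zip(k_table["gene_id"], k_table["K"]))
    ka = [k_map[g] for g in genes_a if g in k_map]
    kb = [k_map[g] for g in genes_b if g in k_map]
    if not ka or not kb:
        raise ParameterError("both gene sets must join the K table non-emptily")
    res = ks_two_sample(ka, kb)
    res.detail["median_difference"] = float(np.median(ka) - np.median(kb))
    return res


class ScoreTrack:
    """Non-overlapping scored intervals (bedGraph) queryable for interval means."""

    def __init__(self, frame: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ParameterError(f"overlapping score records on {chrom}")
            self.by_chrom[str(chrom)] = (starts, ends, sub["score"].to_numpy(dtype=float))

    def interval_mean(self, chrom: str, s: int, e: int,
                      uncovered: str = "zero") -> Optional[float]:
        """Length-weighted mean score over [s, e).

        ``uncovered="zero"`` scores uncovered bases 0 with the full interval
        length as denominator (phastCons convention); ``"exclude"`` averages
        over covered bases only and returns None when nothing is covered.
        """
        if uncovered not in ("zero", "exclude"):
            raise ParameterError("uncovered must be 'zero' or 'exclude'")
        if chrom not in self.by_chrom:
            return 0.0 if uncovered == "zero" else None
        starts, ends, scores = self.by_chrom[chrom]
        lo = np.searchsorted(ends, s, side="right")
        hi = np.searchsorted(starts, e, side="left")
        if hi <= lo:
            return 0.0 if uncovered == "zero" else None
        seg_s = np.maximum(starts[lo:hi], s)
        seg_e = np.minimum(ends[lo:hi], e)
        w = np.maximum(seg_e - seg_s, 0)
        covered = int(w.sum())
        if covered == 0:
            return 0.0 if uncovered == "zero" else None
        total = float((w * scores[lo:hi]).sum())
        denom = (e - s) if uncovered == "zero" else covered
        return total / denom


def conservation_compare(set_a: Sequence[CnvInterval], set_b: Sequence[CnvInterval],
                         track: ScoreTrack, uncovered: str = "zero") -> dict:
    """KS comparison of per-interval mean conservation between two CNV sets.

    Returns the test, both sets' means, cumulative-fraction curve tables
    (score grid vs fraction of intervals at or below it), and the tally of
    intervals excluded for zero coverage under the "exclude" policy.
    """
    def means(cnvs):
        vals, excluded = [], 0
        for c in cnvs:
            m = track.interval_mean(c.chrom, c.start, c.end, uncovered=uncovered)
            if m is None:
                excluded += 1
            else:
                vals.append(m)
        return vals, excluded

    means_a, excl_a = means(set_a)
    means_b, excl_b = means(set_b)
    if not means_a or not means_b:
        raise ParameterError("both sets need at least one scored interval")
    test = ks_two_sample(means_a, means_b)
    test.detail["median_difference"] = float(np.median(means_a) - np.median(means_b))

    def curve(vals):
        v = np.sort(vals)
        return pd.DataFrame({"score": v,
                             "cumulative_fraction": np.arange(1, len(v) + 1) / len(v)})

    return {"test": test, "mean_a": float(np.mean(means_a)),
            "mean_b": float(np.mean(means_b)),
            "curve_a": curve(means_a), "curve_b": curve(means_b),
            "excluded_a": excl_a, "excluded_b": excl_b}


def expression_proportions(genes_hotspot: Sequence[str], genes_background: Sequence[str],
                           expr_table: pd.DataFrame) -> dict:
    """Per-category expression-divergence proportions for two gene sets + 2x2 tests.

    For each category the 2x2 table is (in-category vs not) x (hotspot vs
    background), tested with the Yates-corrected chi-square; categories with a
    zero margin report no test.
    """
    cat_map = dict(zip(expr_table["gene_id"], expr_table["category"]))
    hot = [cat_map[g] for g in genes_hotspot if g in cat_map]
    bg = [cat_map[g] for g in genes_background if g in cat_map]
    if not hot or not bg:
        raise ParameterError("both gene sets must join the expression table non-emptily")
    categories = sorted(set(hot) | set(bg))
    out = {"n_hotspot": len(hot), "n_background": len(bg), "categories": {}}
    for cat in categories:
        a = sum(1 for c in hot if c == cat)
        b = len(hot) - a
        c = sum(1 for c2 in bg if c2 == cat)
        d = len(bg) - c
        entry = {"proportion_hotspot": a / len(hot), "proportion_background": c / len(bg)}
        try:
            entry["test"] = chi_square_yates([[a, b], [c, d]])
        except ParameterError:
            entry["test"] = None
        out["categories"][cat] = entry
    return out
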