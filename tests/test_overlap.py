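"""Interval overlap rules: HC/HR/HCR membership, complex CNVs, hotspot collapsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvhotspots.core import CnvInterval, OverlapCriteria
from cnvhotspots.overlap import (classify_complex, collapse_hotspots,
                                 find_three_species_overlaps,
                                 find_two_species_overlaps, hotspot_summary,
                                 overlap_bp, reciprocal_overlap)

from conftest import random_cnv_set


def iv(id_, s, e, species="human"):
    return CnvInterval(id=id_, chrom="chr1", start=s, end=e, species=species)


@pytest.mark.parametrize("a,b,expected", [
    (("c", 100, 200), ("c", 150, 250), 50),
    (("c", 0, 10), ("c", 10, 20), 0),      # half-open abutting
    (("c", 0, 100), ("c", 0, 100), 100),
    (("c1", 0, 100), ("c2", 0, 100), 0),   # different chromosomes
])
def test_overlap_bp(a, b, expected):
    assert overlap_bp(a, b) == expected


@pytest.mark.parametrize("a,b,expected", [
    (("c", 0, 100), ("c", 10, 110), 0.9),
    (("c", 0, 100), ("c", 50, 400), 50 / 350),
    (("c", 0, 100), ("c", 200, 300), 0.0),
])
def test_reciprocal_overlap(a, b, expected):
    assert reciprocal_overlap(a, b) == pytest.approx(expected)


@given(s1=st.integers(0, 10_000), l1=st.integers(1, 5_000),
       s2=st.integers(0, 10_000), l2=st.integers(1, 5_000))
@settings(max_examples=200, deadline=None)
def test_reciprocal_overlap_symmetric(s1, l1, s2, l2):
    a, b = ("c", s1, s1 + l1), ("c", s2, s2 + l2)
    assert reciprocal_overlap(a, b) == reciprocal_overlap(b, a)
    assert 0.0 <= reciprocal_overlap(a, b) <= 1.0


class TestTwoSpecies:
    def test_anchor_boundary_inclusive(self):
        """A partner covering exactly 50% of the human CNV qualifies (>= rule)."""
        hits = find_two_species_overlaps([iv("h", 0, 100)],
                                         [iv("c", 0, 50, "chimp")])
        assert [a.cnv.id for a in hits] == ["h"]
        assert hits[0].partners == ["c"]

    def test_below_threshold_fails(self):
        assert find_two_species_overlaps([iv("h", 0, 100)],
                                         [iv("c", 0, 49, "chimp")]) == []

    def test_empty_other_set(self):
        assert find_two_species_overlaps([iv("h", 0, 100)], []) == []

    def test_reciprocal_mode_differs_from_anchor(self):
        # a huge partner covers the anchor fully but reciprocally only 10%
        crit = OverlapCriteria(anchor="reciprocal")
        human, other = [iv("h", 0, 100)], [iv("c", 0, 1000, "chimp")]
        assert find_two_species_overlaps(human, other) != []
        assert find_two_species_overlaps(human, other, crit) == []


class TestThreeSpecies:
    def test_full_overlap_is_hcr(self):
        hits = find_three_species_overlaps([iv("h", 0, 100)],
                                           [iv("c", 0, 100, "chimp")],
                                           [iv("r", 0, 100, "macaque")])
        assert len(hits) == 1
        assert hits[0].chimp_partner == "c" and hits[0].macaque_partner == "r"
        assert hits[0].intersection == (0, 100)

    def test_pairwise_ok_but_threeway_short(self):
        """20% pairwise overlaps pass but a 20% three-way intersection fails the 50% rule."""
        hits = find_three_species_overlaps([iv("h", 0, 100)],
                                           [iv("c", 0, 100, "chimp")],
                                           [iv("r", 80, 200, "macaque")])
        assert hits == []

    @pytest.mark.parametrize("empty", ["human", "chimp", "macaque"])
    def test_any_empty_set_gives_empty_hcr(self, empty):
        sets = {"human": [iv("h", 0, 100)],
                "chimp": [iv("c", 0, 100, "chimp")],
                "macaque": [iv("r", 0, 100, "macaque")]}
        sets[empty] = []
        assert find_three_species_overlaps(sets["human"], sets["chimp"],
                                           sets["macaque"]) == []


class TestComplex:
    def test_high_reciprocal_not_complex(self):
        assert classify_complex([iv("a", 0, 100), iv("b", 10, 110)]) == [False, False]

    def test_low_reciprocal_complex(self):
        assert classify_complex([iv("a", 0, 100), iv("b", 50, 400)]) == [True, True]

    def test_singleton_and_disjoint(self):
        assert classify_complex([iv("a", 0, 100)]) == [False]
        assert classify_complex([iv("a", 0, 100), iv("b", 500, 600)]) == [False, False]


class TestCollapse:
    def _hcr(self, intervals):
        human = [iv(f"h{i}", s, e) for i, (s, e) in enumerate(intervals)]
        chimp = [iv(f"c{i}", s, e, "chimp") for i, (s, e) in enumerate(intervals)]
        mac = [iv(f"r{i}", s, e, "macaque") for i, (s, e) in enumerate(intervals)]
        return find_three_species_overlaps(human, chimp, mac)

    def test_gap_zero_two_regions(self):
        regions = collapse_hotspots(self._hcr([(0, 100), (50, 150), (300, 400)]))
        assert [(r.start, r.end) for r in regions] == [(0, 150), (300, 400)]
        assert sorted(regions[0].member_ids) == ["h0", "h1"]

    def test_merge_gap_bridges(self):
        regions = collapse_hotspots(self._hcr([(0, 100), (50, 150), (300, 400)]),
                                    merge_gap=200)
        assert [(r.start, r.end) for r in regions] == [(0, 400)]

    def test_empty(self):
        assert collapse_hotspots([]) == []

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        human = random_cnv_set(rng, 60, "human")
        chimp = random_cnv_set(rng, 60, "chimp")
        mac = random_cnv_set(rng, 60, "macaque")
        hcr = find_three_species_overlaps(human, chimp, mac)
        regions = collapse_hotspots(hcr)
        # collapsing the regions themselves changes nothing
        as_annotations = find_three_species_overlaps(
            [CnvInterval(f"g{i}", r.chrom, r.start, r.end) for i, r in enumerate(regions)],
            [CnvInterval(f"gc{i}", r.chrom, r.start, r.end, species="chimp")
             for i, r in enumerate(regions)],
            [CnvInterval(f"gr{i}", r.chrom, r.start, r.end, species="macaque")
             for i, r in enumerate(regions)])
        again = collapse_hotspots(as_annotations)
        assert [(r.chrom, r.start, r.end) for r in again] == \
            [(r.chrom, r.start, r.end) for r in regions]


def brute_force_memberships(human, chimp, macaque, crit=OverlapCriteria()):
    """Exhaustive all-pairs / all-triples reference for HC/HR/HCR and complex flags."""
    def ov(a, b):
        if a.chrom != b.chrom:
            return 0
        return max(0, min(a.end, b.end) - max(a.start, b.start))

    hc = set()
    hr = set()
    for h in human:
        for c in chimp:
            frac = (ov(h, c) / h.length if crit.anchor == "human"
                    else min(ov(h, c) / h.length, ov(h, c) / c.length))
            if frac >= crit.pairwise_fraction:
                hc.add(h.id)
        for r in macaque:
            frac = (ov(h, r) / h.length if crit.anchor == "human"
                    else min(ov(h, r) / h.length, ov(h, r) / r.length))
            if frac >= crit.pairwise_fraction:
                hr.add(h.id)
    hcr = set()
    for h in human:
        for c in chimp:
            if ov(h, c) / min(h.length, c.length) < crit.three_way_pair_fraction:
                continue
            for r in macaque:
                if ov(h, r) / min(h.length, r.length) < crit.three_way_pair_fraction:
                    continue
                if ov(c, r) / min(c.length, r.length) < crit.three_way_pair_fraction:
                    continue
                tri = min(h.end, c.end, r.end) - max(h.start, c.start, r.start)
                if tri <= 0:
                    continue
                if tri / min(h.length, c.length, r.length) >= crit.three_way_total_fraction:
                    hcr.add(h.id)
                    break
            if h.id in hcr:
                break

    def complex_flags(cnvs):
        out = []
        for i, a in enumerate(cnvs):
            flag = any(ov(a, b) > 0 and
                       min(ov(a, b) / a.length, ov(a, b) / b.length) < 0.5
                       for j, b in enumerate(cnvs) if i != j)
            out.append(flag)
        return out

    return hc, hr, hcr, complex_flags(human)


def test_matches_brute_force_on_random_sets():
    """Interval-index implementation equals the exhaustive scan on random sets."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        human = random_cnv_set(rng, int(rng.integers(5, 80)), "human")
        chimp = random_cnv_set(rng, int(rng.integers(5, 80)), "chimp")
        mac = random_cnv_set(rng, int(rng.integers(5, 80)), "macaque")
        hc, hr, hcr, cflags = brute_force_memberships(human, chimp, mac)
        assert {a.cnv.id for a in find_two_species_overlaps(human, chimp)} == hc
        assert {a.cnv.id for a in find_two_species_overlaps(human, mac)} == hr
        assert {a.cnv.id for a in find_three_species_overlaps(human, chimp, mac)} == hcr
        assert classify_complex(human) == cflags


def test_relaxing_criteria_never_shrinks_sets():
    rng = np.random.default_rng(23)
    human = random_cnv_set(rng, 80, "human")
    chimp = random_cnv_set(rng, 80, "chimp")
    mac = random_cnv_set(rng, 80, "macaque")
    tight = OverlapCriteria(pairwise_fraction=0.6, three_way_pair_fraction=0.3,
                            three_way_total_fraction=0.6)
    loose = OverlapCriteria(pairwise_fraction=0.3, three_way_pair_fraction=0.1,
                            three_way_total_fraction=0.3)
    hc_t = {a.cnv.id for a in find_two_species_overlaps(human, chimp, tight)}
    hc_l = {a.cnv.id for a in find_two_species_overlaps(human, chimp, loose)}
    assert hc_t <= hc_l
    hcr_t = {a.cnv.id for a in find_three_species_overlaps(human, chimp, mac, tight)}
    hcr_l = {a.cnv.id for a in find_three_species_overlaps(human, chimp, mac, loose)}
    assert hcr_t <= hcr_l


def test_hotspot_summary_partitions_regions():
    from cnvhotspots.core import HotspotRegion
    regions = [
        HotspotRegion("chr1", 0, 1_000, ["a"], {}, complex=False),
        HotspotRegion("chr1", 10_000, 13_000, ["b"], {}, complex=False),
        HotspotRegion("chr1", 50_000, 120_000, ["c"], {}, complex=True),
    ]
    genes = [("chr1", 60_000, 61_000)]
    summary = hotspot_summary(regions, genes)
    assert summary["n"] == 3
    n_func = sum(1 for r in summary["regions"] if r["genic"])
    assert n_func + sum(1 for r in summary["regions"] if not r["genic"]) == 3
    assert summary["mean_length_functional"] == pytest.approx(70_000)
    assert summary["mean_length_nonfunctional"] == pytest.approx(2_000)
    assert summary["n_noncomplex"] == 2
    assert hotspot_summary([], genes)["n"] == 0
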