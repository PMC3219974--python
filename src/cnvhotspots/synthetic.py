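"""Synthetic genomes, probe layouts, aCGH samples, multi-species CNV sets and tracks.

Everything downstream of the raw data is testable against planted ground
truth: hotspot CNVs from the three species are centred on a shared core so
that, by construction, every cross-species pair and triple satisfies the
default overlap criteria with margin; non-hotspot CNVs are placed uniformly
on the mappable genome with sizes from a heavy-tailed log-normal law
truncated at a 437 bp minimum (the smallest CNV size the human discovery
sets resolve).  Annotation tracks wire hotspot membership to lower
positive-selection K values, lower conservation, and a higher chance of
between-species differential expression, each with its own effect-size knob.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (AcghSample, CnvInterval, GeneModel, GenomeModel, ParameterError,
                   PlacementError, ProbeLayout, TruthTable)
from .liftover import AlignmentBlockMap, Block
from .overlap import OverlapCriteria
from .permutation import IntervalPlacer

#: log2-ratio shifts for single-copy loss / gain on a diploid background
LOSS_SHIFT = -1.0        # log2(1/2)
GAIN_SHIFT = 0.58        # ~log2(3/2)

DEFAULT_SIZE_LAW = (9.5, 1.2)   # log-mean, log-sd of CNV sizes in bp
MIN_CNV_SIZE = 437              # bp; truncation point of the size law

EXPRESSION_CATEGORIES = ("DE_two_species", "DE_three_species", "directional_human",
                         "stabilizing", "other")
_EXPR_BASE_PROBS = np.array([0.15, 0.10, 0.05, 0.40, 0.30])

_MAX_RETRIES = 1000


def make_genome(n_chromosomes: int, mean_length: int, gap_fraction: float,
                seed: int = 0) -> GenomeModel:
    """A genome of ``n_chromosomes`` with ~``gap_fraction`` of each masked as gaps.

    Chromosome lengths are jittered uniformly within +/-20% of ``mean_length``;
    each chromosome carries five equal-size gaps totalling ``gap_fraction`` of
    its length, at non-overlapping random positions.
    """
    if n_chromosomes < 1:
        raise ParameterError("need at least one chromosome")
    if not (0 <= gap_fraction < 0.5):
        raise ParameterError(f"gap_fraction must be in [0, 0.5), got {gap_fraction}")
    rng = np.random.default_rng(seed)
    chroms = []
    gaps: dict[str, list[tuple[int, int]]] = {}
    for i in range(n_chromosomes):
        name = f"chr{i + 1}"
        length = int(mean_length * rng.uniform(0.8, 1.2))
        chroms.append((name, length))
        if gap_fraction > 0:
            n_gaps = 5
            gap_size = max(1, int(length * gap_fraction / n_gaps))
            placed: list[tuple[int, int]] = []
            for _ in range(n_gaps):
                for _try in range(_MAX_RETRIES):
                    s = int(rng.integers(0, length - gap_size + 1))
                    e = s + gap_size
                    if all(e <= ps or s >= pe for ps, pe in placed):
                        placed.append((s, e))
                        break
                else:
                    raise PlacementError(f"could not place gaps on {name}")
            gaps[name] = sorted(placed)
    return GenomeModel(chromosomes=chroms, gaps=gaps)


def make_probe_layout(genome: GenomeModel, mean_spacing: int, seed: int = 0
                      ) -> ProbeLayout:
    """Probes on the non-gap genome with inter-probe gaps ~ U(0.5, 1.5) x spacing."""
    if mean_spacing < 1:
        raise ParameterError("mean_spacing must be >= 1 bp")
    rng = np.random.default_rng(seed)
    rows_chrom: list[str] = []
    rows_pos: list[int] = []
    for chrom, seg_start, seg_end in genome.segments():
        pos = seg_start + int(rng.uniform(0.5, 1.5) * mean_spacing)
        while pos < seg_end:
            rows_chrom.append(chrom)
            rows_pos.append(pos)
            pos += int(rng.uniform(0.5, 1.5) * mean_spacing)
    if not rows_pos:
        warnings.warn("probe layout is empty (spacing exceeds every segment)")
    df = pd.DataFrame({"chrom": rows_chrom, "pos": rows_pos})
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return ProbeLayout(probes=df, mean_spacing=float(mean_spacing))


def simulate_acgh_sample(layout: ProbeLayout,
                         events: Sequence[tuple[tuple[str, int, int], float]],
                         noise_sd: float, seed: int = 0,
                         sample_id: str = "sample") -> AcghSample:
    """Probe log2 ratio = sum of shifts of covering events + N(0, noise_sd) noise.

    Overlapping events add their shifts.  ``noise_sd`` may be 0 for the
    noiseless limit.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    chroms = layout.probes["chrom"].to_numpy()
    pos = layout.probes["pos"].to_numpy(dtype=np.int64)
    log2 = np.zeros(len(pos))
    for (chrom, s, e), shift in events:
        if not np.isfinite(shift):
            raise ParameterError(f"non-finite shift for event {chrom}:{s}-{e}")
        hit = (chroms == chrom) & (pos >= s) & (pos < e)
        log2[hit] += shift
    if noise_sd > 0:
        log2 += np.random.default_rng(seed).normal(0.0, noise_sd, size=len(pos))
    return AcghSample(sample_id=sample_id,
                      data=pd.DataFrame({"chrom": chroms, "pos": pos, "log2": log2}))


def _draw_sizes(rng: np.random.Generator, n: int, size_law: tuple[float, float],
                min_size: int, max_size: int) -> np.ndarray:
    """Log-normal sizes truncated below at min_size and above at max_size."""
    mu, sigma = size_law
    out = np.zeros(n, dtype=np.int64)
    need = np.arange(n)
    for _ in range(_MAX_RETRIES):
        if len(need) == 0:
            return out
        draw = np.asarray(rng.lognormal(mu, sigma, size=len(need)), dtype=np.int64)
        ok = (draw >= min_size) & (draw <= max_size)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    raise PlacementError("size law truncation failed to converge")


def simulate_multispecies_cnvs(genome: GenomeModel,
                               n_hotspots: int,
                               per_species_counts: tuple[int, int, int],
                               size_law: tuple[float, float] = DEFAULT_SIZE_LAW,
                               hotspot_share: float = 0.3,
                               seed: int = 0,
                               min_size: int = MIN_CNV_SIZE,
                               criteria: OverlapCriteria = OverlapCriteria(),
                               multiallelic_fraction: float = 0.08,
                               ) -> tuple[dict[str, list[CnvInterval]], TruthTable]:
    """Three species' CNV sets with a planted shared-hotspot structure.

    ``hotspot_share`` of each species' CNVs are centred (with <=5% jitter) on
    one of ``n_hotspots`` shared cores, guaranteeing that every cross-species
    pair and triple inside a hotspot meets the three-way overlap criteria;
    the remainder are placed uniformly on the non-gap genome.  Sizes follow
    the truncated log-normal ``size_law`` throughout.  The truth table
    records planted hotspots (the core = smallest member interval) and every
    CNV's hotspot link.
    """
    nH, nC, nR = per_species_counts
    if min(nH, nC, nR) < 0 or n_hotspots < 0:
        raise ParameterError("counts must be >= 0")
    if not (0 <= hotspot_share <= 1):
        raise ParameterError(f"hotspot_share must be in [0, 1], got {hotspot_share}")
    rng = np.random.default_rng(seed)
    placer = IntervalPlacer(genome)
    species_counts = {"human": nH, "chimp": nC, "macaque": nR}

    # per-species sizes and hotspot assignment (round-robin over hotspots)
    sizes: dict[str, np.ndarray] = {}
    hot_assign: dict[str, np.ndarray] = {}
    for sp, n in species_counts.items():
        sizes[sp] = _draw_sizes(rng, n, size_law, min_size, placer.max_size)
        n_hot = int(round(hotspot_share * n)) if n_hotspots > 0 else 0
        assign = np.full(n, -1, dtype=np.int64)
        if n_hot > 0:
            assign[:n_hot] = np.arange(n_hot) % n_hotspots
        hot_assign[sp] = assign

    # place hotspot cores: envelope must hold the largest member + jitter
    hotspot_center: dict[int, tuple[str, int]] = {}
    hotspot_members: dict[int, list[tuple[str, int]]] = {h: [] for h in range(n_hotspots)}
    for sp in species_counts:
        for i, h in enumerate(hot_assign[sp]):
            if h >= 0:
                hotspot_members[int(h)].append((sp, i))
    placed_envelopes: list[tuple[str, int, int]] = []
    for h in range(n_hotspots):
        members = hotspot_members[h]
        if not members:
            continue
        s_max = max(int(sizes[sp][i]) for sp, i in members)
        s_min = min(int(sizes[sp][i]) for sp, i in members)
        envelope = s_max + int(0.1 * s_min) + 2
        for _try in range(_MAX_RETRIES):
            gs, ge = placer.place(np.array([envelope]), rng)
            (chrom, s, e), = placer.decode(gs, ge)
            if all(c != chrom or e <= ps or s >= pe for c, ps, pe in placed_envelopes):
                placed_envelopes.append((chrom, s, e))
                hotspot_center[h] = (chrom, (s + e) // 2)
                break
        else:
            raise PlacementError(f"could not place hotspot {h} (genome too small?)")

    def draw_state(sp: str) -> str:
        if sp == "macaque" and rng.random() < multiallelic_fraction:
            return "multiallelic"
        return "loss" if rng.random() < 0.5 else "gain"

    cnv_sets: dict[str, list[CnvInterval]] = {sp: [] for sp in species_counts}
    truth_rows = []
    for sp, n in species_counts.items():
        # uniform placement for the non-hotspot complement, batched
        bg_idx = np.where(hot_assign[sp] < 0)[0]
        if len(bg_idx):
            gs, ge = placer.place(sizes[sp][bg_idx], rng)
            bg_intervals = placer.decode(gs, ge)
        else:
            bg_intervals = []
        bg_iter = iter(bg_intervals)
        for i in range(n):
            size = int(sizes[sp][i])
            h = int(hot_assign[sp][i])
            if h >= 0:
                chrom, center = hotspot_center[h]
                members = hotspot_members[h]
                s_min = min(int(sizes[s2][i2]) for s2, i2 in members)
                jitter = int(rng.integers(-max(1, s_min // 20), max(1, s_min // 20) + 1))
                start = center + jitter - size // 2
                end = start + size
                hid = f"hotspot_{h}"
            else:
                chrom, start, end = next(bg_iter)
                hid = ""
            cid = f"{sp}_cnv_{i:05d}"
            state = draw_state(sp)
            cnv_sets[sp].append(CnvInterval(id=cid, chrom=chrom, start=start, end=end,
                                            species=sp, state=state))
            truth_rows.append({"id": cid, "species": sp, "chrom": chrom,
                               "start": start, "end": end, "state": state,
                               "hotspot_id": hid})
    cnv_df = pd.DataFrame(truth_rows,
                          columns=["id", "species", "chrom", "start", "end",
                                   "state", "hotspot_id"])

    hot_rows = []
    for h in sorted(hotspot_center):
        members = hotspot_members[h]
        ivs = []
        for sp, i in members:
            row = cnv_df[(cnv_df.species == sp) & (cnv_df.id == f"{sp}_cnv_{i:05d}")]
            ivs.append((int(row.start.iloc[0]), int(row.end.iloc[0])))
        # core = intersection of all member intervals (non-empty by construction,
        # and covered by every member, hence by any collapsed region);
        # envelope = union span of the members (the full unstable region)
        core = (max(s for s, _ in ivs), min(e for _, e in ivs))
        env = (min(s for s, _ in ivs), max(e for _, e in ivs))
        hot_rows.append({"hotspot_id": f"hotspot_{h}", "chrom": hotspot_center[h][0],
                         "start": core[0], "end": core[1],
                         "envelope_start": env[0], "envelope_end": env[1]})
    hotspots_df = pd.DataFrame(hot_rows, columns=["hotspot_id", "chrom", "start", "end",
                                                  "envelope_start", "envelope_end"])
    truth = TruthTable(hotspots=hotspots_df, cnvs=cnv_df,
                       events=pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                                    "state", "log2_shift", "cnv_id"]))
    return cnv_sets, truth


def derive_sample_events(truth: TruthTable, species: str = "macaque",
                         n_samples: int = 17, seed: int = 0,
                         loss_shift: float = LOSS_SHIFT,
                         gain_shift: float = GAIN_SHIFT) -> pd.DataFrame:
    """Assign each CNV of one species to carrier samples with its log2 shift.

    Carrier counts are drawn uniformly from 1..max(1, n_samples // 3) so most
    CNVs are rare, as in population aCGH panels.  Multiallelic CNVs flip sign
    per carrier.  Returns the events table (and stores it on ``truth``).
    """
    rng = np.random.default_rng(seed)
    rows = []
    sub = truth.cnvs[truth.cnvs.species == species]
    for row in sub.itertuples(index=False):
        n_carriers = int(rng.integers(1, max(2, n_samples // 3 + 1)))
        carriers = rng.choice(n_samples, size=min(n_carriers, n_samples), replace=False)
        for s in carriers:
            if row.state == "gain":
                shift = gain_shift
            elif row.state == "loss":
                shift = loss_shift
            else:
                shift = gain_shift if rng.random() < 0.5 else loss_shift
            rows.append({"sample": f"{species}_{int(s):02d}", "chrom": row.chrom,
                         "start": int(row.start), "end": int(row.end),
                         "state": row.state, "log2_shift": shift, "cnv_id": row.id})
    events = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end",
                                         "state", "log2_shift", "cnv_id"])
    truth.events = events
    return events


def make_block_map(genome: GenomeModel, block_size: int = 200_000,
                   drop_fraction: float = 0.07, invert_fraction: float = 0.0,
                   seed: int = 0,
                   keep_intervals: Sequence[tuple[str, int, int]] = (),
                   ) -> AlignmentBlockMap:
    """A near-identity orthology block map over the non-gap genome.

    The mappable genome is tiled into ``block_size`` blocks projecting to the
    same coordinates on the "target" assembly; a random ``drop_fraction`` of
    blocks is removed (emulating lineage-specific or unalignable sequence)
    and ``invert_fraction`` are marked negative-orientation.  Blocks
    intersecting ``keep_intervals`` are never dropped or inverted, so planted
    structure survives mapping.
    """
    rng = np.random.default_rng(seed)
    keep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in keep_intervals:
        keep_by_chrom.setdefault(chrom, []).append((s, e))
    blocks = []
    for chrom, seg_start, seg_end in genome.segments():
        pos = seg_start
        while pos < seg_end:
            end = min(pos + block_size, seg_end)
            protected = any(min(end, ke) - max(pos, ks) > 0
                            for ks, ke in keep_by_chrom.get(chrom, []))
            u = rng.random()
            if protected or u >= drop_fraction:
                orient = "-" if (not protected and u < drop_fraction + invert_fraction) else "+"
                blocks.append(Block(chrom, pos, end, chrom, pos, orient))
            pos = end
    return AlignmentBlockMap(blocks, source_genome="source", target_genome="target")


def simulate_annotations_and_scores(genome: GenomeModel, n_genes: int,
                                    truth: Optional[TruthTable] = None,
                                    genic_bias: float = 1.0,
                                    k_effect: float = 0.0,
                                    cons_effect: float = 0.0,
                                    de_boost: float = 0.0,
                                    seed: int = 0,
                                    cons_bin: int = 500,
                                    ) -> tuple[list[GeneModel], pd.DataFrame,
                                               pd.DataFrame, pd.DataFrame]:
    """Gene models plus K, conservation and expression tracks with hotspot-linked effects.

    Genes land inside planted hotspots with odds multiplied by ``genic_bias``;
    hotspot genes get K lowered by ``k_effect`` (clipped to [0, 1]) and their
    differential-expression categories upweighted by ``de_boost``; conservation
    bins inside hotspots have means lowered by ``cons_effect``.

    Returns ``(genes, k_table, conservation_track, expression_table)`` where
    the conservation track is a bedGraph-like frame (chrom, start, end, score).
    """
    if genic_bias < 1:
        raise ParameterError("genic_bias must be >= 1")
    rng = np.random.default_rng(seed)
    # effects act on the full hotspot envelope (union of member CNVs) when
    # available, since the whole unstable region carries the biology
    hotspots: list[tuple[str, int, int]] = []
    if truth is not None and len(truth.hotspots):
        df = truth.hotspots
        if "envelope_start" in df.columns:
            hotspots = [(r.chrom, int(r.envelope_start), int(r.envelope_end))
                        for r in df.itertuples(index=False)]
        else:
            hotspots = [(r.chrom, int(r.start), int(r.end))
                        for r in df.itertuples(index=False)]
    placer = IntervalPlacer(genome)
    mappable = int(placer.seg_len.sum())
    hot_bp = sum(e - s for _, s, e in hotspots)
    f = hot_bp / mappable if mappable else 0.0
    p_hot = (genic_bias * f) / (genic_bias * f + (1 - f)) if hotspots else 0.0

    genes: list[GeneModel] = []
    in_hotspot: list[bool] = []
    lengths = dict(genome.chromosomes)
    for g in range(n_genes):
        size = int(rng.uniform(5_000, 50_000))
        if rng.random() < p_hot:
            chrom, hs, he = hotspots[int(rng.integers(len(hotspots)))]
            center = (hs + he) // 2
            start = max(0, center - size // 2)
            end = min(lengths[chrom], start + size)
            start = max(0, end - size)
            hot = True
        else:
            size = min(size, placer.max_size)
            gs, ge = placer.place(np.array([size]), rng)
            (chrom, start, end), = placer.decode(gs, ge)
            hot = any(c == chrom and min(end, e) - max(start, s) > 0
                      for c, s, e in hotspots)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        exon_starts = np.sort(rng.choice(
            np.arange(start, max(start + 1, end - 300)),
            size=min(n_exons, max(1, end - 300 - start)), replace=False))
        exons = []
        for es in exon_starts:
            ee = min(end, int(es) + int(rng.integers(100, 301)))
            if exons and es < exons[-1][1]:
                continue
            if ee > es:
                exons.append((int(es), ee))
        if not exons:
            exons = [(start, end)]
        genes.append(GeneModel(gene_id=f"gene_{g:05d}", chrom=chrom, strand=strand,
                               start=start, end=end, exons=exons))
        in_hotspot.append(hot)

    k_base = rng.uniform(0, 1, size=n_genes)
    k = np.clip(k_base - np.where(in_hotspot, k_effect, 0.0), 0.0, 1.0)
    k_table = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "K": k})

    cats = []
    for hot in in_hotspot:
        probs = _EXPR_BASE_PROBS.copy()
        if hot and de_boost > 0:
            probs[:3] *= (1 + de_boost)
            probs /= probs.sum()
        cats.append(EXPRESSION_CATEGORIES[int(rng.choice(len(probs), p=probs))])
    expr_table = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "category": cats})

    cons_rows = []
    for chrom, seg_start, seg_end in genome.segments():
        pos = seg_start
        while pos < seg_end:
            end = min(pos + cons_bin, seg_end)
            hot = any(c == chrom and min(end, e) - max(pos, s) > 0
                      for c, s, e in hotspots)
            mean = 0.5 - (cons_effect if hot else 0.0)
            score = float(np.clip(rng.normal(mean, 0.15), 0.0, 1.0))
            cons_rows.append({"chrom": chrom, "start": pos, "end": end, "score": score})
            pos = end
    cons_track = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "score"])
    return genes, k_table, cons_track, expr_table
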