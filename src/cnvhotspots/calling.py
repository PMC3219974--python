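"""CNV calling from aCGH log2 ratios.

A CNV call is a maximal run of consecutive probes whose log2 ratios deviate
significantly from 0 in the same direction.  "Significant" is operationalised
as a robust per-probe z-score: |log2| / noise_sd >= z_threshold, where
noise_sd is 1.4826 x the median absolute deviation of the sample's ratios.
A run must contain at least ``min_probes`` significant probes (five by
default) and its mean log2 must clear ``min_abs_mean_log2``.  Calls from
multiple samples are merged into loci by 50% reciprocal overlap and the locus
is classified gain, loss, or multiallelic (both directions present among
carriers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AcghSample, CnvCall, CnvLocus, ParameterError
from .overlap import GlobalCoords, candidate_pairs


@dataclass
class CallerParams:
    """Tuning knobs of the consecutive-probe caller."""

    z_threshold: float = 2.0
    min_probes: int = 5
    min_abs_mean_log2: float = 0.3
    max_interrupt: int = 0

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.min_probes < 1 or self.min_abs_mean_log2 < 0 \
                or self.max_interrupt < 0:
            raise ParameterError("caller parameters must be positive (max_interrupt >= 0)")


def estimate_noise(sample: AcghSample) -> float:
    """Robust noise scale of a sample: 1.4826 x MAD of its log2 ratios.

    Requires at least 30 probes so the scale estimate is stable.
    """
    ratios = np.asarray(sample.data["log2"], dtype=float)
    if len(ratios) < 30:
        raise ParameterError(f"sample {sample.sample_id}: need >= 30 probes, got {len(ratios)}")
    if not np.isfinite(ratios).all():
        raise ParameterError(f"sample {sample.sample_id}: non-finite log2 ratios")
    return float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))


def call_cnvs(sample: AcghSample, params: CallerParams = CallerParams(),
              noise_sd: float | None = None) -> list[CnvCall]:
    """Call CNVs in one sample with the consecutive-probe rule.

    Returns one call per maximal same-sign run of significant probes with
    >= ``params.min_probes`` significant members; the call interval spans the
    first to last significant probe (+1 for half-open).  With
    ``max_interrupt`` > 0, a run may absorb up to that many non-significant
    probes in total before a same-sign significant probe resumes it.
    """
    df = sample.data
    if len(df) == 0:
        return []
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=np.int64)
    log2 = df["log2"].to_numpy(dtype=float)
    if not np.isfinite(log2).all():
        raise ParameterError(f"sample {sample.sample_id}: NaN/inf log2 ratio")
    for chrom in np.unique(chroms):
        p = pos[chroms == chrom]
        if len(p) > 1 and (np.diff(p) <= 0).any():
            raise ParameterError(f"sample {sample.sample_id}: probes unsorted on {chrom}")
    if noise_sd is None:
        noise_sd = estimate_noise(sample)
    if noise_sd <= 0:
        # perfectly clean sample: any non-zero ratio is significant
        sig = log2 != 0
    else:
        sig = np.abs(log2) / noise_sd >= params.z_threshold
    sign = np.sign(log2)

    calls: list[CnvCall] = []
    n = len(df)
    i = 0
    while i < n:
        if not sig[i]:
            i += 1
            continue
        chrom = chroms[i]
        run_sign = sign[i]
        idx = [i]          # significant members
        interrupts = 0
        j = i + 1
        while j < n and chroms[j] == chrom:
            if sig[j] and sign[j] == run_sign:
                idx.append(j)
                j += 1
            elif (not sig[j]) and interrupts + 1 <= params.max_interrupt:
                # tentatively absorb; only kept if a same-sign probe follows
                k = j
                used = 0
                while k < n and chroms[k] == chrom and not sig[k] \
                        and interrupts + used + 1 <= params.max_interrupt:
                    k += 1
                    used += 1
                if k < n and chroms[k] == chrom and sig[k] and sign[k] == run_sign:
                    interrupts += used
                    idx.append(k)
                    j = k + 1
                else:
                    break
            else:
                break
        if len(idx) >= params.min_probes:
            span = np.arange(idx[0], idx[-1] + 1)
            mean_log2 = float(log2[span].mean())
            if abs(mean_log2) >= params.min_abs_mean_log2:
                calls.append(CnvCall(
                    chrom=str(chrom), start=int(pos[idx[0]]), end=int(pos[idx[-1]]) + 1,
                    sample_id=sample.sample_id,
                    direction="gain" if run_sign > 0 else "loss",
                    n_probes=len(idx), mean_log2=mean_log2))
        i = j if j > i else i + 1
    return calls


def classify_allelic_state(members: Sequence[CnvCall]) -> str:
    """gain if all member calls are gains, loss if all losses, multiallelic otherwise."""
    if not members:
        raise ParameterError("locus must have at least one member call")
    directions = {m.direction for m in members}
    if directions == {"gain"}:
        return "gain"
    if directions == {"loss"}:
        return "loss"
    return "multiallelic"


def merge_sample_calls(calls: Sequence[CnvCall],
                       reciprocal_threshold: float = 0.5) -> list[CnvLocus]:
    """Merge per-sample calls across samples into loci.

    Single-linkage clustering of calls with reciprocal overlap >= threshold;
    the locus interval is the union of its members and its state comes from
    :func:`classify_allelic_state`.  Carrier count = number of distinct
    samples among the members.  Output ordered by coordinate.
    """
    if not calls:
        return []
    chroms = sorted({c.chrom for c in calls})
    max_end = {ch: max(c.end for c in calls if c.chrom == ch) for ch in chroms}
    gc = GlobalCoords(chroms, [max_end[ch] for ch in chroms])
    s, e = gc.encode([c.chrom for c in calls],
                     np.array([c.start for c in calls], dtype=np.int64),
                     np.array([c.end for c in calls], dtype=np.int64))
    i_idx, j_idx, ov = candidate_pairs(s, e, s, e)
    lengths = e - s
    rec = np.minimum(ov / lengths[i_idx], ov / lengths[j_idx])
    link = rec >= reciprocal_threshold

    parent = list(range(len(calls)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(i_idx[link], j_idx[link]):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj

    groups: dict[int, list[int]] = {}
    for k in range(len(calls)):
        groups.setdefault(find(k), []).append(k)
    loci = []
    for members_idx in groups.values():
        members = [calls[k] for k in members_idx]
        loci.append(CnvLocus(
            chrom=members[0].chrom,
            start=min(m.start for m in members),
            end=max(m.end for m in members),
            members=sorted(members, key=lambda m: (m.sample_id, m.start)),
            state=classify_allelic_state(members),
            carriers=len({m.sample_id for m in members}),
        ))
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    return loci
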