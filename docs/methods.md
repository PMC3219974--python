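# Methods

This note records the models, conventions and design choices behind
`cnvhotspots`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and interval arithmetic

All coordinates are 0-based half-open `[start, end)` base pairs internally
and BED-convention on disk. Overlap of two intervals is
`max(0, min(end) − max(start))`; reciprocal overlap is
`min(overlap/len(a), overlap/len(b))`. Every threshold comparison is
inclusive (≥), so boundary cases are deterministic. Multi-chromosome sets are
handled by encoding each chromosome into a disjoint slot of one integer axis
(with a one-base spacer so abutting ends never cross chromosomes), which lets
the pairwise machinery run as sorted-array sweeps in numpy.

## CNV calling

A probe is significant when |log₂| / σ̂ ≥ z, with σ̂ = 1.4826 × MAD of the
sample's log₂ ratios (robust to the small fraction of probes inside true
CNVs) and z = 2.0 by default. A call is a maximal run of consecutive
same-sign significant probes containing at least `min_probes` (default 5)
significant probes whose mean log₂ clears `min_abs_mean_log2` (default 0.3);
the call spans the first to last significant probe (+1 for half-open), with
no extension toward flanking non-significant probes. `max_interrupt`
(default 0, i.e. strict consecutiveness) optionally lets a run absorb that
many non-significant probes before a same-sign significant probe resumes it;
`n_probes` counts significant probes only.

The exact significance rule behind the original "significantly deviating
from 0" phrasing is not fully specified in public descriptions of this
analysis style; the robust z-score is our operationalisation and is exposed
as configuration.

Two operating characteristics worth knowing:

- With Gaussian noise, a sub-threshold implant (e.g. 4 probes) adjacent to a
  flanking noise probe that happens to clear the z threshold can be extended
  into a 5-probe run at rate ≈ 2Φ(−z) per implant. The test that the
  five-consecutive-probe rule rejects 4-probe implants therefore uses flat
  flanks; chance extension is a property of the noise model, not the rule.
- Single-copy gains sit at log₂ ≈ +0.58, i.e. z ≈ 3.9 at noise sd 0.15, so a
  long gain loses individual probes to the threshold at a few percent per
  probe and strict consecutiveness fragments it into adjacent calls. Losses
  (log₂ ≈ −1.0, z ≈ 6.7) do not fragment in practice. This is why the
  acceptance summary reports both boundary-accurate recall (≥ 50% reciprocal
  match) and locus support (any overlap with an implanted CNV).

Calls are merged across samples by single-linkage clustering at ≥ 50%
reciprocal overlap (the conventional "same CNV" criterion, reused for
consistency); a locus is multiallelic iff its members include both
directions.

## Orthology mapping

The block map is the flattened content of a chained alignment: non-overlapping
source intervals, each projecting rigidly (same length) to a target
chromosome in + or − orientation. An interval maps when ≥
`min_mapped_fraction` (default 0.95, the conventional liftOver remap ratio)
of its bases project AND all projected bases land on one target chromosome in
one orientation; otherwise the failure is classified `unmapped`, `split`, or
`low_coverage`. Minus-orientation blocks reverse coordinates within the
block. A UCSC chain-file importer is provided as an optional adapter; the
core consumes the TSV block format.

## Overlap criteria

The pairwise "50% overlap" rule is ambiguous between anchor-fraction and
reciprocal readings; the default measures the fraction of the *human* CNV
covered by a single partner (anchor mode), since the set is defined as
"human CNVs that overlap ...". Reciprocal mode is a config switch. The
three-way rule requires every pairwise overlap to reach 20% *of the shorter
interval of the pair* — the only scale-free symmetric reading — and the
common intersection to cover 50% of the shortest of the three. When several
partner pairs qualify, the pair maximising the three-way intersection is
kept, remaining ties broken by leftmost coordinates, so results are
deterministic. Relaxing any fraction can only grow the HC/HR/HCR sets
(verified as a property test).

Hotspot collapsing is an automated single-linkage merge (gap ≤ `merge_gap`,
default 0) of HCR CNVs and their partners' projections; a manually curated
merge of the kind used in the original analyses may produce nearby but
different region counts.

## Permutation nulls

Randomisation preserves the exact multiset of interval sizes and places each
interval uniformly over all valid start positions on the mappable genome
(chromosome chosen with probability proportional to its number of valid
starts for that size; placed intervals may overlap each other; none may
touch the gap mask — whether the original analyses masked gaps is unstated,
so masking defaults on and is configurable). Per-iteration RNG substreams are
spawned from the top-level seed (`numpy.random.SeedSequence.spawn`), so
results are reproducible and independent of iteration order.

`enrichment_test` reports fold = observed/mean(null), the standard empirical
p = (1 + #{null ≥ observed})/(N + 1) (never 0, ≤ 1), and a z-score when the
null is non-degenerate. The original analysis style quotes KS-test p-values
against such nulls; comparing a single observation to a null by KS is
statistically unusual, so the empirical p and z are the primary outputs here
and the KS machinery is available separately.

Test statistics: two-sample KS computes D as the exact sup-distance between
ECDFs and its p-value from the asymptotic one-sample KS distribution at
effective size round(nm/(n+m)) — the same formula scipy's `ks_2samp`
evaluates in asymptotic mode, which serves as the independent reference in
the conformance tests. The Yates-corrected χ² uses the closed form
N(|ad−bc| − N/2)² / (m₁m₂n₁n₂), clamped to 0 when |ad−bc| ≤ N/2, with p from
χ²₁; it matches `scipy.stats.chi2_contingency(correction=True)` including
the clamp region.

## Synthetic data: what it emulates, and what it does not

CNV sizes follow a log-normal law (defaults: log-mean 9.5, log-sd 1.2 in bp)
truncated below at 437 bp — the minimum size the high-resolution human
discovery sets resolve — and above at the largest mappable segment. A
configurable `hotspot_share` of each species' CNVs is centred (jitter ≤ 5%
of the smallest member) on shared hotspot cores; centring guarantees every
cross-species pair overlaps by ≥ 90% of the shorter interval and every
triple's intersection covers ≥ 90% of its shortest member, so planted
hotspots satisfy the default criteria with margin (re-verified against the
overlap module in tests). The remaining CNVs are placed uniformly on the
non-gap genome. Placement retries are capped at 1,000 and failure raises
rather than silently shrinking, so the size distribution is never distorted
invisibly.

Each truth-table hotspot records a **core** (intersection of member CNVs;
covered by every member, hence by any collapsed region containing one — used
by recovery tests) and an **envelope** (union span; the full unstable
region). Annotation effects act on envelopes: genes land inside them with
odds multiplied by `genic_bias`, hotspot genes get K lowered by `k_effect`
(clipped to [0, 1]) and their differential-expression categories upweighted
by `de_boost`, and conservation bins inside envelopes have means lowered by
`cons_effect`. Background K is uniform on [0, 1], so the background
fraction with K ≤ 0.05 is ~5%; a calibration helper can instead pick the
threshold that reproduces any target background fraction.

aCGH signal is additive: probe value = Σ shifts of covering events +
N(0, noise_sd), with loss/gain shifts −1.0/+0.58 (log₂ of 1/2 and 3/2 on a
diploid). Not modelled: dye bias, GC waves, replicate arrays, probe-specific
variance, sequence content, segmental-duplication-mediated mechanisms.
Passing tests therefore show the pipeline's rules and statistics behave
correctly under a clean additive-noise model — not that the caller is robust
to array artefacts of real aCGH data.

The synthetic orthology map is near-identity: the mappable genome is tiled
into blocks, a configurable fraction is dropped (emulating unalignable or
lineage-specific sequence, ~7% by default to mirror observed liftover
failure rates), and blocks over planted structure can be protected so truth
guarantees survive mapping.

## Study conditions used by tests and the acceptance script

Problem sizes are chosen to make each check well-powered while keeping the
default suite fast: the null-calibration check uses a 30 Mb genome with 600
observed and 250 target intervals so the overlap-count statistic is wide
(null sd ≫ 1 count) relative to the discreteness of empirical p-values at
N = 200 iterations; effect-detection checks use n_genes = 1,000 with a large
`genic_bias` because hotspot envelopes cover well under 1% of the genome and
the KS tests need ≥ ~40 in-hotspot genes for power at the planted effect
sizes (k_effect 0.5, cons_effect 0.25). The acceptance script runs a 24 Mb
genome, 600/200/200 CNVs, 10 hotspots at 25% share, 10 samples and 500
permutation iterations.

## Degenerate inputs and conventions

- Empty CNV input to mapping reports mapped fraction 1.0 with count 0.
- An empty species set makes HC/HR/HCR empty rather than erroring.
- A zero-noise sample treats any non-zero ratio as significant.
- Conservation for bases uncovered by the score track counts as 0 with the
  full interval length as denominator (phastCons convention); the
  "exclude" policy averages covered bases only and tallies fully uncovered
  intervals.
- "Genes located within" a CNV set means any-overlap of the gene span;
  full-containment is a config alternative.
- Fold enrichment against an all-zero null is reported as +inf (observed > 0)
  or 1 (observed = 0); the z-score is None for degenerate nulls.

## Known limitations

- The caller fragments long single-copy gains under strict consecutiveness
  (see above); `max_interrupt` mitigates this at the cost of the literal
  consecutive-probe rule.
- The automated hotspot merge has no notion of manual curation; region
  counts depend on `merge_gap`.
- Reproducing published headline counts for real primate data requires the
  original CNV tables, chain files and hotspot lists, which are external
  downloads outside this package's scope; the package reproduces the
  *method*, with synthetic inputs standing in for them.
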