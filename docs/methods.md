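# Methods

## Coordinate system and reference

All haplotypes are variant sets against the 16,569-bp rCRS coordinate
system, in the field's notation (`16247G`, `315.1C`, `522d`).
Substitutions are classified as transitions or transversions against
the packaged reference sequence. That reference is a **synthetic
stand-in**: a deterministic sequence of rCRS length and approximate
rCRS base composition, with the bases the analysis logic depends on
pinned to their true values (3107 = N, the placeholder; 16247 = A so
that the classic Polynesian-motif marker 16247G is an A→G transition;
14022 = A; 310/312 = T inside the poly-C stretch). Because variant
classification, FASTA diffing and the simulator all use the same
reference object, the pipeline is internally consistent; analyses of
real mitogenomes should supply the genuine rCRS via the `reference=`
parameters.

## Position mask and character weights

Positions reported as unstable or alignment-ambiguous are excluded
before any network or diversity computation: the ranges 308–315 and
515–522 (any allele), the allele-specific calls 310C, 16182C, 16183C,
16192C, 16518T, 16519C, and position 3107 (the rCRS placeholder,
always). Mask semantics follow the established network-software
convention: ranges exclude any variant at those positions,
allele-specific tokens exclude only that allele. The 16518T entry is
packaged as given and can be overridden in the YAML position config.

Nine hypervariable hotspot positions (146, 150, 152, 195, 16093,
16129, 16189, 16311, 16362) carry character weight 7 instead of the
default 10. If a per-position relative-rate table is supplied, weights
fall by 3 per decade of rate above the median rate (so a 10× hotspot
reproduces 10 → 7), floored at 1. No published per-position rate table
is packaged; the default is 10× at the nine hotspots and 1× elsewhere,
user-overridable.

Indels are parsed and carried through I/O but excluded from networks,
ρ and the clock: the packaged calibration is substitution-based, so
the numerator must be too.

## Networks and resolution

Haplotypes are encoded as binary characters, one per derived allele
per position (a multistate site becomes several characters, with a
warning). The reduced-median construction: (1) *reduction* — for each
pair of incompatible characters (all four gametes observed), the rarer
is split into independent per-background characters when the frequency
ratio reaches the reduction parameter r (default 2), i.e. the rare
change is accepted as recurrent; (2) *median closure* — the node set
is closed under coordinatewise majority of triples (bitwise on
integer masks), adding inferred median haplotypes; nodes one mutation
apart are joined, so residual conflicts appear as cycles
(reticulations). Unobserved leaf medians are pruned; disconnected
components are chain-connected along a canonical geodesic.

Resolution extracts a minimum-weight Steiner tree connecting the
observed haplotypes and the designated root. Character weights
implement the rate-guided preference — a recurrence is cheaper at a
down-weighted hotspot, so conflicts resolve by assigning the repeat to
the high-rate position — and a small multiplicity bonus
(ε·(mult(u)+mult(v)) with ε far below any weight gap) breaks exact
ties in favour of keeping sample-rich nodes intact. Network edges
dropped during resolution are recorded on the tree
(`graph["dropped_edges"]`) so tie-break decisions can be audited.

Three search regimes, chosen by instance size:

* ≤ 10 characters and ≤ 11 terminals: exact Dreyfus–Wagner over the
  **full character hypercube**. This matters: we found instances whose
  minimum-parsimony tree needs Steiner nodes outside the median
  closure, so closure-restricted search (and even a tree-shaped
  closure) can be suboptimal. The exact regime is guaranteed minimal,
  and is verified against an independent exhaustive oracle in the
  test suite.
* larger closures with few terminals: Dreyfus–Wagner restricted to the
  closure graph.
* large datasets (the default above 24 distinct haplotypes):
  an agglomerative builder inserts haplotypes in order of increasing
  distance from the root, attaching each to its nearest node and
  creating the majority-median junction with the best neighbouring
  branch — median-joining-style. It trades the optimality guarantee
  for near-linear cost; on simulated data its per-sample private
  mutation counts match the recorded truth for > 99% of samples, the
  remainder being genuine parsimony ambiguities (see Limitations).

The reduction step is skipped in the exact regime (its early
commitment of rare characters to recurrence can exclude a minimum
tree in chained conflicts); it remains the display and large-data
behaviour.

Rooting is a priori — the haplogroup ancestor supplied as `root_hint`
(the empty profile for simulated data) — not midpoint or outgroup,
because founder dating needs the established clade root.

## Diversity statistics

ρ is computed both as the multiplicity-weighted mean root-to-tip path
length and as the edge sum Σₑ mₑ·nₑ/n; the two are asserted equal.
σ² = Σₑ mₑ·(nₑ/n)², the estimator that treats per-edge mutation counts
as independent Poisson draws; on a star of n tips with k private
mutations each it reduces to √(k/n), and it matches brute-force
Poisson-resampling variance in the tests.

π is the average pairwise difference per site on masked substitution
profiles. The default denominator is the full molecule length (16,569),
reproducing the magnitude of whole-mitogenome diversity tables;
pairs are counted as Σ_{i<j} d_ij / C(n,2). Note this estimator is not
exactly invariant under duplicating every sample (the n/(n−1) factor);
the frequency-weighted form (`corrected=False`), which is exactly
invariant, is provided. Groups with fewer than 15 samples are dropped
from regional tables by default.

## Clock

The default calibration models the expected substitutions per lineage
after *t* years as ρ(t) = t/B + A·(1 − e^(−t/τ)): a long-term neutral
rate of one substitution per B = 3624 years plus a transient excess —
young lineages carry mildly deleterious variants that purifying
selection has not yet purged, so the apparent rate is ~1.4× the
long-term rate at recent time depths and relaxes with time constant
τ ≈ 36.9 kyr. A and τ were solved exactly so the curve reproduces the
standard selection-corrected calibration's published whole-molecule
conversions (ρ 2.464 → 6450 BP; ρ 2.769 → 7270 BP); the curve is then
inverted numerically (it is strictly increasing). Ages convert as
age = curve⁻¹(ρ); CIs transform ρ ± 1.96σ through the same curve —
hence asymmetric in years — and are truncated at 0 BP. Tabular output
rounds to the nearest 10 years; full precision is kept internally.

Calibrations are pluggable: `linear:<B>` (used against simulation
truth, where the generating clock is linear by construction) and
two-column monotone tables (uncorrected years, corrected years; PCHIP
interpolation) selected by a CLI flag.

## Founder analysis

Regions are organised into ordered, nested areas (west → east); the
source for a stage is the union of all earlier areas. For each sink
lineage, the founder node is the most derived node on its root-to-tip
path attributable to the source. Two attribution modes:

* `clade` (default): a node qualifies if at least one source sample
  descends from it — the founder haplotype is inferred
  phylogenetically and may be an internal node no sampled source
  individual carries today. This is unbiased when source lineages keep
  evolving after the split.
* `observed`: a node qualifies only if its exact haplotype occurs in a
  sampled source individual — stricter and fully auditable, but biased
  rootward (older) whenever the founder haplotype has no unchanged
  present-day source representative.

Sink tips sharing a founder node form a cluster; a tip with no
qualifying ancestor is clustered at the tree root and flagged. The
region's founder ρ pools all private diversity
(Σ private mutations / n sink samples); an unweighted per-cluster mean
is available (`weighting="clusters"`). σ uses the Poisson estimator
restricted to private (below-founder) edges. First-area regions are
reported as plain age estimates — their diversity *is* the source —
and regions whose settlement source cannot be pinned down (Micronesia
in the packaged configuration) carry a caveat flag. Subtracting
source-borne diversity can only shorten private paths, so founder ρ
never exceeds the whole-clade ρ, and enlarging the source never
increases it; both guarantees are property-tested.

## Geospatial interpolation

Ordinary kriging with a linear variogram (γ(h) = slope·h, nugget 0; the
slope cancels in the weights) on planar lat/lon treated as Euclidean —
the convention of the classic gridding tools at Pacific scale — with
great-circle distance behind a flag. Zero nugget makes the surface an
exact interpolator at data points; duplicate coordinates are averaged
first, and inputs collapsing to a single location are rejected as
degenerate. Default grid resolution 0.5°; longitudes on a continuous
0–360 scale so the study area does not wrap at the dateline. Heavy-
drift outliers (New Britain in the packaged configuration) are removed
from interpolation inputs but kept in tree building. Surfaces export
as CSV and Surfer-compatible ASCII grids (DSAA).

## Radiocarbon comparison

The packaged table carries, per region, the genetic founder age with
95% CI and published 2σ calibrated radiocarbon ranges for the local
appearance of Lapita (or first settlement beyond the Lapita horizon),
with evidence class and source citation, plus stand-in island
coordinates (the originals are not published; user-overridable).
Overlap uses closed intervals — touching endpoints count as consistent
— and a region with several radiocarbon sources is consistent if any
of them overlaps. On the packaged table exactly five regions are
exceptions (New Ireland, PNG North Coast, Tuvalu, Niue,
Aotearoa/New Zealand); Micronesia is excluded from comparison and
reported as a genetic estimate only. The west-to-east correlation
pairs each genetic point estimate with the (average) radiocarbon
midpoint and reports Pearson r.

## Simulator

A forward lineage simulation, not a coalescent: each island holds a
pool of independently evolving lineages (one pool slot per eventual
sample). At a colonization event, `n_founder_lineages` distinct
lineages are drawn from the source pool (the founder bottleneck),
and pool slots are assigned to founders uniformly at random; every
lineage then accumulates substitutions as a Poisson process with one
expected event per `mutation_interval` years (linear clock, so truth
is unambiguous). Mutated positions are drawn from the non-masked part
of the reference, 10× more often at the nine hotspot positions, and a
repeat hit at an already-mutated position reverts it — generating
realistic recurrent and back mutations, including the classic 16247
instability. All events are recorded per lineage, and replaying a
sample's history reproduces its variant set exactly (tested).

`inject_drift` emulates a heavy-drift population: the island's
distinct haplotypes are ranked (derived types before the ancestral
type, then by frequency), the top (1 − severity) fraction is kept, and
all samples are resampled with geometrically decaying weights (factor
1 − severity) down the ranking — a few derived types end up at high
frequency, π drops, n is preserved; at maximal severity the island is
fixed for one derived type.

The packaged `pacific_scenario` encodes a 15-island west-to-east chain
with the haplogroup originating on the New Guinea north coast at
6.5 ka, colonization truths at the radiocarbon midpoints of the
packaged table where available (e.g. Vanuatu 3230 BP, Tonga 2838 BP)
and at the genetic point estimates otherwise, per-island sample sizes
mirroring the packaged table's n (total 1218), six founder lineages
per colonization, `mutation_interval` = 3624 yr, and a 0.7-severity
drift profile on New Britain. The default nested founder areas are
aligned with the colonization chain so that every island's source lies
in a strictly earlier area — the condition under which founder ρ
estimates the recorded colonization time rather than some earlier
split.

What the simulator does *not* emulate: within-island coalescence and
lineage extinction (pools neither shrink nor compete), population
size dynamics, transversions (all simulated substitutions are
transitions), rate heterogeneity beyond the hotspot dichotomy,
sequencing artefacts, and ancient-DNA sampling. Passing recovery tests
therefore show that the estimator chain is faithful under the founder
model's own assumptions, not that real datasets are free of the
additional noise sources those features introduce.

## Numerical and degenerate-input choices

Monotone inversion of the clock uses Brent root-finding on
[0, 1.5 Myr] with linear extrapolation (and a warning) beyond the
domain. Kriging solves the dense ordinary-kriging system directly
(tens of points). Median closure is capped at 4096 nodes with a
truncation warning. Steiner tie-breaks are deterministic (sorted node
order plus the multiplicity bonus). Zero-length inputs: ρ of an empty
sample set, π of fewer than two samples and founder ρ of zero sink
samples raise typed errors rather than returning NaN.

## Known limitations

* **Parsimony merge deficit.** When a sink-private mutation recurs
  independently on a compatible source background, any
  parsimony-guided reconstruction (including rate-guided manual
  resolution) merges the two origins and the private count loses one.
  On the packaged scenario this affects ~0.8% of sink samples
  (≈ −30 yr on founder ages); it scales with total dataset mutation
  density and is intrinsic to the method, not removable by better
  search.
* **CI coverage at small counts.** The ρ ± 1.96σ interval is a normal
  approximation; for islands whose expected private-mutation total is
  small (μ ≲ 15), exact Poisson computation puts its true coverage at
  ~91–94% rather than 95%, dominated by the discrete lower tail.
* The `observed` source-attribution mode is biased old whenever source
  lineages kept evolving; it is provided for auditability, not as the
  default estimator.
* The agglomerative builder does not guarantee minimum parsimony;
  guarantees hold in the exact regime (≤ 10 characters).
* Great-circle geometry, variogram fitting and model selection are out
  of scope for the kriging stage (linear variogram only).
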