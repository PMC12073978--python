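# Methods

`gldm` implements graph lesion-deficit mapping: inference of the brain
network on which a cognitive function depends, from where focal lesions
co-occur with impaired test scores. Because suitable patient data are
available only on request, the package pairs the analysis with a synthetic
lesion-cohort generator whose defaults emulate the study conditions of a
focal tumour/stroke case series; every stage is validated on that generator.

## The analysis model

**Damage quantification.** Binary lesion masks are intersected with an
integer parcel atlas on the same grid. The damage matrix holds, per patient
and parcel, the fraction of the parcel's voxels lesioned; the lobar group
rule classifies a patient as frontal (posterior) when >= 70% of the lesion
volume lies in frontal (posterior) parcels, with the side taken from the
hemisphere holding the majority of lesioned voxels. A parcel counts as
*damaged* for graph construction when at least a fraction `tau` of its
voxels is destroyed. Default `tau = 0.25`: at the default resolution
(~125-voxel parcels, lesions 1-15% of a hemisphere) a majority-damage
criterion leaves typical focal lesions damaging fewer than one parcel, so
the graph misses most of the anatomy; quarter-damage keeps the focal intent
while making the substrate reliably observable.

**Deficit scores.** Patient scores are anchored to healthy-control moments:
`z = (hc_mean - score) / hc_sd`, higher = more impaired. The linear age
trend is regressed out of z across patients (age is a nuisance for the
anatomy, and the generator builds a real age effect in). Lesion volume is
deliberately not regressed out: in the generator, volume correlates with
substrate coverage, so removing it would remove signal; the option exists
for data where volume is known to be behaviourally inert.

**The layered graph.** Nodes are parcels damaged together with some other
parcel in at least `m_min = 2` patients; each edge (j, k) carries
`support` (number of co-damaged patients), a lesion channel
`w_les = support / n_patients`, and a deficit channel `w_def` = mean z over
the co-damaged patients. The mean (not the sum) decouples deficit evidence
from lesion frequency, which the lesion channel already encodes. Parcels
with no qualifying edge are excluded from the graph: they contribute no
co-occurrence information, and keeping them would inflate the partition
prior below by `ln B` nats each, masking real structure. The
behaviour-permuted null graph shuffles z across patients before computing
`w_def`; its edge set, supports and lesion weights are identical to the
test graph by construction.

**Description length.** Community structure is scored by a flat
microcanonical SBM with two quantile-binned weight channels. For a
partition of the N graph nodes into B blocks:

- adjacency: `S_adj = -(1/2) * sum_rs m_rs ln(m_rs / (n_r n_s))` (diagonal
  counted twice in the symmetric sum, `0 ln 0 = 0`), **plus** the cost of
  declaring the block-pair edge-count matrix,
  `ln C(B(B+1)/2 + E - 1, E)`. Without the declaration term the objective
  is degenerate: an all-singleton partition zeroes the first term at no
  charge and the exhaustive oracle selects it on essentially every graph.
  The term is the exact analogue of the count-declaration cost already
  charged per weight channel.
- each weight channel: edge weights are discretized into `n_bins = 8`
  global quantile bins; per unordered block pair with m edges the cost is
  the multinomial bin entropy `-sum_q c_q ln(c_q / m)` plus
  `ln C(m + n_bins - 1, n_bins - 1)`.
- partition prior: `S_part = N ln B`.

Each graph is binned on its **own** quantiles. This matters for the
test-null comparison: the null's deficit weights are means of randomly
reassigned z values and are therefore CLT-shrunken towards the grand mean.
Binned on the test graph's quantiles they would crowd the central bins and
encode *more* cheaply, inverting the comparison. Own-graph quantile bins
make every graph's marginal bin distribution uniform by construction, so
description lengths differ only through within-block-pair concentration —
exactly the structure the model is meant to detect.

**Fitting.** Agglomerative minimisation: from `B = min(b_max, N)` blocks
(singletons, or a seeded balanced assignment when `b_max < N`) down to one,
alternating up to `n_sweeps = 4` single-node reassignment sweeps (only
strictly DL-decreasing moves; early stop) with greedy best merges (ties by
smallest block-id pair). The best state visited across `n_restarts = 3`
seeded passes is returned. On 50+ random graphs of up to 8 nodes the fit
attains the global optimum found by Bell-number enumeration
(`exhaustive_oracle`); restarts exist because single passes occasionally
land ~1 nat high, which matters when test-null deltas are small. Hierarchy
is reported as the Newick dendrogram of greedy merges from the fitted
partition to a single block, not as a nested prior.

**Model comparison.** `delta = S_null - S_test` in nats acts as the log
posterior odds of the test model; it is reported as `e{delta}` following
the convention for such comparisons. Both models must share an edge set.

**Backprojection and retention.** A parcel's deficit strength is the
support-weighted mean of `w_def` over incident edges; its lesion strength
the mean of `w_les`. Percentile bootstrap CIs (patients resampled with
replacement, graph and strengths recomputed per replicate, `n_boot = 1000`,
alpha = 0.05) quantify sampling uncertainty. A parcel is retained when its
95% deficit-strength CI lies wholly above the 95% interval of the same
parcel's deficit strength under behaviour permutation — the deficit weight
attributable to lesion anatomy alone. The raw lesion-strength CI
(`lesion_reference="per_node"`) and a global lesion-strength band
(`"global"`) are available as alternatives, but the deficit channel (z
units, order 0-3) and the lesion channel (co-occurrence frequencies, order
0.01-0.1) are incommensurate, and comparing them reduces retention to
"mean z above ~0.05", which retains nearly every impaired-adjacent parcel.
The permutation reference implements the same inferential logic as the
test-vs-null model comparison at the single-parcel level. Percentile (not
BCa) intervals are used throughout; at `n_boot = 1000` the added complexity
of BCa buys little for these smooth statistics.

## The synthetic cohort

The generator emulates, with every draw seeded:

- **Atlas**: an even-sagittal-extent grid split at the midplane, each
  hemisphere tessellated by seeded multi-source BFS growth with 4 rounds of
  Lloyd relaxation (roughly equal-volume, face-connected parcels; default
  20x20x20 grid, 64 parcels). Parcels with anterior centroids are labelled
  frontal.
- **Lesions**: one per patient, grown from a random origin by noisy-
  distance priority (`distance x (1 + 0.5 U)`), giving bulky tumour/stroke-
  like blobs confined to one hemisphere; volumes log-uniform between 1% and
  15% of the hemisphere. Origins are right-sided with probability 0.55 and
  anterior with probability 0.58, mirroring the composition of focal
  tumour/stroke case series, which are right- and frontally weighted.
- **Substrate**: a contiguous pair of right frontal parcels seeded at the
  centroid of the right frontal territory. Two parcels (~6% of a
  hemisphere) are comparable to the median simulated lesion, so single
  lesions can destroy most of the substrate and the damage-load
  dose-response spans its full range; a pole-extremity substrate would
  rarely be lesioned deeply enough to be observable.
- **Scores**: `score = clamp(mu0 - beta*load - gamma*(age - mean age) +
  eps, 0, ceiling)` with `load` the mean damage fraction over substrate
  parcels, `eps ~ N(0, noise_sd)`, ages uniform on 20-75. Defaults:
  `mu0 = 80`, `beta = 30` (points lost at full substrate destruction,
  ~5 control SDs), `gamma = 0.2` points/year, `noise_sd = 5`,
  ceiling 100. The clamp is a truncation, as for real bounded percentage
  scores. `eps` is emitted in the cohort table so the formula can be
  re-verified from the artifacts alone.
- **Item responses**: per item, correct with probability
  `logistic(ability_scale * (score/100 - difficulty_q))`; the ART bank (24
  items; 12 progression + 12 odd-one-out crossed with 12 intra- + 12
  cross-dimensional; features 8/8/8 number/colour/size), the DRT bank (24
  items; 12 valid determinate, 6 invalid determinate, 6 invalid
  indeterminate) and a 12-item perceptual baseline. Difficulties encode the
  observed orderings (cross harder than intra, indeterminate harder than
  determinate); exact values are conventions.

What the generator does *not* emulate: vascular-territory or tumour-growth
lesion shapes, multi-lesion patients, registration error, scanner effects,
non-linear age effects, or item-level response dependencies. Passing the
recovery tests therefore shows the pipeline recovers substrates under the
generator's assumptions, not that it would do so at real-data noise levels.

## Group statistics

The behavioural comparison is a linear model `score ~ group + age` with a
type-II F test for the group term (no interaction is modelled; the design
is near-balanced so type-II and type-III coincide in practice). Adjusted
means are evaluated at the grand mean age; pairwise post hocs are
age-adjusted contrasts from the full model thresholded at
`family_alpha / n_comparisons` (0.05/3, conventionally reported as 0.016).
Within-participant condition contrasts model the paired difference on
centred age and test the intercept. Homogeneity of regression slopes is not
tested by default. Equivalence with a normal-equations oracle is asserted
to 1e-8 on 100 seeded datasets, and the F test's type-I error is verified
to sit in [0.04, 0.06] over 2000 null replicates.

## Validation conditions and problem sizes

- Substrate recovery: 64 parcels, 250 patients + 80 controls, `beta = 30`,
  `noise_sd = 5`, 10 seeds per arm. Median Jaccard between retained parcels
  and the true substrate, and the false-retention rate at `beta = 0`.
  Under these conditions the double-interval retention rule has per-parcel
  sensitivity of roughly 0.6-0.75 (10-30 informative patients per parcel,
  load-diluted effects), so the median Jaccard sits near 0.5-0.6 while
  false retention is ~0; the retention rule trades sensitivity for strict
  false-positive control by design.
- Null calibration: strong coupling is `beta = 50` with a 6-parcel
  substrate (many coupled edges; a 2-parcel substrate contributes too few
  edges for the evidence to clear the partition prior, and deltas tie at 0
  even for large effects); 20 seed pairs per arm.
- Oracle equivalence: 50 random graphs, 5-8 nodes; Bell-number
  enumeration, equality within 1e-9 nats.
- Bootstrap coverage: an independent Bernoulli-damage generator (12
  parcels, damage probability 0.25, linear load-deficit model) where the
  population node strength is computable from one 120k-patient cohort;
  200 cohorts of 250 patients, 200 bootstrap replicates each.

## Numerical choices and degenerate inputs

- Quantile bin edges use `numpy` linear interpolation; ties across edges
  are resolved by `searchsorted(..., side="right")`, so constant weight
  channels land in a single bin and cost only the declaration term.
- Sweep and merge acceptance uses a `1e-12` nats margin; merge ties break
  to the smallest block-id pair, making fits reproducible across platforms.
- Empty graphs, empty blocks, misaligned grids, zero-SD references and
  empty lesions raise typed errors rather than propagating NaNs.
- Bootstrap replicates in which a parcel has no qualifying edge contribute
  nothing to that parcel's CI; the usable-replicate count is reported and
  parcels without CIs are marked unevaluated, never retained.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the pipeline derives per-stage seeds from the master seed and the
  stage name, so re-ordering stages cannot change draws.

## Known limitations

- The SBM is flat; hierarchy is reported only as the merge dendrogram.
  Degree correction and nested priors are out of scope.
- The analysis operates at parcel level, not voxel level; spatial leakage
  to neighbours of a true substrate is intrinsic at this resolution, since
  a neighbour's co-damaged patients genuinely tend to be impaired.
- Default test-null deltas on the 2-parcel-substrate cohort are small
  (tens of nats on ~1000-nat entropies) and can fluctuate below zero for
  single seeds; decisive evidence at desk scale needs the denser coupling
  of the strong-coupling condition.
- The permutation retention reference conditions on the observed lesion
  anatomy; it does not model registration error or atlas misassignment.
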