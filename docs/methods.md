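# Methods

## Harmonization model

Pollen types live in a three-level hierarchy HL0 → HL1 → HL2 with
many-to-one parentage at each step (each HL0 type has exactly one HL1
parent; each HL1 name one HL2 parent). Harmonizing a count table to a level
sums the counts of types sharing a name at that level, so per-sample totals
are conserved exactly. Every HL0 type carries a base indicative capacity on
the ordered scale

PRIMARY_INTRODUCED > PRIMARY_NATIVE > ADVENTIVE > APOPHYTE > NONE.

The capacity of a merged type is derived from the multiset of constituent
base capacities by the downgrade rule: (i) a uniform set keeps its
capacity; (ii) any mix containing NONE or APOPHYTE alongside an indicator
becomes APOPHYTE; (iii) a mix of primary/adventive indicators only takes
the weakest; (iv) all-NONE stays NONE. Rule (ii) is the generalization of
the worked *Plantago* case (adventive *P. lanceolata*-type + wild congeners
→ apophyte *Plantago*) and of Cerealia-type → Poaceae; it is exposed as a
pluggable policy (`derive_capacity_map(..., policy=...)`) so alternative
conventions can be tested. Two consequences worth making explicit:

* along the lineage of any HL0 *indicator* type, capacity is non-increasing
  with coarsening;
* along the lineage of a wild (NONE) type merged with indicators, capacity
  *rises* to APOPHYTE — this asymmetry is precisely the mechanism of the
  false-positive signal, not a defect of the rule.

Ecological-group conflicts on merge take the majority group of the
constituents, ties resolved to UPLAND_HERB, with a logged warning. Taxa
missing from the table are passed through with capacity NONE and group
UPLAND_HERB (lenient default) or rejected (`strict=True`): real tables are
never complete, and non-indicator taxa are discarded downstream anyway.

The packaged table `data/indicator_harmonization_synthetic.csv` is a
synthetic emulation assembled from the standard central-European indicator
literature (worked *Plantago*, cereal, Brassicaceae, Cyperaceae,
Rumex/Oxyria, Linum, Cannabis/Humulus merges; harmonization-independent
taxa such as *Artemisia*, *Olea*, *Castanea*, *Vitis*; a neutral arboreal
background; aquatics). It is not a transcription of any published
supplement, so only structural properties (monotone name loss, the worked
merges, downgrade behaviour) are asserted against it — no published
per-level taxon totals.

## Percentages and indicator curves

Percentages use the terrestrial reference sum: counts of TREE, SHRUB,
UPLAND_HERB and TERRESTRIAL_FERN types (fern spores included because
*Pteridium* and *Polypodium* are themselves secondary indicators). EXCLUDED
types (aquatics) are expressed relative to the same denominator but never
enter it, the standard palynological convention; their percentages may
exceed 100. A zero reference sum raises by default
(`drop_empty_samples=True` drops such samples with a warning) — silent
zero-division would be the worst failure mode. Indicator curves sum
percentages per capacity category and sample; PRIMARY pools introduced and
native primaries (they are kept distinct in tables because native crops
warrant cautious interpretation, but plot as one category). Analyses are
restricted to a configurable window, default [−100, 12,000] cal yr BP,
applied *before* any curve or dissimilarity computation. Ages are stored
youngest-first; negative ages are post-1950 samples.

## Sequence-slotting psi

For series A (m positions) and B (n positions) over shared variables,
pairwise Euclidean distances D(i,j) are computed (variables aligned by
label), and the least-cost monotone path from (1,1) to (m,n) is found by
dynamic programming with moves advance-A, advance-B and, by default,
diagonal. Conventions fixed here:

* the path cost includes **both endpoint cells** — with diagonals this
  makes ψ(a, a) = 0 under the formula ψ = ((AB_between − AB_within) /
  AB_within) + 1, since the zero-cost diagonal gives AB_between = 0;
* AB_within is the raw (unweighted) sum of consecutive-position distances
  within each series;
* tie-breaks in backtracking prefer the diagonal, then the move advancing
  the first sequence (ties do not affect the cost, only the reported path);
* both series constant (AB_within = 0) is an error, not ψ = 0.

The DP is validated against exhaustive enumeration of all monotone paths on
random matrices up to 4×4, with and without diagonals, and ψ is checked for
symmetry, scale invariance and joint variable-permutation invariance.

When comparing harmonization levels, the two indicator assemblages have
different type sets by construction. They are aligned on the **union** of
labels with zeros filled (`align_variables`): a type merged away at the
coarser level genuinely contributes 0% there. This choice makes the
between-level dissimilarity reflect both abundance transfer and taxon loss;
aligning on the intersection instead would blind the measure to exactly the
merges under study.

### Time-interval attribution

For the transposed analysis the record is binned into 500-yr intervals
(edges on multiples of the width; a bin [k·w, (k+1)·w) is labelled by its
older edge; post-1950 samples fall in the [−w, 0) bin). The value for
(type, bin) is the mean of the type's **non-zero** percentages in the bin,
zero when the type is absent — so presence, not sampling density, drives
the bin value. Rows (pollen types, the ordering axis) are sorted by the
coarser level's harmonized label and then name, so the fine- and
coarse-level series traverse lineages in comparable order; the ordering is
a parameter since no canonical convention exists. The drop statistic for
bin b is 100·(ψ_full − ψ_without_b)/ψ_full, each leave-one-out ψ recomputed
from scratch; positive drops mark intervals responsible for the
dissimilarity. Removing a bin can legitimately *increase* ψ (negative
drop); only the formula identity is guaranteed and tested.

## Change points

Binary segmentation on the total indicator curve with the Gaussian
mean-and-variance cost C(y) = n·(log 2π + log σ̂² + 1) (twice the negative
log-likelihood at the segment's own MLEs; variance floored at 1e−8 to keep
constant segments finite). Splits are accepted greedily in order of largest
cost reduction while the reduction exceeds the penalty β, up to 4 change
points, minimum segment length 2. Default β = 3·log(n)·k with k = 2
parameters per change point (k = 1 in the mean-only mode, whose cost is the
residual sum of squares) — an MBIC-scale choice; the penalty is exposed
because no canonical value exists for this analysis. Samples enter as an
ordered sequence; unequal time steps are ignored by the detector and ages
are used only to report change-point positions, the standard practice for
stratigraphic series (an explicit limitation: a long hiatus is treated as
one step). The first split is validated against exhaustive single-split
search, and greedy max-gain ordering guarantees that a larger β detects a
subset of a smaller β's change points.

## Paired comparisons and densities

Per category (PRIMARY, ADVENTIVE, APOPHYTE, TOTAL) and level pair, the
summed percentage series are compared with a two-sided Wilcoxon signed-rank
test, pairing by sample index (all levels share the sampling grid, so index
and age pairing coincide). Zero differences are dropped (classical
convention; Pratt's method was considered and rejected to keep the exact
null distribution simple); the exact distribution is used for ≤ 25 untied
pairs, otherwise the normal approximation with continuity correction. The
exact path is validated against full 2^n sign enumeration. Significance is
flagged `*` for p < 0.05 and `**` for p < 0.01; no multiple-testing
correction is applied across the per-site, per-category grid — the tests
are descriptive, and this is documented rather than hidden. When one level
has no taxa in a category (adventives typically vanish at HL2), the
comparison emits an explicit `no data` marker instead of a p-value from an
all-zero curve.

Kernel densities use a Gaussian kernel with the Sheather–Jones
solve-the-equation plug-in bandwidth, implemented here (pilot bandwidths
a = 1.24·λ·n^(−1/7), b = 1.23·λ·n^(−1/9) with λ = min(sd, IQR/1.349);
root-finding by Brent's method) and cross-checked against an independent
implementation of the same equations on a frozen sample (5% tolerance).
Fewer than 3 distinct values fall back to the Silverman rule with a
warning; identical values are an error.

## Synthetic records

The generator draws multinomial counts with a fixed 500-grain sum per
sample — matching how pollen is actually counted (to a target sum), and
inducing the right negative covariance between taxa, unlike independent
Poisson counts. Expected proportions follow per-taxon logistic ramps
(default 10–90% width 300 yr: abrupt enough for change-point recovery,
smooth enough to be realistic) centred on the agriculture onset (7,500 cal
BP) or the intensification (3,500 cal BP). The default 12,000-yr record is
sampled every 100 yr starting at −50 cal BP, exercising the sub-zero bin
edge. The default flora covers every structural case: arboreal background
(NONE), a crop appearing at onset (Cerealia-type, merging into Poaceae at
HL2 with an abundant wild grass), an orchard tree appearing at
intensification (Castanea-type, PRIMARY_NATIVE), an adventive weed
(*P. lanceolata*-type, merging into *Plantago* at HL2 with a wild
congener), a Brassicaceae pair merging already at HL1 (without any HL0→HL1
merge the HL0 and HL1 assemblages would be identical and ψ(HL0, HL1) = 0),
constant apophytes (*Artemisia*, *Pteridium*) and an excluded aquatic
(*Nymphaea*).

What the generator does **not** emulate: pollen productivity and dispersal
physics, chronological (age-model) uncertainty, uneven sampling density,
taphonomic loss, or between-site biogeographic structure. Passing tests
therefore demonstrate that the analysis chain detects the coarsening
artefacts under clean, known conditions — not that any particular real
record is affected to the same degree.

## Problem sizes and determinism

Replicate studies (the psi coarsening ordering and onset-recovery rates)
use 50 independent seeds over the default 121-sample record; the
detection-probability check for a 10-sd mean shift uses 200 replicates of a
100-point series. All simulation is seeded through
`numpy.random.default_rng`; the analysis itself contains no randomness, so
pipeline outputs are byte-identical across reruns. Floats in CSV/JSON
outputs are written with 6 significant digits.
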