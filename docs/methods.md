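# Methods

This note documents the models, conventions and numerical choices
behind `barcodeval`, what the synthetic data generator does and does
not emulate, and the limitations a user should keep in mind.

## Distances

Pairwise distances are Kimura 2-parameter (K2P) estimates.  For a
sequence pair, sites where either sequence carries `-`, `N` or `?` are
excluded (*pairwise deletion* — the default of the R toolchain this
kind of analysis is usually run in, and the only option that tolerates
per-marker missingness without discarding whole columns).  Ambiguity
codes other than N are not resolved; they are illegal input, which
keeps behaviour deterministic.  With transition proportion *P* and
transversion proportion *Q* over the compared sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Cells with no comparable site, or with 1−2P−Q ≤ 0 or 1−2Q ≤ 0
(estimator saturation), are **undefined** and carried as NaN rather
than clamped to a large value: clamping would fabricate distances, and
barcode-scale divergences (≤ ~0.2 substitutions/site) are far from
saturation, so undefined cells signal data problems worth surfacing.
Downstream stages skip and count them; specimens whose every distance
is undefined are excluded from per-query statistics and reported.

The divergence index *K* is the mean number of observed substitutions
(transitions + transversions) over all defined pairs, rounded half-up
to an integer for reporting; the unrounded mean is retained.

## Barcode gap

Two views are computed.  The distribution view reports five-number
summaries of the intra- and interspecific distance sets and an overlap
flag (true when the intraspecific maximum reaches or exceeds the
interspecific minimum).  The per-sequence view compares, for each
specimen, its greatest defined distance to a conspecific (`max_intra`)
with its smallest defined distance to any heterospecific
(`min_inter`); the specimen shows a gap iff `min_inter > max_intra`
strictly — a tie is not separation.  `max_intra` is per-specimen, not
the species-wide maximum, matching the per-sequence granularity of the
reported proportions.  Singleton species take `max_intra = 0`, so any
positive `min_inter` counts as a gap; records carry a singleton flag
because this convention inflates gap counts.

## Identification criteria

All three criteria are leave-one-out: the query is removed from its own
candidate set.  Comparisons with the threshold are inclusive (≤), so a
"1%" bound is met at equality.

* **Near Neighbour**: true iff at least one co-minimal neighbour is
  conspecific (the optimistic tie rule).  Threshold-free.  Singleton
  queries are scored and are necessarily false.
* **Best Close Match**: candidates are sequences within the threshold;
  among them, the co-minimal set decides — all conspecific → correct,
  none → incorrect, mixed → ambiguous; empty candidates → no ID.
* **Threshold (BOLD) rule**: the whole within-threshold set decides
  with the same purity trichotomy.  A pure BOLD set implies a correct
  best close match, which the test suite verifies by enumeration.

Singleton-species queries stay in every denominator; they depress
correct-identification rates exactly as they do in real reference
libraries with unique vouchers.

Category percentages in summaries use largest-remainder apportionment,
so each criterion's row sums to exactly 100 — the convention printed
identification tables follow.  Scalar percentages (gap proportion,
monophyly proportion) are rounded half-up.

## Threshold optimisation

The best-close-match threshold is estimated from the pooled (intra +
inter) distance vector: a Gaussian KDE with Silverman's rule-of-thumb
bandwidth, 0.9·min(sd, IQR/1.34)·n^(−1/5), evaluated on a 512-point
grid from the smallest to the largest distance.  Grid points strictly
below both neighbours are local minima; the smallest is the threshold,
interpreted as the intra/interspecific transition.  If no interior
minimum exists (unimodal pooled distances), the fixed 1% BOLD default
is returned and flagged as a fallback.  Pooled rather than
interspecific-only distances are used because the minimum being sought
is precisely the dip *between* the two components.

A caveat quantified by the test suite: when the interspecific
component has substantial spread, the smoothed density's dip can sit a
few thousandths above the *sample* minimum of the interspecific draws
(the two quantities are tightly correlated, both living in the overlap
of the smoothed tails).  The estimated threshold therefore reliably
clears the intraspecific cluster but should not be read as a strict
lower bound on every interspecific distance.

Threshold policy across taxonomic levels is configurable:
`level_optimised` re-estimates per subset (falling back to the
family-level estimate below 10 distances), `family_level` reuses the
family estimate at lower ranks, and `fixed` applies a constant.  The
BOLD criterion always runs at its fixed 1% regardless of policy, so the
two threshold-based criteria stay comparable across configurations.

## Trees and monophyly

Neighbour joining follows Saitou–Nei agglomeration with the
Studier–Keppler criterion Q(i,j) = (r−2)·d(i,j) − Σd(i,·) − Σd(j,·).
Ties in Q are broken toward the lexicographically smallest pair of
cluster keys (a cluster is keyed by its smallest leaf label), making
the topology invariant to input row order.  Negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving
path lengths through the join; topology is unaffected.  NJ requires a
complete matrix: specimens with any undefined distance are dropped
first with a logged warning — imputation would fabricate signal.

A species with ≥ 2 specimens is monophyletic iff some edge bipartition
of the unrooted tree isolates exactly its specimen set.  Working with
bipartitions avoids the arbitrary-root sensitivity of clade-based
tests.  Singletons trivially "cluster" and are counted monophyletic but
flagged; the report carries both the inclusive proportion and the
proportion over multi-specimen species.

## Synthetic data generator

The generator emulates the structure of a family-scale plant barcoding
study: ~58 species in a hierarchy of genera/subgenera/sections, one to
six accessions per species, four markers with unequal lengths,
substitution rates and sequencing success.

* **Species tree**: pure-birth (Yule) topology, made ultrametric at
  height `interspecific_depth` (expected substitutions/site, root to
  tip, at relative rate 1).  A raw Yule tree conditioned on *n* tips
  places its most recent splits a fraction ~1/(n·ln n) of the height
  from the tips, which would make sister species nearly
  indistinguishable regardless of marker quality.  Recognised species,
  however, are differentiated lineages, not instantaneous splits; the
  generator therefore appends a terminal no-speciation period equal to
  `min_split_frac` (default 0.2) of the final height before rescaling,
  bounding every split away from the present.  This is what lets a
  25-fold intra/inter separation actually manifest as a barcode gap
  for ≥95% of species.
* **Within species**: accessions attach to the species tip as a star,
  each on a branch drawn Exponential(mean `intraspecific_depth`/2), so
  two conspecific accessions diverge by `intraspecific_depth` in
  expectation while keeping the heavy right tail that within-species
  coalescent variation produces.  A full coalescent within species is
  deliberately out of scope; the star is the simplest structure giving
  controlled intra/inter separation.
* **Sequences**: the root sequence is uniform over {A,C,G,T}; each
  branch applies the K2P transition-probability matrix with transition
  rate α and total transversion rate 2β, α/(2β) = κ and α + 2β = 1 per
  unit branch length, independently per site, with branch lengths
  multiplied by the marker's relative rate.  No indels, no
  across-site rate heterogeneity, no selection, uniform base
  frequencies — the simulator is the matched process for the K2P
  estimator by construction.
* **Dropout**: each (specimen, marker) pair is dropped independently
  with the marker's dropout probability, reproducing unequal per-marker
  specimen counts without modelling PCR chemistry.
* **Taxonomy**: genus/subgenus/section labels are assigned to
  monophyletic blocks of the species tree (largest clades opened
  first, deterministically), so level-stratified analyses are well
  defined.  Block sizes follow the topology and can be very uneven —
  including single-species higher taxa, which the pipeline flags as
  degenerate rather than hiding.

Default marker models (lengths 552/771/1034/821; relative rates
0.12/0.19/0.63/1.47; dropout 0.10/0.20/0.30/0.45) reproduce the
observed ordering and rough magnitudes of plastid-vs-nuclear divergence
and sequencing success in published four-marker plant panels: a slow
conservative coding region, a mid-rate coding region, a fast intergenic
spacer and a fast, harder-to-amplify nuclear ribosomal region.

Everything is driven by one `numpy` generator seeded from `SimParams`:
identical parameters give bit-identical sequences, metadata and trees.

What passing tests on this generator do **not** show about real data:
no alignment error or indels, no heterotachy, no introgression or
incomplete lineage sorting placing conspecifics far apart, no
misidentified vouchers.  Real libraries fail identification for those
reasons too; the synthetic regime isolates the purely
distance-geometric behaviour of the criteria.

## Problem sizes

The shipped experiments use study-scale datasets (58 species, 1–6
accessions, ~200 specimens, 1000-bp markers) for the regime analyses,
and smaller simulations (10–12 species) where only structure or
determinism is being checked.  Rule-table enumeration covers all set
partitions of up to five specimens, with the pair-distance grid fully
enumerated up to four specimens and sampled (2000 seeded draws per
partition) at five, where the full cross product adds nothing but time.

## Known limitations

* The K2P estimator's undefined cells make whole specimens drop from
  NJ trees when markers are short and divergent; the report counts
  them, but comparisons across markers with very different missingness
  should read those counts.
* The KDE threshold is a point estimate with no uncertainty attached;
  in heavily overlapping regimes it is volatile, and the pipeline's
  policy mechanism (family-level reuse, fixed fallback) exists partly
  to manage that.
* Monophyly is binary per species; paraphyly caused by a single rogue
  specimen counts the same as complete intermixing.
* Concatenation keeps only specimens sequenced for every member marker
  (the intersection rule), so combined datasets can be much smaller
  and singleton-heavy; summaries are reported per dataset and are not
  sample-size-adjusted across datasets.
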