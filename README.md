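# barcodeval

Multi-criteria evaluation of DNA barcode markers for species
discrimination.

## The problem

A DNA barcode is a short standardized DNA region used to assign unknown
specimens to species — for plants, the core barcodes `rbcLa` + `matK`,
commonly supplemented with `trnH-psbA` and nrITS.  Whether a candidate
marker (or marker combination) actually discriminates the species of a
group has to be demonstrated, and the field evaluates this with several
complementary criteria computed from a reference library of sequences
labelled with species names:

1. **Barcode gap** — is within-species variation separated from
   between-species divergence?  Assessed both at the distribution level
   (ranges/means/medians of intra- vs interspecific distances) and per
   sequence, comparing each specimen's greatest distance to a
   conspecific with its smallest distance to any other species.
2. **Discriminatory power** — leave-one-out identification under three
   distance rules: *Near Neighbour* (is the closest sequence
   conspecific?), *Best Close Match* (the closest sequence within a
   distance threshold decides: correct / incorrect / ambiguous / no ID)
   and the *BOLD rule* (all sequences within 1% form the candidate set;
   the set's purity decides).
3. **Species monophyly** — does each species form a cluster on a
   neighbour-joining phylogram?

`barcodeval` implements this entire evaluation as a tested, reusable
pipeline: per marker, per marker combination (concatenated over the
specimens shared by all members), and per taxonomic level (family /
subgenus / section).  Since reference libraries are rarely
redistributable, the package ships a synthetic multi-marker data
generator with controlled intra/interspecific divergence, hierarchical
taxonomy and per-marker specimen dropout, so every stage can be
exercised and validated without external data.

## Core methods

Pairwise distances use the Kimura 2-parameter model with pairwise
deletion.  With transition proportion *P* and transversion proportion
*Q* over the sites comparable in a pair,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Cells where nothing is comparable or the estimator saturates
(1−2P−Q ≤ 0 or 1−2Q ≤ 0) are carried as undefined and skipped (and
counted) downstream.  The divergence index *K* is the mean number of
observed substitutions between sequence pairs.

Best-close-match thresholds are optimised per dataset from the pooled
pairwise-distance distribution: a Gaussian KDE (Silverman bandwidth,
512-point grid) is scanned for its first local minimum, interpreted as
the intra/interspecific transition; with no interior minimum the BOLD
default of 1% is used and flagged.

Trees are built with neighbour joining (Saitou–Nei agglomeration,
Studier–Keppler criterion, deterministic tie-breaking) and a species is
monophyletic when some bipartition of the unrooted tree isolates
exactly its specimens — a root-free criterion.

## Worked example

```python
import barcodeval as bv
from barcodeval.synthetic_data import MarkerModel, SimParams, simulate_dataset

params = SimParams(
    n_species=20, accessions=(1, 4),
    markers=(MarkerModel("demo", 800, relative_rate=1.0, kappa=2.0),),
    interspecific_depth=0.05, intraspecific_depth=0.002, seed=42,
)
sim = simulate_dataset(params)
dataset = bv.single_marker_dataset(sim.alignments["demo"], sim.specimens)

k2p = bv.distance_matrix(dataset)
raw = bv.distance_matrix(dataset, method="raw_substitutions")
summary = bv.summarize(k2p, raw, dataset.specimens, dataset.total_length)
print(f"{k2p.n} specimens, K = {summary.K} substitutions/pair")
print(f"intra mean = {summary.intra_mean:.4f}, inter mean = {summary.inter_mean:.4f}")

parts = bv.partition_distances(k2p, dataset.specimens)
est = bv.local_minima_threshold(parts.pooled())
print(f"optimised threshold = {est.threshold_pct:.2f}%")

records, excluded = bv.gap_records(k2p, dataset.specimens)
print(f"barcode gap: {bv.gap_summary(records, excluded).pct_with_gap}% of sequences")

_, bcm = bv.best_close_match(k2p, dataset.specimens, est.threshold)
print(f"best close match: {bcm.percentages}")

tree = bv.nj_tree(k2p)
mono = bv.species_monophyly(tree, dataset.specimens)
print(f"monophyletic species: {mono.pct_monophyletic}%")
```

prints

```
46 specimens, K = 61 substitutions/pair
intra mean = 0.0026, inter mean = 0.0850
optimised threshold = 7.15%
barcode gap: 100% of sequences
best close match: {'ambiguous': 0, 'correct': 91, 'incorrect': 9, 'no_id': 0}
monophyletic species: 100%
```

Read: conspecific accessions differ by ~0.3% while species differ by
~8.5% on average, so every sequence shows a barcode gap and every
species is monophyletic on the NJ tree.  The KDE threshold falls in the
gap between the two distance clusters.  Best close match identifies 91%
of queries correctly; the 9% "incorrect" are specimens of singleton
species, which leave-one-out identification can never get right — a
structural limitation the summaries deliberately keep in the
denominator.

The same analysis runs from the shell over FASTA + metadata files or a
fresh simulation:

```sh
barcodeval simulate --n-species 58 --seed 1 --out data/
barcodeval evaluate --synthetic --seed 1 --out report/
barcodeval evaluate --marker rbcLa=data/rbcLa.fasta --marker matK=data/matK.fasta \
    --metadata data/metadata.csv --out report/
```

`evaluate` writes CSV tables (marker summary, gap summary,
identification outcomes per criterion, monophyly per species), Newick
trees, per-query outcome tables and a provenance JSON; reruns with the
same config and seed are byte-identical.

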