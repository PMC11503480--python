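# magqc

Completeness and contamination estimation for bacterial and archaeal
genome bins (MAGs) from protein-domain count profiles, using a two-stage
hybrid of dynamic marker genes and machine-learning refinement.

## The problem

Genomes reconstructed from metagenomes vary enormously in quality, and
every downstream analysis needs to know *how much of the organism's
genome is actually there* (completeness) and *how much foreign material
was binned with it* (contamination). The classical approach counts a
few dozen universal single-copy genes, which cover only a sliver of the
genome and cannot separate a 50/50 mixture of two half-genomes from one
clean genome.

`magqc` instead works on the full protein-domain count profile of a bin
— a sparse vector of copy numbers C(i) over thousands of protein
families — and estimates quality in two stages:

**Stage I (marker-based).** The K most similar reference profiles are
found with the count-coincidence similarity

    sim(C_q, C_r) = |{i : C_q(i) = C_r(i), C_q(i) > 0}|
                    / sqrt(|supp(C_q)| · |supp(C_r)|),

and a query-specific *dynamic marker set* M is extracted: every family
with an identical nonzero count in all K neighbors (markers are not
restricted to single-copy families). With M markers of agreed reference
count C_r(m),

    cont = (1/M) Σ_m [C_q(m)/C_r(m) − 1]_+
    comp = (1/M) Σ_m  C_q(m)/C_r(m)       − cont.

Queries with completeness below 60% or contamination above 30% are
reported directly from stage I; queries missing more than 90% of both
superkingdom universal-marker sets are rejected outright.

**Stage II (regression refinement).** For queries inside the trusted
range, the query/reference count ratios against each neighbor are
compressed into a *count ratio histogram* (CRH): bin centers are all
distinct rationals a/b with a, b ≤ c_max, the left-most bin also
collects families missing from the query, and the right-most bin
collects query-only families and ratios above c_max. The mean CRH over
the K neighbors plus the two stage-I estimates feed two regressors (a
one-hidden-layer MLP with 100 units by default; KNN, random-forest,
linear-SVR and elastic-net alternates are registered), one per quality
index, with separate histogram resolutions (c_max = 6 for completeness,
12 for contamination).

The package also ships the reference-database builder (dereplication by
average-linkage Bray–Curtis clustering, universal-marker discovery with
a 95% single-copy coverage criterion, completeness filtering), a
ground-truth bin simulator (fragmentation, tetramer-signature-matched
contaminants), a synthetic domain world for fully self-contained
testing, and a date-split / two-fold cross-validation evaluation
harness.

A production protein-domain annotator (translated ORF search against
Pfam) is *not* included; the `AnnotationBackend` contract defines the
interface, and an exact-match token annotator stands in for tests and
synthetic data.

## Worked example

```python
import numpy as np
import magqc as m

# A self-contained synthetic world: 12 genomes in 3 clades, 60 core +
# 80 accessory protein families planted as sequence tokens.
world = m.generate_synthetic_world(n_genomes=12, n_core_families=60,
                                   n_accessory_families=80,
                                   genome_length=60_000, n_clades=3, seed=11)
db = m.build_reference_db(world.reference_entries())

# Train the stage-II refinement on simulated bins.
train = m.simulate_query_bins(world, {g.genome_id for g in world.genomes},
                              n_bins_per_genome=8,
                              rng=np.random.default_rng(5),
                              fragment_length=5_000)
model = m.train_quality_model(train, db, m.Stage2Config(seed=0))

# Simulate one degraded bin and predict its quality.
g = world.genomes[0]
bin_ = m.simulate_bin(g, world.genomes, np.random.default_rng(7),
                      fragment_length=5_000)
profile = m.toy_annotate(bin_.contigs, world.catalog, bin_.bin_id)
s1 = m.run_stage1(profile, db, K=9)
pred = m.predict_quality(profile, db, model)

print(f"truth    comp={bin_.truth_completeness:.3f} cont={bin_.truth_contamination:.3f}")
print(f"stage I  comp={s1.completeness_clamped:.3f} cont={s1.contamination:.3f} "
      f"markers={s1.marker_count} route={s1.route}")
print(f"stage II comp={pred.completeness:.3f} cont={pred.contamination:.3f} "
      f"(stage_used={pred.stage_used})")
```

Output:

```
truth    comp=0.833 cont=0.250
stage I  comp=0.900 cont=0.167 markers=60 route=refine
stage II comp=0.894 cont=0.278 (stage_used=stage2)
```

The simulated bin truly contains 83.3% of the source genome with 25.0%
contamination. Stage I, working from 60 dynamic markers, overestimates
completeness (90.0%) and underestimates contamination (16.7%); because
both estimates are inside the trusted range the bin is routed to stage
II, whose regression moves contamination to 27.8% — within 2.8
percentage points of the truth — while completeness stays close at
89.4%.

## Command line

```sh
magqc build-db --profiles profiles.tsv --meta meta.tsv -o db/
magqc predict --input bins.tsv --db db/ --model model/ -o predictions.tsv
magqc make-world -o world/ && magqc simulate --genomes world/ -o bins/
magqc train --bins binprofiles.tsv --manifest bins/manifest.tsv --db db/ -o model/
magqc evaluate --manifest bins/manifest.tsv --predictions predictions.tsv
```

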