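# Methods

## Model overview

`magqc` estimates the completeness and contamination of a genome bin
from its protein-domain count profile, a sparse map from protein-family
identifiers to nonnegative copy counts. The estimation pipeline is:

1. **Prefilter.** Marker-presence completeness (fraction of universal
   single-copy markers present at least once) is computed against the
   bacterial and the archaeal marker set of the reference database. A
   query below 10% on *both* sets is rejected: with that little signal
   the neighbor search is unreliable.
2. **Nearest-neighbor search.** The K references (default K = 9)
   maximizing the count-coincidence similarity are selected. The
   similarity counts families with *exactly equal* nonzero counts,
   normalized by the geometric mean of the support sizes; requiring
   equality means mostly low-copy families contribute, which keeps
   high-copy families and contaminant-inflated counts from dominating.
   Ties are broken by genome id for determinism.
3. **Dynamic markers.** The marker set is the set of families with an
   identical nonzero count across all K neighbors — a query-specific
   generalization of single-copy marker genes that includes stable
   multi-copy families. If the neighborhood is too heterogeneous the
   marker set can be empty; such queries are reported as rejected with
   a machine-readable reason rather than given fabricated estimates.
4. **Stage-I estimate.** With M markers of agreed count C_r(m),
   cont = mean_m [C_q(m)/C_r(m) − 1]_+ and comp = mean_m C_q(m)/C_r(m)
   − cont. Algebraically comp = mean_m min(C_q(m)/C_r(m), 1), so the
   completeness estimate always lies in [0, 1]; the reported value is
   additionally clamped at 1 as a safety net, while the raw value is
   what enters the stage-II feature vector. Contamination is
   unbounded above.
5. **Routing.** Estimates with completeness below 60% *or*
   contamination above 30% are final (strict inequalities, exactly as
   worded in the routing rule); boundary values refine. Stage II is
   trained only on the 60–100% / 0–30% quality range, so outside that
   range its predictions would be extrapolations.
6. **Stage-II refinement.** Count ratio histograms (below) from the
   query against each neighbor are averaged; the two stage-I estimates
   are appended; two independent regressors predict the final indices.
   Outputs are clipped to [0, 1] for completeness and [0, 1] for
   contamination (ceiling configurable).

## Count ratio histograms

Bin centers at resolution c_max are all distinct rationals a/b with
a, b ∈ 1..c_max (11 centers for c_max = 4, 23 for 6, 63 for 12). The
two extreme bins are overloaded rather than adding extra bins: the
left-most bin also counts families present only in the reference
(ratio 0), the right-most also counts families present only in the
query and ratios above c_max. Every family in the union of the two
supports is binned exactly once and the histogram is normalized by the
union support size, so frequencies always sum to 1.

Ratios between centers are assigned to the **nearest center**, with an
exact-midpoint tie going to the center closer to 1 (biasing ties toward
"clean" rather than inflating apparent artifacts). Centers, ratios and
midpoint comparisons use exact rational arithmetic (`fractions`), so
deduplication (2/4 vs 1/2) and tie detection are exact; bin assignments
are memoized on the (query count, reference count, c_max) triple.

A complete uncontaminated bin yields a unit spike at center 1;
incompleteness moves mass into the left-most bin, contamination moves
mass right of center 1. Per-neighbor histograms are normalized first
and then averaged, so the mean CRH also sums to 1.

## Stage-II regressors

Defaults: a one-hidden-layer MLP with 100 units per target, weight
decay 1e-4 for completeness and 1e-7 for contamination, histogram
resolution c_max = 6 (completeness) and 12 (contamination), K = 9.
Alternates registered for the same interface: K-nearest-neighbor,
random forest (library defaults), linear SVR, and elastic net with its
built-in cross-validated path.

Features are standardized inside the model pipeline, with mean and
standard deviation estimated from the training split only. The MLP is
trained with the **lbfgs** solver (full-batch quasi-Newton), a 500
iteration cap and tolerance 1e-6: at the training-set sizes this
package targets (hundreds to a few thousand bins), stochastic
first-order solvers stall far from a minimum, while lbfgs converges
reliably and is deterministic given the seed. All stochastic components
take the configuration seed; identical seeds give bit-identical models
(verified by fingerprint in the tests).

The hyperparameter grid search is an exhaustive cartesian scan scored
by validation MAE (mean of the two indices, percentage points), with a
leakage guard that rejects train/validation bin sets sharing source
genomes.

## Reference database construction

Four deterministic steps: (1) agglomerative clustering of
relative-frequency profiles with average linkage on Bray–Curtis
dissimilarity, cut at 0.10, keeping one representative per cluster;
(2) universal-marker discovery per superkingdom on the representatives
(a family qualifies iff it occurs exactly once in ≥ 95% of them);
(3) removal of genomes whose marker-presence completeness against their
own superkingdom's set falls below 95% — a guard against mislabeled
"complete" inputs; (4) re-clustering of the survivors with the same
method. Design choices where the procedure was open:

* distance, linkage and the cut threshold are not dictated by the
  estimation formulas; Bray–Curtis on relative frequencies with average
  linkage at 0.10 matches the 10% profile-dissimilarity criterion used
  elsewhere in the protocol, and all three are config-exposed;
* cluster representatives are medoids (minimum summed dissimilarity),
  ties broken lexicographically, for determinism;
* the step-3 completeness guard uses the marker-presence fraction
  (simple and monotone in the retained families) rather than the
  stage-I ratio estimator;
* both clustering rounds use the same threshold.

Marker counts are data-dependent: on the synthetic world the builder
finds its own sets (typically ~105–115 per superkingdom out of 150 core
families at desk scale); counts reported for any real reference corpus
depend entirely on that corpus.

## Bin simulator

A simulated bin draws completeness ~ U(60%, 100%) and contamination
~ U(0%, 30%) independently, fragments the query genome into consecutive
20-kb windows (a trailing remainder is kept if ≥ 25% of the fragment
length), samples round(comp × N) fragments without replacement, and
adds round(cont × L_query / fragment_length) contaminant fragments.
Contamination is measured against the complete query genome length.
Contaminants must have a tetramer-signature Bray–Curtis similarity
≥ 80% to the query (canonical 4-mers, 136 dimensions, ambiguous
windows skipped); eligible genomes are consumed in uniform random
order, fragments without replacement within each genome, drawing more
genomes until the target is met and erroring if the eligible pool is
exhausted. `fragment_length = 0` passes native contigs through
unfragmented.

Fragment counts are rounded to nearest; the **realized** base fractions
(not the drawn targets) are recorded as ground truth, so evaluation is
exact regardless of quantization and of the rounding convention. All
randomness flows through one explicitly passed generator.

## Synthetic world

The synthetic world replaces a real reference corpus for testing. Each
genome is a random background sequence with clade-specific GC content
(clades evenly spaced in 0.40–0.60, so tetramer similarity is high
within clades) into which 24-nt family tokens are planted at
non-overlapping positions on either strand; annotation is exact-match
token counting on both strands. Core families are single-copy in
≥ 95% of genomes by construction (each family deviates, to count 0 or
2, in at most 5% of genomes, with 2% expected); accessory families
carry clade-correlated counts in 0..3 with 35% of families jittered
per genome — enough strain-level variation that the 10% dereplication
keeps genomes of one clade apart, as in a dereplicated reference set.
Release dates span three eras (2019, 2021/22, 2023+, roughly 2:1:1
within each clade) to support the date split; a small rooted taxonomy
(root → superkingdom → clade → genome) supports the LCA classifier.
Token planting is verified by re-annotation at generation time, so the
profile round trip is exact by construction.

What the world does **not** emulate: real gene length variation and
ORF structure, annotation noise (false or missed domain hits),
lineage-specific marker erosion, compositional heterogeneity within a
genome, and real contig-length distributions. Passing tests on this
world demonstrate the correctness of the machinery and the end-to-end
learnability of the quality signal, not field accuracy on real MAGs.

## Evaluation protocol and desk-scale sizes

Genomes are split by release date into three parts (half-open
intervals; an entry dated exactly on a split date goes to the later
part): the oldest part is the reference database, the two recent parts
are used in a two-fold cross-validation (train on one, validate on the
other, average the validation MAEs). Contaminants are drawn within
each part so folds stay leakage-free, which is also enforced by an
explicit guard. Error metrics are mean/median absolute error in
percentage points with signed errors defined as predicted − truth
(positive = overestimation); the reported spread is the standard
deviation of the absolute errors.

The package's end-to-end demonstration uses a world of 60 genomes
(6 clades, 150 core + 300 accessory families, 300-kb genomes) with 20
bins per genome at 20-kb fragments — sizes chosen so the full protocol
(database build, featurization, two MLP trainings per fold) completes
in well under a minute while leaving enough bins (~300 per fold) for
the refinement effect to be measurable. At this scale the stage-I MAE
is ≈ 4 %pt for both indices and the MLP refinement improves both; the
margins are naturally smaller than with corpus-scale training data.

## Known limitations

* Stage-I contamination feeding the 30% routing rule is the raw
  (unclamped) estimate.
* Stage II never falls back to stage I on out-of-range predictions; it
  clips instead.
* The annotation backend contract only requires nonnegative integer
  counts per family; whether a production annotator counts per domain
  hit or per ORF does not affect the machinery but does affect the
  meaning of the counts, and reference and query must use the same
  backend.
* The grid search trains one model pair per grid point; no warm
  starting or successive halving.
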