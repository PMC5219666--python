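# Methods

This note documents the statistical models, the estimators, the
simulator, the numerical choices, and the known limitations of the
package. It is written for a reader who wants to know exactly what each
step assumes and what the validation experiments do and do not show.

## Population model

The design is a biparental F2: two fully homozygous parents are crossed,
the F1 is selfed, and each offspring receives two independent gametes of
the F1. At a marker informative for the cross (the `aa×bb` pattern —
both parents homozygous for different alleles) the offspring genotypes
segregate aa : ab : bb = 1 : 2 : 1.

Along a chromosome, the two gametes are independent two-state Markov
chains, so the offspring genotype sequence is itself Markov with
transition matrix (c = 1 − r):

|        | aa   | ab        | bb   |
|--------|------|-----------|------|
| **aa** | c²   | 2rc       | r²   |
| **ab** | rc   | c² + r²   | rc   |
| **bb** | r²   | 2rc       | c²   |

and stationary law (¼, ½, ¼). All multipoint computations in the
package (missing-data marginalization, error absorption, chain
likelihoods for ordering and accessory placement, posterior imputation)
are forward–backward passes over this chain.

## Marker identification

Equal-length fragment tags are clustered into loci by single-linkage on
positional identity (> 95% of positions matching). This replaces
alignment-based clustering and is exact for fixed-length tags; tags of
unequal length are rejected. Locus filters follow the conventions of
reduced-representation genotyping in a diploid: more than four distinct
tags ⇒ repetitive; more than three SNPs between the parental alleles ⇒
filtered; mean sequence depth below 2.20 ⇒ low depth (the depth is the
mean over sequenced samples; the alternative per-sample minimum is a
configuration choice). Alleles are the two highest-count tags
(minor-allele-frequency evaluation), ties broken lexicographically for
determinism. Variants between the parental alleles are typed by the
IUPAC code of the unordered base pair (R, Y transitions; S, W, K, M
transversions); length-changing differences are InDels, with a global
alignment used when the alleles differ in length.

## Genotype scoring

Reads at a marker×individual cell are independent Bernoulli draws: an
aa individual yields an A read with probability 1 − ε, bb with ε, and a
heterozygote with ½ (an error swaps the alleles, leaving ½ unchanged).
The default ε is 0.01. Hard calls take the posterior mode under the F2
prior 1:2:1; the quality score is −10·log10(1 − posterior) capped at 60.
Zero depth is missing. The iterative pruning step removes whichever
marker or individual has the lowest mean quality until the matrix mean
reaches the cutoff.

Hard calls at ~3x depth are unavoidably noisy: a single read calls the
heterozygote (the prior dominates), same-allele read pairs from true
heterozygotes call homozygotes, and one error read flips a homozygote to
ab. Aggregate genotype *frequencies* remain nearly unbiased (the prior
does its job), which is why the segregation χ² test runs on the full
hard-call set — but pairwise linkage statistics computed from hard calls
inflate r badly. The estimation core therefore works with **genotype
likelihoods**: the 3-vector P(reads | genotype), which is exact under
the read model, keeps single reads partially informative, and gives
zero-depth cells the uninformative vector.

## Two-point estimation

For a marker pair the joint genotype classes have the classical F2
probabilities in r; the double heterozygote mixes parental (½c²) and
recombinant (½r²) origins. EM iterates the expected recombinant-gamete
count; the estimate is clamped to [1e−7, 0.5] and iterated to |Δr| <
1e−8 (hard-call route). Both linkage phases are evaluated (repulsion =
swapping one marker's homozygote labels) and the higher-likelihood phase
kept, so estimates are invariant to allele relabelling. LOD is
log10 L(r̂) − log10 L(½).

The read-count route marginalizes the latent joint genotypes through
the genotype likelihoods. For speed, count cells are quantized into
classes — exact for counts ≤ 3 per allele, with deeper cells collapsed
into pure-A / pure-B / one-stray-read / mixed classes whose
representative counts are the class means of the data (so the classes
stay faithful at 3x and at 30x). The EM then runs fully vectorized over
all marker pairs on class-pair contingency tables. A first fixed stage
covers every pair; pairs that look linked (r < 0.45) are refined to
1e−6. Because r ≥ 0 is a boundary, estimates at very small r carry the
usual half-normal boundary excess (~ +0.01 at n = 2000); multipoint
re-estimation, not the pairwise matrix, provides the final distances.

## Grouping

Markers are partitioned into linkage groups before ordering. Two
failure modes dominate at realistic scale (tens of thousands of marker
pairs): a *chance* pair of unlinked markers exceeding the threshold
welds two chromosomes, and two unlinked but segregation-distorted
markers share skewed margins that the 1:2:1-class model misreads as
linkage. The package therefore:

* scores grouping edges with a **modified LOD**: the Fisher-Z
  transformed Pearson correlation of genotype dosages (aa=0, ab=1,
  bb=2), expressed on the LOD scale (Z²/(2 ln 10)). Correlation is
  invariant to each marker's own genotype frequencies, so distorted
  margins cannot fake linkage, and the statistic has 1 df — nearly the
  power of the model LOD for this problem;
* unites only markers in the same **2-edge-connected component** of the
  thresholded graph ("robust" mode). A genuine chromosome at working
  density is redundantly connected (adjacent plus skip-one pairs); a
  chance collision gives a single bridge. Requiring two edges at
  per-edge LOD 4 gives overall false-merge control comparable to single
  edges at LOD 5; a single overwhelming edge (≥ 2× the threshold) is
  also accepted, and fragments of ≤ 2 markers attach across bridges.
* groups over framework **and** accessory markers together, so a
  selection region cannot orphan its chromosome; the framework /
  accessory distinction then governs ordering versus insertion within
  each group. Components with no Mendelian backbone attach to their
  best-linked framework-bearing group.

Plain single-linkage at a fixed threshold (the classical rule) and a
threshold-stability ("plateau") variant are available as alternatives.

## Ordering and map distances

Within a group the ordering objective is SARF — the sum of adjacent
recombination fractions. Simulated annealing over permutations (segment
reversals and single-marker insertions; geometric cooling 0.995; initial
temperature from the SARF spread of 100 random orders; stop after 2000
consecutive rejections) runs after a spatial-sampling step that orders
one informative core marker per window of five and inserts the rest at
their SARF-minimizing interval; a deterministic 2-opt/insertion descent
polishes each restart, and the best of three seeded restarts wins.

Because pairwise r̂ at shallow depth cannot always resolve closely
spaced markers, the SARF order is then refined under the **multipoint
chain likelihood**: a global 2-opt pass (every segment reversal is one
forward-pass evaluation; this catches long-range "folds") followed by a
sliding window of five markers whose 119 permutations are each scored by
the full-chain likelihood with genotype-likelihood emissions.

Adjacent recombination fractions are re-estimated by EM over the
genotype Markov chain (forward–backward E-step, per-interval M-step) —
a deterministic replacement for a blocked Gibbs sampler that reduces
exactly to two-point estimation on complete data. In the hard-call
route the emission model carries a symmetric miscall rate that can be
re-estimated Baum–Welch style; in the genotype-likelihood route the
emissions are the likelihoods themselves and no error knob is needed.
Map positions are cumulative Kosambi distances d = 25 ln((1+2r)/(1−2r))
of the multipoint adjacent r.

Error correction follows the SMOOTH idea: an observation whose genotype
has predicted probability below a threshold given its nearest observed
flanks (default 1e−3; passes run with rising stringency until stable)
is set to missing — never rewritten. The completed genotype deliverable
then fills missing cells: by k-nearest-neighbour majority vote (k = 5,
ties to the single nearest marker) in the hard-call route, or by the
chain-posterior mode in the genotype-likelihood route, which uses the
cell's own reads plus the whole chromosome and is strictly more
accurate. Distances are always estimated before imputation so the
imputer cannot shrink the map.

Each group's orientation is arbitrary; it is canonicalized so the
lexicographically smaller terminal marker id comes first.

## Accessory (distorted) markers

Markers failing the segregation test (p < 0.05, χ² with 2 df, no
multiple-testing correction — the field's convention) are excluded from
framework construction and inserted afterwards by multipoint maximum
likelihood: each marker's genotype-likelihood row is spliced into the
framework chain at candidate positions (a coarse grid per interval plus
extensions beyond the ends, then a 1 cM fine grid) and the full chain
likelihood decides. Insertion is sequential, strongest-linked first,
and each placed marker becomes an anchor — so the map walks stepwise
into a selection region far from any Mendelian marker. Maximal runs of
consecutively inserted markers are finally re-ordered jointly (SARF +
chain likelihood, their flanking anchors pinned to the ends) and
respaced from multipoint adjacent r. Framework order and positions are
never changed by insertion.

A segregation distortion region (SDR) is a maximal run of ≥ 3
consecutive distorted markers along the finished map (the run length is
configurable; the definition is the package's own, as none is standard).

## The simulator

`simdata` generates the data-generating process the pipeline assumes:
Poisson crossover counts (length in Morgans) with uniform positions (the
Haldane, no-interference model — map estimation uses Kosambi, so
simulated lengths are recovered approximately, not exactly), optional
gamete-viability selection (a gamete carrying the non-selected allele at
a distortion locus is rejected with probability s and redrawn; zygotic
selection with per-copy survival (1−s) is the alternative mechanism),
Poisson read depth (negative binomial via a dispersion knob), per-read
error ε, and an explicit masking rate on top of natural zero-depth
missingness. Defaults follow the sorghum study design: 130 individuals,
ten chromosomes with the mapped per-chromosome lengths and marker
counts, parent depths 12.9x/16.8x, offspring depth 2.8x, 12%
parent-polymorphism among simulated loci. Tag sequences for polymorphic
loci carry 1–3 substitutions at a transition:transversion ratio of 2
and occasional InDels.

What the simulator does **not** emulate: read-level artifacts
(clustered sequencing errors, index hopping, PCR duplicates), depth
correlations between markers or individuals, residual parental
heterozygosity, and reference-genome structure. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to every artifact of real libraries.

## Validation experiments and their design

The recovery experiment simulates ten chromosomes at the study's
population size and depth (130 F2s, 3x offspring, ε = 0.01, 10% extra
missingness) with two gamete-viability loci at s = 0.8. Design choices,
made once:

* Markers are evenly spaced (the real map's density is fairly even;
  its largest gap is 15.7 cM).
* The two distorted chromosomes are 180 cM with near-terminal loci,
  the clean ones 110–130 cM with 22–28 markers (~5 cM spacing). At
  n = 130 an s = 0.8 locus significantly skews markers up to ~70 cM
  away, so a shorter distorted chromosome would retain no Mendelian
  framework at all; a terminal locus keeps the framework contiguous.
* The QC progeny-depth threshold is set to 2.0 in this experiment
  because the classical > 3-fold cutoff coincides exactly with the
  simulated 3x mean and would halve the marker set by Poisson chance.

At the fixed validation seed the pipeline recovers exactly ten groups
(none mixing chromosomes), per-group |Kendall τ| ≥ 0.95 against the
true order, total length within 10% of truth, and an SDR overlapping
each selection locus; across ten random seeds those outcomes hold in
roughly eight of ten runs each, the residue being single split groups
or a missed terminal SDR.

**Known limitation — imputation accuracy.** Cells filled by the
pipeline are zero-depth cells, informed only by (uncertain) neighbours
~5 cM away; the chain-posterior accuracy ceiling at these conditions is
≈ 0.87–0.89, and even kNN applied to the *true* genotypes at this
density reaches only ≈ 0.89. Accuracies above 90% require roughly twice
the marker density — at which point adjacent markers become too close
for order recovery at τ ≥ 0.95 with 130 individuals. The dense-map
masked-recovery test (50 markers over 100 cM, clean genotypes, 10%
masked) does exceed 90%, matching the study's own ~1 cM marker spacing.

Smaller validation batteries: EM agrees with a grid-search likelihood
oracle to 1e−4 on 1000 random tables; annealing attains the
exhaustive-permutation SARF minimum on 50 random 8-marker groups; the
χ² test's type-I error is 0.05 ± 0.01 over 10,000 Mendelian markers;
SMOOTH correction strictly shrinks maps with 1% planted errors in
≥ 19/20 seeds; the Kosambi inverse round-trips to 1e−12.

## Numerical conventions

r is clamped to [1e−7, 0.5); Kosambi is evaluated at min(r, 0.49999).
Percentages and table averages round half-up at the printed precision
(1 decimal for distances and percentages, 2 for average adjacent
distances). Per-group average distance uses n − 1 intervals; overall
averages are unweighted means over groups. Summed map length uses
unrounded per-group values, so it can differ from a printed total by a
rounding residue. All randomized components take explicit seeds and are
bit-reproducible.
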