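# Methods

This note documents the models, conventions and design choices behind
`migrasv`: what each stage assumes, which knobs matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Coordinates and records

All intervals are held internally as 0-based half-open; VCF (1-based POS,
END) and GFF3 (1-based closed) are converted at the I/O boundary and
nowhere else. Insertions occupy a 1-bp breakpoint interval with the
inserted length carried separately, which keeps overlap queries
well-defined. Translocations store only the source interval (the partner
breakpoint is metadata), so every SV has exactly one locatable span.
Strand is ignored in all overlap computations.

## Consensus calling and cohort merging

Within an individual, calls from different callers are clustered
greedily in (start, end) order: a call joins the open cluster whose seed
has both breakpoints within `max_dist` (default 1000 bp) and which does
not yet contain a call from the same caller, preferring the nearest
breakpoints with ties broken by smaller seed start. Sorting before
clustering makes the result invariant to the order in which callers or
individuals are supplied. A cluster becomes a consensus call only when
at least two distinct callers agree on the (unphased) genotype; when
several genotypes each reach two supporters the best-supported one wins,
ties to the smaller dosage. Calls shorter than `min_size` (50 bp) are
dropped before clustering, and calls whose alternate sequence contains a
run of more than 10 Ns are removed (scaffolding-gap artifacts).

The cohort merge repeats the same clustering across individuals with the
additional requirement of matching SV type, keeps clusters supported by
at least `min_support_individuals` (default 4), and takes the member
with lower-median start as the representative locus. Individuals without
a call at a retained locus are coded as homozygous reference (dosage 0)
rather than missing — the only closure under which cohort minor-allele
frequencies and allele-frequency spectra are computable from merged
calls; its cost is that genuine missed calls deflate frequencies
slightly. The MAF filter keeps loci with MAF ≥ 0.05 (boundary kept).

## Population-genetic statistics

*Folded AFS.* Minor-allele copy counts per locus category, with
insertions and deletions pooled as INDEL because neither can be
polarized against the reference. Loci at exactly frequency ½ fall in the
top folded bin; monomorphic loci are excluded and counted.

*Tajima's D* uses the standard constants derived from the allele-copy
count n; loci with any missing genotype are dropped so n is uniform.
Under a neutral constant-size frequency spectrum (counts ∝ 1/i) the
expectation of π̂ equals θ_W per construction, so the statistic is
centered near zero — the property the acceptance checks exercise.

*Hudson FST* is computed per locus with the finite-sample correction and
combined genome-wide as a ratio of sums (Σnum/Σden). For PBS, per-locus
FST is clamped to [0, 1−1e−12] so the branch length T = −ln(1−FST) is
finite and non-negative; genome-wide estimates are never clamped. PBS is
per-locus (no windowing); loci with any undefined pairwise FST are
dropped and counted. Outliers are loci at or above the per-group
empirical 95th percentile (`numpy` quantile, method "higher", ties
included), matching the observation that each group gets its own cutoff.

*LD profiles.* r² is the squared Pearson correlation of dosages between
locus pairs, binned by distance (500-bp bins to 10 kb, last bin open).
Inversion strata use only the major- or minor-arrangement homozygotes;
strata with fewer than two individuals are omitted with a warning.
Control regions are size-matched, randomly placed, and rejected until
they overlap neither an inversion nor another control (at most 10,000
attempts per region, then an error); placement is driven by a
caller-supplied seed.

*PCA* standardizes loci to unit sample variance (not binomial p(1−p)
scaling), mean-imputes missing dosages, drops zero-variance loci, and
eigendecomposes the individuals × individuals covariance ZZᵀ/p; scores
are U√λ, consistent with the SVD of Z/√p.

## Migratory traits

Direction and distance come from the loxodrome between breeding and
wintering sites (Earth radius fixed at the mean 6371.0088 km for
determinism). Daily positions are projected onto the breeding–wintering
great circle with the cross-track/along-track construction; route
fractions are clamped to [0, 1] and made monotone with a cumulative
maximum, because position noise can make a bird appear to regress.
Timing is the first date at ≥ 50% of the route, duration the days
between the first dates at ≥ 30% and ≥ 70%, and speed the rhumb distance
divided by that duration (undefined for a same-day jump). A track that
never reaches 70% yields missing timing traits, flagged rather than
guessed. The fall/spring split point is the first date of closest
approach to the wintering site.

Orientation classes follow the wintering-longitude rules (5° E / 20° E
cutoffs north of 37.5° N; 0° E replaces 5° E further south, because
longer routes need less of a westerly component to reach the same
longitude), with boundary longitudes assigned to S. Those longitude
rules alone would label a UK-wintering bird SW, so an NW screen is
applied first: wintering latitude ≥ 45° N and rhumb bearing in
(270°, 360°]. The latitude threshold is configurable.

Direction enters the GWAS as plain degrees clockwise from north. All
generated bearings lie well inside (140°, 330°), so the 0° branch cut of
the circular scale is never crossed and circular regression is not
needed.

## The BSLMM

The model is

    y = 1μ + Xβ + u + ε,  u ~ N(0, σ_b²σ_e²K),  ε ~ N(0, σ_e²I),
    β_j = N(0, σ_a²σ_e²) with probability π, else 0,

with standardized genotype columns, K = WWᵀ/p from centered (mean-imputed)
dosages, and hyperpriors h ~ U(0,1), ρ ~ U(0,1), log π ~ U(log 1/p, 0).
(h, ρ, π) set the scales as σ_a² = hρ/((1−h)πp) and
σ_b² = h(1−ρ)/((1−h)κ) with κ = tr(K)/n, so h is the expected genetic
variance fraction and ρ its sparse share.

The sampler is a single-site spike-and-slab Gibbs sweep over loci
(inclusion odds from the marginal Bayes factor, then a draw from the
conditional slab), with the random effect updated componentwise in the
eigenbasis of K (where its prior is diagonal), a conjugate
inverse-gamma update for σ_e² (prior ∝ 1/σ_e²), random-walk Metropolis
moves on logit(h), logit(ρ) and log π (two proposals per sweep, step
0.5), and a conjugate intercept. PVE is recorded per thinned sample as
Var(Xβ+u)/(Var(Xβ+u)+σ_e²) using the sample variance across individuals
— this mixes faster than h itself and is the quantity reported. PIP is
the inclusion fraction across pooled post-burn-in samples and the
model-averaged effect is the posterior mean of β with zeros included.
Chains are bit-for-bit reproducible given (seed, config); zero-variance
loci are excluded from sampling and reported with PIP 0.

Fixing π = ρ = 1 reduces the sampler to Bayesian ridge regression and
π → 1/p with ρ = 0 to the pure LMM; both limits are exercised in tests
against closed forms. The config defaults (burn-in 10,000; 100,000
steps; thin 10; 4 chains) are a desk-scale analogue of the production
setting (4 chains, 5M burn-in, 20M steps); the pipeline and acceptance
checks use shorter, explicitly stated configurations chosen for their
problem sizes (e.g. burn 3,000 / 12,000 steps / 2 chains at
n ≈ 80–200, p ≈ 2,000–15,000), at which PVE and PIP summaries are stable
across seeds.

Polygenic scores: individuals are partitioned into 4 random folds
(~25% each); each fold's phenotypes are masked, the BSLMM is refit on
the rest, and the prediction for a masked bird is
μ̂ + xβ̄ + û, where û is the BLUP conditional mean of the random effect
given the training residuals and K at the posterior-mean variance
components. The random-effect term is included in the prediction.
Observed is regressed on predicted by OLS for the reported r and p.

Genetic correlations between traits are Pearson correlations of
model-averaged effects over the union of variants with PIP > 0.01 in
either trait; fewer than 3 such variants yields an undefined (NaN)
entry.

## The synthetic generator

The generator produces the study conditions, not arbitrary data:

* **Divergence.** Group allele frequencies follow the Balding–Nichols
  law around a shared ancestral frequency p ~ U(0.05, 0.95) with
  F = 0.02, which makes the expected pairwise Hudson FST equal F —
  matching the weak differentiation (~0.02–0.03) between migratory
  orientation groups. Selected loci are shifted toward fixation in their
  group by a stated amount, clamped to [0, 1].
* **Callers.** Three emulated callers see only the variants an
  individual carries; each call is independently dropped (20%), its
  breakpoints shifted by one shared rounded Normal(0, 150 bp) offset
  (so length stays noise-free and breakpoint clustering is isolated
  from size filtering), and its genotype flipped 1↔2 with probability
  0.02. Jitter is capped below 300 bp, well inside the 1-kb merge
  radius; truth loci are placed ≥ 2 kb apart so false merges are
  detectable.
* **Phenotypes.** Traits are built from genotypes with configured
  variance shares: a polygenic term (Normal effects on all standardized
  loci) scaled empirically to h², focal loci scaled to their shares,
  Gaussian noise filling the remainder; `baseline` may be a
  per-individual vector, which the study profile uses for per-group
  mean directions.
* **Tracks.** Constant-speed daily positions along the great circle with
  isotropic Gaussian position noise (default 50 km, geolocator-like),
  and a few stationary days at each end of a leg.

The **study-shaped profile** has 79 birds (19 NW / 28 SW / 12 SE / 20 S),
~15,000 SVs on a 28-chromosome karyotype-like layout (deletion-dominated
type mix, log-normal sizes with medians 250 bp for indels and 2.5 kb for
inversions), and a 710-bp focal deletion on the small chromosome 27.
The focal variant's frequency follows the direction cline — ancestral
0.30, shifted to ~0.95 in SE and ~0.10 in NW — so genotype at the
deletion tracks migratory direction across all birds, with SE migrants
near-fixed; its trait model gives the deletion 50% of the within-group
direction variance (polygenic 20%, noise 30%, within-group scale 8°) on
top of per-group mean bearings (NW 310°, SW 227°, SE 158° before the
focal shift, S 183°) chosen so that rhumb destinations from the Austrian
breeding area land in the correct classification regions. This cline
design is what makes the deletion the single strongest genetic driver of
direction, the condition under which a sparse GWAS should (and does)
rank it first; a variant differentiated in SE alone carries too little
marginal correlation (≈0.3) to beat the largest chance correlation among
15,000 loci at n = 79 (≈0.5).

What the generator does **not** emulate: reference-biased genotyping,
caller-specific error profiles or systematic breakpoint offsets,
linkage between SV loci outside the purpose-built LD cohort (loci are
independent given group frequencies), sequence content (no FASTA-level
simulation), geolocation shadowing/equinox artifacts, and
year-to-year route variation. Passing tests therefore demonstrate the
statistical machinery under the stated noise models, not robustness to
every artifact of real linked-read data.

## Validation conditions and problem sizes

The acceptance checks run at sizes chosen for a single CPU: consensus
recall on 5,000 truth loci × 6 individuals; FST recovery on
2 × 50 diploids × 5,000 loci; the PBS branch-shift check on 100
replicates of 2,000 loci with 400 diploids per group and a strictly
SE-only shift of 0.6 (NW and SW hold the ancestral frequency at that
locus — at realistic sample sizes the −ln(1−FST) transform amplifies
NW/SW frequency noise at a strongly shifted locus roughly three-fold,
so a shift drawn with drift in all groups cannot be a "clean" focal hit
in most replicates at any n); Tajima's D over 200 neutral replicates of
2,000 loci at n = 40 copies; the folded-AFS goodness of fit at 5,000
loci; BSLMM null and recovery at n = 200 with p = 1,000–2,000; PGS error
rates over 50 replicates at n = 200, p = 500; and the full end-to-end
profile at its default ~15,000 loci.

## Known limitations

* Cohort-level absence-as-reference is an assumption, not an
  observation; it biases AFS tails downward when dropout is high.
* The PBS scan is per-locus; no windowing or smoothing is provided.
* The BSLMM sampler updates one locus at a time; severe inter-locus
  correlation (dense LD) slows mixing, and PIP mass can split across
  near-duplicate loci.
* Direction is treated as a linear trait; analyses of cohorts spanning
  the 0° branch cut need a circular re-encoding first.
* The geodesy is spherical; ellipsoidal corrections (~0.3%) are ignored.
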