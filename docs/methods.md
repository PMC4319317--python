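# Methods

This note records the models, conventions, numerical choices and known
limitations behind `coraldelim`, in the order data flow through the
pipeline.

## Sequence distances

Cloned ITS sequences are compared site by site under **pairwise
deletion**: a column contributes to a pair only when both bases are
unambiguous A/C/G/T. Gaps and IUPAC ambiguity codes are excluded for
that pair alone, matching the convention of the classic distance
software for this marker. A pair with zero comparable sites raises an
error rather than returning a silent zero.

The **Kimura two-parameter** distance uses the transition proportion P
and transversion proportion Q over the compared sites:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and its gamma rate-heterogeneity form with shape *a*:

    d = a/2 [(1-2P-Q)^(-1/a) - 1] + a/4 [(1-2Q)^(-1/a) - 1].

The gamma form tends to the uncorrected one as a → ∞ (checked to 1e-4
at a = 10⁶ in the tests) and always inflates nonzero distances. The
default shape a = 0.2 is the value estimated for this marker by
maximum likelihood in the original study; it enters as configuration,
never re-estimated here. Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raises an
error carrying P and Q and naming the offending pair.

A **weighted difference count** (transitions × 2, transversions × 1,
single-gap sites × 1 by default) is available as the AMOVA distance; a
site gapped in both sequences is no difference at all. The AMOVA
default, however, is the K2P+gamma(0.2) distance: the model statement
governs the variance analysis, and the weighted count is kept as the
configurable alternative.

## Neighbor-Joining and bootstrap

NJ follows the Saitou–Nei agglomeration with the Studier–Keppler Q
criterion. Two behaviours are pinned for reproducibility rather than
left to chance:

* **ties** in the Q minimum go to the first (row, column) pair in scan
  order;
* a **negative branch length** is clamped to zero and its deficit moved
  to the sibling branch, preserving path lengths through the new node
  and keeping Newick output valid.

On an additive (tree-like) matrix this recovers the generating tree's
path lengths to 1e-9 (tested on random trees), and on noisy matrices
the topology matches scikit-bio's independent NJ implementation, which
serves as a cross-check oracle only. Bootstrap support resamples
alignment columns with replacement, rebuilds the tree per replicate,
and reports the percentage of replicates containing each original
bipartition; 1,000 replicates is the default.

## Distance-based AMOVA

The two-level partition uses squared inter-individual distances:

    SS_total  = (1/N) Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,   SS_among = SS_total − SS_within

with df = (G−1, N−G), σ²_b = SS_within/df_within, effective size
n′ = (N − Σn_g²/N)/(G−1), σ²_a = (SS_among/df_among − σ²_b)/n′, and
Φ_ST = σ²_a/(σ²_a+σ²_b). Negative variance components are reported raw
and used unclamped — the convention of the reference population-genetic
software — with a flag on the result. Significance permutes individual
sequences among groups (group sizes fixed) and applies the
(b+1)/(n+1) inclusion rule so p is never exactly zero; an optional mode
permutes whole colonies (all clones together), since the natural
exchangeable unit of a clone library is genuinely ambiguous. A
configuration where every sequence is its own group has no within-group
degrees of freedom and is rejected, not computed. An all-zero distance
matrix reports Φ_ST = 0 with a degenerate flag.

Robustness re-analyses mirror the study design: `one_per_individual`
runs one AMOVA per clone rank (colonies with fewer clones contribute
their last clone), and `drop_group:<region>` excludes one region; the
pipeline drops the region with the largest mean distance to all others.

## Landmark traits

Landmark semantics are fixed as: odd indices 1–23 are septum/calice-wall
junctions (outer ring), even indices 2–24 pali/septal tips (inner ring),
clockwise from the dorsal directive; 25:26 and 27:28 are the septum-width
pairs. A 29th point is accepted and stored but enters no trait, since no
trait definition references it. Calice area (CA) is the shoelace polygon
over the odd ring and fossa area (FA) over the even ring — the trait
definitions only say "polygons connecting the landmarks", so this
assignment is a package convention and the test fixtures are built to it.

Three further readings were genuinely open and are resolved as follows,
each switchable in configuration where an alternative is defensible:

* **X3** ("SW/(1:2:13:14)") is mean(SW1, SW2) / (d(1,2) + d(13,14)), the
  only dimensionally consistent parsing;
* **IRR** sums |SL_k − SL_{k+1}| circularly over the 12 septa (an
  all-pairs variant is available via `irr_mode="all_pairs"`);
* **TRI** is encoded ordered fused=0 < trident=1 < free=2 for the
  discriminant stage, ordered by increasing separation of the triplet.

All linear and area traits are invariant under rigid motion of the
landmark set (relative change ≤ 1e-9 under random rotations) and under
reciprocal rescaling of pixels and scale factor; a complete corallite
emits exactly 47 measured traits (42 linear + 2 areas + 3 discrete).
Missing points degrade per-trait (NaN + warning), never fail the whole
corallite.

## Discriminant analysis

Canonical factors are eigenvectors of W⁻¹B (within/between scatter),
solved as the symmetric generalized problem B v = λ W v and scaled to
unit pooled within-group variance; Wilks' Λ = Π 1/(1+λᵢ) with
Bartlett's χ² approximation for the overall test. Forward stepping uses
Rao's partial F with **F-to-enter 4.0 / F-to-remove 3.9**, the
documented defaults of the classic stepwise discriminant programs of
the era; both are configuration. Jackknifed classification refits the
model without each row and assigns it to the nearest group centroid in
canonical space with equal priors (a raw-space Mahalanobis rule would
be an alternative; the centroid rule matches how canonical plots are
read). Rows with missing selected variables are dropped with a logged
count — no imputation. Corallites are treated as independent rows, as
the classification-matrix row sums imply, which pseudo-replicates
colonies; region-level conclusions should lean on the specimen-level
summaries.

## Mantel concordance

The genetic region matrix holds mean between-region distances; the
morphological matrix for one trait holds |difference of region means|
(region mean = mean of specimen means), since traits are screened one at
a time; a multivariate Euclidean mode over standardized trait means
exists for synthesis plots. The Mantel statistic is the Pearson
correlation of the n(n−1)/2 off-diagonal pairs; the null distribution
jointly permutes rows and columns of one matrix. For n regions with
n! ≤ 50,000 every relabelling is enumerated exactly (p has resolution
1/n!); otherwise Monte Carlo with (b+1)/(n+1). The test is one-sided
positive by default because the scientific hypothesis is concordance;
two-sided is a flag. No multiple-testing correction is applied by
default — the screen reports per-variable significance — and a
Bonferroni/FDR switch is available. OLS regression of the same pairs is
descriptive only: matrix pairs violate independence, so inference
always comes from the permutation test.

## Synthetic data

The sequence generator draws an ancestral sequence at a given GC
content, then region consensus sequences (star topology by default, a
serial chain when genetic distance must approximate a line metric, as
in the coupled generator), then clones; substitution counts are
Poisson(rate × length), placed uniformly with transition probability
R/(R+1) for transition:transversion odds R (default 2). Defaults mirror
the study's sampling design: 6 regions × 4 colonies × 3 clones, ~700
columns, clone-level rate 0.006 subs/site. The between-region rate
default (0.0009 subs/site) was calibrated once, by simulation sweep, so
the realized among-region fraction of molecular variance averages ≈20%
over seeds — the regime the real data occupy — and then frozen. No
rate heterogeneity across sites by default (keeping K2P well-specified
for recovery tests) and no indels; a gap-injection mode exercises
pairwise deletion and gap weighting.

The landmark generator displaces a template corallite (regular 12-fold
rings, outer radius 0.5 mm, inner 0.25 mm — plausible *Porites* calice
dimensions, all in configuration) radially per region, adds isotropic
Gaussian noise per corallite (default 0.02 mm), applies a random rigid
motion drawn from a separate seed stream (so motions can be varied
without touching the noise), and converts to pixels at 0.01 mm/px.
Discrete characters are Poisson (NP, NR) and categorical (TRI) per
region. `simulate_joint` sets regional morphological effects
proportional to realized cumulative genetic divergence along the chain,
mixed with independent uniform noise by the `coupling` weight.

What the generator does **not** emulate — concerted evolution of the
ITS array, alignment ambiguity, indel-rich regions, within-colony
plasticity gradients, observer error in landmark placement, non-radial
shape change — bounds what passing tests show: they validate the
estimators and their calibration under a well-specified model, not
robustness to every pathology of real coral data.

## Problem sizes and tolerances

Desk-scale checks run the full pipeline at the default study design
(72–84 sequences, 240 corallites) and smaller; permutation counts in
tests are a few hundred with exact enumeration wherever feasible, while
the defaults (10,023 for AMOVA/Φ_ST, 9,999 for Mantel) match the
published analysis. Numerical assertions use 1e-9–1e-12 for algebraic
identities, binomial-error bands for Monte-Carlo against exact
enumeration, and generator ground truth (±5 percentage points on the
~20% among-region recovery over 50 seeds) for calibration. All
stochastic stages take explicit seeds; the pipeline derives per-stage
seeds by hashing the stage name with one master seed.
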