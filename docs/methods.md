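# Methods

This note records the models, conventions and numerical choices behind
otomorph, and what the synthetic-data tests do and do not establish.

## Outline model and study design (synthdata)

Synthetic saccular-otolith outlines follow an ellipse-plus-notch model:

    x(t) = s·cos(t)·m(t),  y(t) = s·h·sin(t)·m(t),
    m(t) = 1 − d·exp(−Δ(t, t0)² / (2w²)),

with Δ the wrapped angular difference.  The two free shape parameters map
one-to-one onto the two axes that dominate real saccular-otolith variation:
`h` is relative height (dorsoventral/anteroposterior ratio) and `d` the
depth of the anterior notch.  `d < 1` guarantees a simple closed curve; the
curve is counterclockwise by construction.  This is a deliberately minimal
model: it reproduces the height and notch axes and realistic within-fish
correlation, but not growth rings, crystalline (vateritic) aberrations,
digitization noise, or any other real-outline feature.  Recovery results on
synthetic data therefore validate the *machinery* (decomposition, reduction,
inference), not field-data effect sizes.

The study design crosses 4 species × 3 sites × 2 sexes with 25 fish per
cell by default and two otoliths per fish.  Shape effects act additively on
`h` and `d`:

* allometry: 0.010 per SD of fish size on `h` (0.005 on `d`), matching the
  scale of otolith-area slopes in paired-otolith mixed models;
* site effects on `h` (defaults 0, +0.04, +0.02 for Mutondwe, Kalambo,
  Katukula) and a site-specific female−male effect (+0.03 at Mutondwe only),
  so that exactly one kind of sex difference is planted;
* a fish-level random intercept (variance 4.227e-4) shared by both otoliths
  and an otolith-level residual (variance 8.038e-5).  These defaults put
  the within-fish correlation at the scale seen in paired saccular-otolith
  measurements; the same SDs are applied (independently) to `h` and `d`.

Fish size is lognormal (σ_log = 0.15) around a 900 µm base radius; the
recorded `area_um2` is the polygon area of the generated outline, so the
downstream standardized-area covariate is a measured, slightly noisy proxy
of the latent size that drives the planted allometry — as in real data.

Haplotypes come from a cluster–admixture model, not a coalescent: each
population owns a private cluster (an ancestral sequence with 8
population-specific substitutions); an individual draws from the shared
ancestral pool with probability `m` and from its private cluster otherwise,
then adds a Poisson(1.5) number of private mutations.  `m = 1` is panmixia
(Φ_ST ≈ 0); `m = 0` with mutation-free clusters gives Φ_ST = 1.  Only the
realized Φ_ST matters downstream, and `calibrate_divergence` bisects on `m`
(realized Φ_ST is monotone in 1 − m) to hit a target within ±0.05, averaged
over a stated number of seeds.  Default per-species admixture values (0.25,
0.5, 0.9, 0.35) span weak to strong differentiation, mirroring the spread
observed across rock-dwelling cichlid populations separated by habitat
barriers.

Seeding: one master seed; per-stage streams derive from
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with k = 0 (otolith
dataset), 1 (haplotypes), 2 (calibration), 3 (permutation seeds).  All
derived integer seeds are reduced below 2³¹.

## Elliptic Fourier descriptors (efd)

Coefficients are the exact Fourier integrals of the closed piecewise-linear
polygon (Kuhl–Giardina).  Two parametrizations are supported: `"chord"`
(parameter advances by segment length; the standard convention for digitized
outlines, and the default) and `"uniform"` (constant parameter increment per
sample, which reproduces the analytic coefficients of curves generated at
equally spaced parameter values — an axis-aligned ellipse gives a1 = A,
d1 = B exactly in the high-K limit).  After equal-arc-length resampling
(default 512 points) the two coincide, so the pipeline is insensitive to
the choice.  Inputs traversed clockwise are reversed with a logged warning;
right-side outlines must be mirrored (x negated about the centroid, order
reversed) before analysis and double-mirroring is rejected.

Normalization uses the first-harmonic ellipse: phase-shift the series start
to an end of the semi-major axis, rotate that axis onto +x, divide by the
semi-major length.  The semi-major phase has two solutions π apart whose
coefficient sets differ only in the sign of the even harmonics.  The tie is
broken by a shape-intrinsic anchor: keep the candidate with positive
dorsoventral asymmetry, measured as the third moment of y over the
normalized curve (a smooth statistic that flips sign exactly between the
candidates).  Outlines symmetric about the major axis have no geometric
distinction between the candidates; there a lexicographic comparison of the
rounded coefficient vectors decides.  An earlier purely lexicographic rule
was rejected because it can flip between visually indistinguishable shapes
(it effectively reads the sign of a2, which may pass through zero within a
sample), contaminating downstream PCA with an artificial bimodal axis.
Shapes whose asymmetry statistic sits near zero while their candidates
differ remain a documented edge: the convention is deterministic but may
split such a sample across conventions.  Reflections are deliberately not
normalized away, because otolith chirality is handled by the explicit
mirroring step.

Harmonic count: smallest N with cumulative power ≥ 99.999% of the species
mean shape (the average of the per-specimen normalized coefficient
vectors).  Since the truncated spectrum always sums to 1, reaching the
threshold only at the last computed harmonic is reported as an error asking
for a higher maximum (the default maximum is 25).  On the synthetic
outlines 6–8 harmonics suffice; real otoliths, with sharper features, need
more.

## Shape PCA (shapepca)

PCA eigendecomposes the sample covariance of the normalized coefficients
with the normalization-fixed entries (a1, b1, c1) excluded — they carry
zero variance and only degrade conditioning — while d1 is kept because it
carries the height signal.  Scores are centered projections; trace
conservation and score orthogonality are asserted in tests.  Eigenvector
signs are fixed by reconstruction: +PC1 increases the height-to-width ratio
of the reconstructed outline and +PC2 deepens the notch (maximum radial
deficit against the first-harmonic ellipse); later components take the
largest-|loading|-positive convention.  Retention uses the broken-stick
first-crossover rule: keep the leading components whose variance proportions
strictly exceed b_k, stopping at the first failure.  Under the default
generator the height axis dominates (PC1 ≈ 96%), so broken stick often
retains one PC; the downstream battery nevertheless analyzes PC1 and PC2,
holding the analysis surface fixed across species.  PCA is per species; a
pooled fit is possible by concatenating coefficient tables but cross-species
score comparisons are deliberately avoided.

## Φ_ST (popgen)

Distances are raw counts of differing sites with pairwise deletion of gaps
and ambiguous bases (complete deletion is not offered; pairwise deletion is
the convention for uncorrected distances).  Two-level AMOVA on squared
distances: SSD(total) = Σi<j d²ij / N, SSD(within) the same per population,
mean squares with the unequal-sample-size coefficient
n' = (N − Σ n_p²/N)/(P − 1), σ²_b = MS_within,
σ²_a = (MS_among − MS_within)/n', Φ_ST = σ²_a/(σ²_a + σ²_b).  Computations
run on individual sequences rather than collapsed haplotype frequencies
(equivalent for AMOVA, simpler to verify).  σ²_a may be slightly negative
near panmixia and is reported as computed — no truncation — so the
divergence regression sees the estimator's true sampling behavior.  The
permutation test shuffles individuals among populations with sizes
preserved and uses the add-one rule p = (#{Φ* ≥ Φ} + 1)/(n_perm + 1),
deterministic given its seed; the default is 1,023 permutations.

Divergent-haplotype exclusion flags sequences whose minimum distance to any
other exceeds a threshold (default 5× the median nonzero pairwise
distance) — a minority-outlier rule for putative introgressants.  Balanced
divergent clusters are not excluded (neither is a minority) but are
reported via a warning based on whether the nearest-neighbor graph splits;
the nearest-neighbor scale is used there because cluster structure inflates
the median pairwise distance itself.  All exclusions are logged.  The
threshold is a stated default, not an attempt to reproduce any particular
visual curation of haplotype networks.

## Mixed models (lmm, shapestats)

All models are variance-components LMMs fit by REML on dense matrices,
y = Xβ + Σk Zk uk + ε.  With no penalty the residual scale is profiled out
and the optimizer (Nelder–Mead on log variance ratios, bounded) works in m
dimensions for m random terms; fixed effects and SEs follow by GLS at the
REML variances.  Degrees of freedom for each contrast c use the
Satterthwaite construction: ν = 2(c'Ĉc)²/Var(c'C(θ)c), with the variance
from the inverse expected REML information of the variance parameters.
The engine is cross-checked in tests against statsmodels MixedLM (fixed
effects, SEs, variance components) and against R's lmerTest (Satterthwaite
df within 2%), but neither library stands in for it: statsmodels provides
no Satterthwaite df or covariance priors, which the analysis needs.

Sex tests fit PC ~ scaled area × sex per (species, site, PC), drop the
interaction when its Wald p ≥ 0.05 (logged), and report the female−male
marginal difference at standardized area 0 — stated explicitly to avoid
contrast-coding ambiguity.  The per-test α is 0.05 divided by the planned
grid size (24 ⇒ α = 0.002); cells missing a sex are marked untestable
without shrinking the family.  Site contrasts fit PC ~ scaled area +
species × site per sex, evaluate marginal means at area 0, and adjust the
three within-species pairs with the studentized-range (Tukey) distribution
at the contrast's Satterthwaite df.  Otolith area is z-scored within
species before any model, making all t statistics invariant to area units.

## Divergence model (divergence)

Stage one: per sex × species × PC (16 combinations), the PC is z-scored
within that subset and two models are fit — without the area × site
interaction (intercept differences: pairwise marginal-mean differences at
area 0) and with it (slope differences: pairwise differences of the
per-site allometric slopes).  Eight measures × 4 species × 3 site pairs
give 96 rows.

Stage two stacks the measures into one regression: measure-specific
intercepts and measure-specific Φ_ST slopes (the per-measure-CI display
implies per-measure slopes), responses z-scored within measure, Φ_ST on
its natural 0–1 scale.  Random intercepts: species, measure-within-species,
population pair, and measure-within-pair.  "Population pair" means the
site-pair label (3 levels, crossed with species); nesting pairs within
species would leave measure-within-pair with one level per observation,
confounded with the residual.  A genuinely multivariate residual covariance
is not modelled — the stacked form expresses exactly the stated
random-effects structure.  Variance components are regularized by an
improper Gamma(2.5, 0) prior on each random-effect SD (adding
1.5·log σk to the REML log-likelihood), the maximum-a-posteriori analogue
of weakly-informative covariance priors; with 12 observations per measure
this keeps components off the boundary without forcing them away from
small values.  Each measure's 95% CI is Wald with a Satterthwaite-t
quantile; a null simulation (100 studies, zero slope) puts the coverage of
these CIs at ~96%.  Stage-one SEs are not propagated (two-stage
convention); `weights="ivw"` provides an inverse-variance sensitivity mode.
If all Φ_ST values coincide the slopes are inestimable and the fit raises
rather than returning silent zeros.

## Pipeline and I/O

Every stage materializes its outputs (contour CSV, coefficient and spectrum
tables, score and reconstruction CSVs, per-population FASTA, Φ_ST tables,
test and contrast tables, a JSON run report with counts and seeds); floats
are written with 17 significant digits so write-then-read round-trips
exactly.  Stage dependencies are checked by file presence with explicit
errors; a stage failure aborts downstream stages but preserves completed
outputs and still writes the report.  Reruns with identical config and seed
are bit-identical (asserted in tests).  TPS outline files (POINTS/ID
records) are read and written alongside the CSV dialect; pooled FASTA input
takes a two-column population map.

## Problem sizes in tests

The test suite scales simulations to keep the default run fast while
preserving each property's meaning: oracle and invariance checks run at
full precision; Monte-Carlo calibrations use 40–500 replicates depending on
the cost per replicate (500 panmictic datasets with 199 permutations for
the type-I error band; 100 null studies for CI coverage; 50 seeds for
planted-effect recovery, with the site-ordering check run through the full
contour → EFD → PCA → contrast chain on one species at 10 fish per cell).
The acceptance script runs the complete default design (1,200 otoliths, 12
population samples, 1,023 permutations) in well under a minute.

## Known limitations

* The outline model spans exactly two shape axes; analyses of real otoliths
  will meet higher-dimensional shape spaces where broken-stick retention
  and the PC sign conventions matter more.
* The normalization tie-break, while deterministic, has a documented edge
  for outlines that are nearly 180°-rotation-symmetric yet not exactly
  symmetric about the major axis.
* The haplotype simulator makes no attempt at realistic coalescent
  genealogies, recombination-free linkage, or substitution-model detail;
  it exists to set realized Φ_ST.
* Satterthwaite df and the studentized-range adjustment are approximations;
  exact small-sample agreement with any particular mixed-model tool is not
  a goal, and tests assert tolerance bands rather than bit equality.
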