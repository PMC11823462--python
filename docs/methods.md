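# Methods

This package re-implements, as a tested pipeline over synthetic campaigns,
a nontarget high-resolution mass-spectrometry (HRMS) workflow for
water-soluble organics in PM2.5: feature-table quality control, molecular
formula assignment by dual-ranker consensus, PFAS discovery by diagnostic
fragment series, retention-index-filtered spectral annotation, air-mass
source attribution, and supervised multivariate contrasts. Everything
operates on aligned feature tables — peak picking, deconvolution and
alignment are upstream of this artifact.

## Feature quality control

**Blank rule.** A feature is kept iff its maximal area over real samples
strictly exceeds `blank_factor` (default 5) times the arithmetic mean of
its areas over field blanks. The sample side uses the maximum, not the
mean, so a compound genuinely present in only part of the campaign
survives; this choice is logged and switchable.

**Internal-standard normalization.** The samples x standards matrix of
the eight spiked internal standards is scaled column-wise to unit
variance *without centering* (UVN), and each sample's areas are divided
by its score on the first principal component of that matrix (the t1
score, sign-fixed to a positive mean). A single multiplicative
instrument/batch factor is exactly removed by this construction;
standards with zero variance are passed through unscaled with a warning.
Normalization is fit per ionization mode.

**Cross-mode deduplication.** Neutral masses are derived assuming
[M+H]+ / [M-H]- only (proton 1.007276466 Da; all masses monoisotopic,
from the constants table in `aeronts.constants`). Ions agreeing within
0.001 Da neutral mass and 0.15 min retention time are one compound;
ambiguous multi-matches resolve greedily by smallest mass difference,
and the member from the mode with the larger median area is retained.
Tolerances are inclusive, with a 1e-12 Da/min epsilon so printed boundary
cases are stable against float round-off.

**Scaling.** Areas are scaled per feature to [0, 1] by the feature's
campaign-wide maximum. This makes the source-contribution formula
scale-free across features; all-zero features stay zero.

## Formula assignment

Candidates are every elemental composition over {C,H,N,O,P,S,F,Cl,Br,I}
within `formula_tol_ppm` (default 3 ppm) of the neutral mass, subject to
C >= 1, DBE >= 0 with DBE = C + 1 - H/2 - X/2 + N/2 (X = halogens), the
SENIOR feasibility rule (valence sum even and >= 2*(atoms-1), with
valences C4 H1 N3 O2 P3 S2 X1), and element-ratio caps (H/C <= 4;
heteroatom/C caps configurable, defaults in `aeronts.config`).
Enumeration iterates carbon count over a sorted heteroatom-mass grid, so
it is exact — tests verify set identity against an exhaustive brute-force
generator.

Two independent scorers rank the candidates:

* **Isotope-pattern fit (scorer A)** — negative squared deviation between
  the observed M+1/M+2 abundances and the candidate's first-order
  theoretical pattern (per-atom isotopologue ratios plus the two-13C
  term).
* **Fragment explanation (scorer B)** — the fraction of MS2 intensity
  explainable as subformula ions of the candidate (protonated/
  deprotonated or radical ions, 3 ppm), each peak weighted by
  exp(-(err/sigma)^2/2) with sigma = half the tolerance, so exact
  subformula matches dominate near-coincidences. Without this weighting
  heteroatom-rich decoys saturate the score.

Ties break by smaller |precursor mass error| then Hill string. A formula
is **assigned** only when it appears in both scorers' top two candidates
(best summed rank wins if two formulas qualify); an assigned
Cl-containing formula is retained only when the observed M+2 fraction
reaches half the theoretical 37Cl contribution. No consensus means no
assignment — the feature keeps only its annotation level.

The validation harness (`validate_rankers`) runs the full machinery over
reference standards of known composition and reports the fraction
top-ranked by both scorers (overall and in the fluorine-free subset) and
the fraction with the truth in at least one top-2 list. Element bounds
for this harness derive from each standard's known composition plus a
three-carbon slack, which admits the classic S+4H <-> C3 near-isobar
(3.4 mDa) for heavy standards — validation legitimately knows the truth.

## PFAS screen

The diagnostic series is [CxF2x+1]-, x = 2..14 (13 fragments, constant
CF2 spacing 49.996806 Da; anion masses include the electron). Fragments
are searched in negative-mode MS2 spectra at 0.01 Da with a strict >10%
base-peak intensity threshold; one peak can satisfy only one series
entry (nearest mass wins, ties to lower x). A feature is
`confirmed_pfas` iff >= 2 series fragments match **and** its top-ranked
formula by the fragment scorer carries >= 2 fluorines (a -CF2- moiety);
one criterion alone yields `fragment_only` / `formula_only`.

## Spectral annotation

Library matching restricts candidates to same-mode entries within
0.01 Da precursor tolerance and scores them with a greedy cosine over
sqrt-weighted intensities (pairing tolerance 0.015 Da); matches below
0.70 are discarded. Retention indices come from a least-squares linear
calibration RTI = a*RT + b over the calibrant ladder (strictly
increasing RTIs required). Records with |observed - predicted| RTI above
30 (inclusive boundary, 1e-9 epsilon) are demoted; candidates without a
predicted RTI are flagged `rti_unavailable`, never silently dropped.
Confidence levels: 1 = all gates pass and an in-house standard confirms;
2 = gates pass; 4 = consensus formula only; else unknown.

## Source attribution

Each hourly 48 h back-trajectory is featurized as its concatenated
(lat, lon) endpoints, standardized per coordinate, and clustered with
fuzzy c-means (c = 6, fuzzifier m = 2, four seeded restarts keeping the
lowest objective; zero distances give full membership to the coincident
centroid). A trajectory is *clustered* when its maximal membership
reaches `assignment_threshold` (default 0.6); a sample's cluster weight
for region r is the fraction of its trajectories clustered to r, and the
unclustered fraction is reported separately. Cluster indices are mapped
to named regions by Hungarian matching of membership-weighted mean
origin endpoints to the six regional reference centroids.

The contribution of region r to a feature is

    contribution(r) = sum_s a_s w_r(s) / sum_s sum_r' a_s w_r'(s) x 100,

with a_s the scaled area — the area-weighted share of cluster weights
over the campaign. Group profiles use summed scaled areas. The baseline
is the renormalized mean cluster weight (the relative frequency of
air-mass origin); enrichment = contribution - baseline sums to zero.
This estimator shrinks toward the baseline in proportion to origin
mixing, so exact parameter recovery is asserted only on the balanced
validation layout (below).

## Multivariate contrasts

PCA uses NIPALS on the centered (optionally UV/Pareto-scaled) matrix.
OPLS-DA fits one predictive component plus `n_ortho` (default 1)
orthogonal components; orthogonal scores have exactly zero class
covariance by construction. R2 is the explained class variance; Q2 its
7-fold cross-validated counterpart (folds seeded; scaling refit per
training split). VIP over the single predictive component is
sqrt(p)*|w_j|, whose squares average to one identically; pCorr is the
Pearson correlation of each scaled variable with the predictive score
vector. Markers require VIP strictly above 1.5 and |pCorr| strictly
above 0.5, split by pCorr sign. Default variable scaling is Pareto
(standard for MS areas); UV and none are configurable. Sample classes:
temperature (high iff mean > 15 degC; an exact tie goes low with a
warning) or maritime (regions 1-2 outweigh regions 3-6). DBE contrasts
between marker classes use Welch's t-test.

## Synthetic campaign generator

The generator emulates a 16-month coastal campaign (default 85 samples,
30 field blanks): sinusoidal seasonal temperature (12 +- 11 degC, sd
1.5); air-mass origins drawn per sample from a Dirichlet over six
regions whose concentration shifts with season (maritime regions 1-2
favored in warm months, continental 3-6 in cold); hourly back-
trajectories as jittered tracks from the receptor toward regional
centroids, with a 45% diffuse (unclusterable) fraction, so roughly 55%
of trajectories are clustered at the default threshold. Endpoints are
emitted from -48 h to -6 h: the hour-0 endpoint is the receptor itself,
common to every trajectory and pure noise after standardization.

Compounds carry a formula (CHNOS + occasional Cl), retention time,
Dirichlet(0.4) per-region emission weights, a temperature coefficient
(log-area slope, sd 0.04 /degC), and a lognormal base intensity. Areas
follow

    area = base x sum_r emission_r x weight_r(sample)
           x exp(temp_coeff x (T - Tbar)) x LogNormal(0, sigma) x drift,

with multiplicative lognormal noise (sigma default 0.3 — peak areas are
strictly positive and right-skewed), per-batch drift factors (5 batches,
lognormal sd 0.25) applied to features and internal standards alike, and
a detection floor below which areas read 0 (how aligned tables behave).
5% of compounds are blank contaminants whose sample areas sit below 5x
their blank mean; 2% ionize in both modes (the planted dedup pairs).
Isotope fractions are theoretical with 5% relative noise; MS2 spectra
(70% of compounds) are true subformula fragment ions; measured m/z
carries 0.3 ppm jitter. Planted PFAS are perfluorocarboxylates
CnHF(2n-1)O2 with >= 2 series fragments above 10% intensity and >= 60%
emission on a chosen region.

A `balanced` schedule mode is the designed validation layout: the six
regions cycle deterministically with 99%-pure origins, no diffuse
trajectories, and largest-remainder (noise-free) trajectory
apportionment. Per-region emission recovery is identifiable only under
such a layout — under the seasonal schedule, unequal origin frequencies
and origin mixing shrink contributions toward the baseline, which is the
estimator's documented behavior, not a defect.

What the generator does **not** emulate: chromatographic peak shapes,
raw spectra, adducts beyond protonation, in-source fragmentation,
retention-time drift, correlated noise between co-eluting features, and
real MS2 impurity peaks. Passing tests therefore demonstrate the
correctness and internal consistency of the computations, not
instrument-level robustness.

The ranker-validation fixture encodes a known outcome pattern: 38
standards carry clean truth-derived evidence, 12 (including all 7
fluorinated ones) carry evidence generated from an S+4H <-> C3
near-isobaric decoy (truth masses > 600 Da so both compositions fall
inside the 3 ppm window; isotope evidence interpolated 60/40 toward the
decoy), reproducing tools that fail on fluorinated chemistry while the
truth always stays within one scorer's top two.

## Problem sizes and numerics

The end-to-end demonstration campaign runs 85 samples x 1,200 features
(formula assignment dominates, ~0.1 s/feature); tests use campaigns of
120-300 features. Fuzzy c-means: tolerance 1e-6, <= 300 iterations, 4
restarts. NIPALS: 1e-10 convergence. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; identical seeds give
byte-identical written campaigns.

## Known limitations

* Only [M+H]+/[M-H]- ionization; no adduct or multimer annotation.
* First-order isotope model (no fine structure); adequate at the M+1/M+2
  abundance precision simulated here.
* The fragment scorer checks subformula existence, not bond chemistry, so
  it is more permissive than a fragmentation-tree method; the consensus
  rule and the mass-error weighting carry the specificity.
* Fuzzy c-means operates in standardized coordinate space, not great-
  circle distance; adequate at the regional scale generated here.
* The OPLS-DA Q2 uses simple k-fold CV; no permutation-test suite for R2/Q2
  significance is included.
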