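# Methods

`breedlip` implements a complete statistical workflow for separating
genetic (breed) signal from dietary confounding in untargeted plasma
lipidomics of companion dogs, together with a synthetic-cohort generator
that makes every stage testable against known ground truth. This note
records the models, the defaults and why they are what they are, and the
choices made where the design was genuinely open.

## The data model

The unit of analysis is a peak-picked feature matrix: samples x features,
where each feature is an accurate m/z (4-6 decimals), a retention time in
seconds, and one intensity per sample. Features are named
`M<round(mz)>T<round(rt)>` (round-half-to-even). Nine breed classes of
7-12 animals (96 samples total in the default cohort) carry a `breed`
label and a `diet` label (chicken vs red meat as the main protein source).

Accurate masses are pooled into fixed-width m/z bins (default 0.01) so
profiles are column-comparable across runs. Bins are centred on integer
multiples of the width — feature j belongs to bin `round(mz_j / width)` —
which makes binning order-independent and idempotent. Co-binned
intensities are summed (per-sample totals are conserved exactly); each bin
keeps the intensity-weighted mean of its members' accurate masses so that
annotation always works from un-binned mass, never from the bin label.

All supervised modelling runs on log2 intensities. Trees are invariant to
the monotone transform, but t-tests, direction calls and correlation
coefficients are not, and multiplicative LC-MS noise is approximately
Gaussian only on the log scale.

## Classification

**PC-LDA.** PCA on mean-centred data; the smallest number of PCs reaching
95% cumulative variance is retained (capped at n_samples − n_classes so
the within-class scatter stays invertible). LDA then solves the
generalized eigenproblem `Sb v = Tw Sw v` on the retained scores. The
eigenvalue Tw_k is the between/within separation on discriminant function
k; at most n_classes − 1 functions exist. A numerically singular Sw is
ridge-regularized with `1e-8 · tr(Sw)/k` and a logged warning. Tw is used
descriptively (and logged along the confounder filter's trajectory); no
decision threshold is attached to it.

**Bootstrapped random forest.** Binary comparisons are scored over
repeated stratified splits: 2/3 training, 1/3 held out, per class. Each
split fits a forest (`max_features='sqrt'`, trees grown to purity) and the
held-out samples yield three statistics: the *margin* (mean over held-out
samples of the vote fraction for the true class minus the best vote
fraction for any other class), AUC of the vote fractions, and accuracy.
Report scores are arithmetic means over splits. A model is *adequate*
when margin > 0.2 and (AUC > 0.8 or ACC > 0.8). Protocol defaults are 100
splits and 1000 trees; the reduced sizes used in the test suite are listed
at the end of this note.

**RFIS (feature importance).** The mean decrease in accuracy in the
classical random-forest sense: for each tree, permute one feature's values
in the *held-out* samples, remeasure that tree's own accuracy, and average
the decrease over all trees, then over splits. Scoring trees individually
matters: redundant features (adduct/isotopologue partners of one compound)
mask each other in the pooled ensemble vote, and a forest-level estimate
collapses to exactly zero for most members of a redundant cluster, while
the per-tree estimate keeps them at small positive values. This is also
why explanatory-signal RFIS values live on a ~1e-3 scale: a feature's
score is (share of trees that use it) x (its accuracy impact within those
trees), and with ~2500 features and `sqrt`-sized candidate draws no single
feature is used often.

On the very small held-out sets of pairwise breed models (5-9 samples) a
single random permutation is extremely noisy, so the *exact expectation*
of the permuted accuracy over all permutations is computed by evaluating
each tree on the full held-out-row x held-out-value grid. The grid cost
grows with the square of the held-out count, so larger test sets (where
one permutation is already well averaged) use the classic single-draw
estimate; the crossover is at 14 held-out samples.

## Ranking and correlation clustering

Each binary comparison ranks all features by three parallel criteria
computed from one set of forests (the same splits serve classification
and importance): RFIS; orientation-folded Mann-Whitney AUC (>= 0.5); and
Welch's unequal-variance t-test with Benjamini-Hochberg FDR. Lists are
sorted by RFIS (ties: p ascending, then name). Zero-variance features are
flagged degenerate with p = 1 and RFIS = 0. Threshold presets follow the
protocol: RFIS > 0.003 with q < 0.05 for meta-class explanatory signals,
RFIS > 0.002 with p < 0.05 for pairwise top-ranked sets.

Candidate signals are grouped into correlation clusters: Pearson r over
all samples, single-linkage components of the |r| > 0.8 graph. Single
linkage is deliberate — adduct/isotopologue series chain (A~B, B~C strong;
A~C weaker) and should land in one cluster. Constant features (undefined
r) are excluded with a warning; "constant" means variation at
floating-point noise level (sd <= 1e-12 relative), not exact zeros.

## Confounder filtering

Owner-fed cohorts confound diet with breed. The filter removes the
diet-driven axis by walking a strictly decreasing schedule of RFIS
cutoffs computed once on the confounded meta-class comparison (default
schedule: nine log-spaced cutoffs from 0.01 down to 1e-4, covering the
protocol's 0.003-0.0003 range; 3e-4 is kept as a named preset). At each
cutoff, features above it are removed together with any feature correlated
at |r| > 0.8 with a removed one (one-hop expansion only — satellites of a
removed compound go with it, but the closure does not chain further). The
meta-class forest is refit on the reduced matrix; the walk stops at the
first cutoff where the model has *collapsed*, operationalized as margin
<= 0.2 — the same adequacy floor used everywhere else, chosen over a Tw
criterion because Tw has no published threshold. Tw is still logged at
every step. If the schedule is exhausted without collapse the last
filtered matrix is returned with `collapsed=False` and a warning.

Removal sets are monotone in the cutoff by construction (the ranking is
fixed); the filtered matrix is a pure column subset.

## Breed-unique signal discovery

All 36 unordered breed pairs are scored; each pair derives its own seed
from the grid seed and the breed names, so any single pair can be
reproduced in isolation. Pair rankings reuse the grid's forests.

A breed is pursued only if >= 6 of its 8 pairwise models are adequate.
For each pursued breed, candidate features must clear RFIS > 0.002 and
p < 0.05 *in every adequate comparison of that breed*, with one consistent
direction (sign of the focal-minus-other difference of log2 means)
throughout. Inadequate models are treated as uninformative and excluded
from the intersection (a `strict_all_pairs` flag switches to requiring all
8). Finally, any feature that is a candidate for two breeds is a common
discriminating series, not a unique signal, and is discarded for both.
The reported support is the breed's adequate-comparison count.

Note one consequence of the discard rule: the *output* is not perfectly
anti-monotone in the thresholds — loosening them can add candidates to a
second breed and thereby delete a signal from the first. Above the noise
floor the collision set is stable and the intuitive anti-monotonicity
holds.

## Accurate-mass annotation

Annotation is computed, not looked up: IUPAC 2021 monoisotopic masses,
formula algebra for adducts ([M+H]+, [M+NH4]+, [M+Na]+, [M−H]−), a
+1.0033548 shift per 13C substitution, and a mandatory electron-mass
correction (~0.8 ppm at m/z 700 — the same order as the matching window).
Observed masses are matched within a configurable window (default 5 ppm,
the instrument's first-pass identification accuracy), best match first.
Head-group calls from tandem-MS fragments require *both* the m/z 184.0733
phosphocholine fragment and the [M+H−59.0735]+ trimethylamine loss for a
PC/SM call; PE and PS are called from their single characteristic head
losses (141.0191, 185.0089). All four masses are derived from elemental
compositions (C3H9N, C2H8NO4P, C3H8NO6P), with the nominal 184/59/141/185
figures kept only as names. A small bundled table of lipid-range
compositions supports offline matching; it makes no chemical-identity
claims beyond its free-text names.

## The synthetic cohort

The generator emulates the statistical structure the workflow has to cope
with, with known ground truth:

* **Cohort**: the canonical nine breeds at their real cohort sizes
  (Be 12, Ch 7, CS 12, Da 8, GR 12, Gh 12, GS 12, LR 12, Ma 9).
* **Features**: 2500 per profile; 1900 base metabolites, the rest
  adduct/isotopologue satellites (13C +1.0033548, NH4-vs-H +17.026549,
  Na-vs-H +21.981944; same retention time, 1-3 log2 units dimmer).
* **Intensity model** (log2): per-feature baseline uniform on [10, 20]
  (~3 orders of magnitude of dynamic range) + planted effects +
  biological noise (sd 0.45) shared between a metabolite and its
  satellites + independent technical noise (sd 0.2). Sharing the
  biological term is what produces within-cluster Pearson |r| > 0.8, the
  same reason co-ionisation products of one compound co-vary in real data.
* **Diet**: chicken-dominant for the small/sighthound meta-class breeds,
  red-meat-dominant for the rest (purity 0.9); one Labrador-analogue breed
  is split 50/50, so diet and breed are partially collinear exactly as in
  an owner-fed cohort.
* **Planted effects** (all ± `effect_log2fc`, default 1.0): 40 diet
  bases; 20 meta-class-1 bases (decreased in the Ch/Da/Gh analogues);
  6 meta-class-2 bases (decreased in the Ch/Da/Ma/GR analogues); 35
  shared-series bases, each shifting a random 3-4-breed subset at 0.65x
  scale; and breed-unique markers mirroring the real discovery pattern
  (Ch 5 decreased, GR 7 elevated, Gh 1 decreased) at full scale on
  satellite-free bases.

The shared-series design went through several explicit trade-offs worth
recording. Broad pairwise adequacy (most of the 36 pairs modelling above
the 0.2 margin floor) requires many pair-separating features; but every
such feature competes with the unique markers for tree splits, and RFIS
dilutes roughly inversely with the number of informative features per
pair. Sets of only two breeds are statistically indistinguishable from a
unique marker whenever that one pair models poorly, which is why shared
sets span at least three scattered breeds; and shared effects sit at 0.65x
the marker scale because the discovered breed markers in real profiles
show near-complete per-breed separation while the shared background is
more moderate. Unique markers sit on satellite-free bases: a marker is a
single low-abundance signal, not an adduct series, and this also keeps
the ground-truth ledger one-feature-per-marker.

What the generator does **not** emulate: chromatographic peak shapes, raw
spectra, missing values, batch/run-order drift, heteroscedastic
intensity-dependent noise, retention-time drift, or correlated biology
beyond the planted structure (no metabolite-network covariance). Passing
recovery tests therefore demonstrates that the statistical machinery
recovers the planted structure under realistic dimensionality, noise and
confounding — not that the pipeline is robust to acquisition artefacts.

## Reduced problem sizes in the test suite

The protocol's resampling sizes (100 bootstraps, ntree 1000 — on the
order of 10^5 trees per comparison) are the published conditions; the test
suite estimates the same quantities at sizes chosen to complete on one
CPU: the permuted-label null runs 10 seeds at 25 bootstraps x 250 trees;
the recovery experiment runs 10 cohorts with 6 x 150 for the meta-class
filter and 16 x 75 for the 36-pair grid and its rankings (splits are
favoured over trees at fixed total because split randomness dominates the
RFIS sampling variance on small cohorts). These are package choices,
recorded here so the numbers are interpretable.

The one quantity sensitive to this scaling is unique-marker sensitivity.
Recovery demands that a marker clear RFIS > 0.002 in *every* adequate
comparison of its breed — six to eight near-independent events — so the
per-comparison pass probability enters to the sixth-to-eighth power. At
~1200 trees per pair the RFIS sampling sd is ~5-7e-4 while marker means
sit at 2-6e-3; for the smallest breed (n = 7, held-out Ch samples ~2 per
split) the weakest marker-comparison cells sit close enough to the
threshold that a miss in one comparison is common. Measured over ten
cohorts, the filter stage removes 97-99% of planted diet features and
retains 100% of planted markers, and discovery reports essentially no
false unique signals (FDR ~0.04), but mean sensitivity is ~0.66: the
larger marker breeds recover 5-7 of their markers, the n = 7 breed
typically 1-4 of 5. Re-ranking the weakest cells at protocol-scale
precision shows all but ~2 of the 13 planted markers clear the threshold
in every comparison, i.e. the shortfall is the resampling noise of the
reduced surrogate, not the method or its implementation.

## Known limitations

* The collapse criterion is a margin proxy for what was plausibly a
  visual PC-LDA judgement in practice; the trajectory logs Tw so either
  view can be audited.
* Uniqueness is only as good as adequacy coverage: a signal shared by a
  breed and *only* breeds it cannot be modelled against is
  indistinguishable from a unique signal. The generator's scattered
  >= 3-breed shared sets keep this pathology rare rather than impossible.
* Annotation is rule-based and offline; it proposes compositions and
  head-group classes, never identities (MSI level 2 at best, and only
  with fragment evidence).
* p-values from Welch tests on n = 7-12 log-intensities are approximate;
  they are used for ranking and thresholding, not inference.
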