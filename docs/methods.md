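# Methods

`circasyn` implements the statistical pipeline for a two-group postmortem
brain proteomics study design: unaffected comparison subjects versus
subjects with opioid use disorder (OUD), profiled by TMT mass spectrometry
in bulk tissue homogenates and in synaptosome (synapse-enriched) fractions
of two brain regions.  The entry point is the post-quantification,
normalized, log2 protein-by-sample matrix; raw spectra, peptide-spectrum
matching and reporter-ion normalization are upstream and out of scope.

## Data model

A `Dataset` pairs an `ExpressionMatrix` (proteins x samples, log2) with
one `SubjectRecord` per sample: diagnosis group, region, preparation,
sex, age (years), postmortem interval (hours), TMT plex label, and the
clock time of death (TOD) together with sunrise and sunset on the day of
death.  Proteins with missing values beyond `max_missing_frac` (default
0: any missingness) in either group are dropped before analysis; residual
missing values within tolerance are group-mean imputed.  Linear-scale
input is transformed as `log2(x + pseudocount)` with pseudocount 1.

## Differential expression

Per protein, expression is regressed by OLS on an OUD indicator plus
covariates (TMT plex and sex as dummy blocks; age and PMI numeric;
arbitrary user-supplied per-sample columns, e.g. a measured total peptide
signal).  Residual variances are shrunk toward a pooled prior with an
empirical-Bayes squeeze: hyperparameters (prior df `d0`, prior variance
`s0^2`) are estimated by closed-form moment matching on log residual
variances (digamma/trigamma inversion), the posterior variance is
`(d0*s0^2 + d*s^2)/(d0 + d)`, and the moderated t is referred to a t
distribution on `d + d0` degrees of freedom.  As `d0 -> 0` this reproduces
the per-protein t-test and as `d0 -> inf` the pooled-variance test (both
are property-tested).  Voom-style precision weights are not applied:
those target count data, whereas TMT log-intensities have an
approximately mean-independent variance; the moderated-t squeeze alone is
the standard choice for isobaric-label intensities.

A protein is differentially expressed (DE) when unadjusted `p <= 0.05`
and `|log2FC| >= 0.26` (both boundaries inclusive); 0.26 log2 units is a
20% expression change.  A BH-adjusted FDR column is emitted for
information only — DE calling itself uses the unadjusted threshold pair.

Collinearity between a covariate and the group indicator is a hard error
naming the covariate (detected via the design condition number, with the
offending block identified by elimination).

### RRHO

For cross-region/cross-preparation concordance, proteins are ranked by
`-log10(p) * sign(log2FC)` (ties broken by protein id) and, for every
pair of rank thresholds on a fixed stride, the overlap of the two top
sets is scored by `-log10` of the hypergeometric upper tail.  A
top-vs-top map is structurally blind to anti-concordance (when one
ranking reverses the other, every overlap sits at its support minimum and
the map is identically zero), so a second hypermat is always computed
against the reversed second ranking; `max_cell()` scans both and labels
the result concordant or discordant.

## Synapse enrichment

Within each diagnosis group separately, synaptosome and homogenate
samples are paired by subject; the per-protein mean paired log2
difference gives the enrichment fold.  Significance is a one-sided paired
t (synaptosome > homogenate) with Bonferroni correction over proteins
tested.  A protein is synapse-enriched when Bonferroni `p < 0.05` and
fold `>= 1.25` (inclusive); all others are non-enriched.  Proteins
depleted in synaptosomes are non-enriched by definition, hence the
one-sided test.  Downstream synaptosome DE is restricted to the union of
the group-specific enriched sets (the combination rule is configurable;
the union is the default because a protein confidently synaptic in either
diagnostic state belongs in the synaptic universe).  An unpaired Welch
fallback exists behind a flag for incomplete pairing.

## Diurnal rhythmicity

Each subject contributes one circadian time point: TOD converted to
Zeitgeber time, `ZT = wrap(TOD - sunrise)` into `[-6, 18)`, so ZT0 is
sunrise and deaths up to six hours before sunrise carry negative ZT.
Sunset is parsed and stored; the default conversion anchors on sunrise
only, with a daylength-rescaled variant (sunset mapped to ZT12) behind a
flag.

Per protein and group, a fixed-period single-harmonic cosinor

    y = M + A*cos(2*pi*(t - phi)/24)

is fitted via the linearization `y = M + b1*cos(wt) + b2*sin(wt)`, which
attains the exact nonlinear least-squares optimum for a fixed period
(verified against a brute-force phase-grid oracle).  Amplitude is
`hypot(b1, b2) >= 0`, peak ZT is `atan2(b2, b1)/w` wrapped to `[0, 24)`,
and goodness of fit is `R^2`.  A constant series degenerates to
amplitude 0 and `R^2 = 0` with a warning.

Significance is empirical: the ZT vector is permuted 1000 times, the
model refitted (vectorized — the Gram matrix is permutation-invariant, so
only the basis-response products are recomputed), and

    p_emp = (1 + #{R2_null >= R2_obs}) / (n_perm + 1)

(add-one estimator, so the smallest attainable p is `1/(n_perm+1)`).
Each protein index owns a deterministic substream of the stage seed, so
results do not depend on evaluation order or subsetting.  Proteins with
`p_emp < 0.05` form the rhythmic set of that group.

Heatmap matrices take the top 200 rhythmic proteins (ascending `p_emp`,
ties by descending `R^2`, then id), Z-score each row, order rows by peak
ZT and columns by subject ZT; the row ordering is an explicit output so
the unaffected ordering can be replotted on OUD data and vice versa.

## Differential rhythmicity (dR2)

For proteins rhythmic in at least one group, `dR2 = R2_unaffected -
R2_OUD`.  The null permutes ZT within the unaffected samples and,
independently, within the OUD samples, refits both models 1000 times, and
compares the observed dR2 to the null dR2 in the tail given by its sign
(positive: candidate rhythm loss in OUD; negative: gain); the class is
assigned at `p < 0.05`.  Rhythm-parameter differences (circular phase
difference in `(-12, 12]`, amplitude, mesor) are reported only for
proteins rhythmic in both groups.  Fisher's exact test (two-sided,
matched to an enumeration oracle) compares the two rhythmic sets over the
shared protein background, and the plain set differences (rhythmic only
in one group) are emitted alongside the dR2 calls, clearly labeled.

**Known limitation.**  The within-group ZT-permutation null destroys the
rhythm itself, so when both groups share a genuine strong rhythm the null
dR2 is far tighter than the sampling variability of the observed dR2 and
the test becomes anti-conservative (measured ~17% loss/gain calls at
amplitude/noise = 2 with no true group difference).  Calibration holds in
the rhythm-free no-difference regime (~6% of proteins called at
alpha = 0.05, including the eligibility-selection effect).  Findings on
proteins with strong preserved rhythms in both groups should therefore be
read as descriptive.

## Co-expression networks and MDC

The adjacency is `|cor|^beta` (unsigned default; signed available), with
the soft power chosen as the smallest integer in 1..20 whose connectivity
distribution satisfies a scale-free fit `R^2 >= 0.8` (default 6
otherwise).  Modules are detected on the reference group (unaffected by
default): average-linkage clustering of `1 - TOM` (topological overlap),
a static height cut at 98% of the tallest merge, a minimum module size
(default 30), a module-quality filter (mean within-module TOM must exceed
1.5x the global mean TOM — this is the simplification standing in for a
full dynamic tree cut and discards spurious clusters on unstructured
data), and merging of modules whose eigenproteins (first PC of member
expression) correlate above `1 - merge_cut`.  Labels are color names by
decreasing size; unassigned proteins are grey.

Module differential connectivity is the ratio of size-normalized mean
off-diagonal within-module adjacency, OUD over unaffected.  Two
permutation nulls are computed with 1000 draws each: shuffled
sample-group labels, and random member sets of equal size.  Each scheme
yields a two-sided permutation p for MDC differing from 1 (add-one
estimator); the reported `p_mdc` is the more conservative (max) of the
two, and a significant module is labeled gain (`MDC > 1`) or loss
(`MDC < 1`).  The two-sided construction is deliberate: selecting a
one-sided tail by the observed direction doubles the direction-call rate
under the null (~9% measured at alpha = 0.05), while the two-sided test
is calibrated (~5%) with no measurable power cost on planted losses.

Hubs reuse the soft-power adjacency (a mutual-information network with
DPI pruning is out of scope): within a module, proteins are neighbors
when their adjacency strictly exceeds the 90th quantile of off-diagonal
within-module values; `NHNN_i` counts distinct nodes within `n_hops`
(default 1, configurable) of protein i, and hubs are proteins with NHNN
strictly above the module mean.  Hubs computed per group yield
disease-specific hubs by set difference.  Module enrichment for DE or
rhythmic flags is an upper-tail hypergeometric test with observed/expected
fold.

## Over-representation analysis

Generic GMT input; sets are intersected with the stated background (all
quantified proteins of the relevant preparation/region, never the
genome), sets of size < 3 or > 2000 after intersection are skipped,
overlap significance is the hypergeometric upper tail with BH adjustment
across tested sets, and the enrichment score is the count of query hits
divided by the count of background proteins in the set.

## Synthetic cohorts

The generator emulates the study design: 20 subjects per group (matched
pairs sharing a TMT 10-plex, five pairs per plex), ~2000 proteins,
expression built as mesor + group-specific cosinor + DE shift (OUD) +
covariate slopes + per-plex offset + Gaussian noise (log2 sd 0.3 by
default, typical of TMT protein quantification).  Rhythmic proteins
(default 5%) draw amplitude from 0.2-0.8 log2 units and uniform phase;
a configurable fraction of them (default 30%) lose their rhythm in OUD
(amplitude set to 0), with symmetric rhythm gain available.  DE proteins
(default 2%) draw |log2FC| from 0.3-0.8 with random sign.  Co-expression
modules are induced by shared latent factors with loading `sqrt(r)`, so
the expected pairwise within-module correlation is `r` per group while
the marginal noise variance is preserved.  The paired-preparation variant
adds `log2(fold)` (default folds 1.5-3 on 25% of proteins) plus
independent noise to form the synaptosome matrix.  TOD is uniform on
[0, 24) by default; an "empirical-like" mode mixes a late-night/early-
morning cluster (60% weight, wrapped normal at 04:00 +/- 3 h) with a
uniform component to mimic death-time clustering.  Generation is a pure
function of the seed, and every planted signal is recorded in a
`GroundTruth` table.

What the generator does not emulate: missingness mechanisms, isotopic
interference and ratio compression, protein-level batch x protein
interactions, non-sinusoidal or multi-harmonic rhythms, and covariate
distributions matched to a real cohort.  Passing recovery tests on these
cohorts therefore demonstrates correctness of the statistical machinery
under the stated model, not performance on real tissue data.

## Calibration experiments and problem sizes

Type-I-error checks use 2000 independent null proteins (no planted
signal, `plex_sd = 0`) at 30 samples and 1000 permutations; the p <= 0.05
fraction is required to sit in [0.035, 0.065].  Batch offsets are shared
across proteins, so with `plex_sd > 0` the per-dataset false-positive
fraction is a correlated quantity whose spread far exceeds the binomial
band — calibration is meaningful only with independent proteins, while
the DE calibration keeps plex effects because its design adjusts for
them.  Power checks use amplitude/noise = 2 at n = 30 (rhythm detection),
a planted amplitude 1 -> 0 loss at noise 0.5 and 20 subjects per group
over 50 replicate cohorts (dR2), logFC 0.5 at noise 0.25 (DE), and
module correlation 0.7 -> 0.175 (MDC loss, 50 replicates).  MDC null
calibration uses 2000 module tests (20 cohorts x 100 equal-correlation
modules).  These sizes keep the full test suite and the acceptance script
each within a few minutes on one CPU while leaving the binomial bands
tight enough to detect miscalibration.

## Numerical choices

- Cosinor R^2 is clipped to [0, 1]; `SST = 0` defines `R^2 = 0`.
- Permutation p-values use the add-one estimator everywhere.
- RRHO ranking ties break lexicographically by protein id; top-N rhythm
  selection breaks ties by descending R^2 then id.
- Expression TSVs are written with `%.17g` and parsed with exact float
  conversion, so write/read round-trips bit-identically.
- The trigamma inverse uses Newton iteration (50 steps, relative
  tolerance 1e-10); non-positive moment estimates fall back to an
  infinite prior df (fully pooled variance).
- Seeds: one global seed spawns named `SeedSequence` substreams per stage
  and per protein/module index, so outputs are independent of evaluation
  order and adding a stage never perturbs another stage's draws.
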