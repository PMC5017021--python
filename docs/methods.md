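# Methods

`metabotox` implements the data-evaluation stages of an untargeted LC-MS
metabolomics toxicity screen of the kind used to profile nanoparticle
exposure in cultured cells: a time-course design with control and treated
cultures, several chromatography/ionization datasets per study, and a
QC-heavy path from a picked feature table to annotated, differentially
regulated metabolites.  The package starts at the feature list (rows =
features with m/z and retention time, columns = injections with peak
areas); peak picking from raw spectra is upstream and out of scope.

## Study design and the synthetic generator

The default design is 2 conditions x 6 time points (0, 1, 3, 6, 12, 24 h)
x 3 biological replicates = 36 analytical samples per dataset, plus 6
blank and 8 pooled-QC injections and two internal standards (ethylparaben
and nitrotyrosine) spiked at a constant nominal level into every
injection.  Four datasets are generated by default (RP/HILIC separation x
positive/negative ionization).  The blank and pool injection counts are
configurable assumptions — published study descriptions of this kind
rarely state them.

The generator (`metabotox.simulate`) draws per-cell baseline abundances
log-normally (log10 mean 6, sd 0.8) so that the per-dataset detection
floors (100,000 / 20,000 / 150,000 / 50,000 peak-area units for RP_pos /
RP_neg / HILIC_pos / HILIC_neg) bite on a realistic minority of features.
Three mechanisms shape the measured areas:

1. **Cell numbers.** Controls double every 24 h from a seed density of
   1e6; treated cultures grow identically until a 6 h arrest and then
   decline exponentially at 0.03/h.  Measured sample areas scale with the
   viable cell number of their (condition, time) group — the distortion
   that cell-number normalization exists to remove.  Because of this
   scaling, the generator's per-cell ground-truth fold changes are only
   recoverable *after* normalization, which is exactly the property the
   recovery tests exercise.
2. **Treatment effects.** A configurable fraction of features (default
   10 %) receives a per-cell log2 fold change that ramps linearly (or
   steps) from an onset hour (default 6 h) to the last time point
   (default maximum 2.0) — reproducing the qualitative pattern in which
   differential features appear only at late time points and accumulate.
3. **Noise.** Multiplicative log-normal with mean 1.  Analytical samples
   carry `noise_cv` (default 0.10, biological + technical); internal
   standards, blanks and pools carry `technical_cv` (default 0.05,
   injection repeatability) — the IS is spiked into the extraction
   solvent and pools are repeat injections of one mixture, so neither
   sees biological variation.  Intensities below the dataset's detection
   floor are emitted as zero (dense matrix, explicit censoring).

Blanks carry 0.2 % of the baseline signal, except for a configurable 10 %
of "background" features whose blank level is half the sample baseline,
planted to violate the median-blank rule.  Pools are the mean composition
of all analytical samples.  `spike_known_compounds` appends features at
the [M+H]+ / [M-H]- m/z of reference compounds (proton mass 1.00728 u)
for annotation-recovery tests.  Identical seeds give bit-identical
output.

What the generator does **not** emulate: retention-time drift, batch
effects, correlated features (isotopes/adducts of one metabolite),
missing-at-random dropout, or heavy-tailed contamination.  Passing tests
therefore demonstrate correctness of the algorithms under a clean
generative model, not robustness to every pathology of real LC-MS data.

## QC chain

Filters run in a fixed order — noise threshold, blank filter, IS gate,
pool-RSD filter — followed by normalization; a `FilterReport` reconciles
feature counts exactly at every stage.

* **Noise threshold** (per dataset): a feature is removed when its
  maximum intensity over analytical samples is strictly below the
  threshold.
* **Blank filter**: with B the median intensity across blank injections,
  a feature is retained iff B <= 0.20 x intensity in at least 30 of the
  36 analytical samples.  Both comparisons are inclusive ("not allowed to
  exceed").  For other sample counts the 5/6 fraction is kept via
  `ceil(30/36 * n)`.  All analytical samples count, including time 0.
* **IS gate** (dataset-level): the RSD (sample sd over mean, n-1
  denominator) of each internal standard across all analytical samples
  must be strictly below 20 %; otherwise the dataset is excluded from
  differential analysis.  No features are dropped by the gate.  Because
  the IS is present in blanks too, the blank rule removes IS features by
  construction; the gate is therefore evaluated on the unfiltered table
  (it is feature-independent, so this is order-equivalent).
* **Pool-RSD filter**: features are retained iff their RSD across pooled
  QC injections is strictly below 25 %.  A feature absent from all pools
  (zero mean) is removed as unstable.
* **Normalization**: each analytical sample column is divided by the mean
  viable cell number of its (condition, time) group; units become area
  per cell.  Blanks and pools keep raw areas (they serve QC only).  TIC
  and housekeeping-feature normalization are available as alternatives
  for comparison.

Zeros take part in every comparison as true zeros; nothing is imputed at
the QC stage.

## Differential statistics

Each time point is an independent two-group contrast (control vs treated)
on log2-transformed normalized intensities — a per-timepoint design, not
a longitudinal model.  Variance moderation follows the standard
empirical-Bayes scheme for small-n omics designs: per-feature pooled
variances s^2 with d = n1+n2-2 degrees of freedom are modelled as scaled-F
draws around a prior (d0, s0^2) estimated by moment matching on log s^2
(digamma/trigamma method, Newton inversion of the trigamma function; when
the excess log-variance is non-positive the prior df are infinite).  The
moderated statistic is

    t = (mean_T - mean_C) / sqrt(s2_post (1/n1 + 1/n2)),
    s2_post = (d0 s0^2 + d s^2) / (d0 + d),

with d0 + d degrees of freedom, two-sided.  Hyperparameters and t-values
are cross-checked in the test suite against an independent numerical
solve of the moment equations and against Bioconductor limma.

Two choices handle the detection floor:

* zeros are replaced before the log transform by half the smallest
  non-zero value of their own injection column — after per-column
  normalization the detection limit lives on a column-specific scale,
  which the column minimum tracks;
* a feature is tested at a time point only if it has at least two
  observed (non-zero) values in each group.  Constant imputation of a
  fully censored group would fabricate a near-zero variance and an
  artefactual fold change; requiring two quantified values per group (the
  usual "minimum valid values" rule) keeps the realized false-discovery
  proportion at q < 0.05 near 3 % in the calibration simulations.

Benjamini-Hochberg step-up adjustment is applied across features within
each time point; significance counting defaults to adjusted q < 0.05
(raw-p counting is available, since "p < 0.05 after correction" phrasing
is ambiguous in common usage).

## PCA and clustering

`NipalsPCA` extracts components one at a time by the NIPALS power
iteration with deflation, on a mean-centred and (by default)
unit-variance-scaled matrix of observations x features; Pareto scaling is
available.  Convergence is declared when the relative change of the score
vector falls below 1e-10 (at most 2000 iterations) — the score vector
converges linearly while the eigenvalue converges quadratically, so the
vector criterion is the binding one; scores and loadings agree with an
SVD oracle to better than 1e-6 up to column sign.  R2 per component is
the explained sum-of-squares fraction of the preprocessed matrix.

Q2 uses row-wise cross-validation (default 7 folds, round-robin after a
seeded shuffle).  For component a, starting from the residual matrix
after a-1 full-data components, each fold's loading vector is fitted on
the remaining rows and the held-out rows are predicted by projection;
Q2_a = 1 - PRESS_a/SS_(a-1) and Q2cum = 1 - prod(PRESS_a/SS_(a-1)).
Cross-validation schemes for PCA differ between chemometrics packages and
commercial tools, so Q2 values are comparable within this package but not
numerically interchangeable with other software.  On pure noise the
scheme yields Q2cum near zero (mean ~0.03 over 100 replicates); "strong
two-group structure" — defined here as half the retained metabolome
responding 16-fold at 5 % noise, 3+3 samples at 24 h, 3-fold CV (7 folds
being impossible with 6 rows) — yields Q2cum ~ 0.5.  Outlier injections
are excluded manually via a configuration list, never automatically.

Fold-change trajectories of significant features are clustered
agglomeratively (average linkage on Euclidean distances, via scipy) for
the heat-map display; leaf order is the standard recursive dendrogram
ordering.

## Cross-mode matching and annotation

Features from different datasets are compared through their inferred
neutral mass assuming protonation/deprotonation only ([M+H]+ / [M-H]-,
proton mass 1.00728 u); masses agreeing within +/-5 ppm are linked, and
connected components define the Venn regions of the dataset overlap.

Compound annotation searches a user-supplied reference table at the same
+/-5 ppm tolerance.  Evidence flags map to identification confidence
levels: reference substance matching both retention time and MS2 spectrum
-> level 1; reference retention time only -> level 1a; MS2 match against
a database spectrum without a reference substance -> level 2; exact mass
only -> putative.  MS2 similarity is a square-root-intensity-weighted
cosine over greedily nearest-paired peaks within a fragment tolerance
(default 0.01 u); a similarity >= 0.70 counts as a match, and reference
RT agreement uses +/-0.3 min — both conventional values, stated here
because no community standard fixes them.  Multiple compounds within
tolerance are all reported, ranked by |ppm| and flagged ambiguous.

## Assay calculators

* **Dissolution stoichiometry**: mass fractions from IUPAC conventional
  atomic weights (4-5 significant figures; hydrates additive).  Complete
  dissolution of 10 ug/ml CuO yields 63.546/79.545 x 10 = 7.99 ug/ml
  Cu2+; delivering 8 ug/ml Cu from CuCl2.2H2O requires 8 x 170.48/63.546
  = 21.46 ug/ml.  Measured-over-maximum gives percent dissolution.
* **Glutathione redox**: the two-well luminescence kit reports total
  glutathione and (NEM-blocked) oxidized glutathione, both in reduced-GSH
  equivalents; one GSSG is reduced to two GSH for detection, so GSSG =
  gssg_equiv/2, reduced GSH = total - gssg_equiv, ratio = reduced/GSSG
  (infinite when no GSSG is detected).
* **qPCR**: efficiency-corrected relative expression,
  E_target^dCt_target / E_ref^dCt_ref with dCt = control - treated and
  amplification efficiencies in (1, 2].

## Problem sizes and numerics

The test suite and the acceptance script use 300-400 features per
dataset, 200 simulation replicates for FDR calibration and 100 for the
Q2 null — sizes chosen so the full evaluation completes in well under a
minute per component while keeping Monte-Carlo error far from every
decision boundary.  Notable numerical choices: RSD uses the n-1
standard deviation and is undefined (error) for non-positive means;
trigamma inversion by Newton iteration from the 0.5 + 1/y start; BH
implemented via a reverse cumulative minimum; NIPALS starts from the
column of largest sum of squares; all PCA comparisons are made up to
column sign.

## Limitations

Per-timepoint contrasts ignore the within-replicate correlation across
time; the annotation stage does not score isotope patterns or predict
retention times; pool-based drift correction is deliberately absent; and
the headline multivariate metrics of any real study depend on raw data
and software internals that are not reproducible from a feature-table
contract — the package therefore validates its statistics against
oracles and calibration simulations rather than against any published
study-specific value.
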