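# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and what the passing tests do and do not establish.

## Analysis model

### Connection classes and atrophy scores

Every undirected edge of a connectome falls into exactly one class given the
atlas: corticostriatal (cortex ↔ caudate/putamen), interhemispheric
(cortex ↔ contralateral cortex), intrahemispheric (cortex ↔ ipsilateral
cortex) or striatostriatal. Striatostriatal edges are excluded from every
analysis, since all three analysis classes are defined from the cortical
ROI's point of view.

Per cortical ROI, class connectivity is the **sum** of incident masked edge
weights (a mean is available via `agg="mean"`); corticostriatal connectivity
is kept per striatal target, giving the 4-column response of the
corticostriatal analysis versus 1 column for each cortico-cortical class.
Summation preserves streamline-count semantics; the module is agnostic to
the edge-weight units (streamline counts, FA-weighted, ...), so alternative
weightings are just different input matrices.

Atrophy is the control-referenced z-score with the sign flipped so loss is
positive, computed per ROI × column, then averaged over patients (the group
mean is the default; per-patient matrices are retained). Cells with zero
control variance are excluded and logged; the PLS stage drops ROIs with any
excluded cell in the selected response columns. The rate-of-atrophy variant
applies the identical normalisation to per-subject OLS slopes across visits
(per 12 months, using all visits rather than endpoint differences, which is
robust to middle-visit noise). The consensus mask is computed from controls
at the earliest visit only — network topology is defined by healthy anatomy —
and subjects missing any visit are dropped from the longitudinal mode.

The cross-sectional mode analyses one visit (configurable `first`/`last`,
default `last`). The default matters only for synthetic data: the generator
ramps patient loss linearly from zero at the first visit, so the last visit
is where a cross-section shows the planted group difference. On real data a
baseline cross-section corresponds to a disease process already underway.

### Expression mapping

Probe-level donor data are collapsed to genes by unweighted means. Samples
are matched to cortical ROI centroids by Euclidean distance; the default
mode assigns each sample to its nearest centroid within a rejection radius
(20 mm), giving each ROI a sample set — the convention of regional-expression
tooling — while `closest_sample` implements the strict one-nearest-sample
reading. Exact ties break to the lowest sample id / ROI id. Regional values
are averaged in two stages, within donor then across donors, so donors with
more samples near a region do not dominate it.

ROI quality control is a single pass: two per-ROI statistics across genes —
the mean and the range — are each tested against their cross-ROI
mean + 2·sd, and an ROI exceeding either is excluded (`qc_mode` can restrict
to one statistic). The filter is deliberately not iterated; on its own
output with the original thresholds it is a no-op. No gene-level
normalisation happens here: standardisation lives inside the PLS so that
donor-resampled matrices stay on the raw scale.

### PLS

Both blocks are z-scored across ROIs (columns = genes / response channels).
There is no canonical scaling for mixed-unit predictors; z-scoring makes
gene weights comparable and is the convention of the neuroimaging
transcriptomics literature this follows. Components are extracted by
explicit SVD of the running cross-covariance XᵀY with score deflation of
both blocks. This is deterministic, makes component 1 *exactly* the dominant
singular direction of the standardized cross-covariance (the test oracle),
and maximises score covariance per component. Y-variance fractions are
incremental R² of the standardized response on the cumulative score basis.
Requested components are truncated at the rank bound min(n_ROIs − 1,
n_genes) with a warning; constant predictor columns get zero weight;
a constant response column is an error.

PLS signs are arbitrary, so each component is flipped, if needed, to make
its ROI scores correlate positively with the first response column; flips
are recorded. Gene rankings sort by signed weight, ties broken
lexicographically by gene id; the ascending view exposes the negative pole.

One consequence of column standardisation worth stating: the *amplitude* of
a gene's regional pattern is standardised away, so weight-based recovery of
planted loading magnitudes operates through signal-to-noise (corr ≈
l/√(l² + σ²)) and is only rank-monotone, never exact. At zero expression
noise all loaded genes have identical standardized profiles and their
weights tie — "noise-free" is the degenerate case, not the easy one.

### Enrichment

The ranked statistic is the minimum hypergeometric (mHG) score over all
cutoffs of the ranked list, with its exact p-value from dynamic programming
over the (cutoff, hits) lattice: member placements are monotone lattice
paths; path mass is absorbed the first time it enters a cell whose
hypergeometric tail is ≤ the observed minimum, and the absorbed mass is the
p-value (accumulated directly to avoid 1 − x cancellation; equality uses a
1e−12 relative tolerance). Hypergeometric tails are computed from
gammaln-based log-pmfs. The enrichment universe is the ranked list itself —
the genes surviving the expression pipeline — and term sizes are taken after
intersection with it; terms outside [3, 1000] members are dropped, and
exact-duplicate member sets are collapsed (a stand-in for semantic
redundancy filtering, which is out of scope). BH-FDR is applied across
tested terms (statsmodels). A fixed top-fraction mode (default 10%) with a
plain hypergeometric test is available as the alternative target-list
definition.

Empirical p-values (gene-predictor permutation, mean-weight enrichment) use
the +1-corrected estimator p = (1 + #{null ≥ observed})/(n_perm + 1) and are
therefore in (0, 1]. The competitive test reports the plain fraction of
competitor sets beating the target, with 1/#competitors as the resolution
bound when the target beats them all.

## Synthetic-data design

The generators define the package's study conditions; sizes echo the design
they emulate.

| parameter | default | why |
|---|---|---|
| cortical ROIs | 34/hemisphere (68) | bilateral parcellation scale of the emulated design |
| striatal nodes | 4 (L/R caudate, putamen) | targets of the 4-column corticostriatal response |
| cohort | 72 patients / 85 controls | emulated baseline cohort |
| visits | 0, 12, 24 months | three visits over two years |
| class effect sizes | 0.3 / 0.2 / 0.1 (cs / inter / intra) | the corticostriatal > interhemispheric > intrahemispheric vulnerability hierarchy |
| edge density (cortico-cortical) | 0.35 | sparse structural networks |
| edge weights | log-normal (median 100, σ_log 1) | heavy-tailed streamline counts; distributional form is a modelling convenience, not an empirical claim |
| edge noise | multiplicative, σ_log 0.1 | session/tractography variability |
| genes | 2000 | desk-scale stand-in for a ~20k transcriptome |
| donors | 6 | donor count of the emulated expression atlas |
| probes per gene | 2 | probe-level structure for the collapse stage |
| sample jitter | 2 mm (isotropic) | separates mapping correctness from mapping stress tests |
| baselines | N(8, 1) | log2-like microarray magnitudes (irrelevant after standardisation) |
| expression noise σ | 0.5 | default recovery regime |
| planted amplitude | 2.0 | strong dominant spatial component |
| background components | 40 at amplitude 1.5 | see below |

**Atlas.** Cortical centroids sit on a jittered 22 mm grid in the right
half-space and are mirrored to the left (homologous pairs); the ≥ 16 mm
centroid separation makes nearest-centroid matching of 2 mm-jittered samples
reliable (misassignment probability per sample ≪ 1e−3). Striatal nodes have
fixed near-midline positions.

**Ground truth.** A planted cortical gradient (posterior-weighted
rank-uniform values plus jitter) and half-normal gene loadings, both stored
unit-norm; forward models use max-scaled copies so class effect sizes in
[0, 1) bound the multiplicative loss factor 1 − effect·gradient·t/t_max.
Half-normal (nonnegative) loadings fix the expression–atrophy alignment sign.
In two-profile mode a second gradient is orthogonalised against the first
(then rank-uniformed), the gene universe splits into disjoint 40/40/20%
loading pools, and the intrahemispheric class is driven by the second
profile — the configuration behind the connection-class dissociation tests.

**Connectomes.** A shared base network per cohort; corticostriatal edges are
always present (every cortical region projects to the striatum, and the
4-column response presumes all four targets per ROI), the Erdős–Rényi density
applies to cortico-cortical edges. Patients lose edge weight multiplicatively
along the class gradient, linearly in time; subject × visit noise is
multiplicative log-normal, preserving nonnegativity.

**Background expression components.** Real donor atlases contain many
comparable spatial expression patterns, and the permutation-null behaviour
of the analysis depends on them: with a single planted component, permuted
fits can only re-find (a rotated version of) that component, so null gene
weights stay correlated with the planted loadings — contrary to the
dissociation the method is supposed to show. The generator therefore adds
40 rank-one background components (signed loadings, random ROI gradients
orthogonalised against the planted gradients, amplitude 1.5 vs 2.0 planted).
Orthogonalisation keeps the observed fit clean (gene-weight recovery ρ ≈
0.92, ROI ρ ≈ 0.98 at default conditions) while permuted fits latch onto
background structure: null component-1 variance fractions stay large
(median ≈ 0.4 — p ≫ n overfitting, the analog of large null variances on
real data) yet null weights decorrelate from the truth (median |ρ| ≈ 0.05).

**Gene sets, lists, fold changes.** Planted terms draw 90% of their members
from the top-|loading| pool of their profile; curated "disease" lists are
the top 50 loading genes; fold-change tables mix normal scores of the
loading ranks with noise, with the mixing coefficient solved numerically
(Brent) so the realised Spearman correlation hits the target (default −0.23)
to ~0.01 at any gene count.

**What the generator does not emulate** (hence what passing tests cannot
show): tractography biases and distance-dependent edge artefacts, donor
batch effects and ontology structure among gene sets, spatial autocorrelation
of expression beyond the planted/background components, and site or scanner
effects in the cohort. Recovery results certify the inference chain, not the
biology of any real dataset.

## Null calibration

With all class effects zero, the gene-permutation p-value, the mean-weight
enrichment p-value and the list-overlap p-value are calibrated: rejection
rates at α = 0.05 over 1000 simulated null datasets fall in [0.03, 0.07]
(the acceptance suite's check). The overlap test is discrete, so its
attainable size depends on the configuration; the calibration scenario
(universe 500, two 50-gene lists) was chosen analytically for an attainable
size of 0.048. The scenario uses the corticostriatal response, whose per-ROI
cells come from disjoint edges and are therefore exchangeable across ROIs
under the null.

## Numerical choices and degenerate inputs

- Exact distance/weight ties break deterministically (lowest id,
  lexicographic gene order); all stochastic operations take explicit seeds
  and generators are pure functions of their arguments.
- Report tables are written at 12 significant digits and round-trip within
  1e−10; provenance records a SHA-256 over the config and all input bytes.
- mHG p-values are exact (not asymptotic) and validated against exhaustive
  enumeration for all N ≤ 12, K ≤ 4.
- Degenerate inputs fail loudly: constant response columns, fewer than two
  controls, single-visit slopes, empty gene sets after size filters, QC
  excluding every ROI, inconsistent count arguments.
- Bootstrap weight stabilisation is deliberately absent from the default
  path; rankings are raw component weights.

## Known limitations

- The mHG DP is O(N·K) per term; at 20k-gene scale with thousands of terms a
  compiled implementation would be preferable.
- The exact-duplicate filter does not approximate semantic redundancy
  removal among overlapping gene sets.
- Group-mean atrophy (rather than a mixed model over patients) is the only
  aggregation implemented ahead of the PLS.
- The per-ROI permutation-null score bands are wide under the background-rich
  generator; pattern-level alignment statistics, not single-ROI band
  excursions, carry the dissociation evidence.
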