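# Methods

This note documents the statistical models behind `mitoscreen`, the
parameters that matter, what the synthetic generators emulate (and what
they deliberately do not), and the numerical choices made where the design
was genuinely open.

## Robust effect sizes

All workflows are built on the strictly standardized mean difference
(SSMD). Two forms are used.

**Plate quality.** Per plate replicate,
`SSMD_QC = (median(C+) − median(C−)) / sqrt(MAD(C+)² + MAD(C−)²)` with
`MAD = 1.4826 · median(|x − median(x)|)`. The constant 1.4826 is the
reciprocal of the standard-normal third quartile, making the MAD a
consistent estimate of the S.D. under normality. Because the
PINK1-targeting positive control abolishes recruitment (a "very strong"
control), a plate whose controls fail to separate past `SSMD_QC ≤ −2` is
removed. Gating is applied per plate *replicate*, the conservative
reading; the report lists every plate replicate either way.

**Per-gene effect.** `SSMD_i = (median(well_i) − median(C−)) /
sqrt(s²_well/2 + s₀²/2)`, where `well_i` is the vector of the gene's
replicate values, `C−` pools the negative controls of the gene's plates
(all surviving replicates), `s²_well` uses the n−1 denominator (the
convention that 1.4826·MAD estimates), and `s₀²` — the median over all
wells of the squared across-replicate S.D. — acts as a robust variance
floor that keeps a lucky low-variance well from producing an enormous
score.

Degenerate inputs: a 0/0 SSMD (identical constant inputs) is defined as 0
with a warning; zero spread with a nonzero difference yields a
signed-infinity sentinel with a warning. Missing readouts propagate as NaN
and are dropped pairwise before medians and MADs — real imager exports
contain sporadic failed fields and medians tolerate deletion.

## Row/column artifact correction

Positional gradients (edge evaporation, dispense order) are modelled per
plate replicate and per parameter as `value ~ intercept + b_r·row +
b_c·col` with rows A→1…H→8 and columns 1…12 as numeric covariates, fitted
by Huber M-estimation (IRLS, the conventional 95%-efficiency tuning
`t = 1.345`) so a handful of genuinely active wells cannot masquerade as a
gradient. The slope terms are subtracted; the intercept is retained. The
covariates are centred on the plate middle (4.5, 6.5) before fitting and
subtraction — the slopes are identical either way, but centring leaves the
plate median essentially unchanged by the correction, which is what
"removing the slope" should mean operationally. Controls are included in
the fit and corrected too: the artifact is positional, not biological. All
84 parameters are corrected by default (the supervised workflow consumes
all of them); the parameter list is an argument for callers who want to
correct only the lead readouts.

## Univariate and PCA workflows

After correction and QC, per-gene SSMDs are computed for the three lead
recruitment readouts (fraction of cells with >3 puncta, puncta area per
cell, puncta intensity per cell). The univariate workflow thresholds each
readout at |SSMD| > 3 (strict) and also reports a combined flag: a gene is
a univariate hit if any lead readout crosses the threshold, with the
direction taken from the largest |SSMD|.

The PCA workflow condenses the genes × 3 SSMD matrix by a one-component
SVD: `X = UDVᵀ`, score vector `H = u₁d₁`, loading `W = v₁`, so
`X ≈ HWᵀ`. Numerical choices:

- **No centring or scaling.** SSMDs already share a dimensionless scale,
  and a zero score must mean "no effect" for the ±threshold semantics to
  hold. (Three identical SSMD columns therefore give `H = √3 ×` the
  common column — the consensus score of perfectly correlated readouts is
  √3 larger than each individual SSMD.)
- **Sign convention.** The SVD sign is anchored by making the loading on
  the lead readout positive, so positive scores always mean more
  recruitment; without a convention, positive and negative modulators
  would be interchangeable between runs.
- Genes with missing SSMDs are dropped from the decomposition and
  reported.

A consequence of the √3 inflation: the null distribution of the consensus
score is wider than that of a single SSMD by a factor that grows with the
correlation of the three readouts, so the false-call rate of the ±3 cut is
sensitive to that correlation (see the generator notes below).

Parameter selection mirrors the screen's practice: from a candidate set of
six readouts, the three with the largest median absolute plate-wise
control SSMD are chosen; a manual override is honoured verbatim.

## PLS workflow

The supervised workflow learns the control-separating axis from all
parameters:

1. **Feature selection.** Welch two-sample t test per parameter between
   control classes, Benjamini–Hochberg adjustment, keep adjusted p ≤ 0.05.
   Welch rather than pooled because control classes need not share
   variance; BH because only a false *discovery* rate is specified. A
   parameter constant in both classes gets p = 1.
2. **Outlier removal.** Hotelling's T² per control well, computed in the
   principal-component subspace capturing ≥ 90% of control variance
   (capped at n−2 components — with 84 parameters and a few dozen control
   wells the raw covariance is singular), against the
   `a(n−1)/(n−a) · F(a, n−a)` limit at 99% confidence. Flagged wells are
   excluded from training only.
3. **Model.** PLS regression of the label (negative control = −1,
   positive control = +1) on the selected readouts. The component count
   (≤ 10) minimises stratified 10-fold cross-validated squared prediction
   error, ties to the smaller model; folds are seeded, so training is
   bit-reproducible. Any affine recoding of the labels only rescales the
   downstream SSMDs, which are scale-invariant.
4. **Scoring and QC.** Every well is projected onto the component-1 score.
   The score sign is fixed so negative controls sit at the positive pole
   (the score then behaves like the recruitment readouts). Plate QC runs
   on these scores exactly as on a readout; a second PLS model is fitted
   on the surviving plates (same features, outlier removal re-run) and its
   scores feed the per-gene SSMD and the ±3 / ±1.3 thresholds.

## Cross-screen weighted score

Different studies and methods produce effect measures on different scales,
so each score vector (primary PCA, primary PLS, per-siRNA secondary
measures) is divided by its own maximum absolute value before averaging.
The weighted score — the arithmetic mean of a gene's available normalized
measures — is bounded in [−1, 1], and a gene behaving oppositely across
studies shrinks toward zero: the penalty is the mean itself. Genes absent
from a study are averaged over the measures they have. Selection takes the
top and bottom `⌈0.10·n⌉` genes; the fraction, not a fixed numeric cutoff,
is the portable rule, since any cutoff value is data-determined.
Boundary ties break deterministically by |score| then gene id. Per-siRNA
concordance counts the secondary siRNAs with |SSMD| > 1.3 whose sign
matches the gene's primary direction (0–3).

## Expression gating

Log-intensity values of a cell line's array profile are bimodal:
non-expressed probes at low intensity, expressed genes higher. A
two-component Gaussian mixture is fitted to the per-gene mean intensities
by EM (10 k-means initializations, tolerance 1e−8, 500 iterations,
seeded); the lower-mean component is the non-expressed distribution.
10,000 points are drawn from it, each gene's samples are tested against
the draws, p values are corrected across genes (BH by default; Bonferroni
available), and genes at adjusted p ≤ 0.05 are called expressed.

Two interpretation choices are deliberate. The test is one-sided
(gene greater): "expressed" is definitionally the higher-mean component,
and a two-sided test would call strongly *below*-null genes expressed.
The statistic is Welch's (11 samples against 10,000 draws make pooled
variance inappropriate). A fit whose means collapse within half the wider
S.D., or whose smaller weight drops below 0.05, is flagged degenerate and
the gate refuses to run on it.

This gate is a location test, not a membership test: its accuracy is
limited by how far the per-gene mean uncertainty spreads the effective
decision boundary into the gap between the two modes. It classifies well
when the per-sample scatter is comparable to or larger than the
within-component spread of gene means — the regime of the intended input,
a matrix pooled from multiple platforms and laboratories — and degrades
when samples are nearly noise-free replicates, in which case genes in the
upper tail of the non-expressed mode are confidently (and wrongly) called
expressed. Upstream normalization (RMA, quantile, summarization) is out of
scope; the module requires an already-normalized matrix.

## Enrichment

Over-representation of a reference set among hits uses the exact
hypergeometric tail `P(X ≥ k)` on a universe that defaults to the genes
surviving QC; reference genes outside the universe are dropped and
counted. Fold enrichment is `(k/n)/(K/N)`.

## Time-lapse puncta quantification

Frames arrive as two channels (nuclear dye, puncta reporter) every 15
minutes for 6 hours (25 frames including t = 0). Nuclei are Otsu-
thresholded connected components summarised by fitted ellipses; the
"nucleus diameter" is read as the fitted major-axis length. Puncta come
from the extended-maxima transform — regional maxima of the grayscale
h-reconstruction, so an isolated smooth peak marks the plateau
`intensity ≥ peak − h` — followed by the strict area filter
`5 < area < 2000` pixels. By default `h` is a fraction (0.35) of the
frame's dynamic range after light smoothing (σ = 1 px), which makes
detections invariant to uniform intensity rescaling; both `h` and the
smoothing are configurable, with defaults calibrated on the synthetic
generator.

A punctum is attributed to a nucleus iff its centroid lies within one
nucleus diameter of the nucleus centre (inclusive); among eligible nuclei
the nearest wins, and unattributed puncta are reported, never reassigned.
Tracking is greedy nearest-centroid matching gated at one nucleus diameter
per frame; a track losing its nucleus is terminated and flagged, never
silently bridged. Each complete track is labelled by the 2-hour window
(0–2, 2–4, 4–6 h) containing its count argmax; windows own their upper
edge (a peak at exactly 2 h belongs to 0–2 h) and argmax ties take the
earliest frame. The fold change is peak count over `max(1, count at
t = 0)`.

## Synthetic generators

**Screens.** Readouts are generated in noise-S.D. units: negative controls
at baseline; positive controls shifted by −6 S.D. on the informative
parameters (a very strong control, `SSMD_QC ≈ −4` on clean plates);
planted modulators shifted ±4 S.D. (knockdown of a positive modulator
*suppresses* recruitment: direction −1); linear row/column gradients added
to every well; "bad" plates generated with the control separation
collapsed so they straddle the −2 QC cut. 65 of the 84 parameters are
informative and respond with a common sign (higher = more recruitment);
the rest never respond, which makes control-informed feature selection
testable. Correlation among parameters is induced block-wise (a shared
latent factor per block of 7) rather than via an arbitrary full
covariance. The default within-block correlation is 0.4: blocks remain
visibly correlated, and the default screen keeps the ±3 consensus-score
null rate at the ~1% operating point — stronger correlation inflates the
consensus score's null tail via the √3 effect above, and the knob is
exposed for studying exactly that. The generator does not emulate
cell-count covariates, plate-edge nonlinearity beyond the linear trend, or
siRNA off-target structure; conclusions from passing tests are about the
statistical machinery, not about those biological failure modes.

**Expression.** Per-gene means drawn from
`w·N(μ_on, σ_on) + (1−w)·N(μ_off, σ_off)` (defaults 4/9, σ = 1); per-sample
values add Gaussian noise. Default 11 samples per gene, matching the 8 + 3
public-array design the gate was built for, and a default per-sample
S.D. of 3.0: those 11 arrays come from different platforms and
laboratories, so between-study scatter dominates the within-component
spread of gene means. This is also the regime in which the gate's
location-test character is well calibrated (see above).

**Time-lapse.** Static elliptical nuclei (sub-pixel jitter) on a 256×256
frame, Gaussian-spot puncta (σ = 2 px, amplitude ≫ noise) placed within
0.8 nucleus diameters of their cell, counts following a planted ramp
peaking inside each cell's assigned window. Rendering favours a clean
segmentation contract over optical realism — no point-spread asymmetry,
photobleaching, cell motility or division.

## Problem sizes

The test suite exercises the screen pipeline at 25 plates × 3 replicates
(2,000 genes, 200 planted modulators at 10% prevalence) for null
calibration and recovery, 4-plate screens for unit tests, 2,000-gene
expression matrices, and 9-cell time-lapse stacks replicated over three
seeds; the acceptance script uses the same sizes. These are desk-scale
choices: the statistical guarantees measured (recall, false-positive
rates, calibration) are per-gene properties and do not depend on running
the full 98-plate screen.

## Known limitations

- The linear artifact model cannot remove non-linear spatial effects
  (bowl-shaped evaporation patterns); that is a property of the method,
  not of this implementation.
- The PCA consensus score's null width depends on readout correlation
  (√3 inflation at perfect correlation); the ±3 cut is therefore not a
  fixed-FPR rule across screens.
- The expression gate is a location test against the fitted null
  component, with the calibration caveats described above.
- Tracking is greedy and single-hypothesis; it is adequate for sparse,
  near-static nuclei and will fragment tracks in dense or fast-moving
  fields.
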