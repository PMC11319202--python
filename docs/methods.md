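# Methods

This package implements a three-step pipeline for genetic discovery on
high-dimensional clinical waveforms: (1) learn a low-dimensional
unsupervised embedding of each waveform with a convolutional
variational autoencoder (VAE), optionally injecting expert-defined
features (EDFs) so the latent coordinates capture only residual
variation; (2) run a genome-wide association scan on each latent
coordinate; (3) combine the per-coordinate polygenic scores into a
disease-specific score with a small linear model.  A synthetic-cohort
generator provides data with the statistical structure the pipeline
assumes, so every stage is testable at desk scale.

## Waveform preparation

Spirometry blows arrive as volume–time curves (milliliters at 10-ms
steps).  Flow is the forward finite difference of volume converted to
L/s, with the last value repeated so lengths are preserved (the choice
of difference scheme is free; length preservation simplifies the
two-channel encoder input).  Curves are normalized to 1,000 time
points: longer curves are truncated, shorter flow curves right-padded
with zero and shorter volume curves with their final value.
Flow–volume curves are built by linear interpolation of flow against
the running maximum of the volume trace, on 1,000 evenly spaced volumes
in [0, 6.58] L; grid volumes beyond the blow's final volume get zero
flow (the blow has ended).  The cumulative-maximum monotonicization and
the zero fill are package conventions: they keep the grid fixed and
match the physiology of a finished exhalation.

Per-blow QC applies, in order: the device acceptability flag; hard
range gates (every flow inside the open interval (−10, 20) L/s, every
volume inside (−5, 10) L); a ≥20% nonzero-flow requirement; and cohort
percentile tails, dropping blows whose FEV1, FVC or PEF falls outside
the central 99% (0.5% per tail) of the cohort.  All violated reasons
are reported, not just the first.  Percentile bounds are inclusive
order statistics (the largest value at or below the tail point, the
smallest at or above), which is reproducible under ties.  PPG pulses
(single pulses, 100 points) are filtered on min/max/mean/median falling
inside the cohort's central 99.8% (0.1% per tail).  When an individual
has several blows, the first acceptable one is used; individuals with
none are excluded (signalled, not raised).  Related-individual removal
consumes a user-supplied exclusion list; kinship estimation is out of
scope.  The flow unit inside the (−10, 20) gate is fixed as L/s.

## Expert-defined features

Spirometry: FEV1 = volume at t = 1 s (linear interpolation), FVC = max
volume, FEV1/FVC, PEF = max flow, FEF25–75% = mean instantaneous flow
where volume lies in [0.25 FVC, 0.75 FVC] (equivalent to the
volume-difference definition on exact traces, more robust on discrete
ones).  PPG landmarks are detected after light Savitzky–Golay smoothing
(window 7, order 2): the systolic peak is the argmax; the dicrotic
notch is the most prominent interior local minimum after the peak,
declared absent when no minimum reaches 2% of pulse amplitude (the
floor makes notch absence decidable on noisy pulses); the dicrotic peak
is the largest local maximum after the notch, giving the peak-to-peak
distance; the shoulder is the inflection (second-difference zero
crossing) between systolic peak and notch.  The shoulder convention is
a package decision — biobank PPG fields do not define one.

## The encoder

Both encoder variants share one topology: three same-padded 1-D
convolutions (kernel 5), each followed by 2× max pooling and a leaky
ReLU, then three dense layers, then two linear heads producing the
posterior mean and log-variance of each latent coordinate.  The decoder
mirrors it: three dense layers from the latent, then three convolutions
each preceded by 2× nearest-neighbour upsampling, the last one linear.
Defaults: channels (8, 16, 32), dense widths (128, 64, 32), latent
dimension 5 for the plain model, 2 for the residual one — all
overridable; the contract is the 3-conv/3-dense mirror, not the widths.

The loss is mean squared reconstruction error plus a rescaled KL
divergence to the standard-normal prior, optimized with Adam for a
fixed number of epochs (default 100, no early stopping, no scheduler);
validation loss is recorded only for hyperparameter choice.  In the
residual variant the five EDFs are z-scored with training-set
statistics (unscaled features in liters would dominate the decoder
input) and concatenated to the sampled latent before decoding; the KL
applies only to the learned coordinates.  Encodings are posterior
means — deterministic, no sampling at inference.  Curves enter the
encoder on their raw scale (liters, L/s); no standardization.

The network is a self-contained NumPy implementation with hand-written
backward passes (same-padded conv as k shifted matmuls, max pooling
with the gradient routed to the maximal entries, global gradient-norm
clipping at 10, Adam; the decoder
output bias starts at the per-channel data mean).  Gradients are
verified against finite differences in the test suite and training is
deterministic given the config seed at a fixed thread count.  The leaky
ReLU slope (0.1) prevents the dead-unit collapse that occasionally
trapped plain-ReLU runs in poor optima.  Model persistence is a
directory of JSON config plus flat parameter arrays.

Baselines: PCA on the flattened concatenated channels (top-k, exact
SVD), and a one-knot cubic spline on the volume–time curve — basis
{1, t, t², t³, (t−0.2)³₊} with the knot at the 20% position, exactly
five least-squares coefficients.

Latent spaces from different runs are compared by `align_latents`,
which maximizes the summed |Pearson r| over signed permutations via
linear assignment on the absolute correlation matrix.

## Association and loci

Variant QC keeps variants with MAF ≥ 0.001, imputation INFO ≥ 0.8,
missing call fraction ≤ 0.05 and Hardy–Weinberg equilibrium p ≥ 1e-10
(1-df goodness-of-fit chi-square on hard-call counts).  Association is
ordinary least squares of the (z-scored) phenotype on dosage with
covariates partialled out by QR (Frisch–Waugh); on unrelated,
unstructured cohorts this coincides asymptotically with a mixed-model
scan, and the interface keeps effect-size semantics so a mixed-model
backend could be slotted in.  A rank-based inverse-normal transform is
available behind a flag, off by default.  Phenotype z-scoring affects
only the beta scale, never chi-square or p.

Hits are greedy p-value clumps: the best remaining variant with
p ≤ 5e-8 indexes a clump and same-chromosome variants with dosage
r² ≥ 0.1 to it are discarded; ties at equal p break by (chromosome,
position), which makes the procedure order-invariant and exactly
reproducible.  Loci span the positions of reference-panel variants in
LD (r² ≥ 0.1) with each hit; same-chromosome loci separated by fewer
than 250 kb are merged iteratively, the merged lead being the smallest
p.  r² is the squared Pearson correlation of dosages on a configurable
reference subset (default: the full panel).  The expected chi-square
power statistic sums per-variant chi-squares across coordinate scans
and averages over a variant set; its degrees of freedom equal the
number of coordinates.  Catalog matching labels a locus "known" on any
base-pair overlap with a catalog interval — the simplest reproducible
convention.

## Two-stage polygenic scores

Stage one: s_ik = Σ_j g_ij β̂_jk per coordinate k, after harmonizing
variants by (chromosome, position, alleles) and flipping the dosage to
2 − g when the effect allele is the panel's reference allele.
Strand-ambiguous (A/T, C/G) variants are kept by default — synthetic
panels are strand-unambiguous — with a flag to drop them on real data.
Stage two: least squares of the 0/1 (or continuous) label on the T
coordinate scores plus intercept (logistic regression behind a flag);
y_i = w₀ + Σ_k s_ik w_k.  Weight fitting supports case subsampling to
emulate label-scarce settings (down to ~100 cases).  Whether covariates
belong in the stage-two model alongside the scores is a genuinely open
design point; the default fits scores plus intercept only, and
covariate columns can simply be appended to the score table when
wanted.

Evaluation: AUC-ROC (midrank concordance), AUC-PR (step-integrated
precision–recall), Pearson r, and case prevalence among the top and
bottom 1/5/10/20% of scores (strict rank cut, ties broken by stable
individual order).  Percentile bootstrap CIs use 300 individual-level
resamples by default; two scores share one resample stream (pairing),
and a difference is significant when the two-sided 95% interval of the
paired metric difference excludes zero.  Resamples that lose one label
class are skipped for both methods alike, and reported CIs are widened
to include the point estimate in the rare case a percentile interval
misses it.

## The synthetic cohort

Genotypes are Binomial(2, MAF) dosages (exact Hardy–Weinberg margins)
coupled through an equicorrelated Gaussian copula within LD blocks.
Thresholding attenuates latent correlation, so the latent correlation
is calibrated — via exact bivariate-normal quadrant probabilities and
root finding — so the *dosage* correlation matches the requested
`ld_rho`.  MAFs are drawn per block with small within-block jitter, as
variants in strong LD carry near-identical frequencies.  Blocks are
laid across chromosomes at 20-kb spacing.

Latent factors are f = Gβ + ε over disjoint causal sets, with the noise
variance solved from the realized genetic variance so the factor-level
variance fraction equals the requested heritability; factors are then
standardized.  Covariates (age, sex) are independent of genotype by
design, which keeps the null calibration of the association scan
exactly testable.  Disease labels are Bernoulli draws from a logistic
model on the factors.

Spirograms render flow as a sinusoidal rise to peak flow PEF at
`rise_time` followed by a stretched-exponential decay whose exponent
(`decay_shape`) controls late-curve concavity; the decay timescale is
solved in closed form so the integrated flow equals FVC.  Volume is the
running integral, so it starts at zero, is nondecreasing and asymptotes
to FVC.  Factor 1 (size) drives FVC and PEF; factor 2 (shape) drives
rise time and decay exponent, so the curve family is a genuinely
nonlinear two-parameter manifold — temporal warping is what a low-rank
linear basis cannot capture, which is the property the encoder tests
rely on.  Each blow additionally carries a non-genetic "effort wobble":
a zero-net-volume flow dipole anchored where the blow passes 55% of its
final volume (kept clear of the flow peak).  It leaves FVC, FEV1 and
PEF essentially unchanged, so it is waveform variation the five expert
features cannot see — real spirograms carry such within-blow structure,
and it is precisely the residual signal a feature-injected encoder
exists to capture.  Measurement noise is added to flow and integrated,
giving realistically smooth volume traces.  PPG pulses are a systolic Gaussian
plus a dicrotic component; a narrow dip between them creates the notch
when `notch_depth` > 0, and with a zero depth the dicrotic component is
rescaled just enough to keep the pulse unimodal (a shoulder).

A configurable fraction of blows (default 3%) is corrupted — weak
efforts, overshoots, early terminations, device rejections.  Real
cohorts contain such maneuvers; they are what the percentile-tail QC
exists to remove, and with them present the tails of the cohort
distribution are occupied by corrupted blows, so clean curves pass QC
at well above 99%.

What the generator does *not* emulate: population structure,
relatedness, sex chromosomes, imputation uncertainty, non-additive
genetics, covariate-genotype confounding, multi-beat PPG recordings,
device-specific artifacts.  Passing tests therefore show the pipeline's
statistical machinery is correct under its stated assumptions, not that
the encoder will behave identically on biobank data.

## Problem sizes and numerical choices

Training experiments in the test suite and the reproduction script use
cohorts of 2,000–3,000 individuals and spirogram grids decimated 4×
(250 points, 40-ms steps): the curve anatomy survives decimation and
the encoder experiments then fit a desk-scale compute budget.  Encoder
property experiments train for 60–90 epochs at learning rate 3e-3,
batch 128.  The KL weight trades reconstruction sharpness against
coordinate independence: too weak and the coordinates entangle, too
strong and reconstruction degrades toward the linear baseline.  The
package default of 1e-2 keeps the coordinates near-independent
(pairwise |r| ≤ 0.1) while still reconstructing well below PCA at
matched dimension; the residual model uses 2e-2, where its coordinates
decorrelate from the injected features without losing their advantage
over a features-only decoder.  Association nulls use
2,000 individuals × 5,000 independent variants.  The end-to-end
genetic-recovery experiment splits its 2,000-individual cohort evenly:
variant effects and combination weights come from one half, evaluation
from the other — a 1,000-individual held-out set keeps the 300-rep
paired bootstrap well powered for AUCs near 0.6.  Degenerate inputs:
all-zero volume traces, flat pulses, single-class labels and
rank-deficient covariates raise informative errors; noiseless perfect
association caps chi-square at 1e8 rather than overflowing.

Genotype I/O supports TSV dosage matrices (with a variant metadata
sidecar) and VCF with a DS dosage field; curves travel as long-format
CSV; loci as BED plus TSV.
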