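# Methods

This note records the models implemented in `sacquant`, the assumptions
behind them, the defaults that matter, and what the synthetic-data
tests do and do not demonstrate.

## Codon stabilization coefficients

For each of the 61 sense codons, the CSC is the Pearson correlation
across genes between the codon's within-gene frequency of occurrence
(proportion over sense codons; raw counts available) and the gene's
mRNA half-life. Half-lives enter on their natural scale by default; a
log-scale option exists because both conventions appear in the
literature and the choice changes individual coefficients slightly
without changing signs or rankings in our synthetic checks. Codons
whose frequency does not vary across the gene set get an *undefined*
(NaN) CSC — never 0, since 0 is a meaningful value.

Half-life tables from two sources can be harmonized before
correlation: rule (i) drops genes above Q3 + 10·IQR of a designated
table (quartiles by linear interpolation, the numpy default;
configurable since the convention is not standardized), rule (ii)
drops genes whose rank differs by more than 2,500 between the two
tables (average ranks for ties; applied to the intersection only).

Gene-level metrics weight codon *occurrences*, not codon types:
CSC_g is the arithmetic mean of per-occurrence CSC values (stop codon
and undefined-CSC occurrences excluded, with the skipped count
reported), tAI_g the geometric mean of tAI weights (a zero weight
makes tAI_g 0, with a warning, rather than being floored), and percent
optimal the share of occurrences in a user-supplied optimal set.

The positional profile is a centered 9-codon moving average of
per-codon CSC, reported at 1-based window-center coordinates. Its null
distribution comes from shuffling the within-gene codon order (the CSC
multiset is preserved) 10,000 times by default; positions deviating
from the null mean by more than 2 null SDs are flagged above/below.
Identical-codon genes have null SD 0 and are never flagged.

## Constitutive expression noise

The two-stage model has four reactions: mRNA synthesis (rate k_syn_m),
mRNA decay (k_deg_m per molecule), protein synthesis (k_syn_p per
mRNA), protein decay (k_deg_p per molecule). The promoter is
constitutively active — no bursting — and cell growth and division are
ignored. At stationarity M = k_syn_m/k_deg_m (Poisson marginal) and
P = k_syn_p·M/k_deg_p, and the protein coefficient of variation is

    CV_P = sqrt( 1/P + (1/M) · k_deg_p / (k_deg_p + k_deg_m) )

The second term is mRNA noise filtered by the protein lifetime: when
the protein outlives its mRNA by a large factor, the filter factor
k_deg_p/(k_deg_p+k_deg_m) is small and CV_P approaches the 1/√P
Poisson floor. CV therefore *falls* with protein half-life and *rises*
with mRNA half-life at fixed means — the quantitative reason a
short-lived mRNA is a noise-reduction strategy for a stable protein.
At the checkpoint-gene-like point (P = 6000, M = 3.5, protein HL
360 min, mRNA HL 4 min) the formula gives CV = 0.0575, below the 0.06
threshold used to label grid cells low- vs high-noise. Grid cells
whose implied synthesis rates exceed 25 mRNA·min⁻¹ or
20 protein·mRNA⁻¹·min⁻¹ are flagged infeasible (inclusive bounds).

The stochastic path is an exact SSA (direct method). Initial counts
default to the rounded steady-state means to shorten burn-in
(configurable); the default burn-in for statistics is 10× the slowest
molecular lifetime. Trajectory moments are *time-weighted* over
[burn-in, t_end], since event times are irregular; the final state is
held to t_end so the integration window is complete. Random numbers
are drawn in blocks from a seeded numpy Generator, so identical seeds
give identical trajectories.

## mRNA decay fitting

qPCR preprocessing follows efficiency-corrected ratio normalization:
technical replicates are averaged on the Ct scale, amplification
efficiencies come from dilution standard-curve slopes
(eff = b^(−1/slope) − 1, invariant to the log base b), and relative
expression is the target term over the geometric mean of the reference
terms. With all efficiencies 1 this reduces to 2^(−ΔΔCt).

Three single-series models are fit by nonlinear least squares with
half-life (and fit3's amplitude) kept positive via log
parameterization: fit1 = 2^(−t/HL); fit2 = eff·2^(−t/HL) + (1−eff),
which tolerates a non-decaying floor; fit3 = mRNA0·2^(−t/HL), fit
without the t = 0 points so that a free amplitude absorbs
non-instantaneous metabolic labeling. No automatic model selection is
performed; all three fits are reported. The default objective is
least squares on the natural scale; a `log_residuals` option minimizes
log-scale residuals instead, which is the right choice under
multiplicative noise and markedly more stable for slowly decaying
transcripts whose late timepoints carry almost no natural-scale
signal (our recovery benchmarks use it for exactly that reason).

Genotype contrasts use the linearized model
ln y = ln mRNA0 + (−ln2/HL)·t with fixed effects time, genotype and
their interaction, and random slopes + intercepts per experimental
replicate (statsmodels MixedLM, REML by default; ML available). When
the mixed fit is singular or fails, the module falls back to fixed
effects with a replicate indicator and flags the output. The model is
fit twice with each genotype coded 0 in turn; each genotype's
half-life is −ln2/(its own coding's time coefficient), and the
difference contrast is ln2·i/(t·(t+i)), which equals
HL(coded 1) − HL(coded 0) algebraically. Confidence intervals are
percentile bootstrap, by default parametric (responses re-simulated
from the fitted fixed effects, replicate random effects drawn from the
estimated covariance, Gaussian residuals at the estimated scale, then
refit); replicate-cluster resampling is available. A contrast is
called significant when the interval for the interaction coefficient
(or for the half-life difference) excludes 0. At the small designs the
generators emulate (2 replicates × 5 positive timepoints), a 100-null
calibration run put the empirical type-I rate at 0.09 with nominal
0.05 — within binomial error at that sample size, but users of very
small designs should prefer more replicates or larger n_boot.

## smFISH statistics

Poisson fits to per-cell counts use the closed-form MLE (λ̂ = mean);
the goodness-of-fit chi-square pools sparse tail bins (expected < 5)
and uses bins − 2 degrees of freedom.

Count regression is Poisson with natural-log link on centered
ln(cell length), so exp(genotype coefficient) is the ratio of expected
RNA levels between genotypes at average cell length. The length ×
genotype interaction is included when a likelihood-ratio test improves
the model at P < 0.05 (auto mode; can be forced on/off). Ratio CIs are
percentile bootstrap over cells resampled within genotype. Replicate
random effects in the GLMM style are attempted (variational Poisson
mixed model) only when a replicate column with ≥ 2 levels is present;
otherwise a plain GLM (with replicate fixed effects when applicable)
is used and flagged — single-replicate synthetic benchmarks exercise
the GLM path.

Colocalization: 3D Euclidean nearest-neighbor distances between
channels within each cell (KD-tree; physical µm coordinates are the
caller's responsibility; a precomputed chromatic offset can be applied
per channel). The distance cutoff is a quantile of the nearest-neighbor
distances from a *control* experiment in which both probe colors
target the same transcript, so the control distribution captures
registration and localization error only. The quantile is a design
choice (always recorded in the output): q = 0.95 by default, but note
that a q-quantile cutoff misclassifies a (1−q) share of genuinely
paired spots by construction — at a true colocalized fraction of 0.8,
q = 0.95 recovers ≈ 0.76 while q = 0.99 recovers ≈ 0.79 with
negligible false positives at realistic background spot densities. The
recovery benchmarks use q = 0.99 for that reason.

The dimer (double-intensity) test estimates the mode of each group's
log-intensity kernel density (Silverman bandwidth, 512-point grid) and
declares "doubled" when the peak ratio exceeds √2, the log-scale
midpoint between 1× and 2×. Because it is mode-based, the test detects
a *bulk* shift to doubled intensity; a 50:50 mixture of 1× and 2×
spots keeps its mode near 1× and is deliberately not called doubled.

Random-pairing pull-down model: with tagged monomer fraction
p = r/(1+r), random dimerization yields TT : TU : UU at
p² : 2p(1−p) : (1−p)², and a pull-down on the tag captures every
tag-containing dimer, so the captured tagged:untagged subunit ratio is
1/(1−p) = 1 + r — 2:1 at a 1:1 input, 4:1 at 3:1. Observed ratios far
above this ceiling indicate non-random (e.g. co-translational)
pairing. A Monte-Carlo matcher (uniform perfect matching of n
monomers, fixed tagged count round(p·n)) serves as an independent
check and converges to 1 + r.

## Synthetic data

Each generator draws from an RNG stream derived from
(seed, generator name), so outputs are byte-reproducible and adding
generators never perturbs existing ones.

- *Planted-stability genomes*: per-gene stabilizing-codon content from
  Beta(2,2); body lengths vary ±30% around the nominal 300 codons (as
  real gene lengths do, and so every codon frequency varies across
  genes); half-life is affine in the gene's realized stabilizing-codon
  frequency plus Gaussian noise calibrated to a population correlation
  of 0.7 by default. The start codon is structural (one per gene) and
  therefore sign-neutral. With noise 0 the relationship is exactly
  collinear.
- *Decay series*: rel_expr = mRNA0·2^(−t/HL)·exp(ε), ε ~ N(0, σ²)
  with σ = 0.1 by default, timepoints (0, 2, 5, 10, 20, 40) min and 2
  replicates, matching a small metabolic-labeling experiment; t = 0 is
  fixed at 1 (expression is measured relative to it) while the t > 0
  curve carries amplitude mRNA0 < 1, emulating non-instantaneous
  labeling. Optional per-replicate lognormal jitter of amplitude and
  rate produces random intercepts/slopes.
- *FISH datasets*: cell lengths lognormal (median ≈ 9 µm, σ_log 0.25);
  counts Poisson with log-link on centered log length (baseline
  exp(1.25) ≈ 3.5 mRNA/cell, slope 1.0); spots uniform in an
  L × 3.5 × 3.5 µm box (typical fission-yeast girth — a fixture
  convention, not a biological claim); a planted fraction of channel-A
  spots receive a channel-B partner at isotropic Gaussian jitter
  (σ = 0.1 µm), plus uniform background spots.
- *qPCR plates*: Ct values generated from the efficiency-corrected
  forward model, so normalization inverts them exactly as noise → 0.

What passing these tests shows: the estimators invert their own
forward models at realistic sizes and noise levels, with calibrated
uncertainty. What they do not show: robustness to features of real
data the generators omit — segmentation errors, probe-set efficiency
differences, non-exponential decay (labeling chemistry), extrinsic
noise and cell-cycle structure, spatial clustering of transcripts, or
batch effects across replicates beyond simple random slopes.

## Problem sizes and numerical choices

Benchmarks and the acceptance script use: 6–16 SSA seeds of
50,000–100,000 simulated minutes (protein correlation time ≈ 519 min,
so each run holds ~100–200 independent protein fluctuations); 200
noisy decay series; 100-repeat calibration loops with bootstrap n
reduced to 100–200 (the CLI default remains 10,000, the conventional
choice for reporting). Solver tolerances are least_squares defaults
tightened to 1e-14; decay fits are seeded from a log-linear slope.
Degenerate inputs fail loudly: empty intersections skip the rank rule
with a warning, all-propensity-zero SSA states terminate with an
`absorbed` flag, singular mixed fits fall back and are flagged.

## Known limitations

- The expression model excludes transcriptional bursting, extrinsic
  noise and growth/division; its CV is a lower bound for real cells.
- The hierarchical decay bootstrap is mildly anti-conservative at 2
  replicates (see above).
- The Poisson count regression falls back to fixed effects when
  replicate structure is absent or the variational mixed fit fails;
  with strong between-replicate variation the fixed-effect CIs are too
  narrow.
- The colocalization cutoff is a design choice, not an estimate; the
  reported fraction shifts by ~(1−q) with the chosen quantile.
- tAI weights and codon-optimality tables are inputs; the package does
  not derive them from tRNA gene copy numbers.
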