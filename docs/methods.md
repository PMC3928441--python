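# Methods

`refstab` implements the complete analysis path of a two-group RT-qPCR
reference-gene validation study: relative quantification against standard
curves, stability ranking of candidate reference genes by two independent
algorithms (geNorm and NormFinder), geometric-mean normalization factors,
group comparison of genes of interest, and rank correlation of expression
with echocardiographic indices of diastolic function. Because studies of
this kind rarely deposit raw threshold-cycle (Ct) data, the package ships a
first-class synthetic-data generator that emulates the design the analysis
assumes, so every stage can be validated against known ground truth.

## Relative quantification

Each gene's standard curve is an ordinary least-squares line
`Ct = intercept + slope · log10(q)` fit over a five-point, ten-fold
dilution series. The amplification efficiency follows from the slope as

    E = (10^(−1/slope) − 1) × 100 %

so a slope of −3.3219 cycles per decade corresponds to perfect doubling
(E = 100 %). Sample Cts are averaged over technical replicates **on the Ct
scale** (the convention in qPCR practice), then inverted through the curve,
`q = 10^((Ct − intercept)/slope)`, giving strictly positive relative
quantities in arbitrary units anchored to the dilution series. Quantities
are *relative*: no absolute copy numbers are produced, and no ΔΔCt
shortcut is offered.

Quality flags, all configurable: replicate discordance when the replicate
range exceeds 0.5 cycles; a curve warning when r² < 0.98 or the slope is
non-negative (the curve is still returned; its efficiency is NaN). No
standard-curve outlier rejection is implemented. Missing cells (all
replicates undetermined) trigger a complete-case policy: the sample is
dropped with a logged count, because both stability algorithms require a
complete positive matrix; per-gene exclusion was rejected as harder to
audit. An error is raised if fewer than 3 samples per group survive.

## geNorm

For genes j, k with quantities `a` over samples, the pairwise variation is
`V_jk = SD(log2(a_j/a_k))` (n−1 denominator) and the stability measure is
`M_j = mean_{k≠j} V_jk`. Ratios cancel any sample-specific loading factor,
which is exactly the nuisance reference-gene normalization must remove.
Genes are ranked by stepwise exclusion of the highest-M gene; the final two
cannot be separated (their Ms are equal by construction) and are reported
as an unordered best pair. Ties at removal are broken by input order
(first-listed removed first) and logged; real data essentially never ties.

The number of genes worth using is chosen from
`V_{n/n+1} = SD(log2(NF_n/NF_{n+1}))`, where `NF_n` is the per-sample
geometric mean of the n best genes; the smallest n with V below the cutoff
(default 0.15) is recommended, and the full V series is always computed so
the decision plot is available regardless. All logs are base 2; the base
rescales every M and V uniformly and cannot change a ranking. Because M
and V are invariant to per-gene rescaling (verified to 1e-12), whether
quantities are first rescaled to a per-gene maximum is immaterial and no
rescaling is applied. Genes with M < 0.5 are flagged as highly stable, the
conventional working band.

## NormFinder

Log2 expression is modelled as `y_igj = α_ig + β_gj + ε_igj` with sample
effect β common to all genes and `ε ~ N(0, σ²_ig)`. Within each group the
two-way centred residuals give `u_ig`, which is bias-corrected to

    σ̂²_ig = max(0, I/(I−2) · (u_ig − T_g/(I(I−1)))),  T_g = Σ_i u_ig,

an estimator that is exactly unbiased under the model (checked by
simulation; the max(·,0) clamp — the standard remedy for small-sample
negativity — adds a small upward bias only when the true variance is near
zero). Requiring I ≥ 3 genes comes from the I−2 divisor. Intergroup
deviations `d_ig` are the deviations of the per-gene group means from their
across-group average, computed as the mean of pairwise differences so that
the two-group identity `d_i1 = −d_i2` holds exactly in floating point; they
are shrunk towards zero by `γ̂²/(γ̂² + σ̂²_ig/n_g)` with the between-gene
dispersion estimated by method of moments,
`γ̂² = max(0, Σ d²/((I−1)G) − mean(σ̂²_ig/n_g))`. The published description
of this dispersion estimator is not fully reproduced anywhere accessible;
the method-of-moments form here is pinned by the property suite (exact
reductions, unbiasedness, invariances) rather than by matching any
third-party binary, and only the shrinkage strength depends on the divisor.

The stability value is `ρ_i = mean_g(|d̃_ig| + sqrt(σ̂²_ig/n_g))`, groups
weighted equally (the symmetric treatment of the published model, kept even
for the unbalanced 7 vs 11 design). The best two-gene combination
minimizes the same quantity for the pair average
(`d̃_pair = (d̃_i+d̃_k)/2`, `σ²_pair = (σ̂²_i+σ̂²_k)/4`) over all C(I,2)
pairs exhaustively — this is what rewards two genes with similar-sized,
opposite-direction group deviations. Reproducing the exact floating-point
output of the original Excel add-in is a non-goal.

## Downstream statistics

Genes of interest are divided per sample by the chosen normalization
factor. The fold change is the ratio of arithmetic group means (matching
mean ± SEM reporting; a geometric-mean option exists). Group differences
use the two-sided Mann-Whitney test: exact null distribution when the
pooled data are tie-free and n₁+n₂ ≤ 20 (delegated to scipy's exact
method and verified against complete enumeration of all C(n₁+n₂, n₁)
assignments), otherwise the normal approximation with tie and continuity
corrections. All-identical data yield p = 1 by convention with a warning.
Spearman's rho is the Pearson correlation of midranks; for n ≤ 9 the
two-sided p-value is exact by vectorised enumeration of all n!
permutations (correct under ties), otherwise the t approximation is used.
α = 0.05 throughout, no multiplicity correction by default (a handful of
genes of interest); Holm adjustment is available but off by default.

Echo indices derived from raw measurements: E/A, S/D, E/Em and Em/Am
(lateral and septal), A−Ar durations in ms, and the E-wave deceleration
rate in m/s². A measured deceleration rate takes precedence; otherwise it
is approximated as (E in m/s)/(DT in s) — an approximation, since measured
rates come from the velocity envelope slope. Missing operands propagate as
flagged-absent (NaN), never zero. Baseline-adjusted longitudinal modelling
of echo time courses is out of scope; only cross-sectional nonparametric
statistics are implemented.

The strategy-comparison stage computes one fold change + test per gene of
interest per normalization strategy (multi-gene geometric means and
single-gene normalizers) plus a pairwise percent-difference matrix
`|FC_a − FC_b|/FC_b · 100` — the quantitative form of the observation that
normalizing by an unstable single gene can distort fold changes by tens of
percent.

## Synthetic-data generator

The generator *is* the study design, not a tuning knob. Defaults: 7
control ("normal") and 11 treated ("hyperchol") samples; 10 candidate
reference genes and 4 genes of interest with per-gene amplification
efficiencies between 91.8 % and 103.8 % as estimated in the emulated study;
technical duplicates; five-point ten-fold dilution series per gene. True
log2 abundance per gene × sample is

    y = log2(fold)·[treated] + shift·[treated] + β_j + ε,
    β_j ~ N(0, loading_sd²),  ε ~ N(0, residual_sd²)

and Ct = baseline_ct − y·ln2/ln(1+E/100) + replicate noise, i.e. one cycle
per factor (1+E/100) of template using the gene's own efficiency —
consistent with the standard-curve model, so noise-free simulation closes
the loop exactly (quantification recovers the configured fold changes to
floating-point accuracy). Group effects default to 6-, 3-, 2.5- and
2-fold for the four genes of interest and 1 for references. Reference
instability is injected as a deterministic group shift and/or an inflated
residual SD, giving known worst genes for recovery tests.

The study reported no raw Ct ranges or dispersions, so these defaults are
plausible values chosen once: baseline Cts 18–28 cycles, loading SD 0.5
log2 (±40 % cDNA input variation), residual SD 0.15 log2, technical SD 0.1
cycles. They put the simulated reference-gene M values in the 0.15–0.26
band — the same highly stable regime (< 0.5, best genes < 0.2) as the
emulated study. Echo indices are affine in log2 of normalized Bnp with
Gaussian noise, the simplest monotone link supporting rank-correlation
tests; slopes are signed so that indices that rise with filling pressure
rise with Bnp. Not simulated: plate layout, inter-run calibration,
non-specific amplification, Ct censoring at cycle 40, or any real-data
features beyond the model above — so passing tests demonstrate correctness
of the algorithms under the assumed model, not robustness to artefacts the
model omits.

All randomness flows through one integer seed (numpy `default_rng`);
identical config + seed reproduces every output byte-identically.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 100 random
10 × 18 matrices for oracle equivalence; 200 seeded simulations for
unstable-gene ranking recovery; 500 for fold-change recovery, power and
strategy bias; 1000 for type-I calibration; full-enumeration oracles up to
n₁+n₂ = 14 (Mann-Whitney) and n = 7 (Spearman). One known shortfall is
documented honestly: with the residual SD doubled (0.30 vs 0.15 log2) at
n = 7/11, NormFinder places that gene in the bottom two ranks in only
~74 % of simulations (geNorm: 98 %), because the per-group variance
estimator has ~6–10 degrees of freedom and cannot reliably separate a 4×
variance inflation; the covertly group-shifted gene, in contrast, is
detected by both methods in ≥ 98 % of runs. This is a power property of
the estimators at these sample sizes, not an implementation artefact.

## Known limitations

- Complete-case sample dropping can be wasteful for sparse missingness.
- The NormFinder dispersion estimator's divisor convention affects only
  shrinkage strength; rankings are insensitive in all tested regimes.
- Exact Mann-Whitney requires tie-free data (ties fall back to the
  corrected normal approximation); exact Spearman is limited to n ≤ 9 by
  factorial growth.
- No inter-plate calibration, LVDD grading, or longitudinal echo models.
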