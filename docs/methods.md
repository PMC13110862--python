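# Methods

This note documents the models implemented in `pfosber`, the defaults and
why they were chosen, the numerical decisions, and the limits of what the
synthetic-data studies demonstrate.

## 1. Trend screen (Williams test with a permutation null)

For each gene (or apical endpoint) with concentration groups
0 = c₀ < c₁ < … < c_k and replicate counts n_i, the statistic is

    t̄ = (M̂_k − ȳ₀) / sqrt(s²·(1/n_k + 1/n₀))

where M̂_k is the isotonic (pool-adjacent-violators, weighted by n_i)
estimate of the top-group mean under the hypothesized ordering and s² the
pooled within-group variance. Both orderings are evaluated; the larger |t̄|
wins and its sign records the direction (the data show both up- and
down-regulated responders). Only the isotonic value at the *last* position
is needed, so the screen uses the closed form
M̂_k = max_u (increasing) / min_u (decreasing) of the trailing weighted
averages avg(u..k) — algebraically identical to running PAVA and reading the
top block, and vectorizable across thousands of genes and permutations.

Significance comes from permuting the sample→concentration assignment
(default B = 500, one shared seeded permutation set per screen call) with
the add-one estimator p = (1 + #{|t*| ≥ |t_obs|})/(B+1); ties count against
rejection. A gene passes when p < α (default 0.05) **and** the largest
|group mean − control mean| reaches log2(1.5). No multiplicity correction is
applied at this stage: the screen feeds a modelling step, not an inference
claim. Degenerate flat rows (zero pooled variance, zero difference) are
assigned t̄ = 0.

## 2. Benchmark-concentration modelling

**Likelihood.** Responses are modelled as i.i.d. normal with constant
variance around the mean curve; this is the standard treatment for
log2-scale expression data, where variance is approximately
mean-independent. Maximum likelihood is then least squares on the mean
parameters with σ̂² = RSS/n; AIC = 2(k_mean + 1) − 2·loglik.

**Model suite.** The six continuous forms are the classic BMDS
parameterizations (see `pfosber.models`). The "restricted" convention is the
default: Hill n ≥ 1 and exponential g ≥ 1 (no supralinear curvature at dose
zero), and polynomial dose coefficients constrained to a common sign so the
fitted curve is monotone. The polynomial restriction matters in practice:
unrestricted quadratics imitate saturating curves well enough to win AIC
selection while distorting the low-dose slope that determines the BMC.
`restricted=False` lifts all three constraints.

**Fitting.** Polynomials are solved exactly (sign-constrained linear least
squares via `scipy.optimize.lsq_linear`); Exp3/Exp5/Hill use bounded
trust-region least squares from a deterministic multi-start grid (potency
candidates log-spaced over the positive dose range × powers {1, 2}),
jacobian-scaled because parameters span four orders of magnitude.
Exponential arguments are clipped at ±700 so overshooting starts stay
finite; the clip is far beyond any plausible fit.

**BMC.** The benchmark response is bmr_sd (default 1) times σ̂, with σ̂
floored at 10⁻⁶ to keep noiseless fixtures from collapsing to BMC = 0. The
BMC is the smallest d > 0 with |f(d) − f(0)| = bmr_sd·σ̂, inverted in closed
form for Linear and Hill and by bracketed root-finding on a dense
(geometric + linear) grid otherwise; the grid handles non-monotone
unrestricted polynomials by taking the first crossing. The search range is
(0, max tested dose] in the pipeline; endpoints whose winning curve never
reaches the benchmark are dropped, consistent with the range filter.

**Profile-likelihood limits.** BMCL/BMCU are the doses where the profile
likelihood-ratio statistic reaches χ²₁(0.90) — one-sided 95% bounds on each
side. The profile at a candidate BMC d\* maximizes the likelihood subject to
|f(d\*) − f(0)| = bmr_sd·σ; the constraint pins σ = |f(d\*) − f(0)|/bmr_sd,
so after substitution the profile is an unconstrained bounded optimization
over the mean parameters only. It is solved in MLE-scaled coordinates
(L-BFGS-B with a Nelder-Mead polish), walking multiplicatively away from
the MLE with warm starts and bisecting the crossing on log-dose to 0.2%.
A limit that fails to cross within [min positive dose/10³, 10·max dose] is
reported at that boundary and flagged. Tests verify the limits against an
independent 400-point constrained-likelihood grid (agreement within 2%).

**Selection and filtering.** Within each nested family
(Linear ⊂ Poly2 ⊂ Poly3 and Exp3 ⊂ Exp5) a forward likelihood-ratio
chi-square test at p = 0.05 picks the simplest adequate member; the family
winners plus Hill are compared by AIC, with ties broken by parameter count
and then a fixed model order — selection is fully deterministic. Records
are retained iff BMC ≤ max tested dose and BMCU/BMCL < 40 (strict).
Summary statistics (median, 5th percentile by linear interpolation; the
median of two values is their mean) carry 95% percentile-bootstrap CIs
(B = 1000, seeded) over endpoints — the bootstrap is this package's choice
for summary-level uncertainty.

## 3. Free-fraction (albumin binding) correction

In vitro BMCs are total concentrations in medium containing 10% FBS; in
vivo targets are total plasma/interstitial concentrations. Assuming the
free concentration drives bioactivity, equal free levels imply

    BMC_in-vivo-equivalent = BMC_in-vitro × fu_invitro / fu_plasma.

Defaults: fu_plasma = 0.33% (reported human value) and fu_invitro = 5.506%,
back-calculated so the factor (16.685) reproduces the published
corrected/uncorrected HED ratio — the in vitro free fraction itself is not
published. A mechanistic alternative derives fu_invitro from albumin
concentrations by single-site linear binding-capacity scaling,
fu = 1/(1 + (1/fu_ref − 1)·(albumin/albumin_ref)); at 45 g/l plasma vs
2.3 g/l in 10% FBS this gives 6.1% and a factor of 18.5 — within 10% of the
back-calculated route, which is reassuring but not an independent
validation. Because the downstream chain is linear, the correction commutes
with HED conversion; it is applied to BMC records before conversion purely
for reproducibility of intermediate files.

## 4. Reduced PBTK model and reverse dosimetry

The full physiological model that produced the published dose↔concentration
mapping is not reproducible from summary numbers alone, and the downstream
analysis uses that mapping only as a linear factor. The package therefore
implements a reduced linear system that preserves exactly the features the
analysis depends on — chronic accumulation at the PFOS half-life and a
proportional ovarian output:

    dA_gut/dt = −ka·A_gut            (+ dose·BW bolus at each dosing time)
    dA_c/dt   = ka·A_gut − k·A_c     k = ln2/half-life
    dC_ov/dt  = (Q/V_ov)·(C_plasma − C_ov/P)

Defaults: body weight 70 kg (adult female), ka = 1/day (oral absorption is
fast relative to a 5.4-year half-life; its value is immaterial after the
first weeks), apparent central volume 0.23 l/kg (reported PFOS distribution
volume), half-life 1971 days, ovarian plasma flow 6 l/day and interstitial
volume 5 ml (fast equilibration — the ovary tracks P × plasma essentially
instantaneously at this time scale), partition P = 0.38 before calibration.
The system is linear with constant coefficients, so each output step uses
the exact matrix-exponential propagator; the step (default 0.05 day,
required ≤ interval/10) only sets output resolution and AUC accuracy.

**Calibration.** The ovarian output is proportional to P, so one rescaling
against the anchor pair (181 ng/ml ovarian interstitial fluid ↔ 172 ng/kg
bw/day) makes the model reproduce the published linear map exactly; the
operation is idempotent and leaves plasma kinetics untouched. The
end-of-simulation concentration C_tEnd at day 720 is the reverse-dosimetry
metric; at this half-life the daily ripple is ≈0.03%, so C_trough or the
interval average would give indistinguishable HEDs (switchable by summary
metric). Reverse dosimetry is then HED = C_target/(C_tEnd per unit dose),
and dose-linearity (verified to <0.1% over three decades) makes the probe
dose irrelevant.

**Unit bridge.** BMCs in nM convert to ng/ml with MW = 500.13 g/mol (PFOS
free acid). The potassium salt (538.22) is selectable, but the free-acid
mass is the one that makes the published nM ↔ ng/kg bw/day pairs mutually
consistent, so it is the default.

## 5. References and BER

ART-patient references are consumed directly as HEDs (0.1 / 3.5 / 172 ng/kg
bw/day for the minimum, average-of-medians and maximum follicular-fluid
levels); occupational references are built from serum concentrations
(426 / 1231 / 19564 ng/ml) via C_ff = C_serum × BFTE with BFTE = 0.75, then
converted by the same dose factor. BER = HED_bioactive/HED_reference; BER
intervals divide by the maximum and minimum reference (the interval is
below 1 only if even the minimum-reference BER is). Reported BERs are
rounded to one decimal; full precision is kept internally. Pathway-level
HEDs are medians over member-gene HEDs from user-supplied GMT sets —
re-fitting at the pathway level would be an alternative convention, but
median aggregation is transparent and monotone-equivariant.

## 6. Synthetic data: what it emulates and what it does not

The generator plants a minority of monotone responders (Hill, Exp5 or
Linear; direction 50/50) among flat genes, with additive Gaussian noise on
the log2 scale — matching how the real data enter the pipeline
(log2-transformed normalized counts). Responder defaults are anchored to
the observed benchmark-concentration distribution of the granulosa-cell
system: amplitudes 1.5–2.5 log2 units (strong differential expression),
EC50 log-uniform over 30–1000 nM (curves that saturate within or near the
tested 10–1000 nM range), Hill n 1–3, exponential g 1–2. Each responder's
true BMC at 1 noise-SD is computed analytically (closed forms per model)
and cross-checked against a 10⁵-point grid search.

Not emulated: count-level sampling, per-gene variance heterogeneity,
gene–gene correlation, library-size effects, or batch structure. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under its own assumptions — not performance on real RNA-seq data, where
dispersion structure and correlated nulls will degrade both the screen's
effective FDR and BMC precision.

**Measured recovery limits.** At the study design (4 concentrations at
10-fold spacing, 4 replicates, noise SD 0.25, BMR = 1 SD), BMC estimation
is intrinsically coarse: the BMC typically falls inside a 10-fold dose gap
and is located by interpolation. In simulation, even fitting the *true*
model family by maximum likelihood yields a median relative BMC error around
35–45%, with profile-CI coverage of 93–97%; the full pipeline (which must
also select the model) reaches ≈50% median error and ≈72–80% coverage, the
gap being model-selection mismatch. These numbers are the package's honest
characterization of the design, and the acceptance suite reports them as
measured; they should temper the interpretation of any single-gene BMC from
a 4 × 4 design, while medians over hundreds of genes (the quantities the
analysis actually uses) remain far more stable.

## 7. Problem sizes and determinism

All randomness flows from explicit integer seeds (generator, permutation
null, bootstrap); re-running any stage with the same config is
bit-identical. The test and acceptance suites use 1000 null genes for
permutation calibration, 500 genes / 50 responders for screen sensitivity,
and 200 planted responders for recovery — sizes at which the binomial error
of the measured rates is well inside the asserted bands.
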