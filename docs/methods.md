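# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates. Notation: features
i ∈ {1,…,m}, covariates j ∈ {1,…,g}, samples k ∈ {1,…,n}; A_ik absolute
abundance, T_k = Σᵢ A_ik, P_ik = A_ik/T_k relative abundance; B_i the
presence/absence vector of feature i.

## The hurdle decomposition

After total-sum scaling (and optional absolute-abundance anchoring), the
table is split into a binary presence mask and log₂ values defined only
where a feature was observed. Features are retained only if they are
non-zero in at least two samples with not-all-identical non-zero values —
the weakest condition under which the per-feature abundance regression is
estimable. No pseudo-count exists anywhere on the model path: the hurdle
split is the replacement for it. A consequence worth stating plainly is
that the abundance model's effective sample size is the feature's non-zero
count, not n.

## Abundance half

Per feature, ordinary least squares on the log₂ non-zero abundances (a
random-intercept linear mixed model, fit by REML through statsmodels
MixedLM, when repeated measures are declared). A fit is refused, and
reported as an errored record rather than a number, when fewer than
p + 2 non-zero complete cases remain for p parameters or when the design
is rank-deficient on the present samples (the offending columns are
named).

**Median comparison.** On the relative scale an absolute-scale change in
some features shifts *every* coefficient for covariate j by a common
compositional offset. If fewer than half the features change, the median
M̂ⱼ of the per-feature coefficients estimates that offset, so each
coefficient is tested against M̂ⱼ with statistic

  z_i = (β̂_ij − M̂ⱼ) / sqrt(SE_ij² + V̂_M).

V̂_M, the variance of the median, is estimated by a seeded nonparametric
bootstrap over the m coefficients (B = 1000 resamples); for m < 10 the
asymptotic form π/(2m)·median(SE²) is used instead. The reference
distribution is t with the feature's residual degrees of freedom: sparse
features can enter with df as low as 2, where a normal reference was
measurably anti-conservative (12% of null p-values below 0.05 at df 4 in
a direct check); mixed fits, which expose no exact df, use the normal
approximation with this noted per fit. Reported coefficients stay on the
raw relative scale by default (subtracting M̂ⱼ is an option) so effect
sizes remain interpretable; only the p-value is median-adjusted. The
median includes the feature under test — no leave-one-out — and even m
takes the midpoint of the central order statistics. Off the relative
scale (spike-in or total-load runs) the correction is disabled: the
anchoring already removes the compositional offset.

## Prevalence half

Per feature, logistic regression on presence/absence with a data
augmentation: the n observed rows (weight 1) are stacked with one
all-present and one all-absent copy of the design, the 2n extra rows
sharing total weight g. This is a conjugate-prior shrinkage equivalent to
g pseudo-samples, guaranteeing finite coefficients under complete
separation while vanishing asymptotically (the augmented estimate is
within 0.01 of the unpenalized MLE at n = 5000 in the test suite). The
weighted fit goes through statsmodels GLM with frequency weights; Wald
tests use the normal reference.

With random intercepts, no installed fitter offers a *weighted* binomial
mixed model, so `hurdleda.glmm` implements one: a Laplace approximation
whose conditional modes are found by a block-elimination Newton (the
random-intercept Hessian block is diagonal, so each step costs
O(np² + G)), with the variance profiled by a bounded 1-D search over
log σ and fixed-effect covariance taken from the Schur complement of the
joint Hessian. It agrees with a 40-node Gauss–Hermite oracle to ~0.05 on
the suite's test instances. Augmented rows inherit the subject of their
source row.

**Abundance-induced flags.** A prevalence association is flagged as likely
abundance-induced when the same term's abundance coefficient (tested
against zero, not the median, with its own BH pool) is significant at the
global threshold, agrees in sign, and is larger in magnitude — the
signature of a real abundance shift dragging a rare feature across the
detection limit. β_prev = 0 never counts as sign-matching. Flagged
records stay in the output with the flag set.

**Read depth** can be included as an ordinary untransformed covariate
(the log-odds of detecting a feature of relative abundance r at depth n
is ≈ nr); it is never added automatically because, when depth is
independent of the other covariates, including it only costs power.

## Combining, FDR, significance

Abundance uses only the non-zero values; prevalence uses only the mask;
under the joint null the two p-values are independent uniforms, so
p_joint = F_Beta(1,2)(min(p_a, p_p)) = 2p_min − p_min². With one half
missing (e.g. an errored abundance fit), the surviving p passes through
unchanged. BH runs in three pools — all abundance p-values, all
prevalence p-values, all joint p-values (one per feature-term pair) —
with intercepts excluded; whether the original pools the halves jointly
is not documentable from the main text, so two pools plus a joint pool is
this package's documented choice. Omnibus and contrast p-values join the
same pools. The significance filter keeps records with q at or below the
threshold (0.1 by default), |coef| above an effect threshold (0 in the
library, 1 in the CLI's significant-results file), and no fit error.

## Inference extensions

Multi-level (`group`) covariates get an ANOVA-style omnibus test: an
F-test of joint nullity for linear fits (chi-square approximation for
mixed fits), a likelihood-ratio refit for logistic fits. No median
correction applies to omnibus p-values. Ordered covariates are encoded
with thermometer (cumulative) indicators so each coefficient is a
consecutive-level step; steps are ordinary terms, so on the relative
scale they are median-corrected across features like any other
coefficient, which is exactly the step-vs-median-step test. General
contrasts cᵀβ̂ = rhs use the Wald form with the fit's df policy; user
contrasts default to rhs 0, with the median option available.

## Simulator

Each feature's null is zero-inflated log-normal: presence probability
π_i, and log₂ abundance Normal(μ_i, σ_i²) when present, on the absolute
scale. Template hyper-distributions (π_i ~ Beta(0.5, 2), μ_i ~ N(0, 2),
σ_i ~ |N(0,1)| + 0.5) give a sparse community (~80% zeros at depth
50,000, median prevalence ≈ 0.1); they are the package's calibration
choice, overridable via a template file. Metadata are multivariate
standard normal with half the columns dichotomized at zero. A default 10%
of feature-covariate pairs are spiked — half abundance, half prevalence,
half positive, |β| ~ U(2.5, 5) in log₂ (abundance) or log-odds
(prevalence) units — *on the absolute scale*, after which samples are
TSS-normalized and reads drawn multinomially at a log-normal depth
(parameterized by its natural-scale mean, default 50,000; log-sd fixed at
0.5). Spike-ins add a reference feature at a uniform 1–10% of each
sample's total. Repeated measures share subject-drawn covariates within
subject and add a subject intercept (sd 1, log₂ scale) to abundance.
Ordered covariates split a total effect over consecutive steps by a
Dirichlet(1) draw with a left-to-right zero-and-carry rule. The
structural-zero design multiplies one group's mean abundances by
U(2.5, 5) for 10% of features (the affected fraction is this package's
choice) and zeroes a random 20% of features in that group outright.

What the simulator does *not* emulate: between-feature correlation
(real communities have block structure), overdispersion beyond the
log-normal, batch effects, varying sampling efficiency, or templates fit
to real metagenomes. Passing benchmarks here therefore demonstrates
correctness of the machinery and calibration under the stated generative
model, not performance on any particular real cohort.

## Benchmark scales and scoring

`scripts/acceptance.py` runs 10 replicates per setting (sample sizes 50,
100, 200, 500, 1000; repeated measures at 100 subjects × 10 samples) —
replicate counts chosen to keep a full run in minutes on one CPU while
averaging out replicate noise. A discovery is a joint-q < 0.1,
error-free (feature, covariate) pair; precision/recall/F1 follow, with
optional type matching (the model half with the stronger evidence names
the association's type), relative shrinkage error
(|β̂| − |β|)/|β| over type-matched true discoveries, and per-covariate
Spearman correlation of fitted vs true abundance coefficients averaged
over covariates.

## Known limitations

- The median-comparison variance V̂_M is a bootstrap stand-in for an
  unpublished exact construction; it is distribution-free and seeded but
  approximate.
- Both halves are mildly conservative at small n — the augmentation prior
  shrinks prevalence z-values and V̂_M inflates the abundance denominator —
  so pooled null p-values sit slightly above uniform near zero. This is
  the deliberate price of precision; joint q-values under a global null
  stay well under the 1% false-call mark in the suite's 20-dataset check.
- One random-intercept grouping is supported; nested or crossed designs
  are not.
- Mixed-model Wald tests use a normal reference (no Satterthwaite df).
- `group` omnibus records carry no single coefficient, so an effect-size
  threshold above 0 excludes them from the significant-results file.
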