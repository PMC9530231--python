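# Methods

## Model and assumptions

Estimates are modeled as i.i.d. draws from an estimation context
$\mathcal F^{\theta}_{\mu,\sigma}$ with positive truth θ. The package uses
multiplicative parameterizations for the skewed families,

* log-normal: $a = \theta e^{\mu + \sigma Z}$, $Z \sim N(0,1)$;
* log-Laplace: $a = \theta e^{\mu + L}$, $L \sim \mathrm{Laplace}(0,\sigma)$;
* Pareto: $a = \theta e^{\mu} P$, $P$ standard Pareto with tail index
  $\alpha = 1/\sigma$ (larger σ ⇒ heavier tail);

so that every statistic built on relative errors is invariant to rescaling
the truth (tested to bit-identity for the Monte-Carlo path and to 1e-9 for
the bound). The normal family is additive, $a = \theta + \mu + \sigma Z$,
truncated to the positive half-line by resampling (the resample count is
logged); its CDF provider is the matching truncated normal, so sampler and
bound describe the same distribution.

Influence is the one-parameter class $a^n(\omega) = \omega a_1 +
(1-\omega)\bar a$. Because the draws are exchangeable, "agent 1" is the
central agent without a separate selection step; the generator (below) does
select a central member explicitly because trial tables carry subject
identities. Multi-round opinion dynamics, communication (binary) networks,
and topologies outside this class are out of scope.

## Ω estimation and the lower bound

`estimate_omega` draws one estimate vector per repetition, computes both
aggregates *on the same vector*, and counts strict wins
(`|a(ω)−θ| < |a(0)−θ|`). Ties count as failures, which matters only for
degenerate contexts; ω = 0 is a self-comparison and returns 0 with a
warning. The binomial standard error $\sqrt{\hat p(1-\hat p)/\text{reps}}$
is attached. Sampling is chunked (10^5 repetitions per block) to bound
memory at large `reps`.

The bound maximizes $g(\beta) = F(\beta)(1 - F(n\beta)^{n-1})$ over
$\beta > \theta/(1-\omega)$. Substituting $\beta = \theta/(1-\omega) + e^u$
makes the domain the whole real line in *u*; a deterministic coarse grid
(u ∈ [−20, 40], step 0.05 — slightly more than a full float exponent range
on either side of the edge) is refined by bounded golden-section search to
xatol 1e-8, so results are bit-reproducible, and a brute-force 10^6-point
scan is used as the test oracle. The power $F(n\beta)^{n-1}$ is computed as
$\exp((n-1)\log(1-S(n\beta)))$ from the survival function, which keeps tail
probabilities of order $1/n$ alive at $n = 10^6$ where a naive power
underflows.

`bound_limit_profile` evaluates the bound along n = 10^2 … 10^6 and
classifies the empirical limit with 0.05 bands: below 0.05 and
non-increasing ⇒ vanishing; within 0.05 of 1 ⇒ tends to one; within 0.05 of
0.5 with a flat last step (≤ 0.01) ⇒ tends to one half; anything else is
reported as undetermined rather than forced into a class. The critical
shape is located by scanning a geometric σ grid for the verdict flip; no
closed-form critical values are claimed.

## The R statistic

R is the two-model softmax of the *total* maximum-likelihood
log-likelihoods, $R = 1/(1 + e^{L_N - L_{LN}})$, evaluated through a
numerically safe logistic. Both families have two free parameters, so no
complexity penalty is warranted; the statistic saturates toward 0/1 for
decisive samples and equals 0.5 exactly when the fits are equally good. The
log-normal likelihood includes the change-of-variables term
$-\sum \log x_i$, so the two likelihoods are comparable on the original data
scale. MLE variance uses divisor *n*.

Discrimination is an empirical property, not a guarantee: a normal sample
whose coefficient of variation is small is locally indistinguishable from a
log-normal one (a log-normal with sdlog ≈ CV), and R is then near 0.5
regardless of sample size. Calibration checks therefore use thin-tailed
samples with CV ≈ 0.2, where the decision is sharp at n = 1000. R is
permutation-invariant and nearly (not exactly) scale-invariant; rescaling
by 0.1–10 moves it by < 0.05 in the simulation suite.

Per task, R is computed from the initial estimates of all individuals
across all groups answering that task, pooled within study (the same task
label in two studies is two contexts — different populations induce
different distributions). Tasks with fewer than 5 positive estimates, or a
constant pool, get R = NaN and are excluded downstream (logged).

## Trial pipeline

Filtering follows the task-level rule: any task containing a negative
estimate is dropped whole. Zeros pass this filter and are removed only from
the R pool by positivity. Collective initial/revised estimates are group
means per stage; improvement is strict (a tie is not improvement). Revised
absolute errors are z-scored within task using all trials of both
conditions (sd divisor n−1); single-trial and zero-variance tasks are
excluded, logged.

Both moderation models use random intercepts by group and by study only —
the model equations contain no random slopes. The printed form of the
source logistic equation places the linear predictor inside
$1/(1+\exp(\cdot))$ without a minus sign, which would invert every
coefficient; this package fits the standard logit convention, so a positive
R coefficient means "higher R ⇒ higher improvement probability".

Estimation choices, made after cross-checking against `lme4` on identical
data:

* **Linear model** (REML, `MixedLM`): the default gradient-optimizer cascade
  stalls when a variance component sits at its zero boundary — common here
  because within-task z-scoring removes most study-level variance — so the
  derivative-free Powell search is used; it reproduces the `lmer` optimum
  (coefficients and REML criterion) on the same data. Boundary fits are
  flagged `boundary_variance`, mirroring `lmer`'s singular-fit message.
* **Logistic model** (Laplace/MAP, `BinomialBayesMixedGLM.fit_map`): the
  variational-Bayes alternative understates fixed-effect posterior sds
  (mean-field factorization), inflating z-statistics by ~60% in null
  simulations; the Laplace approximation is calibrated (null z sd ≈ 1.04)
  and matches `glmer` estimates and standard errors to three decimals. The
  optimizer's random start values are drawn from numpy's global legacy
  generator inside statsmodels, so the fit pins that state locally to stay
  deterministic. Quasi-complete separation of the outcome by R is detected
  and flagged, not silently absorbed.

Reported statistics are estimate/SE (z for the logistic, t for the linear
model); `n_obs` always equals the rows entering the fit, and the two models'
populations differ exactly by the control groups.

## Synthetic generator

The generator emulates the structure of multi-study estimation experiments:
4 studies × 12 tasks × 25 fixed groups per study (order 100 groups / 50
tasks, mirroring the reanalyzed corpus' printed dimensions), group sizes
uniform on 4–10, 15% control groups (the corpus' control share), truths
log-uniform on [10, 1000]. Tasks alternate regimes so R spans its range:

* thin-tailed: normal, μ = 0, σ/θ ~ U(0.1, 0.3) — an unbiased crowd with
  realistic relative spread;
* heavy-tailed: log-normal, μ ~ U(0.2, 0.8) (overestimation bias), σ ~
  U(0.5, 1.5) — the right-skewed, excess-kurtosis shape typical of
  empirical estimate distributions.

Interactive groups have a fixed centralization ω_g ~ U(0.2, 0.6) and a
uniformly chosen central member; each member reports
$(1-s)\,a_i + s\,a^*$ plus N(0, 0.05·a*) noise, with susceptibility
s = 0.8 and $a^* = \omega_g a_c + (1-\omega_g)\bar a$. With s = 1 and no
noise the collective revised estimate equals $a^*$ exactly — the minimal
individual-level mechanism consistent with the aggregation model. Control
groups keep their initial estimates (effective ω = 0 exactly), so their
improvement indicator is identically 0 under the strict rule. This plants
the moderation the pipeline must recover: centralization pulls heavy-tailed
aggregates toward a typical member (away from the tail-inflated mean) and
merely perturbs already-accurate thin-tailed aggregates.

The **zero-centralization (null) configuration** sets ω_g ≡ 0, s = 1 and a
token revision noise of 0.001. The noise cannot stay at its default there:
revision noise comparable to a group's collective error makes *strict*
improvement systematically rarer in precise (thin-tailed, low-R) contexts
than in diffuse ones, i.e. it plants a real moderation effect in a
configuration meant to carry none; noise far below the smallest relative
collective error leaves the improvement probability uniformly 1/2. A
perfectly noiseless null is unusable for the logistic model because every
trial ties and the outcome is constant.

What the generator does **not** emulate: multi-round convergence dynamics,
communication-network topology, correlated placement of accurate
individuals in central positions, heterogeneous susceptibility, anchoring,
and attrition/missingness. Passing recovery tests therefore demonstrate
that the pipeline detects the modeled moderation at realistic scale — not
that real experiments satisfy the revision mechanism.

## Problem sizes and determinism

Monte-Carlo defaults: 2·10^4 repetitions per grid cell (se ≤ 0.0035) and
2·10^5 for single reference points (se ≈ 0.001); recovery simulations use
20 generator seeds at the default corpus scale (~16k records each). Grid
cells draw from independent substreams derived from (seed, i, j), so any
cell is reproducible in isolation. All stochastic entry points take an
explicit `numpy.random.Generator` or integer seed; given one seed, every
output — including both model fits — is deterministic.

## Known limitations

* The Laplace z-statistics and REML t-statistics are asymptotic; with very
  few studies (< 4) the study-level variance is weakly identified and
  routinely sits at the boundary (flagged, and consistent with `lme4`).
* The bound's limit classification is numeric; verdicts within the 0.05
  bands at n = 10^6 can in principle differ from the true asymptotic class
  near a critical σ.
* R compares exactly two families; data best described by neither (e.g.
  Pareto tails heavier than log-normal) still map onto the [0, 1] scale by
  relative fit.
* The trial loader expects one initial and one revised record per subject
  and trial; experiments with multiple revision rounds must be reduced to
  first/last upstream.
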