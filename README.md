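# crowdcontext

**When does centralizing social influence help or hurt the wisdom of crowds?**

A group of *n* people independently estimates a positive quantity θ (a
forecast, a count, a calorie total). After communicating, they revise. If
everyone's voice counts equally, the collective estimate is the plain average
— the classical wisdom-of-crowds aggregate. If one person dominates, the
aggregate drifts toward that person's view. `crowdcontext` implements a
framework in which *neither* structure is universally better: the answer
depends on the **estimation context** — the distribution of the initial
estimates.

## The model

Initial estimates are i.i.d. from a family
$\mathcal{F}^{\theta}_{\mu,\sigma}$ parametrized by the truth θ, a systematic
bias μ, and a dispersion/shape σ (log-normal, Pareto, log-Laplace, or
truncated normal). Influence structures are indexed by a centralization
parameter ω ∈ [0, 1] (Freeman centralization on the star/complete/lattice
network class):

$$a^n(\omega) = \omega\, a_{1} + (1-\omega)\,\tfrac1n \sum_{i=1}^{n} a_{i},$$

where agent 1 is a uniformly random "central" agent. The headline statistic
is the probability that centralization beats the equal-voice baseline on the
same draws:

$$\Omega_n(\omega, \mathcal F) = \mathbb P\left[\,|a^n(\omega) - \theta| < |a^n(0) - \theta|\,\right].$$

Ω_n > 1/2 means the context is better suited to centralized influence;
Ω_n < 1/2 favors decentralization. For positive-support distributions with
CDF *F* the package also evaluates the analytic lower bound

$$\Omega_n \ge \sup_{\beta > \theta/(1-\omega)} F(\beta)\left(1 - F(n\beta)^{\,n-1}\right),$$

whose large-*n* limit exhibits phase transitions (0 vs 1/2 vs 1) in σ for
heavy-tailed families: in a decentralized network the sample mean is
dominated by tail risk, while a randomly chosen central agent is rarely an
outlier.

On the empirical side, a task's suitability for centralization is summarized
by the **R statistic**: the normalized relative log-likelihood of a
log-normal versus a normal fit to the pooled initial estimates,
R = 1/(1 + exp(L_N − L_LN)). R ≈ 1 means decisively heavy-tailed, R ≈ 0
decisively thin-tailed. Trial-level moderation is tested with two
mixed-effects models (random intercepts by group and by study): a logistic
regression of group improvement on R (interactive groups), and a linear
regression of the within-task z-scored revised error on R, the interaction
indicator I, and R × I.

A synthetic-data generator emits experiment-shaped trial tables (studies ×
tasks × groups, initial and revised estimates, interactive and control
conditions) with a planted, recoverable moderation effect, so the entire
pipeline is testable without any external download.

## Worked example

```python
import numpy as np
import crowdcontext as cc

# A heavy-tailed, overestimating context: estimates theta*exp(mu + sigma*Z)
ctx = cc.EstimationContext("lognormal", theta=2.0, mu=1.0, sigma=1.0)
est = cc.estimate_omega(ctx, n=50, omega=1/3, reps=200_000,
                        rng=np.random.default_rng(0))
print(f"Omega_50 = {est.p_hat:.3f} +/- {est.se:.3f}")
# Omega_50 = 0.682 +/- 0.001     -> centralization helps (> 0.5)

b = cc.lower_bound(cc.EstimationContext("pareto", 2.0, 0.0, 2.0), n=50, omega=1/3)
print(f"pareto bound = {b.value:.3f}")
# pareto bound = 0.622           -> guaranteed benefit for a very heavy tail

x = np.exp(np.random.default_rng(1).normal(0, 1, 1000))
print(f"R = {cc.compute_R(x).R:.4f}")
# R = 1.0000                     -> decisively heavy-tailed sample
```

End-to-end on a synthetic corpus (4 studies, 48 tasks, 100 groups):

```console
$ crowdcontext run-all --seed 42 --out demo
logistic: b1(R) = +0.886 (z = 6.41); linear: b3(RxI) = -0.577 (t = -3.53); bundle in demo
```

A positive R coefficient in the logistic model says groups improve more
often after social interaction the heavier-tailed their task's estimates; a
negative R × I interaction says interaction lowers the revised error
precisely where R is high — together, the planted moderation, recovered.
The bundle contains `outcomes.csv`, `task_features.csv`, both model JSONs,
`marginal_effects.csv` (the two condition lines cross near R = 0.5) and a
`manifest.json` with row counts at every filter stage.

Other subcommands: `synth` (trial-table generator), `simulate-omega`
(Ω grids with bounds, optional heatmap), `bound`, `compute-r`, `analyze`
(reanalyze any trial table in the documented CSV schema; column names are
remappable via `--config`, so externally deposited datasets can be analyzed
once downloaded manually).

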