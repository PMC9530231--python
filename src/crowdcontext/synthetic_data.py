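"""Synthetic trial-table generator.

Emulates the structure of the reanalyzed laboratory experiments: several
studies, each with a panel of estimation tasks and a set of fixed groups of
participants; every participant gives an initial estimate drawn i.i.d. from
the task's estimation context and a revised estimate after (simulated) social
interaction.  Tasks alternate between thin-tailed contexts (normal around the
truth) and heavy-tailed ones (log-normal with overestimation bias), so the
per-task R feature spans its range and a moderation effect is planted by
construction: centralized revision helps on heavy-tailed tasks and hurts on
thin-tailed ones.

The revision mechanism is the minimal individual-level rule whose group mean
reproduces the centralized aggregate: each interactive group has a fixed
centralization ``omega_g`` and a uniformly chosen central member; the group
target is ``a* = omega_g * a_central + (1 - omega_g) * mean(a)`` and each
member reports ``(1 - s) * own + s * a*`` plus proportional noise.  With
``s = 1`` and no noise the collective revised estimate equals ``a*`` exactly.
Control groups do not interact: revised equals initial (optionally with tiny
noise; default none, so their effective centralization is exactly zero).

Default scale mirrors the reanalyzed corpus' printed dimensions (order 100
groups, order 50 tasks) while keeping generation fast.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .model_core import EstimationContext, Family, sample_initial_estimates

__all__ = ["SynthConfig", "default_config", "null_config",
           "generate_task_catalog", "generate_study"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration.

    Ranges are inclusive; continuous parameters are drawn uniformly from
    their range per task or per group.  ``normal_cv_range`` is the normal
    family's sigma expressed as a fraction of the truth (coefficient of
    variation), keeping thin-tailed tasks thin at every truth magnitude.
    """

    n_studies: int = 4
    tasks_per_study: int = 12
    groups_per_study: int = 25
    group_size: tuple = (4, 10)
    control_fraction: float = 0.15
    theta_range: tuple = (10.0, 1000.0)  # log-uniform
    lognormal_mu_range: tuple = (0.2, 0.8)
    lognormal_sigma_range: tuple = (0.5, 1.5)
    normal_cv_range: tuple = (0.1, 0.3)
    omega_range: tuple = (0.2, 0.6)
    susceptibility: float = 0.8
    revision_noise_sd: float = 0.05  # sd as a fraction of the group target a*
    control_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_studies", "tasks_per_study", "groups_per_study"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.group_size
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid group_size range {self.group_size}")
        if not 0.0 < self.control_fraction < 1.0:
            raise ValueError("control_fraction must lie in (0, 1)")
        n_control = self._n_control
        if n_control < 1 or n_control >= self.groups_per_study:
            raise ValueError(
                "control_fraction must yield at least one control and one "
                "interactive group per study"
            )
        if not 0.0 <= self.susceptibility <= 1.0:
            raise ValueError("susceptibility must lie in [0, 1]")
        if not 0.0 <= self.omega_range[0] <= self.omega_range[1] <= 1.0:
            raise ValueError("omega_range must lie within [0, 1]")
        if self.revision_noise_sd < 0 or self.control_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")

    @property
    def _n_control(self) -> int:
        return math.ceil(self.control_fraction * self.groups_per_study)

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(**overrides) -> SynthConfig:
    """The standard study conditions."""
    return SynthConfig(**overrides)


def null_config(**overrides) -> SynthConfig:
    """Conditions with no planted moderation: zero centralization everywhere.

    Interactive groups still revise (full susceptibility toward the plain
    group mean plus a token proportional noise), so the improvement outcome
    varies, but no group aggregate is pulled toward a central individual.
    The revision noise is set far below the smallest relative collective
    error in the task catalog: noise comparable to a group's error makes
    strict improvement genuinely *less* likely in precise (thin-tailed)
    contexts than in diffuse ones, which would plant a real moderation
    effect in a configuration meant to carry none.
    """
    base = dict(omega_range=(0.0, 0.0), susceptibility=1.0,
                revision_noise_sd=0.001)
    base.update(overrides)
    return SynthConfig(**base)


def generate_task_catalog(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-task estimation contexts, alternating thin- and heavy-tailed.

    Even task indices are thin-tailed (normal, mu = 0, sigma a small fraction
    of theta); odd indices heavy-tailed (log-normal with overestimation
    bias).  Truths are log-uniform over ``theta_range``.
    """
    rows = []
    lo, hi = np.log(cfg.theta_range[0]), np.log(cfg.theta_range[1])
    for s in range(cfg.n_studies):
        study_id = f"study{s}"
        for t in range(cfg.tasks_per_study):
            theta = float(np.exp(rng.uniform(lo, hi)))
            if t % 2 == 0:
                family = Family.NORMAL
                cv = float(rng.uniform(*cfg.normal_cv_range))
                mu, sigma, regime = 0.0, cv * theta, "thin"
            else:
                family = Family.LOGNORMAL
                mu = float(rng.uniform(*cfg.lognormal_mu_range))
                sigma = float(rng.uniform(*cfg.lognormal_sigma_range))
                regime = "heavy"
            rows.append({
                "study_id": study_id, "task_id": f"task{t:02d}", "family": family.value,
                "theta": theta, "mu": mu, "sigma": sigma, "regime": regime,
            })
    return pd.DataFrame(rows)


def generate_study(cfg: SynthConfig, seed: int) -> tuple:
    """Generate a full synthetic corpus: (trial table, ground-truth meta).

    Returns the long-format trial table (two records per subject and trial:
    initial and revised) plus a JSON-able sidecar with the per-task contexts
    and per-group condition, centralization and central-member assignments —
    the oracle for recovery tests.
    """
    rng = np.random.default_rng(seed)
    catalog = generate_task_catalog(cfg, rng)

    group_meta = []
    frames = []
    for s in range(cfg.n_studies):
        study_id = f"study{s}"
        tasks = catalog[catalog["study_id"] == study_id]
        n_groups = cfg.groups_per_study
        is_control = np.zeros(n_groups, dtype=bool)
        is_control[rng.permutation(n_groups)[: cfg._n_control]] = True
        for g in range(n_groups):
            group_id = f"g{g:03d}"
            size = int(rng.integers(cfg.group_size[0], cfg.group_size[1] + 1))
            subjects = [f"{study_id}.{group_id}.p{k:02d}" for k in range(size)]
            control = bool(is_control[g])
            omega_g = 0.0 if control else float(rng.uniform(*cfg.omega_range))
            central_idx = int(rng.integers(size))
            group_meta.append({
                "study_id": study_id, "group_id": group_id,
                "condition": "control" if control else "interactive",
                "omega": omega_g, "size": size,
                "central_subject": subjects[central_idx],
            })
            for task in tasks.itertuples(index=False):
                ctx = EstimationContext(task.family, task.theta, task.mu, task.sigma)
                a = sample_initial_estimates(ctx, size, rng)
                if control:
                    revised = a.copy()
                    if cfg.control_noise_sd > 0:
                        revised = revised + rng.normal(0.0, cfg.control_noise_sd * a)
                else:
                    s_par = cfg.susceptibility
                    target = omega_g * a[central_idx] + (1.0 - omega_g) * a.mean()
                    revised = (1.0 - s_par) * a + s_par * target
                    if cfg.revision_noise_sd > 0:
                        revised = revised + rng.normal(
                            0.0, cfg.revision_noise_sd * target, size)
                frames.append(pd.DataFrame({
                    "study_id": study_id,
                    "task_id": task.task_id,
                    "group_id": group_id,
                    "subject_id": subjects * 2,
                    "stage": ["initial"] * size + ["revised"] * size,
                    "estimate": np.concatenate([a, revised]),
                    "truth": task.theta,
                    "condition": "control" if control else "interactive",
                }))
    trials = pd.concat(frames, ignore_index=True)
    meta = {
        "seed": int(seed),
        "config": cfg.to_dict(),
        "tasks": catalog.to_dict(orient="records"),
        "groups": group_meta,
    }
    return trials, meta
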