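"""Trial-level reanalysis pipeline.

Takes long-format trial tables (individual initial and revised estimates per
study / task / group), builds collective estimates and outcomes, attaches the
per-task heavy-tailedness feature R, and fits the two mixed-effects
moderation models:

* a mixed logistic regression of group improvement on R (interactive groups
  only), random intercepts by group and by study;
* a mixed linear regression of the within-task z-scored absolute error of the
  revised collective estimate on R, the social-interaction indicator I, and
  their interaction R x I, random intercepts by group and by study.

The printed form of the logistic equation in the source methods places the
linear predictor inside ``1/(1+exp(.))`` without a minus sign, which inverts
every coefficient; this module fits the standard convention (logit of the
improvement probability) so that a positive R coefficient means "higher R,
higher probability that social interaction improves the collective estimate",
matching the reported upward trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .context_feature import DegenerateFitError, compute_R

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "IncompleteTrialError",
    "SingularDesignError",
    "DesignError",
    "TRIAL_COLUMNS",
    "MIN_ESTIMATES_FOR_R",
    "Coefficient",
    "RegressionResult",
    "load_trials",
    "validate_trials",
    "filter_positive_tasks",
    "summarize_trial",
    "summarize_trials",
    "compute_task_features",
    "attach_task_features",
    "standardize_errors",
    "fit_improvement_model",
    "fit_error_model",
    "marginal_effects",
]

TRIAL_COLUMNS = (
    "study_id", "task_id", "group_id", "subject_id",
    "stage", "estimate", "truth", "condition",
)
STAGES = ("initial", "revised")
CONDITIONS = ("interactive", "control")

# Tasks with fewer positive pooled initial estimates than this get R = NaN
# and are excluded from the moderation analysis.
MIN_ESTIMATES_FOR_R = 5

_TRIAL_KEY = ["study_id", "task_id", "group_id"]
_TASK_KEY = ["study_id", "task_id"]


class SchemaError(ValueError):
    """Input table does not conform to the trial schema."""


class IncompleteTrialError(SchemaError):
    """A trial lacks initial or revised records."""


class DesignError(ValueError):
    """The outcome table cannot support the requested model."""


class SingularDesignError(DesignError):
    """Design matrix is singular (e.g. the moderator is constant)."""


# ---------------------------------------------------------------------------
# Loading and validation


def load_trials(path, mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a long-format trial table from CSV.

    ``mapping`` renames file columns to the canonical schema
    (canonical name -> column name in the file), so deposits with different
    header dialects load without editing the file.
    """
    df = pd.read_csv(path)
    if mapping:
        rename = {src: canon for canon, src in mapping.items()}
        missing_src = [src for src in rename if src not in df.columns]
        if missing_src:
            raise SchemaError(f"mapped columns absent from file: {missing_src}")
        df = df.rename(columns=rename)
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, dtypes and the one-initial/one-revised structure."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.loc[:, list(TRIAL_COLUMNS)].copy()

    est = pd.to_numeric(df["estimate"], errors="coerce")
    bad = df.index[est.isna() & df["estimate"].notna()]
    if len(bad):
        raise SchemaError(f"non-numeric estimates at rows {list(bad[:10])}")
    if est.isna().any():
        raise SchemaError(f"missing estimates at rows {list(df.index[est.isna()][:10])}")
    df["estimate"] = est.astype(float)

    truth = pd.to_numeric(df["truth"], errors="coerce")
    if truth.isna().any() or (truth <= 0).any():
        raise SchemaError("truth must be a positive number on every row")
    df["truth"] = truth.astype(float)
    n_truth = df.groupby(_TASK_KEY)["truth"].nunique()
    if (n_truth > 1).any():
        raise SchemaError(
            f"truth not constant within task: {list(n_truth[n_truth > 1].index[:5])}"
        )

    for col, allowed in (("stage", STAGES), ("condition", CONDITIONS)):
        bad_vals = set(df[col].unique()) - set(allowed)
        if bad_vals:
            raise SchemaError(f"invalid {col} values: {sorted(map(str, bad_vals))}")

    counts = (
        df.groupby(_TRIAL_KEY + ["subject_id", "stage"], observed=True)
        .size()
        .unstack("stage", fill_value=0)
    )
    for stage in STAGES:
        if stage not in counts.columns:
            raise IncompleteTrialError(f"no '{stage}' records in table")
    problems = counts[(counts["initial"] != 1) | (counts["revised"] != 1)]
    if len(problems):
        raise SchemaError(
            "each (study, task, group, subject) needs exactly one initial and "
            f"one revised record; offenders: {list(problems.index[:5])}"
        )
    return df


def filter_positive_tasks(df: pd.DataFrame) -> pd.DataFrame:
    """Drop every record of any task containing a negative estimate.

    Task-level omission: a single negative estimate removes the whole task.
    Zero estimates pass this filter (they are dropped later by the positivity
    requirement of the log-normal fit).
    """
    has_neg = df.groupby(_TASK_KEY)["estimate"].transform("min") < 0
    n_tasks = df.loc[has_neg, _TASK_KEY].drop_duplicates().shape[0]
    if n_tasks:
        logger.info("filter_positive_tasks: removed %d task(s) with negative estimates", n_tasks)
    out = df.loc[~has_neg].copy()
    if out.empty:
        warnings.warn("all tasks removed by the negative-estimate filter", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Collective estimates and outcomes


def summarize_trial(records: pd.DataFrame) -> pd.Series:
    """Outcome of a single trial (one group answering one task).

    The collective initial/revised estimates are the group means of the
    individual estimates at each stage; improvement requires the revised
    absolute error to be *strictly* smaller (a tie is not improvement).
    """
    out = summarize_trials(records)
    if len(out) != 1:
        raise ValueError(f"expected records of exactly one trial, found {len(out)}")
    return out.iloc[0]


def summarize_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trial outcomes for a full trial table."""
    stages = df.groupby(_TRIAL_KEY + ["stage"], observed=True)["estimate"].mean().unstack("stage")
    if "revised" not in stages.columns or stages["revised"].isna().any():
        bad = [] if "revised" not in stages.columns else list(
            stages.index[stages["revised"].isna()][:5])
        raise IncompleteTrialError(f"trials without revised records: {bad}")
    if "initial" not in stages.columns or stages["initial"].isna().any():
        raise IncompleteTrialError("trials without initial records present")
    meta = df.groupby(_TRIAL_KEY, observed=True)[["truth", "condition"]].first()
    out = stages.join(meta).reset_index()
    out = out.rename(columns={"initial": "collective_initial", "revised": "collective_revised"})
    out["abs_err_initial"] = (out["collective_initial"] - out["truth"]).abs()
    out["abs_err_revised"] = (out["collective_revised"] - out["truth"]).abs()
    out["improved"] = (out["abs_err_revised"] < out["abs_err_initial"]).astype(int)
    out["I"] = (out["condition"] == "interactive").astype(int)
    return out


def compute_task_features(df: pd.DataFrame) -> pd.DataFrame:
    """Per-task R from the pooled initial estimates of all groups.

    Pooling is within study (a task id appearing in two studies is two
    estimation contexts).  Tasks with fewer than ``MIN_ESTIMATES_FOR_R``
    positive initial estimates, or with a degenerate (constant) pool, get
    R = NaN; dropped zero/negative estimates are logged.
    """
    rows = []
    init = df[df["stage"] == "initial"]
    for key, grp in init.groupby(_TASK_KEY, observed=True):
        x = grp["estimate"].to_numpy(dtype=float)
        pos = x[x > 0]
        if len(pos) < len(x):
            logger.info("task %s: dropped %d non-positive initial estimates from the R pool",
                        key, len(x) - len(pos))
        rec = {"study_id": key[0], "task_id": key[1], "n_obs": len(pos)}
        if len(pos) < MIN_ESTIMATES_FOR_R:
            logger.info("task %s: only %d positive estimates (< %d), R = NaN",
                        key, len(pos), MIN_ESTIMATES_FOR_R)
            rec.update(R=np.nan, loglik_lognormal=np.nan, loglik_normal=np.nan,
                       meanlog=np.nan, sdlog=np.nan, mean=np.nan, sd=np.nan)
        else:
            try:
                feat = compute_R(pos, task_id=key)
            except DegenerateFitError:
                logger.info("task %s: degenerate estimate pool, R = NaN", key)
                rec.update(R=np.nan, loglik_lognormal=np.nan, loglik_normal=np.nan,
                           meanlog=np.nan, sdlog=np.nan, mean=np.nan, sd=np.nan)
            else:
                logx = np.log(pos)
                rec.update(
                    R=feat.R,
                    loglik_lognormal=feat.loglik_lognormal,
                    loglik_normal=feat.loglik_normal,
                    meanlog=float(logx.mean()), sdlog=float(logx.std(ddof=0)),
                    mean=float(pos.mean()), sd=float(pos.std(ddof=0)),
                )
        rows.append(rec)
    return pd.DataFrame(rows)


def attach_task_features(df: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Merge each task's R onto its outcome records; drop tasks with R = NaN."""
    feats = compute_task_features(df)[_TASK_KEY + ["R"]]
    merged = outcomes.merge(feats, on=_TASK_KEY, how="left", validate="many_to_one")
    n_drop = int(merged["R"].isna().sum())
    if n_drop:
        logger.info("attach_task_features: excluded %d outcome record(s) without R", n_drop)
    return merged[merged["R"].notna()].reset_index(drop=True)


def standardize_errors(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Within-task z-score of the revised collective absolute error.

    Uses all trials of a task (both conditions) with sd on divisor n-1, so
    errors are comparable across tasks whose truths differ by orders of
    magnitude.  Single-trial and zero-sd tasks are excluded (logged).
    """
    grp = outcomes.groupby(_TASK_KEY, observed=True)["abs_err_revised"]
    n = grp.transform("count")
    mean = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=1))
    ok = (n >= 2) & (sd > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("standardize_errors: excluded %d record(s) from single-trial or "
                    "zero-variance tasks", n_excluded)
    out = outcomes.loc[ok].copy()
    out["z_err"] = (out["abs_err_revised"] - mean[ok]) / sd[ok]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Mixed-effects models


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    se: float
    stat: float  # z (logistic) or t (linear)
    pvalue: float


@dataclass(frozen=True)
class RegressionResult:
    """Fixed effects and variance components of one fitted mixed model."""

    model: str  # "logistic" | "linear"
    coefficients: dict
    random_effects_var: dict
    residual_var: float | None
    n_obs: int
    converged: bool = True
    flags: tuple = ()
    fe_names: tuple = ()
    fe_cov: np.ndarray | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coefficients": {
                k: {"estimate": c.estimate, "se": c.se, "stat": c.stat, "pvalue": c.pvalue}
                for k, c in self.coefficients.items()
            },
            "random_effects_var": dict(self.random_effects_var),
            "residual_var": self.residual_var,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "flags": list(self.flags),
        }


def _as_model_frame(outcomes: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    d = outcomes.loc[:, list(dict.fromkeys(list(cols) + ["study_id", "group_id"]))].copy()
    d["study_id"] = d["study_id"].astype(str)
    # group ids are only unique within study in typical deposits
    d["group_id"] = d["study_id"] + "/" + d["group_id"].astype(str)
    return d.reset_index(drop=True)


def _check_design(d: pd.DataFrame) -> None:
    if d["study_id"].nunique() < 2:
        raise DesignError("need at least 2 studies for a study random intercept")
    if d["R"].nunique() < 2:
        raise SingularDesignError("R is constant across tasks; the moderation design is singular")


def _separation_flags(d: pd.DataFrame) -> tuple:
    """Detect quasi-complete separation of improvement by the scalar R."""
    r0 = d.loc[d["improved"] == 0, "R"]
    r1 = d.loc[d["improved"] == 1, "R"]
    if len(r0) == 0 or len(r1) == 0:
        return ("constant_outcome",)
    if r0.max() < r1.min() or r1.max() < r0.min():
        return ("quasi_separation",)
    return ()


def fit_improvement_model(outcomes: pd.DataFrame) -> RegressionResult:
    """Mixed logistic regression of improvement on R (interactive groups only).

    Random intercepts by group and by study; fitted by the Laplace (MAP)
    approximation of statsmodels' Bayesian mixed GLM, which is deterministic
    given the data and whose curvature-based standard errors are well
    calibrated (mean-field variational fits understate them).  The reported
    statistic for each fixed effect is estimate/SE, a z-statistic.
    """
    d = _as_model_frame(outcomes[outcomes["I"] == 1], ["improved", "R"])
    if d.empty:
        raise DesignError("no interactive groups in the outcome table")
    _check_design(d)
    flags = _separation_flags(d)
    if "constant_outcome" in flags:
        raise DesignError("improvement outcome is constant; logistic model is degenerate")

    model = BinomialBayesMixedGLM.from_formula(
        "improved ~ R",
        vc_formulas={"study": "0 + C(study_id)", "group": "0 + C(group_id)"},
        data=d,
    )
    converged = True
    # statsmodels draws the optimizer's random-effect start values from the
    # global legacy generator; pin it locally so the fit is deterministic.
    state = np.random.get_state()
    try:
        np.random.seed(20220551)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = model.fit_map()
    finally:
        np.random.set_state(state)
    re_var = {
        name: float(np.exp(2.0 * m))  # vcp parameters are log standard deviations
        for name, m in zip(model.vcp_names, fit.vcp_mean)
    }
    # A variance component collapsing to zero puts its log-sd at the edge of
    # the parameter space; the optimizer's gradient test then fires even
    # though the mode is genuine (lme4 reports the same fits as singular).
    boundary = any(v < 1e-6 for v in re_var.values())
    if boundary:
        flags = flags + ("boundary_variance",)
    if any("did not converge" in str(w.message) for w in caught) and not boundary:
        converged = False

    k_fe = len(model.exog_names)
    fe_cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
    fe_se = np.sqrt(np.diag(fe_cov))
    coefs = {}
    for name, est, se in zip(model.exog_names, fit.fe_mean, fe_se):
        z = float(est / se)
        coefs[name] = Coefficient(float(est), float(se), z, float(2 * sps.norm.sf(abs(z))))
    return RegressionResult(
        model="logistic", coefficients=coefs, random_effects_var=re_var,
        residual_var=None, n_obs=len(d), converged=converged, flags=flags,
        fe_names=tuple(model.exog_names), fe_cov=fe_cov,
    )


def fit_error_model(outcomes: pd.DataFrame) -> RegressionResult:
    """Mixed linear regression: z_err ~ R + I + R:I, random intercepts by
    group and by study, fitted by REML.

    A negative interaction coefficient means the revised-estimate error falls
    with R under social interaction, i.e. centralization helps more the
    heavier-tailed the estimation context.
    """
    if "z_err" not in outcomes.columns:
        raise DesignError("outcomes lack z_err; run standardize_errors first")
    d = _as_model_frame(outcomes, ["z_err", "R", "I"])
    d = d[np.isfinite(d["z_err"])]
    if d["I"].nunique() < 2:
        raise DesignError("both interactive and control groups are required")
    _check_design(d)

    model = MixedLM.from_formula(
        "z_err ~ R * I",
        groups="study_id",
        re_formula="1",
        vc_formula={"group": "0 + C(group_id)"},
        data=d,
    )
    # Powell is derivative-free and handles the frequent boundary case
    # (a variance component at zero) where gradient methods stall.
    flags: tuple = ()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        fit = model.fit(reml=True, method="powell", maxiter=2000)
    if any("boundary" in str(w.message).lower() for w in caught):
        flags = ("boundary_variance",)
    converged = bool(getattr(fit, "converged", True))

    k_fe = model.k_fe
    names = list(fit.params.index[:k_fe])
    coefs = {
        name: Coefficient(
            float(fit.params[name]), float(fit.bse[name]),
            float(fit.tvalues[name]), float(fit.pvalues[name]),
        )
        for name in names
    }
    re_var = {
        "study": float(np.asarray(fit.cov_re)[0, 0]),
        "group": float(fit.vcomp[0]),
    }
    return RegressionResult(
        model="linear", coefficients=coefs, random_effects_var=re_var,
        residual_var=float(fit.scale), n_obs=len(d), converged=converged,
        flags=flags, fe_names=tuple(names), fe_cov=np.asarray(fit.cov_params())[:k_fe, :k_fe],
    )


def marginal_effects(result: RegressionResult, r_grid=None) -> pd.DataFrame:
    """Predicted z_err over an R grid for each condition, with 95% CIs.

    Evaluates the fixed-effects surface of the linear model at I = 0 and
    I = 1; the crossing of the two lines marks the R value at which the
    advantage flips between decentralized and centralized influence.
    """
    if result.model != "linear":
        raise ValueError("marginal effects are defined for the linear error model")
    if r_grid is None:
        r_grid = np.linspace(0.0, 1.0, 21)
    r_grid = np.asarray(r_grid, dtype=float)
    names = list(result.fe_names)
    rows = []
    for i_val in (0, 1):
        design = np.zeros((r_grid.size, len(names)))
        for k, name in enumerate(names):
            if name == "Intercept":
                design[:, k] = 1.0
            elif name == "R":
                design[:, k] = r_grid
            elif name == "I":
                design[:, k] = i_val
            elif name in ("R:I", "I:R"):
                design[:, k] = i_val * r_grid
            else:  # pragma: no cover
                raise ValueError(f"unexpected fixed effect {name}")
        beta = np.array([result.coefficients[n].estimate for n in names])
        pred = design @ beta
        var = np.einsum("ij,jk,ik->i", design, result.fe_cov, design)
        half = 1.959963984540054 * np.sqrt(np.maximum(var, 0.0))
        for r, p, h in zip(r_grid, pred, half):
            rows.append({"condition": "interactive" if i_val else "control",
                         "R": float(r), "predicted_z_err": float(p),
                         "ci_low": float(p - h), "ci_high": float(p + h)})
    return pd.DataFrame(rows)
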