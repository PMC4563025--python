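"""Constrained least-squares fitting and comparison of the learning models.

Each model variant is fit per participant by minimising the total squared
difference between the participant's stated predictions and the model's
prediction sequence, with the model's first prediction initialised to the
participant's first prediction in every condition. Optimisation is bounded
multi-start L-BFGS-B (Latin-hypercube starts). Model comparison uses the
least-squares Gaussian forms of AIC/BIC

    AIC = n ln(SSE/n) + 2k,    BIC = n ln(SSE/n) + k ln n,

aggregated over participants, plus likelihood-ratio tests for nested pairs
with the per-participant statistic LR = n ln(SSE_restricted / SSE_full) and
degrees of freedom summed across participants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .models import ModelParams, predict_sequence, running_sd_sequence

__all__ = [
    "ModelSpec",
    "MODELS",
    "FitConfig",
    "FitResult",
    "ComparisonResult",
    "ConditionData",
    "participant_conditions",
    "sse_objective",
    "fit_model",
    "fit_cohort",
    "information_criteria",
    "likelihood_ratio_test",
    "compare_models",
    "is_nested",
]

SD_LEVELS = ("small", "medium", "large")

#: Epsilon floor guarding log(SSE) for perfect (noise-free) fits.
SSE_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of one model variant."""

    name: str
    dynamic: bool  # eta free (Pearce-Hall) vs eta = 0 (Rescorla-Wagner)
    per_sd_alpha: bool  # one initial learning rate per SD level
    scaling: str  # none | linear | log
    nu_free: bool  # free adaptation index vs fixed nu = 1
    label: str = ""

    @property
    def adaptive(self) -> bool:
        return self.scaling != "none"


MODELS: dict[str, ModelSpec] = {
    m.name: m
    for m in [
        ModelSpec("rw", False, False, "none", False, "RW"),
        ModelSpec("rw-sd", False, True, "none", False, "RW, SD-specific alpha"),
        ModelSpec("ph", True, False, "none", False, "PH"),
        ModelSpec("ph-sd", True, True, "none", False, "PH, SD-specific alpha1"),
        ModelSpec("aph-lin-nu1", True, False, "linear", False, "Linear adaptive PH, nu=1"),
        ModelSpec("aph-log-nu1", True, False, "log", False, "Log adaptive PH, nu=1"),
        ModelSpec("aph-lin", True, False, "linear", True, "Linear adaptive PH, free nu"),
        ModelSpec("aph-log", True, False, "log", True, "Log adaptive PH, free nu"),
    ]
}

# Nesting partial order used for likelihood-ratio tests: value = models the
# key can be restricted to. Mirrors the comparison layout of the model-fit
# table (the per-SD-alpha models are treated as restrictions of the adaptive
# models there even though that pair is not strictly parametric).
_NESTED_IN: dict[str, set[str]] = {
    "rw": set(),
    "rw-sd": {"rw"},
    "ph": {"rw"},
    "ph-sd": {"rw", "rw-sd", "ph"},
    "aph-lin-nu1": {"rw", "ph", "ph-sd"},
    "aph-log-nu1": {"rw", "ph", "ph-sd"},
    "aph-lin": {"rw", "ph", "ph-sd", "aph-lin-nu1"},
    "aph-log": {"rw", "ph", "ph-sd", "aph-log-nu1"},
}


def is_nested(restricted: str, full: str) -> bool:
    return restricted in _NESTED_IN.get(full, set())


@dataclass(frozen=True)
class FitConfig:
    """Fitting options: model, trial mask, bounds and multi-start control.

    ``trial_mask`` is the inclusive 1-based range of condition-local trials
    entering the SSE. The default (2, 42) drops trial 1, whose residual is
    identically zero under the first-prediction initialisation.
    ``empirical_sigma`` replaces the fitted initial expected SD with the
    sample SD of each condition's first two rewards and starts the mask at
    trial 3 (the BIC re-fit variant).
    """

    model: str = "ph"
    trial_mask: tuple[int, int] = (2, 42)
    empirical_sigma: bool = False
    pooled: bool = False
    n_starts: int = 10
    seed: int = 0
    nu_bound: float = 1.0  # upper bound; set higher to unconstrain
    sigma_bounds: tuple[float, float] = (0.5, 50.0)
    maxiter: int = 300

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        lo, hi = self.trial_mask
        if not (1 <= lo <= hi <= 42):
            raise ValueError("trial_mask must lie within 1..42")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    @property
    def spec(self) -> ModelSpec:
        return MODELS[self.model]

    def effective_mask(self) -> tuple[int, int]:
        lo, hi = self.trial_mask
        if self.empirical_sigma:
            lo = max(lo, 3)
        return lo, hi


@dataclass(frozen=True)
class ConditionData:
    """One condition's reward and prediction sequences for a participant."""

    condition_id: str
    sd_level: str
    sd_target: float
    ev: float
    rewards: tuple[float, ...]
    predictions: tuple[float, ...]

    def __post_init__(self):
        if len(self.rewards) != len(self.predictions):
            raise ValueError(
                f"{self.condition_id}: {len(self.rewards)} rewards vs "
                f"{len(self.predictions)} predictions"
            )


def participant_conditions(df: pd.DataFrame) -> list[ConditionData]:
    """Split one participant's tidy trial table into ConditionData blocks."""
    conds = []
    for cid, grp in df.groupby("condition_id", sort=True):
        grp = grp.sort_values("trial_in_condition")
        conds.append(
            ConditionData(
                condition_id=str(cid),
                sd_level=str(grp["sd_level"].iloc[0]),
                sd_target=float(grp["sd_target"].iloc[0]),
                ev=float(grp["ev"].iloc[0]),
                rewards=tuple(float(r) for r in grp["reward"]),
                predictions=tuple(float(p) for p in grp["prediction"]),
            )
        )
    return conds


@dataclass
class FitResult:
    """Best-fit parameters with goodness-of-fit summaries."""

    model: str
    params: ModelParams
    theta: dict[str, float]
    sse: float
    n_obs: int
    k: int
    loglik: float
    aic: float
    bic: float
    converged: bool
    start_values: tuple[float, ...]

    def to_dict(self) -> dict:
        out = {"model": self.model, "sse": self.sse, "n_obs": self.n_obs, "k": self.k,
               "loglik": self.loglik, "aic": self.aic, "bic": self.bic,
               "converged": self.converged}
        out.update(self.theta)
        return out


def _param_layout(spec: ModelSpec, config: FitConfig, levels: tuple[str, ...]):
    """Parameter names and box bounds for the optimisation vector."""
    names: list[str] = []
    bounds: list[tuple[float, float]] = []
    if spec.per_sd_alpha:
        for lv in levels:
            names.append(f"alpha1[{lv}]")
            bounds.append((0.0, 1.0))
    else:
        names.append("alpha1")
        bounds.append((0.0, 1.0))
    if spec.dynamic:
        names.append("eta")
        bounds.append((0.0, 1.0))
    if spec.adaptive and spec.nu_free:
        names.append("nu")
        bounds.append((0.0, config.nu_bound))
    if spec.adaptive and not config.empirical_sigma:
        for lv in levels:
            names.append(f"sigma[{lv}]")
            bounds.append(config.sigma_bounds)
    return names, bounds


def _theta_to_params(theta, names, spec: ModelSpec, config: FitConfig, levels) -> ModelParams:
    d = dict(zip(names, theta))
    if spec.per_sd_alpha:
        alpha1 = {lv: d[f"alpha1[{lv}]"] for lv in levels}
    else:
        alpha1 = d["alpha1"]
    eta = d.get("eta", 0.0)
    if spec.adaptive:
        nu = d["nu"] if spec.nu_free else 1.0
        if config.empirical_sigma:
            sigma = 1.0  # placeholder: empirical per-condition SDs live in the data
        else:
            sigma = {lv: d[f"sigma[{lv}]"] for lv in levels}
    else:
        nu, sigma = 0.0, 1.0
    return ModelParams(
        alpha1=alpha1,
        eta=eta,
        nu=nu,
        sigma_init=sigma,
        scaling=spec.scaling,
        nu_fixed=spec.adaptive and not spec.nu_free,
        nu_unconstrained=config.nu_bound > 1.0,
    )


def _prepare(conds: list[ConditionData], config: FitConfig):
    """Precompute per-condition reward lists, running SDs and mask slices."""
    lo, hi = config.effective_mask()
    prepared = []
    for c in conds:
        T = len(c.rewards)
        i0, i1 = lo - 1, min(hi, T)
        if i0 >= i1:
            raise ValueError(f"trial mask {config.trial_mask} excludes every trial")
        sd_tail = running_sd_sequence(c.rewards)
        if config.empirical_sigma:
            sigma_emp = float(np.std(c.rewards[:2], ddof=1))
            sigma_emp = max(sigma_emp, 1e-6)
        else:
            sigma_emp = None
        prepared.append(
            (
                list(c.rewards),
                np.asarray(c.predictions, float),
                c.sd_level,
                sd_tail,
                sigma_emp,
                (i0, i1),
            )
        )
    return prepared


def _sse_prepared(theta, names, spec: ModelSpec, config: FitConfig, prepared) -> float:
    d = dict(zip(names, theta))
    eta = d.get("eta", 0.0)
    nu = (d["nu"] if spec.nu_free else 1.0) if spec.adaptive else 0.0
    total = 0.0
    for rewards, obs, level, sd_tail, sigma_emp, (i0, i1) in prepared:
        alpha1 = d[f"alpha1[{level}]"] if spec.per_sd_alpha else d["alpha1"]
        if spec.adaptive:
            sigma = sigma_emp if config.empirical_sigma else d[f"sigma[{level}]"]
        else:
            sigma = 1.0
        preds = predict_sequence(
            rewards, alpha1, eta, nu, sigma, spec.scaling, obs[0], sd_tail
        )
        seg = obs[i0:i1] - np.asarray(preds[i0:i1])
        total += float(seg @ seg)
    return total


def sse_objective(params: ModelParams, conds: list[ConditionData], config: FitConfig) -> float:
    """Total squared deviation between observed and modelled predictions.

    The model's first prediction is the participant's first prediction in
    each condition; only trials inside the config's mask contribute.
    """
    spec = config.spec
    prepared = _prepare(conds, config)
    total = 0.0
    for rewards, obs, level, sd_tail, sigma_emp, (i0, i1) in prepared:
        alpha1, sigma = params.resolve(level)
        if config.empirical_sigma and spec.adaptive:
            sigma = sigma_emp
        preds = predict_sequence(
            rewards, alpha1, params.eta, params.nu, sigma, params.scaling, obs[0], sd_tail
        )
        seg = obs[i0:i1] - np.asarray(preds[i0:i1])
        total += float(seg @ seg)
    return total


def information_criteria(sse: float, n_obs: int, k: int) -> tuple[float, float, float]:
    """(loglik, AIC, BIC) under the Gaussian concentrated likelihood.

    A zero SSE (perfect fit) is floored at a small epsilon so the log is
    defined; the resulting criteria are then extremely negative, as a
    perfect fit should be.
    """
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    sse = max(float(sse), SSE_FLOOR)
    loglik = -n_obs / 2.0 * (math.log(2.0 * math.pi * sse / n_obs) + 1.0)
    aic = n_obs * math.log(sse / n_obs) + 2 * k
    bic = n_obs * math.log(sse / n_obs) + k * math.log(n_obs)
    return loglik, aic, bic


def _mask_count(conds, config) -> int:
    lo, hi = config.effective_mask()
    return sum(max(0, min(hi, len(c.rewards)) - (lo - 1)) for c in conds)


def fit_model(conds: list[ConditionData], config: FitConfig) -> FitResult:
    """Multi-start bounded least-squares fit of one model to one participant."""
    spec = config.spec
    levels = tuple(lv for lv in SD_LEVELS if any(c.sd_level == lv for c in conds))
    if not levels:
        levels = tuple(sorted({c.sd_level for c in conds}))
    names, bounds = _param_layout(spec, config, levels)
    prepared = _prepare(conds, config)
    lob = np.array([b[0] for b in bounds])
    upb = np.array([b[1] for b in bounds])

    sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
    # manual affine scaling: tolerates degenerate (equal) bounds
    starts = lob + sampler.random(config.n_starts) * (upb - lob)

    def obj(theta):
        return _sse_prepared(theta, names, spec, config, prepared)

    best = None
    best_start = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best, best_start = res, x0
    if not any_success:
        warnings.warn(f"no optimiser start converged for model {spec.name}")

    theta = dict(zip(names, (float(v) for v in best.x)))
    params = _theta_to_params(best.x, names, spec, config, levels)
    n_obs = _mask_count(conds, config)
    k = len(names)
    loglik, aic, bic = information_criteria(best.fun, n_obs, k)
    return FitResult(
        model=spec.name,
        params=params,
        theta=theta,
        sse=float(best.fun),
        n_obs=n_obs,
        k=k,
        loglik=loglik,
        aic=aic,
        bic=bic,
        converged=any_success,
        start_values=tuple(float(v) for v in best_start),
    )


def fit_cohort(
    dataset: pd.DataFrame, config: FitConfig
) -> dict[object, FitResult] | FitResult:
    """Fit one model to every participant (or pooled across participants).

    ``dataset`` is the tidy trial table. A pooled fit shares one parameter
    set across participants by concatenating their conditions into a single
    objective (each condition still initialised to its own first prediction).
    """
    groups = {pid: participant_conditions(g) for pid, g in dataset.groupby("participant_id")}
    if config.pooled:
        conds = [c for cs in groups.values() for c in cs]
        return fit_model(conds, config)
    return {pid: fit_model(conds, config) for pid, conds in groups.items()}


@dataclass
class ComparisonResult:
    """Likelihood-ratio comparison of a nested model pair."""

    restricted: str
    full: str
    lr_per_participant: np.ndarray
    df_per_participant: int
    lr: float
    df: int
    p_value: float
    d_aic: float
    d_bic: float

    def __str__(self) -> str:
        return (
            f"{self.full} vs {self.restricted}: dAIC={self.d_aic:.2f}, "
            f"chi2({self.df})={self.lr:.2f}, p={self.p_value:.3g}"
        )


def likelihood_ratio_test(
    restricted: FitResult | list[FitResult], full: FitResult | list[FitResult]
) -> ComparisonResult:
    """Nested LR test; per-participant statistics and dfs are summed."""
    rs = [restricted] if isinstance(restricted, FitResult) else list(restricted)
    fs = [full] if isinstance(full, FitResult) else list(full)
    if len(rs) != len(fs):
        raise ValueError("restricted and full fit lists differ in length")
    lrs = []
    for r, f in zip(rs, fs):
        if r.n_obs != f.n_obs:
            raise ValueError("restricted and full fits use different data masks")
        if f.sse > r.sse + 1e-9:
            warnings.warn(
                f"full model {f.model} fits worse than {r.model} "
                f"(SSE {f.sse:.4g} > {r.sse:.4g}); LR clamped at 0"
            )
        lr = r.n_obs * math.log(max(r.sse, SSE_FLOOR) / max(f.sse, SSE_FLOOR))
        lrs.append(max(lr, 0.0))
    df_each = fs[0].k - rs[0].k
    if df_each <= 0:
        raise ValueError("full model must have more free parameters than restricted")
    lr_total = float(np.sum(lrs))
    df_total = df_each * len(fs)
    p = float(stats.chi2.sf(lr_total, df_total)) if lr_total > 0 else 1.0
    return ComparisonResult(
        restricted=rs[0].model,
        full=fs[0].model,
        lr_per_participant=np.asarray(lrs),
        df_per_participant=df_each,
        lr=lr_total,
        df=df_total,
        p_value=p,
        d_aic=float(sum(f.aic for f in fs) - sum(r.aic for r in rs)),
        d_bic=float(sum(f.bic for f in fs) - sum(r.bic for r in rs)),
    )


def compare_models(
    dataset: pd.DataFrame,
    models: list[str],
    config: FitConfig | None = None,
    criterion: str = "aic",
) -> dict:
    """Fit several models to a cohort and tabulate the comparisons.

    Returns a dict with per-participant fit table, aggregated criterion
    differences (full minus restricted, lower = better for the row model),
    per-participant best-model counts, and LR tests for nested pairs.
    """
    if not models:
        raise ValueError("need at least one model")
    config = config or FitConfig()
    fits: dict[str, dict] = {}
    for m in models:
        fits[m] = fit_cohort(dataset, replace(config, model=m))
    pids = sorted(next(iter(fits.values())).keys(), key=str)

    rows = []
    for m in models:
        for pid in pids:
            rows.append({"participant_id": pid, **fits[m][pid].to_dict()})
    fit_table = pd.DataFrame(rows)

    agg = {m: sum(f.aic if criterion == "aic" else f.bic for f in fits[m].values()) for m in models}
    d_matrix = pd.DataFrame(
        [[agg[a] - agg[b] for b in models] for a in models], index=models, columns=models
    )

    crit_col = "aic" if criterion == "aic" else "bic"
    best_counts = (
        fit_table.loc[fit_table.groupby("participant_id")[crit_col].idxmin(), "model"]
        .value_counts()
        .reindex(models, fill_value=0)
    )

    lrts = []
    for r in models:
        for f in models:
            if is_nested(r, f):
                lrts.append(
                    likelihood_ratio_test(
                        [fits[r][pid] for pid in pids], [fits[f][pid] for pid in pids]
                    )
                )
    return {
        "fits": fits,
        "fit_table": fit_table,
        "aggregated": agg,
        "d_matrix": d_matrix,
        "best_counts": best_counts,
        "lr_tests": lrts,
    }
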