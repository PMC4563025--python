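"""Synthetic participant cohorts for full-pipeline tests and recovery.

No trial-level human data accompany the task, so cohorts are generated
forward from the learning models: each synthetic participant gets a
counterbalanced task design, a parameter draw (adaptation index nu from a
truncated Normal(0.5133, 0.3495) on [0, 1], matching the fitted cohort
distribution the task was reported with; decay eta ~ Beta(2, 6); initial
learning rate alpha1 ~ Beta(3, 3)), and states the model's prediction plus
Gaussian response noise (default SD 3 points), rounded and clipped to the
0-100 scale. First predictions start near mid-scale, ~N(50, 5). A fifth of
trials are flagged as unannounced control trials and paid by prediction
accuracy; the rest pay 10% of the drawn reward.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from . import task as task_mod
from .fitting import MODELS, FitConfig, fit_cohort
from .models import ModelParams, simulate_adaptive_ph

__all__ = [
    "CohortSpec",
    "ParticipantTruth",
    "control_trial_payoff",
    "generate_participant",
    "generate_cohort",
    "parameter_recovery",
    "model_recovery_confusion",
    "RecoveryReport",
]

N_SESSION_ORDERS = 6


def control_trial_payoff(prediction: float, ev: float, sd: float) -> float:
    """Payoff (GBP) of an unannounced control trial.

    Within 1 SD of the EV: 7.50; more than 1 but less than 2 SDs: 5.00;
    otherwise 2.50.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    dev = abs(prediction - ev)
    if dev <= sd:
        return 7.50
    if dev < 2 * sd:
        return 5.00
    return 2.50


MAIN_TRIAL_PAYOFF_FRACTION = 0.10
CONTROL_FRACTION = 0.20


@dataclass(frozen=True)
class CohortSpec:
    """Generating conditions for a synthetic cohort."""

    n_participants: int = 31
    model: str = "aph-log"
    nu_mean: float = 0.5133
    nu_sd: float = 0.3495
    nu_bounds: tuple[float, float] = (0.0, 1.0)
    eta_a: float = 2.0
    eta_b: float = 6.0
    alpha_a: float = 3.0
    alpha_b: float = 3.0
    noise_sd: float = 3.0
    first_prediction_mean: float = 50.0
    first_prediction_sd: float = 5.0
    round_predictions: bool = True
    control_fraction: float = CONTROL_FRACTION
    #: Number of "exaggerated scalers": members whose nu is drawn uniformly
    #: from ``exaggerated_range`` instead of the truncated Normal (the
    #: study's unconstrained re-fit found 7 of 31 scaling beyond the log SD).
    n_exaggerated: int = 0
    exaggerated_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")


@dataclass(frozen=True)
class ParticipantTruth:
    participant_id: int
    model: str
    alpha1: float
    eta: float
    nu: float

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "model": self.model,
            "alpha1": self.alpha1,
            "eta": self.eta,
            "nu": self.nu,
        }


def _sample_params(spec: CohortSpec, rng: np.random.Generator, exaggerated: bool = False) -> dict:
    m = MODELS[spec.model]
    alpha1 = float(rng.beta(spec.alpha_a, spec.alpha_b))
    eta = float(rng.beta(spec.eta_a, spec.eta_b)) if m.dynamic else 0.0
    if m.adaptive and m.nu_free:
        if exaggerated:
            nu = float(rng.uniform(*spec.exaggerated_range))
        else:
            lo, hi = spec.nu_bounds
            a = (lo - spec.nu_mean) / spec.nu_sd
            b = (hi - spec.nu_mean) / spec.nu_sd
            nu = float(
                stats.truncnorm.rvs(a, b, loc=spec.nu_mean, scale=spec.nu_sd, random_state=rng)
            )
    elif m.adaptive:
        nu = 1.0
    else:
        nu = 0.0
    return {"alpha1": alpha1, "eta": eta, "nu": nu}


def _model_params(spec: CohortSpec, truth: dict, sigma_by_level: dict) -> ModelParams:
    m = MODELS[spec.model]
    return ModelParams(
        alpha1=truth["alpha1"],
        eta=truth["eta"],
        nu=truth["nu"],
        sigma_init=sigma_by_level if m.adaptive else 1.0,
        scaling=m.scaling,
        nu_fixed=m.adaptive and not m.nu_free,
        nu_unconstrained=truth["nu"] > 1.0,
    )


def generate_participant(
    design: task_mod.TaskDesign,
    params: ModelParams,
    noise_sd: float,
    rng: np.random.Generator,
    participant_id: int = 0,
    first_prediction_mean: float = 50.0,
    first_prediction_sd: float = 5.0,
    round_predictions: bool = True,
    control_fraction: float = CONTROL_FRACTION,
) -> pd.DataFrame:
    """Forward-simulate one participant's trial table from a task design.

    The first prediction of each condition is drawn near mid-scale; later
    predictions are the model's, plus additive Gaussian response noise,
    rounded and clipped to [0, 100] (rounding can be disabled for noise-free
    identity checks). Control trials are flagged but generated identically
    (they were unannounced at prediction time).
    """
    frames = []
    for si, session in enumerate(design.sessions, start=1):
        for ci, spec in enumerate(session.conditions):
            rewards = session.rewards[ci]
            p1 = float(rng.normal(first_prediction_mean, first_prediction_sd))
            if round_predictions:
                p1 = float(np.clip(np.rint(p1), 0, 100))
            trace = simulate_adaptive_ph(rewards, params, p1, sd_level=spec.sd_level)
            preds = trace.predictions.copy()
            if noise_sd > 0:
                preds[1:] = preds[1:] + rng.normal(0.0, noise_sd, size=len(preds) - 1)
            if round_predictions:
                preds = np.clip(np.rint(preds), 0, 100)
            n = len(rewards)
            is_control = np.zeros(n, bool)
            n_control = int(round(control_fraction * n))
            if n_control:
                is_control[rng.choice(n, size=n_control, replace=False)] = True
            payoff = np.where(
                is_control,
                [control_trial_payoff(p, spec.ev, spec.sd_target) for p in preds],
                MAIN_TRIAL_PAYOFF_FRACTION * np.asarray(rewards, float),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": participant_id,
                        "session": si,
                        "condition_id": spec.condition_id,
                        "sd_level": spec.sd_level,
                        "sd_target": spec.sd_target,
                        "ev": spec.ev,
                        "trial_in_condition": np.arange(1, n + 1),
                        "reward": rewards,
                        "prediction": preds,
                        "is_control_trial": is_control,
                        "payoff": np.round(payoff, 2),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort dataset plus its ground-truth parameter table.

    Designs are counterbalanced: the first half of the cohort receives
    pairing scheme 1, the rest scheme 2, and session orders rotate through
    the six permutations.
    """
    root = np.random.default_rng(spec.seed)
    sigma_by_level = {"small": 5.0, "medium": 10.0, "large": 15.0}
    data_frames = []
    truth_rows = []
    n_scheme1 = int(np.ceil(spec.n_participants / 2))
    for i in range(spec.n_participants):
        rng = np.random.default_rng(root.integers(2**31))
        scheme = 1 if i < n_scheme1 else 2
        order = i % N_SESSION_ORDERS
        design = task_mod.build_task_design(
            pairing_scheme=scheme, session_order=order, seed=int(rng.integers(2**31))
        )
        truth = _sample_params(spec, rng, exaggerated=i >= spec.n_participants - spec.n_exaggerated)
        params = _model_params(spec, truth, sigma_by_level)
        df = generate_participant(
            design,
            params,
            spec.noise_sd,
            rng,
            participant_id=i + 1,
            first_prediction_mean=spec.first_prediction_mean,
            first_prediction_sd=spec.first_prediction_sd,
            round_predictions=spec.round_predictions,
            control_fraction=spec.control_fraction,
        )
        data_frames.append(df)
        truth_rows.append(
            ParticipantTruth(i + 1, spec.model, truth["alpha1"], truth["eta"], truth["nu"]).to_dict()
        )
    return pd.concat(data_frames, ignore_index=True), pd.DataFrame(truth_rows)


@dataclass
class RecoveryReport:
    """Truth-vs-estimate comparison for a generated cohort."""

    truth: pd.DataFrame
    estimates: pd.DataFrame
    stats: pd.DataFrame  # per parameter: correlation, bias, rmse
    confusion: pd.DataFrame | None = None

    def correlation(self, param: str) -> float:
        return float(self.stats.loc[param, "correlation"])

    def rmse(self, param: str) -> float:
        return float(self.stats.loc[param, "rmse"])


def _recovery_stats(truth: pd.DataFrame, est: pd.DataFrame, params) -> pd.DataFrame:
    rows = {}
    for p in params:
        t = truth[p].to_numpy(float)
        e = est[p].to_numpy(float)
        err = e - t
        corr = np.nan
        if np.std(t) > 0 and np.std(e) > 0:
            corr = float(np.corrcoef(t, e)[0, 1])
        rows[p] = {
            "correlation": corr,
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
        }
    return pd.DataFrame(rows).T


def parameter_recovery(
    spec: CohortSpec, fit_config: FitConfig | None = None
) -> RecoveryReport:
    """Generate a cohort with known parameters and fit the generating model."""
    dataset, truth = generate_cohort(spec)
    config = fit_config or FitConfig(model=spec.model, seed=spec.seed)
    if config.model != spec.model:
        config = dc_replace(config, model=spec.model)
    fits = fit_cohort(dataset, config)
    m = MODELS[spec.model]
    params = ["alpha1"] + (["eta"] if m.dynamic else []) + (
        ["nu"] if (m.adaptive and m.nu_free) else []
    )
    est_rows = []
    for pid in truth["participant_id"]:
        f = fits[pid]
        row = {"participant_id": pid}
        for p in params:
            row[p] = f.theta.get(p, np.nan)
        est_rows.append(row)
    estimates = pd.DataFrame(est_rows)
    stats_df = _recovery_stats(
        truth.set_index("participant_id"), estimates.set_index("participant_id"), params
    )
    return RecoveryReport(truth=truth, estimates=estimates, stats=stats_df)


def model_recovery_confusion(
    generators=("rw", "ph", "aph-log"),
    candidates=("rw", "ph", "aph-log"),
    n_per_model: int = 8,
    noise_sd: float = 3.0,
    seed: int = 0,
    criterion: str = "bic",
    base_spec: CohortSpec | None = None,
) -> pd.DataFrame:
    """Generate small cohorts per model and count best-criterion selections.

    Rows: generating model; columns: selected model. A diagonal-dominant
    matrix means the fitting pipeline can tell the model family apart.
    """
    base = base_spec or CohortSpec()
    rows = []
    for gi, gen in enumerate(generators):
        spec = dc_replace(
            base, model=gen, n_participants=n_per_model, noise_sd=noise_sd,
            seed=seed + 1000 * gi,
        )
        dataset, _ = generate_cohort(spec)
        fits = {
            m: fit_cohort(dataset, FitConfig(model=m, seed=spec.seed)) for m in candidates
        }
        for pid in sorted(next(iter(fits.values())).keys()):
            scores = {
                m: (fits[m][pid].bic if criterion == "bic" else fits[m][pid].aic)
                for m in candidates
            }
            rows.append({"generator": gen, "selected": min(scores, key=scores.get)})
    table = pd.DataFrame(rows)
    return pd.crosstab(table["generator"], table["selected"]).reindex(
        index=list(generators), columns=list(candidates), fill_value=0
    )
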