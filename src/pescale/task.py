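"""Reward-distribution and trial-schedule construction for the prediction task.

The task draws rewards (points, 0-100) from six pseudo-Gaussian
distributions crossing SD in {5, 10, 15} with expected value in {35, 65}.
Each distribution is a fixed multiset of 42 integer rewards with the mean
exactly at the EV, zero skewness (enforced by symmetric construction), a
sample SD within 0.25 points of the target, and a mildly platykurtic shape
(kurtosis ~2.6 for SD 5/10, ~2.57 for SD 15). Within a session two
distributions differing in both SD and EV alternate in 12 short blocks of
5-8 trials (6 blocks, 42 trials per distribution); model fits treat each
distribution's 42 trials as if presented in direct succession.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RewardDistributionSpec",
    "SessionSchedule",
    "TaskDesign",
    "PracticeDesign",
    "InfeasibleDistributionError",
    "OrderingError",
    "construct_reward_multiset",
    "order_rewards",
    "build_session",
    "build_task_design",
    "build_practice_design",
    "PAIRING_SCHEMES",
    "KURTOSIS_TARGETS",
    "OUTLIER_FACTOR",
]

MAIN_SDS = (5, 10, 15)
MAIN_EVS = (35, 65)
N_TRIALS = 42
BLOCKS_PER_CONDITION = 6
BLOCK_RANGE = (5, 8)

#: Printed kurtosis of the six distributions (non-excess; Gaussian = 3).
KURTOSIS_TARGETS = {5: 2.6, 10: 2.6, 15: 2.57}
DEFAULT_KURTOSIS = 2.6

#: A reward is an outlier of its distribution when |r - EV| > 1.5 * SD.
OUTLIER_FACTOR = 1.5

#: Values are confined to EV +/- 2.5 * SD ("no tails"), clamped to [0, 100].
RANGE_FACTOR = 2.5

# The two pairing combinations of (SD, EV) conditions used across sessions.
PAIRING_SCHEMES = {
    1: (((5, 35), (10, 65)), ((10, 35), (15, 65)), ((15, 35), (5, 65))),
    2: (((5, 35), (15, 65)), ((10, 35), (5, 65)), ((15, 35), (10, 65))),
}


class InfeasibleDistributionError(ValueError):
    """Moment targets cannot be met within the admissible integer range."""


class OrderingError(RuntimeError):
    """No reward ordering without consecutive outliers was found."""


def _sd_level_label(sd: float, sds_in_design) -> str:
    order = sorted(set(sds_in_design))
    labels = {1: ("medium",), 2: ("small", "large"), 3: ("small", "medium", "large")}
    return labels[len(order)][order.index(sd)]


@dataclass(frozen=True)
class RewardDistributionSpec:
    """One condition: its EV/SD targets and the 42-value reward multiset."""

    ev: float
    sd_target: float
    sd_level: str
    n_trials: int
    values: tuple[int, ...]

    @property
    def condition_id(self) -> str:
        return f"sd{self.sd_target:g}_ev{self.ev:g}"

    def sample_sd(self) -> float:
        return float(np.std(self.values, ddof=1))

    def sample_skewness(self) -> float:
        return float(stats.skew(self.values, bias=True))

    def sample_kurtosis(self) -> float:
        return float(stats.kurtosis(self.values, fisher=False, bias=True))

    def outliers(self) -> set[int]:
        thr = OUTLIER_FACTOR * self.sd_target
        return {v for v in set(self.values) if abs(v - self.ev) > thr}


def _moments(offsets: np.ndarray, n: int) -> tuple[float, float]:
    """Sample SD and kurtosis of the symmetric multiset {ev +/- d}."""
    s2 = 2.0 * float(np.sum(offsets.astype(float) ** 2))
    s4 = 2.0 * float(np.sum(offsets.astype(float) ** 4))
    sd = np.sqrt(s2 / (n - 1))
    m2 = s2 / n
    kurt = (s4 / n) / (m2 * m2) if m2 > 0 else np.inf
    return sd, kurt


def construct_reward_multiset(
    ev: float, sd_target: float, n: int = N_TRIALS, seed: int = 0
) -> RewardDistributionSpec:
    """Search for a symmetric integer reward multiset with target moments.

    Values come in pairs ``ev + d, ev - d`` (plus a single ``ev`` when ``n``
    is odd), which makes the mean exact and the skewness identically zero.
    A seeded hill-climb over the integer offsets minimises the SD error
    first (weighted heavily) and the kurtosis error second. Results are
    memoised per (ev, sd, n, seed) since the search is deterministic.
    """
    return _construct_cached(float(ev), float(sd_target), int(n), int(seed))


from functools import lru_cache  # noqa: E402


@lru_cache(maxsize=256)
def _construct_cached(ev: float, sd_target: float, n: int, seed: int) -> RewardDistributionSpec:
    if n < 4:
        raise InfeasibleDistributionError("need at least 4 trials")
    if sd_target <= 0:
        raise InfeasibleDistributionError("sd_target must be positive")
    if not float(ev).is_integer():
        raise InfeasibleDistributionError("ev must be an integer for integer rewards")
    dmax = int(min(RANGE_FACTOR * sd_target, ev, 100 - ev))
    m = n // 2
    if dmax < 1 or dmax * np.sqrt(n / (n - 1)) < sd_target - 0.25:
        raise InfeasibleDistributionError(
            f"sd_target={sd_target} unreachable with offsets <= {dmax} for ev={ev}"
        )
    kurt_target = KURTOSIS_TARGETS.get(sd_target, DEFAULT_KURTOSIS)
    rng = np.random.default_rng(seed)

    def cost(off: np.ndarray) -> float:
        # free movement inside the SD tolerance band, steep penalty outside,
        # so the kurtosis target can be tuned without losing the SD target
        sd, kurt = _moments(off, n)
        sd_pen = max(0.0, abs(sd - sd_target) - 0.15)
        return 1000.0 * sd_pen + abs(kurt - kurt_target)

    # start from half-normal quantile offsets
    q = (np.arange(m) + 0.5) / m
    init = np.clip(np.rint(sd_target * stats.halfnorm.ppf(q)), 0, dmax).astype(int)

    best = init.copy()
    best_cost = cost(best)
    for _ in range(3):  # restarts
        if best_cost < 0.01:
            break
        off = best.copy()
        c = cost(off)
        for _ in range(12000):
            if c < 0.01:
                break
            i = rng.integers(m)
            step = int(rng.choice((-2, -1, 1, 2)))
            trial = off.copy()
            trial[i] = np.clip(trial[i] + step, 0, dmax)
            if rng.random() < 0.5:  # paired move: keeps SD roughly fixed
                j = rng.integers(m)
                trial[j] = np.clip(trial[j] - step, 0, dmax)
            tc = cost(trial)
            if tc <= c + 1e-12:
                off, c = trial, tc
        if c < best_cost:
            best, best_cost = off, c

    values = np.sort(np.concatenate([ev + best, ev - best, [ev] * (n % 2)]))
    spec = RewardDistributionSpec(
        ev=float(ev),
        sd_target=float(sd_target),
        sd_level=_sd_level_label(sd_target, MAIN_SDS if sd_target in MAIN_SDS else (sd_target,) * 2),
        n_trials=n,
        values=tuple(int(v) for v in values),
    )
    if abs(spec.sample_sd() - sd_target) > 0.25 or abs(spec.sample_kurtosis() - kurt_target) > 0.05:
        raise InfeasibleDistributionError(
            f"moment search failed for ev={ev}, sd={sd_target}: "
            f"sd={spec.sample_sd():.3f}, kurtosis={spec.sample_kurtosis():.3f}"
        )
    return spec


def order_rewards(spec: RewardDistributionSpec, seed: int = 0, max_tries: int = 2000) -> list[int]:
    """Permute the reward multiset so no two consecutive rewards are outliers."""
    rng = np.random.default_rng(seed)
    outliers = spec.outliers()
    vals = np.asarray(spec.values)
    for _ in range(max_tries):
        perm = rng.permutation(vals)
        flags = np.isin(perm, list(outliers)) if outliers else np.zeros(len(perm), bool)
        if not np.any(flags[:-1] & flags[1:]):
            return [int(v) for v in perm]
    raise OrderingError(
        f"no ordering without consecutive outliers found in {max_tries} shuffles "
        f"for {spec.condition_id} (outliers beyond {OUTLIER_FACTOR} * SD)"
    )


# all 6-part compositions of 42 with parts in [5, 8]
_BLOCK_COMPOSITIONS = [
    c
    for c in itertools.product(range(BLOCK_RANGE[0], BLOCK_RANGE[1] + 1), repeat=BLOCKS_PER_CONDITION)
    if sum(c) == N_TRIALS
]


@dataclass(frozen=True)
class SessionSchedule:
    """Two interleaved conditions: block lengths and the trial order."""

    conditions: tuple[RewardDistributionSpec, RewardDistributionSpec]
    rewards: tuple[tuple[int, ...], tuple[int, ...]]  # condition-local order
    block_lengths: tuple[int, ...]  # 12 blocks, alternating conditions
    start_condition: int  # index (0/1) of the first block's condition
    trial_order: tuple[tuple[int, int], ...]  # (condition index, local trial)

    def __post_init__(self):
        a, b = self.conditions
        if a.sd_target == b.sd_target or a.ev == b.ev:
            raise ValueError("paired conditions must differ in both SD and EV")

    @property
    def n_trials(self) -> int:
        return len(self.trial_order)

    def to_frame(self, session: int, participant_id: str | int = 0) -> pd.DataFrame:
        rows = []
        block_of = {}
        # assign block index per trial
        idx = 0
        for b, length in enumerate(self.block_lengths):
            for _ in range(length):
                block_of[idx] = b + 1
                idx += 1
        for i, (ci, tloc) in enumerate(self.trial_order):
            spec = self.conditions[ci]
            rows.append(
                {
                    "participant_id": participant_id,
                    "session": session,
                    "condition_id": spec.condition_id,
                    "sd_level": spec.sd_level,
                    "sd_target": spec.sd_target,
                    "ev": spec.ev,
                    "block_index": block_of[i],
                    "trial_in_condition": tloc + 1,
                    "reward": self.rewards[ci][tloc],
                }
            )
        return pd.DataFrame(rows)


def _sample_blocks(rng: np.random.Generator) -> tuple[int, ...]:
    return _BLOCK_COMPOSITIONS[rng.integers(len(_BLOCK_COMPOSITIONS))]


def build_session(
    pair: tuple[RewardDistributionSpec, RewardDistributionSpec], seed: int = 0
) -> SessionSchedule:
    """Interleave a condition pair into 12 alternating blocks of 5-8 trials."""
    rng = np.random.default_rng(seed)
    ordered = tuple(
        tuple(order_rewards(spec, seed=int(rng.integers(2**31)))) for spec in pair
    )
    blocks = [_sample_blocks(rng), _sample_blocks(rng)]
    start = int(rng.integers(2))
    lengths = []
    order: list[tuple[int, int]] = []
    counters = [0, 0]
    for b in range(2 * BLOCKS_PER_CONDITION):
        ci = (start + b) % 2
        length = blocks[ci][b // 2]
        lengths.append(length)
        for _ in range(length):
            order.append((ci, counters[ci]))
            counters[ci] += 1
    return SessionSchedule(
        conditions=tuple(pair),
        rewards=ordered,
        block_lengths=tuple(lengths),
        start_condition=start,
        trial_order=tuple(order),
    )


@dataclass(frozen=True)
class TaskDesign:
    """Three sessions covering all six reward distributions once each."""

    sessions: tuple[SessionSchedule, ...]
    pairing_scheme: int
    session_order: int
    seed: int

    @property
    def n_trials(self) -> int:
        return sum(s.n_trials for s in self.sessions)

    def to_frame(self, participant_id: str | int = 0) -> pd.DataFrame:
        frames = [
            s.to_frame(session=i + 1, participant_id=participant_id)
            for i, s in enumerate(self.sessions)
        ]
        return pd.concat(frames, ignore_index=True)

    def conditions(self) -> list[RewardDistributionSpec]:
        return [spec for s in self.sessions for spec in s.conditions]


def _build_design(pairs, sds, session_order: int, seed: int, scheme_id: int) -> TaskDesign:
    orders = list(itertools.permutations(range(len(pairs))))
    if not 0 <= session_order < len(orders):
        raise ValueError(f"session_order must be in [0, {len(orders) - 1}]")
    rng = np.random.default_rng(seed)
    specs = {}
    for pair in pairs:
        for sd, ev in pair:
            if (sd, ev) not in specs:
                # the multisets are fixed task properties: every participant
                # receives the same 42 rewards per condition (only their
                # order and blocking vary), so construction is unseeded here
                spec = construct_reward_multiset(ev, sd, N_TRIALS, seed=0)
                specs[(sd, ev)] = RewardDistributionSpec(
                    ev=spec.ev,
                    sd_target=spec.sd_target,
                    sd_level=_sd_level_label(sd, sds),
                    n_trials=spec.n_trials,
                    values=spec.values,
                )
    sessions = []
    for pi in orders[session_order]:
        pair = tuple(specs[key] for key in pairs[pi])
        sessions.append(build_session(pair, seed=int(rng.integers(2**31))))
    return TaskDesign(
        sessions=tuple(sessions), pairing_scheme=scheme_id, session_order=session_order, seed=seed
    )


def build_task_design(pairing_scheme: int = 1, session_order: int = 0, seed: int = 0) -> TaskDesign:
    """Main task: 3 sessions x 2 conditions x 42 trials = 252 trials."""
    if pairing_scheme not in PAIRING_SCHEMES:
        raise ValueError(f"unknown pairing scheme {pairing_scheme!r}")
    return _build_design(
        PAIRING_SCHEMES[pairing_scheme], MAIN_SDS, session_order, seed, pairing_scheme
    )


@dataclass(frozen=True)
class PracticeDesign(TaskDesign):
    """Two practice sessions from SD {7, 14} x EV {30, 60} distributions."""


PRACTICE_PAIRS = (((7, 30), (14, 60)), ((14, 30), (7, 60)))


def build_practice_design(seed: int = 0, session_order: int = 0) -> PracticeDesign:
    """Practice: 2 sessions x 2 conditions x 42 trials = 168 trials."""
    design = _build_design(PRACTICE_PAIRS, (7, 14), session_order, seed, scheme_id=1)
    return PracticeDesign(
        sessions=design.sessions,
        pairing_scheme=design.pairing_scheme,
        session_order=design.session_order,
        seed=design.seed,
    )
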