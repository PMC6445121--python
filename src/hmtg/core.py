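"""Hidden Multiplier Trust Game: task structure, utility models, behavior generation.

The game: an Investor sends ``I`` of 10 tokens; the investment is multiplied
by ``M2`` (2, 4, or 6) before reaching the Trustee, who returns ``S2`` tokens
from the multiplied pot. The Investor believes the multiplier is always 4,
and the Trustee knows this, so the Trustee's second-order expectation of what
the Investor expects back is fixed at half the believed pot, ``2*I``.

Four utility models describe the Trustee:

* ``GR`` (greed): utility is the raw payoff ``I*M2 - S2``.
* ``GA`` (guilt aversion): payoff minus ``theta`` times a squared shortfall
  from the expected return, ``((2I - S2) / (4I))**2``.
* ``IA`` (inequity aversion): payoff minus ``theta`` times the squared
  deviation from an equal split, ``((I*M2 - S2)/(10 - I + I*M2) - 1/2)**2``.
* ``MS`` (Moral Strategy): a two-parameter model trading a *normalized*
  payoff ``(I*M2 - S2)/(I*M2)`` (weight ``theta``) against the smaller of
  the guilt and inequity losses, with a consistency bias ``phi`` that tilts
  the min toward guilt (``phi < 0``) or inequity (``phi > 0``):

  ``U2 = theta*payoff - (1 - theta)*min(guilt + phi, inequity - phi)``

Predictions are argmaxes of utility over the integer returns ``0..I*M2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MODELS",
    "STRATEGIES",
    "MS_THETA_BOUNDS",
    "MS_PHI_BOUNDS",
    "COMPONENT_THETA_BOUNDS",
    "Trial",
    "TaskSchedule",
    "MSParams",
    "ComponentParams",
    "UtilityTerms",
    "BehaviorRecord",
    "BehaviorDataset",
    "build_schedule",
    "utility",
    "predict_return",
    "predict_schedule",
    "prototype_returns",
    "simulate_behavior",
    "write_behavior_csv",
    "read_behavior_csv",
    "write_schedule_csv",
    "read_schedule_csv",
    "params_to_json",
    "params_from_json",
]

MODELS = ("GR", "GA", "IA", "MS")
STRATEGIES = ("IA", "GA", "MO", "GR")

MS_THETA_BOUNDS = (0.0, 0.5)
MS_PHI_BOUNDS = (-0.1, 0.1)
#: Default box for the one-parameter component models. Wide enough for the
#: social term to dominate the unnormalized payoff over most investments.
COMPONENT_THETA_BOUNDS = (0.0, 1000.0)

MULTIPLIERS = (2, 4, 6)
#: trials per multiplier condition in the standard 80-trial design
CONDITION_COUNTS = {2: 20, 4: 40, 6: 20}
#: zero-investment trials per condition (5% of each)
ZERO_INVESTMENT_COUNTS = {2: 1, 4: 2, 6: 1}


@dataclass(frozen=True)
class Trial:
    """One game trial: investment, true multiplier, believed multiplier."""

    investment: int
    multiplier: int
    believed_multiplier: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.investment <= 10:
            raise ValueError(f"investment must be in 0..10, got {self.investment}")
        if self.multiplier not in MULTIPLIERS:
            raise ValueError(f"multiplier must be one of {MULTIPLIERS}, got {self.multiplier}")
        if self.believed_multiplier != 4:
            raise ValueError("believed_multiplier is fixed at 4 in this task")

    @property
    def pot(self) -> int:
        """Tokens available to the Trustee, ``I * M2``."""
        return self.investment * self.multiplier

    @property
    def expected_return(self) -> int:
        """Second-order expectation ``E2(E1(S2)) = believed_multiplier/2 * I = 2*I``."""
        return self.believed_multiplier // 2 * self.investment


@dataclass(frozen=True)
class TaskSchedule:
    """Ordered list of trials shared by every participant in a cohort."""

    trials: tuple[Trial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def investments(self) -> np.ndarray:
        return np.array([t.investment for t in self.trials], dtype=int)

    @property
    def multipliers(self) -> np.ndarray:
        return np.array([t.multiplier for t in self.trials], dtype=int)

    @property
    def pots(self) -> np.ndarray:
        return self.investments * self.multipliers

    @property
    def modeled(self) -> np.ndarray:
        """Boolean mask of nonzero-investment trials (the modeled trials)."""
        return self.investments > 0

    def combos(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unique modeled (investment, multiplier) combos and the inverse map.

        Returns ``(I, M, inverse)`` where ``inverse`` maps each modeled trial
        to its combo index. Predictions only depend on the combo, so fitting
        evaluates each combo once.
        """
        inv = self.investments
        mult = self.multipliers
        mask = self.modeled
        pairs = np.stack([inv[mask], mult[mask]], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        return uniq[:, 0], uniq[:, 1], inverse


@dataclass(frozen=True)
class MSParams:
    """Moral Strategy Model coordinates (theta, phi)."""

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not MS_THETA_BOUNDS[0] <= self.theta <= MS_THETA_BOUNDS[1]:
            raise ValueError(f"theta out of bounds {MS_THETA_BOUNDS}: {self.theta}")
        if not MS_PHI_BOUNDS[0] <= self.phi <= MS_PHI_BOUNDS[1]:
            raise ValueError(f"phi out of bounds {MS_PHI_BOUNDS}: {self.phi}")


@dataclass(frozen=True)
class ComponentParams:
    """Single social-preference weight for the GA and IA component models."""

    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or self.theta < 0:
            raise ValueError(f"theta must be finite and >= 0, got {self.theta}")


@dataclass(frozen=True)
class UtilityTerms:
    payoff: float
    guilt: float
    inequity: float
    utility: float


@dataclass(frozen=True)
class BehaviorRecord:
    trial: Trial
    returned: int

    def __post_init__(self) -> None:
        if not 0 <= self.returned <= self.trial.pot:
            raise ValueError(
                f"returned={self.returned} outside [0, {self.trial.pot}]"
            )


@dataclass
class BehaviorDataset:
    """Returned-token sequence for one participant, aligned to a schedule."""

    participant_id: str
    schedule: TaskSchedule
    returned: np.ndarray

    def __post_init__(self) -> None:
        self.returned = np.asarray(self.returned, dtype=int)
        if self.returned.shape != (len(self.schedule),):
            raise ValueError("one returned amount per schedule trial required")
        pots = self.schedule.pots
        if np.any(self.returned < 0) or np.any(self.returned > pots):
            raise ValueError("returned amounts outside [0, I*M2]")
        if np.any(self.returned[~self.schedule.modeled] != 0):
            raise ValueError("zero-investment trials must have returned = 0")

    @property
    def records(self) -> list[BehaviorRecord]:
        return [
            BehaviorRecord(t, int(r)) for t, r in zip(self.schedule, self.returned)
        ]

    def modeled_returns(self) -> np.ndarray:
        return self.returned[self.schedule.modeled]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "trial_index": np.arange(len(self.schedule)),
                "investment": self.schedule.investments,
                "multiplier": self.schedule.multipliers,
                "believed_multiplier": 4,
                "returned": self.returned,
            }
        )


def build_schedule(seed: int) -> TaskSchedule:
    """Build the standard 80-trial schedule.

    20/40/20 trials at multipliers 2/4/6, 1/2/1 zero-investment trials per
    condition, and nonzero investments cycling through 1..10 as evenly as the
    per-condition counts allow, so the investment distribution is nearly
    identical across conditions. Trial order is shuffled by ``seed``.
    """
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for m in MULTIPLIERS:
        n = CONDITION_COUNTS[m]
        n_zero = ZERO_INVESTMENT_COUNTS[m]
        n_nonzero = n - n_zero
        investments = [0] * n_zero + [1 + i % 10 for i in range(n_nonzero)]
        trials.extend(Trial(i, m) for i in investments)
    order = rng.permutation(len(trials))
    return TaskSchedule(tuple(trials[i] for i in order))


def _utility_grid(
    model_id: str,
    theta: np.ndarray,
    phi: np.ndarray,
    investment: int,
    multiplier: int,
    s2: np.ndarray,
) -> np.ndarray:
    """Utilities for parameter column-vectors against a row-vector of returns."""
    pot = investment * multiplier
    payoff_raw = pot - s2
    guilt = ((2.0 * investment - s2) / (4.0 * investment)) ** 2
    inequity = (payoff_raw / (10.0 - investment + pot) - 0.5) ** 2
    if model_id == "MS":
        payoff = payoff_raw / pot
        social = np.minimum(guilt + phi, inequity - phi)
        return theta * payoff - (1.0 - theta) * social
    if model_id == "GR":
        return np.broadcast_to(
            payoff_raw.astype(float), np.broadcast_shapes(theta.shape, s2.shape)
        ).copy()
    if model_id == "GA":
        return payoff_raw - theta * guilt
    if model_id == "IA":
        return payoff_raw - theta * inequity
    raise ValueError(f"unknown model {model_id!r}")


def _as_param_arrays(model_id, params) -> tuple[np.ndarray, np.ndarray]:
    if model_id == "MS":
        return np.atleast_1d(params.theta), np.atleast_1d(params.phi)
    if model_id == "GR":
        return np.zeros(1), np.zeros(1)
    return np.atleast_1d(params.theta), np.zeros(1)


def utility(model_id: str, params, trial: Trial, s2: int) -> UtilityTerms:
    """All utility terms for one candidate return ``s2``.

    The payoff term is normalized by the pot for the MS model and raw for the
    component models, matching each model's own formulation.
    """
    if trial.investment < 1:
        raise ValueError("utility undefined for zero-investment trials")
    if not 0 <= s2 <= trial.pot:
        raise ValueError(f"s2={s2} outside [0, {trial.pot}]")
    theta, phi = _as_param_arrays(model_id, params)
    u = float(
        _utility_grid(
            model_id,
            theta[:, None],
            phi[:, None],
            trial.investment,
            trial.multiplier,
            np.array([float(s2)]),
        )[0, 0]
    )
    pot = trial.pot
    guilt = ((2.0 * trial.investment - s2) / (4.0 * trial.investment)) ** 2
    inequity = ((pot - s2) / (10.0 - trial.investment + pot) - 0.5) ** 2
    payoff = (pot - s2) / pot if model_id == "MS" else float(pot - s2)
    return UtilityTerms(payoff=payoff, guilt=guilt, inequity=inequity, utility=u)


def predict_combos(
    model_id: str,
    theta: np.ndarray,
    phi: np.ndarray,
    investments: np.ndarray,
    multipliers: np.ndarray,
) -> np.ndarray:
    """Vectorized argmax predictions.

    Parameters are 1-D arrays of length P (ignored entries allowed for GR);
    ``investments``/``multipliers`` are length-C combo arrays. Returns an
    (P, C) integer array. Ties in utility resolve to the smallest return
    (first maximum in an ascending scan). Zero-investment combos predict 0.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    n_p = theta.shape[0]
    out = np.empty((n_p, len(investments)), dtype=int)
    for c, (i, m) in enumerate(zip(investments, multipliers)):
        i, m = int(i), int(m)
        if i == 0:
            out[:, c] = 0
            continue
        s2 = np.arange(i * m + 1, dtype=float)
        u = _utility_grid(model_id, theta[:, None], phi[:, None], i, m, s2[None, :])
        out[:, c] = np.argmax(u, axis=1)
    return out


def predict_return(model_id: str, params, trial: Trial) -> int:
    """Predicted return: the smallest integer argmax of utility over 0..I*M2.

    Zero-investment trials return 0 by convention (they are excluded from
    modeling; the Trustee cannot respond).
    """
    if trial.investment == 0:
        return 0
    theta, phi = _as_param_arrays(model_id, params)
    return int(
        predict_combos(
            model_id,
            theta,
            phi,
            np.array([trial.investment]),
            np.array([trial.multiplier]),
        )[0, 0]
    )


def predict_schedule(model_id: str, params, schedule: TaskSchedule) -> np.ndarray:
    """Per-trial predicted returns over a whole schedule (0 where I = 0)."""
    theta, phi = _as_param_arrays(model_id, params)
    inv_u, mult_u, inverse = schedule.combos()
    combo_preds = predict_combos(model_id, theta, phi, inv_u, mult_u)[0]
    out = np.zeros(len(schedule), dtype=int)
    out[schedule.modeled] = combo_preds[inverse]
    return out


def prototype_returns(strategy: str, trial: Trial) -> int:
    """Closed-form idealized returns for the four named strategies.

    GR keeps everything; GA returns the expected ``2*I``; IA equalizes final
    totals, ``(I*M2 + I - 10)/2`` with half-integers rounded down and the
    result clipped to the feasible range; MO returns the pointwise minimum of
    the GA and IA prototypes (the cheaper moral rule on each trial).
    """
    i, pot = trial.investment, trial.pot
    if i < 1:
        raise ValueError("prototypes defined for investment >= 1")
    if strategy == "GR":
        return 0
    ga = 2 * i
    ia = int(np.clip((pot + i - 10) // 2, 0, pot))
    if strategy == "GA":
        return ga
    if strategy == "IA":
        return ia
    if strategy == "MO":
        return min(ga, ia)
    raise ValueError(f"unknown strategy {strategy!r}")


def prototype_vector(strategy: str, investments: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
    """Prototype returns over combo arrays; zero-investment entries are 0."""
    out = np.zeros(len(investments), dtype=int)
    for idx, (i, m) in enumerate(zip(investments, multipliers)):
        if int(i) > 0:
            out[idx] = prototype_returns(strategy, Trial(int(i), int(m)))
    return out


def simulate_behavior(
    model_id: str,
    params,
    schedule: TaskSchedule,
    noise_sd: float = 0.0,
    seed: int | None = None,
    participant_id: str = "sim",
) -> BehaviorDataset:
    """Simulate a participant: model argmax plus rounded, clipped Gaussian noise.

    ``noise_sd = 0`` reproduces the deterministic predictions exactly and
    consumes no randomness, so the same seed with different noise levels
    shares no coupling.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    returned = predict_schedule(model_id, params, schedule).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        returned = returned + rng.normal(0.0, noise_sd, size=returned.shape)
    returned = np.clip(np.rint(returned), 0, schedule.pots).astype(int)
    returned[~schedule.modeled] = 0
    return BehaviorDataset(participant_id, schedule, returned)


# ---------------------------------------------------------------------------
# I/O


def write_behavior_csv(datasets: Iterable[BehaviorDataset], path) -> None:
    frames = [d.to_frame() for d in datasets]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _schedule_from_frame(g: pd.DataFrame) -> TaskSchedule:
    g = g.sort_values("trial_index")
    return TaskSchedule(
        tuple(
            Trial(int(i), int(m), int(b))
            for i, m, b in zip(g["investment"], g["multiplier"], g["believed_multiplier"])
        )
    )


def read_behavior_csv(path) -> list[BehaviorDataset]:
    df = pd.read_csv(path)
    out = []
    for pid, g in df.groupby("participant_id", sort=False):
        g = g.sort_values("trial_index")
        out.append(
            BehaviorDataset(str(pid), _schedule_from_frame(g), g["returned"].to_numpy())
        )
    return out


def write_schedule_csv(schedule: TaskSchedule, path) -> None:
    pd.DataFrame(
        {
            "trial_index": np.arange(len(schedule)),
            "investment": schedule.investments,
            "multiplier": schedule.multipliers,
            "believed_multiplier": 4,
        }
    ).to_csv(path, index=False)


def read_schedule_csv(path) -> TaskSchedule:
    return _schedule_from_frame(pd.read_csv(path))


def params_to_json(model_id: str, params) -> str:
    rec = {"model": model_id}
    if model_id == "MS":
        rec.update(theta=params.theta, phi=params.phi)
    elif model_id in ("GA", "IA"):
        rec.update(theta=params.theta)
    return json.dumps(rec)


def params_from_json(text: str):
    rec = json.loads(text)
    model = rec["model"]
    if model == "MS":
        return model, MSParams(rec["theta"], rec["phi"])
    if model in ("GA", "IA"):
        return model, ComponentParams(rec["theta"])
    if model == "GR":
        return model, None
    raise ValueError(f"unknown model {model!r}")
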