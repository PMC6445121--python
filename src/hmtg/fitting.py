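"""Model fitting, AIC comparison, cross-validation, and parameter recovery.

The least-squares objective is the sum of squared differences between the
model's argmax predictions and the observed returns over the nonzero-
investment trials. Because predictions are integer argmaxes, the objective
is piecewise constant in the parameters, which makes gradient-based least
squares uninformative; the fitter therefore uses dense random multi-start
evaluation (uniform within the parameter box) followed by a strict-
improvement pattern search from the best start. Ties between starts resolve
to the earliest start index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    COMPONENT_THETA_BOUNDS,
    MS_PHI_BOUNDS,
    MS_THETA_BOUNDS,
    BehaviorDataset,
    ComponentParams,
    MSParams,
    TaskSchedule,
    build_schedule,
    predict_combos,
    predict_schedule,
    simulate_behavior,
)

__all__ = [
    "K_PARAMS",
    "FitResult",
    "CVResult",
    "RecoveryResult",
    "aic",
    "fit_model",
    "compare_models",
    "cross_validate",
    "recover_parameters",
]

K_PARAMS = {"GR": 0, "GA": 1, "IA": 1, "MS": 2}


@dataclass
class FitResult:
    model_id: str
    params: MSParams | ComponentParams | None
    sse: float
    n_trials: int
    k_params: int
    #: None when sse == 0 (log of zero undefined; subject excluded from comparisons)
    aic: float | None

    def to_dict(self) -> dict:
        d = {
            "model": self.model_id,
            "sse": self.sse,
            "n_trials": self.n_trials,
            "k_params": self.k_params,
            "aic": self.aic,
        }
        if isinstance(self.params, MSParams):
            d.update(theta=self.params.theta, phi=self.params.phi)
        elif isinstance(self.params, ComponentParams):
            d.update(theta=self.params.theta, phi=None)
        else:
            d.update(theta=None, phi=None)
        return d


@dataclass
class CVResult:
    mse_per_trial: float
    pearson_r: float | None
    r_squared: float | None

    @property
    def r_defined(self) -> bool:
        return self.pearson_r is not None


@dataclass
class RecoveryResult:
    r_theta: float
    r_phi: float
    mean_behavior_r: float
    pairs: pd.DataFrame = field(repr=False)
    n_behavior_used: int = 0


def aic(sse: float, n: int, k: int) -> float:
    """Akaike information criterion for a least-squares fit: n*ln(SSE/n) + 2k."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if sse == 0:
        raise ValueError("AIC undefined for sse = 0 (log of zero)")
    return n * math.log(sse / n) + 2 * k


def _objective_factory(behavior: BehaviorDataset):
    """Precompute per-combo sufficient statistics so SSE(params) is cheap.

    Predictions depend only on the (investment, multiplier) combo, so the SSE
    over trials decomposes as  sum(obs^2) - 2*pred.s1 + pred^2.n  per combo.
    """
    inv, mult, inverse = behavior.schedule.combos()
    obs = behavior.modeled_returns().astype(float)
    n_c = np.bincount(inverse, minlength=len(inv)).astype(float)
    s1 = np.bincount(inverse, weights=obs, minlength=len(inv))
    ssq = float(np.sum(obs**2))

    def sse_of(model_id: str, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        preds = predict_combos(model_id, theta, phi, inv, mult).astype(float)
        return ssq - 2.0 * preds @ s1 + (preds**2) @ n_c

    return sse_of, len(obs)


def _pattern_search(sse_of, model_id, x0, sse0, lo, hi, chunk_evals=64):
    """Strict-improvement coordinate pattern search on the piecewise-constant SSE."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    span = hi - lo
    x = np.asarray(x0, dtype=float).copy()
    best = float(sse0)
    step = 0.1 * span
    d = len(x)
    while best > 0 and np.any(step > 1e-4 * span):
        cands = []
        for i in range(d):
            for sgn in (1.0, -1.0):
                c = x.copy()
                c[i] = np.clip(c[i] + sgn * step[i], lo[i], hi[i])
                cands.append(c)
        cands = np.unique(np.array(cands), axis=0)
        theta = cands[:, 0]
        phi = cands[:, 1] if d == 2 else np.zeros(len(cands))
        vals = sse_of(model_id, theta, phi)
        j = int(np.argmin(vals))
        if vals[j] < best:
            best = float(vals[j])
            x = cands[j]
        else:
            step *= 0.5
    return x, best


def fit_model(
    model_id: str,
    behavior: BehaviorDataset,
    n_starts: int = 10_000,
    seed: int | None = None,
    refine: bool = True,
    bounds: tuple | None = None,
) -> FitResult:
    """Multi-start least-squares fit of one model to one participant.

    ``n_starts`` random parameter points are drawn uniformly within the
    bounds and evaluated; the earliest start attaining the minimum SSE wins
    ties (SSE values are exact integers here, so ties are exact). With
    ``refine`` a pattern search then descends from that point, accepting only
    strict improvements, which preserves the tie rule on plateaus.
    """
    if not np.any(behavior.schedule.modeled):
        raise ValueError("behavior has no nonzero-investment trials to fit")
    sse_of, n_trials = _objective_factory(behavior)
    k = K_PARAMS[model_id]

    if model_id == "GR":
        sse = float(sse_of("GR", np.zeros(1), np.zeros(1))[0])
        return FitResult("GR", None, sse, n_trials, 0, None if sse == 0 else aic(sse, n_trials, 0))

    rng = np.random.default_rng(seed)
    if model_id == "MS":
        lo = np.array([MS_THETA_BOUNDS[0], MS_PHI_BOUNDS[0]])
        hi = np.array([MS_THETA_BOUNDS[1], MS_PHI_BOUNDS[1]])
    else:
        b = bounds if bounds is not None else COMPONENT_THETA_BOUNDS
        lo, hi = np.array([b[0]]), np.array([b[1]])
    if bounds is not None and model_id == "MS":
        lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)

    d = len(lo)
    starts = lo + (hi - lo) * rng.random((n_starts, d))
    best_sse = np.inf
    best_x = starts[0]
    chunk = 4096
    for c0 in range(0, n_starts, chunk):
        block = starts[c0 : c0 + chunk]
        theta = block[:, 0]
        phi = block[:, 1] if d == 2 else np.zeros(len(block))
        vals = sse_of(model_id, theta, phi)
        j = int(np.argmin(vals))  # first occurrence wins ties
        if vals[j] < best_sse:
            best_sse = float(vals[j])
            best_x = block[j]
    if refine and best_sse > 0:
        best_x, best_sse = _pattern_search(sse_of, model_id, best_x, best_sse, lo, hi)

    if model_id == "MS":
        params: MSParams | ComponentParams = MSParams(float(best_x[0]), float(best_x[1]))
    else:
        params = ComponentParams(float(best_x[0]))
    return FitResult(
        model_id,
        params,
        best_sse,
        n_trials,
        k,
        None if best_sse == 0 else aic(best_sse, n_trials, k),
    )


def _sign_permutation_p(
    diffs: np.ndarray,
    n_perm: int,
    seed: int | None,
    alternative: str,
) -> float:
    """Sign-flip permutation p for the mean of paired differences.

    Exhaustive over all 2^n sign patterns when feasible (raw proportion,
    identity included); Monte Carlo with a +1 validity guard otherwise.
    """
    n = len(diffs)
    obs = diffs.mean()
    if n <= 20 and 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        means = signs @ diffs / n
        exact = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        means = signs @ diffs / n
        exact = False
    if alternative == "greater":
        count = np.sum(means >= obs)
    elif alternative == "less":
        count = np.sum(means <= obs)
    else:
        count = np.sum(np.abs(means) >= abs(obs))
    if exact:
        return float(count / len(means))
    return float((count + 1) / (len(means) + 1))


def compare_models(
    fits: Mapping[str, Sequence[FitResult]],
    method: str = "sign_permutation",
    n_perm: int = 5000,
    seed: int | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise model comparison on subject-wise AIC differences.

    ``fits`` maps model id to a subject-aligned list of :class:`FitResult`.
    Subjects with undefined AIC (perfect fit) for either model of a pair are
    excluded pairwise. ΔAIC is reported as mean(model_a − model_b); with the
    MS model as ``model_a``, negative values favor MS.
    """
    models = list(fits)
    if pairs is None:
        if "MS" in models:
            pairs = [("MS", m) for m in models if m != "MS"]
        else:
            pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1 :]]
    rows = []
    for a, b in pairs:
        aics_a = np.array([f.aic if f.aic is not None else np.nan for f in fits[a]])
        aics_b = np.array([f.aic if f.aic is not None else np.nan for f in fits[b]])
        usable = ~np.isnan(aics_a) & ~np.isnan(aics_b)
        if usable.sum() < 2:
            raise ValueError(f"fewer than 2 subjects with defined AIC for pair ({a}, {b})")
        diffs = aics_a[usable] - aics_b[usable]
        if method == "paired_t":
            if np.all(diffs == diffs[0]):
                stat, p = 0.0, 1.0
                if diffs[0] != 0:
                    stat, p = np.inf * np.sign(diffs[0]), 0.0
            else:
                res = stats.ttest_1samp(diffs, 0.0, alternative=alternative)
                stat, p = float(res.statistic), float(res.pvalue)
        elif method == "sign_permutation":
            stat = float(diffs.mean())
            p = _sign_permutation_p(diffs, n_perm, seed, alternative)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "n_subjects": int(usable.sum()),
                "delta_aic": float(diffs.mean()),
                "stat": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random folds of near-equal size; remainder trials go to the last folds."""
    order = rng.permutation(n)
    base, rem = divmod(n, n_folds)
    sizes = [base] * (n_folds - rem) + [base + 1] * rem
    folds, start = [], 0
    for s in sizes:
        folds.append(order[start : start + s])
        start += s
    return folds


def cross_validate(
    model_id: str,
    behavior: BehaviorDataset,
    n_folds: int = 5,
    seed: int | None = None,
    n_starts: int = 1000,
) -> CVResult:
    """K-fold cross-validation of held-out trial predictions.

    The nonzero-investment trials are split into ``n_folds`` random folds
    (15/15/15/15/16 for the standard 76); for each fold the model is refit
    on the remainder and predicts the held-out trials. Returns the per-trial
    MSE, Pearson r, and r² pooled over all held-out trials. The correlation
    is None when either the predictions or the behavior are constant.
    """
    modeled_idx = np.flatnonzero(behavior.schedule.modeled)
    n = len(modeled_idx)
    if n < n_folds:
        raise ValueError("fewer modeled trials than folds")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, n_folds, rng)
    trials = behavior.schedule.trials
    preds = np.empty(n)
    obs = behavior.returned[modeled_idx].astype(float)
    for f, hold in enumerate(folds):
        train = np.setdiff1d(np.arange(n), hold)
        sub_sched = TaskSchedule(tuple(trials[modeled_idx[i]] for i in train))
        sub = BehaviorDataset(
            behavior.participant_id, sub_sched, behavior.returned[modeled_idx[train]]
        )
        fit = fit_model(model_id, sub, n_starts=n_starts, seed=None if seed is None else seed + f)
        hold_sched = TaskSchedule(tuple(trials[modeled_idx[i]] for i in hold))
        preds[hold] = predict_schedule(model_id, fit.params, hold_sched)
    mse = float(np.mean((preds - obs) ** 2))
    if np.std(preds) == 0 or np.std(obs) == 0:
        return CVResult(mse, None, None)
    r = float(np.corrcoef(preds, obs)[0, 1])
    return CVResult(mse, r, r * r)


def recover_parameters(
    n_subjects: int = 57,
    n_starts: int = 1000,
    seed: int | None = None,
    schedule_seed: int = 0,
) -> RecoveryResult:
    """Parameter recovery: simulate, refit, correlate true vs recovered.

    Draws ``n_subjects`` (theta, phi) points uniformly within the MS bounds,
    simulates noiseless behavior on the standard schedule, refits with
    ``n_starts`` multi-start iterations per subject, and reports Pearson r
    between true and recovered theta and phi plus the mean per-subject
    correlation between true and recovered-parameter predicted behavior
    (subjects with constant behavior are skipped in that mean, where the
    correlation is undefined).
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    schedule = build_schedule(schedule_seed)
    true_theta = rng.uniform(*MS_THETA_BOUNDS, size=n_subjects)
    true_phi = rng.uniform(*MS_PHI_BOUNDS, size=n_subjects)
    fit_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)

    rec_theta = np.empty(n_subjects)
    rec_phi = np.empty(n_subjects)
    behavior_rs = []
    rows = []
    for i in range(n_subjects):
        true = MSParams(float(true_theta[i]), float(true_phi[i]))
        data = simulate_behavior("MS", true, schedule, noise_sd=0.0, participant_id=f"sim{i:03d}")
        fit = fit_model("MS", data, n_starts=n_starts, seed=int(fit_seeds[i]))
        rec_theta[i], rec_phi[i] = fit.params.theta, fit.params.phi
        true_ret = data.modeled_returns().astype(float)
        pred_ret = predict_schedule("MS", fit.params, schedule)[schedule.modeled].astype(float)
        r = None
        if np.std(true_ret) > 0 and np.std(pred_ret) > 0:
            r = float(np.corrcoef(true_ret, pred_ret)[0, 1])
            behavior_rs.append(r)
        rows.append(
            {
                "participant_id": data.participant_id,
                "true_theta": true.theta,
                "true_phi": true.phi,
                "recovered_theta": fit.params.theta,
                "recovered_phi": fit.params.phi,
                "sse": fit.sse,
                "behavior_r": r,
            }
        )
    pairs = pd.DataFrame(rows)
    return RecoveryResult(
        r_theta=float(np.corrcoef(true_theta, rec_theta)[0, 1]),
        r_phi=float(np.corrcoef(true_phi, rec_phi)[0, 1]),
        mean_behavior_r=float(np.mean(behavior_rs)),
        pairs=pairs,
        n_behavior_used=len(behavior_rs),
    )
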