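"""Strategy-specific pattern analyses.

Cluster strength quantifies how tightly one strategy group's voxel patterns
cluster apart from the other participants' patterns in a parcel:

    score = (between_mean − within_mean) / max(between_mean, within_mean)

with dissimilarity 1 − Pearson r. Group-level inference permutes the sign
of the member scores. Cross-condition variants correlate a member's
pattern in one condition against *other* participants' patterns in another
condition, testing whether strategy-specific patterns generalize across
multiplier contexts. The conjunction of the within-×4 test and both
generalization tests yields a per-strategy "strategy map" of parcels.

The moral-opportunist shift analysis scores each MO participant's ×2 and ×6
patterns against the GA−IA difference map (difference of the two groups'
mean z-scored patterns): positive similarity means GA-like, negative
IA-like. Opportunists are expected to look IA-like in ×2 and GA-like in ×6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import NeuralDataset

__all__ = [
    "ClusterStrengthScore",
    "StrategyMap",
    "MOShiftResult",
    "cluster_strength",
    "cluster_strength_scores",
    "cross_condition_scores",
    "group_sign_test",
    "build_strategy_map",
    "ga_ia_difference_map",
    "mo_shift_analysis",
]


@dataclass
class ClusterStrengthScore:
    participant_id: str
    parcel_id: str
    condition_pair: tuple
    within_mean: float
    between_mean: float
    score: float


@dataclass
class StrategyMap:
    """Parcels significant in the ×4 clustering test and both generalization
    tests, per strategy."""

    parcels: dict  # strategy -> set of parcel ids
    alpha: float

    def __getitem__(self, strategy: str) -> set:
        return self.parcels[strategy]

    def exclusive(self, strategy: str, other: str) -> set:
        """Parcels in ``strategy``'s map but not in ``other``'s."""
        return self.parcels.get(strategy, set()) - self.parcels.get(other, set())

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "parcels": {k: sorted(v) for k, v in self.parcels.items()},
        }


@dataclass
class MOShiftResult:
    #: per MO participant × condition × parcel similarity table
    similarities: pd.DataFrame = field(repr=False)
    #: mean over all parcels: per-participant similarity by condition
    delta_r: float = np.nan
    t_stat: float = np.nan
    p_value: float = np.nan
    #: restricted aggregates over GA-only / IA-only parcels (None if empty set)
    ga_parcel_means: pd.DataFrame | None = None
    ia_parcel_means: pd.DataFrame | None = None
    accuracy: float = np.nan
    n_correct: int = 0
    n_mo: int = 0


def cluster_strength(within_mean: float, between_mean: float) -> float:
    """The silhouette-like score (between − within)/max(between, within)."""
    m = max(between_mean, within_mean)
    if m == 0:
        return 0.0
    return (between_mean - within_mean) / m


def _correlation_dissimilarity(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1 − Pearson r between rows of ``a`` (k, v) and rows of ``b`` (m, v)."""
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    return 1.0 - az @ bz.T / a.shape[1]


def _scores(
    dataset: NeuralDataset,
    from_condition: str,
    to_condition: str,
    parcel_id: str,
    labels: Sequence[str],
    target_group: str,
    exclude_groups: Sequence[str],
) -> list[ClusterStrengthScore]:
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(dataset.participant_ids):
        raise ValueError("one label per participant required")
    members = np.flatnonzero(labels == target_group)
    others = np.flatnonzero(
        (labels != target_group) & ~np.isin(labels, list(exclude_groups))
    )
    if len(members) < 2:
        raise ValueError(f"target group {target_group!r} needs >= 2 members")
    if len(others) < 1:
        raise ValueError("between pool is empty")
    pat_from = dataset.condition_patterns(from_condition, parcel_id)
    pat_to = dataset.condition_patterns(to_condition, parcel_id)
    if np.any(pat_from.std(axis=1) == 0) or np.any(pat_to.std(axis=1) == 0):
        raise ValueError(f"zero-variance pattern in parcel {parcel_id!r}")
    d = _correlation_dissimilarity(pat_from, pat_to)
    out = []
    for i in members:
        within = float(np.mean([d[i, j] for j in members if j != i]))
        between = float(np.mean(d[i, others]))
        out.append(
            ClusterStrengthScore(
                participant_id=dataset.participant_ids[i],
                parcel_id=parcel_id,
                condition_pair=(from_condition, to_condition),
                within_mean=within,
                between_mean=between,
                score=cluster_strength(within, between),
            )
        )
    return out


def cluster_strength_scores(
    dataset: NeuralDataset,
    condition: str,
    parcel_id: str,
    labels: Sequence[str],
    target_group: str,
    exclude_groups: Sequence[str] = ("GR",),
) -> list[ClusterStrengthScore]:
    """Within-condition cluster strength score for each target-group member.

    Dissimilarities are 1 − Pearson r between voxel patterns; the member
    itself is excluded from the within pool. Greedy participants are
    excluded from the between pool by default, mirroring their exclusion
    from the ×4 pattern-clustering analyses (their behavior differs in ×4,
    so including them would confound pattern and behavior differences).
    """
    return _scores(
        dataset, condition, condition, parcel_id, labels, target_group, exclude_groups
    )


def cross_condition_scores(
    dataset: NeuralDataset,
    parcel_id: str,
    labels: Sequence[str],
    target_group: str,
    from_condition: str = "x4",
    to_condition: str = "x2",
    exclude_groups: Sequence[str] = ("GR",),
) -> list[ClusterStrengthScore]:
    """Cross-condition generalization scores.

    Each member's ``from_condition`` pattern is compared against *other*
    participants' ``to_condition`` patterns (self excluded), asking whether
    the strategy-specific pattern carries over to another multiplier
    context.
    """
    return _scores(
        dataset, from_condition, to_condition, parcel_id, labels, target_group, exclude_groups
    )


def group_sign_test(
    scores: Sequence[float] | Sequence[ClusterStrengthScore],
    n_perm: int = 5000,
    seed: int | None = None,
    alternative: str = "greater",
) -> float:
    """Sign-flip permutation test for the mean cluster strength of a group.

    Exhaustive over all 2^n sign patterns when that is at most ``n_perm``
    (raw proportion, identity included); Monte Carlo with a +1/(n+1) guard
    otherwise. One-sided by default (positive mean = meaningful clustering).
    The permutation scheme implicitly controls for group size.
    """
    vals = np.array(
        [s.score if isinstance(s, ClusterStrengthScore) else float(s) for s in scores]
    )
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 scores")
    obs = vals.mean()
    if n <= 20 and 2**n <= n_perm:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        means = signs @ vals / n
        guard = 0
        denom = len(means)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        means = signs @ vals / n
        guard = 1
        denom = n_perm + 1
    if alternative == "greater":
        count = np.sum(means >= obs)
    elif alternative == "less":
        count = np.sum(means <= obs)
    else:
        count = np.sum(np.abs(means) >= abs(obs))
    return float((count + guard) / denom)


def build_strategy_map(
    within_p: Mapping[tuple, float],
    to_x2_p: Mapping[tuple, float],
    to_x6_p: Mapping[tuple, float],
    alpha: float = 0.05,
    strategies: Sequence[str] = ("GA", "IA", "MO"),
) -> StrategyMap:
    """Conjunction of the three tests: within-×4 clustering and the ×4→×2
    and ×4→×6 generalizations, all significant at ``alpha``.

    Each mapping is keyed by (strategy, parcel_id). An empty intersection is
    an empty map, not an error.
    """
    parcels: dict[str, set] = {}
    for s in strategies:
        keys = [k for k in within_p if k[0] == s]
        parcels[s] = {
            parcel
            for (strat, parcel) in keys
            if within_p[(strat, parcel)] < alpha
            and to_x2_p.get((strat, parcel), 1.0) < alpha
            and to_x6_p.get((strat, parcel), 1.0) < alpha
        }
    return StrategyMap(parcels, alpha)


def strategy_map_tests(
    dataset: NeuralDataset,
    labels: Sequence[str],
    condition: str = "x4",
    n_perm: int = 5000,
    seed: int | None = None,
    alpha: float = 0.05,
    strategies: Sequence[str] = ("GA", "IA", "MO"),
) -> tuple[StrategyMap, pd.DataFrame, list]:
    """Run the three sign tests for every (strategy, parcel) and conjoin them.

    Returns the strategy map, a long table of per-member scores with group
    p-values, and the list of strategies skipped for having < 2 members.
    """
    labels = list(labels)
    rng = np.random.default_rng(seed)
    within_p: dict = {}
    to_x2_p: dict = {}
    to_x6_p: dict = {}
    rows = []
    skipped = []
    for strategy in strategies:
        if labels.count(strategy) < 2:
            skipped.append(strategy)
            continue
        for parcel_id in dataset.parcel_ids:
            for tag, store in (
                ("within_x4", within_p),
                ("x4_to_x2", to_x2_p),
                ("x4_to_x6", to_x6_p),
            ):
                if tag == "within_x4":
                    scores = cluster_strength_scores(
                        dataset, condition, parcel_id, labels, strategy
                    )
                else:
                    scores = cross_condition_scores(
                        dataset,
                        parcel_id,
                        labels,
                        strategy,
                        from_condition=condition,
                        to_condition="x2" if tag == "x4_to_x2" else "x6",
                    )
                p_val = group_sign_test(
                    scores, n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1))
                )
                store[(strategy, parcel_id)] = p_val
                rows.extend(
                    {
                        "strategy": strategy,
                        "test": tag,
                        "parcel": parcel_id,
                        "participant_id": s.participant_id,
                        "score": s.score,
                        "p_group": p_val,
                    }
                    for s in scores
                )
    smap = build_strategy_map(within_p, to_x2_p, to_x6_p, alpha=alpha, strategies=[s for s in strategies if s not in skipped])
    return smap, pd.DataFrame(rows), skipped


def _zscore_rows(patterns: np.ndarray) -> np.ndarray:
    sd = patterns.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance pattern cannot be z-scored")
    return (patterns - patterns.mean(axis=1, keepdims=True)) / sd


def ga_ia_difference_map(
    dataset: NeuralDataset,
    labels: Sequence[str],
    condition: str,
    parcel_id: str,
) -> np.ndarray:
    """Mean z-scored GA pattern minus mean z-scored IA pattern.

    Z-scoring is across voxels within participant × condition × parcel, so
    the map reflects pattern shape, not overall activation level. Positive
    voxels are more active in guilt-averse than inequity-averse Trustees.
    """
    labels = np.asarray(labels, dtype=object)
    ga = np.flatnonzero(labels == "GA")
    ia = np.flatnonzero(labels == "IA")
    if len(ga) < 1 or len(ia) < 1:
        raise ValueError("need at least one GA and one IA participant")
    patterns = dataset.condition_patterns(condition, parcel_id)
    z_ga = _zscore_rows(patterns[ga])
    z_ia = _zscore_rows(patterns[ia])
    return z_ga.mean(axis=0) - z_ia.mean(axis=0)


def mo_shift_analysis(
    dataset: NeuralDataset,
    labels: Sequence[str],
    strategy_map: StrategyMap | None = None,
    parcel_ids: Sequence[str] | None = None,
) -> MOShiftResult:
    """Do moral opportunists shift between the GA and IA patterns?

    For each MO participant, condition (×2, ×6) and parcel, computes the
    Pearson similarity of the participant's z-scored pattern to that parcel
    and condition's GA−IA difference map. Aggregates: (i) the mean over all
    parcels, with a paired t test of ×6 vs ×2 (positive Δr means more
    GA-like in ×6); (ii) the same means restricted to GA-only and IA-only
    parcels of ``strategy_map`` when available; (iii) classification: an MO
    participant is correctly classified when their ×6 similarity exceeds
    their ×2 similarity (GA-like exactly when guilt aversion is the cheaper
    moral rule).
    """
    labels = np.asarray(labels, dtype=object)
    mo = np.flatnonzero(labels == "MO")
    if len(mo) < 2:
        raise ValueError("need at least 2 MO participants")
    if parcel_ids is None:
        parcel_ids = dataset.parcel_ids
    conditions = ("x2", "x6")
    rows = []
    for parcel_id in parcel_ids:
        for cond in conditions:
            diff_map = ga_ia_difference_map(dataset, labels, cond, parcel_id)
            if np.std(diff_map) == 0:
                sim = np.zeros(len(mo))
            else:
                z = _zscore_rows(dataset.condition_patterns(cond, parcel_id)[mo])
                dz = (diff_map - diff_map.mean()) / diff_map.std()
                sim = z @ dz / z.shape[1]
            for i, subj_idx in enumerate(mo):
                rows.append(
                    {
                        "participant_id": dataset.participant_ids[subj_idx],
                        "condition": cond,
                        "parcel": parcel_id,
                        "similarity": float(sim[i]),
                    }
                )
    sims = pd.DataFrame(rows)
    by_subj = sims.pivot_table(
        index="participant_id", columns="condition", values="similarity", aggfunc="mean"
    )
    deltas = by_subj["x6"] - by_subj["x2"]
    if np.allclose(deltas.std(ddof=1), 0):
        t_stat, p_value = (np.inf * np.sign(deltas.mean()), 0.0) if deltas.mean() != 0 else (0.0, 1.0)
    else:
        res = stats.ttest_rel(by_subj["x6"], by_subj["x2"])
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    n_correct = int(np.sum(by_subj["x6"] > by_subj["x2"]))

    def _restricted(subset):
        if not subset:
            return None
        sub = sims[sims["parcel"].isin(subset)]
        return sub.pivot_table(
            index="participant_id", columns="condition", values="similarity", aggfunc="mean"
        )

    ga_means = ia_means = None
    if strategy_map is not None:
        ga_means = _restricted(strategy_map.exclusive("GA", "IA"))
        ia_means = _restricted(strategy_map.exclusive("IA", "GA"))

    return MOShiftResult(
        similarities=sims,
        delta_r=float(deltas.mean()),
        t_stat=t_stat,
        p_value=p_value,
        ga_parcel_means=ga_means,
        ia_parcel_means=ia_means,
        accuracy=n_correct / len(mo),
        n_correct=n_correct,
        n_mo=len(mo),
    )
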