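"""Model-driven partition of the theta–phi plane into four strategy zones.

Trustee behavior is simulated on a dense grid of (theta, phi) points, one
predicted-return vector per point over all investment × multiplier
combinations. Hierarchical clustering of these behavior vectors (squared-
Euclidean geometry; Ward linkage by default) cuts the dendrogram at four
clusters, which are then named by matching each cluster's centroid to the
nearest of the four closed-form strategy prototypes (GR, GA, IA, MO).
Participants are assigned to the zone of the nearest grid point in raw
parameter units. Because the zones are built from simulations alone, the
partition is independent of any participant sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core import (
    MS_PHI_BOUNDS,
    MS_THETA_BOUNDS,
    STRATEGIES,
    MSParams,
    predict_combos,
    prototype_vector,
)

__all__ = [
    "GridSimulations",
    "StrategyZones",
    "simulate_grid",
    "cluster_grid",
    "assign_strategy",
    "strategy_counts",
    "cosine_similarity",
]

#: investment (0..10) × multiplier (2,4,6) combos, investment-major
GRID_INVESTMENTS = np.repeat(np.arange(11), 3)
GRID_MULTIPLIERS = np.tile(np.array([2, 4, 6]), 11)


@dataclass
class GridSimulations:
    """Predicted-behavior vectors at evenly spaced (theta, phi) grid points."""

    theta_values: np.ndarray
    phi_values: np.ndarray
    #: (n_points, 2) parameter coordinates, row-major over theta then phi
    points: np.ndarray
    #: (n_points, 33) integer predicted returns
    behavior: np.ndarray

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class StrategyZones:
    """Zone label per grid point plus the clustering record."""

    grid: GridSimulations
    labels: np.ndarray  # array of {"IA","GA","MO","GR"} per grid point
    linkage_matrix: np.ndarray = field(repr=False)
    linkage_method: str = "ward"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.grid.points[:, 0],
                "phi": self.grid.points[:, 1],
                "label": self.labels,
            }
        )

    def linkage_json(self) -> str:
        return json.dumps(
            {"method": self.linkage_method, "linkage": self.linkage_matrix.tolist()}
        )


def simulate_grid(n_theta: int = 101, n_phi: int = 101) -> GridSimulations:
    """Simulate Trustee behavior on an n_theta × n_phi parameter grid.

    Theta spans [0, 0.5] and phi [−0.1, 0.1] inclusive. Each point yields a
    33-vector of predicted returns over investment 0..10 × multiplier
    {2, 4, 6}; zero-investment entries are 0 by convention.
    """
    if n_theta < 2 or n_phi < 2:
        raise ValueError("need at least 2 grid steps per axis")
    theta_values = np.linspace(*MS_THETA_BOUNDS, n_theta)
    phi_values = np.linspace(*MS_PHI_BOUNDS, n_phi)
    tt, pp = np.meshgrid(theta_values, phi_values, indexing="ij")
    points = np.column_stack([tt.ravel(), pp.ravel()])
    behavior = predict_combos(
        "MS", points[:, 0], points[:, 1], GRID_INVESTMENTS, GRID_MULTIPLIERS
    )
    return GridSimulations(theta_values, phi_values, points, behavior)


def _prototype_matrix() -> tuple[list[str], np.ndarray]:
    names = list(STRATEGIES)
    protos = np.stack(
        [prototype_vector(s, GRID_INVESTMENTS, GRID_MULTIPLIERS) for s in names]
    )
    return names, protos.astype(float)


def cluster_grid(
    grid: GridSimulations, n_clusters: int = 4, linkage_method: str = "ward"
) -> StrategyZones:
    """Agglomerative clustering of grid behavior vectors into named zones.

    Ward linkage is applied to the raw behavior vectors (Ward's objective is
    the squared-Euclidean within-cluster variance); other linkage methods
    operate on the condensed squared-Euclidean distance matrix. The tree is
    cut at ``n_clusters`` and each cluster is named by the prototype nearest
    to its centroid; a non-bijective naming raises, signalling degenerate
    clustering (e.g. a grid slice where all points behave identically).
    """
    X = grid.behavior.astype(float)
    if len(np.unique(X, axis=0)) < n_clusters:
        raise ValueError("degenerate grid: fewer distinct behavior patterns than clusters")
    if linkage_method == "ward":
        Z = linkage(X, method="ward")
    else:
        Z = linkage(pdist(X, metric="sqeuclidean"), method=linkage_method)
    cluster_ids = fcluster(Z, t=n_clusters, criterion="maxclust")
    if len(np.unique(cluster_ids)) != n_clusters:
        raise ValueError("clustering produced fewer clusters than requested")

    names, protos = _prototype_matrix()
    labels = np.empty(grid.n_points, dtype=object)
    assigned: dict[int, str] = {}
    for cid in np.unique(cluster_ids):
        centroid = X[cluster_ids == cid].mean(axis=0)
        nearest = names[int(np.argmin(((protos - centroid) ** 2).sum(axis=1)))]
        assigned[int(cid)] = nearest
    if len(set(assigned.values())) != n_clusters:
        raise ValueError(
            f"prototype naming is not a bijection: {assigned} (degenerate clustering)"
        )
    for cid, name in assigned.items():
        labels[cluster_ids == cid] = name
    return StrategyZones(grid, labels, Z, linkage_method)


def assign_strategy(
    params: MSParams, zones: StrategyZones, normalized: bool = False
) -> str:
    """Zone label of the Euclidean-nearest grid point.

    Distances are measured in raw parameter units by default (theta range
    0.5, phi range 0.2); ``normalized=True`` rescales each axis to unit
    range first. Ties break to the lowest row-major grid index.
    """
    pts = zones.grid.points
    d = pts - np.array([params.theta, params.phi])
    if normalized:
        d = d / np.array(
            [
                MS_THETA_BOUNDS[1] - MS_THETA_BOUNDS[0],
                MS_PHI_BOUNDS[1] - MS_PHI_BOUNDS[0],
            ]
        )
    idx = int(np.argmin((d**2).sum(axis=1)))
    return str(zones.labels[idx])


def strategy_counts(labels) -> np.ndarray:
    """Counts per strategy in canonical (IA, GA, MO, GR) order."""
    labels = list(labels)
    return np.array([labels.count(s) for s in STRATEGIES])


def cosine_similarity(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Cosine similarity between two cohort strategy-count vectors."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
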