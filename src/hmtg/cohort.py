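"""Synthetic cohorts with known moral strategies and parcel-wise patterns.

The behavioral generator draws each participant's (theta, phi) uniformly
from their assigned strategy zone and simulates returns from the Moral
Strategy Model with bounded integer noise on the standard 80-trial schedule.
Default group sizes (24 IA, 5 GA, 21 MO, 7 GR) mirror the study sample.

The neural generator produces per-parcel multi-voxel "beta" vectors per
participant × condition with planted statistical structure:

* ``null`` — i.i.d. Gaussian noise, for false-positive calibration.
* ``geometry`` — patterns whose inter-subject correlation distance tracks
  the participants' Euclidean distance in theta–phi space.
* ``group_template`` — a fixed template per coded strategy group, stable
  across conditions; uncoded groups get noise only.
* ``switching`` — GA and IA templates; moral opportunists use the IA
  template in ×2, the GA template in ×6, and a mixture in ×4.

All templates are drawn once per parcel from a seeded Gaussian and
orthonormalized, so the planted structure is identifiable by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MS_PHI_BOUNDS,
    MS_THETA_BOUNDS,
    BehaviorDataset,
    MSParams,
    TaskSchedule,
    build_schedule,
    read_behavior_csv,
    simulate_behavior,
    write_behavior_csv,
)
from .strategy_space import StrategyZones, assign_strategy, cluster_grid, simulate_grid

__all__ = [
    "CONDITIONS",
    "CohortSpec",
    "ParcelSpec",
    "Participant",
    "Cohort",
    "NeuralDataset",
    "default_parcel_specs",
    "generate_cohort",
    "generate_neural",
    "write_dataset",
    "read_dataset",
]

CONDITIONS = ("x2", "x4", "x6")
CONTAINER_VERSION = "1"


@dataclass
class CohortSpec:
    """Study-condition defaults: group sizes as observed, noise at the
    empirical model-error scale (sd ≈ 2.3 tokens, i.e. MSE ≈ 5.3)."""

    group_sizes: dict = field(
        default_factory=lambda: {"IA": 24, "GA": 5, "MO": 21, "GR": 7}
    )
    noise_sd: float = 2.3
    schedule_seed: int = 0
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        for g, n in self.group_sizes.items():
            if g not in ("IA", "GA", "MO", "GR"):
                problems.append(f"unknown strategy group {g!r}")
            elif n < 0:
                problems.append(f"group size for {g} must be >= 0")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        return problems


@dataclass
class ParcelSpec:
    parcel_id: str
    kind: str  # {"null", "geometry", "group_template", "switching"}
    n_voxels: int = 60
    amplitude: float = 4.0
    coded_groups: tuple = ("GA", "IA", "MO")
    #: MO mixture weight on the GA template in the ×4 condition
    mix_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("null", "geometry", "group_template", "switching"):
            raise ValueError(f"unknown parcel kind {self.kind!r}")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        self.coded_groups = tuple(self.coded_groups)


@dataclass
class Participant:
    participant_id: str
    params: MSParams
    strategy: str
    behavior: BehaviorDataset


@dataclass
class Cohort:
    participants: list[Participant]
    schedule: TaskSchedule
    spec: CohortSpec
    zones: StrategyZones | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    @property
    def labels(self) -> list[str]:
        return [p.strategy for p in self.participants]

    @property
    def params_list(self) -> list[MSParams]:
        return [p.params for p in self.participants]


@dataclass
class NeuralDataset:
    """Per participant × condition × parcel voxel patterns."""

    participant_ids: list[str]
    conditions: tuple = CONDITIONS
    #: parcel_id -> (n_participants, n_conditions, n_voxels) array
    betas: dict = field(default_factory=dict)
    parcel_specs: dict = field(default_factory=dict)

    @property
    def parcel_ids(self) -> list[str]:
        return list(self.betas)

    def pattern(self, participant_id: str, condition: str, parcel_id: str) -> np.ndarray:
        i = self.participant_ids.index(participant_id)
        c = self.conditions.index(condition)
        return self.betas[parcel_id][i, c]

    def condition_patterns(self, condition: str, parcel_id: str) -> np.ndarray:
        """(n_participants, n_voxels) patterns for one condition and parcel."""
        return self.betas[parcel_id][:, self.conditions.index(condition)]


def default_parcel_specs(
    n_per_kind: int = 5, n_voxels: int = 60, amplitude: float = 4.0
) -> list[ParcelSpec]:
    """The default 20-parcel battery: 5 parcels of each kind.

    Group-template parcels cycle through coded-group sets so that single-
    strategy and multi-strategy codings are both represented.
    """
    specs: list[ParcelSpec] = []
    codings = [("GA",), ("IA",), ("MO",), ("GA", "IA"), ("GA", "IA", "MO")]
    for kind in ("null", "geometry", "group_template", "switching"):
        for i in range(n_per_kind):
            coded = codings[i % len(codings)] if kind == "group_template" else ("GA", "IA", "MO")
            specs.append(
                ParcelSpec(
                    parcel_id=f"{kind}-{i:02d}",
                    kind=kind,
                    n_voxels=n_voxels,
                    amplitude=amplitude,
                    coded_groups=coded,
                )
            )
    return specs


def _in_zone_interior(theta: float, phi: float, zones: StrategyZones, label: str) -> bool:
    """True when the enclosing grid cell's four corners all carry ``label``.

    Points in boundary cells are ambiguous: a parameter point there can
    produce behavior identical to a neighboring zone's grid point, so its
    strategy label is a coin flip of the assignment rule rather than a
    property of the behavior.
    """
    tv, pv = zones.grid.theta_values, zones.grid.phi_values
    it = int(np.clip(np.searchsorted(tv, theta) - 1, 0, len(tv) - 2))
    ip = int(np.clip(np.searchsorted(pv, phi) - 1, 0, len(pv) - 2))
    n_phi = len(pv)
    corners = [it * n_phi + ip, it * n_phi + ip + 1, (it + 1) * n_phi + ip, (it + 1) * n_phi + ip + 1]
    return all(zones.labels[c] == label for c in corners)


def generate_cohort(
    spec: CohortSpec, zones: StrategyZones | None = None, interior: bool = True
) -> Cohort:
    """Generate a cohort of simulated Trustees with known strategies.

    Parameters are rejection-sampled uniformly within each requested zone
    (uniform over the zone's area); with ``interior`` (default) points in
    grid cells that straddle a zone boundary are rejected, so every
    participant's strategy is unambiguous. Behavior is simulated from the
    MS model with the spec's noise. Deterministic for a fixed spec.
    """
    problems = spec.validate()
    if problems:
        raise ValueError("; ".join(problems))
    if zones is None:
        zones = cluster_grid(simulate_grid())
    for g, n in spec.group_sizes.items():
        if n > 0 and not np.any(zones.labels == g):
            raise ValueError(f"zone {g} has no grid support")
    rng = np.random.default_rng(spec.seed)
    schedule = build_schedule(spec.schedule_seed)
    participants: list[Participant] = []
    idx = 0
    for g in ("IA", "GA", "MO", "GR"):
        for _ in range(spec.group_sizes.get(g, 0)):
            for _attempt in range(100_000):
                theta = rng.uniform(*MS_THETA_BOUNDS)
                phi = rng.uniform(*MS_PHI_BOUNDS)
                params = MSParams(theta, phi)
                if assign_strategy(params, zones) == g and (
                    not interior or _in_zone_interior(theta, phi, zones, g)
                ):
                    break
            else:  # pragma: no cover - zones always have interior area
                raise RuntimeError(f"could not sample a point in zone {g}")
            pid = f"p{idx:03d}"
            behavior = simulate_behavior(
                "MS",
                params,
                schedule,
                noise_sd=spec.noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                participant_id=pid,
            )
            participants.append(Participant(pid, params, g, behavior))
            idx += 1
    return Cohort(participants, schedule, spec, zones)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_vectors(rng: np.random.Generator, n_voxels: int, k: int) -> list[np.ndarray]:
    """k orthonormal Gaussian directions via Gram–Schmidt."""
    vecs: list[np.ndarray] = []
    while len(vecs) < k:
        v = rng.standard_normal(n_voxels)
        for u in vecs:
            v -= (v @ u) * u
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            vecs.append(v / norm)
    return vecs


#: weight of the shared baseline direction in geometry parcels, relative to
#: the theta/phi axes; a strong common component makes the correlation
#: distance between subjects increase monotonically with their parameter-
#: space distance (correlation distance is locally proportional to squared
#: Euclidean distance around a shared mean pattern)
GEOMETRY_BASELINE = 2.0


def generate_neural(
    cohort: Cohort,
    parcel_specs: Sequence[ParcelSpec],
    noise_sd_voxel: float = 1.0,
    seed: int | None = None,
) -> NeuralDataset:
    """Generate parcel beta patterns with the planted structure of each spec.

    With amplitude 0 every parcel reduces to a null parcel. Deterministic
    per seed.
    """
    if noise_sd_voxel < 0:
        raise ValueError("noise_sd_voxel must be >= 0")
    ids = cohort.ids
    labels = cohort.labels
    n = len(ids)
    theta = np.array([p.theta for p in cohort.params_list])
    phi = np.array([p.phi for p in cohort.params_list])
    # Isotropic rescale: one scale factor for both axes (theta spans [-1, 1];
    # phi spans [-0.4, 0.4]). A per-axis rescale would distort the theta:phi
    # aspect ratio and break the correspondence with the raw-unit model RDM.
    scale = 2.0 / (MS_THETA_BOUNDS[1] - MS_THETA_BOUNDS[0])
    mid_theta = (MS_THETA_BOUNDS[0] + MS_THETA_BOUNDS[1]) / 2
    mid_phi = (MS_PHI_BOUNDS[0] + MS_PHI_BOUNDS[1]) / 2
    theta_t = (theta - mid_theta) * scale
    phi_t = (phi - mid_phi) * scale

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(parcel_specs))
    dataset = NeuralDataset(participant_ids=list(ids))
    for spec, child in zip(parcel_specs, children):
        rng = np.random.default_rng(child)
        a = spec.amplitude
        mean = np.zeros((n, len(CONDITIONS), spec.n_voxels))
        if spec.kind == "geometry":
            b, u, v = _orthonormal_vectors(rng, spec.n_voxels, 3)
            m = a * (
                GEOMETRY_BASELINE * b[None, :]
                + theta_t[:, None] * u[None, :]
                + phi_t[:, None] * v[None, :]
            )
            mean[:] = m[:, None, :]
        elif spec.kind == "group_template":
            templates = _orthonormal_vectors(rng, spec.n_voxels, len(spec.coded_groups))
            tmap = dict(zip(spec.coded_groups, templates))
            for i, g in enumerate(labels):
                if g in tmap:
                    mean[i, :, :] = a * tmap[g]
        elif spec.kind == "switching":
            t_ga, t_ia = _orthonormal_vectors(rng, spec.n_voxels, 2)
            w = spec.mix_weight
            for i, g in enumerate(labels):
                if g == "GA":
                    mean[i, :, :] = a * t_ga
                elif g == "IA":
                    mean[i, :, :] = a * t_ia
                elif g == "MO":
                    mean[i, CONDITIONS.index("x2")] = a * t_ia
                    mean[i, CONDITIONS.index("x6")] = a * t_ga
                    mean[i, CONDITIONS.index("x4")] = a * (w * t_ga + (1 - w) * t_ia)
        # "null" parcels keep a zero mean
        noise = rng.standard_normal(mean.shape) * noise_sd_voxel
        dataset.betas[spec.parcel_id] = mean + noise
        dataset.parcel_specs[spec.parcel_id] = spec
    return dataset


# ---------------------------------------------------------------------------
# Container I/O: a directory of CSV/JSON files, re-derivable from seeds.


def write_dataset(path, cohort: Cohort, neural: NeuralDataset | None = None) -> None:
    """Write cohort (and optionally neural) data as a versioned directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": CONTAINER_VERSION,
        "cohort_spec": {
            "group_sizes": cohort.spec.group_sizes,
            "noise_sd": cohort.spec.noise_sd,
            "schedule_seed": cohort.spec.schedule_seed,
            "seed": cohort.spec.seed,
        },
        "participants": [
            {
                "participant_id": p.participant_id,
                "theta": p.params.theta,
                "phi": p.params.phi,
                "strategy": p.strategy,
            }
            for p in cohort.participants
        ],
        "parcels": [],
        "conditions": list(CONDITIONS),
    }
    write_behavior_csv((p.behavior for p in cohort.participants), path / "behavior.csv")
    if neural is not None:
        parcel_dir = path / "parcels"
        parcel_dir.mkdir(exist_ok=True)
        for pid, spec in neural.parcel_specs.items():
            manifest["parcels"].append(
                {
                    "parcel_id": spec.parcel_id,
                    "kind": spec.kind,
                    "n_voxels": spec.n_voxels,
                    "amplitude": spec.amplitude,
                    "coded_groups": list(spec.coded_groups),
                    "mix_weight": spec.mix_weight,
                }
            )
            arr = neural.betas[pid]
            n, nc, nv = arr.shape
            df = pd.DataFrame(arr.reshape(n * nc, nv), columns=[f"v{k}" for k in range(nv)])
            df.insert(0, "participant_id", np.repeat(neural.participant_ids, nc))
            df.insert(1, "condition", np.tile(neural.conditions, n))
            # %.17g round-trips float64 exactly
            df.to_csv(parcel_dir / f"{pid}.csv", index=False, float_format="%.17g")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(path) -> tuple[Cohort, NeuralDataset | None]:
    """Read a dataset container written by :func:`write_dataset`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("version") != CONTAINER_VERSION:
        raise ValueError(
            f"unsupported container version {manifest.get('version')!r}; "
            f"expected {CONTAINER_VERSION!r}"
        )
    spec = CohortSpec(**manifest["cohort_spec"])
    behaviors = {b.participant_id: b for b in read_behavior_csv(path / "behavior.csv")}
    participants = [
        Participant(
            rec["participant_id"],
            MSParams(rec["theta"], rec["phi"]),
            rec["strategy"],
            behaviors[rec["participant_id"]],
        )
        for rec in manifest["participants"]
    ]
    schedule = participants[0].behavior.schedule if participants else None
    cohort = Cohort(participants, schedule, spec)
    neural = None
    if manifest["parcels"]:
        neural = NeuralDataset(
            participant_ids=[p.participant_id for p in participants],
            conditions=tuple(manifest["conditions"]),
        )
        for rec in manifest["parcels"]:
            spec_p = ParcelSpec(
                parcel_id=rec["parcel_id"],
                kind=rec["kind"],
                n_voxels=rec["n_voxels"],
                amplitude=rec["amplitude"],
                coded_groups=tuple(rec["coded_groups"]),
                mix_weight=rec["mix_weight"],
            )
            df = pd.read_csv(
                path / "parcels" / f"{spec_p.parcel_id}.csv", float_precision="round_trip"
            )
            n, nc, nv = len(participants), len(neural.conditions), spec_p.n_voxels
            arr = np.empty((n, nc, nv))
            vcols = [f"v{k}" for k in range(nv)]
            for i, subj in enumerate(neural.participant_ids):
                for c, cond in enumerate(neural.conditions):
                    row = df[(df["participant_id"] == subj) & (df["condition"] == cond)]
                    arr[i, c] = row[vcols].to_numpy()[0]
            neural.betas[spec_p.parcel_id] = arr
            neural.parcel_specs[spec_p.parcel_id] = spec_p
    return cohort, neural
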