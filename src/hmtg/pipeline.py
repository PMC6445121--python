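"""End-to-end synthetic-study pipeline with explicit seeding and manifests.

Stage order mirrors the analysis narrative: simulate behavior → fit models →
compare models → partition the parameter space and assign strategies →
simulate parcel patterns → inter-subject RSA → cluster strength and
cross-condition generalization → strategy maps → moral-opportunist shift.
A single global seed fans out into per-stage child seeds recorded in the
run manifest; re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortSpec,
    ParcelSpec,
    default_parcel_specs,
    generate_cohort,
    generate_neural,
    write_dataset,
)
from .core import MS_PHI_BOUNDS, MS_THETA_BOUNDS, MODELS, write_behavior_csv
from .fitting import compare_models, fit_model
from .isrsa import isrsa_all_parcels
from .patterns import mo_shift_analysis, strategy_map_tests
from .strategy_space import assign_strategy, cluster_grid, simulate_grid

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_full_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    parcels: list = field(default_factory=default_parcel_specs)
    noise_sd_voxel: float = 1.0
    n_starts: int = 10_000
    n_perm_isrsa: int = 10_000
    n_perm_sign: int = 5000
    alpha: float = 0.05
    #: Bonferroni family size; None = number of parcels in the battery
    bonferroni_n: int | None = None
    grid_shape: tuple = (101, 101)
    linkage_method: str = "ward"
    condition: str = "x4"
    fit_theta_bounds: tuple = MS_THETA_BOUNDS
    fit_phi_bounds: tuple = MS_PHI_BOUNDS
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = asdict(self.cohort)
        d["parcels"] = [asdict(p) for p in self.parcels]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortSpec(**d["cohort"])
        if "parcels" in d:
            d["parcels"] = [
                p if isinstance(p, ParcelSpec) else ParcelSpec(**{**p, "coded_groups": tuple(p["coded_groups"])})
                for p in d["parcels"]
            ]
        for key in ("grid_shape", "fit_theta_bounds", "fit_phi_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    text = Path(path).read_text()
    return PipelineConfig.from_dict(yaml.safe_load(text))


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seeds: dict
    outputs: dict
    timings: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "stage_seeds": self.stage_seeds,
                "outputs": self.outputs,
                "timings": self.timings,
            },
            indent=1,
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """All invariant violations in the config; empty list means valid."""
    v: list[str] = []
    v.extend(config.cohort.validate())
    if config.noise_sd_voxel < 0:
        v.append("noise_sd_voxel must be >= 0")
    for name in ("n_starts", "n_perm_isrsa", "n_perm_sign"):
        if getattr(config, name) < 2:
            v.append(f"{name} must be >= 2")
    if not 0 < config.alpha < 1:
        v.append("alpha must be in (0, 1)")
    if config.bonferroni_n is not None and config.bonferroni_n < 1:
        v.append("bonferroni_n must be >= 1")
    if any(s < 2 for s in config.grid_shape):
        v.append("grid_shape entries must be >= 2")
    lo, hi = config.fit_theta_bounds
    if not (MS_THETA_BOUNDS[0] <= lo < hi <= MS_THETA_BOUNDS[1]):
        v.append(f"fit_theta_bounds must lie within {MS_THETA_BOUNDS} (theta)")
    lo, hi = config.fit_phi_bounds
    if not (MS_PHI_BOUNDS[0] <= lo < hi <= MS_PHI_BOUNDS[1]):
        v.append(f"fit_phi_bounds must lie within {MS_PHI_BOUNDS} (phi)")
    if config.condition not in ("x2", "x4", "x6"):
        v.append("condition must be one of x2/x4/x6")
    ids = [p.parcel_id for p in config.parcels]
    if len(set(ids)) != len(ids):
        v.append("parcel ids must be unique")
    return v


def run_full_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Run every stage on synthetic data and write all tables under ``outdir``."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    child = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ("cohort", "fit", "compare", "neural", "isrsa", "signperm"), ss.spawn(6)
        )
    }
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        t0 = time.perf_counter()

        def done(path=None):
            timings[name] = round(time.perf_counter() - t0, 3)
            if path is not None:
                outputs[name] = str(path)

        return done

    try:
        # 1. strategy zones (simulation-only; independent of the cohort)
        done = _stage("zones")
        zones = cluster_grid(
            simulate_grid(*config.grid_shape), linkage_method=config.linkage_method
        )
        zones.to_frame().to_csv(outdir / "zones.csv", index=False)
        done(outdir / "zones.csv")

        # 2. behavior
        done = _stage("behavior")
        cohort_spec = CohortSpec(
            group_sizes=dict(config.cohort.group_sizes),
            noise_sd=config.cohort.noise_sd,
            schedule_seed=config.cohort.schedule_seed,
            seed=child["cohort"],
        )
        cohort = generate_cohort(cohort_spec, zones)
        write_behavior_csv((p.behavior for p in cohort.participants), outdir / "behavior.csv")
        done(outdir / "behavior.csv")

        # 3. model fitting
        done = _stage("fit")
        rng = np.random.default_rng(child["fit"])
        fits = {m: [] for m in MODELS}
        rows = []
        for p in cohort.participants:
            for m in MODELS:
                f = fit_model(
                    m,
                    p.behavior,
                    n_starts=config.n_starts,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                fits[m].append(f)
                rows.append({"participant_id": p.participant_id, **f.to_dict()})
        pd.DataFrame(rows).to_csv(outdir / "fits.csv", index=False)
        done(outdir / "fits.csv")

        # 4. model comparison
        done = _stage("compare")
        comparison = compare_models(
            fits, method="sign_permutation", n_perm=config.n_perm_sign, seed=child["compare"]
        )
        comparison.to_csv(outdir / "comparison.csv", index=False)
        done(outdir / "comparison.csv")

        # 5. strategy assignment from fitted parameters
        done = _stage("assign")
        assigned = [assign_strategy(f.params, zones) for f in fits["MS"]]
        pd.DataFrame(
            {
                "participant_id": cohort.ids,
                "true_strategy": cohort.labels,
                "fitted_theta": [f.params.theta for f in fits["MS"]],
                "fitted_phi": [f.params.phi for f in fits["MS"]],
                "assigned_strategy": assigned,
            }
        ).to_csv(outdir / "assignments.csv", index=False)
        done(outdir / "assignments.csv")

        # 6. neural patterns
        done = _stage("neural")
        neural = generate_neural(
            cohort, config.parcels, noise_sd_voxel=config.noise_sd_voxel, seed=child["neural"]
        )
        write_dataset(outdir / "dataset", cohort, neural)
        done(outdir / "dataset")

        # 7. IS-RSA in the focal condition
        done = _stage("isrsa")
        isrsa_df = isrsa_all_parcels(
            neural,
            [f.params for f in fits["MS"]],
            condition=config.condition,
            n_perm=config.n_perm_isrsa,
            seed=child["isrsa"],
            alpha=config.alpha,
            n_tests=config.bonferroni_n,
        )
        isrsa_df.to_csv(outdir / "isrsa.csv", index=False)
        done(outdir / "isrsa.csv")

        # 8. cluster strength, generalization, strategy maps
        done = _stage("patterns")
        labels = assigned
        strategy_map, score_table, skipped = strategy_map_tests(
            neural,
            labels,
            condition=config.condition,
            n_perm=config.n_perm_sign,
            seed=child["signperm"],
            alpha=config.alpha,
        )
        score_table.to_csv(outdir / "cluster_strength.csv", index=False)
        map_payload = strategy_map.to_json_dict()
        map_payload["skipped_groups"] = skipped
        (outdir / "strategy_maps.json").write_text(json.dumps(map_payload, indent=1))
        done(outdir / "strategy_maps.json")

        # 9. moral-opportunist shift
        done = _stage("mo_shift")
        if labels.count("MO") >= 2 and "GA" not in skipped and "IA" not in skipped:
            mo = mo_shift_analysis(neural, labels, strategy_map)
            summary = {
                "delta_r": mo.delta_r,
                "t_stat": mo.t_stat,
                "p_value": mo.p_value,
                "accuracy": mo.accuracy,
                "n_correct": mo.n_correct,
                "n_mo": mo.n_mo,
            }
            mo.similarities.to_csv(outdir / "mo_similarities.csv", index=False)
        else:
            summary = {"skipped": True, "reason": "insufficient GA/IA/MO members"}
        (outdir / "mo_shift.json").write_text(json.dumps(summary, indent=1))
        done(outdir / "mo_shift.json")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        failed = [n for n in ("zones", "behavior", "fit", "compare", "assign", "neural", "isrsa", "patterns", "mo_shift") if n not in timings]
        stage = failed[0] if failed else "unknown"
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.hash(),
        version=__version__,
        stage_seeds=child,
        outputs=outputs,
        timings=timings,
    )
    (outdir / "manifest.json").write_text(manifest.to_json())
    save_config(config, outdir / "config.yaml")
    return manifest
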