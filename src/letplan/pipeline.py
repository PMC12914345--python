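"""End-to-end experiment orchestration.

One configuration drives the whole chain: phantom construction, spot
placement, the nine-scenario influence computation, the three plan
optimizations (nominal, robust, LET), D95 normalization, and the
evaluation report.  Three shipped configurations (one per anatomical
archetype) reproduce the default study conditions; every run writes a
manifest with the configuration hash and seed so repeated runs are
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beamlets import BeamConfig, compute_influence, place_spots
from .evaluate import compare_plans, normalize_to_d95
from .optimize import ObjectiveSpec, plan_strategy
from .phantom import ARCHETYPES, PhantomSpec, build_phantom, save_phantom
from .uncertainty import generate_scenarios

log = logging.getLogger("letplan")

#: Beam arrangements of the three emulated cases (gantry, couch) in degrees.
DEFAULT_BEAMS = {
    "wraparound": [(180, 0), (270, 15), (90, 345)],
    "abutting": [(245, 0), (180, 0), (112, 0), (315, 0)],
    "inferior_extension": [(105, 0), (255, 0), (285, 90)],
}


class ConfigError(ValueError):
    """Raised when an experiment configuration fails validation."""


@dataclass
class ExperimentConfig:
    """Validated configuration for one archetype experiment."""

    archetype: str
    beams: list = field(default_factory=list)  # (gantry, couch) pairs
    objective: dict = field(default_factory=dict)
    scenarios: dict = field(default_factory=lambda: {"setup_mm": 2.25,
                                                     "range_fraction": 0.035})
    biology: dict = field(default_factory=lambda: {
        "alpha_beta": {"ctv": 10.0, "brainstem": 2.0, "spinal_cord": 2.0},
        "n_fractions": 30,
        "c": 0.04,
    })
    spots: dict = field(default_factory=lambda: {"lateral_spacing": 5.0,
                                                 "layer_step": 5.0})
    solver: dict = field(default_factory=lambda: {"maxiter": 400, "seed": 0})
    evaluation: dict = field(default_factory=lambda: {"d95_reference": 54.0,
                                                      "dose_threshold": 1.0})
    phantom_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigError(f"unknown archetype {self.archetype!r}")
        if not self.beams:
            self.beams = [list(b) for b in DEFAULT_BEAMS[self.archetype]]
        for b in self.beams:
            if len(b) != 2:
                raise ConfigError(f"beam entry {b!r} must be (gantry, couch)")
        for key in ("setup_mm", "range_fraction"):
            if key not in self.scenarios:
                raise ConfigError(f"scenarios config missing {key!r}")

    def objective_spec(self) -> ObjectiveSpec:
        return ObjectiveSpec(**self.objective)

    def phantom_spec(self) -> PhantomSpec:
        spec = PhantomSpec.default(self.archetype)
        for k, v in self.phantom_overrides.items():
            if not hasattr(spec, k):
                raise ConfigError(f"unknown phantom field {k!r}")
            setattr(spec, k, tuple(v) if isinstance(v, list) else v)
        return spec

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict) or "archetype" not in data:
            raise ConfigError("config must be a mapping with an 'archetype' key")
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def default_config(archetype: str) -> ExperimentConfig:
    """Load the shipped per-archetype configuration."""
    name = f"{archetype}.yaml"
    try:
        text = (resources.files("letplan") / "configs" / name).read_text()
    except FileNotFoundError as e:
        raise ConfigError(f"no shipped config for archetype {archetype!r}") from e
    return ExperimentConfig(**yaml.safe_load(text))


@dataclass
class ExperimentResult:
    """Outputs of one archetype run."""

    config: ExperimentConfig
    grid: object
    plans: dict
    influences: dict
    report: object
    structures: dict
    timings: dict
    out_dir: Path | None = None


def run_experiment(config: ExperimentConfig, out_dir=None,
                   seed: int | None = None) -> ExperimentResult:
    """Run phantom -> spots -> scenarios -> three plans -> evaluation.

    ``out_dir=None`` keeps everything in memory; otherwise phantom
    volumes, plan JSONs, report CSVs, and a run manifest are written.
    Deterministic for a fixed configuration and seed.
    """
    t_all = time.time()
    timings = {}
    if seed is not None:
        config.solver["seed"] = int(seed)

    def stage(name):
        log.info("stage %s", name)
        return time.time()

    try:
        t = stage("phantom")
        grid = build_phantom(config.phantom_spec())
        timings["phantom"] = time.time() - t
    except Exception as e:
        raise RuntimeError(f"stage 'phantom' failed: {e}") from e

    iso = grid.voxel_centers()[grid.structure_indices("ctv")].mean(axis=0)
    beams = [BeamConfig(g, c, isocenter=tuple(iso)) for g, c in config.beams]
    structures = {
        n: grid.structure_indices(n) for n in ("ctv", "brainstem", "spinal_cord")
    }
    rows = np.unique(np.concatenate(list(structures.values())))

    try:
        t = stage("spots")
        spots = place_spots(grid, beams, spacing=config.spots["lateral_spacing"],
                            layer_step=config.spots["layer_step"])
        timings["spots"] = time.time() - t
    except Exception as e:
        raise RuntimeError(f"stage 'spots' failed: {e}") from e

    scen = config.scenarios
    scenario_set = generate_scenarios(scen["setup_mm"], scen["range_fraction"])
    try:
        t = stage("influence")
        influences = {
            s.label(): compute_influence(grid, spots, scenario=s, beams=beams,
                                         rows=rows)
            for s in scenario_set
        }
        timings["influence"] = time.time() - t
    except Exception as e:
        raise RuntimeError(f"stage 'influence' failed: {e}") from e

    plans = {}
    for strategy in ("nominal", "robust", "let"):
        try:
            t = stage(f"optimize:{strategy}")
            spec = config.objective_spec()
            if strategy != "let":
                spec.phi_t = spec.phi_o = 0.0
            plans[strategy] = plan_strategy(
                strategy, grid, beams, spec,
                scenario_set=scenario_set, spots=spots,
                influences=influences, rows=rows,
                solver_options=dict(config.solver),
            )
            timings[f"optimize:{strategy}"] = time.time() - t
        except Exception as e:
            raise RuntimeError(f"stage 'optimize:{strategy}' failed: {e}") from e

    try:
        t = stage("normalize+evaluate")
        nominal_infl = influences["nominal"]
        for plan in plans.values():
            normalize_to_d95(plan, nominal_infl, structures["ctv"],
                             reference=config.evaluation["d95_reference"])
        report = compare_plans(
            plans, influences, scenario_set, structures,
            d95_reference=config.evaluation["d95_reference"],
            dose_threshold=config.evaluation["dose_threshold"],
            alpha_beta=config.biology["alpha_beta"],
            n_fractions=config.biology["n_fractions"],
            c_let=config.biology["c"],
        )
        timings["evaluate"] = time.time() - t
    except Exception as e:
        raise RuntimeError(f"stage 'evaluate' failed: {e}") from e

    timings["total"] = time.time() - t_all
    result = ExperimentResult(
        config=config, grid=grid, plans=plans, influences=influences,
        report=report, structures=structures, timings=timings,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_phantom(grid, out_dir / "phantom")
        for strategy, plan in plans.items():
            plan.save(out_dir / f"plan_{strategy}.json")
        report.save(out_dir)
        (out_dir / "scenarios.json").write_text(
            json.dumps(scenario_set.to_json(), indent=2)
        )
        manifest = {
            "package_version": __version__,
            "config_hash": config.content_hash(),
            "seed": config.solver.get("seed", 0),
            "archetype": config.archetype,
            "n_spots": spots.n_spots,
            "structure_counts": grid.structure_counts(),
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "numpy": np.__version__,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        result.out_dir = out_dir
    return result
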