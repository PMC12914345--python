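"""Spot-weight optimization: nominal, worst-case robust, and LET objectives.

All three strategies minimise penalty objectives over nonnegative spot
intensities ``w``:

* the dose objective ``FD(w)`` sums, per structure, mean squared
  underdose/overdose deviations of the constant-RBE-weighted dose (1.1 x
  physical) about the prescription (target) or the maximum-dose level
  (OARs);
* the LET objective ``FL(w) = FD(w) - (phiT/NT) sum_{target} Li^2
  + (phiO/NO) sum_{OAR} Li^2`` additionally rewards high dose-averaged
  LET (LETd) in the target and penalises it in the OARs, with
  ``Li = sum_j Dij Lij wj / sum_j Dij wj``;
* the robust objective applies the objective-wise worst-case
  composition: every individual term of ``FD`` is evaluated in each
  uncertainty scenario and only its worst value (and that scenario's
  gradient) enters the total.

Gradients are analytic throughout, including the quotient-rule term
``dLi/dwj = Dij (Lij - Li) / sum_k Dik wk`` of the LETd map.  The solver
is bound-constrained quasi-Newton (L-BFGS-B) with ``w >= 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize as sciopt

from .beamlets import BeamConfig, InfluenceMatrices, SpotGrid, compute_influence, place_spots
from .phantom import PhantomGrid
from .uncertainty import Scenario, ScenarioSet, nominal_only

STRATEGIES = ("nominal", "robust", "let")

RBE_CONSTANT = 1.1


class OptimizationError(ValueError):
    """Raised for invalid optimization inputs."""


@dataclass
class ObjectiveSpec:
    """Prescription, penalty weights, and LETd priorities.

    Doses are Gy(RBE) at constant RBE 1.1.  ``phi_t``/``phi_o`` are the
    LETd priorities of the LET objective (target reward / OAR penalty);
    zero disables the LET terms.
    """

    prescription: float = 54.0
    d95_floor: float = 51.0
    n_fractions: int = 30
    target_under_weight: float = 300.0
    target_over_weight: float = 150.0
    oar_limits: dict = field(
        default_factory=lambda: {"brainstem": 60.0, "spinal_cord": 57.0}
    )
    oar_weights: dict = field(
        default_factory=lambda: {"brainstem": 300.0, "spinal_cord": 300.0}
    )
    phi_t: float = 0.0
    phi_o: float = 0.0

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise OptimizationError("prescription must be positive")
        if self.phi_t < 0 or self.phi_o < 0:
            raise OptimizationError("LET priorities must be nonnegative")
        for w in (self.target_under_weight, self.target_over_weight,
                  *self.oar_weights.values()):
            if w < 0:
                raise OptimizationError("penalty weights must be nonnegative")


@dataclass
class Plan:
    """Optimized beamlet intensities with provenance."""

    w: np.ndarray
    strategy: str
    objective_history: list = field(default_factory=list)
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise OptimizationError("plan intensities must be nonnegative")
        if self.strategy not in STRATEGIES:
            raise OptimizationError(f"unknown strategy {self.strategy!r}")

    @property
    def intensities(self) -> np.ndarray:
        """Normalized intensities actually delivered (scale applied)."""
        return self.scale * self.w

    def save(self, path) -> Path:
        path = Path(path)
        payload = {
            "strategy": self.strategy,
            "scale": self.scale,
            "w": self.w.tolist(),
            "objective_history": list(map(float, self.objective_history)),
            "meta": self.meta,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path) -> "Plan":
        d = json.loads(Path(path).read_text())
        return cls(
            w=np.asarray(d["w"]),
            strategy=d["strategy"],
            objective_history=d.get("objective_history", []),
            scale=d.get("scale", 1.0),
            meta=d.get("meta", {}),
        )


@dataclass
class LETdMap:
    """Per-voxel dose-averaged LET with its paired physical dose."""

    let: np.ndarray       # keV/um, 0 where dose is 0
    dose: np.ndarray      # physical Gy
    scenario_id: str = "nominal"


# ---------------------------------------------------------------------------
# LETd map (the dose-averaged LET quotient)
# ---------------------------------------------------------------------------

def letd_map(w, influence: InfluenceMatrices, rows=None) -> LETdMap:
    """Dose-averaged LET per voxel: Li = sum_j Dij Lij wj / sum_j Dij wj.

    Voxels with zero total dose get Li = 0.  ``rows`` restricts the
    output to a voxel subset (full grid vectors otherwise).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise OptimizationError("intensities must be nonnegative")
    D = influence.D if rows is None else influence.D[rows]
    DL = influence.DL if rows is None else influence.DL[rows]
    den = D @ w
    num = DL @ w
    let = np.zeros_like(den)
    nz = den > 0
    let[nz] = num[nz] / den[nz]
    return LETdMap(let=let, dose=den, scenario_id=influence.scenario_id)


# ---------------------------------------------------------------------------
# objective factories
# ---------------------------------------------------------------------------

def _structure_rows(structures: dict) -> dict:
    return {k: np.asarray(v, dtype=np.int64) for k, v in structures.items()}


def _dose_terms(infl: InfluenceMatrices, structures: dict, spec: ObjectiveSpec):
    """Pre-sliced (name, kind, level, weight/N, D_sub) quadratic penalty terms."""
    rows = _structure_rows(structures)
    terms = []
    D_t = infl.D[rows["ctv"]].tocsr()
    nt = D_t.shape[0]
    terms.append(("ctv", "under", spec.prescription, spec.target_under_weight / nt, D_t))
    terms.append(("ctv", "over", spec.prescription, spec.target_over_weight / nt, D_t))
    for name, level in spec.oar_limits.items():
        if name not in rows:
            continue
        D_o = infl.D[rows[name]].tocsr()
        no = max(D_o.shape[0], 1)
        terms.append((name, "over", level, spec.oar_weights.get(name, 0.0) / no, D_o))
    return terms


def _term_value_grad(term, w, want_grad=True):
    _, kind, level, wn, D = term
    d = RBE_CONSTANT * (D @ w)
    dev = np.maximum(0.0, level - d) if kind == "under" else np.maximum(0.0, d - level)
    val = wn * float(dev @ dev)
    if not want_grad:
        return val, None
    sign = -1.0 if kind == "under" else 1.0
    g = D.T @ (sign * 2.0 * wn * RBE_CONSTANT * dev)
    return val, g


def make_dose_objective(influence: InfluenceMatrices, structures: dict,
                        spec: ObjectiveSpec):
    """Callable ``w -> (FD, grad)`` with pre-sliced structure matrices."""
    terms = _dose_terms(influence, structures, spec)

    def objective(w):
        w = np.asarray(w, dtype=float)
        f = 0.0
        g = np.zeros_like(w)
        for term in terms:
            v, gr = _term_value_grad(term, w)
            f += v
            g += gr
        return f, g

    return objective


def dose_objective(w, influence: InfluenceMatrices, structures: dict,
                   spec: ObjectiveSpec):
    """FD(w) and its analytic gradient (one-shot convenience wrapper)."""
    w = np.asarray(w, dtype=float)
    D_t = influence.D[_structure_rows(structures)["ctv"]]
    if D_t.shape[1] != w.size:
        raise OptimizationError("w length does not match influence columns")
    return make_dose_objective(influence, structures, spec)(w)


def _let_quadratic(D, DL, w, coef):
    """coef * sum_i Li^2 and its gradient for one voxel set."""
    den = D @ w
    num = DL @ w
    nz = den > 0
    li = np.zeros_like(den)
    li[nz] = num[nz] / den[nz]
    val = coef * float(li @ li)
    c1 = np.zeros_like(den)
    c2 = np.zeros_like(den)
    c1[nz] = 2.0 * coef * li[nz] / den[nz]
    c2[nz] = 2.0 * coef * li[nz] ** 2 / den[nz]
    g = DL.T @ c1 - D.T @ c2
    return val, g


def make_let_objective(influence: InfluenceMatrices, structures: dict,
                       spec: ObjectiveSpec):
    """Callable ``w -> (FL, grad)``: FD minus target-LETd reward plus OAR penalty.

    The OAR LETd sum runs over the union of OAR voxel sets; zero-dose
    voxels contribute zero value and zero gradient.
    """
    rows = _structure_rows(structures)
    dose_obj = make_dose_objective(influence, structures, spec)
    t_rows = rows["ctv"]
    oar_rows = np.unique(
        np.concatenate([rows[n] for n in spec.oar_limits if n in rows])
    )
    D_t = influence.D[t_rows].tocsr()
    DL_t = influence.DL[t_rows].tocsr()
    D_o = influence.D[oar_rows].tocsr()
    DL_o = influence.DL[oar_rows].tocsr()
    nt = max(t_rows.size, 1)
    no = max(oar_rows.size, 1)

    def objective(w):
        w = np.asarray(w, dtype=float)
        f, g = dose_obj(w)
        if spec.phi_t > 0:
            v, gr = _let_quadratic(D_t, DL_t, w, -spec.phi_t / nt)
            f += v
            g += gr
        if spec.phi_o > 0:
            v, gr = _let_quadratic(D_o, DL_o, w, spec.phi_o / no)
            f += v
            g += gr
        return f, g

    return objective


def let_objective(w, influence: InfluenceMatrices, structures: dict,
                  spec: ObjectiveSpec):
    """FL(w) and gradient (one-shot wrapper around the factory)."""
    return make_let_objective(influence, structures, spec)(np.asarray(w, dtype=float))


def make_robust_objective(influences: list, structures: dict, spec: ObjectiveSpec):
    """Objective-wise worst case over scenarios.

    Each quadratic penalty term keeps its maximum value across the
    scenario influence sets; the gradient sums the gradients of the
    active (worst) scenario per term, ties broken by the lowest scenario
    index (np.argmax picks the first maximum).
    """
    if not influences:
        raise OptimizationError("robust objective needs at least one scenario")
    per_scenario_terms = [
        _dose_terms(infl, structures, spec) for infl in influences
    ]
    n_terms = len(per_scenario_terms[0])

    def objective(w):
        w = np.asarray(w, dtype=float)
        values = np.empty((len(per_scenario_terms), n_terms))
        for s, terms in enumerate(per_scenario_terms):
            for t, term in enumerate(terms):
                values[s, t], _ = _term_value_grad(term, w, want_grad=False)
        worst = np.argmax(values, axis=0)
        f = float(values[worst, np.arange(n_terms)].sum())
        g = np.zeros_like(w)
        for t, s in enumerate(worst):
            _, gr = _term_value_grad(per_scenario_terms[s][t], w)
            g += gr
        return f, g

    return objective


def robust_objective(w, influences: list, structures: dict, spec: ObjectiveSpec):
    """Worst-case composite value and gradient (one-shot wrapper)."""
    return make_robust_objective(influences, structures, spec)(np.asarray(w, dtype=float))


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def solve_plan(objective, w0, options: dict | None = None,
               strategy: str = "nominal") -> Plan:
    """Bound-constrained minimisation of ``objective`` over w >= 0.

    ``objective(w)`` must return ``(value, gradient)``.  Deterministic
    given identical inputs; the returned plan never has a higher
    objective value than the start.
    """
    options = dict(options or {})
    w0 = np.asarray(w0, dtype=float)
    if np.any(w0 < 0):
        raise OptimizationError("w0 must be nonnegative")
    f0, _ = objective(w0)
    if not np.isfinite(f0):
        raise OptimizationError("objective is not finite at w0")
    history = [float(f0)]

    def fun(w):
        f, g = objective(w)
        return f, g

    def cb(wk):
        fk, _ = objective(wk)
        history.append(float(fk))

    maxiter = int(options.pop("maxiter", 400))
    ftol = float(options.pop("ftol", 1e-10))
    gtol = float(options.pop("gtol", 1e-9))
    track = bool(options.pop("track_history", False))
    res = sciopt.minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * w0.size,
        callback=cb if track else None,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
    )
    w = np.maximum(res.x, 0.0)
    f_final, _ = objective(w)
    if f_final > f0:  # safeguard: never return worse than the start
        w, f_final = w0, f0
    if not track:
        history.append(float(f_final))
    return Plan(
        w=w,
        strategy=strategy,
        objective_history=history,
        meta={
            "solver": "L-BFGS-B",
            "nit": int(res.nit),
            "converged": bool(res.success),
            "final_objective": float(f_final),
        },
    )


def initial_intensities(influence: InfluenceMatrices, structures: dict,
                        spec: ObjectiveSpec) -> np.ndarray:
    """Uniform start scaled so the mean CTV constant-RBE dose hits the prescription."""
    rows = _structure_rows(structures)["ctv"]
    ones = np.ones(influence.D.shape[1])
    mean_dose = float((influence.D[rows] @ ones).mean())
    if mean_dose <= 0:
        raise OptimizationError("no dose reaches the CTV with unit intensities")
    return ones * spec.prescription / (RBE_CONSTANT * mean_dose)


def plan_strategy(
    strategy: str,
    grid: PhantomGrid,
    beams: list[BeamConfig],
    spec: ObjectiveSpec,
    scenario_set: ScenarioSet | None = None,
    spots: SpotGrid | None = None,
    influences: dict | None = None,
    rows=None,
    solver_options: dict | None = None,
) -> Plan:
    """Build influence data and solve the plan for one strategy.

    ``robust`` uses every scenario in ``scenario_set``; ``nominal`` and
    ``let`` use only the nominal scenario.  Precomputed ``spots`` and
    ``influences`` (label -> InfluenceMatrices) are reused when given so
    the three strategies can share one influence computation.
    """
    if strategy not in STRATEGIES:
        raise OptimizationError(f"unknown strategy {strategy!r}")
    if scenario_set is None:
        scenario_set = nominal_only()
    if spots is None:
        spots = place_spots(grid, beams)
    if rows is None:
        rows = np.unique(
            np.concatenate([grid.structure_indices(n)
                            for n in ("ctv", "brainstem", "spinal_cord")])
        )
    if influences is None:
        influences = {}  # caller-supplied dicts are filled in place for reuse

    def infl_for(scenario: Scenario) -> InfluenceMatrices:
        key = scenario.label()
        if key not in influences:
            influences[key] = compute_influence(
                grid, spots, scenario=scenario, beams=beams, rows=rows
            )
        return influences[key]

    structures = {
        n: grid.structure_indices(n) for n in ("ctv", "brainstem", "spinal_cord")
    }
    nominal_infl = infl_for(Scenario.nominal())
    if strategy == "robust":
        scen_infls = [infl_for(s) for s in scenario_set]
        objective = make_robust_objective(scen_infls, structures, spec)
    elif strategy == "let":
        objective = make_let_objective(nominal_infl, structures, spec)
    else:
        objective = make_dose_objective(nominal_infl, structures, spec)
    w0 = initial_intensities(nominal_infl, structures, spec)
    plan = solve_plan(objective, w0, options=solver_options, strategy=strategy)
    plan.meta.update(
        n_spots=spots.n_spots,
        n_scenarios=len(scenario_set) if strategy == "robust" else 1,
        phi_t=spec.phi_t if strategy == "let" else 0.0,
        phi_o=spec.phi_o if strategy == "let" else 0.0,
    )
    return plan
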