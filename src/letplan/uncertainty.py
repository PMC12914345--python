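"""Setup/range uncertainty scenarios for robust planning.

The default uncertainty model is the discrete nine-scenario set used in
worst-case robust IMPT optimization: one nominal (unperturbed) scenario,
six single-axis setup shifts of +/-2.25 mm (applied independently along
the left-right, anterior-posterior, and superior-inferior axes), and two
range scalings of +/-3.5%.

Sign convention (stated once): a patient shift of +s is realised as an
isocenter shift of -s; only the symmetry of the +/- set matters for the
worst-case composition.  Range uncertainty multiplies the radiological
depth rather than the beam energy — equivalent at this model fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXES = ("x", "y", "z")  # left-right, anterior-posterior, superior-inferior


class ScenarioError(ValueError):
    """Raised for invalid scenario definitions."""


@dataclass(frozen=True)
class Scenario:
    kind: str  # nominal | setup | range
    shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("nominal", "setup", "range"):
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        shift = np.asarray(self.shift, dtype=float)
        if self.kind == "nominal":
            if np.any(shift != 0) or self.range_scale != 1.0:
                raise ScenarioError("nominal scenario must be unperturbed")
        elif self.kind == "setup":
            if self.range_scale != 1.0:
                raise ScenarioError("setup scenario must not scale range")
            if np.count_nonzero(shift) != 1:
                raise ScenarioError("setup scenario needs exactly one nonzero axis")
        else:
            if np.any(shift != 0):
                raise ScenarioError("range scenario must not shift")
            if self.range_scale <= 0:
                raise ScenarioError("range_scale must be positive")

    @classmethod
    def nominal(cls) -> "Scenario":
        return cls(kind="nominal")

    def label(self) -> str:
        if self.kind == "nominal":
            return "nominal"
        if self.kind == "setup":
            ax = int(np.flatnonzero(np.asarray(self.shift))[0])
            val = self.shift[ax]
            return f"setup_{AXES[ax]}{'+' if val > 0 else '-'}{abs(val):g}mm"
        return f"range_{'+' if self.range_scale > 1 else '-'}{abs(self.range_scale - 1) * 100:g}pct"


@dataclass
class ScenarioSet:
    scenarios: list[Scenario]
    setup_mm: float
    range_fraction: float

    def __post_init__(self) -> None:
        kinds = [s.kind for s in self.scenarios]
        if kinds.count("nominal") != 1:
            raise ScenarioError("scenario set must contain exactly one nominal")
        labels = [s.label() for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ScenarioError("scenarios must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    @property
    def nominal_index(self) -> int:
        return next(i for i, s in enumerate(self.scenarios) if s.kind == "nominal")

    def to_json(self) -> list[dict]:
        return [
            {"kind": s.kind, "shift": list(s.shift), "range_scale": s.range_scale}
            for s in self.scenarios
        ]


def generate_scenarios(
    setup_mm: float = 2.25, range_fraction: float = 0.035
) -> ScenarioSet:
    """The nine-scenario set: nominal first, then 6 setup shifts, 2 range scalings.

    ``nominal_only`` evaluation corresponds to ``generate_scenarios(0, 0)``
    degenerating — here zero magnitudes are rejected as they would create
    duplicate scenarios; use ``ScenarioSet([Scenario.nominal()], 0, 0)``
    for a nominal-only set.
    """
    if setup_mm < 0:
        raise ScenarioError("setup_mm must be nonnegative")
    if not (0 <= range_fraction < 1):
        raise ScenarioError("range_fraction must lie in [0, 1)")
    scenarios = [Scenario.nominal()]
    for ax in range(3):
        for sign in (+1.0, -1.0):
            shift = [0.0, 0.0, 0.0]
            shift[ax] = sign * setup_mm
            scenarios.append(Scenario(kind="setup", shift=tuple(shift)))
    for sign in (-1.0, +1.0):
        scenarios.append(Scenario(kind="range", range_scale=1.0 + sign * range_fraction))
    return ScenarioSet(scenarios=scenarios, setup_mm=setup_mm, range_fraction=range_fraction)


def nominal_only() -> ScenarioSet:
    """A scenario set containing only the unperturbed case."""
    return ScenarioSet([Scenario.nominal()], setup_mm=0.0, range_fraction=0.0)


@dataclass
class PerturbedGeometry:
    """Handle produced by :func:`apply_scenario` for influence computation."""

    isocenter_shift: tuple[float, float, float]
    range_scale: float
    scenario: Scenario


def apply_scenario(grid, beams, scenario: Scenario) -> PerturbedGeometry:
    """Translate a scenario into the perturbation applied to the beam geometry.

    A setup shift +s of the patient is equivalent to shifting every
    isocenter by -s; a range scenario passes its scale factor through to
    the radiological-depth integral; nominal is the identity.
    """
    shift = np.asarray(scenario.shift, dtype=float)
    extent = np.asarray(grid.shape) * grid.voxel_size
    if np.any(np.abs(shift) > extent):
        raise ScenarioError("scenario shift exceeds the grid extent")
    return PerturbedGeometry(
        isocenter_shift=tuple(-shift),
        range_scale=scenario.range_scale,
        scenario=scenario,
    )
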