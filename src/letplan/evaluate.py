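"""Plan evaluation: DVH/LETd-VH, D95 normalization, robustness bandwidths.

Conventions (each configurable where it matters):

* every plan is normalized so its nominal-scenario CTV D95 equals the
  common reference (the 54 Gy(RBE) prescription) — dose is linear in the
  intensities, so the rescale is exact, and the LETd map is invariant
  under it (degree-0 homogeneity of the dose-averaged LET quotient);
* LETd statistics zero the LETd wherever the constant-RBE dose is at or
  below 1 Gy, and the mean is taken over all structure voxels including
  the zeroed ones;
* robustness of a statistic is summarised by its worst-case minimum,
  worst-case maximum, and the bandwidth (max - min) across the scenario
  set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .beamlets import InfluenceMatrices
from .biology import RBEParameters, constant_rbe_dose, let_weighted_dose, variable_rbe_dose
from .optimize import LETdMap, Plan, letd_map

D95_REFERENCE = 54.0     # Gy(RBE), the prescription anchor
DOSE_THRESHOLD = 1.0     # Gy(RBE), LETd masking threshold
STRUCTURE_ORDER = ("ctv", "brainstem", "spinal_cord")


class EvaluationError(ValueError):
    """Raised for malformed evaluation inputs."""


@dataclass
class VolumeHistogram:
    """Cumulative ('at least') volume histogram of dose or LETd."""

    abscissa: np.ndarray
    fraction: np.ndarray
    structure: str = ""
    quantity: str = "dose"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.fraction) > 1e-12):
            raise EvaluationError("volume fraction must be nonincreasing")


def _masked_values(values, mask):
    values = np.asarray(values, dtype=float)
    if mask is None:
        return values
    mask = np.asarray(mask)
    out = values[mask] if mask.dtype == bool else values[mask.astype(np.int64)]
    if out.size == 0:
        raise EvaluationError("structure mask selects no voxels")
    return out


def dvh_and_quantile(values, mask=None, q: float = 0.95, structure: str = "",
                     quantity: str = "dose", n_bins: int = 200):
    """Cumulative histogram over the masked voxels and the Dq quantile.

    Dq is the largest value v such that at least a fraction q of the
    masked voxels receive >= v (the sort-based definition of D95).
    """
    if not (0 < q < 1):
        raise EvaluationError("q must lie in (0, 1)")
    vals = _masked_values(values, mask)
    hi = max(float(vals.max()) * 1.05, 1e-12)
    edges = np.linspace(0.0, hi, n_bins + 1)
    frac = (vals[None, :] >= edges[:, None]).mean(axis=1)
    hist = VolumeHistogram(abscissa=edges, fraction=frac, structure=structure,
                           quantity=quantity)
    desc = np.sort(vals)[::-1]
    k = int(np.ceil(q * vals.size))
    dq = float(desc[k - 1])
    return hist, dq


def normalize_to_d95(plan: Plan, influence: InfluenceMatrices, ctv_rows,
                     reference: float = D95_REFERENCE) -> float:
    """Scale the plan so its nominal CTV D95 (constant RBE) equals ``reference``.

    Mutates ``plan.scale`` and returns the applied factor.  Dose is
    linear in the intensities so the post-scale D95 is exact; LETd is
    unchanged.
    """
    dose = constant_rbe_dose(influence.D[np.asarray(ctv_rows)] @ plan.intensities)
    _, d95 = dvh_and_quantile(dose, q=0.95)
    if d95 <= 0:
        raise EvaluationError("cannot normalize: CTV D95 is zero")
    factor = reference / d95
    plan.scale *= factor
    return factor


def masked_letd_stats(let, dose, mask=None, threshold: float = DOSE_THRESHOLD):
    """Mean and max LETd after zeroing voxels with dose <= threshold.

    The mean runs over all masked voxels, zeroed ones included.
    """
    l = _masked_values(let, mask)
    d = _masked_values(dose, mask)
    if l.shape != d.shape:
        raise EvaluationError("LETd and dose maps are not congruent")
    l = np.where(d > threshold, l, 0.0)
    return float(l.mean()), float(l.max())


def robustness_bandwidth(values):
    """(worst-case min, worst-case max, bandwidth) of a statistic across scenarios."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise EvaluationError("bandwidth of an empty scenario set")
    lo, hi = float(vals.min()), float(vals.max())
    return lo, hi, hi - lo


def per_beam_decomposition(w, influence: InfluenceMatrices, rows=None):
    """Per-beam physical dose and LETd maps.

    Beam b's dose is ``D[:, cols_b] @ w[cols_b]``; its LETd applies the
    dose-averaged quotient restricted to those columns.  The per-beam
    doses sum to the total exactly (linearity).
    """
    w = np.asarray(w, dtype=float)
    spots = influence.spots
    cols_seen = np.zeros(spots.n_spots, dtype=int)
    out = {}
    for b in range(spots.n_beams):
        cols = spots.beam_columns(b)
        cols_seen[cols] += 1
        wb = np.zeros_like(w)
        wb[cols] = w[cols]
        out[b] = letd_map(wb, influence, rows=rows)
    if np.any(cols_seen != 1):
        raise EvaluationError("beam partition does not cover all columns exactly once")
    return out


@dataclass
class EvaluationReport:
    """Tidy per-scenario metrics plus bandwidth, biology, and per-beam tables."""

    scenario_metrics: pd.DataFrame
    bandwidths: pd.DataFrame
    biology: pd.DataFrame
    per_beam: pd.DataFrame
    d95_reference: float = D95_REFERENCE
    meta: dict = field(default_factory=dict)

    def save(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.scenario_metrics.to_csv(out_dir / "scenario_metrics.csv", index=False)
        self.bandwidths.to_csv(out_dir / "bandwidths.csv", index=False)
        self.biology.to_csv(out_dir / "biology_summary.csv", index=False)
        self.per_beam.to_csv(out_dir / "per_beam.csv", index=False)
        return out_dir


def compare_plans(
    plans: dict,
    influences: dict,
    scenario_set,
    structures: dict,
    d95_reference: float = D95_REFERENCE,
    dose_threshold: float = DOSE_THRESHOLD,
    alpha_beta: dict | None = None,
    n_fractions: int = 30,
    c_let: float = 0.04,
) -> EvaluationReport:
    """Evaluate normalized plans across all scenarios and structures.

    ``plans`` maps strategy -> Plan (already normalized to the common
    D95 reference), ``influences`` maps scenario label ->
    InfluenceMatrices for every scenario in ``scenario_set``, and
    ``structures`` maps structure name -> flat voxel indices.
    """
    alpha_beta = alpha_beta or {"ctv": 10.0, "brainstem": 2.0, "spinal_cord": 2.0}
    labels = [s.label() for s in scenario_set]
    missing = [l for l in labels if l not in influences]
    if missing:
        raise EvaluationError(f"missing scenario influence sets: {missing}")

    rows_sc, rows_bw, rows_bio, rows_beam = [], [], [], []
    for strategy, plan in plans.items():
        w = plan.intensities
        per_label = {}
        for label in labels:
            infl = influences[label]
            lmap = letd_map(w, infl)
            dose_rbe = constant_rbe_dose(lmap.dose)
            per_label[label] = (lmap, dose_rbe)
            for name in STRUCTURE_ORDER:
                idx = structures[name]
                d = dose_rbe[idx]
                _, d95 = dvh_and_quantile(d, q=0.95)
                lmean, lmax = masked_letd_stats(
                    lmap.let[idx], d, threshold=dose_threshold
                )
                rows_sc.append(
                    {
                        "plan": strategy,
                        "scenario": label,
                        "structure": name,
                        "mean_dose": float(d.mean()),
                        "max_dose": float(d.max()),
                        "d95": d95,
                        "mean_letd": lmean,
                        "max_letd": lmax,
                    }
                )

        df = pd.DataFrame([r for r in rows_sc if r["plan"] == strategy])
        for name in STRUCTURE_ORDER:
            sub = df[df.structure == name]
            for metric in ("mean_dose", "max_dose", "d95", "mean_letd", "max_letd"):
                lo, hi, bw = robustness_bandwidth(sub[metric].to_numpy())
                rows_bw.append(
                    {
                        "plan": strategy,
                        "structure": name,
                        "metric": metric,
                        "wc_min": lo,
                        "wc_max": hi,
                        "bandwidth": bw,
                    }
                )

        # biological effect, nominal scenario
        nom_label = scenario_set.scenarios[scenario_set.nominal_index].label()
        lmap, dose_rbe = per_label[nom_label]
        for name in STRUCTURE_ORDER:
            idx = structures[name]
            params = RBEParameters(alpha_beta_x=alpha_beta[name],
                                   n_fractions=n_fractions, c=c_let)
            phys = lmap.dose[idx]
            letd = np.where(dose_rbe[idx] > dose_threshold, lmap.let[idx], 0.0)
            vrbe = variable_rbe_dose(phys, letd, params)
            comp, total = let_weighted_dose(phys, letd, c=c_let)
            rows_bio.append(
                {
                    "plan": strategy,
                    "structure": name,
                    "var_rbe_mean": float(vrbe.mean()),
                    "var_rbe_max": float(vrbe.max()),
                    "clet_component_mean": float(comp.mean()),
                    "clet_component_max": float(comp.max()),
                    "clet_total_mean": float(total.mean()),
                    "clet_total_max": float(total.max()),
                }
            )

        # per-beam decomposition, nominal scenario
        infl_nom = influences[nom_label]
        beam_maps = per_beam_decomposition(w, infl_nom)
        for b, bmap in beam_maps.items():
            for name in STRUCTURE_ORDER:
                idx = structures[name]
                d = constant_rbe_dose(bmap.dose[idx])
                lmean, lmax = masked_letd_stats(bmap.let[idx], d,
                                                threshold=dose_threshold)
                rows_beam.append(
                    {
                        "plan": strategy,
                        "beam": b,
                        "structure": name,
                        "mean_dose": float(d.mean()),
                        "max_dose": float(d.max()),
                        "mean_letd": lmean,
                        "max_letd": lmax,
                    }
                )

    return EvaluationReport(
        scenario_metrics=pd.DataFrame(rows_sc),
        bandwidths=pd.DataFrame(rows_bw),
        biology=pd.DataFrame(rows_bio),
        per_beam=pd.DataFrame(rows_beam),
        d95_reference=d95_reference,
        meta={"n_scenarios": len(scenario_set), "threshold": dose_threshold},
    )
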