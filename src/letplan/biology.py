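"""Biological-effect models for proton plan evaluation.

Three transforms of the physical dose are provided:

* constant RBE: the clinical 1.1 factor, independent of LET and tissue;
* variable RBE: the phenomenological linear-quadratic model of McNamara
  et al. (2015, Phys. Med. Biol. 60:8399), where RBEmax rises linearly
  with LETd/(alpha/beta)x and RBEmin falls linearly with
  sqrt((alpha/beta)x)*LETd, evaluated at the per-fraction dose;
* the linear LET-weighted surrogate D*(1 + c*LETd) with scaling constant
  c = 0.04 um/keV, whose ``c*LETd*D`` term is the LET-dependent
  biological dose component.

The McNamara coefficients are configuration data (see
:data:`MCNAMARA_COEFFICIENTS`), transcribed from the cited publication,
so that alternative fits can be swapped in without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class BiologyError(ValueError):
    """Raised for invalid biological-model inputs."""


#: Coefficients of the McNamara et al. (2015) proton RBE model:
#: RBEmax = p0 + p1 * LETd / (alpha/beta)x
#: RBEmin = p2 - p3 * sqrt((alpha/beta)x) * LETd
MCNAMARA_COEFFICIENTS = {
    "rbe_max_intercept": 0.99064,
    "rbe_max_slope": 0.35605,     # Gy * um/keV
    "rbe_min_intercept": 1.1012,
    "rbe_min_slope": 0.0038703,   # Gy^-1/2 * um/keV
}

CLET_SCALING = 0.04  # um/keV, scaling constant of the linear RBE surrogate


@dataclass
class RBEParameters:
    """Tissue and fractionation parameters for variable-RBE evaluation."""

    alpha_beta_x: float        # Gy; 2 for OARs, 10 for tumor
    n_fractions: int = 30
    c: float = CLET_SCALING
    coefficients: dict = field(default_factory=lambda: dict(MCNAMARA_COEFFICIENTS))

    def __post_init__(self) -> None:
        if self.alpha_beta_x <= 0:
            raise BiologyError("(alpha/beta)x must be positive")
        if self.n_fractions < 1:
            raise BiologyError("n_fractions must be at least 1")
        if self.c < 0:
            raise BiologyError("c must be nonnegative")


def constant_rbe_dose(physical_dose):
    """Constant-RBE-weighted dose: 1.1 x physical, elementwise."""
    d = np.asarray(physical_dose, dtype=float)
    if np.any(d < 0):
        raise BiologyError("physical dose must be nonnegative")
    return 1.1 * d


def mcnamara_rbe(dose_per_fraction, letd, params: RBEParameters):
    """Variable RBE at per-fraction dose d and dose-averaged LET.

    Linear-quadratic form: with abx = (alpha/beta)x,
    RBE = (sqrt(abx^2 + 4 d abx RBEmax + 4 d^2 RBEmin^2) - abx) / (2 d),
    continuously extended by RBEmax as d -> 0.
    """
    d = np.asarray(dose_per_fraction, dtype=float)
    l = np.asarray(letd, dtype=float)
    if np.any(d < 0) or np.any(l < 0):
        raise BiologyError("dose and LETd must be nonnegative")
    co = params.coefficients
    abx = params.alpha_beta_x
    rbe_max = co["rbe_max_intercept"] + co["rbe_max_slope"] * l / abx
    rbe_min = co["rbe_min_intercept"] - co["rbe_min_slope"] * np.sqrt(abx) * l
    d_safe = np.where(d > 0, d, 1.0)
    rbe = (
        np.sqrt(abx**2 + 4.0 * d_safe * abx * rbe_max + 4.0 * d_safe**2 * rbe_min**2)
        - abx
    ) / (2.0 * d_safe)
    return np.where(d > 0, rbe, rbe_max)


def variable_rbe_dose(physical_dose, letd, params: RBEParameters):
    """Total variable-RBE-weighted dose (Gy(RBE)) per voxel.

    The total physical dose is split into ``n_fractions`` equal
    fractions; RBE is evaluated at the per-fraction dose and the total
    RBE-weighted dose is ``n * RBE(d, LETd) * d``.  Zero-dose voxels map
    to zero.
    """
    dtot = np.asarray(physical_dose, dtype=float)
    d = dtot / params.n_fractions
    rbe = mcnamara_rbe(d, letd, params)
    return params.n_fractions * rbe * d


def let_weighted_dose(physical_dose, letd, c: float = CLET_SCALING):
    """Linear LET-weighted dose surrogate.

    Returns ``(component, total)`` with component = c*LETd*D (the
    LET-dependent biological dose component) and total = D*(1 + c*LETd).
    """
    if c < 0:
        raise BiologyError("c must be nonnegative")
    d = np.asarray(physical_dose, dtype=float)
    l = np.asarray(letd, dtype=float)
    if np.any(d < 0) or np.any(l < 0):
        raise BiologyError("dose and LETd must be nonnegative")
    component = c * l * d
    return component, d + component
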