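"""Synthetic voxel phantoms for IMPT planning experiments.

Three anatomical archetypes of pediatric brain tumors abutting the
brainstem/spinal cord are modelled with piecewise geometry (cylindrical
head with a bone annulus, cylindrical brainstem and spinal cord, and a
CTV whose shape depends on the archetype):

``wraparound``
    A C-shaped (horseshoe) CTV wrapping around the brainstem in the
    axial plane, with a controlled fraction of the brainstem voxels
    inside the CTV (default calibration targets 22%).
``abutting``
    An ellipsoidal CTV sitting lateral/posterior to the brainstem,
    touching its surface.
``inferior_extension``
    A cylindrical CTV centred on the brainstem axis that extends
    inferiorly past the caudal end of the brainstem and overlaps the
    spinal cord.

Coordinate convention (stated once, used everywhere): voxel indices are
0-based; world coordinate of voxel ``i`` along an axis is
``origin + (i + 0.5) * voxel_size``.  Axis 0 runs right->left (+x =
patient left), axis 1 posterior->anterior (+y = anterior), axis 2
inferior->superior (+z = superior).

Densities are relative stopping powers (water = 1): air 0.001, soft
tissue 1.0, bone annulus 1.5.  Construction is a pure, deterministic
function of the :class:`PhantomSpec`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

ARCHETYPES = ("wraparound", "abutting", "inferior_extension")

STRUCTURES = ("ctv", "brainstem", "spinal_cord")

#: default density values (relative stopping power)
DENSITY_AIR = 0.001
DENSITY_SOFT = 1.0
DENSITY_BONE = 1.5


class PhantomError(ValueError):
    """Raised for invalid phantom specifications or unrealizable geometry."""


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic phantom.

    Lengths are in mm, volumes in cc.  ``geometry`` holds the archetype
    specific shape parameters; :meth:`default` fills in values that
    emulate the three study cases (CTV volumes 55.27 / 56.67 / 40.88 cc,
    brainstem and cord sized to match the corresponding voxel counts at
    a 3 mm grid).
    """

    archetype: str
    grid_shape: tuple[int, int, int] = (44, 44, 50)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    target_ctv_volume: float = 55.27  # cc
    head_radius: float = 60.0
    skull_thickness: float = 4.0
    brainstem_radius: float = 9.0
    brainstem_length: float = 42.0
    brainstem_center_xy: tuple[float, float] = (0.0, 8.0)
    cord_radius: float = 5.0
    cord_length: float = 45.0
    densities: dict = field(
        default_factory=lambda: {
            "air": DENSITY_AIR,
            "soft": DENSITY_SOFT,
            "bone": DENSITY_BONE,
        }
    )
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise PhantomError(
                f"unknown archetype {self.archetype!r}; expected one of {ARCHETYPES}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise PhantomError("voxel_size must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise PhantomError("grid_shape must be positive")
        if self.target_ctv_volume <= 0:
            raise PhantomError("target_ctv_volume must be positive")

    @classmethod
    def default(cls, archetype: str) -> "PhantomSpec":
        """Shipped per-archetype configuration emulating the three cases."""
        if archetype == "wraparound":
            # case 1: C-shaped CTV around the brainstem; brainstem 391 vox
            # (10.6 cc), cord 127 vox (3.4 cc) at 3 mm grid.
            return cls(
                archetype=archetype,
                target_ctv_volume=55.27,
                brainstem_radius=9.0,
                brainstem_length=42.0,
                cord_radius=5.0,
                cord_length=45.0,
                geometry={
                    "arc_deg": 250.0,
                    "ctv_length": 36.0,
                    "overlap_fraction": 0.22,
                },
            )
        if archetype == "abutting":
            # case 2: CTV abutting a larger brainstem; brainstem 719 vox
            # (19.4 cc), cord 473 vox (12.8 cc).
            return cls(
                archetype=archetype,
                target_ctv_volume=56.67,
                brainstem_radius=11.0,
                brainstem_length=52.0,
                cord_radius=7.0,
                cord_length=84.0,
                grid_shape=(44, 44, 56),
                geometry={
                    "aspect_z": 2.3,
                    "center_offset_y": 27.0,
                },
            )
        if archetype == "inferior_extension":
            # case 3: CTV extends inferiorly beyond the brainstem and
            # overlaps the cord; brainstem 739 vox (20 cc), cord 95 vox
            # (2.6 cc).
            return cls(
                archetype=archetype,
                target_ctv_volume=40.88,
                brainstem_radius=11.0,
                brainstem_length=53.0,
                cord_radius=5.0,
                cord_length=33.0,
                grid_shape=(44, 44, 56),
                geometry={"ctv_length": 40.0, "inferior_overhang": 36.0},
            )
        raise PhantomError(f"unknown archetype {archetype!r}")


@dataclass
class PhantomGrid:
    """Voxel phantom: density grid plus structure masks.

    ``masks`` maps structure names (``ctv``, ``brainstem``,
    ``spinal_cord``, ``body``) to boolean arrays of the grid shape.
    """

    density: np.ndarray
    masks: dict
    origin: np.ndarray
    voxel_size: np.ndarray
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.any(self.density < 0):
            raise PhantomError("densities must be nonnegative")
        body = self.masks.get("body")
        for name in STRUCTURES:
            m = self.masks.get(name)
            if m is None:
                continue
            if m.shape != self.density.shape:
                raise PhantomError(f"mask {name!r} shape mismatch")
            if body is not None and np.any(m & ~body):
                raise PhantomError(f"structure {name!r} extends outside the body")
        if "ctv" in self.masks and not self.masks["ctv"].any():
            raise PhantomError("CTV mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def voxel_centers(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape (nvox, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + (idx + 0.5) * self.voxel_size

    def structure_indices(self, name: str) -> np.ndarray:
        """Flat voxel indices of a structure mask."""
        if name not in self.masks:
            raise PhantomError(f"no structure named {name!r}")
        return np.flatnonzero(self.masks[name].ravel())

    def structure_counts(self) -> dict:
        """Voxel-count triple (CTV, brainstem, spinal cord)."""
        return {name: int(self.masks[name].sum()) for name in STRUCTURES}

    def structure_volume_cc(self, name: str) -> float:
        return self.masks[name].sum() * self.voxel_volume_cc


def _coordinate_grids(spec: PhantomSpec):
    """World coordinates of voxel centers on the grid, centered on the head axis."""
    shape = np.asarray(spec.grid_shape)
    vs = np.asarray(spec.voxel_size, dtype=float)
    origin = -(shape * vs) / 2.0
    ax = [origin[k] + (np.arange(shape[k]) + 0.5) * vs[k] for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return origin, X, Y, Z


def _bisect_count(make_mask, target_count: int, lo: float, hi: float, iters: int = 40):
    """Deterministic bisection of a scalar shape parameter against a voxel count.

    ``make_mask(p)`` must produce a mask whose count is nondecreasing in p.
    Returns the mask whose count is closest to ``target_count``.
    """
    best = None
    best_err = None
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        m = make_mask(mid)
        c = int(m.sum())
        err = abs(c - target_count)
        if best_err is None or err < best_err:
            best, best_err = m, err
        if c < target_count:
            lo = mid
        else:
            hi = mid
    return best


def build_phantom(spec: PhantomSpec) -> PhantomGrid:
    """Construct the voxel phantom for ``spec``.

    Deterministic: no randomness is involved.  The CTV shape parameter
    (outer radius / ellipsoid scale) is calibrated by bisection on the
    discrete grid so the achieved CTV volume lands within 5% of
    ``spec.target_ctv_volume``; for the ``wraparound`` archetype the
    inner radius is additionally calibrated so the CTV covers the
    configured fraction of brainstem voxels.
    """
    origin, X, Y, Z = _coordinate_grids(spec)
    vs = np.asarray(spec.voxel_size, dtype=float)
    vox_cc = float(np.prod(vs)) / 1000.0
    dens = spec.densities

    r_xy = np.hypot(X, Y)
    body = r_xy <= spec.head_radius
    if not body.any():
        raise PhantomError("grid too small: head does not fit on the grid")

    density = np.full(spec.grid_shape, dens["air"], dtype=float)
    density[body] = dens["soft"]
    skull = body & (r_xy >= spec.head_radius - spec.skull_thickness)
    density[skull] = dens["bone"]

    # brainstem: cylinder along z in the upper part of the grid
    bx, by = spec.brainstem_center_xy
    z_top = float(Z.max()) - 1.5 * vs[2]
    bs_z1 = z_top
    bs_z0 = bs_z1 - spec.brainstem_length
    r_bs = np.hypot(X - bx, Y - by)
    brainstem = (r_bs <= spec.brainstem_radius) & (Z >= bs_z0) & (Z <= bs_z1)
    if not brainstem.any():
        raise PhantomError("grid too small for the brainstem cylinder")

    # spinal cord: thinner cylinder continuing inferiorly
    cord_z1 = bs_z0
    cord_z0 = cord_z1 - spec.cord_length
    cord = (r_bs <= spec.cord_radius) & (Z >= cord_z0) & (Z < cord_z1)
    if not cord.any():
        raise PhantomError("grid too small for the spinal cord")

    target_vox = int(round(spec.target_ctv_volume * 1000.0 / np.prod(vs)))
    geom = spec.geometry

    if spec.archetype == "wraparound":
        arc = float(geom.get("arc_deg", 250.0)) * np.pi / 180.0
        ctv_len = float(geom.get("ctv_length", 36.0))
        frac = float(geom.get("overlap_fraction", 0.22))
        ctv_z1 = bs_z1 - 3.0
        ctv_z0 = ctv_z1 - ctv_len
        theta = np.arctan2(Y - by, X - bx)  # gap faces +x (patient left)
        in_arc = np.abs(np.mod(theta - np.pi, 2 * np.pi) - np.pi) <= arc / 2.0
        zsel = (Z >= ctv_z0) & (Z <= ctv_z1)
        n_bs = int(brainstem.sum())

        def overlap_mask(ri):
            return brainstem & in_arc & zsel & (r_bs >= ri)

        # calibrate the inner radius against the brainstem-overlap fraction
        ri_grid = np.linspace(2.0, spec.brainstem_radius, 60)
        fracs = np.array([overlap_mask(ri).sum() / n_bs for ri in ri_grid])
        ri = float(ri_grid[np.argmin(np.abs(fracs - frac))])

        def ctv_mask(ro):
            return in_arc & zsel & (r_bs >= ri) & (r_bs <= ro) & body

        ctv = _bisect_count(ctv_mask, target_vox, spec.brainstem_radius, spec.head_radius)
    elif spec.archetype == "abutting":
        aspect = float(geom.get("aspect_z", 2.3))
        off_y = float(geom.get("center_offset_y", 27.0))
        cz = 0.5 * (bs_z0 + bs_z1)
        cy = by + off_y

        def ctv_mask(a):
            return (
                ((X - bx) / a) ** 2 + ((Y - cy) / a) ** 2 + ((Z - cz) / (aspect * a)) ** 2
                <= 1.0
            ) & body

        ctv = _bisect_count(ctv_mask, target_vox, 3.0, spec.head_radius)
    else:  # inferior_extension
        ctv_len = float(geom.get("ctv_length", 45.0))
        overhang = float(geom.get("inferior_overhang", 18.0))
        ctv_z0 = bs_z0 - overhang
        ctv_z1 = ctv_z0 + ctv_len

        def ctv_mask(rc):
            return (r_bs <= rc) & (Z >= ctv_z0) & (Z <= ctv_z1) & body

        ctv = _bisect_count(ctv_mask, target_vox, 3.0, spec.head_radius)

    if ctv is None or not ctv.any():
        raise PhantomError("CTV construction produced an empty mask")
    achieved = ctv.sum() * vox_cc
    if abs(achieved - spec.target_ctv_volume) > 0.05 * spec.target_ctv_volume:
        raise PhantomError(
            f"achieved CTV volume {achieved:.2f} cc deviates more than 5% from "
            f"target {spec.target_ctv_volume:.2f} cc; enlarge the grid"
        )

    masks = {
        "ctv": ctv,
        "brainstem": brainstem,
        "spinal_cord": cord,
        "body": body,
    }
    return PhantomGrid(
        density=density, masks=masks, origin=origin, voxel_size=vs, spec=spec
    )


# ---------------------------------------------------------------------------
# persistence (NIfTI volumes + JSON sidecar)
# ---------------------------------------------------------------------------

_SIDE_CAR_REQUIRED = ("voxel_size", "origin", "archetype")


def save_phantom(grid: PhantomGrid, path) -> Path:
    """Write density and masks as NIfTI volumes plus a JSON sidecar.

    ``path`` is a directory; files are ``density.nii``, ``mask_<name>.nii``
    and ``phantom.json``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(grid.voxel_size) + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.density.astype(np.float64), affine),
             path / "density.nii")
    for name, m in grid.masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), affine),
                 path / f"mask_{name}.nii")
    sidecar = {
        "voxel_size": list(map(float, grid.voxel_size)),
        "origin": list(map(float, grid.origin)),
        "archetype": grid.spec.archetype if grid.spec else "unknown",
        "masks": sorted(grid.masks),
        "spec": asdict(grid.spec) if grid.spec else None,
    }
    (path / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_phantom(path) -> PhantomGrid:
    """Read a phantom written by :func:`save_phantom`.

    Raises :class:`PhantomError` naming the offending field for malformed
    sidecars, and propagates parse errors for corrupt volumes.
    """
    path = Path(path)
    sidecar_path = path / "phantom.json"
    if not sidecar_path.exists():
        raise PhantomError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise PhantomError(f"malformed sidecar JSON: {e}") from e
    for key in _SIDE_CAR_REQUIRED:
        if key not in sidecar:
            raise PhantomError(f"sidecar missing required key {key!r}")
    try:
        density = np.asarray(nib.load(path / "density.nii").dataobj, dtype=float)
    except Exception as e:  # nibabel raises several types for corrupt files
        raise PhantomError(f"cannot parse density volume: {e}") from e
    masks = {}
    for name in sidecar.get("masks", []):
        masks[name] = np.asarray(
            nib.load(path / f"mask_{name}.nii").dataobj
        ).astype(bool)
    spec = None
    if sidecar.get("spec"):
        d = dict(sidecar["spec"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["voxel_size"] = tuple(d["voxel_size"])
        d["brainstem_center_xy"] = tuple(d["brainstem_center_xy"])
        spec = PhantomSpec(**d)
    return PhantomGrid(
        density=density,
        masks=masks,
        origin=np.asarray(sidecar["origin"], dtype=float),
        voxel_size=np.asarray(sidecar["voxel_size"], dtype=float),
        spec=spec,
    )
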