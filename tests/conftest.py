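import numpy as np
import pytest
from scipy import sparse

from letplan.beamlets import BeamConfig, InfluenceMatrices, SpotGrid, compute_influence, place_spots
from letplan.phantom import PhantomSpec, build_phantom


def make_small_spec(**overrides):
    """A fast-to-build wraparound phantom for unit tests."""
    kw = dict(
        archetype="wraparound",
        grid_shape=(30, 30, 32),
        target_ctv_volume=12.0,
        head_radius=36.0,
        skull_thickness=3.0,
        brainstem_radius=7.0,
        brainstem_length=30.0,
        cord_radius=4.0,
        cord_length=24.0,
        geometry={"arc_deg": 250.0, "ctv_length": 21.0, "overlap_fraction": 0.22},
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def make_random_influence(n_vox, n_spots, rng, density=0.15, n_beams=2,
                          let_scale=10.0):
    """Random nonnegative D/L matrices sharing one sparsity pattern."""
    mask = rng.random((n_vox, n_spots)) < density
    D = np.where(mask, rng.random((n_vox, n_spots)), 0.0)
    L = np.where(mask, let_scale * rng.random((n_vox, n_spots)), 0.0)
    beam_index = rng.integers(0, n_beams, size=n_spots)
    spots = SpotGrid(
        beam_index=beam_index,
        offset_a=np.zeros(n_spots),
        offset_b=np.zeros(n_spots),
        range_water=np.full(n_spots, 50.0),
        lateral_spacing=5.0,
        layer_step=5.0,
        n_beams=n_beams,
    )
    return InfluenceMatrices(
        D=sparse.csr_matrix(D),
        L=sparse.csr_matrix(L),
        scenario_id="nominal",
        spots=spots,
    ), D, L


def make_random_structures(n_vox, rng):
    """Disjoint random CTV/brainstem/spinal-cord voxel index sets."""
    perm = rng.permutation(n_vox)
    third = max(n_vox // 4, 2)
    return {
        "ctv": np.sort(perm[:third]),
        "brainstem": np.sort(perm[third:2 * third]),
        "spinal_cord": np.sort(perm[2 * third:2 * third + max(third // 2, 1)]),
    }


@pytest.fixture(scope="session")
def small_grid():
    return build_phantom(make_small_spec())


@pytest.fixture(scope="session")
def small_beams(small_grid):
    iso = small_grid.voxel_centers()[small_grid.structure_indices("ctv")].mean(axis=0)
    return [BeamConfig(180, 0, isocenter=tuple(iso)),
            BeamConfig(90, 0, isocenter=tuple(iso))]


@pytest.fixture(scope="session")
def small_spots(small_grid, small_beams):
    return place_spots(small_grid, small_beams)


@pytest.fixture(scope="session")
def small_structures(small_grid):
    return {n: small_grid.structure_indices(n)
            for n in ("ctv", "brainstem", "spinal_cord")}


@pytest.fixture(scope="session")
def small_rows(small_structures):
    return np.unique(np.concatenate(list(small_structures.values())))


@pytest.fixture(scope="session")
def small_influence(small_grid, small_spots, small_beams, small_rows):
    return compute_influence(small_grid, small_spots, beams=small_beams,
                             rows=small_rows)
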