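"""Shared fixtures: phantoms, montages and fluence fields.

Expensive objects (scalp meshes, Monte Carlo runs) are session-scoped so
the suite simulates each field once.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirsmap.mc import OpticalProperties, SimConfig, launch_geometry, normalize_fluence, simulate_fluence
from nirsmap.montage import assign_roles, build_channels, construct_10_10, default_fiducials, scalp_mesh
from nirsmap.volumes import PhantomSpec, make_layered_phantom


SPHERE_RADIUS = 70.0


@pytest.fixture(scope="session")
def sphere_phantom():
    spec = PhantomSpec(outer_radii_mm=(SPHERE_RADIUS,) * 3,
                       grid_shape=(64, 64, 64), voxel_size_mm=2.5,
                       n_sectors=8)
    return spec, *make_layered_phantom(spec)


@pytest.fixture(scope="session")
def sphere_montage(sphere_phantom):
    _, tissue, four, _ = sphere_phantom
    mesh = scalp_mesh(four)
    fid = default_fiducials(four)
    electrodes = construct_10_10(mesh, fid)
    return mesh, fid, electrodes


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    spec = PhantomSpec(outer_radii_mm=(65.0, 75.0, 60.0),
                       grid_shape=(64, 64, 64), voxel_size_mm=2.5,
                       n_sectors=8)
    return spec, *make_layered_phantom(spec)


@pytest.fixture(scope="session")
def ellipsoid_electrodes(ellipsoid_phantom):
    _, tissue, four, _ = ellipsoid_phantom
    return construct_10_10(scalp_mesh(four), default_fiducials(four))


@pytest.fixture(scope="session")
def default_optics():
    return OpticalProperties.default()


@pytest.fixture(scope="session")
def fluence_pair(ellipsoid_phantom, ellipsoid_electrodes, default_optics):
    """Normalized fluence for the Fpz (source) / AFz (detector) optodes."""
    _, tissue, four, atlas = ellipsoid_phantom
    out = {}
    for seed_offset, lab in enumerate(["Fpz", "AFz"]):
        pos, direction = launch_geometry(ellipsoid_electrodes[lab], tissue)
        cfg = SimConfig(n_photons=100_000, seed=101 + seed_offset)
        out[lab] = normalize_fluence(
            simulate_fluence(tissue, default_optics, pos, direction, cfg))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)


@pytest.fixture(scope="session")
def diffusion_run():
    """1e6 isotropic photons at the center of a homogeneous 80^3 medium."""
    from nirsmap.volumes import TissueLabelVolume

    n = 80
    labels = np.ones((n, n, n), dtype=np.int16)
    affine = np.eye(4)
    affine[:3, 3] = -(n - 1) / 2
    vol = TissueLabelVolume(labels=labels, affine=affine,
                            label_names={1: "med"})
    optics = OpticalProperties(table={"med": {"mu_a": 0.01, "mu_s": 1.0,
                                              "g": 0.0, "n": 1.0}})
    cfg = SimConfig(n_photons=1_000_000, seed=7)
    return vol, cfg, simulate_fluence(vol, optics, np.zeros(3), None, cfg)


@pytest.fixture(scope="session")
def montage_tables(sphere_montage):
    _, _, electrodes = sphere_montage
    roles = assign_roles(electrodes)
    channels = build_channels(roles)
    return roles, channels
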