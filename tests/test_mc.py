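"""Photon-transport physics: attenuation, diffusion, conservation, geometry."""

import numpy as np
import pytest

from nirsmap.mc import (
    OpticalProperties,
    SimConfig,
    launch_geometry,
    normalize_fluence,
    simulate_fluence,
)
from nirsmap.volumes import TissueLabelVolume


def _box(n, name="med", voxel=1.0):
    labels = np.ones((n, n, n), dtype=np.int16)
    affine = np.eye(4) * voxel
    affine[3, 3] = 1.0
    affine[:3, 3] = -(n - 1) / 2 * voxel
    return TissueLabelVolume(labels=labels, affine=affine,
                             label_names={1: name})


def _optics(mu_a, mu_s, g=0.0, name="med"):
    return OpticalProperties(table={name: {"mu_a": mu_a, "mu_s": mu_s,
                                           "g": g, "n": 1.0}})


def test_beer_lambert_in_pure_absorber():
    """Unscattered weight reaching depth d follows exp(-mu_a d)."""
    n, mu_a = 60, 0.1
    vol = _box(n)
    n_photons = 200_000
    cfg = SimConfig(n_photons=n_photons, seed=42)
    start = np.array([0.0, 0.0, -(n - 1) / 2])
    fl = simulate_fluence(vol, _optics(mu_a, 0.0), start,
                          np.array([0.0, 0.0, 1.0]), cfg)
    dep = fl.values * mu_a  # absorbed weight per voxel (unit voxels)
    profile = dep.sum(axis=(0, 1))
    beyond = profile[::-1].cumsum()[::-1] / n_photons
    # photons launch at the center of voxel 0, so voxel k starts at depth
    # k - 0.5 along the beam; weight past the far face (depth n - 0.5)
    # escapes and is never deposited
    escape = np.exp(-mu_a * (n - 0.5))
    for k in (5, 10, 20, 40):
        expect = np.exp(-mu_a * (k - 0.5)) - escape
        sigma = np.sqrt(expect * (1 - expect) / n_photons)
        assert abs(beyond[k] - expect) < 3 * sigma, k
    assert fl.escaped_weight / n_photons == pytest.approx(
        escape, abs=3 * np.sqrt(escape / n_photons))


def test_same_seed_is_bit_identical():
    vol = _box(30)
    optics = _optics(0.02, 1.0)
    cfg = SimConfig(n_photons=20_000, seed=9)
    args = (vol, optics, np.zeros(3), np.array([0.0, 0.0, 1.0]), cfg)
    a = simulate_fluence(*args)
    b = simulate_fluence(*args)
    assert np.array_equal(a.values, b.values)
    assert a.total_absorbed_weight == b.total_absorbed_weight
    c = simulate_fluence(vol, optics, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                         SimConfig(n_photons=20_000, seed=10))
    assert not np.array_equal(a.values, c.values)


def test_fluence_matches_diffusion_approximation(diffusion_run):
    """Shell-averaged fluence at 10-25 mm matches (4 pi D r)^-1 exp(-mueff r)."""
    vol, cfg, fl = diffusion_run
    mu_a, mu_sp = 0.01, 1.0
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = np.sqrt(3.0 * mu_a * (mu_a + mu_sp))
    n = vol.labels.shape[0]
    ctr = (n - 1) / 2
    idx = np.indices(vol.labels.shape)
    r = np.sqrt(((idx - ctr) ** 2).sum(axis=0))
    phi = fl.values / cfg.n_photons
    for r0 in (10, 15, 20, 25):
        shell = (r > r0 - 0.5) & (r < r0 + 0.5)
        got = phi[shell].mean()
        expect = np.exp(-mu_eff * r0) / (4 * np.pi * D * r0)
        assert abs(got - expect) / expect < 0.10, r0


def test_energy_conservation(diffusion_run):
    vol, cfg, fl = diffusion_run
    total = fl.total_absorbed_weight + fl.escaped_weight
    assert abs(total - cfg.n_photons) / cfg.n_photons < 1e-3


def test_fluence_nonnegative_finite_zero_outside(diffusion_run):
    _, _, fl = diffusion_run
    assert np.isfinite(fl.values).all()
    assert (fl.values >= 0).all()


def test_track_length_estimator_in_nonabsorbing_voxels():
    """mu_a = 0 voxels accumulate finite fluence via path lengths."""
    n = 21
    labels = np.ones((n, n, n), dtype=np.int16)
    labels[:, :, :8] = 2  # transparent-but-scattering slab
    affine = np.eye(4)
    affine[:3, 3] = -(n - 1) / 2
    vol = TissueLabelVolume(labels=labels, affine=affine,
                            label_names={1: "abs", 2: "clear"})
    optics = OpticalProperties(table={
        "abs": {"mu_a": 0.02, "mu_s": 1.0, "g": 0.0, "n": 1.0},
        "clear": {"mu_a": 0.0, "mu_s": 0.5, "g": 0.0, "n": 1.0}})
    cfg = SimConfig(n_photons=30_000, seed=5)
    fl = simulate_fluence(vol, optics, np.zeros(3), None, cfg)
    clear = fl.values[labels == 2]
    assert np.isfinite(clear).all()
    assert clear.sum() > 0


def test_normalization_inverse_and_single_voxel():
    vol = _box(9)
    cfg = SimConfig(n_photons=5_000, seed=3)
    fl = simulate_fluence(vol, _optics(0.5, 0.5), np.zeros(3), None, cfg)
    norm = normalize_fluence(fl)
    assert norm.normalization == "normalized"
    recovered = norm.values * fl.total_absorbed_weight
    assert np.allclose(recovered, fl.values, rtol=0, atol=1e-12)
    with pytest.raises(ValueError):
        normalize_fluence(norm)
    # pure absorber in a tiny closed box: nearly all weight lands in the
    # launch voxel, whose normalized deposited weight is then 1
    vol1 = _box(3, voxel=10.0)
    fl1 = simulate_fluence(vol1, _optics(5.0, 0.0),
                           np.zeros(3), None, SimConfig(n_photons=100, seed=1))
    n1 = normalize_fluence(fl1)
    dep = n1.values * 5.0 * 1000.0  # value * mu_a * voxel volume
    assert dep.sum() == pytest.approx(1.0, abs=1e-12)


def test_normalized_fluence_invariant_to_photon_count():
    vol = _box(25)
    optics = _optics(0.05, 1.0)
    runs = {}
    for n_ph in (40_000, 80_000):
        fl = normalize_fluence(simulate_fluence(
            vol, optics, np.zeros(3), None,
            SimConfig(n_photons=n_ph, seed=77)))
        # compare a coarse aggregate (central 11^3 block) between runs
        runs[n_ph] = fl.values[7:18, 7:18, 7:18].sum()
    assert runs[40_000] == pytest.approx(runs[80_000], rel=0.02)


def test_midline_source_fluence_is_left_right_symmetric():
    # odd grid so the source column is a voxel center, not a boundary
    vol = _box(41, voxel=2.0)
    optics = _optics(0.02, 1.0)
    cfg = SimConfig(n_photons=200_000, seed=11)
    start = np.array([0.0, 0.0, -40.0])
    fl = simulate_fluence(vol, optics, start, np.array([0.0, 0.0, 1.0]), cfg)
    left = fl.values[:20].sum()
    right = fl.values[21:].sum()
    assert abs(left - right) / (left + right) < 0.02


def test_simulation_error_conditions():
    vol = _box(10)
    optics = _optics(0.1, 1.0)
    cfg = SimConfig(n_photons=10, seed=0)
    with pytest.raises(ValueError, match="outside"):
        simulate_fluence(vol, optics, np.array([100.0, 0, 0]), None, cfg)
    empty = TissueLabelVolume(labels=np.zeros((5, 5, 5), np.int16),
                              affine=np.eye(4), label_names={})
    with pytest.raises(ValueError, match="no head"):
        simulate_fluence(empty, optics, np.zeros(3), None, cfg)
    with pytest.raises(ValueError):
        SimConfig(n_photons=0)
    with pytest.raises(ValueError):
        SimConfig(roulette_threshold=2.0)


def test_launch_geometry_on_sphere(sphere_phantom, sphere_montage):
    _, tissue, four, _ = sphere_phantom
    _, _, electrodes = sphere_montage
    for lab in ("Cz", "T7", "Oz"):
        pos, direction = launch_geometry(electrodes[lab], tissue)
        # nearest-voxel choice agrees with an exhaustive scan over head voxels
        ijk = np.argwhere(tissue.labels > 0)
        world = tissue.voxel_to_world(ijk)
        d = np.linalg.norm(world - electrodes[lab], axis=1)
        assert np.linalg.norm(pos - world[np.argmin(d)]) < 1e-9
        # inward normal points at the sphere center within 2 degrees
        inward = -pos / np.linalg.norm(pos)
        angle = np.degrees(np.arccos(np.clip(direction @ inward, -1, 1)))
        assert angle < 2.0, (lab, angle)


def test_launch_geometry_rejects_far_positions(sphere_phantom):
    _, tissue, _, _ = sphere_phantom
    with pytest.raises(ValueError, match="one voxel"):
        launch_geometry(np.array([0.0, 0.0, 150.0]), tissue)
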