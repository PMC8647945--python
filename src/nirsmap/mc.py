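"""Voxel-based Monte Carlo photon transport.

Weighted photon packets random-walk through the tissue label grid: step
lengths are sampled as ``-ln(xi)/mu_t`` (consumed voxel-by-voxel as optical
depth in heterogeneous media), a fraction ``mu_a/mu_t`` of the packet
weight is deposited at each interaction, new directions are drawn from the
Henyey-Greenstein phase function, and low-weight packets undergo Russian
roulette.  Packets that leave the head or the grid are terminated
(continuous-wave accumulation; no boundary reflection).

Fluence is estimated per voxel as ``deposited weight / (mu_a * voxel
volume)`` in absorbing voxels and by the track-length estimator
(``sum of weight x path length / voxel volume``) where ``mu_a = 0``
(CSF-like media); both are unbiased estimators of the same quantity.

Normalization follows the convention of dividing each optode's fluence by
the total photon weight absorbed inside the head, which makes downstream
specificity values (ratios) independent of photon count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from numba import njit
from scipy.ndimage import gaussian_filter

from .volumes import TissueLabelVolume, _LabelGrid

__all__ = [
    "OpticalProperties",
    "SimConfig",
    "FluenceVolume",
    "simulate_fluence",
    "normalize_fluence",
    "launch_geometry",
]


@dataclass
class OpticalProperties:
    """Per-tissue absorption/scattering parameters.

    ``table`` maps tissue *names* to ``{mu_a, mu_s, g, n}`` with ``mu_a``
    and ``mu_s`` in 1/mm, anisotropy ``g`` in [-1, 1] and refractive index
    ``n >= 1``.  Air/outside is implicitly transparent.
    """

    table: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for name, props in self.table.items():
            missing = {"mu_a", "mu_s", "g", "n"} - set(props)
            if missing:
                raise ValueError(f"{name}: missing optical fields {missing}")
            if props["mu_a"] < 0 or props["mu_s"] < 0:
                raise ValueError(f"{name}: mu_a and mu_s must be >= 0")
            if not -1.0 <= props["g"] <= 1.0:
                raise ValueError(f"{name}: anisotropy g must lie in [-1, 1]")
            if props["n"] < 1.0:
                raise ValueError(f"{name}: refractive index must be >= 1")

    @classmethod
    def default(cls) -> "OpticalProperties":
        """Packaged near-infrared tissue table (see data/optical_properties.yaml)."""
        text = resources.files("nirsmap").joinpath(
            "data", "optical_properties.yaml").read_text()
        return cls(table=yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OpticalProperties":
        return cls(table=yaml.safe_load(Path(path).read_text()))

    def lookup_tables(
        self, vol: TissueLabelVolume
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(mu_a, mu_s, g, n) arrays indexed by the volume's tissue labels."""
        max_label = int(vol.labels.max(initial=0))
        mua = np.zeros(max_label + 1)
        mus = np.zeros(max_label + 1)
        g = np.zeros(max_label + 1)
        n = np.ones(max_label + 1)
        for lab in np.unique(vol.labels):
            lab = int(lab)
            if lab == 0:
                continue
            name = vol.label_names[lab]
            if name not in self.table:
                raise KeyError(f"no optical properties for tissue {name!r}")
            p = self.table[name]
            mua[lab], mus[lab], g[lab], n[lab] = (
                p["mu_a"], p["mu_s"], p["g"], p["n"])
        return mua, mus, g, n


@dataclass
class SimConfig:
    """Monte Carlo run parameters.

    ``n_photons`` defaults to a desk-scale 10^6 (production runs use more);
    ``max_path_mm`` optionally terminates packets whose accumulated path
    exceeds a cutoff (e.g. the distance light travels in 5 ns).
    """

    n_photons: int = 1_000_000
    seed: int = 0
    wavelength_nm: float = 690.0
    roulette_threshold: float = 1e-4
    roulette_survival: int = 10
    boundary_policy: str = "terminate-on-exit"
    max_path_mm: float | None = None

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_threshold < 1.0:
            raise ValueError("roulette_threshold must lie in (0, 1)")
        if self.roulette_survival <= 1:
            raise ValueError("roulette_survival must be > 1")
        if self.boundary_policy != "terminate-on-exit":
            raise ValueError("only 'terminate-on-exit' boundaries are supported")


@dataclass
class FluenceVolume:
    """Per-voxel photon fluence from one optode position."""

    values: np.ndarray
    affine: np.ndarray
    launch_position: np.ndarray
    normalization: str = "raw"
    total_absorbed_weight: float = 0.0
    escaped_weight: float = 0.0
    n_photons: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=float)
        self.launch_position = np.asarray(self.launch_position, dtype=float)
        if (self.values < 0).any():
            raise ValueError("fluence must be non-negative")

    def same_grid(self, other) -> bool:
        return (self.values.shape == other.values.shape
                and np.allclose(self.affine, other.affine))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        nib.save(img, str(path))
        meta = {
            "launch_position": self.launch_position.tolist(),
            "normalization": self.normalization,
            "total_absorbed_weight": self.total_absorbed_weight,
            "escaped_weight": self.escaped_weight,
            "n_photons": self.n_photons,
            "seed": self.seed,
        }
        side = path.with_name(path.name.replace(".nii.gz", "").replace(".nii", "")
                              + ".json")
        side.write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# Transport kernel
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _splitmix64(state):
    z = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rand(s0, s1):
    # xorshift128+ step; returns a double in (0, 1) and the new state
    x = s0
    y = s1
    r = x + y
    x = x ^ (x << np.uint64(23))
    ns1 = x ^ y ^ (x >> np.uint64(18)) ^ (y >> np.uint64(5))
    u = (np.float64(r >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)
    return u, y, ns1


@njit(cache=True, fastmath=True)
def _transport_kernel(labels, mua_lut, mus_lut, g_lut,
                      vx, vy, vz, px, py, pz, dx, dy, dz, isotropic,
                      n_photons, seed, w_thresh, m_survival, max_path,
                      dep, tlen):
    # xorshift128+ stream, seeded through splitmix64 (counter-based per run)
    s0 = _splitmix64(np.uint64(seed))
    s1 = _splitmix64(s0)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)
    nx, ny, nz_ = labels.shape
    escaped = 0.0
    for _ in range(n_photons):
        x, y, z = px, py, pz
        if isotropic:
            u, s0, s1 = _rand(s0, s1)
            ct = 2.0 * u - 1.0
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            u, s0, s1 = _rand(s0, s1)
            phi = 2.0 * np.pi * u
            ux, uy, uz = st * np.cos(phi), st * np.sin(phi), ct
        else:
            ux, uy, uz = dx, dy, dz
        iux = 1.0 / ux if ux != 0.0 else 1e30
        iuy = 1.0 / uy if uy != 0.0 else 1e30
        iuz = 1.0 / uz if uz != 0.0 else 1e30
        w = 1.0
        u, s0, s1 = _rand(s0, s1)
        tau = -np.log(u)
        path = 0.0
        # voxel indices are tracked incrementally while the packet moves
        i = int(np.floor(x / vx))
        j = int(np.floor(y / vy))
        k = int(np.floor(z / vz))
        while True:
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz_:
                escaped += w
                break
            lab = labels[i, j, k]
            if lab == 0:
                escaped += w
                break
            mua = mua_lut[lab]
            mus = mus_lut[lab]
            mut = mua + mus
            # distance to the current voxel's boundary along the direction
            if ux > 0.0:
                tbx = ((i + 1) * vx - x) * iux
            elif ux < 0.0:
                tbx = (i * vx - x) * iux
            else:
                tbx = 1e30
            if uy > 0.0:
                tby = ((j + 1) * vy - y) * iuy
            elif uy < 0.0:
                tby = (j * vy - y) * iuy
            else:
                tby = 1e30
            if uz > 0.0:
                tbz = ((k + 1) * vz - z) * iuz
            elif uz < 0.0:
                tbz = (k * vz - z) * iuz
            else:
                tbz = 1e30
            db = min(tbx, min(tby, tbz))
            if db < 0.0:
                db = 0.0
            di = 1e30 if mut <= 0.0 else tau / mut
            if di < db:
                # interaction inside this voxel
                x += ux * di
                y += uy * di
                z += uz * di
                path += di
                if mua == 0.0:
                    tlen[i, j, k] += w * di
                else:
                    adep = w * mua / mut
                    dep[i, j, k] += adep
                    w -= adep
                if w <= 0.0:
                    break
                # Henyey-Greenstein scattering
                g = g_lut[lab]
                if g != 0.0:
                    u, s0, s1 = _rand(s0, s1)
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                else:
                    u, s0, s1 = _rand(s0, s1)
                    ct = 2.0 * u - 1.0
                st = np.sqrt(max(0.0, 1.0 - ct * ct))
                u, s0, s1 = _rand(s0, s1)
                phi = 2.0 * np.pi * u
                cp, sp = np.cos(phi), np.sin(phi)
                if abs(uz) > 0.99999:
                    nux = st * cp
                    nuy = st * sp
                    nuz = ct * (1.0 if uz > 0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux, uy, uz = nux / norm, nuy / norm, nuz / norm
                iux = 1.0 / ux if ux != 0.0 else 1e30
                iuy = 1.0 / uy if uy != 0.0 else 1e30
                iuz = 1.0 / uz if uz != 0.0 else 1e30
                u, s0, s1 = _rand(s0, s1)
                tau = -np.log(u)
                if w < w_thresh:
                    u, s0, s1 = _rand(s0, s1)
                    if u * m_survival < 1.0:
                        w *= m_survival
                    else:
                        break  # roulette kill (unbiased in expectation)
                if max_path > 0.0 and path > max_path:
                    escaped += w
                    break
            else:
                # cross into the next voxel
                if mua == 0.0 and db > 0.0:
                    tlen[i, j, k] += w * db
                x += ux * db
                y += uy * db
                z += uz * db
                if tbx <= tby and tbx <= tbz:
                    i += 1 if ux > 0.0 else -1
                elif tby <= tbz:
                    j += 1 if uy > 0.0 else -1
                else:
                    k += 1 if uz > 0.0 else -1
                if mut > 0.0:
                    tau -= mut * db
                path += db
                if max_path > 0.0 and path > max_path:
                    escaped += w
                    break
    return escaped


def simulate_fluence(
    vol: TissueLabelVolume,
    optics: OpticalProperties,
    position: np.ndarray,
    direction: np.ndarray | None,
    config: SimConfig,
) -> FluenceVolume:
    """Run photon transport from one optode position.

    Parameters
    ----------
    position
        Launch position in world mm; must lie inside the head.
    direction
        Unit launch direction (pointing into the head), or ``None`` for an
        isotropic point source.

    Returns a raw (unnormalized) :class:`FluenceVolume`; results are
    bit-reproducible for a fixed seed.
    """
    A = vol.affine
    if not np.allclose(A[:3, :3], np.diag(np.diag(A[:3, :3]))) or \
            np.any(np.diag(A[:3, :3]) <= 0):
        raise ValueError("transport requires an axis-aligned RAS affine")
    if not vol.head_mask().any():
        raise ValueError("volume contains no head media")
    v = np.diag(A[:3, :3])
    origin = A[:3, 3]
    # Positions are tracked in the volume frame; voxel i spans
    # [(i - 0.5) v, (i + 0.5) v) around its center, so shift by half a voxel.
    p = (np.asarray(position, dtype=float) - origin) + 0.5 * v
    idx = np.floor(p / v).astype(int)
    if np.any(idx < 0) or np.any(idx >= vol.labels.shape):
        raise ValueError("launch position lies outside the grid")
    if direction is None:
        isotropic = True
        d = np.array([0.0, 0.0, 1.0])
    else:
        isotropic = False
        d = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("direction must be a nonzero vector")
        d = d / norm

    mua, mus, g, _ = optics.lookup_tables(vol)
    labels = np.ascontiguousarray(vol.labels.astype(np.int32))
    dep = np.zeros(vol.labels.shape, dtype=np.float64)
    tlen = np.zeros(vol.labels.shape, dtype=np.float64)
    max_path = -1.0 if config.max_path_mm is None else float(config.max_path_mm)
    escaped = _transport_kernel(
        labels, mua, mus, g,
        float(v[0]), float(v[1]), float(v[2]),
        float(p[0]), float(p[1]), float(p[2]),
        float(d[0]), float(d[1]), float(d[2]), isotropic,
        int(config.n_photons), int(config.seed) & 0x7FFFFFFF,
        float(config.roulette_threshold), float(config.roulette_survival),
        max_path, dep, tlen,
    )
    total_absorbed = float(dep.sum())
    voxel_vol = vol.voxel_volume_mm3
    with np.errstate(divide="ignore", invalid="ignore"):
        flu = np.where(mua[vol.labels] > 0,
                       dep / (mua[vol.labels] * voxel_vol),
                       tlen / voxel_vol)
    flu[vol.labels == 0] = 0.0
    return FluenceVolume(
        values=flu,
        affine=vol.affine.copy(),
        launch_position=np.asarray(position, dtype=float),
        normalization="raw",
        total_absorbed_weight=total_absorbed,
        escaped_weight=float(escaped),
        n_photons=config.n_photons,
        seed=config.seed,
    )


def normalize_fluence(raw: FluenceVolume) -> FluenceVolume:
    """Divide fluence by the total absorbed photon weight.

    The relative spatial pattern is unchanged; downstream specificity is a
    ratio and therefore invariant to the normalization constant.
    """
    if raw.normalization != "raw":
        raise ValueError("fluence volume is already normalized")
    if raw.total_absorbed_weight <= 0:
        raise ValueError("no photon weight absorbed; cannot normalize")
    return replace(raw, values=raw.values / raw.total_absorbed_weight,
                   normalization="normalized")


def launch_geometry(
    electrode_position: np.ndarray,
    vol: _LabelGrid,
    smooth_sigma: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Source placement for an electrode: nearest head voxel + inward normal.

    Returns the world-mm center of the head voxel closest to the electrode
    and the inward surface normal there (gradient of the smoothed head
    mask).  Raises if no head voxel lies within one voxel diagonal of the
    electrode.
    """
    pos = np.asarray(electrode_position, dtype=float)
    mask = vol.labels > 0
    if not mask.any():
        raise ValueError("volume contains no head voxels")
    # Limit the candidate search to surface voxels (head voxels with an
    # outside neighbor) for speed; the nearest head voxel to an on-scalp
    # electrode is always a surface voxel.
    from scipy.ndimage import binary_erosion
    surface = mask & ~binary_erosion(mask)
    ijk = np.argwhere(surface)
    world = vol.voxel_to_world(ijk)
    d = np.linalg.norm(world - pos, axis=1)
    best = int(np.argmin(d))
    tol = float(np.linalg.norm(vol.voxel_size_mm))
    if d[best] > tol:
        raise ValueError(
            f"no head voxel within one voxel radius of {pos} "
            f"(nearest at {d[best]:.1f} mm)")
    voxel = ijk[best]
    smooth = gaussian_filter(mask.astype(np.float32), smooth_sigma)
    grad = np.array(np.gradient(smooth))  # d/d(index)
    gvec = grad[:, voxel[0], voxel[1], voxel[2]] / vol.voxel_size_mm
    norm = np.linalg.norm(gvec)
    if norm < 1e-9:
        gvec = np.asarray(vol.voxel_to_world(
            (np.asarray(vol.labels.shape) - 1) / 2.0)) - world[best]
        norm = np.linalg.norm(gvec)
    direction = gvec / norm  # gradient points toward increasing mask: inward
    return world[best], direction
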