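"""Construction of the 81-position 10-10 scalp montage and its channel set.

The 10-10 system places electrodes at proportional (10%/20%) fractions of
arc length along reference curves on the scalp:

* the mid-sagittal curve from nasion (Nz) to inion (Iz) through the vertex
  (Cz);
* the central coronal curve from the left to the right preauricular point
  (LPA, RPA) through Cz;
* a circumferential ring through Fpz, T7/T8 and Oz;
* a lower ring at fiducial level through Nz, T9/T10 and Iz;
* intermediate coronal curves joining ring positions through the midline
  (e.g. F7 - Fz - F8).

Cz itself is fixed iteratively as the point that bisects both the
sagittal and the coronal curve.  All curves are computed as plane sections
of a triangulated scalp isosurface, so the construction works on any
closed, star-convex head shape (spheres, ellipsoids, segmented heads).

Source/detector roles and the packaged 130-channel pairing follow the
fixed montage design of fNIRS optode-placement practice: 74 of the 81
positions are retained (Nz, N1, N2, AF9, AF10, T9, T10 are unused) and
split into 38 sources and 36 neighboring detectors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from skimage.measure import marching_cubes

from .volumes import _LabelGrid

__all__ = [
    "LABELS_10_10",
    "DEFAULT_EXCLUSIONS",
    "FiducialSet",
    "ElectrodeSet",
    "OptodeRoles",
    "ChannelSet",
    "scalp_mesh",
    "default_fiducials",
    "construct_10_10",
    "assign_roles",
    "build_channels",
    "normalize_label",
    "mirror_label",
]

# The 81 labels of the 10-10 system, grouped by row (anterior to posterior).
LABELS_10_10: tuple[str, ...] = (
    "Nz", "N1", "N2",
    "Fp1", "Fpz", "Fp2",
    "AF9", "AF7", "AF3", "AFz", "AF4", "AF8", "AF10",
    "F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T9", "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "T10",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2",
    "I1", "Iz", "I2",
)

#: Positions not used for optodes (they have no neighboring pairing room).
DEFAULT_EXCLUSIONS: tuple[str, ...] = ("Nz", "N1", "AF9", "T9", "N2", "AF10", "T10")

_CANONICAL = {lab.lower(): lab for lab in LABELS_10_10}


def normalize_label(label: str) -> str:
    """Canonical spelling of a 10-10 label; matching is case-insensitive."""
    key = label.strip().lower()
    if key not in _CANONICAL:
        raise KeyError(f"unknown 10-10 label {label!r}")
    return _CANONICAL[key]


def mirror_label(label: str) -> str:
    """Left-right homologue of a 10-10 label (C3 <-> C4; midline fixed).

    Odd indices are left-hemisphere, even are right; ``mirror`` is an
    involution and a bijection on the 81 labels.
    """
    lab = normalize_label(label)
    if lab.endswith("z"):
        return lab
    head = lab.rstrip("0123456789")
    num = int(lab[len(head):])
    num = num + 1 if num % 2 == 1 else num - 1
    return normalize_label(f"{head}{num}")


@dataclass
class FiducialSet:
    """World-mm positions of the four scalp fiducials."""

    nz: np.ndarray
    iz: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray

    def __post_init__(self) -> None:
        for name in ("nz", "iz", "lpa", "rpa"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.allclose(self.nz, self.iz) or np.allclose(self.lpa, self.rpa):
            raise ValueError("degenerate fiducials")


@dataclass
class ElectrodeSet:
    """Labeled electrode positions (world mm) on the scalp surface."""

    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = {normalize_label(k): np.asarray(v, dtype=float)
                          for k, v in self.positions.items()}

    def __getitem__(self, label: str) -> np.ndarray:
        return self.positions[normalize_label(label)]

    def __contains__(self, label: str) -> bool:
        try:
            return normalize_label(label) in self.positions
        except KeyError:
            return False

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def labels(self) -> list[str]:
        return list(self.positions)


@dataclass
class OptodeRoles:
    """Partition of electrode labels into sources, detectors and excluded."""

    sources: list[str]
    detectors: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sources = [normalize_label(s) for s in self.sources]
        self.detectors = [normalize_label(d) for d in self.detectors]
        self.excluded = [normalize_label(e) for e in self.excluded]
        if set(self.sources) & set(self.detectors):
            raise ValueError("a label cannot be both source and detector")


@dataclass
class ChannelSet:
    """Ordered source-detector pairs with stable 1-based channel ids."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(normalize_label(s), normalize_label(d))
                      for s, d in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate source-detector pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def ids(self) -> list[str]:
        return [f"{s}-{d}" for s, d in self.pairs]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        s, d = pair
        return (normalize_label(s), normalize_label(d)) in self.pairs

    def mirror_pair(self, pair: tuple[str, str]) -> tuple[str, str]:
        s, d = pair
        return mirror_label(s), mirror_label(d)

    def optodes(self) -> set[str]:
        return {s for s, _ in self.pairs} | {d for _, d in self.pairs}


# ---------------------------------------------------------------------------
# Scalp surface and reference-curve geometry
# ---------------------------------------------------------------------------

def scalp_mesh(vol: _LabelGrid, smooth_sigma: float = 1.0) -> trimesh.Trimesh:
    """Triangulated outer head surface in world coordinates.

    The head mask (any nonzero label) is lightly smoothed and the 0.5
    isosurface extracted; vertices are mapped through the volume affine.
    """
    mask = (vol.labels > 0).astype(np.float32)
    if not mask.any():
        raise ValueError("volume contains no head voxels")
    if smooth_sigma > 0:
        mask = gaussian_filter(mask, smooth_sigma)
    verts, faces, _, _ = marching_cubes(mask, level=0.5)
    world = verts @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        # Keep the largest connected component; the head surface must close.
        parts = mesh.split(only_watertight=False)
        mesh = max(parts, key=lambda m: m.area)
    return mesh


def default_fiducials(vol: _LabelGrid) -> FiducialSet:
    """Fiducials for synthetic phantoms: surface extrema along +/-y, +/-x.

    Nasion and inion are the most anterior/posterior scalp points at the
    head-center height; the preauricular points the most lateral ones.
    """
    mask = vol.labels > 0
    if not mask.any():
        raise ValueError("volume contains no head voxels")
    ijk = np.argwhere(mask)
    center = vol.voxel_to_world(ijk.mean(axis=0))
    step = 0.25 * float(np.min(vol.voxel_size_mm))
    t_max = float(np.linalg.norm(
        np.asarray(vol.labels.shape) * vol.voxel_size_mm))
    ts = np.arange(0.0, t_max, step)
    inv = np.linalg.inv(vol.affine)
    dirs = np.array([[0, 1, 0], [0, -1, 0], [-1, 0, 0], [1, 0, 0]], float)
    points = []
    for d in dirs:
        world = center + ts[:, None] * d
        q = np.round(world @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        ok = np.all((q >= 0) & (q < np.asarray(vol.labels.shape)), axis=1)
        hit = np.zeros(len(ts), dtype=bool)
        hit[ok] = mask[q[ok, 0], q[ok, 1], q[ok, 2]]
        if not hit.any():
            raise ValueError("could not cast fiducial ray onto the surface")
        points.append(world[np.max(np.nonzero(hit)[0])])
    return FiducialSet(nz=points[0], iz=points[1], lpa=points[2], rpa=points[3])


def _closed_loops(path) -> list[np.ndarray]:
    loops = []
    for pts in path.discrete:
        pts = np.asarray(pts, dtype=float)
        if len(pts) >= 4 and np.allclose(pts[0], pts[-1], atol=1e-6):
            loops.append(pts)
    return loops


def _section_loop(mesh: trimesh.Trimesh, a, b, c) -> np.ndarray:
    """Closed polyline where the plane through a, b, c cuts the mesh."""
    n = np.cross(np.asarray(b) - a, np.asarray(c) - a)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("section points are collinear")
    path = mesh.section(plane_origin=np.asarray(a), plane_normal=n / norm)
    if path is None:
        raise ValueError("plane does not intersect the scalp surface")
    loops = _closed_loops(path)
    if not loops:
        raise ValueError("plane section is not a closed curve")

    def fit(loop):  # the loop must pass near all three defining points
        return max(
            np.min(np.linalg.norm(loop - np.asarray(p), axis=1))
            for p in (a, b, c)
        )

    return min(loops, key=fit)


def _arc_param(loop: np.ndarray, point: np.ndarray) -> float:
    """Arc-length position of the closest point on a closed polyline."""
    p = np.asarray(point, dtype=float)
    seg = loop[1:] - loop[:-1]
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rel = p - loop[:-1]
    t = np.einsum("ij,ij->i", rel, seg) / np.maximum(seg_len**2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    proj = loop[:-1] + t[:, None] * seg
    d = np.linalg.norm(proj - p, axis=1)
    i = int(np.argmin(d))
    return float(cum[i] + t[i] * seg_len[i])


def _point_at(loop: np.ndarray, s: float) -> np.ndarray:
    seg_len = np.linalg.norm(loop[1:] - loop[:-1], axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = s % total
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg_len) - 1)
    f = (s - cum[i]) / max(seg_len[i], 1e-12)
    return loop[i] + f * (loop[i + 1] - loop[i])


class _Arc:
    """Open arc from A to B along a plane-section loop, through/avoiding C."""

    def __init__(self, loop: np.ndarray, a, b, via=None, avoid=None):
        self.loop = loop
        seg_len = np.linalg.norm(loop[1:] - loop[:-1], axis=1)
        self.total = float(np.sum(seg_len))
        sa = _arc_param(loop, a)
        sb = _arc_param(loop, b)
        forward_len = (sb - sa) % self.total
        if via is not None:
            sc = _arc_param(loop, via)
            use_forward = (sc - sa) % self.total <= forward_len + 1e-9
        elif avoid is not None:
            sc = _arc_param(loop, avoid)
            use_forward = not ((sc - sa) % self.total < forward_len - 1e-9)
        else:
            use_forward = forward_len <= self.total / 2
        self.sa = sa
        self.direction = 1.0 if use_forward else -1.0
        self.length = forward_len if use_forward else self.total - forward_len

    def point(self, fraction: float) -> np.ndarray:
        s = self.sa + self.direction * fraction * self.length
        return _point_at(self.loop, s)


def _arc(mesh, a, b, c, via_c=True, avoid=None) -> _Arc:
    loop = _section_loop(mesh, a, b, c if avoid is None else avoid)
    if avoid is not None:
        return _Arc(loop, a, b, avoid=avoid)
    return _Arc(loop, a, b, via=c)


def construct_10_10(
    scalp: trimesh.Trimesh | _LabelGrid,
    fiducials: FiducialSet,
    *,
    max_iter: int = 25,
    tol_mm: float = 0.05,
    fiducial_tol_mm: float | None = None,
) -> ElectrodeSet:
    """Place the 81 positions of the 10-10 system on a scalp surface.

    Cz is refined iteratively until it bisects both the Nz-Iz and the
    LPA-RPA surface curves; the remaining positions follow by proportional
    subdivision of the reference curves.

    Parameters
    ----------
    scalp
        A closed scalp surface mesh, or a label volume from which one is
        extracted.
    fiducials
        Nasion, inion and preauricular points, on the surface.
    """
    mesh = scalp if isinstance(scalp, trimesh.Trimesh) else scalp_mesh(scalp)
    if not mesh.is_watertight:
        raise ValueError("scalp surface is not closed")
    scale = float(np.cbrt(mesh.volume))
    if fiducial_tol_mm is None:
        fiducial_tol_mm = 0.1 * scale
    fid = {"Nz": fiducials.nz, "Iz": fiducials.iz,
           "LPA": fiducials.lpa, "RPA": fiducials.rpa}
    for name, p in fid.items():
        d = np.min(np.linalg.norm(mesh.vertices - p, axis=1))
        if d > fiducial_tol_mm:
            raise ValueError(f"fiducial {name} is {d:.1f} mm off the surface")
    nz, iz, lpa, rpa = fid["Nz"], fid["Iz"], fid["LPA"], fid["RPA"]

    # --- iterative vertex (Cz) placement ---------------------------------
    cz = mesh.vertices[np.argmax(mesh.vertices[:, 2])]
    for _ in range(max_iter):
        sag = _arc(mesh, nz, iz, cz)
        cz_new = sag.point(0.5)
        cor = _arc(mesh, lpa, rpa, cz_new)
        cz_new = cor.point(0.5)
        shift = np.linalg.norm(cz_new - cz)
        cz = cz_new
        if shift < tol_mm:
            break

    pos: dict[str, np.ndarray] = {}

    # --- mid-sagittal curve: Nz .. Iz through Cz -------------------------
    sag = _arc(mesh, nz, iz, cz)
    midline = ["Nz", "Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz",
               "Oz", "Iz"]
    for i, lab in enumerate(midline):
        pos[lab] = sag.point(i / 10)

    # --- central coronal curve: LPA .. RPA through Cz --------------------
    cor = _arc(mesh, lpa, rpa, pos["Cz"])
    coronal = ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]
    for i, lab in enumerate(coronal, start=1):
        p = cor.point(i / 10)
        if lab != "Cz":
            pos[lab] = p

    # --- lower ring at fiducial level: Nz .. Iz via LPA / RPA ------------
    for via, labs in (
        (lpa, ["N1", "AF9", "F9", "FT9", "T9", "TP9", "P9", "PO9", "I1"]),
        (rpa, ["N2", "AF10", "F10", "FT10", "T10", "TP10", "P10", "PO10", "I2"]),
    ):
        ring = _arc(mesh, nz, iz, via)
        for i, lab in enumerate(labs, start=1):
            pos[lab] = ring.point(i / 10)

    # --- upper circumferential ring through Fpz, T7/T8, Oz ---------------
    for t_lab, labs_front, labs_back in (
        ("T7", ["Fp1", "AF7", "F7", "FT7"], ["TP7", "P7", "PO7", "O1"]),
        ("T8", ["Fp2", "AF8", "F8", "FT8"], ["TP8", "P8", "PO8", "O2"]),
    ):
        front = _arc(mesh, pos["Fpz"], pos[t_lab], pos["Oz"], avoid=pos["Oz"])
        for i, lab in enumerate(labs_front, start=1):
            pos[lab] = front.point(i / 5)
        back = _arc(mesh, pos[t_lab], pos["Oz"], pos["Fpz"], avoid=pos["Fpz"])
        for i, lab in enumerate(labs_back, start=1):
            pos[lab] = back.point(i / 5)

    # --- intermediate coronal rows ---------------------------------------
    rows = (
        ("AF7", "AFz", "AF8", ["AF3"], ["AF4"]),
        ("F7", "Fz", "F8", ["F5", "F3", "F1"], ["F2", "F4", "F6"]),
        ("FT7", "FCz", "FT8", ["FC5", "FC3", "FC1"], ["FC2", "FC4", "FC6"]),
        ("TP7", "CPz", "TP8", ["CP5", "CP3", "CP1"], ["CP2", "CP4", "CP6"]),
        ("P7", "Pz", "P8", ["P5", "P3", "P1"], ["P2", "P4", "P6"]),
        ("PO7", "POz", "PO8", ["PO3"], ["PO4"]),
    )
    for left_lab, mid_lab, right_lab, left_names, right_names in rows:
        l, m, r = pos[left_lab], pos[mid_lab], pos[right_lab]
        half_left = _arc(mesh, l, m, r, avoid=r)
        nl = len(left_names) + 1
        for i, lab in enumerate(left_names, start=1):
            pos[lab] = half_left.point(i / nl)
        half_right = _arc(mesh, m, r, l, avoid=l)
        for i, lab in enumerate(right_names, start=1):
            pos[lab] = half_right.point(i / nl)

    assert len(pos) == len(LABELS_10_10)
    return ElectrodeSet(positions=pos)


# ---------------------------------------------------------------------------
# Roles and channels (packaged montage design)
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> list[dict[str, str]]:
    text = resources.files("nirsmap").joinpath("data", name).read_text()
    lines = [l for l in text.splitlines() if not l.startswith("#")]
    return list(csv.DictReader(lines))


def _packaged_roles() -> dict[str, str]:
    return {row["label"]: row["role"] for row in _load_packaged("optode_roles.csv")}


def packaged_pairing() -> list[tuple[str, str]]:
    """The packaged source-detector pairing table (130 channels)."""
    return [(row["source"], row["detector"])
            for row in _load_packaged("channel_pairs.csv")]


def assign_roles(
    electrodes: ElectrodeSet,
    exclusions: list[str] | None = None,
) -> OptodeRoles:
    """Split retained 10-10 positions into sources and detectors.

    With the default exclusion list (Nz, N1, AF9, T9, N2, AF10, T10) the
    74 remaining positions form 38 sources and 36 detectors, following the
    packaged role table.
    """
    if exclusions is None:
        excl = [normalize_label(e) for e in DEFAULT_EXCLUSIONS]
    else:
        excl = [normalize_label(e) for e in exclusions]
    for e in excl:
        if e not in electrodes:
            raise ValueError(f"excluded label {e!r} not among electrodes")
    roles = _packaged_roles()
    sources, detectors = [], []
    for lab in electrodes.labels:
        if lab in excl:
            continue
        (sources if roles[lab] == "source" else detectors).append(lab)
    return OptodeRoles(sources=sources, detectors=detectors, excluded=excl)


def build_channels(
    roles: OptodeRoles,
    pairing: list[tuple[str, str]] | None = None,
) -> ChannelSet:
    """Form the source-detector channel set from a pairing table.

    The default packaged table pairs neighboring optodes of the 10-10
    layout and yields 130 channels under the default role assignment.
    """
    if pairing is None:
        pairing = packaged_pairing()
    pairs = []
    src = set(roles.sources)
    det = set(roles.detectors)
    for s, d in pairing:
        s, d = normalize_label(s), normalize_label(d)
        if s in roles.excluded or d in roles.excluded:
            raise ValueError(f"channel {s}-{d} references an excluded optode")
        if s not in src:
            raise ValueError(f"{s} is not a source")
        if d not in det:
            raise ValueError(f"{d} is not a detector")
        pairs.append((s, d))
    return ChannelSet(pairs=pairs)
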