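"""Independent reference implementations used as test oracles.

Everything here is deliberately written as plain nested loops or exact
closed-form geometry, sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Nested-loop channel math (small grids only)
# ---------------------------------------------------------------------------

def ref_norm_sens(fl_s: np.ndarray, fl_d: np.ndarray) -> np.ndarray:
    nx, ny, nz = fl_s.shape
    out = np.zeros_like(fl_s, dtype=float)
    total = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                total += fl_s[i, j, k] * fl_d[i, j, k]
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = fl_s[i, j, k] * fl_d[i, j, k] / total
    return out


def ref_brain_sens(field: np.ndarray, four: np.ndarray, brain_label: int = 4
                   ) -> float:
    total = 0.0
    nx, ny, nz = field.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if four[i, j, k] == brain_label:
                    total += field[i, j, k]
    return total


def ref_specificity(field: np.ndarray, roi: np.ndarray, four: np.ndarray,
                    roi_labels: list[int], brain_label: int = 4
                    ) -> dict[int | str, float]:
    bs = ref_brain_sens(field, four, brain_label)
    out: dict[int | str, float] = {}
    nx, ny, nz = field.shape
    for lab in roi_labels:
        s = 0.0
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if roi[i, j, k] == lab:
                        s += field[i, j, k]
        out[lab] = 100.0 * s / bs
    s = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if four[i, j, k] == brain_label and roi[i, j, k] == 0:
                    s += field[i, j, k]
    out["Brain_Outside"] = 100.0 * s / bs
    return out


def ref_compartment_sums(field: np.ndarray, labels: np.ndarray
                         ) -> dict[int, float]:
    out: dict[int, float] = {}
    nx, ny, nz = field.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lab = int(labels[i, j, k])
                out[lab] = out.get(lab, 0.0) + field[i, j, k]
    return out


def ref_coordinate(field: np.ndarray, four: np.ndarray, affine: np.ndarray,
                   brain_label: int = 4) -> np.ndarray:
    bs = ref_brain_sens(field, four, brain_label)
    acc = np.zeros(3)
    nx, ny, nz = field.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if four[i, j, k] == brain_label:
                    world = affine[:3, :3] @ np.array([i, j, k], float) \
                        + affine[:3, 3]
                    acc += world * field[i, j, k]
    return acc / bs


def ref_separation(p: np.ndarray, q: np.ndarray) -> float:
    return math.sqrt(sum((float(a) - float(b)) ** 2 for a, b in zip(p, q)))


# ---------------------------------------------------------------------------
# Exact 10-10 construction on a sphere
# ---------------------------------------------------------------------------

def _sphere_arc(R: float, a: np.ndarray, b: np.ndarray, c: np.ndarray,
                via: bool):
    """Circle cut by the plane through a, b, c on a sphere of radius R.

    Returns a function mapping arc fraction f in [0, 1] to the point on
    the arc from ``a`` to ``b`` that passes through ``c`` (``via=True``)
    or avoids it (``via=False``).  Exact circle geometry; no meshes.
    """
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    center = n * (n @ a)  # projection of the sphere center onto the plane
    r = math.sqrt(max(R * R - center @ center, 0.0))
    e1 = (a - center) / np.linalg.norm(a - center)
    e2 = np.cross(n, e1)

    def ang(p):
        v = p - center
        return math.atan2(v @ e2, v @ e1) % (2 * math.pi)

    tb, tc = ang(b), ang(c)
    fwd = tb  # angle of b going counterclockwise from a (at angle 0)
    c_on_fwd = tc <= tb
    use_fwd = c_on_fwd if via else not c_on_fwd
    span = fwd if use_fwd else fwd - 2 * math.pi

    def point(f: float) -> np.ndarray:
        t = span * f
        return center + r * (math.cos(t) * e1 + math.sin(t) * e2)

    return point


def sphere_10_10(R: float) -> dict[str, np.ndarray]:
    """All 81 10-10 positions on a sphere of radius R, analytically.

    Fiducials: Nz = (0, R, 0), Iz = (0, -R, 0), LPA = (-R, 0, 0),
    RPA = (R, 0, 0); the vertex Cz is (0, 0, R) by symmetry.
    """
    nz = np.array([0.0, R, 0.0])
    iz = np.array([0.0, -R, 0.0])
    lpa = np.array([-R, 0.0, 0.0])
    rpa = np.array([R, 0.0, 0.0])
    cz = np.array([0.0, 0.0, R])
    pos: dict[str, np.ndarray] = {}

    sag = _sphere_arc(R, nz, iz, cz, via=True)
    for i, lab in enumerate(["Nz", "Fpz", "AFz", "Fz", "FCz", "Cz", "CPz",
                             "Pz", "POz", "Oz", "Iz"]):
        pos[lab] = sag(i / 10)
    cor = _sphere_arc(R, lpa, rpa, pos["Cz"], via=True)
    for i, lab in enumerate(["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
                             "T8"], start=1):
        if lab != "Cz":
            pos[lab] = cor(i / 10)
    for via, labs in ((lpa, ["N1", "AF9", "F9", "FT9", "T9", "TP9", "P9",
                             "PO9", "I1"]),
                      (rpa, ["N2", "AF10", "F10", "FT10", "T10", "TP10",
                             "P10", "PO10", "I2"])):
        ring = _sphere_arc(R, nz, iz, via, via=True)
        for i, lab in enumerate(labs, start=1):
            pos[lab] = ring(i / 10)
    for t_lab, front, back in (
            ("T7", ["Fp1", "AF7", "F7", "FT7"], ["TP7", "P7", "PO7", "O1"]),
            ("T8", ["Fp2", "AF8", "F8", "FT8"], ["TP8", "P8", "PO8", "O2"])):
        f_arc = _sphere_arc(R, pos["Fpz"], pos[t_lab], pos["Oz"], via=False)
        for i, lab in enumerate(front, start=1):
            pos[lab] = f_arc(i / 5)
        b_arc = _sphere_arc(R, pos[t_lab], pos["Oz"], pos["Fpz"], via=False)
        for i, lab in enumerate(back, start=1):
            pos[lab] = b_arc(i / 5)
    rows = (("AF7", "AFz", "AF8", ["AF3"], ["AF4"]),
            ("F7", "Fz", "F8", ["F5", "F3", "F1"], ["F2", "F4", "F6"]),
            ("FT7", "FCz", "FT8", ["FC5", "FC3", "FC1"],
             ["FC2", "FC4", "FC6"]),
            ("TP7", "CPz", "TP8", ["CP5", "CP3", "CP1"],
             ["CP2", "CP4", "CP6"]),
            ("P7", "Pz", "P8", ["P5", "P3", "P1"], ["P2", "P4", "P6"]),
            ("PO7", "POz", "PO8", ["PO3"], ["PO4"]))
    for left_lab, mid_lab, right_lab, left_names, right_names in rows:
        l, m, r = pos[left_lab], pos[mid_lab], pos[right_lab]
        nl = len(left_names) + 1
        left_arc = _sphere_arc(R, l, m, r, via=False)
        for i, lab in enumerate(left_names, start=1):
            pos[lab] = left_arc(i / nl)
        right_arc = _sphere_arc(R, m, r, l, via=False)
        for i, lab in enumerate(right_names, start=1):
            pos[lab] = right_arc(i / nl)
    assert len(pos) == 81
    return pos
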