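"""Phantom geometry model.

The system phantom is a 200 mm inner-diameter water-filled sphere containing

* a 57-element fiducial array: 10.0 mm ID spheres on a 40 mm cubic lattice
  (27 internal spheres on a central 3x3x3 grid plus 5 spheres at each of the
  six outward faces),
* three 14-element MR parameter arrays (NiCl2-doped for T1, MnCl2-doped for
  T2, and a proton-density array): 10 spheres equally spaced on a 50 mm
  radius ring plus 4 inner spheres on a 40 mm grid,
* two resolution insets (coarse and fine) of 4x4 hole arrays in five hole
  sizes, each array duplicated at 10 degrees sharing one corner hole
  (155 holes per inset), and
* a pair of opposed 10-degree wedges for slice-profile measurement.

Coordinates follow the scanner/patient convention: +Z superior (bore axis),
+X toward the patient's left, +Y down (posterior).  The origin is the center
of the central fiducial sphere.  All lengths are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

FIDUCIAL_LATTICE_MM = 40.0
FIDUCIAL_ID_MM = 10.0
ARRAY_SPHERE_ID_MM = 15.0
ARRAY_RING_RADIUS_MM = 50.0
ARRAY_INNER_GRID_MM = 40.0
SHELL_RADIUS_MM = 100.0

#: hole diameters (mm) per inset kind
INSET_DIAMETERS = {
    "coarse": (0.6, 0.7, 0.8, 0.9, 1.0),
    "fine": (0.4, 0.5, 0.6, 0.7, 0.8),
}

ARRAY_KINDS = ("NiCl2", "MnCl2", "PD")

# Coronal plane (constant y) of each parameter array; chosen on the 40 mm
# plate grid offset so arrays never collide with fiducial planes.  Only
# relative in-plane geometry matters for the analyses.
ARRAY_PLANE_Y_MM = {"NiCl2": -60.0, "MnCl2": -20.0, "PD": 20.0}


@dataclass(frozen=True)
class SpherePose:
    """One liquid-filled sphere: id, center (mm) and inner diameter."""

    id: int
    center: tuple[float, float, float]
    inner_diameter: float
    group: str

    @property
    def radius(self) -> float:
        return 0.5 * self.inner_diameter


@dataclass(frozen=True)
class HoleSet:
    """A resolution inset: list of (center_xy mm, diameter mm, group_angle deg)."""

    kind: str
    holes: tuple[tuple[tuple[float, float], float, float], ...]

    def by_size(self, diameter: float, angle: float | None = None):
        out = []
        for c, d, a in self.holes:
            if abs(d - diameter) < 1e-9 and (angle is None or abs(a - angle) < 1e-9):
                out.append((c, d, a))
        return out


@dataclass(frozen=True)
class WedgeSpec:
    """Paired slice-profile wedges (one positive, one negative inclination)."""

    wedge_angle_deg: float = 10.0
    height_mm: float = 10.0
    roi_width_mm: float = 4.0
    roi_length_mm: float = 50.0
    orientations: tuple[int, int] = (+1, -1)


def build_fiducial_lattice() -> list[SpherePose]:
    """All 57 fiducial spheres on the 40 mm lattice.

    27 internal spheres fill the central 3x3x3 grid; each of the six outward
    faces carries a cross of 5 spheres (face center at +/-80 mm plus the four
    40 mm-adjacent lattice points).  Numbering increases from right to left
    (+x), then inferior to superior, starting at the most inferior plate.
    """
    a = FIDUCIAL_LATTICE_MM
    pts: list[tuple[tuple[float, float, float], str]] = []
    for z in (-a, 0.0, a):
        for y in (-a, 0.0, a):
            for x in (-a, 0.0, a):
                pts.append(((x, y, z), "fiducial_internal"))
    axes = {"x": 0, "y": 1, "z": 2}
    for ax_name, ax in axes.items():
        for sign, label in ((+1, "+"), (-1, "-")):
            face_group = f"fiducial_face_{label}{ax_name}"
            c = [0.0, 0.0, 0.0]
            c[ax] = sign * 2 * a
            pts.append((tuple(c), face_group))
            for off_ax in sorted(set(range(3)) - {ax}):
                for off in (-a, a):
                    p = [0.0, 0.0, 0.0]
                    p[ax] = sign * 2 * a
                    p[off_ax] = off
                    pts.append((tuple(p), face_group))
    # number by (z, y, x): plate 1 (most inferior) first, right to left within
    pts.sort(key=lambda t: (t[0][2], t[0][1], t[0][0]))
    return [
        SpherePose(i + 1, p, FIDUCIAL_ID_MM, g) for i, (p, g) in enumerate(pts)
    ]


def group_fiducials(fiducials: Iterable[SpherePose]) -> dict[str, list[int]]:
    """Map group name -> sphere ids (7 groups: internal + 6 faces)."""
    groups: dict[str, list[int]] = {}
    for s in fiducials:
        groups.setdefault(s.group, []).append(s.id)
    return groups


def build_parameter_array(kind: str) -> list[SpherePose]:
    """The 14-sphere layout of one MR parameter array.

    Spheres 1-10 sit equally spaced on a 50 mm radius ring (36 deg pitch,
    sphere 1 at the superior position, advancing toward +x); spheres 11-14
    sit on the interior 40 mm grid at (+/-20, +/-20) mm.  The array lies in
    a coronal plane (constant y).
    """
    if kind not in ARRAY_KINDS:
        raise ValueError(f"unknown array kind {kind!r}; expected one of {ARRAY_KINDS}")
    y = ARRAY_PLANE_Y_MM[kind]
    group = f"array_{kind}"
    poses = []
    for i in range(10):
        ang = np.deg2rad(90.0 - 36.0 * i)
        x = ARRAY_RING_RADIUS_MM * np.cos(ang)
        z = ARRAY_RING_RADIUS_MM * np.sin(ang)
        poses.append(SpherePose(i + 1, (float(x), y, float(z)), ARRAY_SPHERE_ID_MM, group))
    half = ARRAY_INNER_GRID_MM / 2.0
    for j, (x, z) in enumerate([(-half, half), (half, half), (-half, -half), (half, -half)]):
        poses.append(SpherePose(11 + j, (x, y, z), ARRAY_SPHERE_ID_MM, group))
    return poses


def _block_holes(diameter: float, pivot: tuple[float, float], angle_deg: float,
                 sign: int = +1):
    """One 4x4 hole block: pitch = 2 x diameter, corner hole at ``pivot``.

    ``sign`` selects the quadrant the block extends into (+1: up/right,
    -1: down/left); ``angle_deg`` rotates the block about the pivot hole
    (the hole shared between the 0 and 10 degree arrays)."""
    pitch = 2.0 * diameter * sign
    base = np.array(
        [[pivot[0] + i * pitch, pivot[1] + j * pitch] for j in range(4) for i in range(4)]
    )
    if angle_deg:
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pv = np.array(pivot)
        base = (base - pv) @ rot.T + pv
    return [((float(x), float(y)), diameter, angle_deg) for x, y in base]


def build_resolution_inset(kind: str) -> HoleSet:
    """All 155 holes of one resolution inset (5 sizes x 31 holes).

    Per size: a 4x4 block at 0 degrees extending up/right from its corner
    hole, plus a duplicate rotated 10 degrees extending down/left from the
    same (shared) corner hole -> 31 distinct holes.  Sharing a single corner
    while occupying opposite quadrants keeps the arrays from overlapping.
    Blocks of successive sizes are laid out left to right with a margin.
    """
    if kind not in INSET_DIAMETERS:
        raise ValueError(f"unknown inset kind {kind!r}")
    diams = INSET_DIAMETERS[kind]
    holes = []
    x0 = 6.0 * diams[0] + 1.0
    for n, d in enumerate(diams):
        pitch = 2.0 * d
        holes.extend(_block_holes(d, (x0, 0.0), 0.0, +1))
        rotated = _block_holes(d, (x0, 0.0), 10.0, -1)
        # drop the pivot hole of the rotated copy: shared with the 0-deg block
        holes.extend(h for h in rotated if np.hypot(h[0][0] - x0, h[0][1]) > 1e-9)
        if n + 1 < len(diams):
            # room for this block's up-right arm and the next one's down-left
            x0 += 3 * pitch + 6.0 * diams[n + 1] + 2.0
    return HoleSet(kind=kind, holes=tuple(holes))


@dataclass(frozen=True)
class PhantomLayout:
    """Queryable geometry of the whole phantom, phantom coordinates (mm)."""

    fiducials: tuple[SpherePose, ...]
    arrays: dict[str, tuple[SpherePose, ...]]
    resolution_insets: dict[str, HoleSet]
    wedges: WedgeSpec = field(default_factory=WedgeSpec)

    @classmethod
    def default(cls) -> "PhantomLayout":
        return cls(
            fiducials=tuple(build_fiducial_lattice()),
            arrays={k: tuple(build_parameter_array(k)) for k in ARRAY_KINDS},
            resolution_insets={k: build_resolution_inset(k) for k in INSET_DIAMETERS},
        )

    def fiducial_by_id(self, sid: int) -> SpherePose:
        return self.fiducials[sid - 1]

    def fiducial_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.fiducials])

    def array_centers(self, kind: str) -> np.ndarray:
        return np.array([s.center for s in self.arrays[kind]])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": "mm",
            "coordinate_convention": "+Z superior, +X left, +Y down; origin at central fiducial",
            "fiducials": [asdict(s) for s in self.fiducials],
            "arrays": {k: [asdict(s) for s in v] for k, v in self.arrays.items()},
            "resolution_insets": {
                k: {"kind": h.kind, "holes": [list(map(list_or_scalar, hh)) for hh in h.holes]}
                for k, h in self.resolution_insets.items()
            },
            "wedges": asdict(self.wedges),
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomLayout":
        def sphere(e):
            return SpherePose(e["id"], tuple(e["center"]), e["inner_diameter"], e["group"])

        insets = {}
        for k, h in d["resolution_insets"].items():
            holes = tuple(((c[0], c[1]), diam, ang) for c, diam, ang in h["holes"])
            insets[k] = HoleSet(kind=h["kind"], holes=holes)
        w = d["wedges"]
        return cls(
            fiducials=tuple(sphere(e) for e in d["fiducials"]),
            arrays={k: tuple(sphere(e) for e in v) for k, v in d["arrays"].items()},
            resolution_insets=insets,
            wedges=WedgeSpec(
                w["wedge_angle_deg"], w["height_mm"], w["roi_width_mm"],
                w["roi_length_mm"], tuple(w["orientations"]),
            ),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "PhantomLayout":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as f:
                d = json.load(f)
        return cls.from_dict(d)


def list_or_scalar(v):
    return list(v) if isinstance(v, (tuple, list)) else v
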