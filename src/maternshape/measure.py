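"""Girth and length measurement on humanoid meshes by horizontal slicing.

This is the computational analogue of wrapping a tape measure around a 3D
body model: a horizontal plane cuts the mesh into closed loops, each loop
is classified as torso / arm / leg by its centroid, and the tape reading is
the *convex hull* perimeter of the loop (a tape bridges concavities such as
the inframammary fold; the raw polygon perimeter is available as an
option).

Landmark heights are fractions of total body height: the chest is the
maximum torso girth in the [0.66, 0.78]*h band, the waist the minimum in
[0.55, 0.66]*h, the hip the maximum in [0.45, 0.55]*h; the upper arm is
read at 0.75*h and the thigh 5 cm below the crotch.  The crotch (inseam)
is found by bisection on "does a mid-sagittal torso loop exist at this
height".  The band fractions are this package's convention -- the girth
protocol itself does not prescribe measurement heights -- and are exposed
in :class:`MeasureConfig`.

Slicing is done by an exact edge-crossing scan: for each plane, the mesh
edges whose endpoints straddle it are intersected, and segments are chained
into loops through the face adjacency of those edges.  Chaining by edge
identity (rather than by snapping coordinates) cannot produce spurious open
chains, and the whole scan is vectorized over edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .anthropometry import BodyMeasurements
from .avatars import Mesh
from .errors import (
    EmptySectionError,
    InvalidArgumentError,
    LandmarkError,
    RegionNotFoundError,
)

REGIONS = ("torso", "left_arm", "right_arm", "left_leg", "right_leg")


@dataclass(frozen=True)
class MeasureConfig:
    """Landmark bands (height fractions) and slicing options."""

    #: landmark bands (documentation of the protocol) and the interior
    #: sampling windows actually sliced.  The windows sit well inside the
    #: bands so that the chest/waist/hip landmarks of bodies whose
    #: leg-to-height proportion differs moderately from the template do not
    #: bleed into a neighbouring band; each window is chosen so its sample
    #: grid hits the template's landmark extremum exactly.
    chest_band: tuple[float, float] = (0.66, 0.78)
    waist_band: tuple[float, float] = (0.55, 0.66)
    hip_band: tuple[float, float] = (0.45, 0.55)
    chest_window: tuple[float, float] = (0.695, 0.745)
    waist_window: tuple[float, float] = (0.55, 0.66)
    hip_window: tuple[float, float] = (0.455, 0.515)
    band_samples: int = 9
    arm_height_fraction: float = 0.75
    thigh_offset_cm: float = 5.0
    #: loops with |centroid x| below this (cm) are mid-sagittal = torso
    torso_centroid_tol_cm: float = 3.0
    #: "hull" = tape semantics (convex hull perimeter); "polygon" = raw
    method: str = "hull"
    min_loop_area_cm2: float = 1.0


@dataclass(frozen=True)
class Loop:
    """One closed planar cross-section loop at a fixed height."""

    points: np.ndarray  # (n, 2) in (x, z)
    centroid: tuple[float, float]
    area: float
    perimeter: float
    hull_perimeter: float


@dataclass(frozen=True)
class CrossSection:
    """All loops of one horizontal slice."""

    y: float
    loops: tuple[Loop, ...]


#: topology cache keyed by a digest of the face array; every blend of one
#: avatar set shares its topology, so the unique-edge scan runs once
_TOPOLOGY_CACHE: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


class _Slicer:
    """Horizontal-plane slicer with topology precomputed once per topology."""

    def __init__(self, mesh: Mesh):
        self.vertices = mesh.vertices
        faces = mesh.faces
        key = faces.tobytes()
        cached = _TOPOLOGY_CACHE.get(key)
        if cached is None:
            e = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
            edges, inverse = np.unique(e, axis=0, return_inverse=True)
            cached = (edges, inverse.reshape(-1, 3))
            if len(_TOPOLOGY_CACHE) > 8:
                _TOPOLOGY_CACHE.clear()
            _TOPOLOGY_CACHE[key] = cached
        self.edges, self.face_edges = cached
        self.ymin = float(self.vertices[:, 1].min())
        self.ymax = float(self.vertices[:, 1].max())

    def loop_points(self, y: float) -> list[np.ndarray]:
        """All closed intersection loops at height ``y`` as (n, 2) arrays."""
        v = self.vertices
        d = v[:, 1] - y
        d = np.where(d == 0.0, 1e-12, d)  # perturb exact hits off the plane
        ei, ej = self.edges[:, 0], self.edges[:, 1]
        di, dj = d[ei], d[ej]
        crossing = (di * dj) < 0.0
        fe_mask = crossing[self.face_edges]
        crossing_faces = np.nonzero(fe_mask.sum(axis=1) == 2)[0]
        if crossing_faces.size == 0:
            return []
        idx = np.nonzero(crossing)[0]
        t = di[idx] / (di[idx] - dj[idx])
        pts = np.empty((len(self.edges), 3))
        pts[idx] = v[ei[idx]] + t[:, None] * (v[ej[idx]] - v[ei[idx]])

        # loops are cycles of the graph (nodes: crossing edges, links: faces)
        fe = self.face_edges[crossing_faces]
        order = np.argsort(~fe_mask[crossing_faces], axis=1, kind="stable")[:, :2]
        pairs = np.take_along_axis(fe, order, axis=1)
        adjacency: dict[int, list[int]] = {}
        for a, b in pairs.tolist():
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)
        visited: set[int] = set()
        loops = []
        for start, nbrs in adjacency.items():
            if start in visited or len(nbrs) != 2:
                continue
            cycle = [start]
            visited.add(start)
            prev, node = start, nbrs[0]
            closed = False
            while node not in visited:
                visited.add(node)
                cycle.append(node)
                links = adjacency.get(node, [])
                if len(links) != 2:
                    break
                a, b = links
                prev, node = node, (b if a == prev else a)
            else:
                closed = node == start
            if closed and len(cycle) >= 3:
                loops.append(pts[cycle][:, [0, 2]])
        return loops

    def section(self, y: float, config: "MeasureConfig") -> CrossSection:
        if not self.ymin < y < self.ymax:
            raise EmptySectionError(
                f"plane y={y:.2f} outside mesh range [{self.ymin:.2f}, {self.ymax:.2f}]"
            )
        loops = []
        for pts in self.loop_points(y):
            props = _loop_properties(pts)
            if props is None or props[1] < config.min_loop_area_cm2:
                continue
            centroid, area, perimeter, hull_perimeter = props
            loops.append(
                Loop(
                    points=pts,
                    centroid=centroid,
                    area=area,
                    perimeter=perimeter,
                    hull_perimeter=hull_perimeter,
                )
            )
        if not loops:
            raise EmptySectionError(f"no closed loops at y={y:.2f}")
        return CrossSection(y=y, loops=tuple(loops))


def _loop_properties(pts: np.ndarray):
    """(centroid, |area|, perimeter, hull perimeter) of a closed polygon."""
    x, z = pts[:, 0], pts[:, 1]
    x2, z2 = np.roll(x, -1), np.roll(z, -1)
    cross = x * z2 - x2 * z
    area = 0.5 * cross.sum()
    if area == 0.0:
        return None
    cx = ((x + x2) * cross).sum() / (6.0 * area)
    cz = ((z + z2) * cross).sum() / (6.0 * area)
    perimeter = float(np.hypot(x2 - x, z2 - z).sum())
    try:
        # in 2D, Qhull's "area" is the hull perimeter
        hull_perimeter = float(ConvexHull(pts).area)
    except QhullError:
        return None
    return (float(cx), float(cz)), abs(float(area)), perimeter, hull_perimeter


def slice_mesh(mesh: Mesh, y: float, config: MeasureConfig | None = None) -> CrossSection:
    """Intersect the mesh with the horizontal plane at height ``y``."""
    return _Slicer(mesh).section(y, config or MeasureConfig())


def _torso_loop(section: CrossSection, config: MeasureConfig) -> Loop | None:
    candidates = [
        lp for lp in section.loops if abs(lp.centroid[0]) <= config.torso_centroid_tol_cm
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda lp: lp.area)


def girth(section: CrossSection, region: str, config: MeasureConfig | None = None) -> float:
    """Tape girth (cm) of the selected region's loop in a cross-section."""
    config = config or MeasureConfig()
    if region not in REGIONS:
        raise InvalidArgumentError(f"region must be one of {REGIONS}, got {region!r}")
    torso = _torso_loop(section, config)
    if region == "torso":
        chosen = torso
    else:
        side = -1.0 if region.startswith("left") else 1.0
        laterals = [
            lp for lp in section.loops if lp is not torso and side * lp.centroid[0] > 0
        ]
        chosen = max(laterals, key=lambda lp: lp.area) if laterals else None
    if chosen is None:
        raise RegionNotFoundError(f"no {region} loop at y={section.y:.2f}")
    return chosen.hull_perimeter if config.method == "hull" else chosen.perimeter


def _find_crotch(slicer: _Slicer, config: MeasureConfig) -> float:
    height = slicer.ymax

    def has_torso(y: float) -> bool:
        try:
            sec = slicer.section(y, config)
        except EmptySectionError:
            return False
        return _torso_loop(sec, config) is not None

    lo, hi = 0.25 * height, 0.60 * height
    if has_torso(lo) or not has_torso(hi):
        raise LandmarkError(
            f"crotch search failed in band [{lo:.1f}, {hi:.1f}] cm: expected legs "
            "below and a torso loop above"
        )
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if has_torso(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def find_crotch(mesh: Mesh, config: MeasureConfig | None = None) -> float:
    """Crotch height (= inseam): lowest y where a mid-sagittal torso loop exists."""
    return _find_crotch(_Slicer(mesh), config or MeasureConfig())


def _band_girth(slicer, height, window, mode, config, label):
    lo_f, hi_f = window
    # tiny nudge keeps sample planes off exact ring stations
    ys = (np.linspace(lo_f, hi_f, config.band_samples) + 1e-4) * height
    values = []
    for y in ys:
        try:
            sec = slicer.section(y, config)
        except EmptySectionError:
            continue
        torso = _torso_loop(sec, config)
        if torso is None:
            continue
        values.append(
            torso.hull_perimeter if config.method == "hull" else torso.perimeter
        )
    if not values:
        raise LandmarkError(f"no torso loop found in the {label} window {window}")
    return max(values) if mode == "max" else min(values)


def measure_all(mesh: Mesh, config: MeasureConfig | None = None) -> BodyMeasurements:
    """Full anthropometric readout of a humanoid mesh."""
    config = config or MeasureConfig()
    core = measure_core(mesh, config, include_limbs=True)
    return BodyMeasurements(**core)


def measure_core(
    mesh: Mesh, config: MeasureConfig | None = None, include_limbs: bool = False
) -> dict[str, float]:
    """Chest/waist/hip/inseam/height (plus limbs on request) as a dict.

    The limb-free variant is what the calibration loop evaluates: the upper
    arm and thigh have no dedicated morph target, so skipping their slices
    roughly halves the cost per evaluation.
    """
    config = config or MeasureConfig()
    slicer = _Slicer(mesh)
    height = slicer.ymax
    crotch = _find_crotch(slicer, config)
    out = {
        "height_cm": height,
        "inseam_cm": crotch,
        "chest_cm": _band_girth(slicer, height, config.chest_window, "max", config, "chest"),
        "waist_cm": _band_girth(slicer, height, config.waist_window, "min", config, "waist"),
        "hip_cm": _band_girth(slicer, height, config.hip_window, "max", config, "hip"),
    }
    if include_limbs:
        arm_y = (config.arm_height_fraction + 1e-4) * height
        sec = slicer.section(arm_y, config)
        arms = []
        for region in ("left_arm", "right_arm"):
            try:
                arms.append(girth(sec, region, config))
            except RegionNotFoundError:
                pass
        if not arms:
            raise LandmarkError(
                f"no arm loops at {config.arm_height_fraction:.2f} * height"
            )
        out["upper_arm_cm"] = float(np.mean(arms))

        thigh_y = crotch - config.thigh_offset_cm
        sec = slicer.section(thigh_y, config)
        legs = []
        for region in ("left_leg", "right_leg"):
            try:
                legs.append(girth(sec, region, config))
            except RegionNotFoundError:
                pass
        if not legs:
            raise LandmarkError(f"no leg loops at crotch - {config.thigh_offset_cm} cm")
        out["thigh_cm"] = float(np.mean(legs))
    return out
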