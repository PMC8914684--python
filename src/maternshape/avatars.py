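"""Procedural synthetic avatar set and Wavefront OBJ mesh I/O.

The morphing pipeline needs seven topology-identical humanoid meshes: a
thin base and six extreme targets (big breast, big waist, big hip, tall,
long legs, pregnant belly).  The originals were commercial assets; this
module generates a redistributable stand-in family procedurally, as lofted
elliptical cross-sections (torso + head as one loft, two legs, two arms,
each closed with flat fan caps).  Every avatar is built from the same
station/ring template, so vertex counts, face lists and anatomical
correspondence are identical across the set -- the precondition for
per-vertex blending.

Coordinate convention: centimetres, Y-up, feet plane at y = 0, bilateral
symmetry about x = 0.  Height is max(y) and girths are horizontal slices.

Anchor dimensions (verified by :mod:`maternshape.measure` at generation
time, 2% tolerance): thin chest/waist/hip/inseam/height of
57/40/68/73/165 cm, big-breast chest 200, big-waist waist 160, big-hip hip
180, tall height 200, long-legs inseam 120.  Each ring polygon is scaled so
its perimeter equals the target girth exactly, which keeps the anchors
resolution-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import GenerationError, InvalidArgumentError, ObjParseError

# ---------------------------------------------------------------------------
# Mesh container and OBJ I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mesh:
    """Triangular mesh: vertices (N, 3) in cm, faces (M, 3) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidArgumentError(f"vertices must be (N, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidArgumentError(f"faces must be (M, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise InvalidArgumentError("face indices out of range")
        if f.size and (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise InvalidArgumentError("degenerate faces (repeated vertex index)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def height(self) -> float:
        return float(self.vertices[:, 1].max())

    def scaled(self, factor: float) -> "Mesh":
        return Mesh(self.vertices * factor, self.faces.copy())


def write_obj(mesh: Mesh, path: str | Path) -> None:
    """Write vertices/faces as a minimal OBJ (6-decimal vertices, 1-based faces)."""
    with open(path, "w") as fh:
        fh.write("# maternshape avatar mesh\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def read_obj(path: str | Path) -> Mesh:
    """Read a Wavefront OBJ with triangular or quad faces.

    Quads are fan-triangulated on read; face order is preserved.  Indices
    must be positive 1-based (0 or negative indices raise
    :class:`ObjParseError` with the offending line number).  Records other
    than ``v``/``f`` are ignored.
    """
    vertices: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ObjParseError("vertex record needs 3 coordinates", lineno)
                try:
                    vertices.append((float(parts[1]), float(parts[2]), float(parts[3])))
                except ValueError as exc:
                    raise ObjParseError(f"bad vertex coordinate: {exc}", lineno) from None
            elif tag == "f":
                idx = []
                for tok in parts[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise ObjParseError(f"bad face index {tok!r}", lineno) from None
                    if i <= 0:
                        raise ObjParseError(
                            f"face index {i} invalid: OBJ indices are 1-based "
                            "and relative (negative) indices are unsupported",
                            lineno,
                        )
                    idx.append(i - 1)
                if len(idx) == 3:
                    faces.append(tuple(idx))
                elif len(idx) == 4:
                    faces.append((idx[0], idx[1], idx[2]))
                    faces.append((idx[0], idx[2], idx[3]))
                else:
                    raise ObjParseError(
                        f"only triangles/quads supported, got {len(idx)} indices", lineno
                    )
    if not vertices:
        raise ObjParseError("no vertex records found")
    arr_f = np.array(faces, dtype=np.int64).reshape(-1, 3)
    if arr_f.size and arr_f.max() >= len(vertices):
        raise ObjParseError(f"face references vertex {arr_f.max() + 1} of {len(vertices)}")
    return Mesh(np.array(vertices, dtype=float), arr_f)


# ---------------------------------------------------------------------------
# Template geometry
# ---------------------------------------------------------------------------

# Thin reference dimensions: height, crotch (inseam) and torso span.
_H0 = 165.0
_L0 = 73.0
_S0 = _H0 - _L0  # 92.0


def _t(height_fraction: float) -> float:
    """Torso-local station (0 at crotch, 1 at head top) of a thin-body height fraction."""
    return (height_fraction * _H0 - _L0) / _S0


# Landmark stations (as thin-body height fractions); the girth bands of the
# measurement protocol have their extremum exactly mid-band.
_HIP_F, _WAIST_F, _CHEST_F = 0.50, 0.605, 0.72

# Thin torso girth profile: (station t, girth cm).  Monotone-preserving
# interpolation keeps band extrema at the control points.
_TORSO_PROFILE = [
    (0.0, 66.0),          # crotch
    (_t(_HIP_F), 68.0),   # hip
    (_t(_WAIST_F), 40.0),  # waist
    (_t(_CHEST_F), 57.0),  # chest
    (_t(0.82), 50.0),     # shoulders
    (_t(0.85), 31.0),     # neck
    (_t(0.88), 33.0),     # chin
    (_t(0.93), 55.0),     # head
    (_t(0.97), 30.0),
    (1.0, 6.0),           # just under the apex
]

# Depth/width aspect ratio of the torso ellipse along the loft.
_TORSO_ASPECT = [
    (0.0, 0.72),
    (_t(_WAIST_F), 0.68),
    (_t(_CHEST_F), 0.65),
    (_t(0.82), 0.55),
    (_t(0.85), 0.90),
    (_t(0.93), 1.00),
    (1.0, 1.00),
]

# Morph-bump windows (thin-body height fractions).  They bracket the
# measurement protocol's sampling windows with enough slack that blends
# whose crotch/height proportion differs from the thin template (realistic
# bodies span roughly 0.427-0.450 versus the template's 0.442) still read
# each landmark inside the intended zone.
_CHEST_WIN = (0.665, 0.775)
_WAIST_HOLD = (0.540, 0.675)    # flat-160 region of the big-waist target
_WAIST_OUTER = (0.532, 0.683)   # cosine ramps outside the hold
_HIP_WIN = (0.455, 0.545)

# Anterior belly bulge of the pregnant-thin avatar (cm peak protrusion and
# vertical support in height fractions, pubis to just below the chest band).
_BELLY_DEPTH = 18.0
_BELLY_SUPPORT = (_L0 / _H0, 0.66)

# Leg template: stations as fractions of inseam, girths and z/x aspect.
_LEG_PROFILE = [
    (0.00, 23.0),
    (0.02, 23.5),
    (0.30, 34.0),
    (0.60, 36.0),
    (0.85, 40.0),
    (1.0 - 5.0 / _L0, 42.0),  # thigh landmark: 5 cm below the crotch
    (1.00, 41.5),
]
_LEG_ASPECT = 1.2      # deeper than wide, keeps the inner edge off x = 0
_LEG_OFFSET_X = 7.5

# Arm template: stations span thin-body height fractions 0.58 (wrist) to
# 0.84 (shoulder); the 0.654 station sits at the 0.75-height landmark.
_ARM_SPAN_F = (0.58, 0.84)
_ARM_PROFILE = [
    (0.000, 16.0),
    (0.200, 18.0),
    (0.450, 24.0),
    (0.654, 26.5),
    (0.850, 27.0),
    (1.000, 26.0),
]
_ARM_OFFSET_X = (19.0, 16.5)  # wrist, shoulder (slightly abducted)


def _interpolator(controls):
    xs, ys = zip(*controls)
    return PchipInterpolator(np.array(xs), np.array(ys))


def _ring_stations(extra=()):
    """Torso loft stations: all control/transition points plus filler."""
    pts = {t for t, _ in _TORSO_PROFILE}
    pts |= {_t(f) for f in (
        _CHEST_WIN[0], _CHEST_WIN[1],
        _WAIST_HOLD[0], _WAIST_HOLD[1],
        _WAIST_OUTER[0], _WAIST_OUTER[1],
        _HIP_WIN[0], _HIP_WIN[1],
    )}
    pts |= {0.05, 0.24, 0.34, 0.44, 0.62, 0.72, 0.96}
    pts |= set(extra)
    return np.array(sorted(p for p in pts if 0.0 <= p <= 1.0))


def _cos_bump(t, lo, hi):
    """Smooth bump on (lo, hi): 0 at the edges, 1 at the centre."""
    t = np.asarray(t, dtype=float)
    u = (t - lo) / (hi - lo)
    out = np.zeros_like(u)
    inside = (u > 0) & (u < 1)
    out[inside] = np.sin(np.pi * u[inside]) ** 2
    return out


def _plateau(t, outer_lo, lo, hi, outer_hi):
    """1 on [lo, hi], cosine ramps down to 0 at outer_lo / outer_hi."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    out[(t >= lo) & (t <= hi)] = 1.0
    rise = (t > outer_lo) & (t < lo)
    out[rise] = 0.5 - 0.5 * np.cos(np.pi * (t[rise] - outer_lo) / (lo - outer_lo))
    fall = (t > hi) & (t < outer_hi)
    out[fall] = 0.5 + 0.5 * np.cos(np.pi * (t[fall] - hi) / (outer_hi - hi))
    return out


def _ring(n: int, girth: float, aspect: float, cx: float, y: float) -> np.ndarray:
    """Elliptical ring polygon whose perimeter equals ``girth`` exactly."""
    k = np.arange(n)
    theta = 2.0 * np.pi * (k + 0.5) / n
    unit = np.stack([np.cos(theta), aspect * np.sin(theta)], axis=1)
    per = np.linalg.norm(np.diff(np.vstack([unit, unit[:1]]), axis=0), axis=1).sum()
    a = girth / per
    ring = np.empty((n, 3))
    ring[:, 0] = cx + a * unit[:, 0]
    ring[:, 1] = y
    ring[:, 2] = a * unit[:, 1]
    return ring


def _tube(rings: list[np.ndarray], bottom_apex, top_apex):
    """Closed loft: stacked rings, quad side faces, flat fan caps."""
    n = rings[0].shape[0]
    verts = np.vstack(rings + [np.asarray(bottom_apex)[None, :], np.asarray(top_apex)[None, :]])
    nr = len(rings)
    i_bot, i_top = nr * n, nr * n + 1
    faces = []
    for r in range(nr - 1):
        base = r * n
        for k in range(n):
            k2 = (k + 1) % n
            faces.append((base + k, base + k2, base + n + k2))
            faces.append((base + k, base + n + k2, base + n + k))
    for k in range(n):
        k2 = (k + 1) % n
        faces.append((i_bot, k2, k))  # bottom fan
        faces.append((i_top, (nr - 1) * n + k, (nr - 1) * n + k2))
    return verts, np.array(faces, dtype=np.int64)


def _build_avatar(
    n_ring: int,
    crotch: float,
    span: float,
    torso_extra_girth,
    belly_depth: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble one avatar; all callers share station lists => shared topology."""
    girth_f = _interpolator(_TORSO_PROFILE)
    aspect_f = _interpolator(_TORSO_ASPECT)
    stations = _ring_stations()

    parts = []
    # torso + head
    rings = []
    for t in stations:
        g = float(girth_f(t)) + float(torso_extra_girth(t))
        y = crotch + t * span
        ring = _ring(n_ring, g, float(aspect_f(t)), 0.0, y)
        if belly_depth:
            hf = (crotch + t * span) / (crotch + span)  # height fraction
            lo, hi = _BELLY_SUPPORT
            if lo < hf < hi:
                f = math.sin(math.pi * (hf - lo) / (hi - lo))
                theta = 2.0 * np.pi * (np.arange(n_ring) + 0.5) / n_ring
                front = np.clip(np.sin(theta), 0.0, None) ** 1.5
                ring[:, 2] += belly_depth * f * front
        rings.append(ring)
    parts.append(_tube(rings, (0.0, crotch, 0.0), (0.0, crotch + span, 0.0)))

    # legs
    leg_girth = _interpolator(_LEG_PROFILE)
    leg_stations = np.array([p for p, _ in _LEG_PROFILE])
    for side in (-1.0, 1.0):
        cx = side * _LEG_OFFSET_X
        rings = [
            _ring(n_ring, float(leg_girth(s)), _LEG_ASPECT, cx, s * crotch)
            for s in leg_stations
        ]
        parts.append(_tube(rings, (cx, 0.0, 0.0), (cx, crotch, 0.0)))

    # arms (positions follow the torso: fractions of the thin torso span)
    arm_girth = _interpolator(_ARM_PROFILE)
    arm_stations = np.array([p for p, _ in _ARM_PROFILE])
    t_lo, t_hi = _t(_ARM_SPAN_F[0]), _t(_ARM_SPAN_F[1])
    for side in (-1.0, 1.0):
        rings = []
        for s in arm_stations:
            t = t_lo + s * (t_hi - t_lo)
            y = crotch + t * span
            cx = side * (_ARM_OFFSET_X[0] + s * (_ARM_OFFSET_X[1] - _ARM_OFFSET_X[0]))
            rings.append(_ring(n_ring, float(arm_girth(s)), 1.0, cx, y))
        bot = rings[0].mean(axis=0)
        top = rings[-1].mean(axis=0)
        parts.append(_tube(rings, bot, top))

    # concatenate parts with index offsets
    verts, faces, offset = [], [], 0
    for v, f in parts:
        verts.append(v)
        faces.append(f + offset)
        offset += len(v)
    return np.vstack(verts), np.vstack(faces)


@dataclass(frozen=True)
class AvatarSet:
    """The seven avatars, in blend order (A, B, C, D, E, F, X)."""

    thin: Mesh
    big_breast: Mesh
    big_waist: Mesh
    big_hip: Mesh
    tall: Mesh
    long_legs: Mesh
    pregnant_thin: Mesh

    def ordered(self) -> tuple[Mesh, ...]:
        return (
            self.thin,
            self.big_breast,
            self.big_waist,
            self.big_hip,
            self.tall,
            self.long_legs,
            self.pregnant_thin,
        )

    names = ("thin", "big_breast", "big_waist", "big_hip", "tall", "long_legs", "pregnant_thin")

    def write_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, mesh in zip(self.names, self.ordered()):
            write_obj(mesh, outdir / f"{name}.obj")

    @classmethod
    def read_dir(cls, indir: str | Path) -> "AvatarSet":
        indir = Path(indir)
        return cls(**{name: read_obj(indir / f"{name}.obj") for name in cls.names})


def _zero(t):
    return np.zeros_like(np.asarray(t, dtype=float))


def generate_synthetic_avatars(
    resolution: int = 40, seed: int = 0, verify: bool = True
) -> AvatarSet:
    """Generate the seven-avatar family at the stated anchor dimensions.

    ``resolution`` is the vertex count per cross-section ring (minimum 16).
    ``seed`` drives a small (0.02 cm SD) surface jitter applied identically
    to all seven avatars, so morph deltas and blend identities are
    unaffected.  With ``verify`` the anchor dimensions are re-measured and a
    :class:`GenerationError` is raised if any misses its target by >2%.
    """
    if resolution < 16 or resolution % 2:
        raise InvalidArgumentError("resolution must be an even integer >= 16")

    girth_f = _interpolator(_TORSO_PROFILE)
    chest_amp = 200.0 - 57.0
    hip_amp = 180.0 - 68.0
    c_lo, c_hi = _t(_CHEST_WIN[0]), _t(_CHEST_WIN[1])
    h_lo, h_hi = _t(_HIP_WIN[0]), _t(_HIP_WIN[1])
    w_olo, w_lo = _t(_WAIST_OUTER[0]), _t(_WAIST_HOLD[0])
    w_hi, w_ohi = _t(_WAIST_HOLD[1]), _t(_WAIST_OUTER[1])

    def chest_bump(t):
        return chest_amp * _cos_bump(t, c_lo, c_hi)

    def hip_bump(t):
        return hip_amp * _cos_bump(t, h_lo, h_hi)

    def waist_plateau(t):
        # lift the whole waist band to exactly 160 (the band minimum rules)
        return (160.0 - girth_f(t)) * _plateau(t, w_olo, w_lo, w_hi, w_ohi)

    recipes = {
        "thin": dict(crotch=_L0, span=_S0, extra=_zero, belly=0.0),
        "big_breast": dict(crotch=_L0, span=_S0, extra=chest_bump, belly=0.0),
        "big_waist": dict(crotch=_L0, span=_S0, extra=waist_plateau, belly=0.0),
        "big_hip": dict(crotch=_L0, span=_S0, extra=hip_bump, belly=0.0),
        "tall": dict(crotch=_L0 * 200.0 / 165.0, span=_S0 * 200.0 / 165.0, extra=_zero, belly=0.0),
        "long_legs": dict(crotch=120.0, span=_S0, extra=_zero, belly=0.0),
        "pregnant_thin": dict(crotch=_L0, span=_S0, extra=_zero, belly=_BELLY_DEPTH),
    }

    meshes: dict[str, Mesh] = {}
    jitter = None
    rng = np.random.default_rng(seed)
    for name, rc in recipes.items():
        v, f = _build_avatar(resolution, rc["crotch"], rc["span"], rc["extra"], rc["belly"])
        if jitter is None:
            jitter = rng.normal(0.0, 0.02, size=v.shape)
        v = v + jitter
        v[:, 1] = np.maximum(v[:, 1], 0.0)  # keep the feet plane at y = 0
        meshes[name] = Mesh(v, f)
    out = AvatarSet(**meshes)

    if verify:
        _verify_anchors(out)
    return out


def _verify_anchors(avatars: AvatarSet, tolerance: float = 0.02) -> None:
    from .measure import measure_all

    thin = measure_all(avatars.thin)
    checks = [
        ("thin chest", thin.chest_cm, 57.0),
        ("thin waist", thin.waist_cm, 40.0),
        ("thin hip", thin.hip_cm, 68.0),
        ("thin inseam", thin.inseam_cm, 73.0),
        ("thin height", thin.height_cm, 165.0),
        ("big_breast chest", measure_all(avatars.big_breast).chest_cm, 200.0),
        ("big_waist waist", measure_all(avatars.big_waist).waist_cm, 160.0),
        ("big_hip hip", measure_all(avatars.big_hip).hip_cm, 180.0),
        ("tall height", avatars.tall.height, 200.0),
        ("long_legs inseam", _crotch_only(avatars.long_legs), 120.0),
    ]
    bad = [
        f"{name}: {value:.2f} vs target {target} "
        f"({100 * abs(value - target) / target:.2f}%)"
        for name, value, target in checks
        if abs(value - target) / target > tolerance
    ]
    if bad:
        raise GenerationError(
            "avatar anchors out of tolerance; increase resolution. " + "; ".join(bad)
        )


def _crotch_only(mesh: Mesh) -> float:
    from .measure import find_crotch

    return find_crotch(mesh)
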