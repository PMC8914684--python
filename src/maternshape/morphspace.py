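"""Morph-target weights and avatar blending.

A body shape is synthesized as a per-vertex affine combination of seven
topology-identical avatars: a thin base (A) plus big-breast (B), big-waist
(C), big-hip (D), tall (E), long-legs (F) morph targets, and a pregnant
belly target (X) used in pregnant mode only:

    P_i = (1 - sum K) * A_i + K0*X_i + K1*B_i + K2*C_i + K3*D_i + K4*E_i + K5*F_i

The base weights K00..K05 are affine rescalings of the *non-pregnant
baseline* girths (evaluated at pre-pregnancy weight) between the thin
avatar's dimensions and each target's maximum.  All pregnancy/postpartum
shape change on top of the baseline is carried by additive corrections
Alp0..Alp5, each a quadratic in BMI whose coefficients are themselves
quadratics in week -- a small calibration tensor (18 rows pregnant, 15
postpartum).  The shipped tensors were calibrated against the original
commercial avatar set and are kept as formula-fidelity constants; a tensor
recalibrated against the bundled synthetic avatars is produced by
:mod:`maternshape.calibration`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .anthropometry import BodyMeasurements, Mode
from .errors import InvalidArgumentError, TopologyError

#: Anchor dimensions (cm) of the avatar family: (thin value, extreme value)
#: per morph axis.  K01 = (chest-57)/(200-57) etc.
ANCHORS = {
    "chest": (57.0, 200.0),
    "waist": (40.0, 160.0),
    "hip": (68.0, 180.0),
    "height": (165.0, 199.0),   # with an extra 1.36 gain factor, see K04
    "inseam": (78.0, (48.0, 120.0)),  # (inseam-78)/(120-48)
}

#: Gain factor applied to the height weight K04 as published.
HEIGHT_GAIN = 1.36

#: Thin-avatar inseam implied by the baseline equations (~73 cm); the K05
#: anchor 78 is inconsistent with it as published and is shipped verbatim --
#: calibration absorbs the offset.

WEIGHT_NAMES = ("k0", "k1", "k2", "k3", "k4", "k5")

# Calibration tensor rows AlpXY -> (A, B, C) with
# AlpXY(week) = C*week^2 + B*week + A, then
# AlpX(bmi)  = AlpX1*bmi^2 + AlpX2*bmi + AlpX3.
_PREGNANT_ALP = {
    "Alp01": (-6.956e-3, 4.582e-4, -8.577e-6),
    "Alp02": (4.671e-1, -2.857e-2, 5.314e-4),
    "Alp03": (-6.945, 3.811e-1, -6.870e-3),
    "Alp11": (-1.033e-4, -2.141e-5, 6.106e-7),
    "Alp12": (5.440e-3, 9.985e-4, -2.975e-5),
    "Alp13": (-1.019e-1, -9.765e-3, 3.342e-4),
    "Alp21": (-3.492e-4, 9.483e-5, -2.375e-6),
    "Alp22": (1.685e-2, -7.334e-3, 1.539e-4),
    "Alp23": (-1.692e-1, 1.215e-1, -2.524e-3),
    "Alp31": (-1.053e-5, 2.944e-5, -3.744e-7),
    "Alp32": (-2.220e-3, -2.386e-3, 4.237e-5),
    "Alp33": (1.524e-2, 4.118e-2, -9.049e-4),
    "Alp41": (1.083e-4, -2.414e-5, 6.383e-7),
    "Alp42": (-4.416e-3, 1.477e-3, -3.730e-5),
    "Alp43": (8.753e-2, -2.232e-2, 5.554e-4),
    "Alp51": (-1.808e-4, 9.690e-6, 6.453e-7),
    "Alp52": (1.370e-2, -1.370e-3, -1.147e-5),
    "Alp53": (-1.656e-1, 2.241e-2, -1.634e-5),
}

_POSTPARTUM_ALP = {
    "Alp11": (3.942e-4, -6.943e-6, 1.720e-7),
    "Alp12": (-2.351e-2, 5.974e-4, -1.915e-5),
    "Alp13": (2.716e-1, -8.912e-3, 3.394e-4),
    "Alp21": (-1.201e-3, 6.315e-5, -1.935e-6),
    "Alp22": (6.153e-2, -2.718e-3, 8.334e-5),
    "Alp23": (-5.699e-1, 1.173e-2, -5.636e-4),
    "Alp31": (1.668e-5, -1.037e-5, 3.959e-7),
    "Alp32": (-4.785e-3, 6.078e-4, -1.986e-5),
    "Alp33": (7.614e-2, -7.619e-3, 1.400e-4),
    "Alp41": (-6.535e-5, 2.052e-5, -9.603e-7),
    "Alp42": (3.961e-3, -5.569e-4, 3.121e-5),
    "Alp43": (-2.846e-2, 1.740e-3, -1.908e-4),
    "Alp51": (-3.400e-4, -1.750e-5, 7.106e-7),
    "Alp52": (1.718e-2, 2.525e-4, -1.226e-5),
    "Alp53": (-1.914e-1, 1.244e-2, -4.478e-4),
}

#: Week domain over which the tensors were fitted; polynomial evaluation is
#: clamped to these before the early-pregnancy belly ramp is applied.
WEEK_DOMAIN = {"pregnant": (12.0, 40.0), "postpartum": (0.0, 24.0)}


@dataclass(frozen=True)
class AlpCalibration:
    """The (weight x BMI-power x week-coefficient) correction tensor.

    ``tensor`` has shape (6, 3, 3): first axis the weight index X (row 0
    unused/zero in postpartum mode), second the BMI-power slot Y (1: BMI^2,
    2: BMI, 3: constant), third the week-polynomial coefficient (A, B, C).
    """

    mode: Mode
    tensor: np.ndarray = field(repr=False)

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (6, 3, 3):
            raise InvalidArgumentError(f"tensor must be (6, 3, 3), got {t.shape}")
        if self.mode == "postpartum" and np.any(t[0] != 0.0):
            raise InvalidArgumentError("postpartum tensor must have zero Alp0 rows")
        object.__setattr__(self, "tensor", t)

    @classmethod
    def pregnant_default(cls) -> "AlpCalibration":
        return cls._from_rows("pregnant", _PREGNANT_ALP)

    @classmethod
    def postpartum_default(cls) -> "AlpCalibration":
        return cls._from_rows("postpartum", _POSTPARTUM_ALP)

    @classmethod
    def _from_rows(cls, mode: Mode, rows: dict[str, tuple]) -> "AlpCalibration":
        t = np.zeros((6, 3, 3))
        for name, abc in rows.items():
            x, y = int(name[3]), int(name[4])
            t[x, y - 1, :] = abc
        return cls(mode=mode, tensor=t)

    @classmethod
    def zeros(cls, mode: Mode) -> "AlpCalibration":
        return cls(mode=mode, tensor=np.zeros((6, 3, 3)))

    def rows(self) -> dict[str, tuple[float, float, float]]:
        """Named rows AlpXY -> (A, B, C), skipping Alp0 in postpartum mode."""
        out = {}
        first = 0 if self.mode == "pregnant" else 1
        for x in range(first, 6):
            for y in (1, 2, 3):
                out[f"Alp{x}{y}"] = tuple(self.tensor[x, y - 1])
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "rows": {k: list(v) for k, v in self.rows().items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AlpCalibration":
        payload = json.loads(Path(path).read_text())
        return cls._from_rows(payload["mode"], {k: tuple(v) for k, v in payload["rows"].items()})


@dataclass(frozen=True)
class BaseWeights:
    """K00..K05 computed from baseline measurements (K00 fixed at 0)."""

    k00: float
    k01: float
    k02: float
    k03: float
    k04: float
    k05: float

    def as_array(self) -> np.ndarray:
        return np.array([self.k00, self.k01, self.k02, self.k03, self.k04, self.k05])


#: Default sanity band for blend weights; violations warn, never clamp.
WEIGHT_BAND = (-0.5, 1.5)
BASE_COEFF_MIN = -0.5


@dataclass(frozen=True)
class MorphWeights:
    """Blend coefficients K0..K5; the thin base avatar gets 1 - sum(K)."""

    mode: Mode
    k0: float
    k1: float
    k2: float
    k3: float
    k4: float
    k5: float

    def __post_init__(self):
        if self.mode == "postpartum" and self.k0 != 0.0:
            raise InvalidArgumentError("postpartum weights must have k0 = 0")
        lo, hi = WEIGHT_BAND
        for name in WEIGHT_NAMES:
            v = getattr(self, name)
            if not lo <= v <= hi:
                warnings.warn(
                    f"morph weight {name}={v:.3f} outside sanity band [{lo}, {hi}]",
                    stacklevel=3,
                )
        if self.base_coefficient < BASE_COEFF_MIN:
            warnings.warn(
                f"base-avatar coefficient {self.base_coefficient:.3f} < {BASE_COEFF_MIN}",
                stacklevel=3,
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in WEIGHT_NAMES])

    @property
    def base_coefficient(self) -> float:
        return 1.0 - float(self.as_array().sum())


def base_weights(measurements: BodyMeasurements, mode: Mode = "pregnant") -> BaseWeights:
    """Affine rescaling of baseline girths onto the avatar morph axes."""
    c_lo, c_hi = ANCHORS["chest"]
    w_lo, w_hi = ANCHORS["waist"]
    h_lo, h_hi = ANCHORS["hip"]
    t_lo, t_hi = ANCHORS["height"]
    i_ref, (i_lo, i_hi) = ANCHORS["inseam"]
    return BaseWeights(
        k00=0.0,
        k01=(measurements.chest_cm - c_lo) / (c_hi - c_lo),
        k02=(measurements.waist_cm - w_lo) / (w_hi - w_lo),
        k03=(measurements.hip_cm - h_lo) / (h_hi - h_lo),
        k04=HEIGHT_GAIN * (measurements.height_cm - t_lo) / (t_hi - t_lo),
        k05=(measurements.inseam_cm - i_ref) / (i_hi - i_lo),
    )


def alp_corrections(
    cal: AlpCalibration, bmi: float, week: float
) -> np.ndarray:
    """Evaluate the correction polynomials -> (alp0..alp5).

    Week enters the AlpXY quadratics clamped to the tensor's fit domain;
    in pregnant mode the belly correction alp0 is then ramped by
    ``week/12`` for weeks below 12 (so it vanishes smoothly at week 0).
    Postpartum alp0 is identically zero.
    """
    if bmi <= 0:
        raise InvalidArgumentError(f"BMI must be positive, got {bmi}")
    if week < 0:
        raise InvalidArgumentError(f"week must be >= 0, got {week}")
    lo, hi = WEEK_DOMAIN[cal.mode]
    wk = float(np.clip(week, lo, hi))
    a, b, c = cal.tensor[..., 0], cal.tensor[..., 1], cal.tensor[..., 2]
    alp_xy = c * wk * wk + b * wk + a              # shape (6, 3)
    powers = np.array([bmi * bmi, bmi, 1.0])
    alp = alp_xy @ powers                           # shape (6,)
    if cal.mode == "pregnant" and week < 12.0:
        alp[0] *= week / 12.0
    if cal.mode == "postpartum":
        alp[0] = 0.0
    return alp


def morph_weights(
    measurements: BodyMeasurements,
    bmi: float,
    week: float,
    cal: AlpCalibration | None = None,
    mode: Mode = "pregnant",
) -> MorphWeights:
    """K_j = K0j + Alp_j.  ``measurements`` must be the non-pregnant
    baseline girths at pre-pregnancy weight; all gestational change is
    carried by the corrections."""
    cal = cal or (
        AlpCalibration.pregnant_default()
        if mode == "pregnant"
        else AlpCalibration.postpartum_default()
    )
    if cal.mode != mode:
        raise InvalidArgumentError(f"calibration mode {cal.mode} != requested {mode}")
    base = base_weights(measurements, mode).as_array()
    alp = alp_corrections(cal, bmi, week)
    k = base + alp
    if mode == "postpartum":
        k[0] = 0.0
    return MorphWeights(mode, *k)


def blend(avatars, weights: MorphWeights):
    """Affine per-vertex combination of the avatar set.

    Returns a new :class:`maternshape.avatars.Mesh` with the shared
    topology.  ``k0`` multiplies the pregnant-thin target and the base thin
    avatar receives ``1 - sum(K)``.
    """
    from .avatars import Mesh

    meshes = avatars.ordered()  # (A, B, C, D, E, F, X)
    faces = meshes[0].faces
    n = meshes[0].vertices.shape[0]
    for m in meshes[1:]:
        if m.vertices.shape[0] != n or not np.array_equal(m.faces, faces):
            raise TopologyError("avatars must share vertex count and face list")
    k = weights.as_array()
    thin, big_breast, big_waist, big_hip, tall, long_legs, pregnant = (
        m.vertices for m in meshes
    )
    v = (
        (1.0 - k.sum()) * thin
        + k[0] * pregnant
        + k[1] * big_breast
        + k[2] * big_waist
        + k[3] * big_hip
        + k[4] * tall
        + k[5] * long_legs
    )
    return Mesh(vertices=v, faces=faces.copy())
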