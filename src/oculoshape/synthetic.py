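"""Synthetic voxel masks, fundus scenes and cohorts with known ground truth.

Every downstream stage (shape fitting, feature extraction, association
modelling) is testable against the generating parameters recorded here, so
no restricted imaging data is ever required. All randomness flows from
explicit seeds; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .eye_shape import AXIS_AP, AXIS_IS, AXIS_NT, VoxelMask
from .fundus import FEATURE_NAMES, FundusScene, Vessel, vessel_caliber_equivalent
from .fundus import KNUDTSON_ARTERIOLE, KNUDTSON_VENULE

__all__ = [
    "EllipsoidSpec",
    "SyntheticMask",
    "make_ellipsoid_mask",
    "FundusSceneSpec",
    "SyntheticScene",
    "make_fundus_scene",
    "CohortSpec",
    "make_cohort",
    "ellipsoid_spec_from_metrics",
]

DEFAULT_SPACING = (1.05, 1.0, 1.0)  # mm, mirrors the acquisition grid


@dataclass
class EllipsoidSpec:
    """Ground truth for one voxelized posterior-eye mask.

    Semidiameters a, b, c (mm) lie along the anterior-posterior,
    nasal-temporal and inferior-superior axes before rotation. Rotation is
    intrinsic x-y-z Euler angles in degrees about the grid axes.
    ``anterior_truncation_fraction`` removes an anterior cap of that fraction
    of the full anterior-posterior extent (models the lens-excluded chamber).
    """

    a: float
    b: float
    c: float
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    surface_noise_sd: float = 0.0
    anterior_truncation_fraction: float = 0.0
    laterality: str = "right"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"semidiameters must be positive, got {(self.a, self.b, self.c)}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.surface_noise_sd < 0:
            raise ValueError("surface_noise_sd must be >= 0")
        if not 0.0 <= self.anterior_truncation_fraction < 0.5:
            raise ValueError(
                "anterior_truncation_fraction must be in [0, 0.5) so the "
                "posterior segment remains the dominant body"
            )

    @property
    def semidiameters(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()

    @property
    def analytic_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.a * self.b * self.c


class SyntheticMask(NamedTuple):
    mask: VoxelMask
    spec: EllipsoidSpec


def make_ellipsoid_mask(
    spec: EllipsoidSpec,
    grid_shape: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> SyntheticMask:
    """Voxelize a rotated (optionally truncated, noisy) ellipsoid.

    A voxel is foreground iff its center lies inside the transformed
    ellipsoid, with the boundary radius perturbed per voxel by zero-mean
    Gaussian noise of ``surface_noise_sd`` mm. Grid axes are labeled
    anterior-posterior, nasal-temporal, inferior-superior in order. The grid
    is auto-sized unless ``grid_shape`` is given, in which case an ellipsoid
    exceeding the bounds is an explicit error.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    rot = spec.rotation_matrix  # columns: ellipsoid body axes in grid frame
    semis = np.asarray(spec.semidiameters)
    # half-extent of the rotated ellipsoid along each grid axis
    half_extent = np.sqrt(((rot * semis[None, :]) ** 2).sum(axis=1))
    margin = 4.0 * spec.surface_noise_sd + 2.0 * spacing.max()
    need = half_extent + margin

    if grid_shape is None:
        shape = tuple(int(np.ceil(2.0 * need[i] / spacing[i])) + 1 for i in range(3))
        center_mm = np.array([(shape[i] - 1) / 2.0 * spacing[i] for i in range(3)])
        center_mm = center_mm + np.asarray(spec.center)
    else:
        shape = tuple(int(s) for s in grid_shape)
        center_mm = np.array([(shape[i] - 1) / 2.0 * spacing[i] for i in range(3)])
        center_mm = center_mm + np.asarray(spec.center)
        extent_mm = np.array([(shape[i] - 1) * spacing[i] for i in range(3)])
        lo = center_mm - half_extent - 3.0 * spec.surface_noise_sd
        hi = center_mm + half_extent + 3.0 * spec.surface_noise_sd
        if np.any(lo < 0) or np.any(hi > extent_mm):
            raise ValueError(
                f"ellipsoid (extent {half_extent} mm around {center_mm}) exceeds "
                f"grid bounds {shape} at spacing {tuple(spacing)}"
            )

    axes_mm = [np.arange(shape[i]) * spacing[i] - center_mm[i] for i in range(3)]
    px, py, pz = np.meshgrid(*axes_mm, indexing="ij")
    pts = np.stack([px, py, pz], axis=-1)  # (nx, ny, nz, 3)
    body = pts @ rot  # components along body axes (R^T p)
    rho = np.sqrt(((body / semis) ** 2).sum(axis=-1))
    r = np.linalg.norm(pts, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_surface = np.where(rho > 0, r / rho, np.inf)
    if spec.surface_noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, spec.surface_noise_sd, size=shape)
        inside = r <= r_surface + noise
    else:
        inside = rho <= 1.0
    if spec.anterior_truncation_fraction > 0:
        cut = spec.a * (1.0 - 2.0 * spec.anterior_truncation_fraction)
        inside &= body[..., 0] <= cut

    mask = VoxelMask(
        grid=inside,
        spacing=tuple(spacing),
        axis_labels=(AXIS_AP, AXIS_NT, AXIS_IS),
        laterality=spec.laterality,
    )
    return SyntheticMask(mask=mask, spec=spec)


def ellipsoid_spec_from_metrics(
    q_h: float, q_v: float, volume: float, **kwargs
) -> EllipsoidSpec:
    """Build an EllipsoidSpec matching target asphericities and volume.

    Inverts Q_h = b^2/a^2 - 1, Q_v = c^2/a^2 - 1 and V = (4/3) pi a b c.
    """
    if q_h <= -1 or q_v <= -1:
        raise ValueError("asphericity must exceed -1")
    if volume <= 0:
        raise ValueError("volume must be positive")
    ratio = np.sqrt((1.0 + q_h) * (1.0 + q_v))
    a = (3.0 * volume / (4.0 * np.pi * ratio)) ** (1.0 / 3.0)
    return EllipsoidSpec(
        a=a, b=a * np.sqrt(1.0 + q_h), c=a * np.sqrt(1.0 + q_v), **kwargs
    )


# ---------------------------------------------------------------------------
# Fundus scenes
# ---------------------------------------------------------------------------


@dataclass
class FundusSceneSpec:
    """Generating parameters (= ground truth) for one synthetic fundus scene."""

    laterality: str = "right"
    od_center: tuple[float, float] = (100.0, 250.0)
    od_semi_major: float = 42.0
    od_semi_minor: float = 38.0
    od_angle: float = 75.0
    fovea_offset: tuple[float, float] = (300.0, -15.0)  # fovea minus OD centre
    arterial_concavity: float = 0.05
    venous_concavity: float = 0.04
    arteriole_widths: tuple[float, ...] = (12.0, 11.0, 10.5, 10.0, 9.5, 9.0)
    venule_widths: tuple[float, ...] = (15.0, 14.0, 13.5, 13.0, 12.5, 12.0)
    waviness: float = 0.0  # sinusoidal amplitude of radial vessels (tortuosity)
    point_noise_sd: float = 0.0  # Gaussian jitter on arcade points
    fpi_value: float | None = 120.0
    background_intensity: float = 30.0
    frame_size: tuple[int, int] = (512, 512)
    ser: float | None = None
    corneal_radius: float | None = None

    def __post_init__(self) -> None:
        if np.allclose(self.fovea_offset, 0):
            raise ValueError("fovea must not coincide with the OD centre (angle undefined)")
        if self.od_semi_minor <= 0 or self.od_semi_major < self.od_semi_minor:
            raise ValueError("OD ellipse requires semi-major >= semi-minor > 0")
        if any(w <= 0 for w in self.arteriole_widths + self.venule_widths):
            raise ValueError("vessel widths must be positive")


class SyntheticScene(NamedTuple):
    scene: FundusScene
    truth: dict  # generating parameters and analytic feature values


def _radial_vessel(origin, angle_deg, length, width, waviness, kind, n=60) -> Vessel:
    t = np.linspace(0.0, length, n)
    theta = np.deg2rad(angle_deg)
    d = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-d[1], d[0]])
    offset = waviness * np.sin(2.0 * np.pi * t / max(length, 1.0) * 3.0)
    pts = np.asarray(origin) + np.outer(t, d) + np.outer(offset, perp)
    return Vessel(points=pts, widths=np.full(n, width), kind=kind, arcade="other")


def make_fundus_scene(spec: FundusSceneSpec, seed: int = 0) -> SyntheticScene:
    """Build a scene whose exact generating parameters are recorded as truth.

    The temporal arcades are parabolas with the configured quadratic
    coefficients in the OD->fovea frame; big-six radial vessels carry the
    configured widths; waviness adds a known sinusoidal tortuosity.
    """
    rng = np.random.default_rng(seed)
    od = np.asarray(spec.od_center, dtype=float)
    fovea = od + np.asarray(spec.fovea_offset, dtype=float)
    u = np.asarray(spec.fovea_offset, dtype=float)
    u = u / np.linalg.norm(u)
    v_perp = np.array([-u[1], u[0]])

    vessels: list[Vessel] = []

    # big-six radial vessels (nasal side, away from the fovea)
    base_angle = np.degrees(np.arctan2(-u[1], -u[0]))
    spread = np.linspace(-60.0, 60.0, max(len(spec.arteriole_widths), 2))
    for i, w in enumerate(spec.arteriole_widths):
        ang = base_angle + spread[i % len(spread)] + 4.0
        vessels.append(_radial_vessel(od, ang, 140.0, w, spec.waviness, "arteriole"))
    for i, w in enumerate(spec.venule_widths):
        ang = base_angle + spread[i % len(spread)] - 4.0
        vessels.append(_radial_vessel(od, ang, 140.0, w, spec.waviness, "venule"))

    # temporal arcades: exact parabolas x = q*y^2 in the OD->fovea frame
    def arcade(coeff, kind, sign, width):
        y = sign * np.linspace(8.0, 170.0, 80)
        x = coeff * y**2
        pts = od + np.outer(x, u) + np.outer(y, v_perp)
        if spec.point_noise_sd > 0:
            pts = pts + rng.normal(0.0, spec.point_noise_sd, size=pts.shape)
        flag = "superior-temporal" if sign > 0 else "inferior-temporal"
        return Vessel(points=pts, widths=np.full(len(y), width), kind=kind, arcade=flag)

    arcade_width = 6.0  # thin, so arcades never enter the big-six pool
    vessels.append(arcade(spec.arterial_concavity, "arteriole", +1, arcade_width))
    vessels.append(arcade(spec.arterial_concavity, "arteriole", -1, arcade_width))
    vessels.append(arcade(spec.venous_concavity, "venule", +1, arcade_width))
    vessels.append(arcade(spec.venous_concavity, "venule", -1, arcade_width))

    intensity = None
    if spec.fpi_value is not None:
        w, h = spec.frame_size
        intensity = np.full((h, w), spec.background_intensity)
        yy, xx = np.mgrid[0:h, 0:w]
        macula = (xx - fovea[0]) ** 2 + (yy - fovea[1]) ** 2 <= 25.0**2
        intensity[macula] = spec.fpi_value

    scene = FundusScene(
        od_center=tuple(od),
        od_semi_major=spec.od_semi_major,
        od_semi_minor=spec.od_semi_minor,
        od_angle=spec.od_angle,
        fovea=tuple(fovea),
        vessels=vessels,
        laterality=spec.laterality,
        ser=spec.ser,
        corneal_radius=spec.corneal_radius,
        intensity=intensity,
        frame_size=spec.frame_size,
    )

    dx, dy = spec.fovea_offset
    if spec.laterality == "left":
        dx = -dx
    # length-weighted arc/chord tortuosity of the generated polylines (exact)
    lengths = [v.arc_length for v in vessels]
    torts = [v.arc_length / v.chord_length - 1.0 for v in vessels]
    big_a = sorted(spec.arteriole_widths, reverse=True)[:6]
    big_v = sorted(spec.venule_widths, reverse=True)[:6]
    ovality = spec.od_semi_major / spec.od_semi_minor
    truth = {
        "od_fovea_distance": float(np.hypot(*spec.fovea_offset)),
        "od_fovea_angle": float(np.degrees(np.arctan2(dy, dx))),
        "od_area": float(np.pi * spec.od_semi_major * spec.od_semi_minor),
        "od_orientation": 90.0 if np.isclose(ovality, 1.0) else float(
            180.0 - (spec.od_angle % 180.0)
            if (spec.od_angle % 180.0) > 90.0
            else spec.od_angle % 180.0
        ),
        "od_ovality": float(ovality),
        "crae": vessel_caliber_equivalent(big_a, KNUDTSON_ARTERIOLE),
        "crve": vessel_caliber_equivalent(big_v, KNUDTSON_VENULE),
        "tortuosity": float(np.average(torts, weights=lengths)),
        "fd": None,  # no analytic value for the rasterized map
        "arterial_concavity": spec.arterial_concavity,
        "venous_concavity": spec.venous_concavity,
        "fpi": spec.fpi_value,
    }
    return SyntheticScene(scene=scene, truth=truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Generating model for a synthetic per-eye cohort.

    Asphericity is linear in SER with slope ``slope_per_2p5D`` per 2.5 D,
    plus a participant-level random intercept shared by both eyes, plus
    per-eye residual noise, plus any direct standardized feature effects.
    Defaults emulate the study sample: SER mean -0.26 D and SD 2.46 D, and
    an asphericity slope of 0.12 per 2.5 D.
    """

    n_participants: int = 100
    p_two_eyes: float = 0.5
    ser_mean: float = -0.26
    ser_sd: float = 2.46
    slope_per_2p5D: float = 0.12
    intercept_sd: float = 0.08
    residual_sd: float = 0.10
    feature_effects: dict = field(default_factory=dict)  # feature -> std. slope
    feature_ser_loading: float = 0.3  # correlation of features with SER
    q_h_mean: float = 0.17
    q_v_mean: float = 0.11
    volume_mean: float = 4433.0
    volume_per_2p5D: float = -240.0  # volume change per +2.5 D of SER
    volume_male_effect: float = 469.0
    volume_residual_sd: float = 400.0
    p_male: float = 0.28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not 0.0 <= self.p_two_eyes <= 1.0:
            raise ValueError("p_two_eyes must be in [0, 1]")
        for name in ("ser_sd", "intercept_sd", "residual_sd", "volume_residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.feature_effects) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names in feature_effects: {sorted(unknown)}")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a per-eye cohort table with known generating parameters.

    Columns: participant_id, eye, ser, age, sex (0=female, 1=male), height,
    Q_h, Q_v, volume_mm3 and the 12 features (as standardized z-scores with
    the configured SER loading). Both eyes of a participant share the random
    intercept. Deterministic given the spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    two_eyes = rng.random(n) < spec.p_two_eyes
    single_eye_side = rng.integers(0, 2, size=n)  # 0 -> left, 1 -> right
    age = rng.normal(54.5, 7.7, size=n)
    sex = (rng.random(n) < spec.p_male).astype(int)
    height = 163.0 + 14.0 * sex + rng.normal(0.0, 6.0, size=n)
    ser_participant = rng.normal(spec.ser_mean, spec.ser_sd, size=n)
    intercept = rng.normal(0.0, spec.intercept_sd, size=n)
    vol_intercept = rng.normal(0.0, spec.volume_residual_sd * 0.5, size=n)

    rows = []
    for i in range(n):
        eyes = ("left", "right") if two_eyes[i] else (("left",) if single_eye_side[i] == 0 else ("right",))
        for eye in eyes:
            ser = ser_participant[i] + rng.normal(0.0, 0.10)
            z_ser = (ser - spec.ser_mean) / spec.ser_sd if spec.ser_sd > 0 else 0.0
            lam = spec.feature_ser_loading
            feats = {}
            direct = 0.0
            for name in FEATURE_NAMES:
                z = lam * z_ser + np.sqrt(max(1.0 - lam**2, 0.0)) * rng.standard_normal()
                feats[name] = z
                direct += spec.feature_effects.get(name, 0.0) * z
            eps_h = rng.normal(0.0, spec.residual_sd)
            eps_v = rng.normal(0.0, spec.residual_sd)
            slope = spec.slope_per_2p5D / 2.5
            q_h = spec.q_h_mean + slope * ser + direct + intercept[i] + eps_h
            q_v = spec.q_v_mean + slope * ser + direct + intercept[i] + eps_v
            volume = (
                spec.volume_mean
                + spec.volume_per_2p5D / 2.5 * ser
                + spec.volume_male_effect * sex[i]
                + 5.0 * (height[i] - 163.0 - 14.0 * sex[i])
                + vol_intercept[i]
                + rng.normal(0.0, spec.volume_residual_sd * 0.5)
            )
            rows.append(
                {
                    "participant_id": f"P{i:05d}",
                    "eye": eye,
                    "ser": ser,
                    "age": age[i],
                    "sex": sex[i],
                    "height": height[i],
                    "Q_h": q_h,
                    "Q_v": q_v,
                    "volume_mm3": volume,
                    **feats,
                }
            )
    return pd.DataFrame(rows)
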