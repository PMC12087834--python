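"""Fundus morphometry from geometric scene annotations.

Computes the 12-feature battery (optic disc geometry, OD-fovea geometry,
vessel calibers CRAE/CRVE, tortuosity, box-counting fractal dimension,
arcade concavity, foveal pixel intensity) from annotated scenes rather than
raw photographs. Dimensional metrics are corrected for ocular magnification.
Missing features are reported as NaN sentinels.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Vessel",
    "FundusScene",
    "FeatureVector",
    "MagnificationConfig",
    "FEATURE_NAMES",
    "magnification_factor",
    "od_fovea_distance",
    "od_fovea_angle",
    "od_metrics",
    "crae",
    "crve",
    "vessel_caliber_equivalent",
    "vessel_tortuosity",
    "vessel_fd",
    "rasterize_vessels",
    "arcade_concavity",
    "foveal_pixel_intensity",
    "extract_features",
    "mirror_scene",
]

FEATURE_NAMES = (
    "od_fovea_distance",
    "od_fovea_angle",
    "od_area",
    "od_orientation",
    "od_ovality",
    "crae",
    "crve",
    "tortuosity",
    "fd",
    "arterial_concavity",
    "venous_concavity",
    "fpi",
)

# Knudtson revised pairing constants for the big-six caliber reduction.
KNUDTSON_ARTERIOLE = 0.88
KNUDTSON_VENULE = 0.95


@dataclass
class Vessel:
    """One vessel centerline with per-point widths."""

    points: np.ndarray  # (N, 2) x, y
    widths: np.ndarray  # (N,)
    kind: str  # "arteriole" | "venule"
    arcade: str = "other"  # "superior-temporal" | "inferior-temporal" | "other"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("vessel needs an (N>=2, 2) point array")
        if len(self.widths) != len(self.points):
            raise ValueError("one width per centerline point required")
        if np.any(self.widths <= 0):
            raise ValueError("vessel widths must be positive")
        if self.kind not in ("arteriole", "venule"):
            raise ValueError(f"unknown vessel kind {self.kind!r}")

    @property
    def summary_width(self) -> float:
        """Per-vessel caliber summary: median of per-point widths."""
        return float(np.median(self.widths))

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class FundusScene:
    """Geometric annotation of one fundus image."""

    od_center: tuple[float, float]
    od_semi_major: float
    od_semi_minor: float
    od_angle: float  # degrees, major-axis angle from image horizontal
    fovea: tuple[float, float]
    vessels: list[Vessel] = field(default_factory=list)
    laterality: str = "right"
    ser: float | None = None  # dioptres
    corneal_radius: float | None = None  # mm
    intensity: np.ndarray | None = None  # optional 2D grid
    frame_size: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.od_semi_minor <= 0 or self.od_semi_major < self.od_semi_minor:
            raise ValueError("OD ellipse requires semi-major >= semi-minor > 0")
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be left/right, got {self.laterality!r}")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.ndim != 2:
                raise ValueError("intensity grid must be 2D")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "od_center": list(self.od_center),
            "od_semi_major": self.od_semi_major,
            "od_semi_minor": self.od_semi_minor,
            "od_angle": self.od_angle,
            "fovea": list(self.fovea),
            "laterality": self.laterality,
            "ser": self.ser,
            "corneal_radius": self.corneal_radius,
            "frame_size": list(self.frame_size),
            "vessels": [
                {
                    "points": v.points.tolist(),
                    "widths": v.widths.tolist(),
                    "kind": v.kind,
                    "arcade": v.arcade,
                }
                for v in self.vessels
            ],
            "intensity": None if self.intensity is None else self.intensity.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "FundusScene":
        obj = json.loads(Path(path).read_text())
        vessels = [
            Vessel(
                points=np.asarray(v["points"]),
                widths=np.asarray(v["widths"]),
                kind=v["kind"],
                arcade=v.get("arcade", "other"),
            )
            for v in obj["vessels"]
        ]
        intensity = obj.get("intensity")
        return cls(
            od_center=tuple(obj["od_center"]),
            od_semi_major=obj["od_semi_major"],
            od_semi_minor=obj["od_semi_minor"],
            od_angle=obj["od_angle"],
            fovea=tuple(obj["fovea"]),
            vessels=vessels,
            laterality=obj["laterality"],
            ser=obj.get("ser"),
            corneal_radius=obj.get("corneal_radius"),
            intensity=None if intensity is None else np.asarray(intensity),
            frame_size=tuple(obj.get("frame_size", (512, 512))),
        )


@dataclass
class FeatureVector:
    od_fovea_distance: float
    od_fovea_angle: float
    od_area: float
    od_orientation: float
    od_ovality: float
    crae: float
    crve: float
    tortuosity: float
    fd: float
    arterial_concavity: float
    venous_concavity: float
    fpi: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class MagnificationConfig:
    """Constants for the ametropia-and-keratometry magnification correction.

    True retinal dimensions per image pixel scale with the distance from the
    eye's second nodal point to the retina, approximated here from an axial
    length estimated linearly from SER and corneal radius. The factor is
    anchored to 1 at the emmetropic reference configuration.
    """

    reference_axial_length: float = 23.3  # mm at SER 0, reference cornea
    reference_corneal_radius: float = 7.8  # mm
    ser_to_axial: float = -0.40  # mm axial length per dioptre of SER
    cr_to_axial: float = 2.0  # mm axial length per mm of corneal radius
    nodal_offset: float = 1.82  # mm, nodal point to cornea (Littmann-style)


def magnification_factor(
    ser: float,
    corneal_radius: float | None = None,
    config: MagnificationConfig = MagnificationConfig(),
) -> float:
    """Multiplicative scale applied to linear dimensional metrics.

    Equal to 1 for the reference emmetropic eye; larger for more myopic
    (longer) eyes, whose true retinal dimensions per image pixel are larger.
    Areas scale with the square of this factor.
    """
    if not -20.0 <= ser <= 10.0:
        raise ValueError(f"SER {ser} D outside plausible range [-20, 10]")
    if corneal_radius is None:
        corneal_radius = config.reference_corneal_radius
    if not 6.5 <= corneal_radius <= 9.5:
        raise ValueError(f"corneal radius {corneal_radius} mm outside [6.5, 9.5]")
    axial = (
        config.reference_axial_length
        + config.ser_to_axial * ser
        + config.cr_to_axial * (corneal_radius - config.reference_corneal_radius)
    )
    reference = config.reference_axial_length - config.nodal_offset
    return (axial - config.nodal_offset) / reference


def _scene_factor(scene: FundusScene, config: MagnificationConfig | None = None) -> float:
    if scene.ser is None:
        return 1.0
    cfg = config or MagnificationConfig()
    return magnification_factor(scene.ser, scene.corneal_radius, cfg)


def _od_fovea_vector(scene: FundusScene) -> np.ndarray:
    d = np.asarray(scene.fovea, dtype=float) - np.asarray(scene.od_center, dtype=float)
    if np.allclose(d, 0):
        raise ValueError("fovea coincides with the OD centre; geometry undefined")
    return d


def od_fovea_distance(
    scene: FundusScene, config: MagnificationConfig | None = None
) -> float:
    """Magnification-corrected Euclidean OD-centre-to-fovea distance (px)."""
    return float(np.linalg.norm(_od_fovea_vector(scene))) * _scene_factor(scene, config)


def od_fovea_angle(scene: FundusScene) -> float:
    """Signed angle (degrees) of the OD->fovea ray versus the horizontal.

    Negative when the fovea lies below the OD-centre horizontal. Left-eye
    scenes are mirrored about the vertical axis first, so the temporal
    direction is consistent across lateralities.
    """
    dx, dy = _od_fovea_vector(scene)
    if scene.laterality == "left":
        dx = -dx
    return math.degrees(math.atan2(dy, dx))


def _fold_axis_angle(angle_deg: float) -> float:
    """Fold an axis (not ray) angle into [0, 90] degrees."""
    a = angle_deg % 180.0
    return 180.0 - a if a > 90.0 else a


def od_metrics(
    scene: FundusScene, config: MagnificationConfig | None = None
) -> tuple[float, float, float]:
    """(area px^2, orientation degrees in [0, 90], ovality >= 1).

    Area is the ellipse formula times the squared magnification factor.
    Orientation is the major-axis angle folded to [0, 90]; circles report 90
    (no oblique axis). Ovality is major/minor axis length ratio.
    """
    f = _scene_factor(scene, config)
    area = math.pi * scene.od_semi_major * scene.od_semi_minor * f * f
    ovality = scene.od_semi_major / scene.od_semi_minor
    if math.isclose(ovality, 1.0, rel_tol=0.0, abs_tol=1e-12):
        orientation = 90.0  # tie-break: a circle is not oblique
    else:
        orientation = _fold_axis_angle(scene.od_angle)
    return area, orientation, ovality


def vessel_caliber_equivalent(widths, k: float) -> float:
    """Iterative big-six pairing reduction of vessel widths.

    Sorts the widths, then repeatedly combines the largest with the smallest
    as ``k * sqrt(w1^2 + w2^2)``; with an odd count the median width carries
    over unpaired. Iterates to a single value.
    """
    vals = sorted(float(w) for w in widths)
    if not vals:
        raise ValueError("no widths to combine")
    if any(w <= 0 for w in vals):
        raise ValueError("widths must be positive")
    while len(vals) > 1:
        nxt = []
        if len(vals) % 2 == 1:
            mid = len(vals) // 2
            nxt.append(vals.pop(mid))
        while vals:
            lo = vals.pop(0)
            hi = vals.pop(-1)
            nxt.append(k * math.hypot(lo, hi))
        vals = sorted(nxt)
    return vals[0]


def _caliber(scene: FundusScene, kind: str, k: float, config) -> float:
    widths = sorted(
        (v.summary_width for v in scene.vessels if v.kind == kind), reverse=True
    )
    if not widths:
        return float("nan")  # feature absent for this eye, not an error
    six = widths[:6]
    return vessel_caliber_equivalent(six, k) * _scene_factor(scene, config)


def crae(
    scene: FundusScene,
    k: float = KNUDTSON_ARTERIOLE,
    config: MagnificationConfig | None = None,
) -> float:
    """Central retinal arteriolar equivalent (px), magnification-corrected."""
    return _caliber(scene, "arteriole", k, config)


def crve(
    scene: FundusScene,
    k: float = KNUDTSON_VENULE,
    config: MagnificationConfig | None = None,
) -> float:
    """Central retinal venular equivalent (px), magnification-corrected."""
    return _caliber(scene, "venule", k, config)


def vessel_tortuosity(scene: FundusScene) -> float:
    """Length-weighted mean of per-vessel (arc/chord - 1), all vessels pooled.

    Zero-chord vessels (closed loops) are excluded with a warning.
    """
    lengths, torts = [], []
    for v in scene.vessels:
        arc = v.arc_length
        chord = v.chord_length
        if chord <= 0:
            warnings.warn("vessel with zero chord length excluded from tortuosity", stacklevel=2)
            continue
        lengths.append(arc)
        torts.append(arc / chord - 1.0)
    if not lengths:
        raise ValueError("no vessels with a nonzero chord")
    w = np.asarray(lengths)
    return float(np.average(torts, weights=w))


def vessel_fd(vessel_map: np.ndarray, min_pixels: int = 10) -> float:
    """Box-counting fractal dimension of a 2D binary vessel map.

    Counts occupied boxes over a dyadic ladder of box sizes from side/4 down
    to 2 px and returns the least-squares slope of log(count) against
    log(1/size). Returns NaN when the foreground is too sparse.
    """
    grid = np.asarray(vessel_map) > 0
    if grid.ndim != 2:
        raise ValueError("vessel map must be 2D")
    side = min(grid.shape)
    if side < 64:
        raise ValueError(f"map side must be >= 64 px, got {side}")
    if grid.sum() < min_pixels:
        return float("nan")
    sizes = []
    s = 2 ** int(math.floor(math.log2(side / 4)))
    while s >= 2:
        sizes.append(s)
        s //= 2
    if len(sizes) < 5:
        raise ValueError("box ladder too short; need >= 5 dyadic sizes")
    counts = []
    for s in sizes:
        nb0 = math.ceil(grid.shape[0] / s)
        nb1 = math.ceil(grid.shape[1] / s)
        padded = np.zeros((nb0 * s, nb1 * s), dtype=bool)
        padded[: grid.shape[0], : grid.shape[1]] = grid
        boxes = padded.reshape(nb0, s, nb1, s).any(axis=(1, 3))
        counts.append(boxes.sum())
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)), np.log(counts), 1)
    return float(slope)


def rasterize_vessels(scene: FundusScene, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterize vessel centerlines into a binary map (for fractal dimension)."""
    from skimage.draw import line

    if shape is None:
        shape = tuple(int(s) for s in scene.frame_size)
    grid = np.zeros(shape, dtype=bool)
    h, w = shape
    for v in scene.vessels:
        pts = np.rint(v.points).astype(int)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            grid[rr[ok], cc[ok]] = True
    return grid


def arcade_concavity(scene: FundusScene, vessel_type: str, min_points: int = 5) -> float:
    """Quadratic coefficient of the temporal arcade in the OD-fovea frame.

    Points of the superior- and inferior-temporal arcades of the requested
    type are transformed to a frame centered on the OD with the first axis
    along OD->fovea, then fitted jointly with a parabola whose axis of
    symmetry is the OD->fovea direction. Positive values mean the arcade
    curves toward the fovea.
    """
    if vessel_type not in ("arteriole", "venule"):
        raise ValueError(f"unknown vessel type {vessel_type!r}")
    pts = [
        v.points
        for v in scene.vessels
        if v.kind == vessel_type and v.arcade in ("superior-temporal", "inferior-temporal")
    ]
    if not pts:
        return float("nan")
    pts = np.vstack(pts)
    if len(pts) < min_points:
        return float("nan")
    u = _od_fovea_vector(scene)
    u = u / np.linalg.norm(u)
    v_perp = np.array([-u[1], u[0]])
    rel = pts - np.asarray(scene.od_center, dtype=float)
    x = rel @ u  # along OD->fovea (toward fovea positive)
    y = rel @ v_perp
    design = np.column_stack([y**2, y, np.ones_like(y)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(coef[0])


def foveal_pixel_intensity(scene: FundusScene, radius: float = 10.0) -> float:
    """Mean intensity within a disc centered on the fovea (NaN if no grid).

    If the disc extends past the image border, the mean is taken over the
    in-bounds intersection and a warning is issued.
    """
    if scene.intensity is None:
        return float("nan")
    grid = scene.intensity
    h, w = grid.shape
    fx, fy = scene.fovea
    if not (0 <= fx < w and 0 <= fy < h):
        raise ValueError("fovea lies outside the intensity grid")
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (xx - fx) ** 2 + (yy - fy) ** 2 <= radius**2
    if fx < radius or fy < radius or fx >= w - radius or fy >= h - radius:
        warnings.warn("foveal disc clipped by the image border", stacklevel=2)
    if not disc.any():
        return float("nan")
    return float(grid[disc].mean())


def mirror_scene(scene: FundusScene) -> FundusScene:
    """Mirror a scene about the vertical axis and toggle laterality."""
    w = scene.frame_size[0]

    def mx(p):
        return (w - 1 - p[0], p[1])

    vessels = [
        Vessel(
            points=np.column_stack([w - 1 - v.points[:, 0], v.points[:, 1]]),
            widths=v.widths.copy(),
            kind=v.kind,
            arcade=v.arcade,
        )
        for v in scene.vessels
    ]
    return FundusScene(
        od_center=mx(scene.od_center),
        od_semi_major=scene.od_semi_major,
        od_semi_minor=scene.od_semi_minor,
        od_angle=180.0 - scene.od_angle,
        fovea=mx(scene.fovea),
        vessels=vessels,
        laterality="left" if scene.laterality == "right" else "right",
        ser=scene.ser,
        corneal_radius=scene.corneal_radius,
        intensity=None if scene.intensity is None else scene.intensity[:, ::-1].copy(),
        frame_size=scene.frame_size,
    )


def extract_features(
    scene: FundusScene,
    config: MagnificationConfig | None = None,
    fpi_radius: float = 10.0,
) -> FeatureVector:
    """Assemble the 12-feature vector for one scene.

    Magnification correction applies to dimensional metrics only (distance,
    area, CRAE, CRVE). Features that cannot be computed are NaN.
    """
    area, orientation, ovality = od_metrics(scene, config)
    try:
        tort = vessel_tortuosity(scene)
    except ValueError:
        tort = float("nan")
    if scene.vessels:
        fd = vessel_fd(rasterize_vessels(scene))
    else:
        fd = float("nan")
    return FeatureVector(
        od_fovea_distance=od_fovea_distance(scene, config),
        od_fovea_angle=od_fovea_angle(scene),
        od_area=area,
        od_orientation=orientation,
        od_ovality=ovality,
        crae=crae(scene, config=config),
        crve=crve(scene, config=config),
        tortuosity=tort,
        fd=fd,
        arterial_concavity=arcade_concavity(scene, "arteriole"),
        venous_concavity=arcade_concavity(scene, "venule"),
        fpi=foveal_pixel_intensity(scene, radius=fpi_radius),
    )
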