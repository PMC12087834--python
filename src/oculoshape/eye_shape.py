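"""Posterior-eye shape metrics from 3D binary masks.

Pipeline: load a binary mask (NIfTI + JSON sidecar), fit an ellipsoid to the
full foreground volume via eigendecomposition of the voxel covariance, and
derive volume, asphericity along the horizontal and vertical meridians,
goodness of fit (radial RMS error) and repeatability statistics (Dice, ICC).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "AXIS_AP",
    "AXIS_NT",
    "AXIS_IS",
    "ANATOMICAL_AXES",
    "VoxelMask",
    "Ellipsoid",
    "ShapeMetrics",
    "load_mask",
    "save_mask",
    "compute_volume",
    "fit_ellipsoid",
    "rms_fit_error",
    "radial_rms",
    "compute_asphericity",
    "classify_asphericity",
    "dice_score",
    "icc_agreement",
    "analyze_mask",
]

AXIS_AP = "anterior-posterior"
AXIS_NT = "nasal-temporal"
AXIS_IS = "inferior-superior"
ANATOMICAL_AXES = (AXIS_AP, AXIS_NT, AXIS_IS)

# Solid uniform ellipsoid: second moment along a principal axis is s**2 / 5,
# so the semidiameter is sqrt(5 * eigenvalue) of the voxel covariance.
SEMIDIAMETER_SCALE = np.sqrt(5.0)

_NIFTI_CODE_TO_AXIS = {
    "R": AXIS_NT,
    "L": AXIS_NT,
    "A": AXIS_AP,
    "P": AXIS_AP,
    "S": AXIS_IS,
    "I": AXIS_IS,
}
# world axis index used when writing masks: NT -> x, AP -> y, IS -> z
_AXIS_TO_WORLD = {AXIS_NT: 0, AXIS_AP: 1, AXIS_IS: 2}


@dataclass
class VoxelMask:
    """3D binary grid with voxel spacing and anatomical axis labels.

    ``axis_labels[i]`` names the anatomical axis that grid axis ``i`` runs
    along; it must be a permutation of :data:`ANATOMICAL_AXES`.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    axis_labels: tuple[str, str, str] = (AXIS_AP, AXIS_NT, AXIS_IS)
    laterality: str = "unknown"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"mask grid must be 3D, got {self.grid.ndim}D")
        self.grid = self.grid > 0
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if sorted(self.axis_labels) != sorted(ANATOMICAL_AXES):
            raise ValueError(
                f"axis_labels must be a permutation of {ANATOMICAL_AXES}, got {self.axis_labels}"
            )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    def foreground_mm(self) -> np.ndarray:
        """(N, 3) coordinates of foreground voxel centers in mm (grid frame)."""
        idx = np.argwhere(self.grid)
        return idx * np.asarray(self.spacing)

    def anatomical_direction(self, axis: str) -> np.ndarray:
        """Unit vector (grid mm frame) of the named anatomical axis."""
        i = self.axis_labels.index(axis)
        e = np.zeros(3)
        e[i] = 1.0
        return e


@dataclass
class Ellipsoid:
    """Ellipsoid with anatomically labeled principal axes.

    ``axes`` rows (and ``semidiameters`` entries) are ordered
    anterior-posterior (a), nasal-temporal (b), inferior-superior (c).
    """

    center: np.ndarray
    axes: np.ndarray  # (3, 3), row i = unit direction of anatomical axis i
    semidiameters: tuple[float, float, float]  # (a, b, c) in mm

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.semidiameters = tuple(float(s) for s in self.semidiameters)
        if any(s <= 0 for s in self.semidiameters):
            raise ValueError(f"semidiameters must be positive, got {self.semidiameters}")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("ellipsoid axes must be orthonormal within 1e-8")

    @property
    def a(self) -> float:
        return self.semidiameters[0]

    @property
    def b(self) -> float:
        return self.semidiameters[1]

    @property
    def c(self) -> float:
        return self.semidiameters[2]

    def radius_along(self, directions: np.ndarray) -> np.ndarray:
        """Surface radius from the center along unit direction(s)."""
        directions = np.atleast_2d(directions)
        u = directions @ self.axes.T  # components along principal axes
        s = np.asarray(self.semidiameters)
        return 1.0 / np.sqrt(((u / s) ** 2).sum(axis=1))

    @property
    def volume(self) -> float:
        """Analytic volume (4/3) * pi * a * b * c in mm^3."""
        a, b, c = self.semidiameters
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass
class ShapeMetrics:
    """Summary metrics for one eye."""

    asphericity_horizontal: float
    asphericity_vertical: float
    volume: float
    rms_error: float
    ellipsoid: Ellipsoid | None = field(default=None, repr=False)


def load_mask(path: str | Path, sidecar: str | Path | None = None) -> VoxelMask:
    """Load a binary mask from NIfTI, resolving spacing and axis labels.

    The sidecar JSON (``{"laterality": "left"|"right"}``) supplies laterality;
    if omitted, ``<path stem>.json`` next to the file is used when present.
    """
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D grid in {path}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel spacing in {path} header: {zooms}")
    codes = nib.aff2axcodes(img.affine)
    try:
        labels = tuple(_NIFTI_CODE_TO_AXIS[c] for c in codes)
    except KeyError as exc:
        raise ValueError(f"unresolvable orientation code {exc} in {path}") from exc
    if sorted(labels) != sorted(ANATOMICAL_AXES):
        raise ValueError(f"orientation {codes} does not span the three anatomical axes")

    laterality = "unknown"
    if sidecar is None:
        candidate = path.with_suffix("").with_suffix(".json")
        if candidate.exists():
            sidecar = candidate
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        laterality = meta.get("laterality", "unknown")
    return VoxelMask(grid=data, spacing=zooms, axis_labels=labels, laterality=laterality)


def save_mask(mask: VoxelMask, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a mask as NIfTI (uint8) with spacing/orientation in the affine."""
    import nibabel as nib

    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for i, label in enumerate(mask.axis_labels):
        affine[_AXIS_TO_WORLD[label], i] = mask.spacing[i]
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps({"laterality": mask.laterality}))


def compute_volume(mask: VoxelMask) -> float:
    """Volume in mm^3: foreground voxel count times voxel volume."""
    n = mask.n_foreground
    if n == 0:
        raise ValueError("cannot compute volume of an empty mask")
    return n * mask.voxel_volume


def fit_ellipsoid(
    mask: VoxelMask, min_voxels: int = 30, strict_axes: bool = False
) -> Ellipsoid:
    """Fit an ellipsoid to the full foreground volume.

    Center is the foreground centroid in mm; axes are the eigenvectors of the
    population covariance of voxel-center coordinates; the semidiameter along
    each axis is sqrt(5 * eigenvalue) (solid uniform ellipsoid relation).
    Each eigen-axis is assigned to the anatomical axis with which it has
    maximal absolute dot product; when two eigen-axes claim the same label
    (strong obliquity or eigenvalue ties) the optimal bijection is used,
    unless ``strict_axes`` is set, in which case a conflict between
    well-separated eigen-axes is an error naming the contested labels.
    """
    pts = mask.foreground_mm()
    if len(pts) < min_voxels:
        raise ValueError(f"need at least {min_voxels} foreground voxels, got {len(pts)}")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)  # population (1/N) normalization
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise ValueError("degenerate covariance (rank < 3): foreground is (near-)coplanar")
    semidiameters = SEMIDIAMETER_SCALE * np.sqrt(eigvals)

    anat_dirs = np.stack([mask.anatomical_direction(a) for a in ANATOMICAL_AXES])
    # |dot| between eigenvector k (column) and anatomical direction j
    affinity = np.abs(anat_dirs @ eigvecs)  # (3 anat, 3 eig)
    claimed = affinity.argmax(axis=0)  # per eigenvector, the anatomical index
    if len(set(claimed)) == 3:
        assignment = claimed
    else:
        counts = np.bincount(claimed, minlength=3)
        dupes = [ANATOMICAL_AXES[i] for i in range(3) if counts[i] > 1]
        rel_spread = (eigvals.max() - eigvals.min()) / eigvals.max()
        if strict_axes and rel_spread > 0.02:
            raise ValueError(
                f"ambiguous axis assignment: multiple eigen-axes map to {dupes}"
            )
        # deterministic fallback (eigenvalue ties / strong obliquity): the
        # bijection maximizing total |dot|; header order breaks exact ties.
        from scipy.optimize import linear_sum_assignment

        anat_idx, eig_idx = linear_sum_assignment(-affinity)
        assignment = np.empty(3, dtype=int)
        assignment[eig_idx] = anat_idx

    axes = np.empty((3, 3))
    semis = np.empty(3)
    for k in range(3):
        j = assignment[k]  # anatomical slot for eigenvector k
        v = eigvecs[:, k]
        if v @ anat_dirs[j] < 0:  # orient toward the positive anatomical direction
            v = -v
        axes[j] = v
        semis[j] = semidiameters[k]
    return Ellipsoid(center=center, axes=axes, semidiameters=tuple(semis))


def boundary_voxels_mm(mask: VoxelMask) -> np.ndarray:
    """Centers (mm) of foreground voxels with >= 1 background 6-neighbor."""
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask.grid, structure=structure, border_value=0)
    boundary = mask.grid & ~interior
    return np.argwhere(boundary) * np.asarray(mask.spacing)


def radial_rms(points: np.ndarray, e: Ellipsoid) -> float:
    """RMS of radial residuals |r_point - r_surface| for points in mm."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = points - e.center
    r = np.linalg.norm(d, axis=1)
    ok = r > 0
    if not ok.any():
        raise ValueError("all points coincide with the ellipsoid center")
    dirs = d[ok] / r[ok, None]
    residuals = r[ok] - e.radius_along(dirs)
    return float(np.sqrt(np.mean(residuals**2)))


def rms_fit_error(mask: VoxelMask, e: Ellipsoid) -> float:
    """Radial RMS error (mm) between the fitted ellipsoid and the mask boundary.

    Residuals are measured along the ray from the ellipsoid center through
    each boundary voxel center. A center outside the mask bounding box raises
    a warning, not an error.
    """
    pts = boundary_voxels_mm(mask)
    if len(pts) == 0:
        raise ValueError("mask has no boundary voxels")
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if np.any(e.center < lo) or np.any(e.center > hi):
        warnings.warn("ellipsoid center lies outside the mask bounding region", stacklevel=2)
    return radial_rms(pts, e)


def compute_asphericity(e: Ellipsoid) -> tuple[float, float]:
    """(Q_h, Q_v) = (b^2/a^2 - 1, c^2/a^2 - 1).

    Zero means spherical along that meridian; negative (long
    anterior-posterior axis) is prolate, positive is oblate.
    """
    a, b, c = e.semidiameters
    return b**2 / a**2 - 1.0, c**2 / a**2 - 1.0


def classify_asphericity(q: float, tol: float = 0.0) -> str:
    if q > tol:
        return "oblate"
    if q < -tol:
        return "prolate"
    return "spherical"


def dice_score(mask_a: VoxelMask, mask_b: VoxelMask) -> float:
    """Dice overlap 2|A & B| / (|A| + |B|) for two masks on the same grid."""
    if mask_a.grid.shape != mask_b.grid.shape:
        raise ValueError(
            f"grid shape mismatch: {mask_a.grid.shape} vs {mask_b.grid.shape}"
        )
    if not np.allclose(mask_a.spacing, mask_b.spacing):
        raise ValueError(f"spacing mismatch: {mask_a.spacing} vs {mask_b.spacing}")
    na, nb = mask_a.n_foreground, mask_b.n_foreground
    if na + nb == 0:
        raise ValueError("Dice score undefined: both masks are empty")
    inter = int((mask_a.grid & mask_b.grid).sum())
    return 2.0 * inter / (na + nb)


@dataclass
class IccResult:
    value: float
    n: int
    form: str


def icc_agreement(measurements: np.ndarray, form: str = "A1") -> IccResult:
    """Intraclass correlation for paired measurements (two raters/sessions).

    ``measurements`` is (n, 2): one row per eye, one column per rater or
    session. Default form is ICC(A,1): two-way, single measurement, absolute
    agreement. ``form="C1"`` gives the consistency variant.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("measurements must be (n, k>=2)")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 paired measurements")
    if np.isnan(x).any():
        raise ValueError("missing values are not allowed within pairs")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("ICC undefined: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form.upper() == "A1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form.upper() == "C1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC form {form!r}; use 'A1' or 'C1'")
    if denom <= 0:
        raise ValueError("ICC undefined: non-positive variance denominator")
    return IccResult(value=float((msr - mse) / denom), n=n, form=form.upper())


def analyze_mask(mask: VoxelMask) -> ShapeMetrics:
    """Fit an ellipsoid and assemble all shape metrics for one mask."""
    ell = fit_ellipsoid(mask)
    q_h, q_v = compute_asphericity(ell)
    return ShapeMetrics(
        asphericity_horizontal=q_h,
        asphericity_vertical=q_v,
        volume=compute_volume(mask),
        rms_error=rms_fit_error(mask, ell),
        ellipsoid=ell,
    )
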