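"""Stage-to-stage registration, Gruen zones, interface shell and ROI summaries.

Scans of the same specimen at different surgical stages are aligned with a
rigid iterative-closest-point (ICP) registration on surface points (SVD /
Kabsch update per iteration).  Periprosthetic regions follow the Gruen
convention operationalised in 3-D: the implant's principal axis is split into
proximal/middle/distal thirds, the sagittal plane of the femur coordinate
system separates lateral (zones 1–3, proximal to distal) from medial (zones
5–7, distal to proximal), and zone 4 is the bone cap distal to the implant
tip.  The bone–implant interface shell is the Euclidean distance-transform
band of a given thickness (mm, anisotropic spacing respected) around the
cavity or implant, intersected with the bone domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, map_coordinates
from scipy.spatial import cKDTree

from .errors import GeometryError, ParameterError
from .volume_io import LabelVolume, VolumeImage

__all__ = [
    "RigidTransform",
    "FemurCoordinateSystem",
    "ROISet",
    "ICPResult",
    "define_fcs",
    "icp_rigid_register",
    "transfer_roi",
    "define_gruen_zones",
    "interface_shell",
    "bv_tv",
    "zone_density_summary",
]


@dataclass
class RigidTransform:
    """World-coordinate rigid motion: x -> R x + t (mm)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,), mm

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ParameterError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ParameterError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ParameterError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class FemurCoordinateSystem:
    """ISB-style anatomical frame.

    ``si`` points superior (condyles to head), ``ml_axis`` spans
    medial–lateral, ``ap`` completes the right-handed set.  The frame itself
    is always right-handed; the ``side`` flag decides which ``ml_axis`` sign
    is anatomically lateral (``lateral_direction``).
    """

    origin: np.ndarray
    si: np.ndarray
    ml_axis: np.ndarray
    ap: np.ndarray
    side: str = "right"

    @property
    def lateral_direction(self) -> np.ndarray:
        return self.ml_axis if self.side == "right" else -self.ml_axis

    @property
    def rotation(self) -> np.ndarray:
        """Rows (ml, ap, si): world -> anatomical rotation matrix."""
        return np.vstack([self.ml_axis, self.ap, self.si])


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"{what} is degenerate (zero length)")
    return v / n


def define_fcs(
    head_center: np.ndarray,
    condyle_midpoint: np.ndarray,
    lateral_point: np.ndarray,
    side: str = "right",
) -> FemurCoordinateSystem:
    """Anatomical frame from three landmarks via Gram–Schmidt.

    The superior axis runs from the condylar midpoint to the head center; the
    medial–lateral axis is the lateral landmark direction orthogonalised
    against it; anterior–posterior completes the right-handed frame.
    Collinear landmarks raise :class:`GeometryError`.
    """
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    head = np.asarray(head_center, dtype=np.float64)
    cond = np.asarray(condyle_midpoint, dtype=np.float64)
    lat = np.asarray(lateral_point, dtype=np.float64)
    si = _unit(head - cond, "superior axis")
    v = lat - cond
    ml = v - (v @ si) * si
    if np.linalg.norm(ml) < 1e-9:
        raise GeometryError("landmarks are collinear; frame is undetermined")
    ml = _unit(ml, "medial-lateral axis")
    ap = np.cross(si, ml)  # (ml, ap, si) right-handed
    return FemurCoordinateSystem(origin=head, si=si, ml_axis=ml, ap=ap, side=side)


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_mm: float
    n_iterations: int


def _procrustes(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst`` (Kabsch)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise GeometryError("degenerate (collinear) point sets; rotation undetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, dc - r @ sc)


def icp_rigid_register(
    source_points: np.ndarray,
    target_points: np.ndarray,
    max_iterations: int = 60,
    tolerance_mm: float = 1e-5,
) -> ICPResult:
    """Rigid ICP: nearest-neighbour correspondences (k-d tree, no trimming)
    with an SVD Procrustes update, until the RMS improves by less than
    ``tolerance_mm`` or ``max_iterations`` is reached."""
    src = np.atleast_2d(np.asarray(source_points, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(target_points, dtype=np.float64))
    if src.shape[0] < 3 or dst.shape[0] < 3:
        raise ParameterError("need at least 3 points per set")
    tree = cKDTree(dst)
    transform = RigidTransform.identity()
    prev_rms = np.inf
    rms = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        moved = transform.apply(src)
        dists, idx = tree.query(moved)
        transform = _procrustes(src, dst[idx])
        rms = float(np.sqrt(np.mean(dists**2)))
        if abs(prev_rms - rms) < tolerance_mm:
            break
        prev_rms = rms
    moved = transform.apply(src)
    dists, _ = tree.query(moved)
    rms = float(np.sqrt(np.mean(dists**2)))
    return ICPResult(transform=transform, rms_mm=rms, n_iterations=it)


def _grid_world_coords(shape, spacing, origin):
    axes = [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def transfer_roi(
    roi: LabelVolume,
    transform: RigidTransform,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
    target_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    order: int = 0,
) -> LabelVolume | VolumeImage:
    """Resample labels onto a target grid through a world-space rigid motion.

    ``transform`` maps source world coordinates to target world coordinates;
    labels use nearest-neighbour (order 0) so values stay integral, densities
    can use trilinear (order 1).  Voxels falling outside the source grid get 0.
    """
    inv = transform.inverse()
    zz, yy, xx = _grid_world_coords(target_shape, target_spacing, target_origin)
    world = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    src_world = inv.apply(world)
    src_idx = (src_world - np.asarray(roi.origin)) / np.asarray(roi.spacing)
    if order == 0:
        # explicit nearest-neighbour: positions within half a pitch of the
        # outermost voxel centers still belong to the grid
        rounded = np.rint(src_idx).astype(np.int64)
        valid = np.all(
            (rounded >= 0) & (rounded < np.asarray(roi.shape)), axis=1
        )
        sampled = np.zeros(len(rounded), dtype=roi.voxels.dtype)
        r = rounded[valid]
        sampled[valid] = roi.voxels[r[:, 0], r[:, 1], r[:, 2]]
        return LabelVolume(sampled.reshape(target_shape), target_spacing, target_origin)
    sampled = map_coordinates(
        roi.voxels,
        src_idx.T,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    ).reshape(target_shape)
    return VolumeImage(sampled, target_spacing, target_origin, roi.unit_tag)


@dataclass
class ROISet:
    """Gruen zones 1–7 plus the bone–implant interface shell."""

    zones: LabelVolume  # values 1..7, 0 elsewhere
    shell: LabelVolume | None
    shell_thickness_mm: float | None
    implant_axis: np.ndarray
    implant_center: np.ndarray


def define_gruen_zones(
    implant_mask: LabelVolume,
    fcs: FemurCoordinateSystem,
    bone_domain: LabelVolume,
) -> ROISet:
    """Split the periprosthetic bone domain into the seven Gruen zones.

    The implant axis is its principal (PCA) axis oriented proximally along
    the FCS superior axis.  Along the axis the implant length is cut into
    thirds; on the lateral side zones run 1 (proximal) to 3 (distal), on the
    medial side 5 (distal) to 7 (proximal); bone beyond the distal tip is
    zone 4.
    """
    imp = implant_mask.voxels > 0
    if not imp.any():
        raise ParameterError("implant mask is empty")
    dom = bone_domain.voxels > 0
    if not dom.any():
        raise ParameterError("bone domain is empty")

    sp = np.asarray(implant_mask.spacing)
    og = np.asarray(implant_mask.origin)
    imp_idx = np.argwhere(imp).astype(np.float64)
    imp_world = imp_idx * sp + og
    center = imp_world.mean(axis=0)
    cov = np.cov((imp_world - center).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis @ fcs.si < 0:
        axis = -axis  # axis points proximal

    t_imp = (imp_world - center) @ axis
    t_min, t_max = float(t_imp.min()), float(t_imp.max())
    length = t_max - t_min
    if length <= 0:
        raise GeometryError("implant mask has no extent along its axis")
    b1 = t_min + length / 3.0
    b2 = t_min + 2.0 * length / 3.0

    dom_idx = np.argwhere(dom).astype(np.float64)
    dom_world = dom_idx * sp + og
    t_dom = (dom_world - center) @ axis
    s_dom = (dom_world - center) @ fcs.lateral_direction

    zone = np.zeros(t_dom.shape, dtype=np.int32)
    below = t_dom < t_min
    inside = (t_dom >= t_min) & (t_dom <= t_max)
    third = np.where(t_dom > b2, 2, np.where(t_dom > b1, 1, 0))  # 2 = proximal third
    lateral = s_dom > 0
    zone[below] = 4
    zone[inside & lateral] = (3 - third)[inside & lateral]  # 1 prox .. 3 dist
    zone[inside & ~lateral] = (5 + third)[inside & ~lateral]  # 5 dist .. 7 prox

    zones = np.zeros(implant_mask.shape, dtype=np.int32)
    ii = tuple(np.argwhere(dom).T)
    zones[ii] = zone
    return ROISet(
        zones=LabelVolume(zones, implant_mask.spacing, implant_mask.origin),
        shell=None,
        shell_thickness_mm=None,
        implant_axis=axis,
        implant_center=center,
    )


def interface_shell(
    mask: LabelVolume,
    thickness_mm: float,
    bone_domain: LabelVolume,
) -> LabelVolume:
    """Distance-transform band of ``thickness_mm`` around ``mask``, restricted
    to the bone domain.  Distances are Euclidean in mm (anisotropic spacing)."""
    if thickness_mm <= 0:
        raise ParameterError(f"shell thickness must be positive, got {thickness_mm}")
    m = mask.voxels > 0
    if not m.any():
        raise ParameterError("reference mask is empty")
    dist = distance_transform_edt(~m, sampling=mask.spacing)
    shell = (dist > 0) & (dist <= thickness_mm) & (bone_domain.voxels > 0)
    return LabelVolume(shell.astype(np.int32), mask.spacing, mask.origin)


def bv_tv(bone_mask: LabelVolume, roi: LabelVolume) -> float:
    """Bone volume fraction: bone voxels over total voxels in the ROI."""
    if bone_mask.shape != roi.shape:
        raise ParameterError("bone mask and ROI grids differ")
    r = roi.voxels > 0
    n = int(r.sum())
    if n == 0:
        raise ParameterError("ROI is empty")
    return float((bone_mask.voxels > 0)[r].sum() / n)


def zone_density_summary(
    density: VolumeImage,
    rois: ROISet,
    bone_mask: LabelVolume,
    implant_mask: LabelVolume | None = None,
) -> pd.DataFrame:
    """Per-zone mean density and BV/TV.

    Reports both the bone-masked mean (real-density reading) and the
    whole-ROI mean (apparent-density reading).  If ``implant_mask`` is given,
    a 1-voxel rind around the implant is excluded from the bone mask to guard
    against bright-implant bleed-in.  Empty zones appear with NaN means.
    """
    if density.shape != rois.zones.shape or density.shape != bone_mask.shape:
        raise ParameterError("density, zones and bone mask grids differ")
    bone = bone_mask.voxels > 0
    if implant_mask is not None:
        from scipy.ndimage import binary_dilation

        rind = binary_dilation(implant_mask.voxels > 0)
        bone = bone & ~rind
    rows = []
    for z in range(1, 8):
        zm = rois.zones.voxels == z
        n = int(zm.sum())
        nb = int((zm & bone).sum())
        rows.append(
            {
                "zone": z,
                "n_voxels": n,
                "n_bone_voxels": nb,
                "bvtv": nb / n if n else np.nan,
                "mean_density_bone_gcc": (
                    float(density.voxels[zm & bone].mean()) if nb else np.nan
                ),
                "mean_density_roi_gcc": float(density.voxels[zm].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("zone")
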