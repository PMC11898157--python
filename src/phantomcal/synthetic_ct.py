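"""Synthetic CT ground truth: calibration phantom, femur, surgical stages.

Every downstream stage of the pipeline (segmentation, calibration, ROI
morphometry) is validated against volumes generated here, where the voxel-wise
density, the tissue labels and the total bone mass are known exactly.

The scene model is deliberately idealised:

* the density calibration phantom is a block of base polymer with cylindrical
  inserts of certified density (partial-volume voxels at the cylinder surface
  are rendered by 3x supersampling);
* the femur is a tapered tube: a cortical shell of uniform tissue density
  around a medullary canal filled with marrow and a trabecular network drawn
  from a smoothed Gaussian random field thresholded to a target bone volume
  fraction (BV/TV);
* broaching removes the trabecular bone inside a tapered prismatic cavity and
  re-deposits a configurable fraction of the removed mass as debris into a
  thin shell around the cavity, nearest voxels first (osseodensification);
* implantation fills the cavity with implant material;
* a scanner maps density to intensity affinely, with gain and offset that
  depend on voltage, exposure and filtration, plus additive Gaussian noise;
* a medical-CT analogue is produced by block-averaging to ~0.5 mm voxels
  (partial-volume effect) and re-noising.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .errors import GenerationError, GeometryError, ParameterError, SpecError
from .reference_data import INSERT_MEASUREMENTS
from .volume_io import LabelVolume, VolumeImage, block_average_resample

__all__ = [
    "BACKGROUND",
    "MARROW",
    "TRABECULAR",
    "CORTICAL",
    "IMPLANT",
    "CAVITY",
    "PHANTOM_BASE",
    "INSERT_BASE",
    "BONE_LABELS",
    "Insert",
    "PhantomSpec",
    "ScanProtocol",
    "BonePhantomParams",
    "SurgicalStageParams",
    "GroundTruth",
    "default_phantom_spec",
    "default_phantom_grid",
    "generate_phantom",
    "generate_femur",
    "cavity_mask",
    "apply_broaching",
    "retention_for_shell_bvtv_delta",
    "insert_implant",
    "render_scan",
    "scan_gain",
    "scan_offset",
    "simulate_medical_ct",
    "INTENSITY_MODEL",
]

# tissue / material labels
BACKGROUND = 0
MARROW = 1
TRABECULAR = 2
CORTICAL = 3
IMPLANT = 4
CAVITY = 5
PHANTOM_BASE = 6
INSERT_BASE = 10  # insert k carries label INSERT_BASE + k

BONE_LABELS = (TRABECULAR, CORTICAL)

#: Affine intensity model: I = gain * rho + offset + N(0, noise_sd), with
#: gain = gain0 * (kV/100)^a * (ms/100)^b * filter_factor and
#: offset = offset0 * filter_factor.  The protocol dependence is a documented
#: modelling choice; only the affine form matters for calibration.
INTENSITY_MODEL = {
    "gain0": 1000.0,
    "voltage_exponent": 0.65,
    "exposure_exponent": 0.35,
    "offset0": 40.0,
    "filter_factors": {
        "no": 1.0,
        "0.25 mm Cu": 0.92,
        "0.25 mm Sn": 0.85,
        "0.75 mm Sn": 0.72,
    },
}


@dataclass(frozen=True)
class Insert:
    """One cylindrical phantom insert (axis along array axis 0)."""

    material: str
    density_gcc: float
    radius_mm: float
    height_mm: float
    center_mm: tuple[float, float, float]  # (z, y, x) world, mm


@dataclass
class PhantomSpec:
    inserts: list[Insert]
    base_density_gcc: float = 1.05

    def __post_init__(self) -> None:
        if len(self.inserts) < 2:
            raise SpecError("need at least 2 inserts for a calibration line")
        dens = [i.density_gcc for i in self.inserts]
        if any(d <= 0 for d in dens) or self.base_density_gcc <= 0:
            raise SpecError("densities must be strictly positive")
        if len(set(round(d, 12) for d in dens)) != len(dens):
            raise SpecError("insert densities must be pairwise distinct")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1 :]:
                z_gap = abs(a.center_mm[0] - b.center_mm[0])
                if z_gap < (a.height_mm + b.height_mm) / 2:
                    dxy = np.hypot(
                        a.center_mm[1] - b.center_mm[1], a.center_mm[2] - b.center_mm[2]
                    )
                    if dxy < a.radius_mm + b.radius_mm:
                        raise SpecError(f"inserts {a.material} and {b.material} overlap")


@dataclass
class ScanProtocol:
    """Scanner settings for one acquisition."""

    voltage_kv: float = 100.0
    exposure_ms: float = 100.0
    filter: str = "0.25 mm Cu"
    voxel_size_mm: float = 0.07
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0 or self.exposure_ms <= 0 or self.voxel_size_mm <= 0:
            raise ParameterError("voltage, exposure and voxel size must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.filter not in INTENSITY_MODEL["filter_factors"]:
            raise ParameterError(
                f"unknown filter {self.filter!r}; "
                f"known: {sorted(INTENSITY_MODEL['filter_factors'])}"
            )


@dataclass
class BonePhantomParams:
    """Idealised femur segment: cortical tube with a trabecular canal.

    ``outer_radius_mm`` is (proximal, distal) — the periosteal radius tapers
    linearly along the shaft (axis 0; index 0 is distal).
    """

    outer_radius_mm: tuple[float, float] = (7.0, 6.0)
    cortical_thickness_mm: float = 1.8
    cortical_density_gcc: float = 1.95
    trabecular_density_gcc: float = 1.85
    bvtv: float = 0.30
    correlation_length_mm: float = 0.5
    marrow_density_gcc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.outer_radius_mm):
            self.outer_radius_mm = (float(self.outer_radius_mm),) * 2  # type: ignore[assignment]
        if not 0 < self.bvtv < 1:
            raise SpecError(f"BV/TV must be in (0, 1), got {self.bvtv}")
        if self.cortical_thickness_mm >= min(self.outer_radius_mm):
            raise SpecError("cortical thickness must be smaller than the outer radius")
        for d in (
            self.cortical_density_gcc,
            self.trabecular_density_gcc,
            self.marrow_density_gcc,
        ):
            if d <= 0:
                raise SpecError("densities must be positive")
        if self.correlation_length_mm <= 0:
            raise SpecError("correlation length must be positive")


@dataclass
class SurgicalStageParams:
    """Broach/implant geometry (tapered square prism entering from the
    proximal end) and the debris mass budget."""

    implant_proximal_width_mm: float = 6.0
    implant_distal_width_mm: float = 4.0
    implant_length_mm: float = 16.0
    debris_retention: float = 1.0
    shell_thickness_mm: float = 1.0
    implant_density_gcc: float = 4.43
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.implant_proximal_width_mm, self.implant_distal_width_mm) <= 0:
            raise SpecError("implant widths must be positive")
        if self.implant_length_mm <= 0 or self.shell_thickness_mm <= 0:
            raise SpecError("implant length and shell thickness must be positive")
        if not 0 <= self.debris_retention <= 1:
            raise SpecError(f"debris_retention must be in [0, 1], got {self.debris_retention}")


@dataclass
class GroundTruth:
    """Known density map, tissue labels and mass bookkeeping for one stage."""

    density: VolumeImage  # g/cc
    labels: LabelVolume
    bone_mass_g: float
    insert_masses_g: dict[int, float] = field(default_factory=dict)
    realised_bvtv: float | None = None
    unplaced_debris_mass_g: float = 0.0

    @property
    def voxel_volume_cc(self) -> float:
        return self.density.voxel_volume_mm3 / 1000.0

    def bone_mask(self) -> np.ndarray:
        return self.labels.mask(*BONE_LABELS)

    def compute_bone_mass(self) -> float:
        """Mass (g) = sum of density * voxel volume over bone-labelled voxels."""
        m = self.bone_mask()
        return float(self.density.voxels[m].sum() * self.voxel_volume_cc)

    def clone(self) -> "GroundTruth":
        return GroundTruth(
            density=VolumeImage(
                self.density.voxels.copy(),
                self.density.spacing,
                self.density.origin,
                self.density.unit_tag,
            ),
            labels=LabelVolume(
                self.labels.voxels.copy(), self.labels.spacing, self.labels.origin
            ),
            bone_mass_g=self.bone_mass_g,
            insert_masses_g=dict(self.insert_masses_g),
            realised_bvtv=self.realised_bvtv,
            unplaced_debris_mass_g=self.unplaced_debris_mass_g,
        )


# ---------------------------------------------------------------------------
# phantom


def default_phantom_spec(
    radius_mm: float = 3.0, height_mm: float = 8.0, ring_radius_mm: float = 9.0
) -> PhantomSpec:
    """Five polymer inserts at their certified (mass/volume) mean densities,
    arranged on a ring, in a base polymer block."""
    densities = {
        mat: (mass / v_laser + mass / v_ct) / 2 * 1000.0
        for mat, _, mass, v_laser, v_ct in INSERT_MEASUREMENTS
    }
    n = len(densities)
    center_z = height_mm / 2 + 1.2
    center_xy = ring_radius_mm + radius_mm + 1.2
    inserts = []
    for k, (mat, rho) in enumerate(densities.items()):
        ang = 2 * np.pi * k / n
        inserts.append(
            Insert(
                material=mat,
                density_gcc=rho,
                radius_mm=radius_mm,
                height_mm=height_mm,
                center_mm=(
                    center_z,
                    center_xy + ring_radius_mm * np.sin(ang),
                    center_xy + ring_radius_mm * np.cos(ang),
                ),
            )
        )
    return PhantomSpec(inserts=inserts)


def default_phantom_grid(
    spec: PhantomSpec, spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Smallest grid (with a 1 mm margin) containing every insert of ``spec``."""
    zmax = max(i.center_mm[0] + i.height_mm / 2 for i in spec.inserts)
    ymax = max(i.center_mm[1] + i.radius_mm for i in spec.inserts)
    xmax = max(i.center_mm[2] + i.radius_mm for i in spec.inserts)
    shape = tuple(int(np.ceil((ext + 1.0) / s)) for ext, s in zip((zmax, ymax, xmax), spacing))
    return shape, spacing


def _axis_coords(shape, spacing, origin):
    return [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]


def generate_phantom(
    spec: PhantomSpec,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    supersample: int = 3,
) -> GroundTruth:
    """Voxelise the phantom with partial-volume surface voxels.

    Interior voxels carry the certified insert density exactly; voxels cut by
    a cylinder surface get the volume-weighted mixture of insert and base
    density, estimated by ``supersample``^3 sub-voxel sampling.
    """
    density = np.full(shape, spec.base_density_gcc, dtype=np.float64)
    labels = np.full(shape, PHANTOM_BASE, dtype=np.int32)
    coords = _axis_coords(shape, spacing, origin)
    vox_cc = float(np.prod(spacing)) / 1000.0
    s = int(supersample)
    if s < 1:
        raise ParameterError("supersample must be >= 1")
    offs = [((np.arange(s) + 0.5) / s - 0.5) * spacing[a] for a in range(3)]

    insert_masses: dict[int, float] = {}
    for k, ins in enumerate(spec.inserts):
        cz, cy, cx = ins.center_mm
        half_h, r = ins.height_mm / 2, ins.radius_mm
        lo = (cz - half_h, cy - r, cx - r)
        hi = (cz + half_h, cy + r, cx + r)
        world_lo = [coords[a][0] - spacing[a] / 2 for a in range(3)]
        world_hi = [coords[a][-1] + spacing[a] / 2 for a in range(3)]
        if any(lo[a] < world_lo[a] or hi[a] > world_hi[a] for a in range(3)):
            raise SpecError(f"insert {ins.material} does not fit in the grid")
        sl = []
        for a, (l, h) in enumerate(zip(lo, hi)):
            i0 = int(np.searchsorted(coords[a], l - spacing[a])) - 1
            i1 = int(np.searchsorted(coords[a], h + spacing[a])) + 1
            sl.append(slice(max(i0, 0), min(i1, shape[a])))

        # the cylinder indicator factorises into a z part and an (y, x) part,
        # so occupancy is the product of the two supersampled means
        zc = coords[0][sl[0]]
        z_sub = zc[:, None] + offs[0][None, :]
        occ_z = (np.abs(z_sub - cz) <= half_h).mean(axis=1)

        yc = coords[1][sl[1]]
        xc = coords[2][sl[2]]
        y_sub = (yc[:, None] + offs[1][None, :]).ravel()
        x_sub = (xc[:, None] + offs[2][None, :]).ravel()
        in_xy = (y_sub[:, None] - cy) ** 2 + (x_sub[None, :] - cx) ** 2 <= r**2
        occ_xy = in_xy.reshape(len(yc), s, len(xc), s).mean(axis=(1, 3))

        occ = occ_z[:, None, None] * occ_xy[None, :, :]
        box = (sl[0], sl[1], sl[2])
        density[box] = density[box] * (1 - occ) + ins.density_gcc * occ
        label_val = INSERT_BASE + k
        lbl_box = labels[box]
        lbl_box[occ > 0.5] = label_val
        labels[box] = lbl_box
        insert_masses[label_val] = float(occ.sum()) * vox_cc * ins.density_gcc

    return GroundTruth(
        density=VolumeImage(density, spacing, origin, "g/cc"),
        labels=LabelVolume(labels, spacing, origin),
        bone_mass_g=0.0,
        insert_masses_g=insert_masses,
    )


# ---------------------------------------------------------------------------
# femur


def generate_femur(
    params: BonePhantomParams,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (0.16, 0.16, 0.16),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> GroundTruth:
    """Tapered cortical tube with a thresholded-random-field trabecular canal.

    The trabecular network is a Gaussian random field smoothed to the given
    correlation length and thresholded at the canal-restricted quantile that
    realises the target BV/TV; the realised fraction is recorded and must land
    within +-0.02 of the target.  Cortical voxels carry the cortical tissue
    density exactly (no partial-volume mixing), which makes shell-masked means
    exact oracles downstream.
    """
    coords = _axis_coords(shape, spacing, origin)
    nz = shape[0]
    t = np.arange(nz) / max(nz - 1, 1)
    r_prox, r_dist = params.outer_radius_mm
    r_outer = r_dist + (r_prox - r_dist) * t  # index 0 = distal
    r_inner = r_outer - params.cortical_thickness_mm

    cy = (coords[1][0] + coords[1][-1]) / 2
    cx = (coords[2][0] + coords[2][-1]) / 2
    d_xy = np.hypot(coords[1][:, None] - cy, coords[2][None, :] - cx)

    cortical = (d_xy[None, :, :] <= r_outer[:, None, None]) & (
        d_xy[None, :, :] > r_inner[:, None, None]
    )
    canal = d_xy[None, :, :] <= r_inner[:, None, None]
    n_canal = int(canal.sum())
    if n_canal == 0:
        raise GenerationError("medullary canal is empty on this grid")

    rng = np.random.default_rng(params.seed)
    fld = rng.standard_normal(shape)
    sigma = [params.correlation_length_mm / s for s in spacing]
    fld = gaussian_filter(fld, sigma=sigma)
    thr = np.quantile(fld[canal], 1.0 - params.bvtv)
    bone_trab = canal & (fld >= thr)
    realised = bone_trab.sum() / n_canal
    if abs(realised - params.bvtv) > 0.02:
        raise GenerationError(
            f"realised BV/TV {realised:.3f} misses target {params.bvtv:.3f} "
            "(correlation length too large for this grid?)"
        )

    density = np.zeros(shape, dtype=np.float64)
    labels = np.full(shape, BACKGROUND, dtype=np.int32)
    labels[canal] = MARROW
    density[canal] = params.marrow_density_gcc
    labels[bone_trab] = TRABECULAR
    density[bone_trab] = params.trabecular_density_gcc
    labels[cortical] = CORTICAL
    density[cortical] = params.cortical_density_gcc

    gt = GroundTruth(
        density=VolumeImage(density, spacing, origin, "g/cc"),
        labels=LabelVolume(labels, spacing, origin),
        bone_mass_g=0.0,
        realised_bvtv=float(realised),
    )
    gt.bone_mass_g = gt.compute_bone_mass()
    return gt


# ---------------------------------------------------------------------------
# surgical stages


def cavity_mask(gt: GroundTruth, stage: SurgicalStageParams) -> np.ndarray:
    """Geometric broach cavity: tapered square prism entering from the
    proximal (top-index) end, centred on the canal axis."""
    shape = gt.labels.shape
    spacing, origin = gt.labels.spacing, gt.labels.origin
    coords = _axis_coords(shape, spacing, origin)
    z = coords[0]
    z_top = z[-1]
    z_bot = z_top - stage.implant_length_mm
    in_z = z >= z_bot
    u = np.clip((z - z_bot) / stage.implant_length_mm, 0.0, 1.0)  # 0 distal tip, 1 proximal
    half_w = (
        stage.implant_distal_width_mm
        + (stage.implant_proximal_width_mm - stage.implant_distal_width_mm) * u
    ) / 2.0

    cy = (coords[1][0] + coords[1][-1]) / 2
    cx = (coords[2][0] + coords[2][-1]) / 2
    dy = np.abs(coords[1] - cy)
    dx = np.abs(coords[2] - cx)
    cav = (
        in_z[:, None, None]
        & (dy[None, :, None] <= half_w[:, None, None])
        & (dx[None, None, :] <= half_w[:, None, None])
    )
    bad = cav & ~gt.labels.mask(MARROW, TRABECULAR, CAVITY, IMPLANT)
    if bad.any():
        raise GeometryError(
            f"implant cavity leaves the medullary canal at {int(bad.sum())} voxels"
        )
    return cav


def apply_broaching(gt: GroundTruth, stage: SurgicalStageParams) -> GroundTruth:
    """Remove trabecular bone in the cavity and re-deposit debris in a shell.

    A fraction ``debris_retention`` of the removed trabecular mass is placed
    back into the distance-transform band of ``shell_thickness_mm`` around the
    cavity by converting marrow voxels to trabecular bone, nearest to the
    cavity surface first (seeded random tie-break).  The final voxel gets a
    fractional density so the mass budget is met exactly; if the shell cannot
    absorb the budget at full occupancy the surplus is recorded in
    ``unplaced_debris_mass_g``.
    """
    out = gt.clone()
    spacing = out.labels.spacing
    vox_cc = out.voxel_volume_cc
    cav = cavity_mask(out, stage)

    removed_trab = cav & (out.labels.voxels == TRABECULAR)
    removed_mass = float(out.density.voxels[removed_trab].sum() * vox_cc)
    out.density.voxels[cav] = 0.0
    out.labels.voxels[cav] = CAVITY

    budget = stage.debris_retention * removed_mass
    placed = 0.0
    if budget > 0:
        dist = distance_transform_edt(~cav, sampling=spacing)
        band = (dist > 0) & (dist <= stage.shell_thickness_mm)
        cand = band & (out.labels.voxels == MARROW)
        idx = np.flatnonzero(cand)
        rng = np.random.default_rng(stage.seed)
        order = np.lexsort((rng.random(idx.size), dist.ravel()[idx]))
        idx = idx[order]

        rho_t = _trabecular_density(gt)
        dm = rho_t * vox_cc  # bone mass added per fully converted voxel
        n_full = min(int(budget // dm), idx.size)
        flat_d = out.density.voxels.ravel()
        flat_l = out.labels.voxels.ravel()
        flat_d[idx[:n_full]] = rho_t
        flat_l[idx[:n_full]] = TRABECULAR
        placed = n_full * dm
        rem = budget - placed
        if rem > 1e-9 * max(dm, 1.0) and n_full < idx.size:
            flat_d[idx[n_full]] = rem / vox_cc
            flat_l[idx[n_full]] = TRABECULAR
            placed += rem

    out.unplaced_debris_mass_g = budget - placed
    out.bone_mass_g = out.compute_bone_mass()
    return out


def _trabecular_density(gt: GroundTruth) -> float:
    trab = gt.labels.voxels == TRABECULAR
    if not trab.any():
        raise GenerationError("ground truth contains no trabecular bone")
    return float(np.median(gt.density.voxels[trab]))


def retention_for_shell_bvtv_delta(
    gt: GroundTruth, stage: SurgicalStageParams, delta_pp: float
) -> float:
    """Debris retention that raises the interface-shell BV/TV by ``delta_pp``
    percentage points; raises if the removed mass cannot supply it."""
    cav = cavity_mask(gt, stage)
    dist = distance_transform_edt(~cav, sampling=gt.labels.spacing)
    band = (dist > 0) & (dist <= stage.shell_thickness_mm)
    tv = band & gt.labels.mask(MARROW, TRABECULAR)
    n_tv = int(tv.sum())
    n_marrow = int((band & (gt.labels.voxels == MARROW)).sum())
    n_flip = int(round(delta_pp / 100.0 * n_tv))
    if n_flip > n_marrow:
        raise GenerationError(
            f"shell has only {n_marrow} marrow voxels; +{delta_pp} points needs {n_flip}"
        )
    vox_cc = gt.voxel_volume_cc
    removed = cav & (gt.labels.voxels == TRABECULAR)
    removed_mass = float(gt.density.voxels[removed].sum() * vox_cc)
    needed = n_flip * _trabecular_density(gt) * vox_cc
    if removed_mass <= 0 or needed > removed_mass:
        raise GenerationError(
            f"broached mass {removed_mass:.3f} g cannot supply {needed:.3f} g of debris"
        )
    return needed / removed_mass


def insert_implant(gt: GroundTruth, stage: SurgicalStageParams) -> GroundTruth:
    """Fill the broached cavity with implant material; bone is untouched."""
    if not (gt.labels.voxels == CAVITY).any():
        raise GeometryError("insert_implant requires a broached (cavity-bearing) state")
    out = gt.clone()
    cav = out.labels.voxels == CAVITY
    out.labels.voxels[cav] = IMPLANT
    out.density.voxels[cav] = stage.implant_density_gcc
    out.bone_mass_g = out.compute_bone_mass()
    return out


# ---------------------------------------------------------------------------
# scanners


def scan_gain(protocol: ScanProtocol) -> float:
    m = INTENSITY_MODEL
    return (
        m["gain0"]
        * (protocol.voltage_kv / 100.0) ** m["voltage_exponent"]
        * (protocol.exposure_ms / 100.0) ** m["exposure_exponent"]
        * m["filter_factors"][protocol.filter]
    )


def scan_offset(protocol: ScanProtocol) -> float:
    return INTENSITY_MODEL["offset0"] * INTENSITY_MODEL["filter_factors"][protocol.filter]


def render_scan(gt: GroundTruth, protocol: ScanProtocol) -> VolumeImage:
    """Affine density-to-intensity rendering with additive Gaussian noise."""
    gain, offset = scan_gain(protocol), scan_offset(protocol)
    intensity = gain * gt.density.voxels + offset
    if protocol.noise_sd > 0:
        rng = np.random.default_rng(protocol.seed)
        intensity = intensity + rng.normal(0.0, protocol.noise_sd, size=intensity.shape)
    return VolumeImage(intensity, gt.density.spacing, gt.density.origin, "intensity")


def simulate_medical_ct(
    vol: VolumeImage,
    target_spacing_mm: float = 0.5,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> VolumeImage:
    """Degrade a micro-CT-resolution scan to clinical resolution.

    Block-averages to approximately ``target_spacing_mm`` voxels (factor =
    round(target / spacing) per axis) — the partial-volume effect — then adds
    fresh Gaussian noise.
    """
    if any(s >= target_spacing_mm for s in vol.spacing):
        raise ParameterError(
            f"input spacing {vol.spacing} is already at or coarser than "
            f"{target_spacing_mm} mm"
        )
    factors = tuple(max(int(round(target_spacing_mm / s)), 1) for s in vol.spacing)
    coarse = block_average_resample(vol, factors)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coarse.voxels = coarse.voxels + rng.normal(0.0, noise_sd, size=coarse.voxels.shape)
    return coarse
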