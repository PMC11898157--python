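"""Intensity-to-density calibration and its validation statistics.

The workflow: certify each phantom insert's density from its measured mass and
volume (``density = mass / volume``), regress certified density on the mean
segmented intensity of each insert (ordinary least squares, density on
intensity), and map whole volumes voxel-wise through the fitted line.
Agreement between two density maps of the same object is summarised
Bland–Altman style: bias, SD of the paired differences (precision), 1.96·SD
limits of agreement, Pearson correlation and the regression slope of one
measurement on the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .reference_data import INSERT_MEASUREMENTS
from .volume_io import LabelVolume, VolumeImage

__all__ = [
    "InsertMeasurement",
    "CalibrationLine",
    "AgreementStats",
    "insert_density_from_mass_volume",
    "build_insert_table",
    "default_insert_table",
    "fit_calibration",
    "map_density",
    "count_extrapolated",
    "agreement_stats",
]


def insert_density_from_mass_volume(mass_g: float, volume_mm3: float) -> float:
    """Density in g/cc from a mass in g and a volume in mm³.

    ``g/mm³ -> g/cc`` is a factor 1000.  Rounding happens only at report time.
    """
    if mass_g <= 0 or volume_mm3 <= 0:
        raise ParameterError(f"mass and volume must be positive, got {mass_g}, {volume_mm3}")
    return mass_g / volume_mm3 * 1000.0


@dataclass(frozen=True)
class InsertMeasurement:
    """Mass/volume certification of one insert by two independent methods."""

    material: str
    mass_g: float
    volume_laser_mm3: float
    volume_ct_mm3: float
    density_laser_gcc: float
    density_ct_gcc: float
    density_mean_gcc: float

    @classmethod
    def from_measurements(
        cls, material: str, mass_g: float, volume_laser_mm3: float, volume_ct_mm3: float
    ) -> "InsertMeasurement":
        d_laser = insert_density_from_mass_volume(mass_g, volume_laser_mm3)
        d_ct = insert_density_from_mass_volume(mass_g, volume_ct_mm3)
        return cls(
            material=material,
            mass_g=mass_g,
            volume_laser_mm3=volume_laser_mm3,
            volume_ct_mm3=volume_ct_mm3,
            density_laser_gcc=d_laser,
            density_ct_gcc=d_ct,
            density_mean_gcc=(d_laser + d_ct) / 2.0,  # mean of unrounded values
        )


def build_insert_table(
    materials: list[str],
    masses_g: list[float],
    volumes_laser_mm3: list[float],
    volumes_ct_mm3: list[float],
) -> pd.DataFrame:
    """Insert certification table with both per-method densities and their mean."""
    if not len(materials) == len(masses_g) == len(volumes_laser_mm3) == len(volumes_ct_mm3):
        raise ParameterError("material, mass and volume lists must have equal length")
    rows = [
        InsertMeasurement.from_measurements(m, g, vl, vc)
        for m, g, vl, vc in zip(materials, masses_g, volumes_laser_mm3, volumes_ct_mm3)
    ]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("material")


def default_insert_table() -> pd.DataFrame:
    """Certification table of the reference five-insert polymer phantom."""
    mats, _, masses, v_laser, v_ct = zip(*INSERT_MEASUREMENTS)
    return build_insert_table(list(mats), list(masses), list(v_laser), list(v_ct))


@dataclass
class CalibrationLine:
    """OLS fit of density (g/cc) on mean intensity: rho = slope * I + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    n: int
    density_range: tuple[float, float]

    def predict(self, intensity: np.ndarray | float) -> np.ndarray | float:
        return self.slope * intensity + self.intercept


def fit_calibration(points: list[tuple[float, float]]) -> CalibrationLine:
    """Ordinary least squares with intercept, solved from the normal equations.

    ``points`` are (mean insert intensity, certified density g/cc) pairs;
    at least two distinct intensities are required.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ParameterError("need >= 2 (intensity, density) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ParameterError("intensities are all identical; the line is undetermined")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    fitted = slope * x + intercept
    resid = y - fitted
    syy = float(((y - ym) ** 2).sum())
    r2 = 1.0 if syy == 0 else 1.0 - float((resid**2).sum()) / syy
    return CalibrationLine(
        slope=slope,
        intercept=intercept,
        r_squared=max(min(r2, 1.0), 0.0),
        residuals=resid,
        n=len(x),
        density_range=(float(y.min()), float(y.max())),
    )


def map_density(vol: VolumeImage, line: CalibrationLine) -> VolumeImage:
    """Voxel-wise density map, clamped below at 0 g/cc (physical floor)."""
    if vol.unit_tag != "intensity":
        raise ParameterError(f"map_density expects an intensity volume, got {vol.unit_tag!r}")
    rho = np.maximum(line.predict(vol.voxels.astype(np.float64)), 0.0)
    return VolumeImage(rho, vol.spacing, vol.origin, "g/cc")


def count_extrapolated(vol: VolumeImage, line: CalibrationLine) -> dict[str, float]:
    """How many voxels map outside the certified insert density range.

    Predictions inside [min insert density, max insert density] are
    interpolations; anything outside relies on extrapolating the line.
    """
    pred = line.predict(vol.voxels.astype(np.float64))
    lo, hi = line.density_range
    below = int((pred < lo).sum())
    above = int((pred > hi).sum())
    return {
        "below": below,
        "above": above,
        "fraction": (below + above) / pred.size,
    }


@dataclass
class AgreementStats:
    """Bland–Altman style agreement between paired density measurements."""

    bias_gcc: float
    sd_gcc: float
    loa_gcc: float  # 1.96 * sd, half-width of the limits of agreement
    pearson_r: float
    slope: float  # OLS slope of measurement 2 on measurement 1
    n: int


def agreement_stats(
    d1: VolumeImage, d2: VolumeImage, mask: LabelVolume | np.ndarray
) -> AgreementStats:
    """Voxel-paired agreement between two density maps over a mask."""
    if d1.shape != d2.shape:
        raise ParameterError(f"grid mismatch: {d1.shape} vs {d2.shape}")
    m = mask.voxels.astype(bool) if isinstance(mask, VolumeImage) else np.asarray(mask, bool)
    if m.shape != d1.shape:
        raise ParameterError("mask grid does not match the density volumes")
    a = d1.voxels[m].astype(np.float64)
    b = d2.voxels[m].astype(np.float64)
    if a.size < 2:
        raise ParameterError("mask must select at least 2 voxels")
    diff = b - a
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.array_equal(a, b):
        r = 1.0
    elif a.std() == 0 or b.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    var_a = float(a.var(ddof=0))
    slope = 1.0 if var_a == 0 else float(np.cov(a, b, ddof=0)[0, 1] / var_a)
    return AgreementStats(
        bias_gcc=bias,
        sd_gcc=sd,
        loa_gcc=1.96 * sd,
        pearson_r=r,
        slope=slope,
        n=int(a.size),
    )
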