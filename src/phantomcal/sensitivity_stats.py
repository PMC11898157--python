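"""Scan-parameter sensitivity study (full-factorial DOE) and group statistics.

The design crosses scanner voltage, exposure and filtration; for every
protocol the whole pipeline is re-run — render the phantom and the specimen,
segment the inserts, fit the calibration line, segment bone, map density —
and the bone-masked mean density is recorded.  Sensitivity is the sample
standard deviation σ of those per-protocol means, reported with the 6σ span;
a one-way ANOVA across per-scan voxel subsamples tests whether the protocol
shifts the mean density.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .density_calibration import fit_calibration, map_density
from .errors import ParameterError
from .segmentation import mean_intensity_per_label, segment_inserts, watershed_bone_segmentation
from .synthetic_ct import INSERT_BASE, GroundTruth, PhantomSpec, ScanProtocol, render_scan

__all__ = [
    "DOEResult",
    "AnovaResult",
    "doe_grid",
    "run_doe",
    "sensitivity_summary",
    "one_way_anova",
    "anova_null_rejection_rate",
    "stage_change_report",
]


@dataclass
class DOEResult:
    rows: pd.DataFrame  # one row per protocol: settings, mean density, variance
    sigma_gcc: float
    six_sigma_gcc: float


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: list[float]


def doe_grid(
    voltages_kv: list[float],
    exposures_ms: list[float],
    filters: list[str],
    voxel_size_mm: float = 0.07,
    noise_sd: float = 5.0,
    base_seed: int = 0,
) -> list[ScanProtocol]:
    """Full Cartesian product, voltage slowest and filter fastest, one
    distinct seed per protocol."""
    if not (voltages_kv and exposures_ms and filters):
        raise ParameterError("level lists must be non-empty")
    protocols = []
    for i, (v, e, f) in enumerate(itertools.product(voltages_kv, exposures_ms, filters)):
        protocols.append(
            ScanProtocol(
                voltage_kv=v,
                exposure_ms=e,
                filter=f,
                voxel_size_mm=voxel_size_mm,
                noise_sd=noise_sd,
                seed=base_seed + i,
            )
        )
    return protocols


def run_doe(
    protocols: list[ScanProtocol],
    phantom_gt: GroundTruth,
    specimen_gt: GroundTruth,
    spec: PhantomSpec,
    smoothing_sigma_mm: float = 0.2,
) -> DOEResult:
    """Re-run the full calibration+mapping pipeline per protocol.

    The ground truth is fixed across protocols (same specimen on the bed);
    only the scanner settings and noise realisations change.  Phantom and
    specimen renders of one protocol use decorrelated seeds derived from the
    protocol seed.
    """
    certified = [ins.density_gcc for ins in spec.inserts]
    rows = []
    for p in protocols:
        phantom_scan = render_scan(phantom_gt, p)
        insert_labels = segment_inserts(phantom_scan, spec)
        hists = mean_intensity_per_label(
            phantom_scan, insert_labels, [INSERT_BASE + k for k in range(len(certified))]
        )
        line = fit_calibration(
            [(hists[INSERT_BASE + k].mean, certified[k]) for k in range(len(certified))]
        )
        spec_scan = render_scan(specimen_gt, replace(p, seed=p.seed + 90_001))
        bone = watershed_bone_segmentation(spec_scan, smoothing_sigma_mm=smoothing_sigma_mm)
        rho = map_density(spec_scan, line)
        vals = rho.voxels[bone.voxels > 0]
        rows.append(
            {
                "voltage_kv": p.voltage_kv,
                "exposure_ms": p.exposure_ms,
                "filter": p.filter,
                "mean_density_gcc": float(vals.mean()),
                "variance_gcc2": float(vals.var(ddof=1)),
                "calibration_r2": line.r_squared,
            }
        )
    df = pd.DataFrame(rows)
    df.index = pd.RangeIndex(1, len(df) + 1, name="scan")
    sigma, six_sigma = sensitivity_summary(df["mean_density_gcc"].tolist())
    return DOEResult(rows=df, sigma_gcc=sigma, six_sigma_gcc=six_sigma)


def sensitivity_summary(means_gcc: list[float]) -> tuple[float, float]:
    """Sample standard deviation (n−1 denominator) of the per-protocol mean
    densities, and its 6σ span."""
    m = np.asarray(means_gcc, dtype=np.float64)
    if m.size < 2:
        raise ParameterError("need at least 2 mean densities")
    sigma = float(m.std(ddof=1))
    return sigma, 6.0 * sigma


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across sample groups."""
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ParameterError("each group needs at least 2 observations")
    f, p = stats.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        group_means=[float(a.mean()) for a in arrays],
    )


def anova_null_rejection_rate(
    n_groups: int = 3,
    n_per_group: int = 12,
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null replicates (all groups from one normal distribution)
    the ANOVA rejects at level ``alpha`` — a calibration check that should
    land near ``alpha``."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        data = rng.standard_normal((n_groups, n_per_group))
        res = one_way_anova(list(data))
        rejections += res.p_value < alpha
    return rejections / n_replicates


def stage_change_report(
    zone_summaries: dict[str, pd.DataFrame],
    shell_bvtv: dict[str, float] | None = None,
    baseline: str = "pre",
) -> pd.DataFrame:
    """Zone-wise density change of each stage relative to the baseline stage.

    ``zone_summaries`` maps stage name to a :func:`zone_density_summary`
    table; ``shell_bvtv`` optionally maps stage name to the interface-shell
    BV/TV, reported as a change in percentage points.  Zones that are empty
    in either stage are excluded from the aggregate rows; the aggregate
    min/max/mean across zones are attached in ``DataFrame.attrs["aggregate"]``.
    """
    if baseline not in zone_summaries:
        raise ParameterError(f"baseline stage {baseline!r} missing from summaries")
    base = zone_summaries[baseline]
    records = []
    for stage, summ in zone_summaries.items():
        if stage == baseline:
            continue
        for zone in summ.index:
            d_bone = (
                summ.loc[zone, "mean_density_bone_gcc"]
                - base.loc[zone, "mean_density_bone_gcc"]
            )
            d_roi = (
                summ.loc[zone, "mean_density_roi_gcc"] - base.loc[zone, "mean_density_roi_gcc"]
            )
            rec = {
                "stage": stage,
                "zone": zone,
                "delta_density_bone_gcc": d_bone,
                "delta_density_roi_gcc": d_roi,
                "delta_bvtv_pp": 100.0 * (summ.loc[zone, "bvtv"] - base.loc[zone, "bvtv"]),
            }
            if shell_bvtv is not None and stage in shell_bvtv and baseline in shell_bvtv:
                rec["shell_delta_bvtv_pp"] = 100.0 * (shell_bvtv[stage] - shell_bvtv[baseline])
            records.append(rec)
    out = pd.DataFrame(records)
    valid = out.dropna(subset=["delta_density_roi_gcc"])
    out.attrs["aggregate"] = {
        "min_delta_density_roi_gcc": float(valid["delta_density_roi_gcc"].min()),
        "max_delta_density_roi_gcc": float(valid["delta_density_roi_gcc"].max()),
        "mean_delta_density_roi_gcc": float(valid["delta_density_roi_gcc"].mean()),
    }
    return out
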