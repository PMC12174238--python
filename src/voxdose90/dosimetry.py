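"""Local-deposition voxel dosimetry for Y-90 radioembolization.

The local deposition method (LDM) assumes every voxel's activity deposits
its complete decay energy locally.  Over full decay, Y-90 releases
49.67 J per GBq, so a voxel of mass ``m`` kg holding ``A`` GBq absorbs
``D = 49.67 * A / m`` Gy.  Activity maps come from count images via the
patient-relative conversion: counts are scaled so the field-of-view total
equals the net administered activity (administered minus residual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import CompartmentSet, ScalarVolume

#: Energy released per unit activity by Y-90 integrated over complete decay.
Y90_J_PER_GBQ = 49.67

#: Default soft-tissue density assumed for liver and tumor voxels.
DEFAULT_DENSITY_G_PER_ML = 1.03


@dataclass
class CalibrationInput:
    """Counts, the field-of-view they represent, and the net activity."""

    counts: ScalarVolume
    net_activity_GBq: float
    fov_mask: np.ndarray | None = None  # None: the whole grid is the FOV

    def __post_init__(self):
        if self.counts.quantity != "counts":
            raise ValueError("calibration input must be a counts volume")
        if self.net_activity_GBq <= 0:
            raise ValueError("net_activity_GBq must be positive")
        if self.fov_mask is not None:
            m = np.asarray(self.fov_mask).astype(bool)
            if m.shape != tuple(self.counts.grid.shape):
                raise ValueError("fov_mask shape does not match the counts grid")
            self.fov_mask = m


def calibrate_activity(cal: CalibrationInput) -> ScalarVolume:
    """Patient-relative conversion of counts to a GBq activity map.

    Each in-FOV voxel receives ``counts * net / total(counts in FOV)``;
    voxels outside the FOV are set to zero.  The output total equals the
    net administered activity by construction.
    """
    values = cal.counts.values
    fov = cal.fov_mask if cal.fov_mask is not None else np.ones(values.shape, bool)
    total = float(values[fov].sum())
    if total <= 0:
        raise ValueError("cannot calibrate empty field: zero counts in the FOV")
    activity = np.where(fov, values * (cal.net_activity_GBq / total), 0.0)
    return ScalarVolume(cal.counts.grid, activity, "activity_GBq")


def ldm_dose(
    activity: ScalarVolume, density_g_per_mL: float = DEFAULT_DENSITY_G_PER_ML
) -> ScalarVolume:
    """Convert an activity map to an absorbed-dose map by local deposition.

    ``D_voxel [Gy] = 49.67 [J/GBq] * A_voxel [GBq] / m_voxel [kg]`` with
    ``m_voxel = density * voxel_volume_mL / 1000``.
    """
    if activity.quantity != "activity_GBq":
        raise ValueError("ldm_dose expects an activity_GBq volume")
    if density_g_per_mL <= 0:
        raise ValueError("density must be positive")
    voxel_mass_kg = density_g_per_mL * activity.grid.voxel_volume_mL / 1000.0
    if voxel_mass_kg <= 0:
        raise ValueError("non-positive voxel volume")
    dose = Y90_J_PER_GBQ * activity.values / voxel_mass_kg
    return ScalarVolume(activity.grid, dose, "dose_Gy")


def _role_doses(dose: ScalarVolume, comp: CompartmentSet, role: str) -> np.ndarray:
    if dose.quantity != "dose_Gy":
        raise ValueError("expected a dose_Gy volume")
    if tuple(dose.grid.shape) != tuple(comp.grid.shape):
        raise ValueError("dose and compartments live on different grids")
    mask = comp.require(role, nonempty=True)
    return dose.values[mask]


def mean_dose(dose: ScalarVolume, comp: CompartmentSet, role: str) -> float:
    """Mean absorbed dose (Gy) over one compartment.

    With uniform voxel size and density the mass-weighted mean reduces to
    the arithmetic mean of voxel doses.
    """
    return float(_role_doses(dose, comp, role).mean())


def tn_ratio(
    dose: ScalarVolume,
    comp: CompartmentSet,
    tumor_role: str = "perfused_tumor",
    normal_role: str = "perfused_normal",
) -> float:
    """Tumor-to-normal ratio: mean tumor dose over mean perfused-normal dose."""
    normal = mean_dose(dose, comp, normal_role)
    if normal <= 0:
        raise ValueError("undefined T/N: perfused-normal mean dose is zero")
    return mean_dose(dose, comp, tumor_role) / normal


def dvh(
    dose: ScalarVolume, comp: CompartmentSet, role: str, n_bins: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative dose-volume histogram for one compartment.

    Returns ``(dose_Gy, volume_percent)`` where ``volume_percent[i]`` is the
    exact fraction of compartment voxels receiving at least ``dose_Gy[i]``,
    evaluated on a uniform grid from 0 to the maximum voxel dose.  The curve
    starts at 100% and is non-increasing.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    doses = np.sort(_role_doses(dose, comp, role))
    grid = np.linspace(0.0, float(doses[-1]), int(n_bins))
    # fraction of voxels >= threshold, from the sorted array
    n = doses.size
    at_least = n - np.searchsorted(doses, grid, side="left")
    return grid, 100.0 * at_least / n


def d_metric(dose: ScalarVolume, comp: CompartmentSet, role: str, x: float) -> float:
    """D_x: the dose (Gy) received by at least x% of the compartment volume.

    Computed from exact order statistics: with voxel doses sorted in
    descending order ``d(1) >= ... >= d(n)``, ``D_x = d(ceil(x*n/100))``,
    so ``D_100`` is the minimum voxel dose.  No interpolation is applied.
    """
    if not 0 < x <= 100:
        raise ValueError("x must lie in (0, 100]")
    doses = np.sort(_role_doses(dose, comp, role))[::-1]
    k = math.ceil(x * doses.size / 100.0)
    return float(doses[k - 1])


def v_metric(
    dose: ScalarVolume, comp: CompartmentSet, role: str, threshold_Gy: float
) -> float:
    """V_d: percent of the compartment volume receiving at least ``threshold_Gy``."""
    doses = _role_doses(dose, comp, role)
    return 100.0 * float((doses >= threshold_Gy).mean())


@dataclass
class RoleDoseStats:
    mean_dose_Gy: float
    volume_mL: float
    min_dose_Gy: float
    max_dose_Gy: float
    d_metrics_Gy: dict = field(default_factory=dict)  # x% -> Gy
    v_metrics_percent: dict = field(default_factory=dict)  # Gy -> % volume
    dvh_dose_Gy: np.ndarray | None = None
    dvh_volume_percent: np.ndarray | None = None


@dataclass
class DoseReport:
    """Per-compartment dose summary for one imaging modality."""

    modality: str
    roles: dict  # role -> RoleDoseStats
    tn_ratio: float | None = None

    def to_dict(self, include_dvh: bool = False) -> dict:
        out: dict = {"modality": self.modality, "tn_ratio": self.tn_ratio, "roles": {}}
        for role, st in self.roles.items():
            entry = {
                "mean_dose_Gy": st.mean_dose_Gy,
                "volume_mL": st.volume_mL,
                "min_dose_Gy": st.min_dose_Gy,
                "max_dose_Gy": st.max_dose_Gy,
                "d_metrics_Gy": {str(k): v for k, v in st.d_metrics_Gy.items()},
                "v_metrics_percent": {str(k): v for k, v in st.v_metrics_percent.items()},
            }
            if include_dvh and st.dvh_dose_Gy is not None:
                entry["dvh"] = {
                    "dose_Gy": st.dvh_dose_Gy.tolist(),
                    "volume_percent": st.dvh_volume_percent.tolist(),
                }
            out["roles"][role] = entry
        return out


def dose_report(
    dose: ScalarVolume,
    comp: CompartmentSet,
    roles: tuple | None = None,
    d_levels: tuple = (10, 50, 90),
    v_levels_Gy: tuple = (),
    n_bins: int = 1000,
    modality: str = "",
    tumor_role: str = "perfused_tumor",
    normal_role: str = "perfused_normal",
) -> DoseReport:
    """Assemble mean doses, DVHs and D/V metrics for a set of compartments.

    D metrics are always taken from exact order statistics, never read off
    the binned DVH export.
    """
    if roles is None:
        roles = tuple(r for r in comp.roles if comp.masks[r].any())
    stats = {}
    for role in roles:
        doses = _role_doses(dose, comp, role)
        grid, percent = dvh(dose, comp, role, n_bins=n_bins)
        stats[role] = RoleDoseStats(
            mean_dose_Gy=float(doses.mean()),
            volume_mL=comp.volume_mL(role),
            min_dose_Gy=float(doses.min()),
            max_dose_Gy=float(doses.max()),
            d_metrics_Gy={x: d_metric(dose, comp, role, x) for x in d_levels},
            v_metrics_percent={g: v_metric(dose, comp, role, g) for g in v_levels_Gy},
            dvh_dose_Gy=grid,
            dvh_volume_percent=percent,
        )
    tn = None
    if tumor_role in comp and normal_role in comp:
        if comp.masks[tumor_role].any() and comp.masks[normal_role].any():
            try:
                tn = tn_ratio(dose, comp, tumor_role, normal_role)
            except ValueError:
                tn = None
    return DoseReport(modality=modality, roles=stats, tn_ratio=tn)


@dataclass(frozen=True)
class LungShuntResult:
    lsf: float
    gm_lung: float
    gm_liver: float


def lung_shunt_fraction(
    anterior: np.ndarray,
    posterior: np.ndarray,
    lung_roi: np.ndarray,
    liver_roi: np.ndarray,
) -> LungShuntResult:
    """Lung shunt fraction from anterior/posterior planar ROI counts.

    For each organ the geometric mean of the two conjugate views is taken
    on the ROI totals, ``gm = sqrt(anterior_total * posterior_total)``, and
    ``LSF = gm_lung / (gm_lung + gm_liver)``.
    """
    ant = np.asarray(anterior, dtype=float)
    post = np.asarray(posterior, dtype=float)
    lung = np.asarray(lung_roi).astype(bool)
    liver = np.asarray(liver_roi).astype(bool)
    if ant.shape != post.shape or ant.shape != lung.shape or ant.shape != liver.shape:
        raise ValueError("planar images and ROI masks must share one shape")
    gm_lung = math.sqrt(float(ant[lung].sum()) * float(post[lung].sum()))
    liver_a, liver_p = float(ant[liver].sum()), float(post[liver].sum())
    if liver_a <= 0 or liver_p <= 0:
        raise ValueError("zero liver counts on a planar view; cannot form LSF")
    gm_liver = math.sqrt(liver_a * liver_p)
    return LungShuntResult(lsf=gm_lung / (gm_lung + gm_liver), gm_lung=gm_lung, gm_liver=gm_liver)


def lung_dose(net_activity_GBq: float, lsf: float, lung_mass_kg: float = 1.0) -> float:
    """Mean lung dose (Gy) from the shunted activity fraction.

    Single-compartment local deposition applied to the lungs:
    ``49.67 * net * LSF / lung_mass``.
    """
    if lung_mass_kg <= 0:
        raise ValueError("lung_mass_kg must be positive")
    if not 0 <= lsf <= 1:
        raise ValueError("lsf must lie in [0, 1]")
    return Y90_J_PER_GBQ * net_activity_GBq * lsf / lung_mass_kg
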