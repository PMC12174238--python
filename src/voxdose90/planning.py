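"""Multicompartment activity prescription for Y-90 radioembolization.

Given per-compartment dose-per-unit-activity factors from a predictive
(MAA) count image, the planner picks the administered activity that
reaches the tumor target dose when possible while never exceeding the
normal-tissue ceiling or the lung limits.  Doses are linear in activity
under local deposition, so each constraint is a simple activity bound.

Default targets and limits by device:

* glass: tumor 250 Gy (HCC) / 200 Gy (metastasis); whole-liver normal
  tissue limited to a configurable ceiling in the 50-90 Gy window
  (default 90, with a warning once the plan exceeds 50);
* resin: tumor 100 Gy; perfused normal tissue limited to 40 Gy;
* lungs: 30 Gy per treatment and 50 Gy cumulative, either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CompartmentSet, ScalarVolume
from .dosimetry import (
    CalibrationInput,
    DEFAULT_DENSITY_G_PER_ML,
    Y90_J_PER_GBQ,
    calibrate_activity,
    ldm_dose,
    mean_dose,
)

GLASS_NORMAL_WINDOW_GY = (50.0, 90.0)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PlanConstraints:
    """Dose targets and limits for one device/disease combination."""

    device: str
    disease: str
    tumor_target_Gy: float
    normal_limit_Gy: float
    lung_limit_Gy: float = 30.0
    lung_cumulative_limit_Gy: float = 50.0
    prior_lung_dose_Gy: float = 0.0

    def __post_init__(self):
        if self.device not in ("glass", "resin"):
            raise ValueError("device must be 'glass' or 'resin'")
        if self.disease not in ("HCC", "metastasis"):
            raise ValueError("disease must be 'HCC' or 'metastasis'")
        for name in ("tumor_target_Gy", "normal_limit_Gy", "lung_limit_Gy",
                     "lung_cumulative_limit_Gy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prior_lung_dose_Gy < 0:
            raise ValueError("prior_lung_dose_Gy must be >= 0")

    @property
    def normal_role(self) -> str:
        """Glass constrains whole-liver normal tissue, resin the perfused normal."""
        return "normal_liver" if self.device == "glass" else "perfused_normal"

    @classmethod
    def defaults(
        cls,
        device: str,
        disease: str = "metastasis",
        normal_limit_Gy: float | None = None,
        prior_lung_dose_Gy: float = 0.0,
    ) -> "PlanConstraints":
        if device == "glass":
            target = 250.0 if disease == "HCC" else 200.0
            limit = GLASS_NORMAL_WINDOW_GY[1] if normal_limit_Gy is None else normal_limit_Gy
            if not GLASS_NORMAL_WINDOW_GY[0] <= limit <= GLASS_NORMAL_WINDOW_GY[1]:
                raise ValueError(
                    "glass normal-liver ceiling must lie in the "
                    f"{GLASS_NORMAL_WINDOW_GY} Gy window"
                )
        else:
            target = 100.0
            limit = 40.0 if normal_limit_Gy is None else normal_limit_Gy
        return cls(
            device=device,
            disease=disease,
            tumor_target_Gy=target,
            normal_limit_Gy=limit,
            prior_lung_dose_Gy=prior_lung_dose_Gy,
        )


@dataclass
class PlanResult:
    prescribed_GBq: float
    predicted_doses_Gy: dict
    binding_constraint: str
    tumor_target_met: bool
    lung_dose_Gy: float
    feasible: bool
    reason: str = ""
    warnings: list = field(default_factory=list)


def dose_per_GBq(
    predictive_counts: ScalarVolume,
    comp: CompartmentSet,
    density_g_per_mL: float = DEFAULT_DENSITY_G_PER_ML,
    fov_mask: np.ndarray | None = None,
) -> dict:
    """Per-compartment mean dose per unit administered activity (Gy/GBq).

    Calibrates the predictive counts to 1 GBq (patient-relative), runs the
    local-deposition conversion, and returns the mean dose of every
    non-empty compartment.  The factors are invariant to any overall
    rescaling of the counts.
    """
    cal = CalibrationInput(predictive_counts, net_activity_GBq=1.0, fov_mask=fov_mask)
    dose = ldm_dose(calibrate_activity(cal), density_g_per_mL)
    return {
        role: mean_dose(dose, comp, role)
        for role in comp.roles
        if comp.masks[role].any()
    }


def prescribe(
    s: dict,
    constraints: PlanConstraints,
    lsf: float = 0.0,
    lung_mass_kg: float = 1.0,
    tumor_role: str | None = None,
) -> PlanResult:
    """Choose the administered activity under target and limit constraints.

    ``s`` maps compartment roles to Gy per GBq.  The tumor target activity
    is ``target / s_tumor``; the limit activity is the tightest of the
    normal-tissue ceiling and the remaining lung headroom
    ``min(per-treatment limit, cumulative limit - prior lung dose)``.  The
    prescription is the smaller of target and limit activity; when the
    target is out of reach the limit activity is prescribed and
    ``tumor_target_met`` is False.  Constraint ties are reported in the
    fixed priority order tumor_target, normal_tissue, lung.
    """
    if not 0 <= lsf < 1:
        raise ValueError("lsf must lie in [0, 1)")
    if lung_mass_kg <= 0:
        raise ValueError("lung_mass_kg must be positive")
    if tumor_role is None:
        tumor_role = "perfused_tumor" if "perfused_tumor" in s else "tumor"
    if tumor_role not in s or s[tumor_role] <= 0:
        raise ValueError(f"tumor factor s[{tumor_role!r}] must be present and positive")
    normal_role = constraints.normal_role
    if normal_role not in s or s[normal_role] <= 0:
        raise ValueError(f"normal-tissue factor s[{normal_role!r}] must be present and positive")

    s_lung = Y90_J_PER_GBQ * lsf / lung_mass_kg  # Gy per GBq administered
    lung_headroom = min(
        constraints.lung_limit_Gy,
        constraints.lung_cumulative_limit_Gy - constraints.prior_lung_dose_Gy,
    )
    if lung_headroom <= 0:
        return PlanResult(
            prescribed_GBq=0.0,
            predicted_doses_Gy={role: 0.0 for role in s},
            binding_constraint="lung",
            tumor_target_met=False,
            lung_dose_Gy=0.0,
            feasible=False,
            reason="cumulative lung limit exhausted; treatment not performed",
        )

    a_target = constraints.tumor_target_Gy / s[tumor_role]
    a_normal = constraints.normal_limit_Gy / s[normal_role]
    a_lung = lung_headroom / s_lung if s_lung > 0 else np.inf
    a_limit = min(a_normal, a_lung)
    prescribed = min(a_target, a_limit)

    # fixed priority order for ties: tumor target, then normal tissue, then lung
    if prescribed >= a_target - _TIE_TOL:
        binding = "tumor_target"
    elif a_normal <= a_lung:
        binding = "normal_tissue"
    else:
        binding = "lung"

    predicted = {role: factor * prescribed for role, factor in s.items()}
    result = PlanResult(
        prescribed_GBq=prescribed,
        predicted_doses_Gy=predicted,
        binding_constraint=binding,
        tumor_target_met=prescribed >= a_target - _TIE_TOL,
        lung_dose_Gy=s_lung * prescribed,
        feasible=prescribed > 0,
        reason="" if prescribed > 0 else "no deliverable activity under constraints",
    )
    if (
        constraints.device == "glass"
        and predicted.get(normal_role, 0.0) > GLASS_NORMAL_WINDOW_GY[0]
    ):
        result.warnings.append(
            "predicted whole-liver normal dose exceeds the 50 Gy floor of "
            "the glass 50-90 Gy window"
        )
    return result
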