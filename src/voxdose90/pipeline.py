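"""End-to-end workflow: simulate, shunt, dose, plan, compare.

Mirrors the clinical sequence: estimate the lung shunt fraction from
planar views, bring the predictive (SPECT-like) and verification
(PET-like) count images into a common frame, convert both to dose with
the same segmentations, derive the activity prescription from the
predictive image, and (optionally) run the paired agreement statistics
over a cohort CSV.  Every artifact carries provenance (config hash, seed,
package version) and the run is deterministic for fixed seeds.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io as vio
from .core import RigidTransform, resample
from .dosimetry import (
    CalibrationInput,
    calibrate_activity,
    dose_report,
    ldm_dose,
    lung_dose,
    lung_shunt_fraction,
)
from .phantom import (
    PET_PSF_FWHM_MM,
    SPECT_PSF_FWHM_MM,
    PhantomSpec,
    make_phantom,
    pet_grid,
    simulate_modality,
    simulate_planar,
    spect_grid,
)
from .planning import PlanConstraints, dose_per_GBq, prescribe
from .stats import PairedMetric, agreement_report

RUN_CONFIG_KEYS = {
    "seed",
    "phantom",
    "noise",
    "counts_per_GBq",
    "spect_psf_fwhm_mm",
    "pet_psf_fwhm_mm",
    "disease",
    "density_g_per_mL",
    "lung_mass_kg",
    "normal_limit_Gy",
    "prior_lung_dose_Gy",
    "registration",
    "icc_definition",
    "ba_method",
    "pairs_csv",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


def _stage(log, name):
    log.append(f"stage: {name}")


def registration_from_config(reg: dict | None) -> RigidTransform:
    """Build the SPECT-to-reference rigid transform from config parameters.

    ``euler_deg_zyx`` are intrinsic rotations in degrees applied in Z, Y,
    X order; ``translation_mm`` is the world-frame shift.
    """
    if not reg:
        return RigidTransform.identity()
    vio.validated_config(reg, {"euler_deg_zyx", "translation_mm"}, "registration")
    return RigidTransform.from_euler_zyx(
        reg.get("euler_deg_zyx", (0.0, 0.0, 0.0)),
        reg.get("translation_mm", (0.0, 0.0, 0.0)),
    )


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full synthetic workflow and write its artifact directory."""
    vio.validated_config(config, RUN_CONFIG_KEYS, "run")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []
    seed = int(config.get("seed", 0))
    prov = vio.provenance(config, seed)

    def fail(stage: str, exc: Exception):
        log.append(f"stage: {stage} FAILED: {exc}")
        (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
        raise StageError(f"[{stage}] {exc}") from exc

    # --- phantom -----------------------------------------------------
    try:
        _stage(log, "phantom")
        phantom_cfg = dict(config.get("phantom", {}))
        phantom_cfg.setdefault("seed", seed)
        spec = PhantomSpec(**vio._tuplify(phantom_cfg))
        truth = make_phantom(spec)
        vio.write_volume(truth.activity, out / "truth_activity.nii.gz")
        vio.write_compartments(truth.compartments, out / "masks.nii.gz")
        vio.write_json({**prov, "spec": asdict(spec), "metrics": _jsonable(truth.metrics)},
                       out / "truth.json")
    except StageError:
        raise
    except Exception as exc:
        fail("phantom", exc)

    noise = config.get("noise", "poisson")
    cpg = float(config.get("counts_per_GBq", 1.0e6))
    density = float(config.get("density_g_per_mL", spec.density_g_per_mL))
    lung_mass = float(config.get("lung_mass_kg", 1.0))

    # --- lung shunt from planar views --------------------------------
    try:
        _stage(log, "lung_shunt")
        planar = simulate_planar(truth, noise=noise, counts_per_GBq=cpg, seed=seed + 1)
        shunt = lung_shunt_fraction(
            planar.anterior, planar.posterior, planar.lung_roi, planar.liver_roi
        )
        vio.write_planar(planar.anterior, planar.pixel_mm, out / "planar_anterior.nii.gz")
        vio.write_planar(planar.posterior, planar.pixel_mm, out / "planar_posterior.nii.gz")
        vio.write_planar(planar.lung_roi.astype(float), planar.pixel_mm,
                         out / "planar_lung_roi.nii.gz")
        vio.write_planar(planar.liver_roi.astype(float), planar.pixel_mm,
                         out / "planar_liver_roi.nii.gz")
        vio.write_json(
            {**prov, "lsf": shunt.lsf, "gm_lung": shunt.gm_lung,
             "gm_liver": shunt.gm_liver,
             "lung_dose_Gy_at_net": lung_dose(spec.net_activity_GBq, shunt.lsf, lung_mass)},
            out / "lsf.json",
        )
    except StageError:
        raise
    except Exception as exc:
        fail("lung_shunt", exc)

    # --- emission scans ----------------------------------------------
    try:
        _stage(log, "acquisition")
        spect_counts = simulate_modality(
            truth, spect_grid(truth),
            float(config.get("spect_psf_fwhm_mm", SPECT_PSF_FWHM_MM)),
            noise=noise, counts_per_GBq=cpg, seed=seed + 2,
        )
        pet_counts = simulate_modality(
            truth, pet_grid(truth),
            float(config.get("pet_psf_fwhm_mm", PET_PSF_FWHM_MM)),
            noise=noise, counts_per_GBq=cpg, seed=seed + 3,
        )
        vio.write_volume(spect_counts, out / "spect_counts.nii.gz")
        vio.write_volume(pet_counts, out / "pet_counts.nii.gz")
    except StageError:
        raise
    except Exception as exc:
        fail("acquisition", exc)

    # --- dosimetry on the common frame -------------------------------
    transform = registration_from_config(config.get("registration"))
    hepatic_GBq = spec.net_activity_GBq * (1.0 - shunt.lsf)
    reports = {}
    try:
        _stage(log, "dosimetry")
        for label, counts, tfm in (
            ("spect", spect_counts, transform),
            ("pet", pet_counts, RigidTransform.identity()),
        ):
            common = resample(counts, tfm, truth.activity.grid, "conserve_total")
            activity = calibrate_activity(CalibrationInput(common, hepatic_GBq))
            dose = ldm_dose(activity, density)
            report = dose_report(dose, truth.compartments,
                                 roles=tuple(r for r in truth.compartments.roles
                                             if r != "lungs"),
                                 modality=label)
            reports[label] = report
            vio.write_json({**prov, **report.to_dict()}, out / f"dose_{label}.json")
            for role in ("perfused_tumor", "perfused_normal"):
                if role in report.roles:
                    st = report.roles[role]
                    vio.write_dvh_csv(st.dvh_dose_Gy, st.dvh_volume_percent,
                                      out / f"dvh_{label}_{role}.csv")
        log.append(
            "dosimetry: tn_spect=%.4f tn_pet=%.4f"
            % (reports["spect"].tn_ratio or np.nan, reports["pet"].tn_ratio or np.nan)
        )
    except StageError:
        raise
    except Exception as exc:
        fail("dosimetry", exc)

    # --- planning from the predictive image --------------------------
    try:
        _stage(log, "planning")
        common_spect = resample(spect_counts, transform, truth.activity.grid,
                                "conserve_total")
        s = dose_per_GBq(common_spect, truth.compartments, density)
        constraints = PlanConstraints.defaults(
            spec.device,
            config.get("disease", "metastasis"),
            normal_limit_Gy=config.get("normal_limit_Gy"),
            prior_lung_dose_Gy=float(config.get("prior_lung_dose_Gy", 0.0)),
        )
        plan = prescribe(s, constraints, lsf=shunt.lsf, lung_mass_kg=lung_mass)
        vio.write_json(
            {**prov, "constraints": asdict(constraints),
             "dose_per_GBq": _jsonable(s), "plan": _jsonable(asdict(plan))},
            out / "plan.json",
        )
    except StageError:
        raise
    except Exception as exc:
        fail("planning", exc)

    # --- cohort agreement statistics (optional) ----------------------
    agreement = None
    if config.get("pairs_csv"):
        try:
            _stage(log, "compare")
            pairs = read_pairs_csv(config["pairs_csv"])
            agreement = agreement_report(
                pairs,
                icc_definition=config.get("icc_definition", "absolute_agreement"),
                ba_method=config.get("ba_method", "nonparametric"),
            )
            vio.write_json({**prov, **_jsonable(agreement)}, out / "agreement.json")
        except StageError:
            raise
        except Exception as exc:
            fail("compare", exc)

    log.append("done")
    (out / "pipeline_log.txt").write_text("\n".join(log) + "\n")
    return {
        "truth": truth,
        "lsf": shunt,
        "reports": reports,
        "plan": plan,
        "agreement": agreement,
        "out_dir": out,
    }


def read_pairs_csv(path):
    """Read paired cohort metrics from CSV.

    Expected columns: ``metric, stratum, case_id, value_spect, value_pet``;
    one :class:`PairedMetric` per (metric, stratum) ordered by case_id.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"metric", "stratum", "case_id", "value_spect", "value_pet"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairs CSV is missing columns {sorted(missing)}")
    pairs = []
    for (metric, stratum), grp in df.groupby(["metric", "stratum"], sort=True):
        grp = grp.sort_values("case_id")
        pairs.append(
            PairedMetric(
                metric=str(metric),
                stratum=str(stratum),
                x=tuple(grp["value_spect"].astype(float)),
                y=tuple(grp["value_pet"].astype(float)),
            )
        )
    return pairs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
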