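"""Digital liver phantoms with known dosimetric ground truth.

A phantom is an ellipsoidal liver holding one or more spherical tumors,
split into a perfused and a non-perfused part by a single sagittal plane
(mirroring unilobar treatments), plus a lung slab superior to the liver
receiving the shunted activity fraction.  Activity is piecewise uniform:
one concentration in perfused normal tissue and ``true_TN`` times that in
perfused tumor, so the tumor-to-normal ratio, compartment mean doses,
D-metrics and lung shunt fraction are all known exactly before any
simulated acquisition degrades them.

Acquisitions are emulated by count-conserving resampling onto a
modality-specific grid, isotropic Gaussian blur (the point-spread
function), scaling to an expected count budget, and optional Poisson
noise.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CompartmentSet, RigidTransform, ScalarVolume, VoxelGrid, resample
from .dosimetry import (
    DEFAULT_DENSITY_G_PER_ML,
    d_metric,
    ldm_dose,
    mean_dose,
    tn_ratio,
)

#: Emission-scan voxel spacings (mm) for the two emulated tomographs.
SPECT_SPACING_MM = (4.42, 4.42, 2.50)
PET_SPACING_MM = (2.34, 2.34, 2.78)

#: Default system blur, stated configuration of this generator (FWHM, mm).
SPECT_PSF_FWHM_MM = 12.0
PET_PSF_FWHM_MM = 5.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, activity and acquisition ground truth for one phantom.

    Defaults are sized to a typical unilobar radioembolization case: a
    ~1.7 L liver, a ~110 mL tumor, a perfused fraction around 0.63, a
    tumor-to-normal concentration ratio of 3.75 and 2.35 GBq net activity.
    """

    liver_semiaxes_mm: tuple = (90.0, 60.0, 75.0)
    tumor_centers_mm: tuple = ((-35.0, 0.0, 10.0),)
    tumor_radii_mm: tuple = (30.0,)
    true_TN: float = 3.75
    perfused_fraction: float = 0.625
    net_activity_GBq: float = 2.35
    lung_shunt_true: float = 0.05
    device: str = "glass"
    seed: int = 0
    grid_spacing_mm: tuple = (2.5, 2.5, 2.5)
    heterogeneity_sigma: float = 0.0  # log-normal voxel texture, off by default
    density_g_per_mL: float = DEFAULT_DENSITY_G_PER_ML
    lung_gap_mm: float = 10.0
    lung_thickness_mm: float = 50.0

    def __post_init__(self):
        if len(self.tumor_centers_mm) != len(self.tumor_radii_mm):
            raise ValueError("tumor centers and radii must have equal length")
        if any(r <= 0 for r in self.tumor_radii_mm):
            raise ValueError("tumor radii must be positive")
        if self.true_TN < 0:
            raise ValueError("true_TN must be non-negative")
        if not 0 < self.perfused_fraction <= 1:
            raise ValueError("perfused_fraction must lie in (0, 1]")
        if self.net_activity_GBq <= 0:
            raise ValueError("net_activity_GBq must be positive")
        if not 0 <= self.lung_shunt_true < 1:
            raise ValueError("lung_shunt_true must lie in [0, 1)")
        if self.device not in ("glass", "resin"):
            raise ValueError("device must be 'glass' or 'resin'")


@dataclass
class PhantomTruth:
    """A phantom's noise-free activity, compartments, and true metrics.

    ``activity`` holds the hepatic activity only; its total equals
    ``net_activity_GBq * (1 - lung_shunt_true)``.  ``metrics`` stores the
    ground-truth values every downstream estimator should recover on the
    clean path: per-compartment mean doses, T/N, tumor D10/D50/D90, LSF.
    """

    spec: PhantomSpec
    activity: ScalarVolume
    compartments: CompartmentSet
    liver_activity_GBq: float
    metrics: dict = field(default_factory=dict)


def _build_grid(spec: PhantomSpec) -> VoxelGrid:
    a, b, c = spec.liver_semiaxes_mm
    margin = 12.0
    lung_top = c + spec.lung_gap_mm + spec.lung_thickness_mm
    lo = (-a - margin, -b - margin, -c - margin)
    hi = (a + margin, b + margin, lung_top + margin)
    sp = spec.grid_spacing_mm
    shape = tuple(int(np.ceil((h - l) / s)) for l, h, s in zip(lo, hi, sp))
    origin = tuple(l + s / 2.0 for l, s in zip(lo, sp))
    return VoxelGrid(shape=shape, spacing_mm=sp, origin_mm=origin)


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the phantom and compute its ground-truth dosimetry.

    Deterministic for a fixed ``spec.seed`` (the seed only matters when
    ``heterogeneity_sigma > 0``).
    """
    grid = _build_grid(spec)
    X, Y, Z = grid.voxel_centers()
    a, b, c = spec.liver_semiaxes_mm

    liver = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    if not liver.any():
        raise ValueError("liver mask is empty; check semiaxes vs grid spacing")

    tumor = np.zeros(grid.shape, bool)
    for (cx, cy, cz), r in zip(spec.tumor_centers_mm, spec.tumor_radii_mm):
        if (cx / a) ** 2 + (cy / b) ** 2 + (cz / c) ** 2 > 1.0:
            raise ValueError("tumor outside liver: center beyond the liver ellipsoid")
        tumor |= (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= r**2
    if (tumor & ~liver).any():
        raise ValueError("tumor outside liver: every tumor must lie inside the liver")

    # Sagittal split: the perfused lobe is the left-of-plane fraction of
    # liver voxels, matching a unilobar injection territory.
    x_liver = X[liver]
    threshold = np.quantile(x_liver, spec.perfused_fraction)
    perfused = liver & (X <= threshold)
    if not perfused.any():
        raise ValueError("perfused region is empty")

    normal = liver & ~tumor
    masks = {
        "whole_liver": liver,
        "tumor": tumor,
        "normal_liver": normal,
        "perfused": perfused,
        "perfused_tumor": perfused & tumor,
        "perfused_normal": perfused & normal,
        "lungs": _lung_slab(spec, X, Y, Z),
    }
    comp = CompartmentSet(grid, masks)
    comp.check_identities()

    # Piecewise-uniform concentrations: c in perfused normal, TN*c in
    # perfused tumor, zero elsewhere; then scale so the hepatic total is
    # the administered activity minus the shunted fraction.
    weights = np.zeros(grid.shape)
    weights[masks["perfused_normal"]] = 1.0
    weights[masks["perfused_tumor"]] = spec.true_TN
    if spec.heterogeneity_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sig = spec.heterogeneity_sigma
        texture = rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=grid.shape)
        weights *= texture
    total_w = weights.sum()
    if total_w <= 0:
        raise ValueError("no activity in the perfused region")
    liver_activity = spec.net_activity_GBq * (1.0 - spec.lung_shunt_true)
    activity = ScalarVolume(grid, weights * (liver_activity / total_w), "activity_GBq")

    truth = PhantomTruth(
        spec=spec,
        activity=activity,
        compartments=comp,
        liver_activity_GBq=liver_activity,
    )
    truth.metrics = _truth_metrics(truth)
    return truth


def _lung_slab(spec: PhantomSpec, X, Y, Z) -> np.ndarray:
    a, b, c = spec.liver_semiaxes_mm
    z_lo = c + spec.lung_gap_mm
    z_hi = z_lo + spec.lung_thickness_mm
    return (
        (Z > z_lo)
        & (Z <= z_hi)
        & (np.abs(X) <= 0.9 * a)
        & (np.abs(Y) <= 0.9 * b)
    )


def _truth_metrics(truth: PhantomTruth) -> dict:
    spec = truth.spec
    dose = ldm_dose(truth.activity, spec.density_g_per_mL)
    comp = truth.compartments
    means = {}
    for role in comp.roles:
        if role != "lungs" and comp.masks[role].any():
            means[role] = mean_dose(dose, comp, role)
    metrics: dict = {"mean_dose_Gy": means, "lsf": spec.lung_shunt_true}
    if comp.masks["perfused_tumor"].any() and comp.masks["perfused_normal"].any():
        metrics["tn_ratio"] = tn_ratio(dose, comp)
        metrics["d_metrics_Gy"] = {
            "perfused_tumor": {
                x: d_metric(dose, comp, "perfused_tumor", x) for x in (10, 50, 90)
            }
        }
    return metrics


def spect_grid(truth: PhantomTruth) -> VoxelGrid:
    """SPECT-like acquisition grid covering the phantom extent."""
    return truth.activity.grid.covering(SPECT_SPACING_MM)


def pet_grid(truth: PhantomTruth) -> VoxelGrid:
    """PET-like acquisition grid covering the phantom extent."""
    return truth.activity.grid.covering(PET_SPACING_MM)


def _blur_conserving(values: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian blur whose kernel is renormalized so the total is conserved."""
    total = values.sum()
    out = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="constant", cval=0.0)
    out_total = out.sum()
    if total > 0 and out_total > 0:
        out *= total / out_total
    return np.clip(out, 0.0, None)


def simulate_modality(
    truth: PhantomTruth,
    grid: VoxelGrid,
    psf_fwhm_mm: float,
    noise: str = "none",
    counts_per_GBq: float = 1.0e6,
    seed: int = 0,
) -> ScalarVolume:
    """Emulate a tomographic count image of the hepatic activity.

    The noise-free truth is resampled with total conservation onto the
    acquisition grid, blurred with an isotropic Gaussian point-spread
    function of the given FWHM, scaled to expected counts, and Poisson
    sampled if requested.  Bit-identical for identical seeds.
    """
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be non-negative")
    if counts_per_GBq <= 0:
        raise ValueError("counts_per_GBq must be positive")
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    resampled = resample(truth.activity, RigidTransform.identity(), grid, "conserve_total")
    values = resampled.values
    if psf_fwhm_mm > 0:
        sigma_vox = tuple(
            psf_fwhm_mm * _FWHM_TO_SIGMA / s for s in grid.spacing_mm
        )
        values = _blur_conserving(values, sigma_vox)
    expected = values * counts_per_GBq
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        expected = rng.poisson(expected).astype(float)
    return ScalarVolume(grid, expected, "counts")


@dataclass
class PlanarStudy:
    """Conjugate anterior/posterior planar count images with organ ROIs.

    The posterior view is the anterior projection mirrored about the
    patient's left-right axis; the ROI masks are left-right symmetric so
    the same mask applies to both views.
    """

    anterior: np.ndarray
    posterior: np.ndarray
    lung_roi: np.ndarray
    liver_roi: np.ndarray
    pixel_mm: tuple


def simulate_planar(
    truth: PhantomTruth,
    pixel_mm: tuple | None = None,
    noise: str = "none",
    counts_per_GBq: float = 1.0e6,
    seed: int = 0,
) -> PlanarStudy:
    """Project the phantom (liver plus shunted lung activity) to 2-D views.

    The lung slab holds ``lung_shunt_true`` of the net activity, placed
    uniformly.  Projection is a straight sum along the anterior-posterior
    axis (no attenuation), so the geometric-mean shunt estimator is exact
    on the noise-free path.  ``pixel_mm`` requests integer rebinning of
    the native grid resolution.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    spec = truth.spec
    grid = truth.activity.grid
    act3d = truth.activity.values.copy()
    lungs = truth.compartments.require("lungs", nonempty=True)
    lung_activity = spec.net_activity_GBq * spec.lung_shunt_true
    if lung_activity > 0:
        act3d[lungs] += lung_activity / lungs.sum()

    expected = act3d.sum(axis=1) * counts_per_GBq  # (x, z) image
    liver_proj = truth.compartments.require("whole_liver").any(axis=1)
    lung_proj = lungs.any(axis=1)
    # symmetrize so the same ROI is valid on the mirrored posterior view
    liver_roi = liver_proj | liver_proj[::-1]
    lung_roi = lung_proj | lung_proj[::-1]
    if (liver_roi & lung_roi).any():
        raise ValueError("lung and liver ROIs overlap; increase the lung gap")

    ant_expected = expected
    post_expected = expected[::-1]
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        anterior = rng.poisson(ant_expected).astype(float)
        posterior = rng.poisson(post_expected).astype(float)
    else:
        anterior = ant_expected.copy()
        posterior = post_expected.copy()

    px = (grid.spacing_mm[0], grid.spacing_mm[2])
    if pixel_mm is not None:
        fx = max(1, int(round(pixel_mm[0] / px[0])))
        fz = max(1, int(round(pixel_mm[1] / px[1])))
        anterior = _rebin(anterior, fx, fz)
        posterior = _rebin(posterior, fx, fz)
        lung_roi = _rebin(lung_roi.astype(float), fx, fz) > 0
        liver_roi = _rebin(liver_roi.astype(float), fx, fz) > 0
        px = (px[0] * fx, px[1] * fz)
    return PlanarStudy(anterior, posterior, lung_roi, liver_roi, px)


def _rebin(img: np.ndarray, fx: int, fz: int) -> np.ndarray:
    nx = -(-img.shape[0] // fx) * fx
    nz = -(-img.shape[1] // fz) * fz
    padded = np.zeros((nx, nz), dtype=float)
    padded[: img.shape[0], : img.shape[1]] = img
    return padded.reshape(nx // fx, fx, nz // fz, fz).sum(axis=(1, 3))
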