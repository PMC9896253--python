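"""Synthetic inputs for the whole pipeline: head-CT-like phantoms with known
tissue composition, matched probabilistic atlases, and registry-style patient
cohorts.

The phantom head is deliberately geometric rather than anatomical — an
ellipsoidal intracranial space with a cortical gray-matter ribbon at the
surface, a sulcal CSF rim folded just beneath it, a white-matter core, and
two ellipsoidal ventricle-like CSF cavities.  The estimator under test uses
only Hounsfield-unit statistics and coarse spatial priors, so this geometry
is sufficient to exercise it while the true per-voxel tissue fractions (and
hence the true CSF/ICV ratio) remain known exactly.  A single ``atrophy``
knob in [0, 1] scales both the sulcal rim thickness and the ventricle size,
mapping monotonically to the true CSF/ICV ratio.

The cohort generator mirrors a national EVT registry: covariates with the
codings of the prediction models, outcome drawn from a logistic model whose
coefficients default to the published effect sizes, a small fraction of
deaths with unknown cause, and defaults calibrated so the marginal event
rate is ~6% and the group mean CSF/ICV ratios are ~9% (edema) vs ~14%
(no edema).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit

from . import cohort as _cohort
from .errors import (
    DegeneratePhantomError,
    InvalidRateError,
    InvalidSpecError,
    InvalidTransformError,
    ShapeError,
)

TISSUES = ("csf", "gm", "wm")
CLASSES = TISSUES + ("background",)
BACKGROUND_HU = -1000.0

DEFAULT_HU_MEANS = {"csf": 5.0, "gm": 40.0, "wm": 30.0}
DEFAULT_HU_SDS = {"csf": 4.0, "gm": 5.0, "wm": 5.0}


# ---------------------------------------------------------------------------
# Phantom image generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head phantom.

    ``atrophy`` in [0, 1] scales the sulcal CSF rim thickness (up to
    ``rim_max_mm``) and the ventricle semi-axes; 0 disables both CSF
    compartments entirely.  ``pve_blur_sigma`` (mm) smooths the binary
    anatomy into fractional tissue maps, emulating the scanner's partial
    volume effect; ``noise_sd`` (HU) is additive Gaussian image noise.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    atrophy: float = 0.5
    pve_blur_sigma: float = 1.0
    noise_sd: float = 5.0
    hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    hu_sds: dict = field(default_factory=lambda: dict(DEFAULT_HU_SDS))
    seed: int = 0
    # geometry (mm)
    head_semiaxes: tuple[float, float, float] = (70.0, 80.0, 65.0)
    gm_thickness_mm: float = 10.0
    rim_max_mm: float = 6.0
    ventricle_semiaxes_max: tuple[float, float, float] = (18.0, 30.0, 14.0)
    ventricle_offset_mm: float = 16.0
    supersample: int = 3

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be three positive ints: {self.grid_shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InvalidSpecError(f"voxel_size must be three positive mm: {self.voxel_size}")
        if not 0.0 <= self.atrophy <= 1.0:
            raise InvalidSpecError(f"atrophy must lie in [0, 1]: {self.atrophy}")
        if self.pve_blur_sigma < 0 or self.noise_sd < 0:
            raise InvalidSpecError("pve_blur_sigma and noise_sd must be nonnegative")
        for t in TISSUES:
            if t not in self.hu_means or t not in self.hu_sds:
                raise InvalidSpecError(f"hu_means/hu_sds must cover tissue {t!r}")
            if self.hu_sds[t] <= 0:
                raise InvalidSpecError(f"hu_sds[{t!r}] must be strictly positive")
        if self.supersample < 1:
            raise InvalidSpecError("supersample must be >= 1")


@dataclass
class TissueMap:
    """Ground-truth per-voxel fractional composition over (csf, gm, wm, background)."""

    fractions: np.ndarray  # shape (X, Y, Z, 4), rows sum to 1
    voxel_size: tuple[float, float, float]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def class_index(self, name: str) -> int:
        return CLASSES.index(name)


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units with voxel geometry."""

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray  # 4x4 voxel-to-world (mm)


@dataclass
class ProbAtlas:
    """Probabilistic tissue priors over (csf, gm, wm); remainder is extracranial."""

    probs: np.ndarray  # shape (X, Y, Z, 3)
    voxel_size: tuple[float, float, float]
    intracranial_mask_threshold: float = 0.5
    misalignment: np.ndarray = field(default_factory=lambda: np.eye(4))


@dataclass(frozen=True)
class VolumeTruth:
    csf_ml: float
    gm_ml: float
    wm_ml: float
    icv_ml: float
    ratio_pct: float


def _grid_affine(voxel_size) -> np.ndarray:
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    return aff


def make_tissue_map(spec: PhantomSpec) -> TissueMap:
    """Build the ground-truth fractional tissue map of a phantom head.

    Anatomy is evaluated at ``supersample``-fold subvoxel resolution and
    averaged to voxel fractions, then smoothed with ``pve_blur_sigma`` so the
    map is fractional (partial-volume) rather than binary.  The construction
    is fully deterministic.
    """
    spec.validate()
    ss = int(spec.supersample)
    shape = tuple(int(s) for s in spec.grid_shape)
    vs = np.asarray(spec.voxel_size, dtype=float)
    fov = np.array(shape) * vs
    center = fov / 2.0
    semi = np.asarray(spec.head_semiaxes, dtype=float)
    abar = float(np.mean(semi))

    axes_mm = [
        (np.arange(shape[i] * ss) + 0.5) * (vs[i] / ss) - center[i] for i in range(3)
    ]
    x = axes_mm[0][:, None, None]
    y = axes_mm[1][None, :, None]
    z = axes_mm[2][None, None, :]
    rho = np.sqrt((x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2)

    gm_rho = spec.gm_thickness_mm / abar
    rim_rho = spec.atrophy * spec.rim_max_mm / abar

    labels = np.zeros(rho.shape, dtype=np.uint8)  # 0=bg, 1=csf, 2=gm, 3=wm
    inside = rho <= 1.0
    labels[inside] = 3
    labels[inside & (rho > 1.0 - gm_rho - rim_rho)] = 1  # sulcal CSF rim
    labels[inside & (rho > 1.0 - gm_rho)] = 2            # cortical GM ribbon

    vsemi = spec.atrophy * np.asarray(spec.ventricle_semiaxes_max, dtype=float)
    if np.all(vsemi > 0):
        for sign in (-1.0, 1.0):
            vx = x - sign * spec.ventricle_offset_mm
            vrho = np.sqrt(
                (vx / vsemi[0]) ** 2 + (y / vsemi[1]) ** 2 + (z / vsemi[2]) ** 2
            )
            labels[(vrho <= 1.0) & inside] = 1

    fractions = np.empty(shape + (4,), dtype=float)
    codes = {1: 0, 2: 1, 3: 2, 0: 3}  # label -> class channel (csf, gm, wm, background)
    for label, chan in codes.items():
        mask = (labels == label).astype(float)
        mask = mask.reshape(shape[0], ss, shape[1], ss, shape[2], ss)
        fractions[..., chan] = mask.mean(axis=(1, 3, 5))

    if spec.pve_blur_sigma > 0:
        sigma_vox = [spec.pve_blur_sigma / vs[i] for i in range(3)]
        for c in range(4):
            fractions[..., c] = ndimage.gaussian_filter(
                fractions[..., c], sigma=sigma_vox, mode="nearest"
            )
    np.clip(fractions, 0.0, 1.0, out=fractions)
    fractions /= fractions.sum(axis=-1, keepdims=True)
    return TissueMap(fractions=fractions, voxel_size=tuple(float(v) for v in vs))


def true_volumes(tmap: TissueMap) -> VolumeTruth:
    """Ground-truth tissue volumes (mL) and the true CSF/ICV ratio (%)."""
    vol = tmap.voxel_volume_ml
    csf = float(tmap.fractions[..., 0].sum()) * vol
    gm = float(tmap.fractions[..., 1].sum()) * vol
    wm = float(tmap.fractions[..., 2].sum()) * vol
    icv = csf + gm + wm
    if icv <= 0:
        raise DegeneratePhantomError("phantom has zero intracranial volume")
    return VolumeTruth(csf, gm, wm, icv, 100.0 * csf / icv)


def render_ct(tmap: TissueMap, spec: PhantomSpec) -> CTVolume:
    """Render a noisy CT volume from a tissue map.

    Per-voxel HU is the fraction-weighted mix of the class HU means
    (background at -1000 HU) plus Gaussian noise of SD ``noise_sd``; the
    draw is seeded by ``spec.seed``.
    """
    spec.validate()
    if tmap.fractions.shape[:3] != tuple(spec.grid_shape):
        raise ShapeError(
            f"tissue map {tmap.fractions.shape[:3]} does not match spec grid {spec.grid_shape}"
        )
    means = np.array([spec.hu_means[t] for t in TISSUES] + [BACKGROUND_HU])
    hu = tmap.fractions @ means
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
    return CTVolume(
        values=hu,
        voxel_size=tmap.voxel_size,
        affine=_grid_affine(tmap.voxel_size),
    )


def _world_to_voxel_affine(M_mm: np.ndarray, voxel_size) -> tuple[np.ndarray, np.ndarray]:
    """Convert a world (mm) affine to an index-space (matrix, offset) pair.

    Voxel centers sit at (i + 1/2) * voxel_size, so S: i -> mm has a half-voxel
    offset; the index map is S^-1 M S.
    """
    vs = np.asarray(voxel_size, dtype=float)
    A = M_mm[:3, :3]
    t = M_mm[:3, 3]
    Avox = A * vs[None, :] / vs[:, None]
    # offset in index space: S^-1 (A (0.5*vs) + t) - 0.5
    off = (A @ (0.5 * vs) + t) / vs - 0.5
    return Avox, off


def make_atlas(
    tmap: TissueMap,
    blur_sigma: float = 1.25,
    misalign: np.ndarray | None = None,
    intracranial_mask_threshold: float = 0.5,
) -> ProbAtlas:
    """Derive a probabilistic atlas from the ground-truth tissue map.

    The tissue fractions are smoothed by ``blur_sigma`` (mm) — emulating the
    population averaging of a real template — then resampled through the
    world-space affine ``misalign`` (atlas(v) samples the truth at
    ``misalign @ v``).  The applied misalignment is recorded so registration
    recovery can be verified.
    """
    if misalign is None:
        misalign = np.eye(4)
    misalign = np.asarray(misalign, dtype=float)
    if misalign.shape != (4, 4) or abs(np.linalg.det(misalign[:3, :3])) < 1e-12:
        raise InvalidTransformError("misalign must be an invertible 4x4 affine")

    vs = np.asarray(tmap.voxel_size, dtype=float)
    probs = np.array(tmap.fractions[..., :3], dtype=float, copy=True)
    if blur_sigma > 0:
        sigma_vox = [blur_sigma / vs[i] for i in range(3)]
        for c in range(3):
            probs[..., c] = ndimage.gaussian_filter(probs[..., c], sigma=sigma_vox, mode="nearest")
    if not np.allclose(misalign, np.eye(4)):
        Avox, off = _world_to_voxel_affine(misalign, vs)
        out = np.empty_like(probs)
        for c in range(3):
            out[..., c] = ndimage.affine_transform(
                probs[..., c], Avox, offset=off, order=1, mode="constant", cval=0.0
            )
        probs = out
    np.clip(probs, 0.0, 1.0, out=probs)
    return ProbAtlas(
        probs=probs,
        voxel_size=tmap.voxel_size,
        intracranial_mask_threshold=intracranial_mask_threshold,
        misalignment=misalign,
    )


def atrophy_for_ratio(
    target_ratio_pct: float,
    spec: PhantomSpec | None = None,
    tol: float = 0.02,
) -> float:
    """Invert the atrophy -> true-ratio map by bisection on the given spec."""
    spec = spec or PhantomSpec()

    def f(a: float) -> float:
        return true_volumes(make_tissue_map(replace(spec, atrophy=a))).ratio_pct - target_ratio_pct

    lo, hi = 0.0, 1.0
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo <= 0 <= f_hi):
        raise InvalidSpecError(
            f"target ratio {target_ratio_pct}% outside achievable range "
            f"[{f_lo + target_ratio_pct:.1f}, {f_hi + target_ratio_pct:.1f}]%"
        )
    return float(optimize.brentq(f, lo, hi, xtol=tol / 10.0))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateDistributions:
    """Marginal covariate distributions of the simulated registry.

    Age is Normal(68, 14) years; the CSF/ICV percentage is Normal with a
    configurable correlation to age (older brains hold more CSF).  The
    CSF/ICV location/scale defaults were calibrated once, together with the
    numerically solved intercept, so that the outcome model with the
    published effect sizes yields ~6% prevalence and group CSF/ICV means of
    ~9% vs ~14%.
    """

    age_mean: float = 68.0
    age_sd: float = 14.0
    nihss_mean: float = 16.0
    nihss_sd: float = 6.0
    aspects_mean: float = 8.2
    aspects_sd: float = 1.8
    ica_p: float = 0.27
    collateral_probs: tuple[float, ...] = (0.06, 0.33, 0.38, 0.23)
    otg_mean: float = 210.0
    otg_sd: float = 65.0
    otg_range: tuple[float, float] = (60.0, 390.0)
    etici_probs: tuple[float, ...] = (0.10, 0.05, 0.25, 0.15, 0.15, 0.13, 0.17)
    one_plane_p: float = 0.03
    csf_icv_mean: float = 13.72
    csf_icv_sd: float = 5.75
    age_csf_corr: float = 0.3

    def validate(self) -> None:
        for name, p in (("ica_p", self.ica_p), ("one_plane_p", self.one_plane_p)):
            if not 0.0 <= p <= 1.0:
                raise InvalidSpecError(f"{name} must lie in [0, 1]")
        for name, probs in (
            ("collateral_probs", self.collateral_probs),
            ("etici_probs", self.etici_probs),
        ):
            probs = np.asarray(probs, dtype=float)
            if np.any(probs < 0) or not math.isclose(float(probs.sum()), 1.0, abs_tol=1e-9):
                raise InvalidSpecError(f"{name} must be nonnegative and sum to 1")
        if not -1.0 < self.age_csf_corr < 1.0:
            raise InvalidSpecError("age_csf_corr must lie in (-1, 1)")


# log odds ratios of the published extended model (per coded unit)
EXTENDED_LOG_ORS = {
    "age_dec": math.log(1.1),
    "nihss": math.log(1.1),
    "aspects_inv": math.log(1.1),
    "ica_occl": math.log(1.9),
    "collat_inv": math.log(2.8),
    "otg_h": math.log(1.3),
    "unsucc_reperf": math.log(1.9),
    "csf_icv_inv": math.log(1.2),
}

# log odds ratios of the published basic model
BASIC_LOG_ORS = {
    "age_dec": math.log(1.5),
    "nihss": math.log(1.1),
    "aspects_inv": math.log(1.2),
    "ica_occl": math.log(2.2),
    "collat_inv": math.log(2.5),
    "otg_h": math.log(1.3),
    "unsucc_reperf": math.log(1.6),
}

TARGET_PREVALENCE = 40.0 / 683.0
DEFAULT_DEATH_UNKNOWN_RATE = 18.0 / 701.0


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a registry-like cohort.

    ``coefficients`` holds the log-odds per coded predictor (the key
    ``"intercept"`` included); predictors missing from the dict contribute
    nothing to the linear predictor.  A ``death_unknown_rate`` fraction of
    patients is relabelled as death-with-unknown-cause independently of the
    covariates.
    """

    n: int = 683
    coefficients: dict = field(default_factory=dict)
    covariates: CovariateDistributions = field(default_factory=CovariateDistributions)
    death_unknown_rate: float = DEFAULT_DEATH_UNKNOWN_RATE
    missingness_rates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise InvalidSpecError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.death_unknown_rate <= 1.0:
            raise InvalidSpecError("death_unknown_rate must lie in [0, 1]")
        for k, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise InvalidRateError(f"missingness rate for {k!r} outside [0, 1]")
        self.covariates.validate()


def _draw_covariates(dists: CovariateDistributions, n: int, rng) -> pd.DataFrame:
    d = dists
    age = rng.normal(d.age_mean, d.age_sd, n)
    nihss = np.clip(np.round(rng.normal(d.nihss_mean, d.nihss_sd, n)), 0, 42)
    aspects = np.clip(np.round(rng.normal(d.aspects_mean, d.aspects_sd, n)), 0, 10)
    ica = (rng.random(n) < d.ica_p).astype(int)
    collateral = rng.choice(4, size=n, p=np.asarray(d.collateral_probs))
    otg = np.clip(rng.normal(d.otg_mean, d.otg_sd, n), *d.otg_range)
    etici = rng.choice(list(_cohort.ETICI_GRADES), size=n, p=np.asarray(d.etici_probs))
    one_plane = (rng.random(n) < d.one_plane_p).astype(int)
    # CSF/ICV correlated with age through a Gaussian copula on the age draw
    eps = rng.normal(0.0, 1.0, n)
    csf = (
        d.csf_icv_mean
        + d.age_csf_corr * d.csf_icv_sd * (age - d.age_mean) / d.age_sd
        + math.sqrt(1.0 - d.age_csf_corr**2) * d.csf_icv_sd * eps
    )
    csf = np.clip(csf, 0.0, 100.0)
    success = np.array(
        [_cohort.is_successful_reperfusion(g, bool(p)) for g, p in zip(etici, one_plane)],
        dtype=int,
    )
    return pd.DataFrame(
        {
            "age_yr": age,
            "nihss": nihss,
            "aspects": aspects,
            "ica_occlusion": ica,
            "collateral_score": collateral,
            "otg_minutes": otg,
            "etici": etici,
            "dsa_one_plane": one_plane,
            "reperfusion_success": success,
            "csf_icv_pct": csf,
        }
    )


def _linear_predictor(coded: pd.DataFrame, coefficients: dict) -> np.ndarray:
    lp = np.full(len(coded), float(coefficients.get("intercept", 0.0)))
    for name, beta in coefficients.items():
        if name == "intercept":
            continue
        if name not in coded.columns:
            raise InvalidSpecError(f"coefficient for unknown predictor {name!r}")
        lp = lp + float(beta) * coded[name].to_numpy(dtype=float)
    return lp


_INTERCEPT_CACHE: dict = {}


def calibrate_intercept(
    coefficients: dict,
    dists: CovariateDistributions | None = None,
    target_prevalence: float = TARGET_PREVALENCE,
    n_mc: int = 200_000,
    seed: int = 20140316,
) -> float:
    """Solve the intercept so the marginal event rate matches the target.

    Uses a fixed Monte-Carlo sample of covariates and Brent root finding on
    the mean predicted probability; deterministic for given arguments.
    """
    dists = dists or CovariateDistributions()
    key = (tuple(sorted((k, round(v, 12)) for k, v in coefficients.items() if k != "intercept")),
           dists, round(target_prevalence, 9), n_mc, seed)
    if key in _INTERCEPT_CACHE:
        return _INTERCEPT_CACHE[key]
    rng = np.random.default_rng(seed)
    raw = _draw_covariates(dists, n_mc, rng)
    coded = _cohort.code_covariates(raw)
    slopes = {k: v for k, v in coefficients.items() if k != "intercept"}
    lp0 = _linear_predictor(coded, slopes)

    def f(c: float) -> float:
        return float(np.mean(expit(c + lp0))) - target_prevalence

    c = float(optimize.brentq(f, -15.0, 5.0, xtol=1e-10))
    _INTERCEPT_CACHE[key] = c
    return c


def default_cohort_spec(
    model: str = "extended",
    n: int = 683,
    seed: int = 0,
    death_unknown_rate: float = DEFAULT_DEATH_UNKNOWN_RATE,
) -> CohortSpec:
    """The calibrated default cohort: published log-odds plus solved intercept."""
    if model == "extended":
        slopes = dict(EXTENDED_LOG_ORS)
    elif model == "basic":
        slopes = dict(BASIC_LOG_ORS)
    else:
        raise InvalidSpecError(f"model must be 'basic' or 'extended', got {model!r}")
    coefs = dict(slopes)
    coefs["intercept"] = calibrate_intercept(slopes)
    return CohortSpec(n=n, coefficients=coefs, seed=seed, death_unknown_rate=death_unknown_rate)


def _clinical_fields(outcome: np.ndarray, rng) -> pd.DataFrame:
    """Draw surgery/death/triad/midline-shift fields consistent with the outcome.

    Edema patients split between the surgery-or-death criterion and the
    triad-plus-shift criterion; non-edema patients get sub-threshold shifts
    (with a rare non-edema decompressive surgery, mirroring e.g. surgery for
    symptomatic hemorrhage); unknown-cause deaths carry a death flag with no
    attribution.
    """
    n = len(outcome)
    surgery = np.zeros(n, dtype=int)
    death = np.zeros(n, dtype=int)
    attributed = np.zeros(n, dtype=int)
    triad = np.zeros(n, dtype=int)
    shift = rng.uniform(0.0, 4.5, n)
    mrs = np.clip(np.round(rng.normal(3.0, 1.8, n)), 0, 6).astype(int)

    edema = outcome == _cohort.MALIGNANT_EDEMA
    idx = np.flatnonzero(edema)
    branch_a = rng.random(len(idx)) < 0.65  # surgery/death attributed to edema
    for i, a in zip(idx, branch_a):
        if a:
            if rng.random() < 0.5:
                surgery[i] = 1
            else:
                death[i] = 1
            attributed[i] = 1
            if rng.random() < 0.5:
                triad[i] = 1
                shift[i] = rng.uniform(6.0, 16.0)
        else:
            triad[i] = 1
            shift[i] = rng.uniform(6.0, 16.0)
        mrs[i] = min(6, int(round(rng.normal(5.4, 0.8))))
        if death[i]:
            mrs[i] = 6

    unknown = outcome == _cohort.DEATH_UNKNOWN
    death[unknown] = 1
    mrs[unknown] = 6

    no_ed = outcome == _cohort.NO_MALIGNANT_EDEMA
    rare_surgery = no_ed & (rng.random(n) < 0.0015)
    surgery[rare_surgery] = 1

    return pd.DataFrame(
        {
            "surgery_7d": surgery,
            "death_7d": death,
            "edema_attributed": attributed,
            "clinical_triad": triad,
            "midline_shift_mm": shift,
            "mrs_90d": mrs,
        }
    )


def simulate_cohort(cspec: CohortSpec) -> pd.DataFrame:
    """Simulate a registry-like cohort table.

    Covariates are drawn from the spec's marginal distributions, the outcome
    from a Bernoulli on the logistic linear predictor, and a
    ``death_unknown_rate`` fraction is relabelled death-with-unknown-cause
    independently of the covariates.  Clinical flag fields are generated so
    that :func:`csficv.cohort.classify_edema` reproduces the simulated
    category exactly.  Deterministic for a fixed seed.
    """
    cspec.validate()
    rng = np.random.default_rng(cspec.seed)
    raw = _draw_covariates(cspec.covariates, cspec.n, rng)
    coded = _cohort.code_covariates(raw)
    lp = _linear_predictor(coded, cspec.coefficients)
    y = rng.random(cspec.n) < expit(lp)

    outcome = np.where(y, _cohort.MALIGNANT_EDEMA, _cohort.NO_MALIGNANT_EDEMA).astype(object)
    unknown = rng.random(cspec.n) < cspec.death_unknown_rate
    outcome[unknown] = _cohort.DEATH_UNKNOWN

    clinical = _clinical_fields(outcome, rng)
    table = pd.concat([raw, clinical], axis=1)
    table.insert(0, "patient_id", np.arange(cspec.n))
    table["outcome"] = outcome
    if cspec.missingness_rates:
        table = inject_missingness(table, cspec.missingness_rates, seed=int(rng.integers(2**31)))
    return table


def inject_missingness(table: pd.DataFrame, rates: dict, seed: int = 0) -> pd.DataFrame:
    """Mask covariate values completely at random at the given per-column rates.

    The outcome (and the clinical fields that define it) are never masked.
    """
    protected = {"outcome", "surgery_7d", "death_7d", "edema_attributed",
                 "clinical_triad", "patient_id"}
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise InvalidRateError(f"rate for {col!r} outside [0, 1]: {rate}")
        if col in protected:
            raise InvalidRateError(f"column {col!r} must not be masked")
        if col not in out.columns or rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        out[col] = table[col].where(~mask)  # upcasts to float/object with NaN
    return out
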