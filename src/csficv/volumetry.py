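"""Automatic CSF/ICV measurement from noncontrast head CT.

The measurement never segments individual voxels.  Instead, a probabilistic
tissue atlas provides coarse spatial priors: every voxel inside the atlas'
intracranial mask contributes its volume to three Hounsfield-unit histograms,
weighted by the atlas probability of CSF, gray matter and white matter.
Gaussian mixtures are then fitted jointly — each tissue's components against
its own atlas-attributed histogram, all components together against the
pooled intracranial histogram — with per-tissue initial values taken from
single-Gaussian moment fits.  Because the fit is expressed in volume units,
the area under each tissue's components *is* that tissue's volume; the three
areas sum to the intracranial volume (ICV) and the CSF area over the ICV is
the CSF/ICV ratio.  This makes the volume estimate robust to image noise:
noise widens the Gaussians but leaves their areas nearly unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm

import SimpleITK as sitk

from .errors import (
    ConstraintViolationError,
    DegenerateFitError,
    EmptyMaskError,
    InvalidSpecError,
    RegistrationError,
    ShapeError,
    StageError,
)
from .phantom import BACKGROUND_HU, DEFAULT_HU_MEANS, DEFAULT_HU_SDS, CTVolume, ProbAtlas, TISSUES


@dataclass(frozen=True)
class HistogramConfig:
    """HU binning for the volume-vs-HU histograms.

    The range brackets CSF/GM/WM with generous margin below water so that
    air-contaminated boundary voxels land in regular bins far away from any
    plausible tissue component instead of polluting the CSF region.
    """

    hu_min: float = -100.0
    hu_max: float = 80.0
    bin_width: float = 1.0

    def validate(self) -> None:
        if not self.hu_min < self.hu_max:
            raise InvalidSpecError("hu_min must be < hu_max")
        if self.bin_width <= 0:
            raise InvalidSpecError("bin_width must be positive")

    @property
    def edges(self) -> np.ndarray:
        n = int(np.ceil((self.hu_max - self.hu_min) / self.bin_width))
        return self.hu_min + self.bin_width * np.arange(n + 1)


@dataclass(frozen=True)
class MixtureFitConfig:
    """Gaussian-mixture fit settings.

    One component per tissue is the minimal model; the defaults use extra
    components because partial-volume voxels smear each tissue's histogram
    into a continuum that a single Gaussian cannot absorb without biasing
    its area: CSF carries a bridge toward brain HU, and gray/white matter
    carry bridges toward CSF and (at the brain surface) toward air, which is
    why their mean bounds extend well below their peak locations.  The
    component ordering mean_CSF < mean_WM < mean_GM is checked on the
    area-weighted per-tissue means at the optimum.

    ``pooled_weight`` sets how strongly the joint fit couples all
    components to the pooled intracranial histogram in addition to each
    tissue's own atlas-attributed histogram (0 decouples the tissues; large
    values approach a pure pooled fit that discards the atlas attribution).
    """

    n_components: dict = field(
        default_factory=lambda: {"csf": 2, "gm": 3, "wm": 2}
    )
    mean_bounds: dict = field(
        default_factory=lambda: {"csf": (-10.0, 25.0), "wm": (10.0, 35.0), "gm": (-10.0, 60.0)}
    )
    sd_bounds: tuple[float, float] = (0.1, 30.0)
    pooled_weight: float = 0.3
    tol: float = 1e-8
    max_nfev: int = 2000

    def validate(self) -> None:
        for t in TISSUES:
            if self.n_components.get(t, 0) < 1:
                raise InvalidSpecError(f"need >= 1 component for tissue {t!r}")
            lo, hi = self.mean_bounds[t]
            if not lo < hi:
                raise InvalidSpecError(f"empty mean bounds for tissue {t!r}")
        if not 0 < self.sd_bounds[0] < self.sd_bounds[1]:
            raise InvalidSpecError("sd bounds must satisfy 0 < lo < hi")
        if self.pooled_weight < 0:
            raise InvalidSpecError("pooled_weight must be nonnegative")


@dataclass
class HUHistogramSet:
    """Per-tissue volume-vs-HU histograms (volumes in mL per bin)."""

    edges: np.ndarray
    volumes: dict  # tissue -> (n_bins,) array of mL
    masked_volume_ml: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def pooled(self) -> np.ndarray:
        return sum(self.volumes[t] for t in TISSUES)


@dataclass(frozen=True)
class GaussianComponent:
    area_ml: float
    mean_hu: float
    sd_hu: float


@dataclass
class MixtureFit:
    """Fitted Gaussian components per tissue, with diagnostics."""

    components: dict  # tissue -> list[GaussianComponent]
    residual_norm: float
    n_evaluations: int
    converged: bool

    def tissue_volume_ml(self, tissue: str) -> float:
        return float(sum(c.area_ml for c in self.components[tissue]))


@dataclass
class VolumeEstimate:
    csf_ml: float
    gm_ml: float
    wm_ml: float
    icv_ml: float
    ratio_pct: float
    fit: MixtureFit | None = None

    def as_dict(self) -> dict:
        return {
            "csf_ml": self.csf_ml,
            "gm_ml": self.gm_ml,
            "wm_ml": self.wm_ml,
            "icv_ml": self.icv_ml,
            "ratio_pct": self.ratio_pct,
        }


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------


def _to_sitk(arr: np.ndarray, voxel_size) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0)), dtype=np.float64))
    img.SetSpacing(tuple(float(v) for v in voxel_size))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def _atlas_predicted_hu(atlas: ProbAtlas, hu_means: dict) -> np.ndarray:
    p = atlas.probs
    hu = sum(p[..., i] * hu_means[t] for i, t in enumerate(TISSUES))
    return hu + (1.0 - p.sum(axis=-1)) * BACKGROUND_HU


def _transform_to_matrix(tx: sitk.Transform) -> np.ndarray:
    tx = tx.Downcast()
    if isinstance(tx, sitk.CompositeTransform):
        tx = tx.GetNthTransform(tx.GetNumberOfTransforms() - 1).Downcast()
    A = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = c + t - A @ c
    return M


def register_atlas(
    ct: CTVolume,
    atlas: ProbAtlas,
    mode: str = "identity",
    hu_means: dict | None = None,
) -> tuple[ProbAtlas, np.ndarray]:
    """Align the atlas to the CT grid.

    ``identity`` assumes the atlas is already aligned and only checks the
    grids agree.  ``affine`` estimates an affine transform by intensity-based
    registration (correlation metric between the CT and the atlas-predicted
    HU image, multiresolution gradient descent) and resamples the atlas
    probabilities through it.  Returns the (re)aligned atlas and the
    recovered world-space 4x4 transform (fixed CT coordinates to atlas
    coordinates; identity when nothing was estimated).
    """
    if atlas.probs.shape[:3] != ct.values.shape:
        raise ShapeError(
            f"atlas grid {atlas.probs.shape[:3]} does not match CT grid {ct.values.shape}"
        )
    if mode == "identity":
        return atlas, np.eye(4)
    if mode != "affine":
        raise InvalidSpecError(f"mode must be 'identity' or 'affine', got {mode!r}")

    hu_means = hu_means or dict(DEFAULT_HU_MEANS)
    fixed = _to_sitk(ct.values, ct.voxel_size)
    moving = _to_sitk(_atlas_predicted_hu(atlas, hu_means), atlas.voxel_size)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    final = reg.Execute(fixed, moving)

    metric = float(reg.GetMetricValue())  # negative correlation; -1 is perfect
    if metric > -0.5:
        raise RegistrationError(
            f"registration did not converge (final correlation {-metric:.3f})",
            metric_value=metric,
        )

    aligned = np.empty_like(atlas.probs)
    for c in range(3):
        chan = _to_sitk(atlas.probs[..., c], atlas.voxel_size)
        out = sitk.Resample(chan, fixed, final, sitk.sitkLinear, 0.0)
        aligned[..., c] = _from_sitk(out)
    np.clip(aligned, 0.0, 1.0, out=aligned)
    new_atlas = ProbAtlas(
        probs=aligned,
        voxel_size=ct.voxel_size,
        intracranial_mask_threshold=atlas.intracranial_mask_threshold,
        misalignment=np.eye(4),
    )
    return new_atlas, _transform_to_matrix(final)


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------


def build_histograms(
    ct: CTVolume,
    atlas: ProbAtlas,
    cfg: HistogramConfig | None = None,
) -> HUHistogramSet:
    """Accumulate per-tissue volume-vs-HU histograms over the atlas mask.

    Only voxels whose summed tissue probability reaches the atlas'
    intracranial threshold contribute; each contributes its voxel volume
    split across tissues by the atlas probabilities.  HU values outside the
    configured range accumulate into the end bins, so the histogram total
    equals the masked probabilistic volume exactly.
    """
    cfg = cfg or HistogramConfig()
    cfg.validate()
    if atlas.probs.shape[:3] != ct.values.shape:
        raise ShapeError("atlas and CT grids differ")
    psum = atlas.probs.sum(axis=-1)
    mask = psum >= atlas.intracranial_mask_threshold
    if not mask.any():
        raise EmptyMaskError("atlas intracranial mask selects no voxels")

    edges = cfg.edges
    voxel_ml = float(np.prod(ct.voxel_size)) / 1000.0
    hu = np.clip(ct.values[mask], edges[0], np.nextafter(edges[-1], -np.inf))
    volumes = {}
    for i, t in enumerate(TISSUES):
        w = atlas.probs[..., i][mask] * voxel_ml
        volumes[t], _ = np.histogram(hu, bins=edges, weights=w)
    masked_volume = float(psum[mask].sum()) * voxel_ml
    return HUHistogramSet(edges=edges, volumes=volumes, masked_volume_ml=masked_volume)


# ---------------------------------------------------------------------------
# Mixture fitting
# ---------------------------------------------------------------------------


def _component_bins(area: float, mean: float, sd: float, edges: np.ndarray) -> np.ndarray:
    """Volume contributed to each bin by one Gaussian component (exact CDF)."""
    return area * np.diff(norm.cdf(edges, loc=mean, scale=sd))


def _stage1_inits(hists: HUHistogramSet, cfg: MixtureFitConfig):
    """Per-tissue single-Gaussian moment fits, split into initial components."""
    centers = hists.centers
    inits = []  # (tissue, area, mean, sd)
    for t in TISSUES:
        v = hists.volumes[t]
        area = float(v.sum())
        lo, hi = cfg.mean_bounds[t]
        k = cfg.n_components[t]
        if area <= 0:
            for j in range(k):
                inits.append((t, 0.0, lo + (j + 1) * (hi - lo) / (k + 1), 3.0))
            continue
        mean = float((v * centers).sum() / area)
        var = float((v * (centers - mean) ** 2).sum() / area)
        sd = float(np.sqrt(max(var, 1.0)))
        mean = float(np.clip(mean, lo + 1e-3, hi - 1e-3))
        sd = float(np.clip(sd, cfg.sd_bounds[0] * 1.01, cfg.sd_bounds[1] * 0.99))
        offsets = np.linspace(-0.8 * sd, 0.8 * sd, k) if k > 1 else [0.0]
        for off in offsets:
            m = float(np.clip(mean + off, lo + 1e-3, hi - 1e-3))
            inits.append((t, area / k, m, sd))
    return inits


def fit_mixtures(hists: HUHistogramSet, cfg: MixtureFitConfig | None = None) -> MixtureFit:
    """Two-stage Gaussian-mixture fit to the intracranial HU histograms.

    Stage 1 fits one Gaussian per tissue to that tissue's own histogram by
    weighted moments (initialisation).  Stage 2 refits all components
    jointly by bounded least squares on bin volumes, with each tissue's
    components matched to its atlas-attributed histogram and all components
    together coupled to the pooled intracranial histogram
    (``cfg.pooled_weight``), so the summed areas track the pooled volume
    while the atlas attribution anchors which tissue owns which mass.
    The CSF < WM < GM ordering of the area-weighted tissue means is
    verified at the optimum; a violation raises
    :class:`ConstraintViolationError`.
    """
    cfg = cfg or MixtureFitConfig()
    cfg.validate()
    pooled = hists.pooled()
    if float(pooled.sum()) <= 0:
        raise EmptyMaskError("histograms are empty; nothing to fit")

    inits = _stage1_inits(hists, cfg)
    edges = hists.edges
    total = float(pooled.sum())
    owners = [t for t, *_ in inits]
    x0, lo_b, hi_b, scales = [], [], [], []
    for t, area, mean, sd in inits:
        mlo, mhi = cfg.mean_bounds[t]
        x0 += [area, mean, sd]
        lo_b += [0.0, mlo, cfg.sd_bounds[0]]
        hi_b += [2.0 * total, mhi, cfg.sd_bounds[1]]
        scales += [max(total / 3.0, 1e-3), 5.0, 2.0]

    w_pool = cfg.pooled_weight

    def residuals(x: np.ndarray) -> np.ndarray:
        per = {t: np.zeros(len(edges) - 1) for t in TISSUES}
        for k, t in enumerate(owners):
            a, mu, sd = x[3 * k : 3 * k + 3]
            per[t] += _component_bins(a, mu, sd, edges)
        parts = [per[t] - hists.volumes[t] for t in TISSUES]
        parts.append(w_pool * (sum(per.values()) - pooled))
        return np.concatenate(parts)

    res = optimize.least_squares(
        residuals,
        x0=np.asarray(x0, dtype=float),
        bounds=(np.asarray(lo_b), np.asarray(hi_b)),
        x_scale=np.asarray(scales),
        xtol=cfg.tol,
        ftol=cfg.tol,
        gtol=cfg.tol,
        max_nfev=cfg.max_nfev,
    )

    components: dict[str, list[GaussianComponent]] = {t: [] for t in TISSUES}
    for k, t in enumerate(owners):
        a, mu, sd = res.x[3 * k : 3 * k + 3]
        components[t].append(GaussianComponent(float(a), float(mu), float(sd)))

    fit = MixtureFit(
        components=components,
        residual_norm=float(np.linalg.norm(res.fun)),
        n_evaluations=int(res.nfev),
        converged=bool(res.success),
    )

    # ordering check on area-weighted tissue means (only for tissues that
    # actually carry volume; an absent tissue has no meaningful mean)
    means = {}
    for t in TISSUES:
        vol = fit.tissue_volume_ml(t)
        if vol > 1e-3 * total:
            means[t] = sum(c.area_ml * c.mean_hu for c in components[t]) / vol
    order = [t for t in ("csf", "wm", "gm") if t in means]
    vals = [means[t] for t in order]
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ConstraintViolationError(
            f"component ordering violated: {' / '.join(f'{t}={means[t]:.1f}HU' for t in order)}"
        )
    return fit


def compute_volumes(fit: MixtureFit, allow_nonconverged: bool = False) -> VolumeEstimate:
    """Tissue volumes from component areas; ICV is their sum, ratio = CSF/ICV."""
    if not fit.converged and not allow_nonconverged:
        raise DegenerateFitError("mixture fit did not converge (pass allow_nonconverged=True to override)")
    csf = fit.tissue_volume_ml("csf")
    gm = fit.tissue_volume_ml("gm")
    wm = fit.tissue_volume_ml("wm")
    icv = csf + gm + wm
    if icv <= 0:
        raise DegenerateFitError("fitted intracranial volume is not positive")
    return VolumeEstimate(csf, gm, wm, icv, 100.0 * csf / icv, fit=fit)


def measure_csf_icv(
    ct: CTVolume,
    atlas: ProbAtlas,
    hist_cfg: HistogramConfig | None = None,
    fit_cfg: MixtureFitConfig | None = None,
    registration: str = "identity",
) -> VolumeEstimate:
    """End-to-end measurement: registration, histograms, mixture fit, volumes.

    Deterministic given its inputs.  Errors from individual stages are
    re-raised wrapped in :class:`StageError` with the stage name attached.
    """
    stages = (
        ("register_atlas", lambda: register_atlas(ct, atlas, mode=registration)),
    )
    try:
        aligned, _ = stages[0][1]()
    except Exception as exc:
        raise StageError("register_atlas", exc) from exc
    try:
        hists = build_histograms(ct, aligned, hist_cfg)
    except Exception as exc:
        raise StageError("build_histograms", exc) from exc
    try:
        fit = fit_mixtures(hists, fit_cfg)
    except Exception as exc:
        raise StageError("fit_mixtures", exc) from exc
    try:
        return compute_volumes(fit, allow_nonconverged=True)
    except Exception as exc:
        raise StageError("compute_volumes", exc) from exc
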