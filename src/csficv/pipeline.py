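"""End-to-end study orchestration.

``run_study`` reproduces the whole analysis from one seeded configuration:
simulate a registry cohort, optionally measure each patient's CSF/ICV ratio
from a rendered phantom CT instead of using the generative truth, classify
outcomes, inject and impute missing values, fit the basic and extended
logistic models on each completed dataset, pool them, and compare
discrimination (c-statistics, DeLong) and goodness of fit (likelihood-ratio
test).  Everything written to the output directory is a deterministic
function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

_pkg_version = "0.1.0"

from . import cohort as chrt
from . import comparison as cmp
from . import models as mdl
from . import phantom as phm
from . import volumetry as vol
from .errors import StageError

log = logging.getLogger("csficv.pipeline")

DEFAULT_MISSINGNESS = {
    "nihss": 0.02,
    "aspects": 0.02,
    "collateral_score": 0.02,
    "otg_minutes": 0.01,
    "csf_icv_pct": 0.01,
}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full study run."""

    n_patients: int = 683
    seed: int = 7
    m_imputations: int = 5
    imaging: bool = True  # measure CSF/ICV from rendered phantoms
    phantom: phm.PhantomSpec = field(default_factory=phm.PhantomSpec)
    hist_cfg: vol.HistogramConfig = field(default_factory=vol.HistogramConfig)
    fit_cfg: vol.MixtureFitConfig = field(default_factory=vol.MixtureFitConfig)
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    atlas_blur_mm: float = 1.25
    calibration_points: int = 13

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "phantom" in raw:
            p = raw["phantom"]
            for key in ("grid_shape", "voxel_size", "head_semiaxes", "ventricle_semiaxes_max"):
                if key in p:
                    p[key] = tuple(p[key])
            raw["phantom"] = phm.PhantomSpec(**p)
        if "hist_cfg" in raw:
            raw["hist_cfg"] = vol.HistogramConfig(**raw["hist_cfg"])
        if "fit_cfg" in raw:
            raw["fit_cfg"] = vol.MixtureFitConfig(**raw["fit_cfg"])
        return cls(**raw)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str))
        return path


def _measure_cohort_ratios(table: pd.DataFrame, config: RunConfig, seed: int) -> pd.DataFrame:
    """Replace each patient's CSF/ICV value with a phantom-measured one.

    A calibration curve (atrophy -> true ratio) is computed once on the
    configured phantom geometry and inverted per patient by interpolation;
    each patient gets a phantom with their true ratio, an independent noise
    seed, and the standard measurement pipeline.
    """
    spec = config.phantom
    atroph = np.linspace(0.02, 1.0, config.calibration_points)
    ratios = np.array(
        [
            phm.true_volumes(phm.make_tissue_map(replace(spec, atrophy=float(a)))).ratio_pct
            for a in atroph
        ]
    )
    out = table.copy()
    out["csf_icv_true_pct"] = out["csf_icv_pct"]
    measured = np.empty(len(out))
    for k, (idx, row) in enumerate(out.iterrows()):
        target = float(np.clip(row["csf_icv_pct"], ratios[0], ratios[-1]))
        a = float(np.interp(target, ratios, atroph))
        pspec = replace(spec, atrophy=a, seed=(seed + k) % (2**31))
        tmap = phm.make_tissue_map(pspec)
        ct = phm.render_ct(tmap, pspec)
        atlas = phm.make_atlas(tmap, blur_sigma=config.atlas_blur_mm)
        est = vol.measure_csf_icv(ct, atlas, config.hist_cfg, config.fit_cfg)
        measured[k] = est.ratio_pct
    out["csf_icv_pct"] = measured
    return out


def run_study(config: RunConfig, out_dir) -> dict:
    """Execute the full study and write a machine-readable report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = datetime.now(timezone.utc).isoformat()
    log.info("csficv %s on python %s; seed=%d n=%d",
             _pkg_version, platform.python_version(), config.seed, config.n_patients)

    stage = "simulate_cohort"
    try:
        cspec = phm.default_cohort_spec("extended", n=config.n_patients, seed=config.seed)
        table = phm.simulate_cohort(cspec)
        log.info("simulated %d patients", len(table))

        volumetry_diag = {}
        if config.imaging:
            stage = "volumetry"
            table = _measure_cohort_ratios(table, config, seed=config.seed * 1009 + 1)
            err = table["csf_icv_pct"] - table["csf_icv_true_pct"]
            volumetry_diag = {
                "mean_abs_error_pp": float(err.abs().mean()),
                "max_abs_error_pp": float(err.abs().max()),
                "bias_pp": float(err.mean()),
            }
            log.info("volumetry mean |error| %.2f pp", volumetry_diag["mean_abs_error_pp"])

        stage = "classify"
        table["outcome"] = chrt.classify_edema_table(table)
        analysed = chrt.exclude_death_unknown(table)
        log.info("%d patients analysed (%d death_unknown excluded)",
                 len(analysed), len(table) - len(analysed))

        stage = "missingness"
        masked = phm.inject_missingness(analysed, config.missingness_rates,
                                        seed=config.seed * 7919 + 3)
        completed = chrt.impute_missing(masked, m=config.m_imputations,
                                        seed=config.seed * 104729 + 5)

        stage = "models"
        fits_b, fits_e, cstats_b, cstats_e, delong_ps, lrt_stats, lrt_ps = [], [], [], [], [], [], []
        for comp in completed:
            coded = chrt.code_covariates(comp)
            fb = mdl.fit_logistic(coded, chrt.BASIC_PREDICTORS)
            fe = mdl.fit_logistic(coded, chrt.EXTENDED_PREDICTORS)
            fits_b.append(fb)
            fits_e.append(fe)
            y = coded["outcome_event"].to_numpy()
            sb, se_ = fb.predict(coded), fe.predict(coded)
            cstats_b.append(cmp.c_statistic(sb, y).auc)
            cstats_e.append(cmp.c_statistic(se_, y).auc)
            delong_ps.append(cmp.delong_test(se_, sb, y).p_value)
            lrt = cmp.likelihood_ratio_test(fb, fe)
            lrt_stats.append(lrt.statistic)
            lrt_ps.append(lrt.p_value)

        pooled_b = mdl.pool_fits(fits_b)
        pooled_e = mdl.pool_fits(fits_e)
        or_b = mdl.odds_ratios(pooled_b)
        or_e = mdl.odds_ratios(pooled_e)
        vifs = mdl.vif(chrt.code_covariates(completed[0]).dropna(), chrt.EXTENDED_PREDICTORS)

        stage = "comparison"
        coded0 = chrt.code_covariates(completed[0])
        y0 = coded0["outcome_event"].to_numpy()
        roc_b = cmp.c_statistic(fits_b[0].predict(coded0), y0)
        roc_e = cmp.c_statistic(fits_e[0].predict(coded0), y0)
        cmp.export_roc({"basic": roc_b, "extended": roc_e}, out_dir)

        stage = "summary"
        summary = chrt.summarize_groups(analysed)

        report = {
            "config": {"n_patients": config.n_patients, "seed": config.seed,
                       "m_imputations": config.m_imputations, "imaging": config.imaging},
            "versions": {"csficv": _pkg_version, "python": platform.python_version(),
                         "numpy": np.__version__, "pandas": pd.__version__},
            "started_utc": t0,
            "n_analysed": int(len(analysed)),
            "n_events": int((analysed["outcome"] == chrt.MALIGNANT_EDEMA).sum()),
            "volumetry": volumetry_diag,
            "odds_ratios": {"basic": or_b.round(6).to_dict("index"),
                            "extended": or_e.round(6).to_dict("index")},
            "vif": {k: float(v) for k, v in vifs.items()},
            "c_statistic": {"basic_median": float(np.median(cstats_b)),
                            "extended_median": float(np.median(cstats_e))},
            "delong_p_median": float(np.median(delong_ps)),
            "lrt": {"statistic_median": float(np.median(lrt_stats)),
                    "p_median": float(np.median(lrt_ps))},
        }

        table.to_csv(out_dir / "cohort.csv", index=False)
        or_b.to_csv(out_dir / "or_basic.csv")
        or_e.to_csv(out_dir / "or_extended.csv")
        summary.to_csv(out_dir / "group_summary.csv")
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        log.info("report written to %s", out_dir)
        return report
    except StageError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
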