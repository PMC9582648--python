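"""End-to-end study orchestration: simulate -> estimate -> report.

:func:`run_study` reproduces the shape of a two-arm CMME study on fully
synthetic data: a repeatability arm (8 goats, 2 scans/observers, 4
cardiac cycles each) and a paired sedation arm (8 goats measured at
baseline and after a sedative that damps inflow velocities and slows
the heart).  Velocity maps are generated per goat and scan, segmental
IVPD/IVPG are estimated per cycle by the Euler pipeline, and the three
report emitters produce the repeatability table, the paired-comparison
table and the conventional-vs-CMME correlation table, plus one
machine-readable JSON summary.  Identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cmm_io import PairedTable, StudyTable, ValidationError
from .compare_stats import correlation_report, paired_report
from .euler_ivp import IVPD_COMPONENTS, AnalysisConfig, analyze_recording
from .repro_stats import repeatability_report
from .synthetic_cmm import InflowParams, generate_inflow_field

log = logging.getLogger("cmme_ivp.pipeline")

__all__ = ["PipelineConfig", "run_study"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end study, with the study's defaults.

    Physical constants: blood density 1060 kg/m^3, 133.322 Pa/mmHg.
    Decision thresholds: significance level 0.05, CV class bounds 15/25 %,
    ICC acceptability 0.75, rank-biserial cutoffs 0.1/0.4/0.6.
    """

    seed: int = 0
    rho: float = 1060.0
    mmhg_per_pa: float = 1.0 / 133.322
    sigma_s: float = 0.002
    sigma_t: float = 0.006
    total_span: str = "scanline"
    e_wave_only: bool = False
    icc_form: str = "icc2_1"
    alpha: float = 0.05
    cv_thresholds: tuple[float, float] = (15.0, 25.0)
    icc_threshold: float = 0.75
    rc_cutoffs: tuple[float, float, float] = (0.1, 0.4, 0.6)
    # cohort shape
    n_goats: int = 8
    n_scans: int = 2
    n_cycles: int = 4
    # synthetic physiology
    noise_sd: float = 0.02
    goat_peak_cv: float = 0.10     # between-goat spread of peak velocities
    sedation_effect: float = 0.72  # post/baseline inflow-velocity ratio
    sedation_hr_effect: float = 1.2  # post/baseline heart-period ratio

    def __post_init__(self) -> None:
        lo, hi = self.cv_thresholds
        if not 0 < lo < hi:
            raise ValidationError("cv_thresholds must be positive and ordered")
        if not all(a < b for a, b in zip(self.rc_cutoffs, self.rc_cutoffs[1:])):
            raise ValidationError("rc_cutoffs must be strictly increasing")
        if self.alpha <= 0 or self.icc_threshold <= 0:
            raise ValidationError("alpha and icc_threshold must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        for key in ("cv_thresholds", "rc_cutoffs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv_thresholds"] = list(self.cv_thresholds)
        d["rc_cutoffs"] = list(self.rc_cutoffs)
        return d

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(rho=self.rho, sigma_s=self.sigma_s,
                              sigma_t=self.sigma_t, total_span=self.total_span,
                              e_wave_only=self.e_wave_only)


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Named, reproducible substream of the root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _goat_params(base: InflowParams, rng: np.random.Generator,
                 goat_cv: float) -> InflowParams:
    """Per-goat physiologic variation of the inflow model."""
    f = float(np.exp(rng.normal(0.0, goat_cv)))
    lvl = float(base.lv_length * np.exp(rng.normal(0.0, 0.05)))
    lvl = min(lvl, base.scan_length - 0.005)
    return dataclasses.replace(base, peak_E=base.peak_E * f,
                               peak_A=base.peak_A * f, lv_length=lvl)


def _measure(params: InflowParams, cfg: PipelineConfig, map_seed: int):
    """Generate one recording and return its per-cycle component values."""
    p = dataclasses.replace(params, noise_sd=cfg.noise_sd, seed=map_seed,
                            n_beats=cfg.n_cycles)
    vmap, _ = generate_inflow_field(p)
    return analyze_recording(vmap, cfg.analysis_config())


def _variable_names() -> list[str]:
    return [f"{c}_{kind}" for kind in ("ivpd", "ivpg") for c in IVPD_COMPONENTS]


def run_study(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run both study arms and write the report bundle into ``out_dir``.

    Returns the JSON-serialisable summary that is also written to
    ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    base_params = InflowParams()
    log.info("stage=start seed=%d n_goats=%d", cfg.seed, cfg.n_goats)

    # ---- repeatability arm -------------------------------------------
    rng_rep = _substream(cfg.seed, 1)
    records = []
    for i in range(cfg.n_goats):
        gp = _goat_params(base_params, rng_rep, cfg.goat_peak_cv)
        for j in range(cfg.n_scans):
            map_seed = int(rng_rep.integers(0, 2 ** 31 - 1))
            rec = _measure(gp, cfg, map_seed)
            for k, (d, g) in enumerate(zip(rec.ivpd, rec.ivpg)):
                for c in IVPD_COMPONENTS:
                    records.append({"goat_id": f"goat{i + 1}",
                                    "scan_id": chr(ord("A") + j),
                                    "cycle_index": k + 1,
                                    "variable": f"{c}_ivpd", "value": getattr(d, c)})
                    records.append({"goat_id": f"goat{i + 1}",
                                    "scan_id": chr(ord("A") + j),
                                    "cycle_index": k + 1,
                                    "variable": f"{c}_ivpg", "value": getattr(g, c)})
    study = StudyTable(pd.DataFrame.from_records(records))
    table2 = repeatability_report(study, _variable_names(),
                                  icc_form=cfg.icc_form, alpha=cfg.alpha)
    table2.to_csv(out / "repeatability_report.csv", index=False)
    log.info("stage=repeatability n_records=%d", len(study.df))

    # ---- paired sedation arm -----------------------------------------
    rng_pair = _substream(cfg.seed, 2)
    paired_records = []
    conv_rows = {}
    cmme_rows = {}
    for i in range(cfg.n_goats):
        gp = _goat_params(base_params, rng_pair, cfg.goat_peak_cv)
        jitter = float(np.exp(rng_pair.normal(0.0, 0.06)))
        post_p = dataclasses.replace(
            gp,
            peak_E=gp.peak_E * cfg.sedation_effect * jitter,
            peak_A=gp.peak_A * cfg.sedation_effect * jitter,
            heart_period=gp.heart_period * cfg.sedation_hr_effect,
        )
        for cond, p in (("baseline", gp), ("post", post_p)):
            map_seed = int(rng_pair.integers(0, 2 ** 31 - 1))
            rec = _measure(p, cfg, map_seed)
            for c in IVPD_COMPONENTS:
                paired_records.append({"goat_id": f"goat{i + 1}", "condition": cond,
                                       "variable": f"{c}_ivpd",
                                       "value": rec.mean_ivpd[c]})
                paired_records.append({"goat_id": f"goat{i + 1}", "condition": cond,
                                       "variable": f"{c}_ivpg",
                                       "value": rec.mean_ivpg[c]})
            subject = f"goat{i + 1}:{cond}"
            conv_rows[subject] = {"HR_bpm": 60.0 / p.heart_period,
                                  "E_peak_mps": p.peak_E}
            cmme_rows[subject] = {f"{c}_ivpd": rec.mean_ivpd[c]
                                  for c in IVPD_COMPONENTS}
    paired = PairedTable(pd.DataFrame.from_records(paired_records))
    table1 = paired_report(paired, _variable_names(), alpha=cfg.alpha)
    table1.to_csv(out / "paired_report.csv", index=False)
    log.info("stage=paired n_records=%d", len(paired.df))

    conv = pd.DataFrame.from_dict(conv_rows, orient="index").sort_index()
    cmme = pd.DataFrame.from_dict(cmme_rows, orient="index").sort_index()
    table3 = correlation_report(conv, cmme)
    table3.to_csv(out / "correlation_report.csv", index=False)
    log.info("stage=correlation n_pairs=%d", len(table3))

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "package_version": __version__,
        "config": cfg.to_dict(),
        "repeatability": _round_records(table2),
        "paired": _round_records(table1),
        "correlation": _round_records(table3),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("stage=done out_dir=%s", out)
    return summary


def _round_records(df: pd.DataFrame, digits: int = 10) -> list[dict]:
    """Records with floats rounded for stable, readable JSON."""
    out = []
    for rec in df.to_dict(orient="records"):
        out.append({k: (round(v, digits) if isinstance(v, float) else v)
                    for k, v in rec.items()})
    return out
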