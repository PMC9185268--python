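"""Config-driven end-to-end calibration runner.

The workflow reproduces the standard NIRS calibration protocol:

1. average replicate scans into one spectrum per sample;
2. pre-screen spectral outliers (GH > 3) on the scatter-corrected data;
3. order samples by spectral (GH) distance and split roughly 1-in-5 into
   an external validation set, the rest forming the calibration set;
4. per trait and per candidate math treatment, run six-segment
   cross-validation with up to two T/H outlier elimination passes;
5. keep the treatment with the lowest SECV, refit on the surviving
   calibration samples, and evaluate on the held-out validation set;
6. emit a per-trait evaluation report plus the serialized models, the
   split, and the outlier log.

Configuration is a plain mapping (or YAML file) with keys::

    spectra: <wide CSV path>          # omit to generate synthetic data
    reference: <reference CSV path>
    traits: [protein, tpc, ...]       # default: all reference columns
    treatments: ["1,4,4,1 snv_dt", "2,5,5,2 snv_dt"]
    split_k: 5
    cv: {max_factors: 12, n_segments: 6, t_limit: 2.5, h_limit: 3.0,
         passes: 2, epsilon: 0.02}
    h_prescreen: 3.0
    seed: 1
    synthetic: {n: 144, replicates: 6}   # used when spectra is omitted
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .mpls import CVResult, cross_validate
from .outliers import remove_spectral_outliers
from .selection import center_order, split_every_k
from .spectra import (ReferenceTable, SpectralSet, average_replicates,
                      read_reference, read_spectra, write_spectra)
from .stats import (EvaluationReport, classify_model, prediction_error,
                    r_squared, rer, rpd, sec, summary_stats)
from .treatments import MathTreatment, apply_treatment, parse_math_treatment

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

DEFAULT_TREATMENTS = ("1,4,4,1 snv_dt", "2,5,5,2 snv_dt")


@dataclass
class PipelineConfig:
    spectra: str | None = None
    reference: str | None = None
    traits: list[str] | None = None
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    split_k: int = 5
    h_prescreen: float = 3.0
    max_factors: int = 12
    n_segments: int = 6
    t_limit: float = 2.5
    h_limit: float = 3.0
    passes: int = 2
    epsilon: float = 0.02
    seed: int = 1
    synthetic_n: int = 144
    synthetic_replicates: int = 6
    outdir: str | None = None

    @classmethod
    def from_mapping(cls, m: dict) -> "PipelineConfig":
        cv = m.get("cv", {})
        syn = m.get("synthetic", {})
        return cls(
            spectra=m.get("spectra"),
            reference=m.get("reference"),
            traits=m.get("traits"),
            treatments=tuple(m.get("treatments", DEFAULT_TREATMENTS)),
            split_k=int(m.get("split_k", 5)),
            h_prescreen=float(m.get("h_prescreen", 3.0)),
            max_factors=int(cv.get("max_factors", 12)),
            n_segments=int(cv.get("n_segments", 6)),
            t_limit=float(cv.get("t_limit", 2.5)),
            h_limit=float(cv.get("h_limit", 3.0)),
            passes=int(cv.get("passes", 2)),
            epsilon=float(cv.get("epsilon", 0.02)),
            seed=int(m.get("seed", 1)),
            synthetic_n=int(syn.get("n", 144)),
            synthetic_replicates=int(syn.get("replicates", 6)),
            outdir=m.get("outdir"),
        )


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return PipelineConfig.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    report: EvaluationReport
    cal_ids: list[str]
    val_ids: list[str]
    prescreen_removed: list[str]
    models: dict[str, object] = field(default_factory=dict)   # trait -> MPLSModel
    cv_results: dict[str, CVResult] = field(default_factory=dict)
    outlier_log: pd.DataFrame | None = None


def _load_inputs(cfg: PipelineConfig) -> tuple[SpectralSet, ReferenceTable]:
    if cfg.spectra is None:
        from .synthetic import generate_dataset

        return generate_dataset(n=cfg.synthetic_n,
                                replicates=cfg.synthetic_replicates,
                                seed=cfg.seed)
    if cfg.reference is None:
        raise ValueError("config must name a reference table when spectra "
                         "are read from file")
    spectra = read_spectra(cfg.spectra)
    refs = read_reference(cfg.reference)
    return spectra, refs


def run_pipeline(config: PipelineConfig | dict | str | Path) -> PipelineResult:
    """Run the whole calibration workflow; see the module docstring."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    elif isinstance(config, dict):
        cfg = PipelineConfig.from_mapping(config)
    else:
        cfg = config

    spectra, refs = _load_inputs(cfg)
    traits = cfg.traits or refs.traits
    missing = [t for t in traits if t not in refs.traits]
    if missing:
        raise ValueError(f"reference table lacks traits {missing}")
    treatments = [parse_math_treatment(c) for c in cfg.treatments]

    # 1. replicate averaging (no-op when scans are already sample-level)
    if "sample" in spectra.labels.columns:
        spectra = average_replicates(spectra, "sample")

    # 2. GH pre-screen on scatter-corrected spectra
    screened = apply_treatment(spectra, MathTreatment(scatter="snv_dt"))
    _, pre_report = remove_spectral_outliers(screened, cfg.h_prescreen)
    kept_ids = [s for s in spectra.sample_ids
                if s not in set(pre_report.removed_ids)]
    spectra = spectra.subset(kept_ids)

    # 3. spectral ordering and external-validation split
    ordered = center_order(apply_treatment(spectra, MathTreatment(scatter="snv_dt")))
    cal_ids, val_ids = split_every_k(ordered, cfg.split_k)

    records, models, cv_results, outlier_rows = [], {}, {}, []
    for trait in traits:
        y_all = refs.trait(trait)
        best = None
        for t in treatments:
            treated = apply_treatment(spectra, t)
            cal = treated.subset(cal_ids)
            ok = ~y_all.reindex(cal_ids).isna().to_numpy()
            Xc = cal.absorbance[ok]
            yc = y_all.reindex(cal_ids).to_numpy(dtype=float)[ok]
            cv = cross_validate(
                Xc, yc, max_factors=cfg.max_factors,
                n_segments=cfg.n_segments, t_limit=cfg.t_limit,
                h_limit=cfg.h_limit, passes=cfg.passes,
                epsilon=cfg.epsilon, seed=cfg.seed,
            )
            if best is None or cv.secv < best[1].secv:
                best = (t, cv, cal, yc)
        t, cv, cal, yc = best
        model = cv.final_model
        model.treatment = t
        model.trait = trait
        model.grid = cal.grid

        ok_idx = np.flatnonzero(~y_all.reindex(cal_ids).isna().to_numpy())
        ok_ids = [cal_ids[i] for i in ok_idx]
        surv = cv.surviving_idx
        surv_ids = [ok_ids[i] for i in surv]
        y_surv = yc[surv]
        stats_cal = summary_stats(y_surv)
        yhat_cal = model.predict(cal.absorbance[ok_idx][surv])
        sec_val = sec(y_surv, yhat_cal, model.n_factors)

        treated_val = apply_treatment(spectra, t).subset(val_ids)
        okv = ~y_all.reindex(val_ids).isna().to_numpy()
        yv = y_all.reindex(val_ids).to_numpy(dtype=float)[okv]
        yhat_v = model.predict(treated_val.absorbance[okv])
        pe = prediction_error(yv, yhat_v)
        stats_val = summary_stats(yv)
        r2v = r_squared(yv, yhat_v)
        rpd_p = rpd(stats_val["sd"], pe["sep"])
        rer_v = rer(stats_val["range"][1] - stats_val["range"][0], pe["sep"])
        bands = classify_model(r2v, rpd_p, rer_v)

        for p, ids_pass in enumerate(cv.t_removed, start=1):
            outlier_rows += [{"trait": trait, "sample_id": ok_ids[i],
                              "pass": p, "reason": "T"} for i in ids_pass]
        for p, ids_pass in enumerate(cv.h_removed, start=1):
            outlier_rows += [{"trait": trait, "sample_id": ok_ids[i],
                              "pass": p, "reason": "H"} for i in ids_pass]

        records.append({
            "trait": trait, "treatment": t.code, "n_factors": model.n_factors,
            "n_cal": len(surv_ids), "n_val": int(okv.sum()),
            "range_cal_low": stats_cal["range"][0],
            "range_cal_high": stats_cal["range"][1],
            "range_val_low": stats_val["range"][0],
            "range_val_high": stats_val["range"][1],
            "mean": stats_cal["mean"], "sd": stats_cal["sd"],
            "cv": stats_cal["cv"],
            "sec": sec_val, "r2_cal": r_squared(y_surv, yhat_cal),
            "r2_cv": cv.r2_cv, "secv": cv.secv, "rpd_cv": cv.rpd_cv,
            "sep": pe["sep"], "bias": pe["bias"], "r2_val": r2v,
            "rpd_p": rpd_p, "rer": rer_v,
            "r2_band": bands.r2_band, "rpd_band": bands.rpd_band,
            "rer_band": bands.rer_band, "quality_band": bands.combined,
        })
        models[trait] = model
        cv_results[trait] = cv

    result = PipelineResult(
        report=EvaluationReport.from_records(records),
        cal_ids=cal_ids, val_ids=val_ids,
        prescreen_removed=list(pre_report.removed_ids),
        models=models, cv_results=cv_results,
        outlier_log=pd.DataFrame(outlier_rows,
                                 columns=["trait", "sample_id", "pass", "reason"]),
    )
    if cfg.outdir:
        _write_artifacts(result, cfg, spectra, refs)
    return result


def _write_artifacts(result: PipelineResult, cfg: PipelineConfig,
                     spectra: SpectralSet, refs: ReferenceTable) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.csv")
    (out / "report.txt").write_text(result.report.to_text() + "\n")
    split = pd.DataFrame(
        [{"sample_id": s, "set": "CAL"} for s in result.cal_ids]
        + [{"sample_id": s, "set": "VAL"} for s in result.val_ids]
    )
    split.to_csv(out / "split.csv", index=False)
    if result.outlier_log is not None:
        result.outlier_log.to_csv(out / "outliers.csv", index=False)
    for trait, model in result.models.items():
        model.to_json(out / f"model_{trait}.json")
    write_spectra(spectra, out / "spectra_averaged.csv")
    refs.to_csv(out / "reference.csv")
    (out / "config.json").write_text(json.dumps(cfg.__dict__, default=str,
                                                indent=1))
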