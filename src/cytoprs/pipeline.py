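"""End-to-end orchestration: simulate -> segment -> extract -> train -> evaluate.

Produces a comparison report in the style of the study's method-vs-baseline
table: for the texture PRS and for the machine blast-percentage baseline,
prognostic metrics (HR, CI, log-rank p, C-index) and predictive metrics
(AUC, accuracy, sensitivity, specificity, precision) on identical patient
splits. Training never touches validation outcomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cytoprs import __version__
from cytoprs.classify import fit_lda, roc_analysis
from cytoprs.features.catalog import PATIENT_FEATURE_NAMES
from cytoprs.features.extract import FeatureExtractionResult, extract_cohort_features
from cytoprs.segment import (
    MYELOBLAST,
    SegmentationConfig,
    instances_to_label_image,
    pool_pixel_metrics,
    segment_tile,
)
from cytoprs.simulate import Cohort, SimulationParams, simulate_cohort
from cytoprs.survival import (
    PRSModel,
    dichotomize,
    fit_cox,
    km_logrank,
    lasso_cox_select,
    prs_score,
    SurvivalData,
)

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "split", "rfs_days", "event", "relapse_1yr", "age", "sex", "comorbidity_index"]


@dataclass
class RunConfig:
    out_dir: str | None = None
    seed: int = 0
    n_patients: int = 60
    simulation: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    use_truth_masks: bool = True
    evaluate_segmentation_stage: bool = False
    n_folds: int = 5
    n_levels: int = 16
    version: str = __version__

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def resolved(self) -> dict:
        sim = dataclasses.asdict(self.simulation_params())
        return {**dataclasses.asdict(self), "simulation_resolved": sim}

    def simulation_params(self) -> SimulationParams:
        overrides = dict(self.simulation)
        overrides.setdefault("tile_px", 256)
        return SimulationParams(n_patients=self.n_patients, seed=self.seed, **overrides)


def patient_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per patient with split and outcomes (tile rows collapsed)."""
    return (
        manifest[PATIENT_COLUMNS]
        .drop_duplicates("patient_id")
        .reset_index(drop=True)
    )


def _evaluate_risk_method(
    name: str,
    patients: pd.DataFrame,
    risk: np.ndarray,
    lda_features: np.ndarray,
) -> dict:
    """Shared prognostic + predictive evaluation of one scalar risk score.

    The LDA classifier, the Cox threshold and every other trained quantity
    use the training split only.
    """
    is_train = (patients["split"] == "train").to_numpy()
    is_val = ~is_train
    times = patients["rfs_days"].to_numpy(dtype=float)
    events = patients["event"].to_numpy(dtype=int)
    relapse = patients["relapse_1yr"].to_numpy(dtype=int)
    if lda_features.ndim == 1:
        lda_features = lda_features[:, None]

    threshold = float(risk[is_train].mean())
    lda = fit_lda(lda_features[is_train], relapse[is_train])

    out: dict = {"method": name, "risk_threshold": threshold}
    for split, sel in (("train", is_train), ("val", is_val)):
        entry: dict = {}
        cox = fit_cox(times[sel], events[sel], pd.DataFrame({name: risk[sel]}))
        entry["hr"] = float(cox.hr.iloc[0])
        entry["hr_ci95"] = [float(cox.ci95["lower"].iloc[0]), float(cox.ci95["upper"].iloc[0])]
        entry["cox_p"] = float(cox.wald_p.iloc[0])
        entry["cindex"] = float(cox.cindex)

        groups = np.where(dichotomize(risk[sel], threshold), "high", "low")
        if len(np.unique(groups)) == 2:
            lr = km_logrank(times[sel], events[sel], groups)
            entry["logrank_chi2"] = lr.chi2
            entry["logrank_p"] = lr.p
        else:
            entry["logrank_chi2"] = None
            entry["logrank_p"] = None

        scores = lda.decision_scores(lda_features[sel])
        if len(np.unique(relapse[sel])) == 2:
            roc = roc_analysis(scores, relapse[sel])
            entry["auc"] = roc.auc
            entry.update({k: v for k, v in roc.oop_metrics.items()})
        else:
            entry["auc"] = None
        out[split] = entry
    return out


def blast_percentage_baseline(features: pd.DataFrame, patients: pd.DataFrame) -> dict:
    """Evaluate the machine blast-percentage as risk feature and classifier input."""
    merged = patients.merge(features[["patient_id", "blast_percentage"]], on="patient_id")
    ok = merged["blast_percentage"].notna()
    excluded = merged.loc[~ok, "patient_id"].tolist()
    merged = merged[ok].reset_index(drop=True)
    pct = merged["blast_percentage"].to_numpy(dtype=float)
    result = _evaluate_risk_method("blast_percentage", merged, pct, pct)
    result["excluded_patients"] = excluded
    return result


def texture_prs_method(
    features: pd.DataFrame, patients: pd.DataFrame, n_folds: int, seed: int
) -> tuple[dict, PRSModel]:
    """LASSO-Cox feature selection on the training split, then shared evaluation."""
    merged = patients.merge(features, on="patient_id")
    feat_cols = [c for c in PATIENT_FEATURE_NAMES if c in merged.columns]
    ok = merged[feat_cols].notna().all(axis=1)
    merged = merged[ok].reset_index(drop=True)
    train = merged[merged["split"] == "train"]

    data = SurvivalData(
        times=train["rfs_days"].to_numpy(),
        events=train["event"].to_numpy(),
        X=train[feat_cols],
    )
    model = lasso_cox_select(data, n_folds=n_folds, seed=seed)
    risk = prs_score(model, merged[feat_cols])
    lda_X = merged[list(model.selected)].to_numpy(dtype=float)
    result = _evaluate_risk_method("texture_prs", merged, risk, lda_X)
    result["selected_features"] = list(model.selected)
    result["lambda"] = model.lambda_
    return result, model


def multivariable_cox(
    patients: pd.DataFrame, risk: np.ndarray, covariates: tuple[str, ...] = ("age", "sex", "comorbidity_index")
) -> dict:
    """PRS plus clinical covariates, fit per split."""
    out = {}
    for split in ("train", "val"):
        sel = (patients["split"] == split).to_numpy()
        X = patients.loc[sel, list(covariates)].astype(float).reset_index(drop=True)
        X.insert(0, "prs", risk[sel])
        cox = fit_cox(
            patients.loc[sel, "rfs_days"].to_numpy(),
            patients.loc[sel, "event"].to_numpy(dtype=int),
            X,
        )
        out[split] = {
            "hr": {k: float(v) for k, v in cox.hr.items()},
            "wald_p": {k: float(v) for k, v in cox.wald_p.items()},
            "cindex": float(cox.cindex),
        }
    return out


def _segmentation_stage(cohort: Cohort, seg_config: SegmentationConfig) -> dict:
    pairs = []
    n_exact = 0
    for tile_id, tile in cohort.tiles.items():
        instances = segment_tile(tile.rgb, seg_config)
        pred = instances_to_label_image(instances, tile.rgb.shape[:2], MYELOBLAST) > 0
        truth = tile.blast_mask > 0
        pairs.append((pred, truth))
        n_pred = sum(1 for inst in instances if inst.cell_class == MYELOBLAST)
        n_exact += int(n_pred == tile.blast_mask.max())
    pooled = pool_pixel_metrics(pairs)
    return {
        "tpr": pooled.tpr,
        "tnr": pooled.tnr,
        "f1": pooled.f1,
        "n_tiles": len(pairs),
        "exact_count_fraction": n_exact / max(len(pairs), 1),
    }


@dataclass
class PipelineResult:
    report: dict
    features: pd.DataFrame
    prs_model: PRSModel
    cohort: Cohort
    report_hash: str


def report_hash(report: dict) -> str:
    return hashlib.sha256(json.dumps(report, sort_keys=True).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline per the run configuration."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    params = config.simulation_params()
    logger.info("simulate: %d patients x %d tiles", params.n_patients, params.tiles_per_patient)
    cohort = simulate_cohort(params, out_dir / "cohort" if out_dir else None)
    source = cohort if not cohort.tiles == {} else (out_dir / "cohort")

    seg_config = SegmentationConfig(**config.segmentation)
    seg_report = None
    if config.evaluate_segmentation_stage or not config.use_truth_masks:
        if cohort.tiles:
            seg_report = _segmentation_stage(cohort, seg_config)
            logger.info("segmentation: pooled F1 %.3f", seg_report["f1"])

    extraction: FeatureExtractionResult = extract_cohort_features(
        source,
        manifest=cohort.manifest,
        use_truth_masks=config.use_truth_masks,
        seg_config=seg_config,
        n_levels=config.n_levels,
    )
    features = extraction.features
    patients = patient_table(cohort.manifest)
    patients = patients[patients["patient_id"].isin(features["patient_id"])].reset_index(drop=True)
    logger.info(
        "extract: %d patients, %d excluded", len(patients), len(extraction.exclusions)
    )

    texture, model = texture_prs_method(features, patients, config.n_folds, config.seed)
    merged = patients.merge(features, on="patient_id")
    feat_cols = [c for c in PATIENT_FEATURE_NAMES if c in merged.columns]
    risk = prs_score(model, merged[feat_cols])
    multivar = multivariable_cox(merged, risk)
    baseline = blast_percentage_baseline(features, patients)

    report = {
        "version": config.version,
        "seed": config.seed,
        "n_patients": int(params.n_patients),
        "n_tiles": int(len(cohort.manifest)),
        "counts": {
            "patients_in": int(params.n_patients),
            "patients_excluded": len(extraction.exclusions),
            "tiles_processed": int(len(cohort.manifest)),
        },
        "exclusions": extraction.exclusions,
        "segmentation": seg_report,
        "methods": {"texture_prs": texture, "blast_percentage": baseline},
        "multivariable_cox": multivar,
    }
    digest = report_hash(report)

    if out_dir:
        features.to_csv(out_dir / "features.csv", index=False)
        model.to_json(out_dir / "model.json")
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        (out_dir / "report.md").write_text(_markdown_report(report))
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh)
        pd.DataFrame(extraction.exclusions).to_csv(out_dir / "exclusions.csv", index=False)

    return PipelineResult(
        report=report, features=features, prs_model=model, cohort=cohort, report_hash=digest
    )


def _fmt(x) -> str:
    if x is None:
        return "-"
    return f"{x:.3f}" if isinstance(x, float) else str(x)


def _markdown_report(report: dict) -> str:
    lines = [
        "# Pipeline comparison report",
        "",
        f"version {report['version']}, seed {report['seed']}, "
        f"{report['n_patients']} patients / {report['n_tiles']} tiles",
        "",
        "| method | split | HR | log-rank p | C-index | AUC | accuracy | sensitivity | precision |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for name, method in report["methods"].items():
        for split in ("train", "val"):
            m = method[split]
            lines.append(
                f"| {name} | {split} | {_fmt(m['hr'])} | {_fmt(m['logrank_p'])} | "
                f"{_fmt(m['cindex'])} | {_fmt(m.get('auc'))} | {_fmt(m.get('accuracy'))} | "
                f"{_fmt(m.get('sensitivity'))} | {_fmt(m.get('precision'))} |"
            )
    if report.get("segmentation"):
        seg = report["segmentation"]
        lines += [
            "",
            f"Segmentation (pooled over {seg['n_tiles']} tiles): "
            f"TPR {seg['tpr']:.3f}, TNR {seg['tnr']:.3f}, F1 {seg['f1']:.3f}",
        ]
    sel = report["methods"]["texture_prs"].get("selected_features", [])
    lines += ["", f"Selected texture features: {', '.join(sel)}", ""]
    return "\n".join(lines)
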