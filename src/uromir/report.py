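"""Pipeline orchestration, cohort characteristics tables and run reports.

``run_pipeline`` wires the stages end to end — (optional) simulation,
preprocessing, cascade screening, LOOCV classification, longitudinal trend
calls — writes every intermediate table as TSV, and records a JSON manifest
with the configuration echo and per-stage feature counts so the selection
funnel is auditable.  ``cohort_summary`` produces the patient-characteristics
table (n, age, sex with the male/female ratio, smoking, and any alcohol or
stage columns present).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, longitudinal, screen, simulate
from .preprocess import FilterThresholds, preprocess as preprocess_chain

logger = logging.getLogger(__name__)

_CATEGORY_VOCAB = {
    "sex": ("male", "female"),
    "smoking": ("current", "past", "never"),
    "alcohol": ("current", "past", "never"),
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class CohortSummary:
    """Characteristics of one cohort (one row per patient)."""

    cohort: str
    n: int
    age_mean: float
    age_sd: float
    n_male: int
    n_female: int
    gender_ratio: float | None  # male/female to one decimal; None when no females
    tabulations: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def gender_ratio_label(self) -> str:
        return "NA" if self.gender_ratio is None else f"{self.gender_ratio:g}"


def gender_ratio(n_male: int, n_female: int) -> float | None:
    """Male/female ratio rounded to one decimal; undefined (None) when the
    cohort has no female patients."""
    if n_female == 0:
        return None
    return round(n_male / n_female, 1)


def cohort_summary(meta: pd.DataFrame) -> dict[str, CohortSummary]:
    """Per-cohort characteristics from sample metadata.

    Longitudinal repeats are collapsed to one row per patient before
    tabulation.  Unknown category values are rejected with the offending
    rows listed.
    """
    bad = meta[~meta["cohort"].isin(simulate.COHORTS)]
    if not bad.empty:
        raise ValueError(f"unknown cohort labels in rows: {bad.index.tolist()}")
    if "patient_id" in meta.columns:
        per_patient = meta.drop_duplicates(subset="patient_id")
    else:
        per_patient = meta
    for col, vocab in _CATEGORY_VOCAB.items():
        if col in per_patient.columns:
            bad = per_patient[~per_patient[col].isin(vocab)]
            if not bad.empty:
                raise ValueError(
                    f"unknown {col} values {sorted(bad[col].unique())} in rows {bad.index.tolist()}"
                )
    out: dict[str, CohortSummary] = {}
    for cohort, grp in per_patient.groupby("cohort", sort=False):
        n_male = int((grp["sex"] == "male").sum()) if "sex" in grp.columns else 0
        n_female = int((grp["sex"] == "female").sum()) if "sex" in grp.columns else 0
        tabs = {}
        for col in ("smoking", "alcohol", "stage"):
            if col in grp.columns:
                tabs[col] = grp[col].value_counts().to_dict()
        out[cohort] = CohortSummary(
            cohort=cohort,
            n=len(grp),
            age_mean=float(grp["age"].mean()) if "age" in grp.columns else float("nan"),
            age_sd=float(grp["age"].std(ddof=1)) if "age" in grp.columns else float("nan"),
            n_male=n_male,
            n_female=n_female,
            gender_ratio=gender_ratio(n_male, n_female),
            tabulations=tabs,
        )
    return out


def format_cohort_summary(summaries: dict[str, CohortSummary]) -> str:
    cohorts = list(summaries)
    lines = ["Patient characteristics", "\t" + "\t".join(cohorts)]
    lines.append("n\t" + "\t".join(str(summaries[c].n) for c in cohorts))
    lines.append(
        "Age mean (SD)\t"
        + "\t".join(f"{summaries[c].age_mean:.1f} ({summaries[c].age_sd:.1f})" for c in cohorts)
    )
    lines.append("Male\t" + "\t".join(str(summaries[c].n_male) for c in cohorts))
    lines.append("Female\t" + "\t".join(str(summaries[c].n_female) for c in cohorts))
    lines.append(
        "Gender ratio (M/F)\t" + "\t".join(summaries[c].gender_ratio_label for c in cohorts)
    )
    for col in ("smoking", "alcohol", "stage"):
        if any(col in summaries[c].tabulations for c in cohorts):
            for value in sorted({v for c in cohorts for v in summaries[c].tabulations.get(col, {})}):
                lines.append(
                    f"{col}:{value}\t"
                    + "\t".join(str(summaries[c].tabulations.get(col, {}).get(value, 0)) for c in cohorts)
                )
    return "\n".join(lines)


@dataclass
class PipelineConfig:
    """One flat configuration for an end-to-end run.

    Exactly one input source: either ``signals_path``/``metadata_path`` or a
    ``simulation`` config.  Every analysis threshold is a named field with
    the study default.
    """

    output_dir: Path | str = "uromir_run"
    signals_path: Path | str | None = None
    metadata_path: Path | str | None = None
    simulation: simulate.SimulationConfig | None = None
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cascade_thresholds: screen.CascadeThresholds = field(
        default_factory=screen.CascadeThresholds
    )
    penalty: float = 1.0
    min_delta: float = 0.0
    n_longitudinal_patients: int = 2
    seed: int = 0

    def validate(self) -> None:
        from_files = self.signals_path is not None and self.metadata_path is not None
        if from_files == (self.simulation is not None):
            raise ValueError(
                "exactly one input source required: signals_path+metadata_path or simulation"
            )


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Identical configuration and seed reproduce every output byte for byte.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    # --- input stage -------------------------------------------------------
    stage = "input"
    try:
        truth = None
        long_signals = long_meta = None
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            signals, meta, truth = simulate.generate_cohort_signals(sim)
            simulate.write_fixture_bundle(signals, meta, truth, outdir)
            if config.n_longitudinal_patients >= 1 and len(truth.planted):
                patterns = {
                    fid: ("down_up" if d == "up" else "up_down")
                    for fid, d in truth.directions.items()
                }
                long_signals, long_meta, _ = simulate.generate_longitudinal_series(
                    sim, config.n_longitudinal_patients, patterns
                )
                simulate.write_signals(long_signals, outdir / "signals_longitudinal.tsv")
                simulate.write_metadata(long_meta, outdir / "metadata_longitudinal.tsv")
            manifest["simulation"] = dataclasses.asdict(sim)
        else:
            signals = simulate.read_signals(config.signals_path)
            meta = simulate.read_metadata(config.metadata_path)
            long_ids = meta.loc[meta["timepoint"].isin(simulate.TIMEPOINTS), "sample_id"]
            if not long_ids.empty:
                long_signals = signals[[c for c in signals.columns if c in set(long_ids)]]
                long_meta = meta[meta["sample_id"].isin(long_ids)]
                signals = signals.drop(columns=long_signals.columns)
                meta = meta[~meta["sample_id"].isin(long_ids)]
            manifest["inputs"] = {
                "signals": str(config.signals_path),
                "metadata": str(config.metadata_path),
            }
        manifest["stages"]["input"] = {
            "n_features": int(signals.shape[0]),
            "n_samples": int(signals.shape[1]),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- preprocessing -----------------------------------------------------
    stage = "preprocess"
    try:
        expr, plog = preprocess_chain(signals, config.filter_thresholds)
        expr.to_csv(outdir / "expr.tsv", sep="\t", float_format="%.10g",
                    index_label="feature_id")
        manifest["stages"]["preprocess"] = plog.stage_counts
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- screening cascade -------------------------------------------------
    stage = "screen"
    try:
        cascade = screen.run_cascade(expr, meta, config.cascade_thresholds)
        cdir = outdir / "cascade"
        cdir.mkdir(exist_ok=True)
        (cdir / "analysis1.txt").write_text("\n".join(cascade.analysis1) + "\n")
        (cdir / "analysis2_up.txt").write_text("\n".join(cascade.analysis2_up) + "\n")
        (cdir / "analysis2_down.txt").write_text("\n".join(cascade.analysis2_down) + "\n")
        _write_tsv(cascade.analysis3, cdir / "analysis3.tsv")
        _write_tsv(cascade.audit, cdir / "audit.tsv")
        manifest["stages"]["screen"] = cascade.stage_counts
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- classification ----------------------------------------------------
    stage = "classify"
    evaluation = None
    try:
        selected = cascade.analysis3_selected
        if selected:
            evaluation = classify.evaluate_classifier(expr, meta, selected, config.penalty)
            edir = outdir / "eval"
            edir.mkdir(exist_ok=True)
            _write_tsv(
                pd.DataFrame(
                    {
                        "sample_id": evaluation.sample_ids,
                        "label": evaluation.labels.astype(int),
                        "loocv_score": evaluation.loocv,
                    }
                ),
                edir / "loocv_scores.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "threshold": evaluation.roc.thresholds,
                        "tpr": evaluation.roc.tpr,
                        "fpr": evaluation.roc.fpr,
                    }
                ),
                edir / "roc.tsv",
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "n_features": len(selected),
                            "auc": evaluation.auc,
                            "ci_low": evaluation.auc_ci_low,
                            "ci_high": evaluation.auc_ci_high,
                            "penalty": evaluation.penalty,
                        }
                    ]
                ),
                edir / "summary.tsv",
            )
            pf = classify.per_feature_auc(expr, meta, cascade.directions)
            _write_tsv(pf, edir / "per_feature_auc.tsv")
            classify.plot_roc(evaluation.roc, evaluation.auc, edir / "roc.png")
            manifest["stages"]["classify"] = {
                "n_features": len(selected),
                "auc": evaluation.auc,
                "auc_ci": [evaluation.auc_ci_low, evaluation.auc_ci_high],
            }
        else:
            manifest["stages"]["classify"] = {"n_features": 0, "skipped": "empty selection"}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- longitudinal trends ----------------------------------------------
    stage = "trend"
    consistent = None
    try:
        if long_signals is not None and cascade.analysis3_selected:
            long_expr, _ = preprocess_chain(long_signals, config.filter_thresholds)
            avail = [f for f in cascade.analysis3_selected if f in long_expr.index]
            series = longitudinal.extract_trajectories(long_expr.loc[avail], long_meta)
            calls = longitudinal.evaluate_patient(series, cascade.directions, config.min_delta)
            tdir = outdir / "trend"
            tdir.mkdir(exist_ok=True)
            _write_tsv(calls, tdir / "calls.tsv")
            if calls["patient_id"].nunique() >= 2:
                consistent = longitudinal.cross_patient_concordance(calls)
                _write_tsv(consistent, tdir / "consistent_features.tsv")
            manifest["stages"]["trend"] = {
                "n_features": len(avail),
                "n_patients": int(calls["patient_id"].nunique()),
                "n_concordant_calls": int(calls["concordant"].sum()),
                "n_consistent": 0 if consistent is None else len(consistent),
            }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- report ------------------------------------------------------------
    stage = "report"
    try:
        summaries = cohort_summary(meta)
        lines = [format_cohort_summary(summaries), "", cascade.summary()]
        if evaluation is not None:
            lines += ["", evaluation.summary()]
        if consistent is not None:
            lines += [
                "",
                "Cross-patient consistent markers: "
                + (", ".join(consistent["feature_id"]) if len(consistent) else "(none)"),
            ]
        (outdir / "report.txt").write_text("\n".join(lines) + "\n")
        import numpy as _np
        import pandas as _pd
        import scipy as _sp

        from . import __version__

        manifest["versions"] = {
            "uromir": __version__,
            "numpy": _np.__version__,
            "scipy": _sp.__version__,
            "pandas": _pd.__version__,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return manifest
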