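"""End-to-end pipeline: simulate → score → aggregate → analyze.

Configuration is a YAML file that round-trips losslessly; every run writes
a manifest recording the configuration hash, the seed, row counts at each
stage, and rejection/conservation bookkeeping, so that identical
(config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import analysis, scoring, synthetic, transactions
from .analysis import RegressionSpec
from .scoring import ScoringCriteria
from .synthetic import SimulationConfig, SpendModel
from .transactions import SemesterCalendar

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


class ConfigFileError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, seeds and per-stage settings for one pipeline run."""

    out_dir: str = "ffhs_out"
    catalog_path: str | None = None
    ledger_path: str | None = None
    covariates_path: str | None = None
    seed: int = 0
    simulate: bool = False
    log_level: str = "INFO"
    criteria: ScoringCriteria = field(default_factory=ScoringCriteria)
    calendar: SemesterCalendar = field(default_factory=SemesterCalendar)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    regression: RegressionSpec = field(default_factory=RegressionSpec)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, Mapping):
                return {str(k): plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = plain(self)
        # the simulation block embeds a calendar; keep only the top-level one
        d["simulation"].pop("calendar", None)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigFileError(f"unknown config key(s): {sorted(unknown)}")

        def windows(m):
            return {k: tuple(tuple(x) for x in v) for k, v in m.items()}

        calendar = d.pop("calendar", None)
        cal = SemesterCalendar(
            terms=windows(calendar["terms"]),
            allowed=tuple(calendar["allowed"])
            if calendar.get("allowed") else None,
        ) if calendar else SemesterCalendar()

        crit = d.pop("criteria", None)
        criteria = ScoringCriteria(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in crit.items()}) if crit else ScoringCriteria()

        sim = d.pop("simulation", None)
        if sim:
            sim = dict(sim)
            spend = sim.pop("spend_model", None)
            sim["spend_model"] = (SpendModel(**spend) if spend
                                  else SpendModel())
            sim["semesters"] = tuple(sim.get("semesters",
                                             SimulationConfig.semesters))
            if "target_score_distribution" in sim:
                sim["target_score_distribution"] = tuple(
                    sim["target_score_distribution"])
            if "gpa_band_probs" in sim:
                sim["gpa_band_probs"] = tuple(sim["gpa_band_probs"])
            if "age_probs" in sim:
                sim["age_probs"] = {int(k): v
                                    for k, v in sim["age_probs"].items()}
            simulation = SimulationConfig(**sim, calendar=cal)
        else:
            simulation = SimulationConfig(calendar=cal)

        reg = d.pop("regression", None)
        regression = RegressionSpec(**reg) if reg else RegressionSpec()
        return cls(criteria=criteria, calendar=cal, simulation=simulation,
                   regression=regression, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=level.upper(),
                        format="%(levelname)s %(name)s: %(message)s")


# ---------------------------------------------------------------------------
# Input validation

#: Per-table schema: (required columns, {column: (min, max) numeric range})
SCHEMAS: dict[str, tuple[tuple[str, ...], dict[str, tuple[float, float]]]] = {
    "catalog": (
        scoring.CATALOG_COLUMNS,
        {c: (0.0, float("inf")) for c in (
            "calories", "total_fat_g", "saturated_fat_g", "trans_fat_g",
            "cholesterol_mg", "sodium_mg", "carbohydrate_g", "fiber_g",
            "sugars_g", "protein_g", "price")},
    ),
    "ledger": (
        transactions.LEDGER_COLUMNS,
        {"price": (0.0, float("inf"))},
    ),
    "covariates": (
        transactions.COVARIATE_COLUMNS,
        {"age": (10.0, 120.0), "gpa": (0.0, 4.0),
         "international": (0.0, 1.0), "low_income": (0.0, 1.0),
         "dining_hall_visits": (0.0, float("inf")),
         "rec_center_visits": (0.0, float("inf"))},
    ),
}


def validate_inputs(paths: Mapping[str, str],
                    schemas: Mapping = SCHEMAS) -> list[dict[str, Any]]:
    """Check each input file against its schema without mutating anything.

    ``paths`` maps table kind ("catalog", "ledger", "covariates") to a file
    path.  Returns a list of violation dicts with keys file, severity, row,
    column, message; an empty list means all files are clean.  Duplicate
    (student, timestamp, item) ledger rows are reported as warnings only —
    repeat purchases are legitimate.
    """
    report: list[dict[str, Any]] = []

    def add(kind, path, severity, row, column, message):
        report.append({"file": str(path), "table": kind,
                       "severity": severity, "row": row,
                       "column": column, "message": message})

    for kind, path in paths.items():
        if kind not in schemas:
            raise ConfigFileError(f"no schema for table kind {kind!r}")
        required, ranges = schemas[kind]
        df = pd.read_csv(path)
        for col in required:
            if col not in df.columns:
                add(kind, path, "error", None, col, "missing column")
        for col, (lo, hi) in ranges.items():
            if col not in df.columns:
                continue
            vals = pd.to_numeric(df[col], errors="coerce")
            for idx in df.index[vals.isna() & df[col].notna()]:
                add(kind, path, "error", int(idx), col, "not numeric")
            bad = df.index[(vals < lo) | (vals > hi)]
            for idx in bad:
                add(kind, path, "error", int(idx), col,
                    f"value {df[col][idx]} outside [{lo}, {hi}]")
        na_cols = [c for c in required if c in df.columns
                   and c != "modifier_text" and df[c].isna().any()]
        for col in na_cols:
            idx = int(df.index[df[col].isna()][0])
            add(kind, path, "error", idx, col, "missing value")
        if kind == "ledger" and {"student_id", "timestamp",
                                 "item_id"} <= set(df.columns):
            dup = df.duplicated(["student_id", "timestamp", "item_id"])
            if dup.any():
                add(kind, path, "warning", int(df.index[dup][0]), None,
                    f"{int(dup.sum())} duplicated (student, timestamp, "
                    f"item) row(s) — treated as repeat purchases")
        if kind == "ledger" and "timestamp" in df.columns:
            parsed = pd.to_datetime(df["timestamp"], errors="coerce")
            for idx in df.index[parsed.isna()]:
                add(kind, path, "error", int(idx), "timestamp",
                    "unparseable timestamp")
    return report


# ---------------------------------------------------------------------------
# Orchestration

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "counts": {},
        "conservation": {},
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    catalog_path = config.catalog_path
    ledger_path = config.ledger_path
    covariates_path = config.covariates_path

    if config.simulate:
        stage("simulate")
        try:
            sim = dataclasses.replace(config.simulation, seed=config.seed,
                                      calendar=config.calendar)
            catalog, students, ledger = synthetic.generate_all(
                sim, config.criteria)
            catalog_path = out / "catalog.csv"
            covariates_path = out / "students.csv"
            ledger_path = out / "ledger.csv"
            _write_csv(catalog.drop(columns=["ffhs"]), catalog_path)
            _write_csv(students, covariates_path)
            ledger = ledger.copy()
            ledger["timestamp"] = ledger["timestamp"].dt.strftime(
                "%Y-%m-%dT%H:%M:%S")
            _write_csv(ledger, ledger_path)
        except Exception as exc:
            raise PipelineError(f"[simulate] {exc}") from exc

    for label, p in (("catalog", catalog_path), ("ledger", ledger_path),
                     ("covariates", covariates_path)):
        if p is None:
            raise PipelineError(f"[setup] no {label} path configured and "
                                f"simulation not requested")

    stage("score")
    try:
        catalog_df = scoring.read_catalog(catalog_path)
        scored_df, summary = scoring.score_frame(catalog_df, config.criteria)
        _write_csv(scored_df, out / "scored_catalog.csv")
        hist = pd.DataFrame({"ffhs": list(summary.histogram),
                             "n_items": list(summary.histogram.values())})
        _write_csv(hist, out / "item_score_histogram.csv")
        manifest["counts"]["catalog_items"] = summary.n_items
        manifest["catalog"] = {
            "mean_score": summary.mean_score,
            "modal_score": summary.modal_score,
            "component_prevalence": dict(summary.component_prevalence),
        }
    except Exception as exc:
        raise PipelineError(f"[score] {exc}") from exc

    stage("aggregate")
    try:
        ledger_df = transactions.read_ledger(ledger_path)
        scores = scored_df.set_index("item_id")["ffhs"]
        scores.index = scores.index.astype(str)
        records, report = transactions.student_average_ffhs(
            ledger_df, scores, config.calendar)
        covariates = transactions.read_covariates(covariates_path)
        merged = transactions.merge_covariates(records, covariates)
        _write_csv(merged, out / "student_semesters.csv")
        manifest["counts"].update(
            ledger_rows=report.n_input,
            transactions_aggregated=report.n_aggregated,
            rejected_out_of_term=report.n_out_of_term,
            rejected_unresolved=report.n_unresolved,
            student_semesters=len(merged),
        )
        manifest["conservation"] = {
            "spend_input": report.spend_input,
            "spend_aggregated": report.spend_aggregated,
            "spend_rejected": report.spend_rejected,
            "transactions_balance": (report.n_input == report.n_aggregated
                                     + report.n_out_of_term
                                     + report.n_unresolved),
        }
    except Exception as exc:
        raise PipelineError(f"[aggregate] {exc}") from exc

    stage("analyze")
    try:
        results = analysis.fit_wls(merged, config.regression)
        coef = analysis.render_coefficient_table(results, config.regression)
        _write_csv(coef, out / "coefficients.csv")
        summary_tab = transactions.cohort_summary(merged)
        _write_csv(analysis.render_descriptive_table(summary_tab),
                   out / "descriptives.csv")
        # Student Average FFHS histogram (0.1-wide bins over 0-7)
        binned = pd.cut(merged["avg_ffhs"],
                        bins=[i / 10 for i in range(71)],
                        include_lowest=True)
        avg_hist = (binned.value_counts().sort_index()
                    .rename_axis("avg_ffhs_bin").reset_index(name="n"))
        avg_hist["avg_ffhs_bin"] = avg_hist["avg_ffhs_bin"].astype(str)
        _write_csv(avg_hist, out / "student_avg_histogram.csv")
        comp = analysis.compare_sex_means(merged)
        manifest["analysis"] = {
            "strata_n": {k: v.nobs for k, v in results.items()},
            "mean_avg_ffhs": float(merged["avg_ffhs"].mean()),
            "mean_avg_ffhs_female": comp.mean_female,
            "mean_avg_ffhs_male": comp.mean_male,
            "sex_difference": comp.difference,
            "sex_comparison_p": comp.p_value,
        }
    except Exception as exc:
        raise PipelineError(f"[analyze] {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
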