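"""Purchase-ledger ingestion and per-student-semester aggregation.

Each ledger row is one purchased item (multi-item baskets appear as multiple
rows).  Rows are assigned to academic semesters by a configurable calendar,
joined to item scores, and averaged into the study outcome: the Student
Average FFHS — the unweighted mean score over every item a student purchased
that semester, repeat purchases counted each time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical ledger CSV columns (ISO-8601 timestamps).
LEDGER_COLUMNS = ("student_id", "timestamp", "item_id", "price",
                  "modifier_text")

#: Canonical covariate-table columns, keyed on (student_id, semester).
COVARIATE_COLUMNS = ("student_id", "semester", "sex", "age",
                     "race_ethnicity", "international", "low_income",
                     "gpa", "dining_hall_visits", "rec_center_visits")

RACE_LEVELS = ("White", "African American", "Asian/Pacific Islander",
               "Hispanic", "Other")

GPA_BANDS = ("0.01-2.0", "2.01-3.0", "3.01-4.0")


class LedgerError(ValueError):
    """A ledger row cannot be processed (unresolvable item, bad price...)."""


class OutOfTermError(ValueError):
    """A timestamp falls outside every configured academic term."""


@dataclass(frozen=True)
class SemesterCalendar:
    """Month/day windows defining academic terms, applied to any year.

    Default: fall = Aug 1 – Dec 31, spring = Jan 1 – May 31; summer excluded.
    A spring label carries its calendar year (``spring2017`` is
    Jan–May 2017).  ``allowed`` optionally restricts to a fixed set of
    semester labels; anything else is rejected as out of term.
    """

    terms: Mapping[str, tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=lambda: {"fall": ((8, 1), (12, 31)),
                                 "spring": ((1, 1), (5, 31))})
    allowed: tuple[str, ...] | None = None

    def assign(self, timestamp) -> str | None:
        """Semester label for a timestamp, or None if out of term."""
        ts = pd.Timestamp(timestamp)
        key = (ts.month, ts.day)
        for season, (start, end) in self.terms.items():
            if start <= key <= end:
                label = f"{season}{ts.year}"
                if self.allowed is not None and label not in self.allowed:
                    return None
                return label
        return None

    def assign_series(self, timestamps: pd.Series) -> pd.Series:
        """Vectorised :meth:`assign` over a timestamp series."""
        ts = pd.to_datetime(timestamps)
        key = list(zip(ts.dt.month, ts.dt.day))
        labels = pd.Series([None] * len(ts), index=timestamps.index,
                           dtype=object)
        for season, (start, end) in self.terms.items():
            mask = np.array([start <= k <= end for k in key])
            labels[mask] = season + ts.dt.year.astype(str)[mask]
        if self.allowed is not None:
            labels[~labels.isin(self.allowed)] = None
        return labels

    def window(self, label: str) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Inclusive (start, end-of-day) timestamps for a semester label."""
        for season, (start, end) in self.terms.items():
            if label.startswith(season):
                year = int(label[len(season):])
                return (pd.Timestamp(year, *start),
                        pd.Timestamp(year, *end) + pd.Timedelta(days=1)
                        - pd.Timedelta(seconds=1))
        raise OutOfTermError(f"label {label!r} matches no configured term")


DEFAULT_CALENDAR = SemesterCalendar()


def assign_semester(timestamp, calendar: SemesterCalendar = DEFAULT_CALENDAR,
                    ) -> str:
    """Map one timestamp to its semester label; raise if out of term."""
    label = calendar.assign(timestamp)
    if label is None:
        raise OutOfTermError(f"{timestamp} falls outside every configured "
                             f"term")
    return label


@dataclass(frozen=True)
class AggregationReport:
    """Row bookkeeping from one aggregation pass (conservation checks)."""

    n_input: int
    n_aggregated: int
    n_out_of_term: int
    n_unresolved: int
    spend_input: float
    spend_aggregated: float
    spend_rejected: float


def read_ledger(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LEDGER_COLUMNS if c not in df.columns
               and c != "modifier_text"]
    if missing:
        raise LedgerError(f"ledger {path} lacks column(s): {missing}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise LedgerError(f"covariate table {path} lacks column(s): "
                          f"{missing}")
    return df


def student_average_ffhs(ledger: pd.DataFrame,
                         scores: Mapping[str, int] | pd.Series,
                         calendar: SemesterCalendar = DEFAULT_CALENDAR,
                         on_unresolved: str = "error",
                         ) -> tuple[pd.DataFrame, AggregationReport]:
    """Aggregate a transaction ledger into per-student-semester records.

    Parameters
    ----------
    ledger
        DataFrame with at least student_id, timestamp, item_id, price.
    scores
        item_id -> FFHS mapping from the scored catalog.
    on_unresolved
        ``"error"`` (default) raises on a ledger item id absent from
        ``scores``; ``"drop"`` discards such rows with a logged count.

    Returns the records table (student_id, semester, n_items, total_spend,
    avg_ffhs) sorted by (student_id, semester), plus an
    :class:`AggregationReport` with rejection and spend bookkeeping.
    """
    if len(ledger) == 0:
        raise LedgerError("empty transaction ledger")
    if (ledger["price"] < 0).any():
        bad = ledger.index[ledger["price"] < 0][0]
        raise LedgerError(f"negative price at ledger row {bad}")

    df = ledger.copy()
    score_map = pd.Series(scores, name="ffhs") if not isinstance(
        scores, pd.Series) else scores.rename("ffhs")
    score_map.index = score_map.index.astype(str)
    df["item_id"] = df["item_id"].astype(str)

    unresolved_mask = ~df["item_id"].isin(score_map.index)
    n_unresolved = int(unresolved_mask.sum())
    if n_unresolved:
        bad_ids = sorted(df.loc[unresolved_mask, "item_id"].unique())
        if on_unresolved == "error":
            raise LedgerError(
                f"{n_unresolved} transaction(s) reference unknown item "
                f"id(s): {bad_ids[:10]}")
        logger.warning("dropping %d transactions with unknown item ids %s",
                       n_unresolved, bad_ids[:10])
        df = df[~unresolved_mask]

    df["semester"] = calendar.assign_series(df["timestamp"])
    out_of_term = df["semester"].isna()
    n_out_of_term = int(out_of_term.sum())
    if n_out_of_term:
        logger.info("rejecting %d out-of-term transactions", n_out_of_term)
    kept = df[~out_of_term].copy()
    if len(kept) == 0:
        raise LedgerError("no transactions remain after term filtering")
    kept["ffhs"] = kept["item_id"].map(score_map)

    grouped = (kept.groupby(["student_id", "semester"], sort=True)
               .agg(n_items=("item_id", "size"),
                    total_spend=("price", "sum"),
                    avg_ffhs=("ffhs", "mean"))
               .reset_index())
    report = AggregationReport(
        n_input=len(ledger),
        n_aggregated=len(kept),
        n_out_of_term=n_out_of_term,
        n_unresolved=n_unresolved,
        spend_input=float(ledger["price"].sum()),
        spend_aggregated=float(kept["price"].sum()),
        spend_rejected=float(ledger["price"].sum() - kept["price"].sum()),
    )
    return grouped, report


def merge_covariates(records: pd.DataFrame,
                     covariates: pd.DataFrame) -> pd.DataFrame:
    """Inner-join aggregated score records with the covariate table."""
    merged = records.merge(covariates, on=["student_id", "semester"],
                           how="inner", validate="one_to_one")
    dropped = len(records) - len(merged)
    if dropped:
        logger.warning("%d student-semester record(s) had no covariate row",
                       dropped)
    return merged


# ---------------------------------------------------------------------------
# Descriptive statistics

def _mean_sd(x: pd.Series) -> tuple[float, float]:
    if len(x) == 0:
        return float("nan"), float("nan")
    return float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else float("nan")


def gpa_band(gpa: pd.Series) -> pd.Series:
    """Band GPA into the three reported intervals (left-open at 0)."""
    return pd.cut(gpa, bins=[0.0, 2.0, 3.0, 4.0], labels=GPA_BANDS,
                  include_lowest=True)


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: overall and sex-stratified summary statistics.

    Returns a tidy frame with columns (variable, statistic, total, female,
    male).  Strata with no observations are reported with zero counts, not
    dropped.  Dispersion uses the sample (n−1) formula.
    """
    if len(records) == 0:
        raise LedgerError("cohort_summary requires at least one record")

    strata = {"total": records,
              "female": records[records["sex"] == "female"],
              "male": records[records["sex"] == "male"]}

    rows: list[tuple[str, str, dict[str, float]]] = []

    def add(variable: str, statistic: str, fn) -> None:
        rows.append((variable, statistic,
                     {name: fn(df) for name, df in strata.items()}))

    add("n", "count", lambda d: float(len(d)))
    add("avg_ffhs", "mean", lambda d: _mean_sd(d["avg_ffhs"])[0])
    add("avg_ffhs", "sd", lambda d: _mean_sd(d["avg_ffhs"])[1])
    add("age", "median",
        lambda d: float(d["age"].median()) if len(d) else float("nan"))
    add("age", "iqr",
        lambda d: float(d["age"].quantile(0.75) - d["age"].quantile(0.25))
        if len(d) else float("nan"))
    for level in RACE_LEVELS:
        add(f"race:{level}", "count",
            lambda d, lv=level: float((d["race_ethnicity"] == lv).sum()))
        add(f"race:{level}", "pct",
            lambda d, lv=level: 100.0 * (d["race_ethnicity"] == lv).mean()
            if len(d) else 0.0)
    for flag, label in (("international", "international"),
                        ("low_income", "low_income")):
        add(label, "count", lambda d, f=flag: float(d[f].sum()))
        add(label, "pct",
            lambda d, f=flag: 100.0 * d[f].mean() if len(d) else 0.0)
    add("total_spend", "mean", lambda d: _mean_sd(d["total_spend"])[0])
    add("total_spend", "sd", lambda d: _mean_sd(d["total_spend"])[1])
    for band in GPA_BANDS:
        add(f"gpa_band:{band}", "count",
            lambda d, b=band: float((gpa_band(d["gpa"]) == b).sum()))
        add(f"gpa_band:{band}", "pct",
            lambda d, b=band: 100.0 * (gpa_band(d["gpa"]) == b).mean()
            if len(d) else 0.0)
    for col in ("dining_hall_visits", "rec_center_visits"):
        add(col, "mean", lambda d, c=col: _mean_sd(d[c])[0])
        add(col, "sd", lambda d, c=col: _mean_sd(d[c])[1])

    return pd.DataFrame(
        [{"variable": v, "statistic": s, **vals} for v, s, vals in rows])
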