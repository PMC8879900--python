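"""Synthetic campus food-sales data with known ground truth.

The real transaction database behind this kind of study is proprietary, so
this module fabricates all three input tables — item catalog, student
covariate table, transaction ledger — with the statistical structure the
downstream analysis assumes:

* **Catalog.**  Each item is assigned a target score drawn from a
  configurable distribution (default concentrated at 2–3, matching the
  reported catalog shape), then a nutrient profile is constructed that the
  scoring algorithm maps to *exactly* that score: the subset of passing
  criteria is drawn uniformly among the C(7, k) possibilities and each
  nutrient is placed strictly inside (or outside) its threshold with
  jitter.
* **Cohort.**  Covariates are drawn from marginals defaulting to the
  published cohort (44.4% female, 33.1% low income, GPA bands 13/33/54%,
  etc.).  Demographics are fixed per student; behavioural covariates are
  redrawn each semester.
* **Ledger.**  Each student-semester gets a count of transactions and
  per-transaction prices from the spend model; item choice follows a
  mixture-tilted discrete choice over score strata, so that the expected
  Student Average FFHS is an exact affine function of the covariates:

      E[avg_ffhs | x, sex] = m0 + offset_sex + beta_sex' (x - xbar_sex)

  where ``m0`` is the catalog-distribution mean score.  Per-sex planted
  effects ``beta_sex`` default to the published stratified coefficients, on
  the same covariate scale the regression uses, making end-to-end parameter
  recovery a fair, exactly-specified test.

Everything is deterministic given (seed, config).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import scoring
from .analysis import DESIGN_COLUMNS, build_design
from .scoring import (COMPONENTS, DEFAULT_CRITERIA, NutrientProfile,
                      ScoringCriteria, score_frame)
from .transactions import DEFAULT_CALENDAR, RACE_LEVELS, SemesterCalendar


class ConfigError(ValueError):
    pass


# Published stratified coefficients, used as the default planted effects.
_FEMALE_EFFECTS = {
    "age": -0.0104,
    "race:African American": -0.0302,
    "race:Asian/Pacific Islander": 0.0123,
    "race:Hispanic": 0.0149,
    "race:Other": -0.0204,
    "international": 0.0079,
    "low_income": -0.0097,
    "spend_hundreds": -0.0106,
    "gpa": 0.0253,
    "dining_hall_visits": 0.0014,
    "rec_visits_per10": -0.00208,
}
_MALE_EFFECTS = {
    "age": 0.1297,
    "race:African American": -0.0204,
    "race:Asian/Pacific Islander": 0.0897,
    "race:Hispanic": 0.0514,
    "race:Other": -0.0356,
    "international": -0.324,
    "low_income": -0.0246,
    "spend_hundreds": -0.0114,
    "gpa": 0.1098,
    "dining_hall_visits": 0.0067,
    "rec_visits_per10": 0.0022,
}


def default_effect_vector() -> dict[str, dict[str, float]]:
    return {"female": dict(_FEMALE_EFFECTS), "male": dict(_MALE_EFFECTS)}


def null_effect_vector() -> dict[str, dict[str, float]]:
    """All planted effects zero (for calibration studies)."""
    return {"female": {}, "male": {}}


@dataclass(frozen=True)
class SpendModel:
    """Per-transaction price and per-student-semester transaction count.

    Prices are Gamma with the given mean and coefficient of variation;
    counts are 1 + negative binomial (Gamma–Poisson mixture) with the given
    mean and dispersion, so every record has at least one item.  Defaults
    reproduce the reported semester spend of about $303 (SD $208) from
    about 45 transactions averaging $6.75.
    """

    price_mean: float = 6.75
    price_cv: float = 0.25
    transactions_mean: float = 45.0
    transactions_dispersion: float = 2.3  # NB size parameter r

    def validate(self) -> None:
        if self.price_mean <= 0 or self.price_cv <= 0:
            raise ConfigError("price_mean and price_cv must be > 0")
        if self.transactions_mean <= 1:
            raise ConfigError("transactions_mean must be > 1")
        if self.transactions_dispersion <= 0:
            raise ConfigError("transactions_dispersion must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; defaults emulate the studied cohort.

    ``n_students`` is the number of meal-plan students per semester; each
    appears once in every semester of ``semesters`` (defaults give
    ~35.4k student-semester observations, the published scale).
    """

    seed: int = 0
    n_items: int = 3781
    n_students: int = 5908
    semesters: tuple[str, ...] = ("fall2016", "spring2017", "fall2017",
                                  "spring2018", "fall2018", "spring2019")
    #: P(item score = s) for s = 0..7; mean 2.87, mode 3
    target_score_distribution: tuple[float, ...] = (
        0.03, 0.12, 0.27, 0.30, 0.15, 0.08, 0.04, 0.01)
    female_share: float = 0.444
    race_probs: Mapping[str, float] = field(default_factory=lambda: {
        "African American": 0.22, "Asian/Pacific Islander": 0.05,
        "Hispanic": 0.07, "White": 0.59, "Other": 0.07})
    international_prob: float = 0.02
    low_income_prob: float = 0.331
    #: age distribution (median 19, IQR 2)
    age_probs: Mapping[int, float] = field(default_factory=lambda: {
        17: 0.05, 18: 0.28, 19: 0.30, 20: 0.18, 21: 0.10,
        22: 0.05, 23: 0.02, 24: 0.01, 25: 0.01})
    gpa_band_probs: tuple[float, float, float] = (0.13, 0.33, 0.54)
    dining_mean: float = 44.94
    dining_sd: float = 27.93
    rec_mean: float = 17.72
    rec_sd: float = 30.7
    #: planted per-sex effects on the regression-scaled design columns
    effect_vector: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_effect_vector)
    #: per-sex intercept shift of the expected score around m0
    sex_offset: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.0, "male": -0.05})
    spend_model: SpendModel = field(default_factory=SpendModel)
    #: SD of the i.i.d. per-transaction shock on the linear predictor
    noise_scale: float = 0.15
    calendar: SemesterCalendar = field(default_factory=SemesterCalendar)

    def validate(self) -> None:
        if self.n_items <= 0:
            raise ConfigError("n_items must be > 0")
        if self.n_students <= 0:
            raise ConfigError("n_students must be > 0")
        if not self.semesters:
            raise ConfigError("at least one semester is required")
        for name, probs in (
                ("target_score_distribution",
                 list(self.target_score_distribution)),
                ("race_probs", list(self.race_probs.values())),
                ("age_probs", list(self.age_probs.values())),
                ("gpa_band_probs", list(self.gpa_band_probs))):
            arr = np.asarray(probs, float)
            if (arr < 0).any():
                raise ConfigError(f"{name} has negative probabilities")
            if abs(arr.sum() - 1.0) > 1e-8:
                raise ConfigError(f"{name} must sum to 1, got {arr.sum()}")
        if len(self.target_score_distribution) != 8:
            raise ConfigError("target_score_distribution needs 8 entries "
                              "(scores 0-7)")
        for p in (self.female_share, self.international_prob,
                  self.low_income_prob):
            if not 0 <= p <= 1:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        for sex in ("female", "male"):
            for key in self.effect_vector.get(sex, {}):
                if key not in DESIGN_COLUMNS:
                    raise ConfigError(
                        f"effect_vector[{sex!r}] has unknown covariate "
                        f"{key!r}; valid: {DESIGN_COLUMNS}")
        self.spend_model.validate()

    @property
    def mean_item_score(self) -> float:
        return float(np.dot(np.arange(8), self.target_score_distribution))


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # stage-local generators, all derived from the one configured seed
    return np.random.default_rng([int(config.seed) % (2**31), stage])


# ---------------------------------------------------------------------------
# Catalog construction

# Per-criterion sampling intervals: values drawn strictly inside a "pass"
# interval satisfy the default Table thresholds with margin; "fail"
# intervals sit strictly outside.  Margins are wide enough that closed vs
# open window endpoints cannot flip an award.
_PASS_FAIL = {
    # component: (pass interval, fail-low interval, fail-high interval|None)
    "fat":     ((0.21, 0.34), (0.03, 0.18), (0.37, 0.60)),
    "satfat":  ((0.01, 0.09), (0.11, 0.30), None),
    "sodium":  ((0.20, 1.10), (1.20, 3.50), None),
    "carb":    ((0.46, 0.64), (0.08, 0.42), (0.68, 0.95)),
    "fiber":   ((1.45, 4.00), (0.00, 1.30), None),
    "sugar":   ((0.00, 0.09), (0.11, 0.45), None),
    "protein": ((0.11, 0.29), (0.01, 0.09), (0.32, 0.55)),
}

_VENDORS = ("Campus Grill", "Union Coffee Bar", "Market Express",
            "Chicken Shack", "Stadium Concessions", "Sub Stop")


def build_profile(pattern: Sequence[bool], calories: float = 400.0,
                  rng: np.random.Generator | None = None) -> NutrientProfile:
    """Construct a profile whose default-criteria awards equal ``pattern``.

    ``pattern`` gives pass/fail for the seven components in
    :data:`ffhs.scoring.COMPONENTS` order.  Without an ``rng`` each value
    sits at its interval midpoint (fail uses the low branch); with one,
    values are jittered uniformly inside the interval and two-sided
    failures pick a side at random.
    """
    if len(pattern) != len(COMPONENTS):
        raise ConfigError("pattern must have 7 entries")

    def draw(interval):
        lo, hi = interval
        if rng is None:
            return (lo + hi) / 2.0
        return float(rng.uniform(lo, hi))

    values = {}
    for comp, ok in zip(COMPONENTS, pattern):
        p, flo, fhi = _PASS_FAIL[comp]
        if ok:
            values[comp] = draw(p)
        elif fhi is not None and rng is not None and rng.random() < 0.5:
            values[comp] = draw(fhi)
        else:
            values[comp] = draw(flo)
    return NutrientProfile(
        calories=calories,
        total_fat=values["fat"] * calories / scoring.KCAL_PER_G_FAT,
        saturated_fat=values["satfat"] * calories / scoring.KCAL_PER_G_FAT,
        sodium=values["sodium"] * calories,
        carbohydrate=values["carb"] * calories / scoring.KCAL_PER_G_CARB,
        fiber=values["fiber"] * calories / 100.0,
        sugars=values["sugar"] * calories / scoring.KCAL_PER_G_CARB,
        protein=values["protein"] * calories / scoring.KCAL_PER_G_PROTEIN,
        trans_fat=0.0,
        cholesterol=0.0,
    )


def _uniform_subsets(rng: np.random.Generator, sizes: np.ndarray,
                     ) -> np.ndarray:
    """Boolean (n, 7) mask; row i is a uniform random size_i subset."""
    u = rng.random((len(sizes), len(COMPONENTS)))
    ranks = u.argsort(axis=1).argsort(axis=1)
    return ranks < sizes[:, None]


def generate_catalog(config: SimulationConfig,
                     criteria: ScoringCriteria = DEFAULT_CRITERIA,
                     ) -> pd.DataFrame:
    """Generate an item catalog whose realized FFHS histogram equals the
    drawn target histogram exactly (verified internally).

    Returns a DataFrame with the canonical catalog columns plus ``ffhs``
    (the construction target, equal to the realized score).
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_items
    targets = rng.choice(8, size=n, p=config.target_score_distribution)
    masks = _uniform_subsets(rng, targets)
    calories = np.round(rng.uniform(50.0, 800.0, n), 0)

    values: dict[str, np.ndarray] = {}
    for j, comp in enumerate(COMPONENTS):
        p, flo, fhi = _PASS_FAIL[comp]
        ok = masks[:, j]
        v = np.empty(n)
        v[ok] = rng.uniform(*p, int(ok.sum()))
        nk = ~ok
        if fhi is None:
            v[nk] = rng.uniform(*flo, int(nk.sum()))
        else:
            side_hi = rng.random(int(nk.sum())) < 0.5
            lows = rng.uniform(*flo, int((~side_hi).sum()))
            highs = rng.uniform(*fhi, int(side_hi.sum()))
            vv = np.empty(int(nk.sum()))
            vv[~side_hi] = lows
            vv[side_hi] = highs
            v[nk] = vv
        values[comp] = v

    df = pd.DataFrame({
        "item_id": [f"I{i + 1:05d}" for i in range(n)],
        "name": [f"Item {i + 1:05d}" for i in range(n)],
        "vendor": rng.choice(_VENDORS, n),
        "price": np.round(rng.gamma(9.0, config.spend_model.price_mean / 9.0,
                                    n), 2),
        "calories": calories,
        "total_fat_g": values["fat"] * calories / scoring.KCAL_PER_G_FAT,
        "saturated_fat_g": (values["satfat"] * calories
                            / scoring.KCAL_PER_G_FAT),
        "trans_fat_g": np.zeros(n),
        "cholesterol_mg": np.round(rng.uniform(0.0, 150.0, n), 0),
        "sodium_mg": values["sodium"] * calories,
        "carbohydrate_g": values["carb"] * calories / scoring.KCAL_PER_G_CARB,
        "fiber_g": values["fiber"] * calories / 100.0,
        "sugars_g": values["sugar"] * calories / scoring.KCAL_PER_G_CARB,
        "protein_g": values["protein"] * calories / scoring.KCAL_PER_G_PROTEIN,
    })

    scored, _ = score_frame(df, criteria)
    realized = scored["ffhs"].to_numpy()
    if not np.array_equal(realized, targets):
        bad = int(np.flatnonzero(realized != targets)[0])
        raise RuntimeError(  # pragma: no cover - generator contract
            f"constructed item {df['item_id'][bad]} scored {realized[bad]} "
            f"instead of target {targets[bad]}")
    df["ffhs"] = targets
    return df


# ---------------------------------------------------------------------------
# Cohort construction

def _neg_binomial(rng: np.random.Generator, mean: float, sd: float,
                  size: int) -> np.ndarray:
    """Gamma–Poisson counts with the requested mean and SD (SD² > mean)."""
    var = sd * sd
    if var <= mean:
        return rng.poisson(mean, size)
    r = mean * mean / (var - mean)
    lam = rng.gamma(r, mean / r, size)
    return rng.poisson(lam)


def generate_students(config: SimulationConfig) -> pd.DataFrame:
    """Generate the student-semester covariate table.

    One row per (student, semester); demographics (sex, race, age,
    international, low income) are constant within a student, behavioural
    covariates (GPA, dining-hall and recreation-center visits) are redrawn
    each semester.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_students
    sems = list(config.semesters)

    sex = np.where(rng.random(n) < config.female_share, "female", "male")
    races = list(config.race_probs)
    race = rng.choice(races, n, p=[config.race_probs[r] for r in races])
    intl = rng.random(n) < config.international_prob
    low = rng.random(n) < config.low_income_prob
    ages = np.array(list(config.age_probs))
    age = rng.choice(ages, n, p=list(config.age_probs.values()))
    ids = np.array([f"S{i + 1:05d}" for i in range(n)])

    frames = []
    band_edges = [(0.01, 2.0), (2.01, 3.0), (3.01, 4.0)]
    for sem in sems:
        band = rng.choice(3, n, p=config.gpa_band_probs)
        lo = np.array([band_edges[b][0] for b in band])
        hi = np.array([band_edges[b][1] for b in band])
        gpa = np.round(rng.uniform(lo, hi), 2)
        dining = _neg_binomial(rng, config.dining_mean, config.dining_sd, n)
        rec = _neg_binomial(rng, config.rec_mean, config.rec_sd, n)
        frames.append(pd.DataFrame({
            "student_id": ids, "semester": sem, "sex": sex,
            "age": age, "race_ethnicity": race,
            "international": intl.astype(int),
            "low_income": low.astype(int),
            "gpa": gpa, "dining_hall_visits": dining,
            "rec_center_visits": rec,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Ledger construction

def _linear_predictor(students: pd.DataFrame, spend: np.ndarray,
                      config: SimulationConfig) -> np.ndarray:
    """Per-record eta = sex offset + beta_sex' (x - xbar_sex)."""
    frame = students.copy()
    frame["total_spend"] = spend
    X = build_design(frame).to_numpy(float)
    sex = students["sex"].to_numpy()
    eta = np.zeros(len(students))
    for s in ("female", "male"):
        mask = sex == s
        if not mask.any():
            continue
        beta = np.array([config.effect_vector.get(s, {}).get(c, 0.0)
                         for c in DESIGN_COLUMNS])
        centered = X[mask] - X[mask].mean(axis=0)
        eta[mask] = (dict(config.sex_offset).get(s, 0.0)
                     + centered @ beta)
    return eta


def generate_ledger(students: pd.DataFrame, catalog: pd.DataFrame,
                    config: SimulationConfig,
                    criteria: ScoringCriteria = DEFAULT_CRITERIA,
                    return_truth: bool = False):
    """Generate the transaction ledger for a cohort against a catalog.

    Per transaction the item's score stratum is drawn from the catalog
    distribution tilted toward 7 (or 0) with probability |eta_t| scaled by
    the distance to the boundary, where
    ``eta_t = eta_record + Normal(0, noise_scale)``; this makes
    ``E[score | record] = m0 + eta_record`` exactly.  The item is then
    uniform within its score stratum, the price is an independent draw from
    the spend model, and the timestamp is uniform inside the record's
    semester window.

    With ``return_truth=True`` also returns a per-record frame holding the
    planted linear predictor and closed-form expected Student Average FFHS.
    """
    config.validate()
    if len(students) == 0:
        raise ConfigError("empty student cohort")
    if len(catalog) == 0:
        raise ConfigError("empty item catalog")
    rng = _rng(config, 3)

    if "ffhs" not in catalog.columns:
        catalog, _ = score_frame(catalog, criteria)

    # item pools by score stratum
    order = np.argsort(catalog["ffhs"].to_numpy(), kind="stable")
    pool_ids = catalog["item_id"].to_numpy()[order]
    pool_scores = catalog["ffhs"].to_numpy()[order]
    sizes = np.bincount(pool_scores, minlength=8)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    available = np.flatnonzero(sizes > 0)
    # scores with no items are remapped to the nearest populated stratum
    remap = np.array([available[np.argmin(np.abs(available - s))]
                      for s in range(8)])

    N = len(students)
    sm_ = config.spend_model
    counts = 1 + _neg_binomial(
        rng, sm_.transactions_mean - 1.0,
        np.sqrt(max((sm_.transactions_mean - 1.0)
                    * (1 + (sm_.transactions_mean - 1.0)
                       / sm_.transactions_dispersion), 1e-9)),
        N)
    T = int(counts.sum())
    rep = np.repeat(np.arange(N), counts)

    shape = 1.0 / (sm_.price_cv ** 2)
    prices = np.round(rng.gamma(shape, sm_.price_mean / shape, T), 2)
    spend = np.bincount(rep, weights=prices, minlength=N)

    eta = _linear_predictor(students, spend, config)
    eta_t = eta[rep]
    if config.noise_scale > 0:
        eta_t = eta_t + rng.normal(0.0, config.noise_scale, T)

    m0 = config.mean_item_score
    lam = np.where(eta_t >= 0,
                   np.clip(eta_t / (7.0 - m0), 0.0, 1.0),
                   np.clip(-eta_t / m0, 0.0, 1.0))
    base = rng.choice(8, T, p=config.target_score_distribution)
    forced = rng.random(T) < lam
    score_t = np.where(forced, np.where(eta_t >= 0, 7, 0), base)
    score_t = remap[score_t]

    within = np.floor(rng.random(T) * sizes[score_t]).astype(np.int64)
    item_ids = pool_ids[offsets[score_t] + within]

    # timestamps uniform inside each record's semester window
    sem_labels = students["semester"].to_numpy()
    uniq = pd.unique(sem_labels)
    windows = {s: config.calendar.window(s) for s in uniq}
    start = np.array([windows[s][0].value // 10**9 for s in sem_labels])
    span = np.array([(windows[s][1].value - windows[s][0].value) // 10**9
                     for s in sem_labels])
    secs = start[rep] + np.floor(rng.random(T) * span[rep]).astype(np.int64)
    timestamps = pd.to_datetime(secs, unit="s")

    ledger = pd.DataFrame({
        "student_id": students["student_id"].to_numpy()[rep],
        "timestamp": timestamps,
        "item_id": item_ids,
        "price": prices,
        "modifier_text": "",
    }).sort_values(["timestamp", "student_id", "item_id"],
                   kind="stable").reset_index(drop=True)

    if not return_truth:
        return ledger
    truth = students[["student_id", "semester", "sex"]].copy()
    truth["n_items"] = counts
    truth["total_spend"] = spend
    truth["eta"] = eta
    truth["expected_avg_ffhs"] = m0 + eta
    return ledger, truth


def generate_all(config: SimulationConfig,
                 criteria: ScoringCriteria = DEFAULT_CRITERIA,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Catalog, student covariates and ledger in one deterministic call."""
    catalog = generate_catalog(config, criteria)
    students = generate_students(config)
    ledger = generate_ledger(students, catalog, config, criteria)
    return catalog, students, ledger
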