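"""Fast-Food Health Score (FFHS) computation.

The FFHS rates a fast-food menu item on a 0–7 integer scale: one point for
each of seven nutrient criteria the item satisfies, every criterion expressed
relative to the item's energy content,

====================  =======================================
component             criterion (default thresholds)
====================  =======================================
fat                   20–35% of calories from total fat
satfat                <10% of calories from saturated fat
sodium                <1.15 mg sodium per calorie
carb                  45–65% of calories from carbohydrate
fiber                 ≥1.4 g fiber per 100 calories
sugar                 <10% of calories from sugars
protein               10–30% of calories from protein
====================  =======================================

Gram quantities are converted to calories with the Atwater factors
(9 kcal/g fat, 4 kcal/g carbohydrate and protein).  Trans fat and
cholesterol are carried in the nutrient profile for completeness but are
never scored.  Items with zero calories make the percent-of-calories shares
undefined; two explicit conventions are provided (see
:class:`ScoringCriteria.zero_calorie_policy`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Component names in the order they are reported.
COMPONENTS: tuple[str, ...] = (
    "fat", "satfat", "sodium", "carb", "fiber", "sugar", "protein",
)

#: Canonical catalog CSV columns.
CATALOG_COLUMNS: tuple[str, ...] = (
    "item_id", "name", "vendor", "price", "calories",
    "total_fat_g", "saturated_fat_g", "trans_fat_g", "cholesterol_mg",
    "sodium_mg", "carbohydrate_g", "fiber_g", "sugars_g", "protein_g",
)


class ScoringError(ValueError):
    """Base class for scoring failures."""


class ValidationError(ScoringError):
    """A nutrient value violates its domain (e.g. negative grams)."""


class MissingNutrientError(ScoringError):
    """A nutrient required for scoring is absent and imputation is off."""


class DuplicateItemError(ScoringError):
    """A catalog contains repeated item identifiers."""


class _Undefined:
    """Sentinel for an energy share that does not exist (zero calories)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "undefined"


#: Returned by :func:`energy_share` when calories == 0 under the
#: ``undefined_share`` policy.
UNDEFINED = _Undefined()

# Atwater energy-conversion factors, kcal per gram.
KCAL_PER_G_FAT = 9.0
KCAL_PER_G_CARB = 4.0
KCAL_PER_G_PROTEIN = 4.0


@dataclass(frozen=True)
class NutrientProfile:
    """FDA Restaurant Nutrients for one menu item, per serving as sold.

    ``trans_fat`` (g) and ``cholesterol`` (mg) are carried for completeness
    but never enter the score.  ``None`` marks a missing value; missing
    values are flagged at scoring time, never silently imputed.
    """

    calories: float | None          # kcal
    total_fat: float | None         # g
    saturated_fat: float | None     # g
    sodium: float | None            # mg
    carbohydrate: float | None      # g
    fiber: float | None             # g
    sugars: float | None            # g
    protein: float | None           # g
    trans_fat: float | None = 0.0   # g, carried, unused
    cholesterol: float | None = 0.0  # mg, carried, unused

    #: Fields that must be present and finite to score an item.
    REQUIRED = (
        "calories", "total_fat", "saturated_fat", "sodium",
        "carbohydrate", "fiber", "sugars", "protein",
    )

    def missing_fields(self) -> list[str]:
        out = []
        for name in self.REQUIRED:
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                out.append(name)
        return out

    def validate(self) -> None:
        """Raise if any required field is missing or negative."""
        missing = self.missing_fields()
        if missing:
            raise MissingNutrientError(
                f"missing nutrient value(s): {', '.join(missing)}"
            )
        for name in self.REQUIRED:
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    def scaled(self, k: float) -> "NutrientProfile":
        """Return the profile with every field (and calories) scaled by k."""

        def mul(v):
            return None if v is None else v * k

        return replace(
            self,
            calories=mul(self.calories),
            total_fat=mul(self.total_fat),
            saturated_fat=mul(self.saturated_fat),
            sodium=mul(self.sodium),
            carbohydrate=mul(self.carbohydrate),
            fiber=mul(self.fiber),
            sugars=mul(self.sugars),
            protein=mul(self.protein),
            trans_fat=mul(self.trans_fat),
            cholesterol=mul(self.cholesterol),
        )


@dataclass(frozen=True)
class ScoringCriteria:
    """Thresholds and edge-case conventions of the scoring algorithm.

    Defaults reproduce the published algorithm exactly.  Window bounds are
    fractions of calories; ``sodium_per_kcal_max`` is mg per kcal;
    ``fiber_per_100kcal_min`` is grams per 100 kcal.

    ``boundary_policy``
        ``closed_windows`` (default): "between 20% and 35%" includes both
        endpoints.  ``open_windows``: windows exclude their endpoints.
        One-sided criteria keep their literal reading under either policy
        ("less than" strict, "or more" inclusive).
    ``zero_calorie_policy``
        ``undefined_share`` (default): with 0 calories every
        percent-of-calories and per-calorie criterion is unsatisfied, while
        the fiber floor (1.4 g per 100 kcal → ≥ 0 g) is trivially met.
        ``no_points``: a zero-calorie item scores 0.
    ``missing_policy``
        ``error`` (default): refuse to score an incomplete profile.
        ``impute_zero``: treat missing nutrients as 0 with a logged warning.
    """

    fat_share_window: tuple[float, float] = (0.20, 0.35)
    satfat_share_max: float = 0.10
    sodium_per_kcal_max: float = 1.15
    carb_share_window: tuple[float, float] = (0.45, 0.65)
    fiber_per_100kcal_min: float = 1.4
    sugar_share_max: float = 0.10
    protein_share_window: tuple[float, float] = (0.10, 0.30)
    kcal_per_g_fat: float = KCAL_PER_G_FAT
    kcal_per_g_carb: float = KCAL_PER_G_CARB
    kcal_per_g_protein: float = KCAL_PER_G_PROTEIN
    zero_calorie_policy: str = "undefined_share"
    boundary_policy: str = "closed_windows"
    missing_policy: str = "error"

    def __post_init__(self) -> None:
        for name in ("fat_share_window", "carb_share_window",
                     "protein_share_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name}: lower bound {lo} must be "
                                      f"< upper bound {hi}")
        for name in ("satfat_share_max", "sodium_per_kcal_max",
                     "fiber_per_100kcal_min", "sugar_share_max",
                     "kcal_per_g_fat", "kcal_per_g_carb",
                     "kcal_per_g_protein"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.zero_calorie_policy not in ("undefined_share", "no_points"):
            raise ValidationError(
                f"unknown zero_calorie_policy {self.zero_calorie_policy!r}")
        if self.boundary_policy not in ("closed_windows", "open_windows"):
            raise ValidationError(
                f"unknown boundary_policy {self.boundary_policy!r}")
        if self.missing_policy not in ("error", "impute_zero"):
            raise ValidationError(
                f"unknown missing_policy {self.missing_policy!r}")

    def in_window(self, x: float, window: tuple[float, float]) -> bool:
        lo, hi = window
        if self.boundary_policy == "closed_windows":
            return lo <= x <= hi
        return lo < x < hi


DEFAULT_CRITERIA = ScoringCriteria()


@dataclass(frozen=True)
class ScoredItem:
    """A menu item with its per-component awards and total FFHS."""

    item_id: str
    profile: NutrientProfile
    awards: Mapping[str, bool]
    ffhs: int

    def __post_init__(self) -> None:
        if set(self.awards) != set(COMPONENTS):
            raise ScoringError("awards must cover exactly the 7 components")
        if self.ffhs != sum(self.awards.values()):
            raise ScoringError("ffhs must equal the number of awards")


def energy_share(nutrient_grams: float, kcal_per_gram: float,
                 calories: float,
                 policy: str = "undefined_share"):
    """Fraction of an item's calories contributed by one nutrient.

    Returns ``nutrient_grams * kcal_per_gram / calories`` for positive
    calories.  With zero calories the share does not exist: the
    ``undefined_share`` policy returns the :data:`UNDEFINED` sentinel and the
    ``no_points`` policy returns ``UNDEFINED`` as well (the distinction
    matters only to how :func:`score_item` treats the fiber criterion).
    """
    if nutrient_grams < 0:
        raise ValidationError(f"nutrient_grams must be >= 0, "
                              f"got {nutrient_grams}")
    if calories < 0:
        raise ValidationError(f"calories must be >= 0, got {calories}")
    if calories == 0:
        return UNDEFINED
    return nutrient_grams * kcal_per_gram / calories


def _impute(profile: NutrientProfile) -> NutrientProfile:
    missing = profile.missing_fields()
    if missing:
        logger.warning("imputing 0 for missing nutrient(s) %s", missing)
        profile = replace(profile, **{name: 0.0 for name in missing})
    return profile


def score_item(profile: NutrientProfile,
               criteria: ScoringCriteria = DEFAULT_CRITERIA,
               item_id: str = "") -> ScoredItem:
    """Apply the seven-criterion algorithm to one nutrient profile.

    Awards are evaluated on exact comparisons of the stated inequalities;
    shares are never rounded first.
    """
    if criteria.missing_policy == "impute_zero":
        profile = _impute(profile)
    try:
        profile.validate()
    except ScoringError as exc:
        raise type(exc)(f"item {item_id or '<unnamed>'}: {exc}") from None

    cal = profile.calories
    awards: dict[str, bool] = {}
    if cal == 0:
        for c in COMPONENTS:
            awards[c] = False
        if criteria.zero_calorie_policy == "undefined_share":
            # fiber floor scales with calories: >= 1.4 * 0 / 100 = 0 g
            awards["fiber"] = profile.fiber >= 0.0
    else:
        fat_share = profile.total_fat * criteria.kcal_per_g_fat / cal
        satfat_share = profile.saturated_fat * criteria.kcal_per_g_fat / cal
        carb_share = profile.carbohydrate * criteria.kcal_per_g_carb / cal
        sugar_share = profile.sugars * criteria.kcal_per_g_carb / cal
        protein_share = (profile.protein * criteria.kcal_per_g_protein / cal)
        awards["fat"] = criteria.in_window(fat_share,
                                           criteria.fat_share_window)
        awards["satfat"] = satfat_share < criteria.satfat_share_max
        awards["sodium"] = profile.sodium / cal < criteria.sodium_per_kcal_max
        awards["carb"] = criteria.in_window(carb_share,
                                            criteria.carb_share_window)
        awards["fiber"] = (profile.fiber
                           >= criteria.fiber_per_100kcal_min * cal / 100.0)
        awards["sugar"] = sugar_share < criteria.sugar_share_max
        awards["protein"] = criteria.in_window(protein_share,
                                               criteria.protein_share_window)
    return ScoredItem(item_id=item_id, profile=profile, awards=awards,
                      ffhs=sum(awards.values()))


@dataclass(frozen=True)
class CatalogSummary:
    """Catalog-level score distribution and per-component prevalence."""

    n_items: int
    #: share of items awarded each component's point
    component_prevalence: Mapping[str, float]
    #: count of items at each score 0–7 (all keys always present)
    histogram: Mapping[int, int]

    @property
    def mean_score(self) -> float:
        return sum(s * n for s, n in self.histogram.items()) / self.n_items

    @property
    def modal_score(self) -> int:
        return max(self.histogram, key=lambda s: (self.histogram[s], -s))


def score_catalog(catalog: Iterable[tuple[str, NutrientProfile]],
                  criteria: ScoringCriteria = DEFAULT_CRITERIA,
                  ) -> tuple[list[ScoredItem], CatalogSummary]:
    """Score every item in a catalog, preserving order.

    ``catalog`` yields ``(item_id, profile)`` pairs.  Raises on an empty
    catalog or duplicate item ids.
    """
    items = list(catalog)
    if not items:
        raise ScoringError("cannot score an empty catalog")
    seen: set[str] = set()
    dups: list[str] = []
    for item_id, _ in items:
        if item_id in seen:
            dups.append(item_id)
        seen.add(item_id)
    if dups:
        raise DuplicateItemError(f"duplicate item ids: {sorted(set(dups))}")

    scored = [score_item(profile, criteria, item_id=item_id)
              for item_id, profile in items]
    n = len(scored)
    prevalence = {c: sum(s.awards[c] for s in scored) / n
                  for c in COMPONENTS}
    hist = {k: 0 for k in range(8)}
    for s in scored:
        hist[s.ffhs] += 1
    return scored, CatalogSummary(n_items=n, component_prevalence=prevalence,
                                  histogram=hist)


# ---------------------------------------------------------------------------
# Delimited-text interface

_FRAME_FIELDS = {
    "calories": "calories",
    "total_fat": "total_fat_g",
    "saturated_fat": "saturated_fat_g",
    "trans_fat": "trans_fat_g",
    "cholesterol": "cholesterol_mg",
    "sodium": "sodium_mg",
    "carbohydrate": "carbohydrate_g",
    "fiber": "fiber_g",
    "sugars": "sugars_g",
    "protein": "protein_g",
}


def read_catalog(path) -> pd.DataFrame:
    """Read a catalog CSV and check the canonical header."""
    df = pd.read_csv(path)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns
               and c not in ("name", "vendor", "price")]
    if missing:
        raise ScoringError(f"catalog {path} lacks column(s): {missing}")
    return df


def profiles_from_frame(df: pd.DataFrame) -> list[tuple[str, NutrientProfile]]:
    """Build ``(item_id, NutrientProfile)`` pairs from catalog rows."""
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for attr, col in _FRAME_FIELDS.items():
            v = getattr(row, col, None)
            kwargs[attr] = None if v is None or (
                isinstance(v, float) and math.isnan(v)) else float(v)
        out.append((str(row.item_id), NutrientProfile(**kwargs)))
    return out


def score_frame(df: pd.DataFrame,
                criteria: ScoringCriteria = DEFAULT_CRITERIA,
                ) -> tuple[pd.DataFrame, CatalogSummary]:
    """Score a catalog DataFrame; returns it with awards_* and ffhs appended."""
    scored, summary = score_catalog(profiles_from_frame(df), criteria)
    out = df.copy()
    for c in COMPONENTS:
        out[f"awards_{c}"] = [s.awards[c] for s in scored]
    out["ffhs"] = [s.ffhs for s in scored]
    return out, summary


def scores_by_item(scored: Sequence[ScoredItem]) -> dict[str, int]:
    """Map item_id -> ffhs, for joining against a transaction ledger."""
    return {s.item_id: s.ffhs for s in scored}
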