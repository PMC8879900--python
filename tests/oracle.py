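"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written in a different style from the package (percent scale,
cross-multiplied inequalities, plain dict/loop aggregation) so that a shared
bug is unlikely.
"""

from __future__ import annotations


def naive_score(calories, fat, satfat, sodium, carb, fiber, sugar, protein,
                zero_policy="undefined_share"):
    """Criterion-by-criterion re-derivation of the seven-point score."""
    points = {}
    if calories <= 0:
        for name in ("fat", "satfat", "sodium", "carb", "sugar", "protein"):
            points[name] = False
        points["fiber"] = zero_policy == "undefined_share" and fiber >= 0
    else:
        def pct(grams, kcal_per_g):
            return 100.0 * grams * kcal_per_g / calories

        points["fat"] = 20.0 <= pct(fat, 9) <= 35.0
        points["satfat"] = pct(satfat, 9) < 10.0
        points["sodium"] = sodium < 1.15 * calories
        points["carb"] = 45.0 <= pct(carb, 4) <= 65.0
        points["fiber"] = 100.0 * fiber >= 1.4 * calories
        points["sugar"] = pct(sugar, 4) < 10.0
        points["protein"] = 10.0 <= pct(protein, 4) <= 30.0
    return sum(points.values()), points


def brute_force_aggregate(ledger, scores, assign):
    """Group-and-average re-computation of per-student-semester records.

    ``ledger`` is iterated row by row; ``assign`` maps a timestamp to a
    semester label or None.  Returns {(student_id, semester):
    (n_items, total_spend, avg_ffhs)}.
    """
    buckets: dict[tuple, list] = {}
    for row in ledger.itertuples(index=False):
        sem = assign(row.timestamp)
        if sem is None:
            continue
        buckets.setdefault((row.student_id, sem), []).append(
            (scores[str(row.item_id)], row.price))
    out = {}
    for key, rows in buckets.items():
        n = len(rows)
        spend = sum(p for _, p in rows)
        avg = sum(s for s, _ in rows) / n
        out[key] = (n, spend, avg)
    return out


def random_profile_kwargs(rng):
    """Random valid nutrient amounts spanning the realistic ranges."""
    return dict(
        calories=float(rng.uniform(1.0, 900.0)),
        total_fat=float(rng.uniform(0.0, 60.0)),
        saturated_fat=float(rng.uniform(0.0, 30.0)),
        sodium=float(rng.uniform(0.0, 2500.0)),
        carbohydrate=float(rng.uniform(0.0, 130.0)),
        fiber=float(rng.uniform(0.0, 15.0)),
        sugars=float(rng.uniform(0.0, 70.0)),
        protein=float(rng.uniform(0.0, 60.0)),
    )
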