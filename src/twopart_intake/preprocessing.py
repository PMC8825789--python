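"""Energy standardization, meat quartiles and descriptive tables.

Intakes are expressed per 2,000 kcal of the day's total energy so that
participants with different energy needs are comparable and part of any
energy-related misreporting cancels.  Population meat quartiles are plain
empirical quartiles of the energy-standardized exposure over the *total*
population (all age groups pooled) — the two-part model plays no role in
defining them — and predictions are later evaluated at each quartile's mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "energy_standardize",
    "QuartileSpec",
    "assign_quartiles",
    "person_exposure",
    "build_meat_quartiles",
    "descriptive_table",
]

REFERENCE_KCAL = 2000.0


def energy_standardize(grams, day_energy_kcal):
    """Rescale grams to g/2,000 kcal: ``grams * 2000 / day_energy_kcal``.

    Accepts scalars or arrays; zero grams stay zero (standardization never
    creates consumption).  Raises on non-positive energy, identifying the
    offending positions.
    """
    grams = np.asarray(grams, dtype=float)
    kcal = np.asarray(day_energy_kcal, dtype=float)
    bad = ~(kcal > 0)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))[:5].tolist()
        raise ValueError(f"non-positive day energy at positions {idx}")
    if np.any(grams < 0):
        raise ValueError("negative grams")
    out = grams * (REFERENCE_KCAL / kcal)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class QuartileSpec:
    """Population quartile cutpoints and within-quartile mean exposure."""

    cutpoints: tuple[float, float, float]
    quartile_means: tuple[float, float, float, float]
    basis: str  # "person" | "day"

    def __post_init__(self):
        c = self.cutpoints
        if not (c[0] < c[1] < c[2]):
            raise ValueError("cutpoints must be strictly ordered")
        m = self.quartile_means
        if not (m[0] <= m[1] <= m[2] <= m[3]):
            raise ValueError("quartile means must be ordered")


def assign_quartiles(values, basis: str = "person"
                     ) -> tuple[QuartileSpec, np.ndarray]:
    """Empirical quartiles over the pooled values.

    Uses the (n+1)p order-statistic rule with linear interpolation
    (``numpy`` method ``"weibull"``, the convention of the major survey
    statistics packages): on the integers 1..100 the cutpoints are
    25.25 / 50.5 / 75.75.  Returns the spec plus integer labels 1–4 per
    input value; a value equal to a cutpoint goes to the lower quartile.
    Requires at least 8 values and non-degenerate spread.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise ValueError("need at least 8 values to form quartiles")
    cutpoints = np.quantile(values, [0.25, 0.5, 0.75], method="weibull")
    if not (cutpoints[0] < cutpoints[1] < cutpoints[2]):
        raise ValueError("quartiles undefined: exposure values are too concentrated")
    labels = np.searchsorted(cutpoints, values, side="left") + 1
    means = tuple(float(values[labels == q].mean()) for q in (1, 2, 3, 4))
    spec = QuartileSpec(tuple(float(c) for c in cutpoints), means, basis)
    return spec, labels


def person_exposure(data: pd.DataFrame, basis: str = "person") -> pd.Series:
    """Exposure value per basis unit: the participant's mean over recall
    days (``basis="person"``, the default) or one value per participant-day.
    Exposure is stored once per participant-day across food groups, so the
    frame is first reduced to unique participant-days."""
    days = data.drop_duplicates(["participant_id", "day"])[
        ["participant_id", "day", "exposure"]]
    if basis == "person":
        return days.groupby("participant_id")["exposure"].mean()
    if basis == "day":
        return days.set_index(["participant_id", "day"])["exposure"]
    raise ValueError(f"unknown quartile basis {basis!r}")


def build_meat_quartiles(data: pd.DataFrame, basis: str = "person"
                         ) -> tuple[QuartileSpec, pd.Series]:
    """Quartile spec + per-unit labels from the exposure column of a recall
    frame, over the total population (all age groups pooled)."""
    exp = person_exposure(data, basis)
    spec, labels = assign_quartiles(exp.to_numpy(), basis=basis)
    return spec, pd.Series(labels, index=exp.index, name="meat_quartile")


def descriptive_table(data: pd.DataFrame,
                      quartile_labels: pd.Series | None = None,
                      beverage_groups: Iterable[str] = ()) -> pd.DataFrame:
    """Per-age-group (and optionally per meat quartile) descriptives.

    Reports mean and SD of daily energy intake (kcal), energy density
    (kcal/100 g over non-beverage food; beverages other than milk are
    excluded via ``beverage_groups``), and mean energy-standardized intake
    (g/2,000 kcal) per food group.  Returns a long frame with columns
    ``age_group, meat_quartile, metric, mean, sd`` where ``meat_quartile``
    is ``"all"`` for the unstratified rows.
    """
    if data.empty:
        raise ValueError("empty dataset")
    if data["kcal"].isna().any():
        raise ValueError("missing day energy (kcal)")
    df = data.copy()
    df["g_per_2000"] = energy_standardize(df["grams"], df["kcal"])
    if quartile_labels is not None:
        df = df.merge(quartile_labels.rename("meat_quartile"),
                      left_on="participant_id", right_index=True, how="left")
    else:
        df["meat_quartile"] = np.nan

    rows = []

    def summarize(sub: pd.DataFrame, age: str, quartile) -> None:
        days = sub.drop_duplicates(["participant_id", "day"])
        rows.append((age, quartile, "energy_kcal",
                     days["kcal"].mean(), days["kcal"].std()))
        food = sub[~sub["food_group"].isin(set(beverage_groups))]
        per_day = food.groupby(["participant_id", "day"]).agg(
            grams=("grams", "sum"), kcal=("kcal", "first"))
        eaten = per_day[per_day["grams"] > 0]
        density = eaten["kcal"] / (eaten["grams"] / 100.0)
        rows.append((age, quartile, "energy_density_kcal_per_100g",
                     density.mean(), density.std()))
        for fg, fsub in sub.groupby("food_group"):
            rows.append((age, quartile, f"intake_{fg}_g_per_2000kcal",
                         fsub["g_per_2000"].mean(), fsub["g_per_2000"].std()))

    for age, asub in df.groupby("age_group"):
        summarize(asub, age, "all")
        if quartile_labels is not None:
            for q, qsub in asub.groupby("meat_quartile"):
                summarize(qsub, age, int(q))

    return pd.DataFrame(rows, columns=["age_group", "meat_quartile",
                                       "metric", "mean", "sd"])
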