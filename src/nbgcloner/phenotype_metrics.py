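"""Cohort-level diabetes phenotype metrics for longitudinal mouse data.

Definitions follow the conventions used in NZO-based positional-cloning
cohorts: an animal is *diabetic* when its random blood glucose is at or
above 300 mg/dL for at least three consecutive weekly measurements; the
*case fatality rate* (CFR) is the fraction of diabetic animals that died
within the study window; *severe hyperglycemia* is a strictly-greater
comparison against 500 mg/dL at a fixed age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DIABETIC_GLUCOSE_MGDL = 300.0
DIABETIC_RUN_WEEKS = 3
SEVERE_GLUCOSE_MGDL = 500.0
STUDY_END_WEEK = 20


@dataclass
class PhenotypeTable:
    """Longitudinal per-animal phenotypes.

    ``data`` is a long-format frame with columns
    ``animal, genotype_group, week, glucose, weight, insulin`` (one row per
    animal-week; weeks are positive integers, glucose in mg/dL, weight in g,
    insulin in ng/mL). ``death_week`` maps animal id to the week of death;
    animals absent from the map survived the study. No observations may
    follow an animal's death week.
    """

    data: pd.DataFrame
    death_week: dict[str, int] = field(default_factory=dict)

    REQUIRED = ("animal", "genotype_group", "week", "glucose")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        if len(self.data):
            weeks = self.data["week"].to_numpy()
            if (weeks < 1).any() or not np.all(weeks == weeks.astype(int)):
                raise ValueError("weeks must be positive integers")
            if (self.data["glucose"].to_numpy() <= 0).any():
                raise ValueError("glucose values must be positive")
        for animal, dw in self.death_week.items():
            obs = self.data.loc[self.data["animal"] == animal, "week"]
            if len(obs) and (dw < obs.min() or (obs > dw).any()):
                raise ValueError(
                    f"animal {animal}: observations inconsistent with death week {dw}"
                )

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.data["animal"]))

    def glucose_series(self, animal: str) -> pd.Series:
        sub = self.data[self.data["animal"] == animal]
        return pd.Series(
            sub["glucose"].to_numpy(), index=sub["week"].to_numpy(), name=animal
        ).sort_index()

    def group_of(self, animal: str) -> str:
        return self.data.loc[self.data["animal"] == animal, "genotype_group"].iloc[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["dead"] = [
            int(self.death_week.get(a, -1) == w)
            for a, w in zip(out["animal"], out["week"])
        ]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path)
        death = {}
        if "dead" in df.columns:
            for a, w in df.loc[df["dead"] == 1, ["animal", "week"]].itertuples(
                index=False
            ):
                death[a] = int(w)
            df = df.drop(columns=["dead"])
        return cls(df, death)


def classify_diabetic(
    glucose_by_week: Mapping[int, float] | pd.Series,
    threshold: float = DIABETIC_GLUCOSE_MGDL,
    run_weeks: int = DIABETIC_RUN_WEEKS,
) -> bool:
    """True iff some run of >= ``run_weeks`` consecutive observed weeks all
    have glucose >= ``threshold`` (inclusive: "equal or over").

    A missing week breaks a run: runs are evaluated over consecutive week
    numbers, not merely consecutive rows.
    """
    series = pd.Series(dict(glucose_by_week)).sort_index()
    if series.empty:
        raise ValueError("empty glucose series")
    run = 0
    prev_week = None
    for week, value in series.items():
        consecutive = prev_week is not None and week == prev_week + 1
        if value >= threshold:
            run = run + 1 if (consecutive and run > 0) else 1
        else:
            run = 0
        if run >= run_weeks:
            return True
        prev_week = week
    return False


def diabetes_onset_week(
    glucose_by_week: Mapping[int, float] | pd.Series,
    threshold: float = DIABETIC_GLUCOSE_MGDL,
    run_weeks: int = DIABETIC_RUN_WEEKS,
) -> int | None:
    """Week at which the diabetic run rule is first satisfied, else None."""
    series = pd.Series(dict(glucose_by_week)).sort_index()
    if series.empty:
        raise ValueError("empty glucose series")
    run = 0
    prev_week = None
    for week, value in series.items():
        consecutive = prev_week is not None and week == prev_week + 1
        if value >= threshold:
            run = run + 1 if (consecutive and run > 0) else 1
        else:
            run = 0
        if run >= run_weeks:
            return int(week)
        prev_week = week
    return None


def diabetes_prevalence(
    cohort: PhenotypeTable,
    threshold: float = DIABETIC_GLUCOSE_MGDL,
    run_weeks: int = DIABETIC_RUN_WEEKS,
) -> tuple[float, pd.Series]:
    """Fraction of diabetic animals plus the cumulative-by-week curve.

    The cumulative curve gives, for every observed week, the fraction of the
    whole cohort diagnosed at or before that week (non-decreasing by
    construction). Both the final fraction and the curve are returned because
    either may be the quantity plotted in a prevalence panel.
    """
    animals = cohort.animals
    if not animals:
        raise ValueError("empty cohort")
    onsets = {}
    for a in animals:
        onset = diabetes_onset_week(cohort.glucose_series(a), threshold, run_weeks)
        if onset is not None:
            onsets[a] = onset
    n = len(animals)
    weeks = sorted(cohort.data["week"].unique())
    curve = pd.Series(
        [sum(1 for w in onsets.values() if w <= week) / n for week in weeks],
        index=weeks,
        name="cumulative_prevalence",
        dtype=float,
    )
    return len(onsets) / n, curve


def case_fatality_rate(
    cohort: PhenotypeTable,
    study_end_week: int = STUDY_END_WEEK,
    threshold: float = DIABETIC_GLUCOSE_MGDL,
    run_weeks: int = DIABETIC_RUN_WEEKS,
) -> float:
    """Deaths among diabetic animals at or before ``study_end_week``, divided
    by the number of diabetic animals (not the whole cohort).

    Returns NaN with a warning when no animal qualifies as diabetic: the rate
    is undefined, not zero.
    """
    diabetic = [
        a
        for a in cohort.animals
        if classify_diabetic(cohort.glucose_series(a), threshold, run_weeks)
    ]
    if not diabetic:
        warnings.warn("no diabetic animals: case fatality rate undefined")
        return float("nan")
    deaths = sum(
        1
        for a in diabetic
        if a in cohort.death_week and cohort.death_week[a] <= study_end_week
    )
    return deaths / len(diabetic)


def severe_hyperglycemia_fraction(
    cohort: PhenotypeTable,
    threshold: float = SEVERE_GLUCOSE_MGDL,
    week: int = 15,
) -> float:
    """Fraction of animals with glucose strictly above ``threshold`` at
    ``week``, among animals observed at that week (dead animals drop out of
    the denominator)."""
    at_week = cohort.data[cohort.data["week"] == week]
    if at_week.empty:
        raise ValueError(f"no observations at week {week}")
    return float((at_week["glucose"] > threshold).mean())


def bin_islet_areas(areas, bin_width: float = 10_000.0) -> np.ndarray:
    """Histogram of islet areas into half-open bins [k*w, (k+1)*w).

    A value exactly on a boundary falls in the upper bin. Returns the count
    per bin from bin 0 up to the bin of the largest area; an empty input
    yields a zero-length count vector.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        return np.zeros(0, dtype=int)
    if (areas < 0).any():
        raise ValueError("negative islet area")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    idx = np.floor(areas / bin_width).astype(int)
    return np.bincount(idx)
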