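"""Mortality surfaces: age x year grids of central death rates.

The central death rate ``m_{x,t}`` is deaths at age ``x`` in year ``t``
divided by person-years of exposure.  All models in this package operate on
the logged rates ``ln m_{x,t}`` of a complete (gap-free) surface; missing
cells are carried explicitly as NaN by the reader and must be resolved
(by restricting ages/years) before modelling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySurface",
    "read_hmd_mx",
    "average_populations",
    "group_five_year",
]


class SurfaceAlignmentError(ValueError):
    """Raised when surfaces that must share a grid do not."""


@dataclass
class MortalitySurface:
    """A population's central death rates on an age x year grid.

    Parameters
    ----------
    ages : ndarray of int
        Age labels, strictly increasing.  An open age group (e.g. "110+")
        is stored under its lower bound.
    years : ndarray of int
        Calendar years, strictly increasing with unit step.
    m : ndarray, shape (n_ages, n_years)
        Central death rates (per person-year).  Strictly positive where
        observed; NaN marks a missing cell.
    population_id : str
        Free-text label.
    """

    ages: np.ndarray
    years: np.ndarray
    m: np.ndarray
    population_id: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (self.ages.size, self.years.size):
            raise ValueError(
                f"rate matrix shape {self.m.shape} does not match "
                f"{self.ages.size} ages x {self.years.size} years"
            )
        if self.ages.size and np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if self.years.size > 1 and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        observed = ~np.isnan(self.m)
        if np.any(self.m[observed] <= 0):
            raise ValueError("observed death rates must be strictly positive")

    @property
    def n_ages(self) -> int:
        return self.ages.size

    @property
    def n_years(self) -> int:
        return self.years.size

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.m))

    @property
    def log_m(self) -> np.ndarray:
        """ln m_{x,t}; finite wherever m is observed, NaN where missing."""
        with np.errstate(invalid="ignore"):
            return np.log(self.m)

    def require_complete(self, context: str = "model fitting") -> None:
        if not self.is_complete:
            n = int(np.isnan(self.m).sum())
            raise ValueError(
                f"surface '{self.population_id}' has {n} missing cells; "
                f"{context} requires a complete surface"
            )

    def window(self, year_from: int, year_to: int) -> "MortalitySurface":
        """Restrict to years [year_from, year_to] inclusive."""
        mask = (self.years >= year_from) & (self.years <= year_to)
        if not mask.any():
            raise ValueError(f"no years in [{year_from}, {year_to}]")
        return MortalitySurface(
            self.ages, self.years[mask], self.m[:, mask], self.population_id
        )

    def to_frame(self) -> pd.DataFrame:
        """Rates as a DataFrame with ages as rows and years as columns."""
        return pd.DataFrame(self.m, index=self.ages, columns=self.years)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().rename_axis("age").to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf, population_id: str = "") -> "MortalitySurface":
        df = pd.read_csv(path_or_buf, index_col=0)
        return cls(
            df.index.to_numpy(int),
            df.columns.to_numpy(int),
            df.to_numpy(float),
            population_id,
        )


_SEX_COLUMNS = {"female": "Female", "male": "Male", "total": "Total"}


def read_hmd_mx(
    source,
    sex: str = "total",
    age_max: int = 100,
    year_range: tuple[int, int] | None = None,
    population_id: str = "",
) -> MortalitySurface:
    """Read an HMD ``Mx_1x1.txt`` table into a :class:`MortalitySurface`.

    The format is a text header block followed by whitespace-delimited
    columns ``Year  Age  Female  Male  Total``.  ``Age`` may be an open
    group like ``110+`` (stored under 110) and rates may be ``"."``
    (missing; stored as NaN, never as zero).

    Parameters
    ----------
    source : path or text stream
    sex : {"female", "male", "total"}
    age_max : int
        Keep ages 0..age_max.
    year_range : (int, int), optional
        Inclusive year window; defaults to all years present.
    """
    if sex not in _SEX_COLUMNS:
        raise ValueError(f"sex must be one of {sorted(_SEX_COLUMNS)}, got {sex!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()

    records: list[tuple[int, int, float]] = []
    col = {"female": 2, "male": 3, "total": 4}[sex]
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "Year":
            header_seen = True
            continue
        if not parts[0].isdigit():
            if header_seen:
                raise ValueError(f"line {lineno}: malformed row {line!r}")
            continue  # free-text header block
        if len(parts) < 5:
            raise ValueError(f"line {lineno}: expected 5 columns, got {len(parts)}")
        year = int(parts[0])
        age_str = parts[1]
        try:
            age = int(age_str.rstrip("+"))
        except ValueError:
            raise ValueError(f"line {lineno}: unparseable age {age_str!r}") from None
        raw = parts[col]
        if raw == ".":
            rate = np.nan
        else:
            try:
                rate = float(raw)
            except ValueError:
                raise ValueError(
                    f"line {lineno}: unparseable rate {raw!r}"
                ) from None
        records.append((year, age, rate))

    if not records:
        raise ValueError("no data rows found")

    df = pd.DataFrame(records, columns=["year", "age", "rate"])
    df = df[df["age"] <= age_max]
    if year_range is not None:
        lo, hi = year_range
        df = df[(df["year"] >= lo) & (df["year"] <= hi)]
        if df.empty or df["year"].min() > lo or df["year"].max() < hi:
            raise ValueError(
                f"requested years [{lo}, {hi}] not fully present in source"
            )
    if df.empty:
        raise ValueError("no rows after age/year selection")

    df = df.drop_duplicates(subset=["year", "age"], keep="first")
    wide = df.pivot(index="age", columns="year", values="rate")  # keeps NaN cells
    wide = wide.sort_index().sort_index(axis=1)
    return MortalitySurface(
        wide.index.to_numpy(int),
        wide.columns.to_numpy(int),
        wide.to_numpy(float),
        population_id,
    )


def _check_aligned(surfaces: list[MortalitySurface]) -> None:
    first = surfaces[0]
    for s in surfaces[1:]:
        if not (
            np.array_equal(s.ages, first.ages)
            and np.array_equal(s.years, first.years)
        ):
            raise SurfaceAlignmentError(
                f"surface '{s.population_id}' grid does not match "
                f"'{first.population_id}'"
            )


def average_populations(
    surfaces: list[MortalitySurface], population_id: str = "average"
) -> MortalitySurface:
    """Cell-wise average of log rates across populations.

    The result's log rate is the arithmetic mean of the input log rates,
    i.e. the output rate is the geometric mean of the input rates.  This is
    the averaged population on which a multi-population common factor is
    fitted.
    """
    if not surfaces:
        raise ValueError("need at least one surface")
    _check_aligned(surfaces)
    for s in surfaces:
        s.require_complete("population averaging")
    mean_log = np.mean([s.log_m for s in surfaces], axis=0)
    return MortalitySurface(
        surfaces[0].ages, surfaces[0].years, np.exp(mean_log), population_id
    )


def group_five_year(surface: MortalitySurface) -> MortalitySurface:
    """Regroup single-year ages 0..100 into abridged five-year groups.

    Groups are {0, 1-4, 5-9, ..., 95-99, 100} (22 groups), labelled by
    their lower bound; each group's log rate is the unweighted mean of the
    member log rates.
    """
    if not np.array_equal(surface.ages, np.arange(101)):
        raise ValueError("five-year grouping requires single-year ages 0..100")
    surface.require_complete("five-year grouping")
    bounds = [(0, 0), (1, 4)] + [(a, a + 4) for a in range(5, 100, 5)] + [(100, 100)]
    log_m = surface.log_m
    grouped = np.empty((len(bounds), surface.n_years))
    labels = np.empty(len(bounds), dtype=int)
    for g, (lo, hi) in enumerate(bounds):
        labels[g] = lo
        grouped[g] = log_m[lo : hi + 1].mean(axis=0)
    return MortalitySurface(
        labels, surface.years, np.exp(grouped), surface.population_id
    )
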