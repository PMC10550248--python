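"""Age estimation, sample composition, sex-ratio test and age-range trimming.

Red kangaroo age is estimated from molar progression: the molar index
``M`` counts molars that have moved past the posterior rims of the
zygomatic arches, and age follows ``log_e(A) = 2.2278 + 0.359 M`` with
``A`` in days.  Because the source aging curve's unit convention cannot
be verified here, a post-hoc multiplicative ``scale`` is exposed
(default 1.0, i.e. the formula exactly as printed).

The two study populations differ in sampling intensity and age span;
``trim_to_common_age_range`` implements the rule of restricting one
population to the age interval observed in the other before any
between-population comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AGE_INTERCEPT, AGE_SLOPE, DAYS_PER_YEAR, PROPERTIES


def age_from_molar_index(molar_index, scale: float = 1.0):
    """Age in days from the molar index, ``exp(2.2278 + 0.359 M) * scale``.

    Strictly increasing in ``M``; vectorised over array input.
    Raises ``ValueError`` for negative or non-finite molar indices.
    """
    m = np.asarray(molar_index, dtype=float)
    if not np.all(np.isfinite(m)) or np.any(m < 0):
        raise ValueError("molar index must be finite and >= 0")
    out = np.exp(AGE_INTERCEPT + AGE_SLOPE * m) * scale
    return float(out) if np.isscalar(molar_index) else out


def molar_index_from_age(age_days, scale: float = 1.0):
    """Inverse of :func:`age_from_molar_index` (used by the generator)."""
    a = np.asarray(age_days, dtype=float)
    if np.any(a <= 0):
        raise ValueError("age must be strictly positive")
    out = (np.log(a / scale) - AGE_INTERCEPT) / AGE_SLOPE
    return float(out) if np.isscalar(age_days) else out


def with_ages(records: pd.DataFrame, scale: float = 1.0) -> pd.DataFrame:
    """Return a copy with ``age_days`` and ``age_years`` derived from M."""
    out = records.copy()
    out["age_days"] = age_from_molar_index(out["molar_index"].to_numpy(), scale=scale)
    out["age_years"] = out["age_days"] / DAYS_PER_YEAR
    return out


@dataclass
class SexRatioTest:
    """Pearson chi-squared homogeneity test on a 2x2 population-by-sex table."""

    counts: np.ndarray
    statistic: float
    df: int
    p: float
    yates: bool


def sex_ratio_test(counts, yates: bool = True) -> SexRatioTest:
    """Chi-squared test of equal sex ratios across the two populations.

    ``counts`` is the 2x2 table of (population x sex) counts.  The
    continuity correction defaults on, matching the conventional default
    for 2x2 tables; set ``yates=False`` for the uncorrected statistic.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    stat, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return SexRatioTest(counts=table.astype(int), statistic=float(stat), df=int(df),
                        p=float(p), yates=yates)


def generations_since(year_start: int, year_end: int, months_per_generation: float = 30.0) -> int:
    """Minimum whole generations elapsed between two calendar years.

    With 30 months per generation, 1975 to 2018 gives floor(43 * 12 / 30)
    = 17 generations.
    """
    if year_end < year_start:
        raise ValueError("year_end must not precede year_start")
    return int(math.floor((year_end - year_start) * 12.0 / months_per_generation))


@dataclass
class TrimReport:
    """Outcome of restricting one population to the other's age range."""

    kept: pd.DataFrame
    excluded_below: int
    excluded_above: int
    reference_range_years: tuple[float, float]
    reference_population: str
    trimmed_population: str


def trim_to_common_age_range(
    records: pd.DataFrame,
    reference_population: str = "dingoes_common",
    trimmed_population: str = "dingoes_rare",
) -> TrimReport:
    """Drop trimmed-population specimens outside the reference age range.

    The reference interval is the closed ``[min, max]`` of the reference
    population's ages; boundary ages are kept (exclusion requires strict
    exteriority).  The reference population itself is never touched.
    Idempotent: re-trimming the kept table removes nothing.
    """
    if "age_years" not in records.columns or records["age_years"].isna().any():
        raise ValueError("all records need an age_years value before trimming")
    for pop in (reference_population, trimmed_population):
        if pop not in PROPERTIES:
            raise ValueError(f"unknown population {pop!r}")
        if not (records["property"] == pop).any():
            raise ValueError(f"population {pop!r} is empty")

    ref_ages = records.loc[records["property"] == reference_population, "age_years"]
    lo, hi = float(ref_ages.min()), float(ref_ages.max())
    in_trim = records["property"] == trimmed_population
    below = in_trim & (records["age_years"] < lo)
    above = in_trim & (records["age_years"] > hi)
    kept = records.loc[~(below | above)].reset_index(drop=True)
    return TrimReport(
        kept=kept,
        excluded_below=int(below.sum()),
        excluded_above=int(above.sum()),
        reference_range_years=(lo, hi),
        reference_population=reference_population,
        trimmed_population=trimmed_population,
    )


def demographic_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-population counts, female proportion and age quantiles.

    Returns one row per population with columns ``n``, ``n_female``,
    ``n_male``, ``female_prop`` and (when ages are present) ``age_min``,
    ``age_median``, ``age_max`` in years.
    """
    if len(records) == 0:
        raise ValueError("cannot summarise an empty specimen table")
    rows = []
    for pop, grp in records.groupby("property", sort=True):
        n_f = int((grp["sex"] == "female").sum())
        n_m = int((grp["sex"] == "male").sum())
        row = {
            "property": pop,
            "n": len(grp),
            "n_female": n_f,
            "n_male": n_m,
            "female_prop": n_f / len(grp),
        }
        if "age_years" in grp.columns and grp["age_years"].notna().all():
            row["age_min"] = float(grp["age_years"].min())
            row["age_median"] = float(grp["age_years"].median())
            row["age_max"] = float(grp["age_years"].max())
        rows.append(row)
    return pd.DataFrame(rows).set_index("property")
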