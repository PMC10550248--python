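"""Seasonal vegetation-index anomalies and the site-difference
randomization test.

The enhanced vegetation index (EVI) arrives as a long table of 16-day
composites per grid cell.  Negative composites are clamped to zero
(they indicate bare ground or water, not vegetation).  Each observation
is then standardized against its own cell's calendar-month climatology
over the full record:

    dEVI(i, t) = (EVI(i, t) - mean_m[EVI(i, .)]) / sd_m[EVI(i, .)]

with the sample (n-1) standard deviation, so a cell-month group with
any spread has anomaly mean 0 and sd 1 by construction.  A moving
window of 6 consecutive composites (96 days) can be averaged over the
anomalies to suppress residual cloud/aerosol noise.

The between-site contrast is the difference of pooled anomaly medians
(south minus north).  Its null distribution is built by randomly
reassigning anomaly values between the sites: ``full_shuffle`` pools
all values and re-splits them at the original sizes; ``within_time_swap``
flips the site labels independently at each shared time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClampResult:
    observations: pd.DataFrame
    n_clamped: int


def clamp_nonnegative(observations: pd.DataFrame) -> ClampResult:
    """Replace negative index values with zero, counting replacements."""
    out = observations.copy()
    neg = out["evi"] < 0
    out.loc[neg, "evi"] = 0.0
    return ClampResult(observations=out, n_clamped=int(neg.sum()))


@dataclass
class AnomalySeries:
    """Per-observation standardized anomalies with month climatologies."""

    table: pd.DataFrame  # cell_id, site, date, evi, month, delta_evi [, w_smoothed]
    month_baselines: pd.DataFrame  # per (cell_id, month): mean, sd, flagged
    window: int | None = None

    @property
    def delta_evi(self) -> np.ndarray:
        return self.table["delta_evi"].to_numpy()


def seasonal_anomaly(observations: pd.DataFrame) -> AnomalySeries:
    """Standardize each cell's series against its calendar-month baseline.

    Requires >= 2 observations in every (cell, month) group; a group with
    zero spread yields anomaly 0 and is flagged in the baselines table.
    """
    df = observations.copy().sort_values(["site", "cell_id", "date"]).reset_index(drop=True)
    df["month"] = pd.to_datetime(df["date"]).dt.month

    sizes = df.groupby(["cell_id", "month"]).size()
    singletons = sizes[sizes < 2]
    if len(singletons):
        cell, month = singletons.index[0]
        raise ValueError(
            f"cell {cell!r}, calendar month {month}: only {singletons.iloc[0]} "
            "observation(s); need >= 2 to standardize"
        )

    grp = df.groupby(["cell_id", "month"])["evi"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # sample sd, ddof=1
    zero_sd = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        anom = (df["evi"] - mean) / sd
    anom[zero_sd] = 0.0
    df["delta_evi"] = anom

    baselines = (
        df.groupby(["cell_id", "month"])["evi"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    baselines["flagged"] = baselines["sd"] == 0
    return AnomalySeries(table=df, month_baselines=baselines)


def moving_window(anomalies: AnomalySeries, window: int = 6) -> AnomalySeries:
    """Forward moving average of anomalies over consecutive composites.

    ``w_smoothed`` at composite t is the mean of the ``window`` anomalies
    starting at t; it is undefined (NaN) where the window overruns the
    series end.  ``window=1`` reproduces the anomalies exactly.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    df = anomalies.table.copy()
    smoothed = np.full(len(df), np.nan)
    any_defined = False
    for _, grp in df.groupby(["site", "cell_id"], sort=False):
        grp = grp.sort_values("date")
        vals = grp["delta_evi"].to_numpy()
        if len(vals) >= window:
            any_defined = True
            w = np.convolve(vals, np.ones(window) / window, mode="valid")
            smoothed[grp.index[: len(w)]] = w
    if not any_defined:
        import warnings

        warnings.warn(f"window of {window} composites exceeds every series length")
    df["w_smoothed"] = smoothed
    return AnomalySeries(table=df, month_baselines=anomalies.month_baselines, window=window)


@dataclass
class RandomizationResult:
    """Observed vs. randomized between-site median difference."""

    observed: float
    null_draws: np.ndarray
    ci_low: float
    ci_high: float
    p: float
    n_iter: int
    seed: int
    mode: str
    n_south: int = 0
    n_north: int = 0


def randomization_median_test(
    south,
    north,
    n_iter: int = 10000,
    seed: int = 0,
    mode: str = "full_shuffle",
) -> RandomizationResult:
    """Randomization test for the south-minus-north median difference.

    Each iteration reassigns values between the sites — ``full_shuffle``
    pools everything and re-splits at the original sample sizes;
    ``within_time_swap`` (for series aligned on shared dates) flips the
    two sites' values independently per time point — and records the
    resulting null median difference.  The two-sided p-value compares
    |observed| against the null draws, counting the observed arrangement
    in both numerator and denominator; the 2.5th/97.5th percentiles of
    the null distribution delimit the band expected under pure chance.
    """
    south = np.asarray(south, dtype=float)
    north = np.asarray(north, dtype=float)
    if south.size == 0 or north.size == 0:
        raise ValueError("both sites need at least one value")
    if mode not in ("full_shuffle", "within_time_swap"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "within_time_swap" and south.size != north.size:
        raise ValueError("within_time_swap needs series aligned on shared dates")
    if n_iter < 100:
        import warnings

        warnings.warn(f"n_iter={n_iter} gives unstable percentile estimates")

    observed = float(np.median(south) - np.median(north))
    rng = np.random.default_rng(seed)
    ns = south.size
    draws = np.empty(n_iter)
    if mode == "full_shuffle":
        pool = np.concatenate([south, north])
        for i in range(n_iter):
            perm = rng.permutation(pool)
            draws[i] = np.median(perm[:ns]) - np.median(perm[ns:])
    else:
        for i in range(n_iter):
            flip = rng.random(ns) < 0.5
            s = np.where(flip, north, south)
            n_ = np.where(flip, south, north)
            draws[i] = np.median(s) - np.median(n_)

    extreme = int(np.sum(np.abs(draws) >= abs(observed) - 1e-12))
    p = (1 + extreme) / (n_iter + 1)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return RandomizationResult(
        observed=observed,
        null_draws=draws,
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(p),
        n_iter=n_iter,
        seed=seed,
        mode=mode,
        n_south=int(ns),
        n_north=int(north.size),
    )


def site_anomaly_test(
    anomalies: AnomalySeries,
    n_iter: int = 10000,
    seed: int = 0,
    mode: str = "full_shuffle",
    use_smoothed: bool = False,
) -> RandomizationResult:
    """Run the randomization test on pooled per-site anomaly values.

    All cells and dates are pooled per site (the default analysis uses
    the raw anomalies; set ``use_smoothed`` to test the moving-window
    values instead).
    """
    col = "w_smoothed" if use_smoothed else "delta_evi"
    df = anomalies.table.dropna(subset=[col])
    south = df.loc[df["site"] == "south", col].to_numpy()
    north = df.loc[df["site"] == "north", col].to_numpy()
    if mode == "within_time_swap":
        wide = df.pivot_table(index="date", columns="site", values=col, aggfunc="median")
        wide = wide.dropna()
        south, north = wide["south"].to_numpy(), wide["north"].to_numpy()
    return randomization_median_test(south, north, n_iter=n_iter, seed=seed, mode=mode)
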