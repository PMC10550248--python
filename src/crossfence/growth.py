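"""Von Bertalanffy growth modelling and grouped parameter contrasts.

The saturating growth curve

    L(t) = L_inf * (1 - exp(-k * (t - t0)))

is fitted by damped Gauss-Newton (Levenberg-Marquardt) least squares,
with ages in years so the growth coefficient ``k`` has units of 1/year.
Two-group comparisons (sexes or populations) refit the curve jointly as
baseline-plus-delta for each parameter and report Wald t statistics on
the deltas, ``t = delta / SE(delta)`` with ``df = n - 6``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

TRAIT_COLUMNS = {
    "cranial_size": "cranial_size",
    "weight": "weight_kg",
    "pes": "pes_length_cm",
}

PARAM_NAMES = ("L_inf", "k_growth", "t0")


def vb_curve(t, L_inf: float, k: float, t0: float):
    """Evaluate the growth curve; L(t0) = 0 and L -> L_inf as t -> inf."""
    return L_inf * (1.0 - np.exp(-k * (np.asarray(t, dtype=float) - t0)))


@dataclass
class GrowthModelFit:
    """Fitted growth parameters for one or two groups.

    For two-group fits, ``params`` holds the baseline (first group) and
    ``deltas`` the group-2-minus-group-1 offsets for each parameter, with
    Wald standard errors, t statistics and two-sided p-values.
    """

    trait: str
    groups: tuple[str, ...]
    params: dict[str, float]
    se: dict[str, float]
    deltas: dict[str, float] = field(default_factory=dict)
    delta_se: dict[str, float] = field(default_factory=dict)
    t_stats: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    df: int = 0
    n: int = 0
    residual_sd: float = float("nan")
    rss: float = float("nan")
    converged: bool = False
    n_iterations: int = 0

    def group_params(self, group: str) -> tuple[float, float, float]:
        """(L_inf, k, t0) for one fitted group."""
        if group == self.groups[0] or not self.deltas:
            return tuple(self.params[p] for p in PARAM_NAMES)
        return tuple(self.params[p] + self.deltas[p] for p in PARAM_NAMES)

    def predict(self, t, group: str | None = None):
        g = group if group is not None else self.groups[0]
        return vb_curve(t, *self.group_params(g))


def _initial_params(ages: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Self-start heuristic: asymptote above the data, rate from the
    log-linearised curve, zero-size age at the origin."""
    L0 = 1.05 * float(np.max(sizes))
    frac = 1.0 - sizes / L0
    ok = frac > 1e-12
    if ok.sum() >= 2 and np.ptp(ages[ok]) > 0:
        slope = np.polyfit(ages[ok], np.log(frac[ok]), 1)[0]
        k0 = max(-slope, 1e-3)
    else:
        k0 = 1.0 / max(np.ptp(ages), 1.0)
    return np.array([L0, k0, 0.0])


def _ls_fit(residual_fn, x0: np.ndarray, n: int):
    sol = optimize.least_squares(
        residual_fn, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        max_nfev=200 * (len(x0) + 1),
    )
    dof = n - len(x0)
    rss = float(2.0 * sol.cost)
    s2 = rss / dof if dof > 0 else float("nan")
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(x0), np.nan)
    return sol, rss, se, dof


def fit_vb(ages, sizes, init: tuple[float, float, float] | None = None,
           trait: str = "trait", group: str = "all") -> GrowthModelFit:
    """Least-squares fit of the growth curve to one group.

    Requires at least 4 observations spanning a nonzero age range.
    Non-convergence is reported on the returned fit (``converged`` flag)
    rather than raised, carrying the best iterate found.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if t.size < 4:
        raise ValueError(f"need at least 4 observations, got {t.size}")
    if np.ptp(t) <= 0:
        raise ValueError("ages must span a nonzero range")
    x0 = np.asarray(init, dtype=float) if init is not None else _initial_params(t, y)

    sol, rss, se, dof = _ls_fit(lambda p: vb_curve(t, *p) - y, x0, t.size)
    params = dict(zip(PARAM_NAMES, map(float, sol.x)))
    return GrowthModelFit(
        trait=trait,
        groups=(group,),
        params=params,
        se=dict(zip(PARAM_NAMES, map(float, se))),
        df=dof,
        n=int(t.size),
        residual_sd=math.sqrt(rss / dof) if dof > 0 else float("nan"),
        rss=rss,
        converged=bool(sol.success),
        n_iterations=int(sol.nfev),
    )


def compare_vb_groups(
    records: pd.DataFrame,
    trait: str,
    grouping: str = "sex",
    free_deltas: tuple[bool, bool, bool] = (True, True, True),
) -> GrowthModelFit:
    """Joint two-group growth fit with per-parameter contrasts.

    Each parameter is modelled as baseline + delta * I(second group); the
    groups are the sorted levels of the ``grouping`` column (``sex`` or
    ``property``).  ``free_deltas`` can pin individual deltas at zero;
    with all deltas pinned the fit collapses to the pooled single-group
    fit.  Wald ``t = delta/SE`` is reported with ``df = n - p`` where p
    counts the free parameters.
    """
    col = TRAIT_COLUMNS.get(trait, trait)
    group_col = {"sex": "sex", "population": "property"}.get(grouping, grouping)
    data = records.dropna(subset=["age_years", col])
    levels = tuple(sorted(data[group_col].unique()))
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")
    t = data["age_years"].to_numpy(dtype=float)
    y = data[col].to_numpy(dtype=float)
    g = (data[group_col] == levels[1]).to_numpy(dtype=float)
    if min((g == 0).sum(), (g == 1).sum()) < 4:
        raise ValueError("each group needs at least 4 observations")

    free = np.asarray(free_deltas, dtype=bool)
    # initialise from separate per-group fits: robust against the mixed-group
    # log-linearisation landing in a degenerate basin
    try:
        fit1 = fit_vb(t[g == 0], y[g == 0])
        fit2 = fit_vb(t[g == 1], y[g == 1])
        base0 = np.array([fit1.params[p] for p in PARAM_NAMES])
        delta0 = np.array([fit2.params[p] - fit1.params[p] for p in PARAM_NAMES])
    except Exception:
        base0 = _initial_params(t, y)
        delta0 = np.zeros(3)
    x0 = np.concatenate([base0, delta0[free]])

    def unpack(p):
        base = p[:3]
        deltas = np.zeros(3)
        deltas[free] = p[3:]
        return base, deltas

    def resid(p):
        base, deltas = unpack(p)
        L = base[0] + deltas[0] * g
        k = base[1] + deltas[1] * g
        t0 = base[2] + deltas[2] * g
        return L * (1.0 - np.exp(-k * (t - t0))) - y

    sol, rss, se, dof = _ls_fit(resid, x0, t.size)
    base, deltas = unpack(sol.x)
    se_base = se[:3]
    se_delta = np.full(3, np.nan)
    se_delta[free] = se[3:]

    t_stats, p_values, d_se, d_val = {}, {}, {}, {}
    for i, name in enumerate(PARAM_NAMES):
        if not free[i]:
            continue
        d_val[name] = float(deltas[i])
        d_se[name] = float(se_delta[i])
        tval = deltas[i] / se_delta[i] if se_delta[i] > 0 else float("nan")
        t_stats[name] = float(tval)
        p_values[name] = float(2.0 * stats.t.sf(abs(tval), dof)) if dof > 0 else float("nan")

    return GrowthModelFit(
        trait=trait,
        groups=levels,
        params=dict(zip(PARAM_NAMES, map(float, base))),
        se=dict(zip(PARAM_NAMES, map(float, se_base))),
        deltas=d_val,
        delta_se=d_se,
        t_stats=t_stats,
        p_values=p_values,
        df=dof,
        n=int(t.size),
        residual_sd=math.sqrt(rss / dof) if dof > 0 else float("nan"),
        rss=rss,
        converged=bool(sol.success),
        n_iterations=int(sol.nfev),
    )


def divergence_age(fit: GrowthModelFit, threshold: float, t_max: float = 50.0,
                   tol: float = 1e-9) -> float:
    """Smallest age at which the two fitted curves differ by more than
    ``threshold`` trait units; ``inf`` if they never do before ``t_max``.

    Found by grid scan for the first crossing followed by bisection, so a
    non-monotone absolute difference still yields its first crossing.
    """
    if len(fit.groups) != 2 or not fit.deltas:
        raise ValueError("divergence_age needs a fitted two-group model")
    p1 = fit.group_params(fit.groups[0])
    p2 = fit.group_params(fit.groups[1])

    def gap(t):
        return abs(vb_curve(t, *p1) - vb_curve(t, *p2)) - threshold

    t_lo = max(p1[2], p2[2])
    if threshold == 0.0 and any(abs(d) > 0 for d in fit.deltas.values()):
        return float(t_lo)
    grid = np.linspace(t_lo, t_max, 2048)
    vals = np.array([gap(t) for t in grid])
    above = np.flatnonzero(vals > 0)
    if above.size == 0:
        return float("inf")
    i = above[0]
    if i == 0:
        return float(grid[0])
    lo, hi = grid[i - 1], grid[i]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))
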