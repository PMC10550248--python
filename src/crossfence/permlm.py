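"""Residual-randomization permutational linear models (RRPP).

Univariate and multivariate responses share one engine: sequential
(type-I) sums of squares from nested least-squares projections, with a
null distribution for each term built by permuting the residuals of that
term's reduced model, adding them back to the reduced fitted values, and
recomputing the F statistic.  This is the standard resampling scheme for
Procrustes ANOVA on shape data, and it reduces exactly to classical
regression F statistics in the univariate single-term case.

The permutation p-value counts the observed arrangement as one
permutation: ``p = (1 + #{F_perm >= F_obs}) / n_perm``, so the smallest
attainable p is ``1/n_perm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AliasingError(ValueError):
    """A design term adds no new dimensions (rank-deficient design)."""


def build_term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for one model term.

    Numeric columns contribute themselves; categorical columns contribute
    treatment-coded dummies (sorted levels, first dropped); ``a:b``
    contributes all pairwise products of the two factors' columns.
    """
    if ":" in term:
        left, right = term.split(":", 1)
        a = build_term_columns(data, left)
        b = build_term_columns(data, right)
        return np.hstack([a[:, [i]] * b[:, [j]] for i in range(a.shape[1]) for j in range(b.shape[1])])
    col = data[term]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float).reshape(-1, 1)
    levels = sorted(col.unique())
    return np.column_stack([(col == lv).to_numpy(dtype=float) for lv in levels[1:]])


@dataclass
class PermLMResult:
    """Sequential-SS permutation ANOVA table."""

    terms: tuple[str, ...]
    ss: dict[str, float]
    df: dict[str, int]
    r_squared: dict[str, float]
    f: dict[str, float]
    p: dict[str, float]
    n_perm: int
    seed: int
    total_ss: float
    residual_ss: float
    residual_df: int
    coefficients: np.ndarray | None = None  # OLS coefs of the full model
    design_info: dict = field(default_factory=dict)

    @property
    def residual_r_squared(self) -> float:
        return self.residual_ss / self.total_ss if self.total_ss > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "df": self.df[t], "SS": self.ss[t], "R2": self.r_squared[t],
             "F": self.f[t], "P": self.p[t]}
            for t in self.terms
        ]
        rows.append({"term": "residual", "df": self.residual_df, "SS": self.residual_ss,
                     "R2": self.residual_r_squared, "F": np.nan, "P": np.nan})
        return pd.DataFrame(rows).set_index("term")


def rrpp_lm(
    Y,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "rrpp",
) -> PermLMResult:
    """Permutational linear model with sequential sums of squares.

    Parameters
    ----------
    Y
        ``(n,)`` or ``(n, p)`` response matrix.
    data
        Covariate/factor table, one row per observation.
    terms
        Ordered model terms; each term is tested against the residual
        mean square of the full model.
    method
        ``"rrpp"`` permutes each term's reduced-model residuals (the
        default); ``"full"`` permutes the raw response rows instead.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n = Y.shape[0]
    if len(data) != n:
        raise ValueError("response and covariate table disagree on n")
    if method not in ("rrpp", "full"):
        raise ValueError(f"unknown permutation method {method!r}")

    # nested design matrices: intercept, then cumulative terms
    blocks = [np.ones((n, 1))]
    dfs: list[int] = []
    rank_prev = 1
    for term in terms:
        cols = build_term_columns(data, term)
        X = np.hstack(blocks + [cols])
        rank = np.linalg.matrix_rank(X)
        if rank <= rank_prev:
            raise AliasingError(
                f"term {term!r} is aliased with earlier terms (adds no rank)"
            )
        dfs.append(rank - rank_prev)
        rank_prev = rank
        blocks.append(cols)
    total_df = rank_prev
    if n <= total_df:
        raise ValueError(f"need n > model df ({total_df}), got n = {n}")

    # orthonormal bases of the nested column spaces
    qs = []
    X = np.empty((n, 0))
    for b in blocks:
        X = np.hstack([X, b])
        q, _ = np.linalg.qr(X)
        qs.append(q[:, : np.linalg.matrix_rank(X)])

    def seq_stats(Ymat):
        """Sequential SS per term + residual SS for one response matrix."""
        norms = [float(np.sum((q.T @ Ymat) ** 2)) for q in qs]
        tot = float(np.sum(Ymat**2))
        ss_terms = np.diff(norms)
        return ss_terms, tot - norms[-1]

    ss_obs, ss_res = seq_stats(Y)
    df_res = n - total_df
    ms_res = ss_res / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_obs / np.asarray(dfs)) / ms_res if ms_res > 0 else np.where(
            ss_obs > 0, np.inf, 0.0
        )
    ss_total = float(np.sum((Y - Y.mean(axis=0)) ** 2))

    rng = np.random.default_rng(seed)
    exceed = np.ones(len(terms))  # observed case counts as one permutation
    fitted_red = [qs[j] @ (qs[j].T @ Y) for j in range(len(terms))]
    resid_red = [Y - fr for fr in fitted_red]
    for _ in range(n_perm - 1):
        perm = rng.permutation(n)
        for j in range(len(terms)):
            if method == "rrpp":
                Yp = fitted_red[j] + resid_red[j][perm]
            else:
                Yp = Y[perm]
            ssp, ssr = seq_stats(Yp)
            msr = ssr / df_res
            fp = (ssp[j] / dfs[j]) / msr if msr > 0 else (np.inf if ssp[j] > 0 else 0.0)
            tol = 1e-12 * max(1.0, abs(f_obs[j])) if np.isfinite(f_obs[j]) else 0.0
            if fp >= f_obs[j] - tol:
                exceed[j] += 1
    p_vals = exceed / n_perm

    beta, *_ = np.linalg.lstsq(np.hstack(blocks), Y, rcond=None)
    return PermLMResult(
        terms=tuple(terms),
        ss=dict(zip(terms, map(float, ss_obs))),
        df=dict(zip(terms, map(int, dfs))),
        r_squared={t: float(s / ss_total) for t, s in zip(terms, ss_obs)},
        f=dict(zip(terms, map(float, f_obs))),
        p=dict(zip(terms, map(float, p_vals))),
        n_perm=n_perm,
        seed=seed,
        total_ss=ss_total,
        residual_ss=float(ss_res),
        residual_df=int(df_res),
        coefficients=beta,
        design_info={"method": method, "model_df": int(total_df)},
    )


RESPONSES = ("shape", "cranial_size", "weight", "pes")


def interpopulation_tests(
    records: pd.DataFrame,
    shapes,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    use_symmetric: bool = True,
) -> dict[tuple[str, str], PermLMResult]:
    """Between-population permutation models, run separately per sex.

    For each sex, models ``response ~ age + population`` for cranial
    shape (multivariate symmetric Procrustes coordinates), cranial
    centroid size, body weight and pes length.  An ``age:population``
    interaction is added and the interaction model is retained whenever
    its permutation p-value is at most ``alpha``.
    """
    from .morphometrics import AlignedShapeSet  # local import avoids a cycle

    assert isinstance(shapes, AlignedShapeSet)
    shape_block = shapes.symmetric_component if use_symmetric else shapes.procrustes_coords
    flat = shape_block.reshape(shapes.n, -1)
    if len(set(shapes.specimen_ids)) != len(shapes.specimen_ids):
        raise ValueError("duplicate specimen ids in the aligned shape set")
    id_to_row = {sid: i for i, sid in enumerate(shapes.specimen_ids)}

    results: dict[tuple[str, str], PermLMResult] = {}
    for si, sex in enumerate(("female", "male")):
        sub = records[records["sex"] == sex].reset_index(drop=True)
        cells = sub.groupby("property").size()
        if len(cells) < 2 or (cells < 2).any():
            raise ValueError(f"{sex}: need both populations represented, got {dict(cells)}")
        rows = [id_to_row[s] for s in sub["specimen_id"]]
        responses = {
            "shape": flat[rows],
            "cranial_size": shapes.centroid_sizes[rows],
            "weight": sub["weight_kg"].to_numpy(dtype=float),
            "pes": sub["pes_length_cm"].to_numpy(dtype=float),
        }
        data = sub[["age_years", "property"]]
        for ri, (name, Y) in enumerate(responses.items()):
            sub_seed = seed + 1000 * si + ri
            base = rrpp_lm(Y, data, ["age_years", "property"], n_perm=n_perm, seed=sub_seed)
            inter = rrpp_lm(
                Y, data, ["age_years", "property", "age_years:property"],
                n_perm=n_perm, seed=sub_seed,
            )
            keep = inter if inter.p["age_years:property"] <= alpha else base
            results[(sex, name)] = keep
    return results
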