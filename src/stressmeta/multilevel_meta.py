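"""Multilevel random-effects meta-analysis with known sampling covariance.

Model
-----
For a vector of effect sizes y with design matrix X,

    y ~ N(X beta, M),    M = V + sum_t sigma_t^2 Z_t Z_t',

where V is the *known* sampling variance-covariance matrix (block-diagonal
by cluster: effect sizes computed from the same organisms share a control
arm and are assigned correlation r, default 0.5) and each random term t is
a categorical grouping (study, species, country, author group) contributing
a variance component sigma_t^2; an effect-size-level identifier is always
included to absorb residual heterogeneity.

Variance components are estimated by (restricted) maximum likelihood over
log sigma_t^2 with L-BFGS-B and seedable multi-starts; fixed effects are
the GLS solution at the optimum with covariance (X' M^-1 X)^-1.  Inference
is Wald-z (symmetric CIs); the omnibus moderator test Q_M is a Wald
chi-square on all non-intercept coefficients (on all coefficients for
cell-means models without intercept).  Model comparison across random
structures uses ML AICs; reported fits default to REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VMatrix",
    "RandomStructure",
    "MetaFit",
    "ConvergenceError",
    "build_vmatrix",
    "fit_meta",
    "select_random_structure",
    "pooled_by_level",
    "latitude_metaregression",
]

_LOG_S2_BOUNDS = (-30.0, 5.0)
_Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """The likelihood optimizer failed to converge; carries the trace."""

    def __init__(self, message: str, trace: list | None = None) -> None:
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class VMatrix:
    """Known sampling variance-covariance matrix, block-diagonal by cluster.

    Diagonal entries are the effect sizes' sampling variances; within a
    cluster the covariance of effects i and j is r * sqrt(v_i * v_j); across
    clusters it is zero.
    """

    matrix: np.ndarray
    cluster_ids: tuple
    r: float

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


def build_vmatrix(effects: pd.DataFrame, r: float = 0.5) -> VMatrix:
    """Build the V matrix for a long effect-size table.

    ``effects`` needs ``variance`` (> 0) and ``cluster_id`` columns; row
    order is preserved, so V aligns with the table as passed.
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"correlation r must be in [0, 1), got {r}")
    v = effects["variance"].to_numpy(dtype=float)
    if not (v > 0).all():
        raise ValueError("all sampling variances must be > 0")
    clusters = effects["cluster_id"].to_numpy()
    s = np.sqrt(v)
    same = clusters[:, None] == clusters[None, :]
    V = np.where(same, r * np.outer(s, s), 0.0)
    np.fill_diagonal(V, v)
    return VMatrix(matrix=V, cluster_ids=tuple(clusters), r=r)


@dataclass(frozen=True)
class RandomStructure:
    """Random-effect grouping terms; the effect-size identifier (residual
    heterogeneity) is always part of the model and is implicit here."""

    terms: tuple[str, ...] = ()

    def __str__(self) -> str:
        return " + ".join(self.terms + ("effect_size_id",))


@dataclass
class MetaFit:
    """A fitted multilevel meta-analytic model."""

    beta: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pval: pd.Series
    cov: pd.DataFrame
    variance_components: dict[str, float]
    qm: float
    qm_df: int
    qm_p: float
    loglik: float
    aic: float
    method: str
    k: int
    p: int
    converged: bool
    optimizer_trace: list = field(default_factory=list, repr=False)
    fitted: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "pval": self.pval,
            }
        )


def _indicator_crossprods(
    effects: pd.DataFrame, random: RandomStructure
) -> list[tuple[str, np.ndarray]]:
    """Z_t Z_t' for each random term (boolean same-group matrices) plus the
    always-included effect-size-level identity."""
    out: list[tuple[str, np.ndarray]] = []
    for term in random.terms:
        if term not in effects.columns:
            raise KeyError(f"random term {term!r} not a column of the effect table")
        g = effects[term].to_numpy()
        out.append((term, (g[:, None] == g[None, :]).astype(float)))
    out.append(("effect_size_id", np.eye(len(effects))))
    return out


def _neg_loglik(
    log_s2: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    ZZ: list[np.ndarray],
    reml: bool,
) -> float:
    M = V.copy()
    for ls, zz in zip(log_s2, ZZ):
        M += math.exp(ls) * zz
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_M = 2.0 * np.log(np.diag(L)).sum()
    Minv_y = np.linalg.solve(L.T, np.linalg.solve(L, y))
    Minv_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
    XtMX = X.T @ Minv_X
    try:
        beta = np.linalg.solve(XtMX, X.T @ Minv_y)
    except np.linalg.LinAlgError:
        return np.inf
    resid = y - X @ beta
    Minv_resid = np.linalg.solve(L.T, np.linalg.solve(L, resid))
    quad = resid @ Minv_resid
    k, p = X.shape
    ll = -0.5 * ((k - p if reml else k) * math.log(2 * math.pi) + logdet_M + quad)
    if reml:
        sign, logdet_XtMX = np.linalg.slogdet(XtMX)
        if sign <= 0:
            return np.inf
        ll -= 0.5 * logdet_XtMX
    return -ll


def _design_matrix(
    effects: pd.DataFrame,
    moderators: Sequence[str] | None,
    cell_means: bool,
) -> tuple[np.ndarray, list[str]]:
    k = len(effects)
    if not moderators:
        return np.ones((k, 1)), ["intercept"]
    cats: list[pd.Series] = []
    cont: list[str] = []
    for m in moderators:
        col = effects[m]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cont.append(m)
        else:
            cats.append(col.astype(str))
    cols: dict[str, np.ndarray] = {}
    if cats:
        if cell_means:
            combo = cats[0].str.cat(cats[1:], sep=":") if len(cats) > 1 else cats[0]
            for level in sorted(combo.unique()):
                cols[level] = (combo == level).to_numpy(dtype=float)
        else:
            cols["intercept"] = np.ones(k)
            for c in cats:
                levels = sorted(c.unique())
                for level in levels[1:]:  # first level is the reference
                    cols[f"{c.name}[{level}]"] = (c == level).to_numpy(dtype=float)
    else:
        cols["intercept"] = np.ones(k)
    for m in cont:
        cols[m] = effects[m].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns by greedy QR-style elimination
        keep: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
        aliased = [names[j] for j in range(X.shape[1]) if j not in keep]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def fit_meta(
    effects: pd.DataFrame,
    V: VMatrix,
    moderators: Sequence[str] | None = None,
    random: RandomStructure = RandomStructure(),
    method: str = "REML",
    *,
    cell_means: bool = False,
    n_restarts: int = 2,
    seed: int | None = 0,
    tol: float = 1e-10,
    fixed_components: Mapping[str, float] | None = None,
) -> MetaFit:
    """Fit the multilevel model y ~ N(X beta, V + sum_t sigma_t^2 Z_t Z_t').

    ``moderators`` are column names of ``effects``; categorical columns are
    dummy-coded against a reference level (or expanded to cell means when
    ``cell_means=True``), numeric columns enter linearly.  ``method`` is
    ``"REML"`` (default, for reported models) or ``"ML"`` (required for AIC
    comparison across fixed-effect structures).

    ``fixed_components`` pins named variance components (including the
    implicit ``effect_size_id`` residual term) at given values instead of
    estimating them — useful for degenerate inputs (a single effect size)
    and for oracle checks at known truth.
    """
    if method not in ("REML", "ML"):
        raise ValueError(f"method must be 'REML' or 'ML', got {method!r}")
    y = effects["value"].to_numpy(dtype=float)
    k = len(y)
    X, names = _design_matrix(effects, moderators, cell_means)
    p = X.shape[1]
    _check_rank(X, names)
    if V.k != k:
        raise ValueError("V matrix does not match the effect table")

    named_ZZ = _indicator_crossprods(effects, random)
    fixed = dict(fixed_components or {})
    unknown_fixed = set(fixed) - {name for name, _ in named_ZZ}
    if unknown_fixed:
        raise KeyError(f"fixed components not in the random structure: {sorted(unknown_fixed)}")
    free_named = [(name, zz) for name, zz in named_ZZ if name not in fixed]
    V_eff = V.matrix.copy()
    for name, zz in named_ZZ:
        if name in fixed:
            if fixed[name] < 0:
                raise ValueError(f"fixed variance component {name!r} must be >= 0")
            V_eff += fixed[name] * zz
    ZZ = [zz for _, zz in free_named]
    q = len(ZZ)
    if k < p + (1 if q else 0):
        raise ValueError(f"need more effect sizes than fixed parameters: k={k}, p={p}")
    reml = method == "REML"

    if q == 0:
        best_x = np.empty(0)
        best_fun = _neg_loglik(best_x, y, X, V_eff, ZZ, reml)
        trace = [{"x0": [], "fun": float(best_fun), "success": True}]
        best_success = True
    else:
        args = (y, X, V_eff, ZZ, reml)
        # crude scale for starting values: marginal variance of y
        scale = max(float(np.var(y)), 1e-6)
        starts = [np.full(q, math.log(scale / q))]
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            starts.append(np.log(scale) + rng.uniform(-4.0, 1.0, size=q))

        best = None
        trace = []
        for x0 in starts:
            res = optimize.minimize(
                _neg_loglik,
                x0,
                args=args,
                method="L-BFGS-B",
                bounds=[_LOG_S2_BOUNDS] * q,
                options={"maxiter": 500, "ftol": tol},
            )
            trace.append({"x0": x0.tolist(), "fun": float(res.fun), "success": bool(res.success)})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("variance-component optimization failed to converge", trace)
        best_x, best_fun, best_success = best.x, float(best.fun), bool(best.success)

    sigma2 = {name: math.exp(v) for (name, _), v in zip(free_named, best_x)}
    sigma2.update(fixed)
    M = V_eff.copy()
    for s2, zz in zip(best_x, ZZ):
        M += math.exp(s2) * zz
    L = np.linalg.cholesky(M)
    Minv_X = np.linalg.solve(L.T, np.linalg.solve(L, X))
    XtMX = X.T @ Minv_X
    cov = np.linalg.inv(XtMX)
    beta = cov @ (Minv_X.T @ y)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))

    loglik = -best_fun
    aic = 2.0 * (p + q) - 2.0 * loglik if not reml else 2.0 * q - 2.0 * loglik

    tested = [i for i, n in enumerate(names) if n != "intercept"] if "intercept" in names \
        else list(range(p))
    if tested:
        b_t = beta[tested]
        cov_t = cov[np.ix_(tested, tested)]
        qm = float(b_t @ np.linalg.solve(cov_t, b_t))
        qm_df = len(tested)
        qm_p = float(stats.chi2.sf(qm, qm_df))
    else:
        qm, qm_df, qm_p = float("nan"), 0, float("nan")

    idx = pd.Index(names, name="coef")
    return MetaFit(
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        ci_low=pd.Series(beta - _Z95 * se, index=idx),
        ci_high=pd.Series(beta + _Z95 * se, index=idx),
        pval=pd.Series(pval, index=idx),
        cov=pd.DataFrame(cov, index=idx, columns=idx),
        variance_components=sigma2,
        qm=qm,
        qm_df=qm_df,
        qm_p=qm_p,
        loglik=loglik,
        aic=aic,
        method=method,
        k=k,
        p=p,
        converged=best_success,
        optimizer_trace=trace,
        fitted=X @ beta,
    )


def select_random_structure(
    effects: pd.DataFrame,
    V: VMatrix,
    candidates: Iterable[RandomStructure],
) -> tuple[RandomStructure, pd.DataFrame]:
    """Pick the AIC-minimizing random structure among candidates.

    Each candidate is fitted by ML without moderators (intercept only); the
    effect-size identifier is implicit in every candidate.  Returns the
    winner and the full AIC ladder (failed fits recorded with NaN and
    excluded from the comparison).  Ties go to the structure with fewer
    terms.
    """
    rows = []
    fits: list[tuple[RandomStructure, float]] = []
    for cand in candidates:
        try:
            fit = fit_meta(effects, V, moderators=None, random=cand, method="ML")
            rows.append(
                {"structure": str(cand), "n_terms": len(cand.terms),
                 "loglik": fit.loglik, "aic": fit.aic, "converged": fit.converged}
            )
            fits.append((cand, fit.aic))
        except (ConvergenceError, np.linalg.LinAlgError):
            rows.append(
                {"structure": str(cand), "n_terms": len(cand.terms),
                 "loglik": float("nan"), "aic": float("nan"), "converged": False}
            )
    if not fits:
        raise ConvergenceError("no candidate random structure converged")
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    best = min(fits, key=lambda cf: (round(cf[1], 10), len(cf[0].terms)))
    return best[0], table


def pooled_by_level(
    effects: pd.DataFrame,
    V: VMatrix,
    random: RandomStructure = RandomStructure(),
    grouping: Sequence[str] = ("stressor",),
    method: str = "REML",
    min_k: int = 2,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, MetaFit]:
    """Pooled estimate and 95% CI per level of a (possibly crossed) grouping.

    Fits one cell-means model with the grouping moderators, so every level
    shares the variance components and the V matrix.  Levels with fewer
    than ``min_k`` effect sizes are still estimated but flagged.  Returns
    the per-level table and the underlying fit (whose Q_M tests all level
    means jointly).
    """
    grouping = list(grouping)
    combo = effects[grouping].astype(str).agg(":".join, axis=1)
    counts = combo.value_counts()
    fit = fit_meta(
        effects, V, moderators=grouping, random=random, method=method,
        cell_means=True, seed=seed,
    )
    rows = []
    for level in fit.beta.index:
        k_level = int(counts.get(level, 0))
        pv = fit.pval[level]
        stars = "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""
        rows.append(
            {
                "level": level,
                "k": k_level,
                "estimate": fit.beta[level],
                "se": fit.se[level],
                "ci_low": fit.ci_low[level],
                "ci_high": fit.ci_high[level],
                "pval": pv,
                "stars": stars,
                "flagged_low_k": k_level < min_k,
            }
        )
    return pd.DataFrame(rows), fit


def latitude_metaregression(
    effects: pd.DataFrame,
    V: VMatrix,
    random: RandomStructure = RandomStructure(),
    method: str = "REML",
    seed: int | None = 0,
) -> MetaFit:
    """Meta-regression of effect size on absolute latitude (degrees).

    The intercept is the pooled effect at the equator; the slope is the
    change in lnRR per degree of absolute latitude.
    """
    lat = effects["abs_latitude"].to_numpy(dtype=float)
    if np.ptp(lat) == 0:
        raise ValueError("absolute latitude has zero variance; meta-regression undefined")
    return fit_meta(
        effects, V, moderators=["abs_latitude"], random=random, method=method, seed=seed
    )
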