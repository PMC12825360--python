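"""Per-gene factorial ANOVA fits and nested-model tests.

Two fitting paths share one :class:`FitResult` contract:

* **Fixed effects** — ordinary least squares on treatment-coded factor
  designs. Nested models are compared with the exact F-test on residual
  sums of squares.
* **Random intercept** — Gaussian maximum likelihood with a single
  random-intercept grouping (subjects). The likelihood is profiled: for a
  fixed variance ratio lambda = sigma_u^2 / sigma_e^2 the covariance is
  V = sigma_e^2 (I + lambda Z Z'), the GLS coefficients and sigma_e^2 have
  closed forms, and the remaining 1-D problem in log(lambda) is solved by
  bounded scalar optimization (the boundary lambda = 0 is evaluated
  exactly, so degenerate genes cannot fail to converge). Nested models are
  compared with the chi-square likelihood-ratio test; ML rather than REML
  because every comparison changes the fixed-effect structure.

Model specifications are term sets over {f1, f2, f3} main effects and
their interactions, with the marginality hierarchy enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .datatypes import ObservationDesign

# canonical term names; interactions are colon-joined sorted factor names
MAIN_TERMS = ("f1", "f2", "f3")


def _term_factors(term: str) -> tuple[str, ...]:
    return tuple(term.split(":"))


@dataclass(frozen=True)
class ModelSpec:
    """A factorial model: a set of fixed terms plus an optional random intercept.

    Terms are factor names ("f1") or interactions ("f1:f2", "f1:f2:f3").
    The marginality hierarchy is enforced: every interaction requires all
    its lower-order marginals.
    """

    terms: frozenset[str] = frozenset()
    random_intercept: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        for term in self.terms:
            fs = _term_factors(term)
            if len(fs) != len(set(fs)):
                raise ValueError(f"repeated factor in term {term!r}")
            if len(fs) > 1:
                # every proper non-empty subset of the factors must be present
                from itertools import combinations

                for r in range(1, len(fs)):
                    for sub in combinations(sorted(fs), r):
                        if ":".join(sub) not in self.terms:
                            raise ValueError(
                                f"term {term!r} requires marginal {':'.join(sub)!r}"
                            )

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.terms <= other.terms
            and self.random_intercept == other.random_intercept
        )

    def __repr__(self) -> str:  # stable, readable
        t = "+".join(sorted(self.terms, key=lambda s: (s.count(":"), s))) or "1"
        return f"ModelSpec({t}{' | subject' if self.random_intercept else ''})"


def spec(*terms: str, random_intercept: bool = False) -> ModelSpec:
    """Convenience constructor: ``spec("f1", "f2", "f1:f2")``."""
    return ModelSpec(frozenset(terms), random_intercept)


# The five two-way candidate models (full, additive, f1-only, f2-only, null).
TWO_WAY_SPECS = {
    "full": spec("f1", "f2", "f1:f2"),
    "additive": spec("f1", "f2"),
    "f1_only": spec("f1"),
    "f2_only": spec("f2"),
    "null": spec(),
}

# The ten three-way candidate models, all with a subject random intercept.
THREE_WAY_SPECS = {
    "full": spec("f1", "f2", "f3", "f1:f2", "f2:f3", "f1:f3", "f1:f2:f3",
                 random_intercept=True),
    "all_two_way": spec("f1", "f2", "f3", "f1:f2", "f2:f3", "f1:f3",
                        random_intercept=True),
    "no_f1f2": spec("f1", "f2", "f3", "f2:f3", "f1:f3", random_intercept=True),
    "no_f2f3": spec("f1", "f2", "f3", "f1:f2", "f1:f3", random_intercept=True),
    "no_f1f3": spec("f1", "f2", "f3", "f1:f2", "f2:f3", random_intercept=True),
    "additive": spec("f1", "f2", "f3", random_intercept=True),
    "f1_only": spec("f1", random_intercept=True),
    "f2_only": spec("f2", random_intercept=True),
    "f3_only": spec("f3", random_intercept=True),
    "null": spec(random_intercept=True),
}


@dataclass
class FitResult:
    """Summary of one per-gene model fit.

    For fixed-effect (OLS) fits ``rss``/``df_resid`` drive F-tests; for
    random-intercept ML fits ``loglik`` drives likelihood-ratio tests.
    ``n_fixed_params`` is the column rank of the fixed-effect design, so
    rank-deficient (incomplete) designs are counted correctly.
    """

    spec: ModelSpec
    n_obs: int
    n_fixed_params: int
    rss: Optional[float] = None
    df_resid: Optional[int] = None
    loglik: Optional[float] = None
    sigma_u2: Optional[float] = None
    sigma_e2: Optional[float] = None
    converged: bool = True


def design_matrix(design: ObservationDesign, model: ModelSpec,
                  mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Treatment-coded (reference level dropped) design matrix with intercept.

    Columns for an interaction are products of the marginal dummy columns.
    The matrix may be rank-deficient when factor-level combinations are
    missing; fitting handles that via the pseudo-inverse and reports the
    actual rank.
    """
    factors = design.factors()
    n = design.n_obs
    if mask is None:
        mask = np.ones(n, dtype=bool)
    idx = np.flatnonzero(mask)

    dummies: dict[str, list[np.ndarray]] = {}
    for name, arr in factors.items():
        levels = sorted({str(v) for v in arr})  # full-design levels: stable coding
        cols = [(arr[idx].astype(str) == lev).astype(float) for lev in levels[1:]]
        dummies[name] = cols

    columns = [np.ones(len(idx))]
    for term in sorted(model.terms, key=lambda t: (t.count(":"), t)):
        fs = _term_factors(term)
        if len(fs) == 1:
            columns.extend(dummies[fs[0]])
        else:
            prod_cols = [np.ones(len(idx))]
            for f in fs:
                prod_cols = [p * d for p in prod_cols for d in dummies[f]]
            columns.extend(prod_cols)
    return np.column_stack(columns)


def fit_fixed(y: np.ndarray, design: ObservationDesign, model: ModelSpec,
              mask: Optional[np.ndarray] = None) -> FitResult:
    """OLS fit of a fixed-effect spec; exact RSS and residual df.

    Rank-deficient designs are handled by the minimum-norm least-squares
    solution; ``n_fixed_params`` is the design rank so df accounting stays
    exact when factor-level combinations are absent.
    """
    if model.random_intercept:
        raise ValueError("fit_fixed requires a fixed-effect spec")
    y = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.isfinite(y)
    X = design_matrix(design, model, mask=mask)
    yv = y[mask]
    beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    rss = float(resid @ resid)
    return FitResult(
        spec=model,
        n_obs=len(yv),
        n_fixed_params=int(rank),
        rss=max(rss, 0.0),
        df_resid=len(yv) - int(rank),
    )


def f_test_nested(full: FitResult, reduced: FitResult) -> float:
    """Exact F-test p-value for a reduced fixed-effect model against a full one.

    Degenerate cases follow the conventions: identical RSS -> p = 1
    (nothing gained by the extra terms); a saturated full model with zero
    RSS against a reduced model with positive RSS -> p = 0.
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError(f"{reduced.spec} is not nested in {full.spec}")
    if full.df_resid is None or reduced.df_resid is None:
        raise ValueError("f_test_nested requires fixed-effect fits")
    df_num = reduced.df_resid - full.df_resid
    if df_num <= 0:
        raise ValueError("no degrees of freedom for the comparison")
    if full.df_resid <= 0:
        raise ValueError("full model has zero residual degrees of freedom")
    rss_f, rss_r = full.rss, reduced.rss
    if rss_r <= rss_f or np.isclose(rss_r, rss_f, rtol=1e-12, atol=0.0):
        return 1.0
    if rss_f <= 1e-12 * rss_r:  # saturated full model (exact fit)
        return 0.0
    F = ((rss_r - rss_f) / df_num) / (rss_f / full.df_resid)
    return float(stats.f.sf(F, df_num, full.df_resid))


def f_statistic_nested(full: FitResult, reduced: FitResult) -> tuple[float, int, int]:
    """The F statistic and its (numerator, denominator) df, for reporting."""
    df_num = reduced.df_resid - full.df_resid
    F = ((reduced.rss - full.rss) / df_num) / (full.rss / full.df_resid)
    return float(F), int(df_num), int(full.df_resid)


def _profile_loglik(log_lam: float, yv: np.ndarray, X: np.ndarray,
                    group_sizes: np.ndarray, group_index: list[np.ndarray]) -> float:
    """Profiled ML log-likelihood of the random-intercept model at log(lambda).

    V = I + lambda Z Z' is block diagonal with blocks I + lambda 11', so
    V^{-1} x = x - (lambda / (1 + lambda n_g)) * 1 * sum(x_g) per group and
    log|V| = sum log(1 + lambda n_g). Both the GLS coefficients and the
    profiled sigma_e^2 are closed-form given lambda.
    """
    lam = np.exp(log_lam) if np.isfinite(log_lam) else 0.0
    n = len(yv)
    # apply V^{-1/2}-equivalent via direct V^{-1} inner products
    def vinv(x: np.ndarray) -> np.ndarray:
        out = x.copy()
        for g, idxg in enumerate(group_index):
            shrink = lam / (1.0 + lam * group_sizes[g])
            out[idxg] -= shrink * x[idxg].sum(axis=0)
        return out

    XtVX = X.T @ vinv(X)
    XtVy = X.T @ vinv(yv[:, None])[:, 0]
    beta = np.linalg.pinv(XtVX, rcond=1e-10) @ XtVy
    r = yv - X @ beta
    quad = float(r @ vinv(r[:, None])[:, 0])
    quad = max(quad, 1e-300)
    logdet = float(np.sum(np.log1p(lam * group_sizes)))
    sigma2 = quad / n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def fit_mixed(y: np.ndarray, design: ObservationDesign, model: ModelSpec,
              mask: Optional[np.ndarray] = None) -> FitResult:
    """ML fit of a fixed-effect spec plus a subject random intercept.

    The 1-D profiled likelihood in log(lambda), lambda = sigma_u^2/sigma_e^2,
    is maximized on [1e-8, 1e4] by bounded Brent search seeded from a coarse
    grid; the boundary lambda = 0 (no subject variance) is evaluated exactly
    and wins ties, so the fit is defined for every input including genes
    with zero subject-level variance.
    """
    if not model.random_intercept:
        raise ValueError("fit_mixed requires random_intercept=True")
    if design.subject is None:
        raise ValueError("design has no subject grouping (required for mixed fits)")
    y = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.isfinite(y)
    subj = design.subject[mask].astype(str)
    if len(np.unique(subj)) < 2:
        raise ValueError("mixed fit requires >= 2 subjects")
    X = design_matrix(design, model, mask=mask)
    yv = y[mask]
    rank = int(np.linalg.matrix_rank(X))
    groups = np.unique(subj)
    group_index = [np.flatnonzero(subj == g) for g in groups]
    group_sizes = np.array([len(ix) for ix in group_index], dtype=float)

    if np.allclose(yv, yv[0]):
        # constant response: likelihood degenerate; report boundary fit
        return FitResult(spec=model, n_obs=len(yv), n_fixed_params=rank,
                         loglik=np.inf, sigma_u2=0.0, sigma_e2=0.0)

    def negll(log_lam: float) -> float:
        return -_profile_loglik(log_lam, yv, X, group_sizes, group_index)

    ll_zero = _profile_loglik(-np.inf, yv, X, group_sizes, group_index)
    grid = np.linspace(np.log(1e-8), np.log(1e4), 25)
    vals = np.array([negll(g) for g in grid])
    best = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        negll,
        bounds=(max(best - 2.0, np.log(1e-9)), min(best + 2.0, np.log(1e5))),
        method="bounded",
        options={"xatol": 1e-8},
    )
    ll_opt, lam_opt = -res.fun, float(np.exp(res.x))
    if ll_zero >= ll_opt:
        ll_opt, lam_opt = ll_zero, 0.0

    # recover variance components at the optimum for reporting
    def vinv(x, lam):
        out = x.copy()
        for g, idxg in enumerate(group_index):
            out[idxg] -= (lam / (1.0 + lam * group_sizes[g])) * x[idxg].sum(axis=0)
        return out

    beta = np.linalg.pinv(X.T @ vinv(X, lam_opt), rcond=1e-10) @ (
        X.T @ vinv(yv[:, None], lam_opt)[:, 0]
    )
    r = yv - X @ beta
    sigma_e2 = float(r @ vinv(r[:, None], lam_opt)[:, 0]) / len(yv)
    return FitResult(
        spec=model,
        n_obs=len(yv),
        n_fixed_params=rank,
        loglik=float(ll_opt),
        sigma_u2=lam_opt * sigma_e2,
        sigma_e2=sigma_e2,
    )


def lrt_nested(full: FitResult, reduced: FitResult) -> float:
    """Chi-square LRT p-value for nested ML fits with identical random structure.

    The deviance is clipped at zero (finite-sample optimization noise can
    make it marginally negative); df counts fixed-effect parameters only.
    """
    if not reduced.spec.is_nested_in(full.spec):
        raise ValueError(f"{reduced.spec} is not nested in {full.spec}")
    if full.loglik is None or reduced.loglik is None:
        raise ValueError("lrt_nested requires ML fits")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df <= 0:
        raise ValueError("no degrees of freedom for the comparison")
    if np.isinf(full.loglik) and np.isinf(reduced.loglik):
        return 1.0  # both degenerate (constant response)
    D = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return float(stats.chi2.sf(D, df))
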