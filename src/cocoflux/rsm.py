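"""Quadratic response-surface fitting on coded FCD factors.

The model is the usual two-factor second-order polynomial

    Y = b0 + b1*x1 + b2*x2 + b11*x1^2 + b22*x2^2 + b12*x1*x2

fitted by ordinary least squares over all individual samples (replicates
included, so replicated conditions carry proportional weight).  Term
pruning follows the classical RSM workflow: fit the full model, drop
every non-intercept term with p >= alpha, refit the reduced model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from cocoflux.doe import FCDDataset, FactorSpec

__all__ = [
    "TERMS",
    "QuadraticSurface",
    "AnovaReport",
    "OptimumPoint",
    "fit_quadratic",
    "prune_by_significance",
    "anova",
    "optimize_surface",
]

#: Term order of the coefficient vector.
TERMS = ("1", "x1", "x2", "x1^2", "x2^2", "x1:x2")


def _columns(points: np.ndarray) -> np.ndarray:
    """Full 6-column model matrix for coded points of shape (n, 2)."""
    x1, x2 = points[:, 0], points[:, 1]
    return np.column_stack([np.ones_like(x1), x1, x2, x1 * x1, x2 * x2, x1 * x2])


@dataclass
class QuadraticSurface:
    """A fitted (possibly reduced) quadratic response surface.

    ``coefficients`` is always length 6 in :data:`TERMS` order with exact
    zeros for excluded terms; ``covariance`` covers included terms only.
    """

    response_name: str
    coefficients: np.ndarray
    included: np.ndarray  # bool mask over TERMS; intercept always True
    covariance: np.ndarray
    residual_variance: float
    n_samples: int
    term_pvalues: dict[str, float] = field(default_factory=dict)
    factors: tuple[FactorSpec, FactorSpec] | None = None

    @property
    def included_terms(self) -> tuple[str, ...]:
        return tuple(t for t, m in zip(TERMS, self.included) if m)

    def predict(self, point, with_se: bool = True):
        """Evaluate the surface at a coded point.

        Returns ``(value, se)`` where ``se`` is the prediction standard
        error of the fitted mean response from the coefficient covariance
        (or ``None`` when ``with_se=False``).  Points outside [-1, 1]^2
        trigger an extrapolation warning.
        """
        point = np.asarray(point, dtype=float)
        if np.any(np.abs(point) > 1.0 + 1e-9):
            warnings.warn(
                f"prediction at coded {point.tolist()} extrapolates outside the design box",
                stacklevel=2,
            )
        v = _columns(point.reshape(1, 2))[0]
        value = float(v @ self.coefficients)
        if not with_se:
            return value, None
        vi = v[self.included]
        se = float(np.sqrt(vi @ self.covariance @ vi))
        return value, se

    def predict_actual(self, pressure: float, temperature: float):
        """Evaluate at actual-unit factor levels (requires stored factors)."""
        if self.factors is None:
            raise ValueError("surface has no factor specs; cannot code actual units")
        coded = (self.factors[0].code(pressure), self.factors[1].code(temperature))
        return self.predict(coded)

    # ---- serialization -------------------------------------------------

    def to_json_dict(self) -> dict:
        d = {
            "response": self.response_name,
            "included_terms": list(self.included_terms),
            "coefficients": {t: float(c) for t, c in zip(TERMS, self.coefficients)},
            "covariance": self.covariance.tolist(),
            "n": self.n_samples,
            "sigma2": self.residual_variance,
            "term_pvalues": self.term_pvalues,
        }
        if self.factors is not None:
            d["factors"] = [
                {"name": f.name, "units": f.units, "low": f.low, "high": f.high}
                for f in self.factors
            ]
        return d

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "QuadraticSurface":
        included = np.array([t in d["included_terms"] for t in TERMS])
        coef = np.array([d["coefficients"][t] for t in TERMS])
        factors = None
        if "factors" in d:
            factors = tuple(FactorSpec(**f) for f in d["factors"])
        return cls(
            response_name=d["response"],
            coefficients=coef,
            included=included,
            covariance=np.asarray(d["covariance"], dtype=float),
            residual_variance=float(d["sigma2"]),
            n_samples=int(d["n"]),
            term_pvalues=d.get("term_pvalues", {}),
            factors=factors,  # type: ignore[arg-type]
        )

    @classmethod
    def load_json(cls, path) -> "QuadraticSurface":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


class SingularFitError(ValueError):
    """Design matrix is rank-deficient for the requested terms."""


def fit_quadratic(
    dataset: FCDDataset,
    response: str,
    terms: tuple[str, ...] | None = None,
) -> QuadraticSurface:
    """OLS fit of the (optionally reduced) quadratic over all samples.

    ``terms`` selects a subset of :data:`TERMS`; the intercept is always
    included.  Raises :class:`SingularFitError` when the design cannot
    support the requested terms.
    """
    X, y = dataset.samples(response)
    if terms is None:
        terms = TERMS
    mask = np.array([t == "1" or t in terms for t in TERMS])
    A = _columns(X)[:, mask]
    n, p = A.shape
    if n < p:
        raise SingularFitError(f"{n} samples cannot identify {p} terms")
    if np.linalg.matrix_rank(A) < p:
        raise SingularFitError(f"rank-deficient design for terms {terms}")
    res = sm.OLS(y, A).fit()
    beta = np.asarray(res.params)
    sigma2 = float(res.mse_resid) if n > p else 0.0
    cov = np.asarray(res.cov_params())
    pvals = np.asarray(res.pvalues)
    full_coef = np.zeros(6)
    full_coef[mask] = beta
    term_p = {t: float(pv) for t, pv in zip(np.array(TERMS)[mask], pvals)}
    return QuadraticSurface(
        response_name=response,
        coefficients=full_coef,
        included=mask,
        covariance=cov,
        residual_variance=sigma2,
        n_samples=n,
        term_pvalues=term_p,
        factors=dataset.factors,
    )


def prune_by_significance(
    dataset: FCDDataset, response: str, alpha: float = 0.05
) -> QuadraticSurface:
    """Fit the full quadratic, drop terms with p >= alpha, refit.

    The intercept is never dropped; a tie at p == alpha retains the term.
    If everything else is dropped an intercept-only model is returned with
    a warning.
    """
    full = fit_quadratic(dataset, response)
    keep = tuple(
        t for t in TERMS[1:] if full.term_pvalues[t] < alpha
    )
    if not keep:
        warnings.warn(
            f"all non-intercept terms non-significant at alpha={alpha}; "
            "returning intercept-only model",
            stacklevel=2,
        )
    return fit_quadratic(dataset, response, terms=keep)


@dataclass
class AnovaReport:
    """Classical RSM ANOVA with a lack-of-fit / pure-error split."""

    response_name: str
    terms: dict[str, dict[str, float]]  # estimate, se, t, p per included term
    ss_regression: float
    ss_residual: float
    ss_lack_of_fit: float | None
    ss_pure_error: float | None
    df_regression: int
    df_residual: int
    df_lack_of_fit: int | None
    df_pure_error: int | None
    f_cal: float
    f_tab: float
    alpha: float
    r_squared: float

    @property
    def ss_total(self) -> float:
        return self.ss_regression + self.ss_residual

    @property
    def adequate(self) -> bool:
        return self.f_cal > self.f_tab


def anova(
    dataset: FCDDataset, surface: QuadraticSurface, alpha: float = 0.05
) -> AnovaReport:
    """ANOVA of a fitted surface against the dataset it was fitted on.

    Pure error comes from replicate scatter within conditions; without any
    replication the lack-of-fit split is unavailable (flagged by ``None``).
    """
    X, y = dataset.samples(surface.response_name)
    yhat = _columns(X) @ surface.coefficients
    ybar = y.mean()
    ss_total = float(np.sum((y - ybar) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_reg = ss_total - ss_res
    p = int(surface.included.sum())
    n = len(y)
    df_reg, df_res = p - 1, n - p

    # pure error: within-condition replicate scatter
    groups: dict[tuple, list[float]] = {}
    for row, val in zip(X, y):
        groups.setdefault(tuple(np.round(row, 9)), []).append(val)
    n_cond = len(groups)
    replicated = n > n_cond
    if replicated:
        ss_pe = float(
            sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in groups.values())
        )
        df_pe = n - n_cond
        ss_lof = max(ss_res - ss_pe, 0.0)
        df_lof = n_cond - p
    else:
        ss_pe = df_pe = ss_lof = df_lof = None  # type: ignore[assignment]

    ms_reg = ss_reg / df_reg if df_reg > 0 else np.nan
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    f_cal = ms_reg / ms_res if ms_res > 0 else np.inf
    f_tab = float(stats.f.ppf(1.0 - alpha, df_reg, df_res)) if df_reg > 0 else np.nan
    r2 = ss_reg / ss_total if ss_total > 0 else 1.0

    se = np.sqrt(np.diag(surface.covariance))
    est = surface.coefficients[surface.included]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, est / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_res)
    terms = {
        t: {"estimate": float(b), "se": float(s), "t": float(tv), "p": float(pv)}
        for t, b, s, tv, pv in zip(surface.included_terms, est, se, tvals, pvals)
    }
    return AnovaReport(
        response_name=surface.response_name,
        terms=terms,
        ss_regression=ss_reg,
        ss_residual=ss_res,
        ss_lack_of_fit=ss_lof,
        ss_pure_error=ss_pe,
        df_regression=df_reg,
        df_residual=df_res,
        df_lack_of_fit=df_lof,
        df_pure_error=df_pe,
        f_cal=float(f_cal),
        f_tab=f_tab,
        alpha=alpha,
        r_squared=float(r2),
    )


@dataclass
class OptimumPoint:
    coded: tuple[float, float]
    actual: tuple[float, float] | None
    value: float
    se: float
    on_boundary: bool
    flat: bool = False


def optimize_surface(
    surface: QuadraticSurface,
    direction: str = "max",
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((-1.0, 1.0), (-1.0, 1.0)),
) -> OptimumPoint:
    """Global optimum of the quadratic over a coded box, in closed form.

    Candidates are the interior stationary point (if the Hessian is
    nonsingular and the point lies in the box), the 1-D stationary points
    on each edge, and the four corners.  Deterministic.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    b = surface.coefficients
    (lo1, hi1), (lo2, hi2) = bounds
    grad = np.array([b[1], b[2]])
    H = np.array([[2 * b[3], b[5]], [b[5], 2 * b[4]]])
    flat = np.allclose(b[1:], 0.0)

    candidates: list[tuple[float, float]] = [
        (lo1, lo2), (lo1, hi2), (hi1, lo2), (hi1, hi2)
    ]
    if abs(np.linalg.det(H)) > 1e-12:
        sp = np.linalg.solve(H, -grad)
        if lo1 - 1e-12 <= sp[0] <= hi1 + 1e-12 and lo2 - 1e-12 <= sp[1] <= hi2 + 1e-12:
            candidates.append((float(np.clip(sp[0], lo1, hi1)),
                               float(np.clip(sp[1], lo2, hi2))))
    # edges: fix one coordinate, 1-D quadratic in the other
    for x1 in (lo1, hi1):
        if abs(b[4]) > 1e-15:  # d/dx2 [..] = b2 + 2 b22 x2 + b12 x1 = 0
            x2 = -(b[2] + b[5] * x1) / (2 * b[4])
            if lo2 <= x2 <= hi2:
                candidates.append((x1, float(x2)))
    for x2 in (lo2, hi2):
        if abs(b[3]) > 1e-15:
            x1 = -(b[1] + b[5] * x2) / (2 * b[3])
            if lo1 <= x1 <= hi1:
                candidates.append((float(x1), x2))

    sign = 1.0 if direction == "max" else -1.0
    best, best_val = None, -np.inf
    for c in candidates:
        v, _ = _safe_eval(surface, c)
        if sign * v > best_val:
            best, best_val = c, sign * v
    assert best is not None
    value, se = _safe_eval(surface, best)
    on_boundary = any(
        abs(x - e) < 1e-9 for x, (l, h) in zip(best, bounds) for e in (l, h)
    )
    actual = None
    if surface.factors is not None:
        actual = tuple(f.decode(c) for f, c in zip(surface.factors, best))
    return OptimumPoint(
        coded=best, actual=actual, value=value, se=se,
        on_boundary=on_boundary, flat=flat,
    )


def _safe_eval(surface: QuadraticSurface, point):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return surface.predict(point)
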