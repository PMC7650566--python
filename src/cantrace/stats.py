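"""Poisson mixed model for substitution counts, LRT, and overdispersion.

Substitution counts per specimen per processing level are modelled as
Poisson with a log link:

    nNS ~ Level * Species + (1 | Individual/Species)

i.e. fixed effects for level, species and their interaction, plus random
intercepts for the grouping terms.  Fitting maximises the Laplace
approximation to the marginal likelihood: for each group the random effect
is profiled out at its conditional mode (inner Newton solve) and the
marginal contribution picks up the usual -1/2 log(sigma^2 * W + 1)
curvature correction.  Fixed effects use treatment coding with the
reference level and species chosen as the alphabetically first category
(L1 and the first species, for the default data).

A note on ``(1 | Individual/Species)``: the literal expansion is random
intercepts for Individual and for Individual:Species.  When each
individual belongs to exactly one species the two grouping partitions are
identical and only the *sum* of the two variances is identified; the fit
therefore collapses them and reports a single variance component.  The
``species/individual`` nesting (species blocks containing individuals) is
also supported and fits two genuine components.

Overdispersion is estimated Bolker-style as the ratio of the Pearson
residual sum of squares (residuals computed at the conditional means) to
the residual degrees of freedom, with an upper-tail chi-square p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps


class DataError(ValueError):
    """Counts are not non-negative integers, or duplicated specimen-levels."""


class NestingError(ValueError):
    """Models passed to the LRT are not nested."""


class ResidualDomainError(ValueError):
    """A fitted mean of zero with a positive count has undefined residual."""


@dataclass(frozen=True)
class NSCountRecord:
    individual: str
    species: str
    level: str
    n_ns: int


@dataclass
class GLMMFit:
    """Fitted Poisson mixed model (Laplace approximation)."""

    coef: dict[str, float]
    se: Optional[dict[str, float]]
    var_components: dict[str, float]
    loglik: float
    n_params: int
    converged: bool
    fixed_formula: str
    random_formula: str
    n_obs: int
    singular_design: bool = False
    degenerate: bool = False
    # internals for residuals / refits
    _y: Optional[np.ndarray] = field(default=None, repr=False)
    _fitted: Optional[np.ndarray] = field(default=None, repr=False)
    _u_hat: Optional[dict[str, np.ndarray]] = field(default=None, repr=False)

    @property
    def fitted_means(self) -> np.ndarray:
        """Conditional means exp(X beta + Z u_hat)."""
        if self._fitted is None:
            raise ValueError("fit carries no fitted means (degenerate fit)")
        return self._fitted


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class OverdispersionResult:
    ratio: float
    residual_df: int
    pearson_ss: float
    p_value: float


# ---------------------------------------------------------------------------
# design construction


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "nNS" in df.columns and "n_ns" not in df.columns:
            df = df.rename(columns={"nNS": "n_ns"})
    else:
        df = pd.DataFrame(
            [
                {
                    "individual": r.individual,
                    "species": r.species,
                    "level": r.level,
                    "n_ns": r.n_ns,
                }
                for r in records
            ]
        )
    required = {"individual", "species", "level", "n_ns"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"records lack columns {sorted(missing)}")
    y = df["n_ns"].to_numpy()
    if not np.all(np.equal(np.mod(y, 1), 0)) or np.any(y < 0):
        raise DataError("counts must be non-negative integers")
    dup = df.duplicated(subset=["individual", "level"])
    if dup.any():
        raise DataError("duplicated (individual, level) records")
    return df


def _parse_fixed(formula: str) -> tuple[list[str], bool]:
    """Return (main-effect factors, interaction?) from a tiny formula DSL.

    Accepted: ``1``, ``level``, ``species``, ``level+species``,
    ``level*species`` (case-insensitive, whitespace ignored).
    """
    f = formula.replace(" ", "").lower()
    if f in ("1", ""):
        return [], False
    if "*" in f:
        parts = f.split("*")
        interaction = True
    else:
        parts = f.split("+")
        interaction = False
    for p in parts:
        if p not in ("level", "species"):
            raise ValueError(f"unknown fixed-effect factor {p!r}")
    return parts, interaction and len(parts) == 2


def build_fixed_design(
    df: pd.DataFrame, formula: str
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with stable coefficient names.

    Reference categories are the alphabetically first level and species.
    Names follow ``level[L2]``, ``species[SKJ]``, ``level[L2]:species[SKJ]``.
    """
    factors, interaction = _parse_fixed(formula)
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    dummies: dict[str, tuple[list[str], np.ndarray]] = {}
    for fac in factors:
        cats = sorted(df[fac].astype(str).unique())
        mat = np.column_stack(
            [(df[fac].astype(str) == c).to_numpy(float) for c in cats[1:]]
        ) if len(cats) > 1 else np.empty((n, 0))
        dummies[fac] = (cats[1:], mat)
        for c in cats[1:]:
            names.append(f"{fac}[{c}]")
        cols.append(mat)
    if interaction:
        lcats, lmat = dummies["level"]
        scats, smat = dummies["species"]
        inter_cols = []
        for i, lc in enumerate(lcats):
            for j, sc in enumerate(scats):
                inter_cols.append(lmat[:, i] * smat[:, j])
                names.append(f"level[{lc}]:species[{sc}]")
        if inter_cols:
            cols.append(np.column_stack(inter_cols))
    X = np.column_stack([c for c in cols if c.size])
    return X, names


def _parse_random(df: pd.DataFrame, spec: str) -> list[tuple[str, np.ndarray, int]]:
    """Expand a nesting spec into grouping terms (name, codes, n_groups).

    ``a/b`` expands to intercepts for ``a`` and ``a:b``.  Terms whose group
    partitions coincide are collapsed into one (confounded variance is only
    identified in sum).
    """
    spec = spec.replace(" ", "").lower()
    if "/" in spec:
        outer, inner = spec.split("/")
        term_names = [outer, f"{outer}:{inner}"]
    else:
        term_names = [spec]
    terms = []
    for name in term_names:
        if ":" in name:
            a, b = name.split(":")
            labels = df[a].astype(str) + ":" + df[b].astype(str)
        else:
            labels = df[name].astype(str)
        codes, uniques = pd.factorize(labels, sort=True)
        terms.append((name, codes.astype(np.int64), len(uniques)))
    # collapse partitions that are identical up to relabelling
    kept: list[tuple[str, np.ndarray, int]] = []
    for term in terms:
        dup = False
        for kname, kcodes, kn in kept:
            if term[2] == kn and _same_partition(term[1], kcodes):
                dup = True
                break
        if not dup:
            kept.append(term)
    return kept


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    first_a = pd.factorize(a)[0]
    first_b = pd.factorize(b)[0]
    return bool(np.array_equal(first_a, first_b))


# ---------------------------------------------------------------------------
# Laplace machinery


def _inner_modes_single(
    eta0: np.ndarray,
    y_sum: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    sigma2: float,
    u0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for the per-group conditional modes (scalar per group)."""
    u = u0.copy()
    inv = 1.0 / sigma2
    for _ in range(60):
        mu = np.exp(eta0 + u[codes])
        W = np.bincount(codes, weights=mu, minlength=n_groups)
        grad = y_sum - W - u * inv
        step = grad / (W + inv)
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(grad)) < 1e-10:
            break
    mu = np.exp(eta0 + u[codes])
    W = np.bincount(codes, weights=mu, minlength=n_groups)
    return u, W


class _LaplaceObjective:
    """Negative Laplace log-likelihood over (beta, log sigma_k)."""

    def __init__(self, X, y, terms, var_fixed=None):
        self.X = X
        self.y = y
        self.terms = terms  # list of (name, codes, n_groups)
        self.var_fixed = var_fixed
        self.const = -float(np.sum(special.gammaln(y + 1)))
        self._warm: dict[int, np.ndarray] = {
            k: np.zeros(t[2]) for k, t in enumerate(terms)
        }
        self.p = X.shape[1]

    def n_var_params(self) -> int:
        return 0 if self.var_fixed is not None else len(self.terms)

    def split(self, theta):
        beta = theta[: self.p]
        if self.var_fixed is not None:
            sigmas = [self.var_fixed] * len(self.terms)
        else:
            sigmas = [float(np.exp(t)) for t in theta[self.p :]]
        return beta, sigmas

    def loglik(self, theta) -> float:
        beta, sigmas = self.split(theta)
        eta0 = self.X @ beta
        if not self.terms or all(s == 0.0 for s in sigmas):
            mu = np.exp(eta0)
            return float(np.sum(self.y * eta0 - mu)) + self.const

        if len(self.terms) == 1:
            name, codes, G = self.terms[0]
            sigma2 = sigmas[0] ** 2
            if sigma2 < 1e-12:
                mu = np.exp(eta0)
                return float(np.sum(self.y * eta0 - mu)) + self.const
            y_sum = np.bincount(codes, weights=self.y.astype(float), minlength=G)
            u, W = _inner_modes_single(eta0, y_sum, codes, G, sigma2, self._warm[0])
            self._warm[0] = u
            eta = eta0 + u[codes]
            mu = np.exp(eta)
            ll = float(np.sum(self.y * eta - mu)) + self.const
            ll -= float(np.sum(u * u) / (2.0 * sigma2))
            ll -= 0.5 * float(np.sum(np.log1p(sigma2 * W)))
            return ll

        return self._loglik_blocks(eta0, sigmas)

    def _loglik_blocks(self, eta0, sigmas) -> float:
        """General nested case: joint mode per outer block, dense Laplace."""
        (n1, c1, G1), (n2, c2, G2) = self.terms
        s1, s2 = sigmas[0] ** 2, sigmas[1] ** 2
        y = self.y.astype(float)
        ll = self.const
        for b in range(G1):
            idx = np.flatnonzero(c1 == b)
            sub_codes, sub_unique = pd.factorize(c2[idx])
            q = 1 + len(sub_unique)
            # Z columns: outer intercept, then each inner group
            Z = np.zeros((len(idx), q))
            Z[:, 0] = 1.0
            Z[np.arange(len(idx)), 1 + sub_codes] = 1.0
            d = np.concatenate(([max(s1, 1e-12)], np.full(len(sub_unique), max(s2, 1e-12))))
            z = np.zeros(q)
            e0 = eta0[idx]
            yb = y[idx]
            for _ in range(100):
                mu = np.exp(e0 + Z @ z)
                grad = Z.T @ (yb - mu) - z / d
                H = (Z * mu[:, None]).T @ Z + np.diag(1.0 / d)
                step = np.linalg.solve(H, grad)
                step = np.clip(step, -4.0, 4.0)
                z = z + step
                if np.max(np.abs(grad)) < 1e-9:
                    break
            mu = np.exp(e0 + Z @ z)
            W = (Z * mu[:, None]).T @ Z
            ll += float(np.sum(yb * (e0 + Z @ z) - mu))
            ll -= 0.5 * float(np.sum(z * z / d))
            sign, logdet = np.linalg.slogdet(np.diag(d) @ W + np.eye(q))
            ll -= 0.5 * float(logdet)
        return ll

    def __call__(self, theta) -> float:
        return -self.loglik(theta)

    def conditional_means(self, theta) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        beta, sigmas = self.split(theta)
        eta0 = self.X @ beta
        if not self.terms or all(s < 1e-9 for s in sigmas):
            return np.exp(eta0), {t[0]: np.zeros(t[2]) for t in self.terms}
        if len(self.terms) == 1:
            name, codes, G = self.terms[0]
            sigma2 = max(sigmas[0] ** 2, 1e-12)
            y_sum = np.bincount(codes, weights=self.y.astype(float), minlength=G)
            u, _ = _inner_modes_single(eta0, y_sum, codes, G, sigma2, self._warm[0])
            return np.exp(eta0 + u[codes]), {name: u}
        # blocks: recompute modes
        (n1, c1, G1), (n2, c2, G2) = self.terms
        s1, s2 = max(sigmas[0] ** 2, 1e-12), max(sigmas[1] ** 2, 1e-12)
        mu_all = np.zeros(len(self.y))
        u1 = np.zeros(G1)
        u2 = np.zeros(G2)
        y = self.y.astype(float)
        for b in range(G1):
            idx = np.flatnonzero(c1 == b)
            sub_codes, sub_unique = pd.factorize(c2[idx])
            q = 1 + len(sub_unique)
            Z = np.zeros((len(idx), q))
            Z[:, 0] = 1.0
            Z[np.arange(len(idx)), 1 + sub_codes] = 1.0
            d = np.concatenate(([s1], np.full(len(sub_unique), s2)))
            z = np.zeros(q)
            e0 = (self.X @ self.split(theta)[0])[idx]
            yb = y[idx]
            for _ in range(100):
                mu = np.exp(e0 + Z @ z)
                grad = Z.T @ (yb - mu) - z / d
                H = (Z * mu[:, None]).T @ Z + np.diag(1.0 / d)
                z = z + np.clip(np.linalg.solve(H, grad), -4.0, 4.0)
                if np.max(np.abs(grad)) < 1e-9:
                    break
            mu_all[idx] = np.exp(e0 + Z @ z)
            u1[b] = z[0]
            u2[sub_unique] = z[1:]
        return mu_all, {n1: u1, n2: u2}


# ---------------------------------------------------------------------------
# public fitting API


def fit_poisson_glmm(
    records,
    fixed: str = "level*species",
    random: str = "individual/species",
    var_fixed: Optional[float] = None,
    compute_se: bool = True,
    max_iter: int = 200,
    gtol: float = 1e-6,
) -> GLMMFit:
    """Maximum-likelihood Poisson GLMM via the Laplace approximation.

    ``var_fixed`` pins the random-effect standard deviation (0 gives the
    plain fixed-effects Poisson regression through the same code path);
    otherwise each variance component is estimated on the log-sd scale.
    Deterministic given the data: starting values are the log mean count
    for the intercept and zeros elsewhere.
    """
    df = _records_frame(records)
    y = df["n_ns"].to_numpy(float)
    X, names = build_fixed_design(df, fixed)
    terms = _parse_random(df, random)
    n, p = X.shape

    singular = False
    keep = np.ones(p, dtype=bool)
    col_norms = np.abs(X).sum(axis=0)
    if np.any(col_norms == 0):
        singular = True
        keep = col_norms > 0
    Xk = X[:, keep]
    kept_names = [nm for nm, k in zip(names, keep) if k]

    if y.sum() == 0:
        coef = {nm: float("nan") for nm in names}
        return GLMMFit(
            coef=coef, se=None,
            var_components={t[0]: 0.0 for t in terms},
            loglik=0.0, n_params=Xk.shape[1] + (0 if var_fixed is not None else len(terms)),
            converged=False, fixed_formula=fixed, random_formula=random,
            n_obs=n, singular_design=singular, degenerate=True,
            _y=y, _fitted=np.zeros(n),
        )

    obj = _LaplaceObjective(Xk, y, terms, var_fixed=var_fixed)
    beta0 = np.zeros(Xk.shape[1])
    beta0[0] = math.log(y.mean() + 0.5)
    if var_fixed is not None:
        theta0 = beta0
    else:
        theta0 = np.concatenate([beta0, np.full(len(terms), math.log(0.3))])

    res = optimize.minimize(
        obj, theta0, method="BFGS",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    theta = res.x
    loglik = -float(res.fun)
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3

    beta, sigmas = obj.split(theta)
    coef = {nm: float("nan") for nm in names}
    coef.update({nm: float(b) for nm, b in zip(kept_names, beta)})

    se = None
    if compute_se:
        se_vals = _wald_se(obj, theta)
        se = {nm: float("nan") for nm in names}
        se.update({nm: float(s) for nm, s in zip(kept_names, se_vals[: len(beta)])})

    var_components = {
        t[0]: float(s**2) for t, s in zip(terms, sigmas)
    }
    mu, u_hat = obj.conditional_means(theta)
    n_params = Xk.shape[1] + (0 if var_fixed is not None else len(terms))
    return GLMMFit(
        coef=coef, se=se, var_components=var_components,
        loglik=loglik, n_params=n_params, converged=converged,
        fixed_formula=fixed, random_formula=random, n_obs=n,
        singular_design=singular, degenerate=False,
        _y=y, _fitted=mu, _u_hat=u_hat,
    )


def _wald_se(obj: _LaplaceObjective, theta: np.ndarray) -> np.ndarray:
    """Standard errors from a central-difference Hessian of the objective."""
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((k, k))
    f0 = obj(theta)
    # diagonal
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        H[i, i] = (obj(theta + e) - 2 * f0 + obj(theta - e)) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                obj(theta + ei + ej) - obj(theta + ei - ej)
                - obj(theta - ei + ej) + obj(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def likelihood_ratio_test(full: GLMMFit, reduced: GLMMFit) -> LRTResult:
    """2 * (loglik_full - loglik_reduced) against chi-square(df)."""
    if full.n_obs != reduced.n_obs:
        raise NestingError("models fitted to different data")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise NestingError(
            f"reduced model must have fewer parameters (df = {df})"
        )
    stat = 2.0 * (full.loglik - reduced.loglik)
    p = float(sps.chi2.sf(max(stat, 0.0), df))
    return LRTResult(statistic=float(stat), df=df, p_value=p)


def overdispersion(fit: GLMMFit, records=None) -> OverdispersionResult:
    """Pearson-residual overdispersion ratio and chi-square p-value."""
    y = fit._y
    mu = fit.fitted_means
    if y is None:
        raise ValueError("fit carries no response vector")
    zero_bad = (mu == 0) & (y > 0)
    if np.any(zero_bad):
        raise ResidualDomainError("fitted mean 0 with positive count")
    r = np.zeros_like(mu)
    nz = mu > 0
    r[nz] = (y[nz] - mu[nz]) / np.sqrt(mu[nz])
    ss = float(np.sum(r * r))
    rdf = fit.n_obs - fit.n_params
    if rdf <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    return OverdispersionResult(
        ratio=ss / rdf,
        residual_df=rdf,
        pearson_ss=ss,
        p_value=float(sps.chi2.sf(ss, rdf)),
    )


def fit_summary_frame(fit: GLMMFit) -> pd.DataFrame:
    """Coefficient table (estimate, SE) for CSV/JSON export."""
    rows = []
    for name, est in fit.coef.items():
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": fit.se.get(name) if fit.se else float("nan"),
            }
        )
    return pd.DataFrame(rows)
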