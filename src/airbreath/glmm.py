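"""Laplace-approximate mixed-effects models for counts.

Implements negative-binomial (NB2) and Poisson GLMMs with a log link and one
or more crossed/nested random-intercept factors, in the statsmodels idiom: a
Model class built from arrays or a formula, whose ``fit()`` returns a Results
object carrying estimates, standard errors and a ``summary()`` table.

Model
-----
y_i | u  ~  NB2(mu_i, theta)    with  Var(y) = mu + mu^2/theta
log mu_i = x_i' beta + z_i' u (+ offset)
u_g ~ N(0, sigma_g^2) independently within each grouping factor g.

Estimation follows the standard Laplace strategy for GLMMs: for candidate
variance parameters (and theta), beta and the random-effect modes u are found
jointly by penalised iteratively reweighted least squares (PIRLS); the
marginal log-likelihood is then the penalised log-likelihood at the mode minus
half the log-determinant of the random-effect block of the working Hessian,

    ll = sum_i log f(y_i | u*) - u*' D^-1 u* / 2 - log det(I + D Z'WZ) / 2 .

The outer optimisation over (log sigma^2_g, log theta) uses Nelder-Mead,
which is derivative-free and robust at the sigma -> 0 boundary.  Fixed-effect
covariances are read off the beta block of the inverse joint working Hessian,
conditional on the variance parameters — the same convention as lme4's glmer.

With no random factors the machinery reduces to an ordinary ML negative
binomial (or Poisson) regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

__all__ = [
    "NegativeBinomialMixedModel",
    "PoissonMixedModel",
    "MixedGLMResults",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when PIRLS or the outer optimiser fails; carries the trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


def _nb_loglik(y, mu, theta):
    return np.sum(
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _poisson_loglik(y, mu):
    return np.sum(y * np.log(mu) - mu - special.gammaln(y + 1))


class _Family:
    """Log-link count family: log-likelihood and expected-information weights."""

    name = ""

    def loglik(self, y, mu, theta):  # pragma: no cover - interface
        raise NotImplementedError

    def weights(self, mu, theta):  # pragma: no cover - interface
        raise NotImplementedError


class _NegBin(_Family):
    name = "negative binomial"

    def loglik(self, y, mu, theta):
        return _nb_loglik(y, mu, theta)

    def weights(self, mu, theta):
        # E[-d2 l / d eta2] for NB2 with log link
        return mu * theta / (mu + theta)


class _Poisson(_Family):
    name = "poisson"

    def loglik(self, y, mu, theta):
        return _poisson_loglik(y, mu)

    def weights(self, mu, theta):
        return mu


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


@dataclass
class _REStructure:
    names: list[str]
    Z: np.ndarray  # (n, q) stacked indicator blocks
    block_sizes: list[int]
    level_labels: list[list] = field(default_factory=list)

    @property
    def q(self) -> int:
        return self.Z.shape[1] if self.Z.size else 0

    def variance_diag(self, sigma2: np.ndarray) -> np.ndarray:
        """Diagonal of D: each block's variance repeated over its levels."""
        return np.repeat(sigma2, self.block_sizes)


class _MixedGLMBase:
    """Shared machinery; subclasses pin the family."""

    family: _Family

    def __init__(
        self,
        endog,
        exog,
        groups: dict[str, np.ndarray] | None = None,
        exog_names: list[str] | None = None,
        offset=None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        if np.any(self.endog < 0) or np.any(self.endog != np.round(self.endog)):
            raise ValueError("response must be non-negative integers")
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        self.nobs = self.endog.size
        self.offset = np.zeros(self.nobs) if offset is None else np.asarray(offset, float)
        self.exog_names = exog_names or [f"x{j}" for j in range(self.exog.shape[1])]
        blocks, sizes, names, labels = [], [], [], []
        for name, fac in (groups or {}).items():
            codes, lvls = pd.factorize(np.asarray(fac))
            blocks.append(_indicator(codes, len(lvls)))
            sizes.append(len(lvls))
            names.append(name)
            labels.append(list(lvls))
        Z = np.hstack(blocks) if blocks else np.zeros((self.nobs, 0))
        self.re = _REStructure(names=names, Z=Z, block_sizes=sizes, level_labels=labels)

    # -- construction from formulas -------------------------------------------------
    @classmethod
    def from_formula(
        cls,
        formula: str,
        data: pd.DataFrame,
        groups: str | None = None,
        nested: str | None = None,
        offset=None,
    ):
        """Build from a patsy formula.

        ``groups`` names the outer random-intercept factor; ``nested``
        optionally names a factor nested within it (e.g. fish within group),
        encoded as an additional random intercept on the group:individual
        interaction — the standard nesting construction.
        """
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        grp: dict[str, np.ndarray] = {}
        if groups is not None:
            grp[groups] = data[groups].to_numpy()
            if nested is not None:
                combined = (
                    data[groups].astype(str) + ":" + data[nested].astype(str)
                ).to_numpy()
                grp[f"{nested}:{groups}"] = combined
        elif nested is not None:
            raise ValueError("nested requires groups")
        model = cls(
            endog=y.to_numpy().ravel(),
            exog=X.to_numpy(),
            groups=grp,
            exog_names=list(X.columns),
            offset=offset,
        )
        model.formula = formula
        model.data = data
        return model

    # -- inner PIRLS ----------------------------------------------------------------
    def _pirls(self, d_diag, theta, beta0=None, u0=None, maxiter=200, tol=1e-10):
        """Penalised IRLS for (beta, u) at fixed variance parameters.

        Returns beta, u, converged W, mu and an iteration trace.
        """
        X, Z, y = self.exog, self.re.Z, self.endog
        n, p = X.shape
        q = self.re.q
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        if beta0 is None and p > 0:
            # start from the intercept at the mean response if present
            ybar = max(y.mean(), 1e-3)
            if np.allclose(X[:, 0], 1.0):
                beta[0] = np.log(ybar)
        u = np.zeros(q) if u0 is None else u0.copy()
        pen_inv = 1.0 / d_diag if q else np.zeros(0)
        trace = []
        obj_prev = -np.inf
        for it in range(maxiter):
            eta = self.offset + X @ beta + (Z @ u if q else 0.0)
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
            W = self.family.weights(mu, theta)
            # working response on the linear-predictor scale
            z = eta - self.offset + (y - mu) / mu
            C = np.hstack([X, Z]) if q else X
            A = C.T @ (C * W[:, None])
            if q:
                A[p:, p:] += np.diag(pen_inv)
            b = C.T @ (W * z)
            try:
                sol = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular working system: {exc}", trace)
            step_beta, step_u = sol[:p], sol[p:]
            delta = max(
                np.max(np.abs(step_beta - beta)) if p else 0.0,
                np.max(np.abs(step_u - u)) if q else 0.0,
            )
            beta, u = step_beta, step_u
            obj = self.family.loglik(y, np.exp(np.clip(self.offset + X @ beta + (Z @ u if q else 0.0), -30, 30)), theta)
            if q:
                obj -= 0.5 * np.sum(u**2 * pen_inv)
            trace.append((it, float(obj), float(delta)))
            if delta < tol or abs(obj - obj_prev) < tol * (1 + abs(obj)):
                return beta, u, W, mu, trace
            obj_prev = obj
        raise ConvergenceError(
            f"PIRLS did not converge in {maxiter} iterations", trace
        )

    # -- Laplace marginal log-likelihood ---------------------------------------------
    def _laplace_loglik(self, d_diag, theta, warm):
        beta, u, W, mu, trace = self._pirls(
            d_diag, theta, beta0=warm.get("beta"), u0=warm.get("u")
        )
        warm["beta"], warm["u"] = beta, u
        X, Z, y = self.exog, self.re.Z, self.endog
        eta = np.clip(self.offset + X @ beta + (Z @ u if self.re.q else 0.0), -30, 30)
        mu = np.exp(eta)
        ll = self.family.loglik(y, mu, theta)
        if self.re.q:
            W = self.family.weights(mu, theta)
            ZtWZ = Z.T @ (Z * W[:, None])
            M = np.eye(self.re.q) + ZtWZ * d_diag[None, :]
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                raise ConvergenceError("non-positive-definite Laplace Hessian", trace)
            ll += -0.5 * np.sum(u**2 / d_diag) - 0.5 * logdet
        return ll, beta, u, W, mu

    def _has_theta(self) -> bool:
        return isinstance(self.family, _NegBin)

    def fit(self, start_theta=None, maxiter=500, disp=False) -> "MixedGLMResults":
        """Maximum (Laplace-approximate) likelihood fit."""
        y = self.endog
        k_vc = len(self.re.block_sizes)
        # method-of-moments theta start, clipped to a sane range
        if self._has_theta():
            m, v = y.mean(), y.var(ddof=1) if y.size > 1 else y.mean()
            if start_theta is None:
                start_theta = m**2 / (v - m) if v > m > 0 else 10.0
            start_theta = float(np.clip(start_theta, 0.05, 100.0))
        warm: dict = {}
        outer_trace: list = []
        # bounds keep the likelihood in its numerically trustworthy range:
        # theta <= 1e4 (already Poisson to ~1e-4 in the loglik) avoids
        # catastrophic cancellation in gammaln(y+theta)-gammaln(theta)
        lo = np.concatenate(
            [np.full(k_vc, -20.0), [-5.0] if self._has_theta() else []]
        )
        hi = np.concatenate(
            [np.full(k_vc, 5.0), [np.log(1e4)] if self._has_theta() else []]
        )

        def negll(params):
            clipped = np.clip(params, lo, hi)
            penalty = 1e4 * float(np.sum((params - clipped) ** 2))
            log_s2 = clipped[:k_vc]
            d_diag = self.re.variance_diag(np.exp(log_s2)) if k_vc else np.zeros(0)
            theta = np.exp(clipped[k_vc]) if self._has_theta() else None
            try:
                ll = self._laplace_loglik(d_diag, theta, warm)[0]
            except ConvergenceError:
                return 1e10
            outer_trace.append((list(clipped), float(ll)))
            return -ll + penalty

        x0 = np.concatenate(
            [np.full(k_vc, -1.0), [np.log(start_theta)] if self._has_theta() else []]
        )
        if x0.size:
            res = optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter,
                    "xatol": 1e-6,
                    "fatol": 1e-9,
                    "adaptive": True,
                },
            )
            if not res.success and res.fun >= 1e10:
                raise ConvergenceError(
                    f"outer optimisation failed: {res.message}", outer_trace
                )
            params = np.clip(res.x, lo, hi)
        else:
            params = x0
        sigma2 = np.exp(params[:k_vc]) if k_vc else np.zeros(0)
        # collapse numerically-zero components to the boundary
        sigma2 = np.where(sigma2 < 1e-8, 0.0, sigma2)
        d_diag = self.re.variance_diag(np.maximum(sigma2, 1e-12)) if k_vc else np.zeros(0)
        theta = float(np.exp(params[k_vc])) if self._has_theta() else None
        ll, beta, u, W, mu = self._laplace_loglik(d_diag, theta, warm)
        cov_beta = self._cov_beta(W, d_diag)
        n_params = len(self.exog_names) + k_vc + (1 if self._has_theta() else 0)
        return MixedGLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_beta, index=self.exog_names, columns=self.exog_names
            ),
            vc=dict(zip(self.re.names, sigma2)),
            theta=theta,
            llf=float(ll),
            ranef=self._ranef_frame(u),
            fittedvalues=mu,
            n_params=n_params,
        )

    def _cov_beta(self, W, d_diag):
        X, Z = self.exog, self.re.Z
        p, q = X.shape[1], self.re.q
        XtWX = X.T @ (X * W[:, None])
        if not q:
            return np.linalg.inv(XtWX)
        XtWZ = X.T @ (Z * W[:, None])
        ZtWZ = Z.T @ (Z * W[:, None]) + np.diag(1.0 / d_diag)
        # Schur complement of the random-effect block
        return np.linalg.inv(XtWX - XtWZ @ np.linalg.solve(ZtWZ, XtWZ.T))

    def _ranef_frame(self, u):
        out = {}
        start = 0
        for name, size, labels in zip(
            self.re.names, self.re.block_sizes, self.re.level_labels
        ):
            out[name] = pd.Series(u[start : start + size], index=labels)
            start += size
        return out


class NegativeBinomialMixedModel(_MixedGLMBase):
    """NB2 GLMM with log link and random intercepts, Laplace-ML estimation."""

    family = _NegBin()


class PoissonMixedModel(_MixedGLMBase):
    """Poisson GLMM with log link and random intercepts, Laplace-ML estimation."""

    family = _Poisson()


@dataclass
class MixedGLMResults:
    """Estimates, uncertainties and fit statistics of a mixed count model."""

    model: _MixedGLMBase
    params: pd.Series
    cov_params: pd.DataFrame
    vc: dict
    theta: float | None
    llf: float
    ranef: dict
    fittedvalues: np.ndarray
    n_params: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict_fixed(self) -> np.ndarray:
        """Linear predictor from fixed effects only (log scale)."""
        return self.model.offset + self.model.exog @ self.params.to_numpy()

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.params - z * self.bse,
                "upper": self.params + z * self.bse,
            }
        )

    def summary(self) -> str:
        lines = [
            f"{self.model.family.name.title()} mixed model (Laplace ML)",
            f"  observations: {self.nobs}   log-likelihood: {self.llf:.3f}",
        ]
        if self.theta is not None:
            lines.append(f"  dispersion (theta): {self.theta:.4f}")
        for name, s2 in self.vc.items():
            lines.append(f"  random intercept var[{name}]: {s2:.5f}")
        lines.append("")
        tbl = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
            }
        )
        lines.append(tbl.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)
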