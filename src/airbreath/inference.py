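"""Mixed-effects model battery, likelihood-ratio selection and Nakagawa R2.

The study design is repeated-measures: each fish belongs to one group, each
group is measured at two acclimation temperatures and three ambient oxygen
levels.  Gaussian responses (log SMR, dispersion coefficient, speed, cohesion)
are fitted with linear mixed models (random intercepts, optionally fish nested
within group); count responses (air breaths per group or per fish) with
negative-binomial (default) or Poisson GLMMs with a log link.

Model choice follows backward elimination by likelihood-ratio tests on ML
fits at alpha = 0.05, with one domain constraint: log body mass is never
dropped while log SMR remains in a model, so metabolic effects are always
read conditional on allometric scaling.  Explained variance is summarised by
the marginal and conditional R2 of Nakagawa & Schielzeth: the variance of the
fixed-effect linear predictor relative to the total of fixed, random and
residual variance (marginal), or fixed + random relative to the same total
(conditional).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import special, stats

from .glmm import MixedGLMResults, NegativeBinomialMixedModel, PoissonMixedModel

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "R2Result",
    "fit_lmm",
    "fit_nb_glmm",
    "fit_model",
    "likelihood_ratio_test",
    "nakagawa_r2",
    "select_model",
    "MODEL_BATTERY",
]


@dataclass(frozen=True)
class ModelSpec:
    """One model of the battery.

    ``formula`` is a patsy fixed-effects formula; ``groups`` the outer
    random-intercept factor; ``nested`` an optional factor nested within it.
    ``forced`` terms are never dropped during selection; ``forced_while``
    maps a term to a guard term: the key cannot be dropped while the guard is
    still in the model (mass kept while SMR remains).
    """

    name: str
    formula: str
    groups: str = "group"
    nested: str | None = None
    family: str = "gaussian"  # gaussian | negbinom | poisson
    forced: tuple = ()
    forced_while: dict = field(default_factory=dict)

    def with_formula(self, formula: str) -> "ModelSpec":
        return ModelSpec(
            self.name, formula, self.groups, self.nested, self.family,
            self.forced, self.forced_while,
        )


@dataclass
class FitResult:
    """Family-agnostic view of a fitted mixed model."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    statistics: pd.Series  # z (counts) or t-like (gaussian)
    pvalues: pd.Series
    vc: dict  # variance components by factor name
    scale: float | None  # residual variance (gaussian)
    theta: float | None  # NB size parameter
    llf: float
    nobs: int
    n_params: int
    fitted_fixed: np.ndarray  # fixed-effects-only linear predictor
    raw: object = None  # underlying results object

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "stat": self.statistics,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        head = [
            f"model {self.spec.name!r} ({self.spec.family}), n={self.nobs}, "
            f"logLik={self.llf:.3f}",
            f"  formula: {self.spec.formula}",
        ]
        for k, v in self.vc.items():
            head.append(f"  var[{k}] = {v:.5f}")
        if self.scale is not None:
            head.append(f"  residual var = {self.scale:.5f}")
        if self.theta is not None:
            head.append(f"  NB size (theta) = {self.theta:.4f}")
        return "\n".join(head) + "\n" + self.summary_frame().to_string(
            float_format=lambda v: f"{v: .4f}"
        )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float
    full_name: str = ""
    reduced_name: str = ""


@dataclass(frozen=True)
class R2Result:
    r2_marginal: float
    r2_conditional: float


def _check_log_terms(formula: str, data: pd.DataFrame) -> None:
    """Fail early, with row numbers, when a log transform would hit <= 0."""
    import re

    for col in re.findall(r"np\.log\((\w+)\)", formula):
        if col in data.columns:
            bad = data.index[data[col] <= 0].tolist()
            if bad:
                raise ValueError(
                    f"non-positive values passed to log({col}) in rows {bad}"
                )


def fit_lmm(
    spec: ModelSpec, data: pd.DataFrame, reml: bool = False, **fit_kws
) -> FitResult:
    """Gaussian linear mixed model with random intercepts.

    ML by default so likelihood-ratio tests between nested fixed-effect
    structures are valid; ``reml=True`` refits a final model by REML.
    Nesting (fish within group) enters as a variance component on the
    group:individual interaction.
    """
    import statsmodels.formula.api as smf

    _check_log_terms(spec.formula, data)
    data = data.reset_index(drop=True)
    vc_formula = None
    if spec.nested is not None:
        data = data.copy()
        data["_nested_"] = (
            data[spec.groups].astype(str) + ":" + data[spec.nested].astype(str)
        )
        vc_formula = {spec.nested: "0 + C(_nested_)"}
    model = smf.mixedlm(
        spec.formula, data, groups=data[spec.groups], re_formula="1",
        vc_formula=vc_formula,
    )
    # a single optimiser occasionally under-converges or hits a singular
    # Hessian at the zero-variance boundary; run a small ensemble and keep
    # the best finite likelihood (an explicit method= skips the ensemble)
    methods = fit_kws.pop("method", None)
    # powell matters at the zero-variance boundary, where the gradient
    # methods stall short of the optimum
    ensemble = [methods] if methods is not None else ["lbfgs", "bfgs", "powell"]
    res = None
    last_exc: Exception | None = None

    def _try(meth):
        nonlocal res, last_exc
        try:
            cand = model.fit(reml=reml, method=meth, **fit_kws)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
            return
        if not (np.isfinite(cand.llf) and np.isfinite(cand.scale)):
            last_exc = ValueError(f"non-finite likelihood with {meth}")
            return
        if res is None or cand.llf > res.llf:
            res = cand

    for meth in ensemble:
        _try(meth)
    if res is None and methods is None:
        _try("nm")
    if res is None:
        raise ValueError(f"singular design in {spec.name!r}: {last_exc}") from last_exc
    fe = res.fe_params
    # cov_re / vcomp are already on the data scale after fitting
    vc = {spec.groups: float(res.cov_re.iloc[0, 0])}
    if spec.nested is not None:
        vc[f"{spec.nested}:{spec.groups}"] = float(res.vcomp[0])
    X = patsy.dmatrix(spec.formula.split("~", 1)[1], data, return_type="dataframe")
    fitted_fixed = X.to_numpy() @ fe.to_numpy()
    n_params = len(fe) + 1 + len(vc)  # + residual variance
    return FitResult(
        spec=spec,
        params=fe,
        bse=res.bse_fe,
        statistics=res.tvalues[fe.index],
        pvalues=res.pvalues[fe.index],
        vc=vc,
        scale=float(res.scale),
        theta=None,
        llf=float(res.llf),
        nobs=int(res.nobs),
        n_params=n_params,
        fitted_fixed=fitted_fixed,
        raw=res,
    )


def fit_nb_glmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Negative-binomial (or Poisson) GLMM via the in-house Laplace fitter."""
    _check_log_terms(spec.formula, data)
    data = data.reset_index(drop=True)
    cls = {
        "negbinom": NegativeBinomialMixedModel,
        "poisson": PoissonMixedModel,
    }[spec.family]
    model = cls.from_formula(
        spec.formula, data, groups=spec.groups, nested=spec.nested
    )
    res: MixedGLMResults = model.fit()
    return FitResult(
        spec=spec,
        params=res.params,
        bse=res.bse,
        statistics=res.zvalues,
        pvalues=res.pvalues,
        vc=dict(res.vc),
        scale=None,
        theta=res.theta,
        llf=res.llf,
        nobs=res.nobs,
        n_params=res.n_params,
        fitted_fixed=res.predict_fixed(),
        raw=res,
    )


def fit_model(spec: ModelSpec, data: pd.DataFrame, **kwargs) -> FitResult:
    if spec.family == "gaussian":
        return fit_lmm(spec, data, **kwargs)
    return fit_nb_glmm(spec, data)


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> LRTResult:
    """2*(logLik difference) against chi-square with the parameter-count df.

    Both fits must be ML (never REML) and the reduced model nested in the
    full one.
    """
    stat = 2.0 * (full.llf - reduced.llf)
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("reduced model must have fewer parameters than full")
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic ({stat:.3g}): models not nested or not converged"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        full_name=full.spec.formula,
        reduced_name=reduced.spec.formula,
    )


def nakagawa_r2(fit: FitResult, nb_resid: str = "lognormal") -> R2Result:
    """Marginal and conditional R2 for a mixed model.

    r2m = var_f / (var_f + sum var_r + var_e);
    r2c = (var_f + sum var_r) / (same denominator),
    where var_f is the (population) variance of the fixed-effect linear
    predictor.  For the Gaussian family var_e is the residual variance; for
    count families the observation-level variance on the latent log scale uses
    a distribution-specific approximation: ``lognormal`` -> ln(1 + 1/lam +
    1/theta), ``trigamma`` -> psi_1((1/lam + 1/theta)^-1), with lam the
    expected count at the average linear predictor (1/theta omitted for
    Poisson).
    """
    var_f = float(np.var(fit.fitted_fixed))
    var_r = float(sum(fit.vc.values()))
    if fit.spec.family == "gaussian":
        var_e = float(fit.scale)
    else:
        inv_theta = 1.0 / fit.theta if fit.theta is not None else 0.0
        lam = float(np.exp(np.mean(fit.fitted_fixed) + 0.5 * var_r))
        disp = 1.0 / lam + inv_theta
        if nb_resid == "lognormal":
            var_e = float(np.log1p(disp))
        elif nb_resid == "trigamma":
            var_e = float(special.polygamma(1, 1.0 / disp))
        else:
            raise ValueError(f"unknown nb_resid {nb_resid!r}")
    total = var_f + var_r + var_e
    if total <= 0:
        raise ValueError("zero total variance; R2 undefined")
    return R2Result(
        r2_marginal=var_f / total, r2_conditional=(var_f + var_r) / total
    )


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------


def _terms(formula: str) -> list[str]:
    rhs = formula.split("~", 1)[1]
    desc = patsy.ModelDesc.from_formula("y ~" + rhs)
    out = []
    for t in desc.rhs_termlist:
        if t.factors:  # skip intercept
            out.append(":".join(f.code for f in t.factors))
    return out


def _formula_without(formula: str, drop: str) -> str:
    lhs = formula.split("~", 1)[0].strip()
    kept = [t for t in _terms(formula) if t != drop]
    rhs = " + ".join(kept) if kept else "1"
    return f"{lhs} ~ {rhs}"


def _droppable(terms: list[str], spec: ModelSpec) -> list[str]:
    """Terms that respect marginality, forcing, and the mass-while-SMR guard."""
    out = []
    factor_sets = {t: set(t.split(":")) for t in terms}
    for t in terms:
        if t in spec.forced:
            continue
        guard = spec.forced_while.get(t)
        if guard is not None and guard in terms:
            continue
        if any(
            factor_sets[t] < factor_sets[o] for o in terms if o != t
        ):  # appears in a higher-order interaction
            continue
        out.append(t)
    return out


def select_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    **fit_kwargs,
) -> tuple[FitResult, list[dict]]:
    """Backward elimination by LRT from the full model of ``spec``.

    At each step every droppable term (not forced, not guarded, not nested in
    a retained interaction) is tested by refitting without it; the term with
    the largest p-value above ``alpha`` is removed.  Stops when every
    remaining droppable term tests significant.  Returns the final fit and a
    trace of every test performed.
    """
    if not _terms(spec.formula):
        raise ValueError("empty candidate list: formula has no droppable terms")
    current = spec
    fit = fit_model(current, data, **fit_kwargs)
    trace: list[dict] = []
    while True:
        cand = _droppable(_terms(current.formula), current)
        if not cand:
            break
        tests = []
        for term in cand:
            reduced_spec = current.with_formula(
                _formula_without(current.formula, term)
            )
            try:
                reduced_fit = fit_model(reduced_spec, data, **fit_kwargs)
                lrt = likelihood_ratio_test(fit, reduced_fit)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("drop test for %r failed: %s", term, exc)
                continue
            tests.append((term, reduced_spec, reduced_fit, lrt))
            trace.append(
                {
                    "step": len(trace),
                    "term": term,
                    "statistic": lrt.statistic,
                    "df": lrt.df,
                    "p": lrt.p_value,
                    "dropped": False,
                }
            )
        drops = [t for t in tests if t[3].p_value > alpha]
        if not drops:
            break
        term, reduced_spec, reduced_fit, lrt = max(drops, key=lambda t: t[3].p_value)
        trace[-len(tests) + [t[0] for t in tests].index(term)]["dropped"] = True
        current, fit = reduced_spec, reduced_fit
    return fit, trace


# ---------------------------------------------------------------------------
# the battery: one spec per response of the study
# ---------------------------------------------------------------------------

MODEL_BATTERY: dict[str, ModelSpec] = {
    # temperature & allometry effects on standard metabolic rate
    "smr": ModelSpec(
        name="smr",
        formula="np.log(smr) ~ np.log(mass) + C(temp)",
        groups="group",
        nested="fish_id",
        family="gaussian",
    ),
    # environment & group dynamics effects on total group breaths
    "group_abf": ModelSpec(
        name="group_abf",
        formula="abf_group ~ C(temp) + C(o2) + speed + cohesion",
        groups="group",
        family="negbinom",
    ),
    # environment & dynamics effects on breathing synchrony
    "cd": ModelSpec(
        name="cd",
        formula="cd ~ C(temp) + C(o2) + speed + cohesion",
        groups="group",
        family="gaussian",
    ),
    # individual breath counts: physiology and environment, all interactions
    "indiv_abf": ModelSpec(
        name="indiv_abf",
        formula="abf ~ np.log(mass) + np.log(smr) + C(o2) * C(temp)",
        groups="group",
        nested="fish_id",
        family="negbinom",
        forced_while={"np.log(mass)": "np.log(smr)"},
    ),
    # group activity
    "activity": ModelSpec(
        name="activity",
        formula="speed ~ cohesion + C(temp) * C(o2)",
        groups="group",
        family="gaussian",
    ),
    # group cohesion
    "cohesion": ModelSpec(
        name="cohesion",
        formula="cohesion ~ speed + C(temp) * C(o2)",
        groups="group",
        family="gaussian",
    ),
}
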