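"""Candidate trend models, AICc ranking, Akaike weights, and contrasts.

Every response (MC indices, day-of-year of WBP use, log movement indices) is
confronted with the same three-model candidate set:

    Base                  = CONES + SEX + CONES x SEX
    Base + YEAR
    Base + YEAR + YEAR x CONES

fit respectively by weighted least squares (per-bear responses, weighted by
the bear's fix-success weight), quantile regression at tau in {0.1, 0.5, 0.9}
(bear-day day-of-year responses), or a mixed-effects linear model with a
random intercept per bear-year (bear-day movement responses, fit by ML so
AICc is comparable across fixed-effect sets).  Models are ranked by AICc with
Akaike weights; effects are summarized as model-predicted contrasts with Wald
95% confidence intervals.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

BASE_TERMS = "CONES + C(SEX) + CONES:C(SEX)"
CANDIDATE_FORMULAS = {
    "Base": BASE_TERMS,
    "Base + YEAR": BASE_TERMS + " + YEAR",
    "Base + YEAR + YEAR x CONES": BASE_TERMS + " + YEAR + YEAR:CONES",
}
Z95 = 1.96


def classify_cone_year(counts):
    """Rate each year's median cone count "good" or "poor".

    The threshold is the overall median of the supplied counts, taken as the
    lower median (the ceil(n/2)-th order statistic); a count equal to the
    median rates "good".  This convention reproduces the published annual
    ratings exactly, including the years whose count sits at the median.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("empty cone-count table")
    vals = np.sort([c for _, c in counts])
    lower_median = float(vals[(len(vals) - 1) // 2])
    return ["good" if c >= lower_median else "poor" for _, c in counts]


def aicc(loglik, K, n):
    """AICc = -2 logLik + 2K + 2K(K+1)/(n - K - 1); requires n > K + 1."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={K + 1}")
    return float(-2 * loglik + 2 * K + 2 * K * (K + 1) / (n - K - 1))


def akaike_weights(delta_aicc):
    """w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)."""
    d = np.asarray(delta_aicc, dtype=float)
    if (d < 0).any():
        raise ValueError("delta AICc values must be >= 0")
    w = np.exp(-d / 2)
    return w / w.sum()


@dataclass
class ModelSpec:
    response: str
    family: str                     # "linear-weighted" | "quantile" | "mixed-linear"
    name: str                       # candidate-set label, e.g. "Base + YEAR"
    formula_terms: str
    tau: float | None = None

    @property
    def formula(self):
        return f"{self.response} ~ {self.formula_terms}"


@dataclass
class ModelFit:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    K: int
    aicc: float
    delta_aicc: float | None = None
    akaike_weight: float | None = None
    note: str | None = None
    extra: dict = field(default_factory=dict)


def candidate_specs(response, family, tau=None):
    return [ModelSpec(response=response, family=family, name=name,
                      formula_terms=terms, tau=tau)
            for name, terms in CANDIDATE_FORMULAS.items()]


def _check_rank(result, spec):
    X = result.model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        names = result.model.exog_names
        raise ValueError(
            f"rank-deficient design for {spec.name!r}: "
            f"rank {rank} < {X.shape[1]} columns {names}"
        )


def fit_linear_weighted(data, spec, weights=None):
    """Weighted least squares with a Gaussian likelihood.

    ``weights`` are the per-bear overall fix-success weights (column name or
    array); all-equal weights reduce exactly to OLS.  K counts the intercept,
    slopes, and the residual variance.
    """
    w = np.ones(len(data)) if weights is None else (
        data[weights].to_numpy() if isinstance(weights, str) else np.asarray(weights)
    )
    model = smf.wls(spec.formula, data=data, weights=w)
    res = model.fit()
    _check_rank(res, spec)
    n = int(res.nobs)
    K = len(res.params) + 1
    return ModelFit(
        spec=spec, params=res.params, bse=res.bse,
        cov=res.cov_params(), loglik=float(res.llf), n=n, K=K,
        aicc=aicc(res.llf, K, n), extra={"result": res},
    )


def _quantile_loglik(resid, tau):
    """Asymmetric-Laplace log likelihood at the MLE of its scale."""
    rho = np.sum(resid * (tau - (resid < 0)))
    n = len(resid)
    if rho <= 0:  # perfect fit; likelihood unbounded -- cap at machine scale
        rho = np.finfo(float).tiny * n
    sigma = rho / n
    return float(n * (np.log(tau * (1 - tau)) - np.log(sigma) - 1))


def fit_quantile(data, spec, tau=None, n_boot=500, seed=0):
    """Quantile regression by check-loss minimization.

    The AICc likelihood uses the asymmetric-Laplace construction with scale
    estimated at its maximum.  Standard errors and the coefficient covariance
    come from a seeded xy-pair bootstrap (``n_boot`` resamples; 0 disables it
    and falls back to the analytic kernel-based covariance).
    """
    tau = tau if tau is not None else spec.tau
    if tau is None or not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    if len(data) == 0:
        raise ValueError("empty data")
    if data[spec.response].nunique() < 2:
        # constant response: the check loss is minimized by that constant at
        # every tau; return the degenerate intercept-only solution
        c = float(data[spec.response].iloc[0])
        names = ["Intercept"]
        params = pd.Series([c], index=names)
        n = len(data)
        ll = _quantile_loglik(np.zeros(n), tau)
        K = 2
        zero = pd.DataFrame(np.zeros((1, 1)), index=names, columns=names)
        return ModelFit(spec=spec, params=params,
                        bse=pd.Series(np.zeros(1), index=names), cov=zero,
                        loglik=ll, n=n, K=K, aicc=aicc(ll, K, n),
                        note="constant response: intercept-only degenerate fit",
                        extra={"tau": tau})
    model = smf.quantreg(spec.formula, data=data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(q=tau)
    _check_rank(res, spec)
    n = int(res.nobs)
    ll = _quantile_loglik(np.asarray(res.resid), tau)
    K = len(res.params) + 1

    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    b = smf.quantreg(spec.formula, data=data.iloc[idx]).fit(q=tau)
                boot.append(b.params.reindex(res.params.index))
            except Exception:
                continue
        bootdf = pd.DataFrame(boot)
        cov = pd.DataFrame(np.cov(bootdf.to_numpy(), rowvar=False),
                           index=res.params.index, columns=res.params.index)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=res.params.index)
    else:
        cov = res.cov_params()
        bse = res.bse
    return ModelFit(
        spec=spec, params=res.params, bse=bse, cov=cov,
        loglik=ll, n=n, K=K, aicc=aicc(ll, K, n),
        extra={"result": res, "tau": tau},
    )


def fit_mixed(data, spec, groups="bear_year"):
    """Linear mixed model, random intercept per bear-year, fit by ML.

    Falls back to a fixed-effects OLS fit (with a note) when only one group
    is present.  K counts fixed effects + random-intercept variance +
    residual variance.
    """
    grp = data[groups] if isinstance(groups, str) else pd.Series(groups)
    if grp.nunique() < 2:
        res = smf.ols(spec.formula, data=data).fit()
        _check_rank(res, spec)
        n, K = int(res.nobs), len(res.params) + 1
        return ModelFit(
            spec=spec, params=res.params, bse=res.bse, cov=res.cov_params(),
            loglik=float(res.llf), n=n, K=K, aicc=aicc(res.llf, K, n),
            note="single group: fell back to fixed-effects OLS",
            extra={"result": res},
        )
    model = smf.mixedlm(spec.formula, data=data, groups=grp)
    X = model.exog
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {spec.name!r}: columns {model.exog_names}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    fe = res.fe_params
    cov = pd.DataFrame(np.asarray(res.cov_params())[: len(fe), : len(fe)],
                       index=fe.index, columns=fe.index)
    n = int(res.nobs)
    K = len(fe) + 2
    return ModelFit(
        spec=spec, params=fe, bse=res.bse_fe, cov=cov,
        loglik=float(res.llf), n=n, K=K, aicc=aicc(res.llf, K, n),
        extra={"result": res, "group_var": float(res.cov_re.iloc[0, 0])},
    )


def lrt_random_effect(fixed_fit, mixed_fit):
    """Boundary LRT for the random intercept: 50:50 chi2_0 / chi2_1 mixture."""
    if fixed_fit.spec.formula_terms != mixed_fit.spec.formula_terms:
        raise ValueError("fits are not nested: fixed-effect terms differ")
    if fixed_fit.n != mixed_fit.n:
        raise ValueError("fits use different data")
    stat = max(0.0, 2 * (mixed_fit.loglik - fixed_fit.loglik))
    p = 0.5 if stat == 0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p


def rank_models(candidates):
    """Sort a candidate set by AICc; attach delta AICc and Akaike weights."""
    if len(candidates) < 1:
        raise ValueError("empty candidate set")
    ns = {f.n for f in candidates}
    if len(ns) > 1:
        raise ValueError(f"candidates fit to different n: {sorted(ns)}")
    fits = sorted(candidates, key=lambda f: f.aicc)
    best = fits[0].aicc
    deltas = [f.aicc - best for f in fits]
    ws = akaike_weights(deltas)
    for f, d, w in zip(fits, deltas, ws):
        f.delta_aicc = float(d)
        f.akaike_weight = float(w)
    return fits


def model_table(fits):
    """Candidate-set summary in published-table form."""
    return pd.DataFrame([
        {
            "response": f.spec.response,
            "family": f.spec.family,
            "model": f.spec.name,
            "K": f.K,
            "n": f.n,
            "logLik": f.loglik,
            "AICc": f.aicc,
            "dAICc": f.delta_aicc,
            "weight": f.akaike_weight,
        }
        for f in fits
    ])


@dataclass
class ContrastEstimate:
    description: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float


_CAT_RE = re.compile(r"^C\((\w+)\)\[T\.([^\]]+)\]$")


def _design_row(param_names, setting):
    """Evaluate one predictor setting into a design vector for the params."""
    row = np.empty(len(param_names))
    for i, name in enumerate(param_names):
        val = 1.0
        for factor in name.split(":"):
            factor = factor.strip()
            if factor == "Intercept":
                continue
            if factor in setting:  # direct dummy setting, e.g. averaging sexes
                val *= float(setting[factor])
                continue
            m = _CAT_RE.match(factor)
            if m:
                var, level = m.groups()
                if var not in setting:
                    raise ValueError(f"setting missing term {var!r}")
                val *= 1.0 if str(setting[var]) == level else 0.0
            else:
                if factor not in setting:
                    raise ValueError(f"setting missing term {factor!r}")
                val *= float(setting[factor])
        row[i] = val
    return row


def predict_contrast(fit, setting_a, setting_b, description=""):
    """Model-predicted difference (a - b) with a Wald 95% CI.

    Categorical predictors (SEX) may be given as the level name or, to
    average over sexes, as the proportion of the non-reference level via
    ``{"SEX_M": 0.5}``-style numeric settings in place of ``"SEX"``.
    """
    names = list(fit.params.index)
    xa = _design_row(names, setting_a)
    xb = _design_row(names, setting_b)
    c = xa - xb
    beta = fit.params.to_numpy()
    Sigma = fit.cov.to_numpy()
    est = float(c @ beta)
    se = float(np.sqrt(c @ Sigma @ c))
    return ContrastEstimate(
        description=description or "contrast",
        estimate=est, se=se,
        ci_lower=est - Z95 * se, ci_upper=est + Z95 * se,
    )


def predict_value(fit, setting):
    """Model-predicted response at one predictor setting (point estimate)."""
    x = _design_row(list(fit.params.index), setting)
    return float(x @ fit.params.to_numpy())
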