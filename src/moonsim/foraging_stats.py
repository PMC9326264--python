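"""Statistical workflow for binary foraging records under ALAN treatments.

The pipeline mirrors a standard mixed-model analysis of a designed
behavioural experiment:

1. a global binomial GLM with fixed structure
   ``ALAN*Moonlight + ALAN*NightOfObservation + ALAN*TimeOfDay``;
2. all-subsets (marginality-respecting) model selection ranked by AIC with
   Akaike weights, keeping the smallest top set whose cumulative weight
   reaches 0.99;
3. a likelihood-ratio test of the selected model against the intercept-only
   model;
4. a refit as a binomial GLMM with random intercepts for tank and for snail
   nested in tank, by Laplace-approximate maximum likelihood (penalized
   IRLS over the joint fixed/random coefficients, Nelder-Mead over the two
   variance components — the same approximation lme4's ``glmer`` uses by
   default);
5. Type III term tests: each term dropped singly from the selected model and
   tested by likelihood ratio;
6. per-treatment moonlight slopes (estimated marginal trends) with all
   pairwise differences, unadjusted;
7. simulation-based prediction intervals.

Treatment coding uses the no-ALAN control as reference level throughout.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm

__all__ = [
    "GLOBAL_TERMS",
    "SELECTED_TERMS",
    "ModelSpec",
    "FitResult",
    "TermTest",
    "SlopeComparison",
    "build_design",
    "fit_glm",
    "fit_glmm",
    "fit_global_and_select",
    "lrt",
    "type3_tests",
    "moonlight_slopes",
    "predict_intervals",
]

MAIN_TERMS = ("ALAN", "Moonlight", "Night", "TimeOfDay")
INTERACTIONS = ("ALAN:Moonlight", "ALAN:Night", "ALAN:TimeOfDay")
GLOBAL_TERMS = MAIN_TERMS + INTERACTIONS
#: the fixed structure the study's selection retained
SELECTED_TERMS = ("ALAN", "Moonlight", "Night", "TimeOfDay",
                  "ALAN:Moonlight", "ALAN:Night")

TREATMENT_ORDER = ("control", "0.1lx", "0.5lx", "1lx", "10lx", "10lx-mit", "50lx")


def _respects_marginality(terms) -> bool:
    ts = set(terms)
    for inter in ts & set(INTERACTIONS):
        a, b = inter.split(":")
        if a not in ts or b not in ts:
            return False
    return True


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure plus the on/off nested random intercepts."""

    fixed_terms: tuple[str, ...] = SELECTED_TERMS
    random: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - set(GLOBAL_TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        if not _respects_marginality(self.fixed_terms):
            raise ValueError("interaction present without both main effects")


@dataclass(frozen=True)
class TermTest:
    term: str
    chi_sq: float
    df: int
    p_value: float


@dataclass(frozen=True)
class SlopeComparison:
    pair: tuple[str, str]
    difference: float  # logit per lux
    se: float
    z: float
    p_value: float  # unadjusted


@dataclass
class FitResult:
    """A fitted binomial model (GLM or Laplace GLMM)."""

    terms: tuple[str, ...]
    method: str  # "glm" or "glmm-laplace"
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_params: int  # fixed coefficients + variance components
    converged: bool
    nobs: int
    variance_components: dict = field(default_factory=dict)
    singular: bool = False
    design_info: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


# ---------------------------------------------------------------------------
# design matrices

_REQUIRED_COLUMNS = (
    "treatment", "nightly_max_moon_lux", "night_index", "time_of_day", "foraging",
)


def _treatment_levels(data: pd.DataFrame) -> tuple[str, ...]:
    present = list(pd.unique(data["treatment"]))
    ordered = [t for t in TREATMENT_ORDER if t in present]
    extras = sorted(set(present) - set(ordered))
    return tuple(ordered + extras)


def _check_data(data: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    num = data[["nightly_max_moon_lux", "night_index"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        raise ValueError("non-finite covariates")
    if not data["foraging"].isin((0, 1)).all():
        raise ValueError("foraging must be binary 0/1")


def build_design(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Model matrix (with intercept) for a subset of the global terms.

    Treatment-coded: control is the reference ALAN level, "day" the
    reference time-of-day stratum.  Each term owns its columns, so a term
    can be dropped independently (as Type III testing requires).
    """
    _check_data(data)
    levels = _treatment_levels(data)
    moon = data["nightly_max_moon_lux"].to_numpy(dtype=float)
    night = data["night_index"].to_numpy(dtype=float)
    tod = (data["time_of_day"] == "night").to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}
    dummies = {
        lvl: (data["treatment"] == lvl).to_numpy(dtype=float) for lvl in levels[1:]
    }
    for term in GLOBAL_TERMS:  # fixed ordering
        if term not in terms:
            continue
        if term == "ALAN":
            for lvl, d in dummies.items():
                cols[f"ALAN[{lvl}]"] = d
        elif term == "Moonlight":
            cols["Moonlight"] = moon
        elif term == "Night":
            cols["Night"] = night
        elif term == "TimeOfDay":
            cols["TimeOfDay[night]"] = tod
        elif term == "ALAN:Moonlight":
            for lvl, d in dummies.items():
                cols[f"ALAN[{lvl}]:Moonlight"] = d * moon
        elif term == "ALAN:Night":
            for lvl, d in dummies.items():
                cols[f"ALAN[{lvl}]:Night"] = d * night
        elif term == "ALAN:TimeOfDay":
            for lvl, d in dummies.items():
                cols[f"ALAN[{lvl}]:TimeOfDay[night]"] = d * tod
    return pd.DataFrame(cols, index=data.index)


def _design_info(data: pd.DataFrame) -> dict:
    return {
        "treatment_levels": _treatment_levels(data),
        "moonlux_range": (
            float(data["nightly_max_moon_lux"].min()),
            float(data["nightly_max_moon_lux"].max()),
        ),
    }


# ---------------------------------------------------------------------------
# GLM

def fit_glm(data: pd.DataFrame, terms=GLOBAL_TERMS) -> FitResult:
    """Binomial GLM by IRLS maximum likelihood."""
    X = build_design(data, terms)
    y = data["foraging"].to_numpy(dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    converged = bool(getattr(res, "converged", True)) and np.all(
        np.isfinite(res.params)
    )
    return FitResult(
        terms=tuple(t for t in GLOBAL_TERMS if t in terms),
        method="glm",
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        loglik=float(res.llf),
        n_params=X.shape[1],
        converged=converged,
        nobs=len(y),
        design_info=_design_info(data),
    )


def _candidate_term_sets():
    sets = []
    for mains in itertools.chain.from_iterable(
        itertools.combinations(MAIN_TERMS, k) for k in range(len(MAIN_TERMS) + 1)
    ):
        allowed = [
            i for i in INTERACTIONS
            if all(part in mains for part in i.split(":"))
        ]
        for inters in itertools.chain.from_iterable(
            itertools.combinations(allowed, k) for k in range(len(allowed) + 1)
        ):
            sets.append(tuple(mains) + tuple(inters))
    return sets


def fit_global_and_select(
    data: pd.DataFrame, cum_weight: float = 0.99
) -> tuple[pd.DataFrame, ModelSpec]:
    """All-subsets AIC selection over the global fixed structure.

    Fits every marginality-respecting submodel (35 candidates including the
    intercept-only model) as a binomial GLM, ranks by AIC, and keeps the
    smallest top set of models whose Akaike weights accumulate to
    ``cum_weight``.  Returns the ranked table (columns terms, df, loglik,
    AIC, delta_AIC, weight, cum_weight, selected) and the best model's spec.
    """
    rows = []
    for terms in _candidate_term_sets():
        fit = fit_glm(data, terms)
        if not fit.converged:
            warnings.warn(f"model {terms or ('(Intercept)',)} did not converge; excluded")
            continue
        rows.append(
            {"terms": " + ".join(fit.terms) or "(Intercept)",
             "df": fit.n_params, "loglik": fit.loglik, "AIC": fit.aic,
             "_terms": fit.terms}
        )
    tab = pd.DataFrame(rows).sort_values("AIC", kind="mergesort").reset_index(drop=True)
    tab["delta_AIC"] = tab["AIC"] - tab["AIC"].iloc[0]
    rel = np.exp(-0.5 * tab["delta_AIC"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab["cum_weight"] = tab["weight"].cumsum()
    n_keep = int(np.searchsorted(tab["cum_weight"].to_numpy(), cum_weight) + 1)
    n_keep = min(n_keep, len(tab))
    tab["selected"] = np.arange(len(tab)) < n_keep
    best = ModelSpec(fixed_terms=tuple(tab["_terms"].iloc[0]), random=False)
    return tab.drop(columns="_terms"), best


def lrt(full: FitResult, reduced: FitResult) -> TermTest:
    """Likelihood-ratio test of nested fits on the same data."""
    if full.nobs != reduced.nobs:
        raise ValueError("fits are not on the same data")
    if not set(reduced.terms) <= set(full.terms) or reduced.n_params > full.n_params:
        raise ValueError("reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    chi = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi, df))
    return TermTest(term="full vs reduced", chi_sq=chi, df=df, p_value=p)


# ---------------------------------------------------------------------------
# GLMM: Laplace-approximate binomial mixed model, nested random intercepts

def _grouping(data: pd.DataFrame):
    if not {"tank_id", "snail_id"} <= set(data.columns):
        raise ValueError("GLMM requires tank_id and snail_id grouping columns")
    tanks, tank_idx = np.unique(data["tank_id"], return_inverse=True)
    snails, snail_idx = np.unique(data["snail_id"], return_inverse=True)
    n = len(data)
    q = len(tanks) + len(snails)
    Z = np.zeros((n, q))
    Z[np.arange(n), tank_idx] = 1.0
    Z[np.arange(n), len(tanks) + snail_idx] = 1.0
    return Z, len(tanks), len(snails)


def _pirls(y, J, pen_diag, theta0=None, tol=1e-9, maxiter=100):
    """Penalized IRLS: maximize sum(y*eta - log(1+exp(eta))) - 0.5 theta'P theta."""
    n, p = J.shape
    theta = np.zeros(p) if theta0 is None else theta0.copy()
    ok = False
    for _ in range(maxiter):
        eta = J @ theta
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = J.T @ (y - mu) - pen_diag * theta
        H = (J.T * w) @ J
        H[np.diag_indices_from(H)] += pen_diag
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # halving line search on the penalized objective
        def obj(t):
            e = J @ t
            return float(
                y @ e - np.logaddexp(0, e).sum() - 0.5 * (pen_diag * t * t).sum()
            )
        f0 = obj(theta)
        alpha = 1.0
        for _ in range(30):
            cand = theta + alpha * step
            if obj(cand) >= f0 - 1e-12:
                break
            alpha *= 0.5
        theta = theta + alpha * step
        if np.max(np.abs(grad)) < tol * max(1.0, np.abs(f0)):
            ok = True
            break
    return theta, ok


def _laplace_loglik(y, X, Z, q_tank, sigmas, theta0=None):
    """Profile Laplace log-likelihood at given (sigma_tank, sigma_snail)."""
    n, p = X.shape
    q = Z.shape[1]
    J = np.hstack([X, Z])
    var = np.concatenate([
        np.full(q_tank, sigmas[0] ** 2), np.full(q - q_tank, sigmas[1] ** 2)
    ])
    pen = np.concatenate([np.zeros(p), 1.0 / np.maximum(var, 1e-12)])
    theta, ok = _pirls(y, J, pen, theta0)
    eta = J @ theta
    mu = special.expit(eta)
    u = theta[p:]
    w = np.clip(mu * (1 - mu), 1e-10, None)
    Huu = (Z.T * w) @ Z
    Huu[np.diag_indices_from(Huu)] += pen[p:]
    sign, logdet_H = np.linalg.slogdet(Huu)
    ll_cond = float(y @ eta - np.logaddexp(0, eta).sum())
    ll = (
        ll_cond
        - 0.5 * float(np.sum(np.log(np.maximum(var, 1e-12))))
        - 0.5 * float(u * u @ (1.0 / np.maximum(var, 1e-12)))
        - 0.5 * logdet_H
    )
    return ll, theta, ok


def _fit_glmm_raw(data, terms, start_sigmas=(0.3, 0.3)):
    """GLMM fit for an arbitrary term set (marginality not enforced — Type
    III reduced models legitimately drop a main effect under its interaction)."""
    Xdf = build_design(data, terms)
    X = Xdf.to_numpy()
    y = data["foraging"].to_numpy(dtype=float)
    Z, q_tank, q_snail = _grouping(data)
    state = {"theta": None}

    def negloglik(log_sig):
        sig = np.exp(np.clip(log_sig, -12.0, 3.0))
        ll, theta, _ = _laplace_loglik(y, X, Z, q_tank, sig, state["theta"])
        state["theta"] = theta
        return -ll

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            negloglik, np.log(np.asarray(start_sigmas, dtype=float)),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
        )
    sig = np.exp(np.clip(res.x, -12.0, 3.0))
    ll, theta, inner_ok = _laplace_loglik(y, X, Z, q_tank, sig, state["theta"])
    p = X.shape[1]
    # conditional covariance of the fixed effects: beta block of the inverse
    # penalized joint Hessian (what glmer's vcov reports)
    J = np.hstack([X, Z])
    eta = J @ theta
    w = np.clip(special.expit(eta) * (1 - special.expit(eta)), 1e-10, None)
    var = np.concatenate([
        np.full(q_tank, sig[0] ** 2), np.full(q_snail, sig[1] ** 2)
    ])
    pen = np.concatenate([np.zeros(p), 1.0 / np.maximum(var, 1e-12)])
    H = (J.T * w) @ J
    H[np.diag_indices_from(H)] += pen
    cov_full = np.linalg.inv(H)
    return FitResult(
        terms=tuple(t for t in GLOBAL_TERMS if t in terms),
        method="glmm-laplace",
        params=pd.Series(theta[:p], index=Xdf.columns),
        cov=pd.DataFrame(cov_full[:p, :p], index=Xdf.columns, columns=Xdf.columns),
        loglik=float(ll),
        n_params=p + 2,
        converged=bool(res.success and inner_ok),
        nobs=len(y),
        variance_components={"sigma_tank": float(sig[0]), "sigma_snail": float(sig[1])},
        singular=bool(np.any(sig < 1e-3)),
        design_info=_design_info(data),
    )


def fit_glmm(
    data: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    start_sigmas: tuple[float, float] = (0.3, 0.3),
) -> FitResult:
    """Binomial GLMM with random intercepts for tank and snail-in-tank.

    Laplace-approximate ML: the fixed coefficients and random-effect modes
    are maximized jointly by penalized IRLS, and the two variance components
    by Nelder-Mead on the profiled Laplace log-likelihood — the same
    approximation glmer uses at its default settings.  A fit whose estimated
    standard deviations hit the lower boundary (< 1e-3) is returned with
    ``singular=True``; estimates are still reported.
    """
    if not spec.random:
        return fit_glm(data, spec.fixed_terms)
    return _fit_glmm_raw(data, spec.fixed_terms, start_sigmas)


# ---------------------------------------------------------------------------
# Type III term tests


def type3_tests(data: pd.DataFrame, spec: ModelSpec = ModelSpec()) -> list[TermTest]:
    """Type III likelihood-ratio tests: each term dropped singly.

    Every term of the spec — main effects in the presence of their
    interactions, interactions in the presence of their mains — is removed
    from the full model and the two fits compared by likelihood ratio.
    With treatment coding this reproduces the stepwise Type III ANOVA
    convention of mixed-model packages.
    """
    fit_full = (
        fit_glmm(data, spec) if spec.random else fit_glm(data, spec.fixed_terms)
    )
    out = []
    for term in spec.fixed_terms:
        kept = tuple(t for t in spec.fixed_terms if t != term)
        if spec.random:
            fit_red = _fit_glmm_raw(data, kept)
        else:
            fit_red = fit_glm(data, kept)
        df = fit_full.n_params - fit_red.n_params
        chi = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
        out.append(
            TermTest(term=term, chi_sq=chi, df=df, p_value=float(stats.chi2.sf(chi, df)))
        )
    return out


# ---------------------------------------------------------------------------
# estimated marginal trends and predictions

def moonlight_slopes(fit: FitResult):
    """Per-treatment moonlight slope (logit per lux) and pairwise contrasts.

    The slope of treatment t is the Moonlight coefficient plus t's
    interaction coefficient; standard errors come from the coefficient
    covariance.  All pairwise differences are returned with unadjusted
    two-sided normal p-values.
    """
    if "ALAN:Moonlight" not in fit.terms or "Moonlight" not in fit.terms:
        raise ValueError("fitted model lacks the ALAN:Moonlight interaction")
    levels = fit.design_info["treatment_levels"]
    names = list(fit.params.index)
    V = fit.cov.to_numpy()
    beta = fit.params.to_numpy()

    def contrast(level):
        c = np.zeros(len(names))
        c[names.index("Moonlight")] = 1.0
        key = f"ALAN[{level}]:Moonlight"
        if key in names:
            c[names.index(key)] = 1.0
        return c

    rows = []
    cvecs = {}
    for lvl in levels:
        c = contrast(lvl)
        cvecs[lvl] = c
        est = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        rows.append({"treatment": lvl, "slope": est, "se": se})
    slopes = pd.DataFrame(rows)
    pairs = []
    for a, b in itertools.combinations(levels, 2):
        d = cvecs[a] - cvecs[b]
        est = float(d @ beta)
        se = float(np.sqrt(d @ V @ d))
        z = est / se if se > 0 else 0.0
        pairs.append(
            SlopeComparison(
                pair=(a, b), difference=est, se=se, z=z,
                p_value=float(2 * stats.norm.sf(abs(z))),
            )
        )
    return slopes, pairs


def predict_intervals(
    fit: FitResult,
    newdata: pd.DataFrame,
    n_draws: int = 1000,
    level: float = 0.95,
    include_random: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation-based prediction intervals on the probability scale.

    Coefficient vectors are drawn from N(beta_hat, V); optionally a random
    intercept draw (tank + snail variance) is added.  The point prediction
    is the inverse-logit of the linear predictor at beta_hat.  Rows whose
    moonlight covariate lies outside the fitted range are flagged
    ``extrapolated`` rather than rejected.
    """
    X = build_design(
        newdata.assign(foraging=0) if "foraging" not in newdata.columns else newdata,
        fit.terms,
    )
    missing = [c for c in fit.params.index if c not in X.columns]
    for c in missing:  # levels absent from newdata
        X[c] = 0.0
    X = X[list(fit.params.index)].to_numpy()
    rng = np.random.default_rng(seed)
    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    # guard: V may be exactly zero (degenerate); multivariate_normal handles psd
    draws = rng.multivariate_normal(beta, V, size=n_draws, method="svd")
    eta = X @ draws.T  # (n, n_draws)
    if include_random and fit.variance_components:
        tot = np.sqrt(
            fit.variance_components.get("sigma_tank", 0.0) ** 2
            + fit.variance_components.get("sigma_snail", 0.0) ** 2
        )
        eta = eta + rng.standard_normal(eta.shape) * tot
    probs = special.expit(eta)
    lo, hi = np.percentile(
        probs, [100 * (1 - level) / 2, 100 * (1 + level) / 2], axis=1
    )
    point = special.expit(X @ beta)
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    mlo, mhi = fit.design_info.get("moonlux_range", (-np.inf, np.inf))
    moon = newdata["nightly_max_moon_lux"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "predicted": point,
            "lower": lo,
            "upper": hi,
            "extrapolated": (moon < mlo) | (moon > mhi),
        },
        index=newdata.index,
    )
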