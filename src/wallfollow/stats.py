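"""Group comparisons and count regression for the behavioural indicators.

Covers the study-style analysis chain: Kruskal-Wallis rank tests with tie
correction, Dunnett's T3 post-hoc pairwise comparisons (Welch statistics
with a studentized-maximum-modulus family correction), negative-binomial
regression for the overdispersed SL-count response, and AICc-based full
model averaging over candidate predictor subsets.

The regression is a fixed-effects negative-binomial GLM on per-trial rows
(optionally on per-individual aggregates); repeated-measures random-effect
structure is deliberately out of scope.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.discrete.discrete_model import NegativeBinomial

__all__ = [
    "KruskalResult",
    "PairwiseComparison",
    "NBGlmFit",
    "ModelAverageResult",
    "kruskal_wallis",
    "dunnett_t3",
    "fit_negative_binomial_glm",
    "model_average_full",
    "aicc",
]


@dataclass(frozen=True)
class KruskalResult:
    H: float
    df: int
    p_value: float
    tie_correction: float


def kruskal_wallis(groups: list[np.ndarray]) -> KruskalResult:
    """Kruskal-Wallis H with mid-rank tie correction, chi-square p-value.

    H = [12 / (N(N+1))] * sum R_j^2 / n_j - 3(N+1), divided by the tie
    factor 1 - sum(t^3 - t) / (N^3 - N); p is the upper tail of
    chi-square(k - 1).  All-identical data yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    k = len(groups)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - float(((counts ** 3 - counts).sum()) / (N ** 3 - N))
    if tie == 0.0:  # every observation identical
        return KruskalResult(0.0, k - 1, 1.0, 1.0)
    H = H / tie
    H = max(0.0, H)
    return KruskalResult(float(H), k - 1, float(sps.chi2.sf(H, k - 1)), tie)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float  # Welch-type t
    df: float         # Welch-Satterthwaite
    p_unadjusted: float
    p_adjusted: float


def dunnett_t3(groups: list[np.ndarray],
               labels: list[str] | None = None) -> list[PairwiseComparison]:
    """Dunnett's T3: all pairwise Welch comparisons under unequal variances.

    Each pair gets a Welch t statistic with Satterthwaite df; the family
    correction treats the m = k(k-1)/2 comparisons through the studentized
    maximum modulus: p_adj = 1 - (2 F_t(|t|; df) - 1)^m, the SMM tail for
    independent t variates (a Sidak-style bound for the dependent case).
    With exactly two groups this is the plain Welch test.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]
    m = k * (k - 1) // 2
    out: list[PairwiseComparison] = []
    for (i, a), (j, b) in itertools.combinations(enumerate(groups), 2):
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        denom = va + vb
        diff = a.mean() - b.mean()
        if denom == 0.0:
            stat = 0.0 if diff == 0.0 else math_inf_sign(diff)
            df = float(len(a) + len(b) - 2)
        else:
            stat = diff / np.sqrt(denom)
            df = denom ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        p_un = float(2.0 * sps.t.sf(abs(stat), df)) if np.isfinite(stat) else 0.0
        p_adj = float(1.0 - (1.0 - p_un) ** m)
        out.append(PairwiseComparison(labels[i], labels[j], float(stat),
                                      float(df), p_un, min(1.0, p_adj)))
    return out


def math_inf_sign(x: float) -> float:
    return float(np.inf) if x > 0 else float(-np.inf)


@dataclass(frozen=True)
class NBGlmFit:
    coefficients: pd.DataFrame  # estimate, se per term
    dispersion: float           # NB size parameter (1 / alpha)
    alpha: float
    log_likelihood: float
    aicc: float
    n: int
    k_params: int               # regression terms + dispersion


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_negative_binomial_glm(response, predictors: pd.DataFrame | None = None,
                              offset=None, add_intercept: bool = True,
                              maxiter: int = 200) -> NBGlmFit:
    """ML negative-binomial (NB2) regression with log link.

    ``response`` must be non-negative integers (the SL-normalised distance
    response is rounded to the nearest count upstream); predictors are
    expected standardized.  Coefficients and the dispersion parameter are
    jointly maximised.  Non-convergence raises with the optimiser trace.
    """
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-9):
        raise ValueError("response must be non-negative integers")
    if np.all(y == 0):
        raise ValueError("all-zero response: NB mean undefined on log scale")
    names: list[str] = []
    if predictors is None or predictors.shape[1] == 0:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    else:
        X = predictors.to_numpy(dtype=float)
        names = list(predictors.columns)
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["intercept"] + names
    model = NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=maxiter, method="bfgs")
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, maxiter=maxiter * 4, method="nm",
                            start_params=res.params)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            f"NB fit did not converge: {res.mle_retvals}")
    params = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    alpha = float(params[-1])
    alpha = max(alpha, 1e-12)
    coef = pd.DataFrame({"estimate": params[:-1], "se": ses[:-1]}, index=names)
    n = len(y)
    k = len(params)  # regression terms + alpha
    ll = float(res.llf)
    return NBGlmFit(coefficients=coef, dispersion=1.0 / alpha, alpha=alpha,
                    log_likelihood=ll, aicc=aicc(ll, k, n), n=n, k_params=k)


@dataclass(frozen=True)
class ModelAverageResult:
    candidates: pd.DataFrame            # predictors, k, aicc, delta, weight, retained
    averaged_coefficients: pd.DataFrame  # estimate, adjusted_se, ci_lo, ci_hi, important
    importance: pd.Series


def model_average_full(response, predictors: pd.DataFrame,
                       candidates: list[tuple[str, ...]] | None = None,
                       delta_threshold: float = 2.0,
                       fitter=None, ci_z: float = 1.959963984540054
                       ) -> ModelAverageResult:
    """AICc full model averaging over candidate predictor subsets.

    Each candidate (a tuple of predictor names; default all subsets) is fit
    with ``fitter`` (default the NB regression); candidates whose sample
    size cannot support AICc are dropped with a warning.  Models within
    ``delta_threshold`` of the best AICc are retained; Akaike weights are
    renormalised over that set.  Full averaging sets a coefficient to zero
    (with zero variance) in models that omit it; the adjusted SE folds in
    between-model spread: SE = sum_i w_i sqrt(se_i^2 + (b_i - b_bar)^2).
    A parameter is flagged important when its 95% CI excludes zero.
    """
    if fitter is None:
        fitter = fit_negative_binomial_glm
    all_names = list(predictors.columns)
    if candidates is None:
        candidates = [tuple(c) for r in range(len(all_names) + 1)
                      for c in itertools.combinations(all_names, r)]
    if not candidates:
        raise ValueError("need at least one candidate model")
    rows = []
    fits = []
    for cand in candidates:
        sub = predictors[list(cand)]
        try:
            fit = fitter(response, sub if len(cand) else None)
        except ValueError as exc:
            warnings.warn(f"dropping candidate {cand}: {exc}", stacklevel=2)
            continue
        rows.append({"predictors": cand, "k": fit.k_params, "aicc": fit.aicc})
        fits.append(fit)
    if not fits:
        raise ValueError("no candidate model could be fit")
    table = pd.DataFrame(rows)
    table["delta"] = table["aicc"] - table["aicc"].min()
    table["retained"] = table["delta"] <= delta_threshold
    w = np.where(table["retained"], np.exp(-table["delta"] / 2.0), 0.0)
    table["weight"] = w / w.sum()
    terms = ["intercept"] + all_names
    est = pd.Series(0.0, index=terms)
    for fit, wt in zip(fits, table["weight"]):
        if wt == 0.0:
            continue
        est = est.add(wt * fit.coefficients["estimate"].reindex(terms,
                                                                fill_value=0.0))
    se = pd.Series(0.0, index=terms)
    for fit, wt in zip(fits, table["weight"]):
        if wt == 0.0:
            continue
        b = fit.coefficients["estimate"].reindex(terms, fill_value=0.0)
        v = (fit.coefficients["se"].reindex(terms, fill_value=0.0)) ** 2
        se = se.add(wt * np.sqrt(v + (b - est) ** 2))
    avg = pd.DataFrame({"estimate": est, "adjusted_se": se,
                        "ci_lo": est - ci_z * se, "ci_hi": est + ci_z * se})
    avg["important"] = (avg["ci_lo"] > 0) | (avg["ci_hi"] < 0)
    importance = pd.Series(
        {name: float(table.loc[[name in c for c in table["predictors"]],
                               "weight"].sum())
         for name in all_names})
    return ModelAverageResult(candidates=table, averaged_coefficients=avg,
                              importance=importance)
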