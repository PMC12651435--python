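"""Prognostic statistics layer.

Univariate and forward-selected binary logistic models with Wald tests,
Bonferroni flags at 15 covariates, chained-equations multiple imputation
(conditioning always on the complete WFNS and RMS scores), leave-one-out AUC
with per-fold variable selection, and the descriptive tests used alongside
(Pearson chi-square, Mann-Whitney, Spearman, detectable-effect-size power).

Forward selection enters variables by score (Rao) tests against the current
model and removes them by Wald tests, mirroring the convention of the major
clinical-statistics packages; thresholds default to p_in = 0.05 and
p_out = 0.10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

_Z95 = 1.96  # two-sided 95% Wald quantile as conventionally reported


@dataclass
class LogisticResult:
    term: str
    beta: float
    se: float
    wald_p: float
    converged: bool = True

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + _Z95 * self.se))


@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n: int = 0
    probabilities: np.ndarray | None = None


# -- logistic fitting --------------------------------------------------------

def _design(table: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    X = table[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(table)), X])


def fit_logistic(table: pd.DataFrame, predictors: list[str], outcome: str
                 ) -> dict[str, LogisticResult]:
    """Maximum-likelihood binary logistic fit with per-coefficient Wald tests.

    Quasi-complete separation does not raise: the affected fit is returned
    with ``converged=False`` (the clinical-table analogue of a "did not
    converge" entry).  Used columns must be complete.
    """
    cols = list(predictors) + [outcome]
    sub = table[cols]
    if sub.isna().any().any():
        raise ValueError("missing values in used columns; impute first")
    y = sub[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both events and non-events")
    X = _design(sub, predictors)
    names = ["intercept"] + list(predictors)
    converged = True
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, warn_convergence=False)
        beta, se = fit.params, fit.bse
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # statsmodels raises on perfect separation
        beta, se, converged = _irls_logit_fallback(X, y)
    if converged and (np.any(np.abs(beta) > 15) or np.any(se > 50) or np.any(~np.isfinite(se))):
        converged = False  # quasi-separation: Wald statistics are meaningless
    se = np.where(np.isfinite(se), se, np.inf)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return {name: LogisticResult(name, float(b), float(s), float(pv), converged)
            for name, b, s, pv in zip(names, beta, se, p)}


def _irls_logit_fallback(X: np.ndarray, y: np.ndarray,
                         max_iter: int = 25) -> tuple[np.ndarray, np.ndarray, bool]:
    """Capped Newton iterations for separated data: returns the last iterate."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        H = (X * W[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.maximum(np.diag(cov), 0)), False


def predict_probability(result: dict[str, LogisticResult], row: pd.Series,
                        predictors: list[str]) -> float:
    eta = result["intercept"].beta
    for name in predictors:
        eta += result[name].beta * float(row[name])
    return float(1 / (1 + np.exp(-np.clip(eta, -30, 30))))


# -- multiplicity and selection ---------------------------------------------

def bonferroni_flags(p_values, m: int = 15, alpha: float = 0.05) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected level ``alpha / m``.

    The cutoff is inclusive: at m = 15, p = 0.0033 (to the printed precision)
    still flags.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.asarray(p_values, dtype=float) <= alpha / m


def _score_tests(table: pd.DataFrame, current: list[str], candidates: list[str],
                 outcome: str) -> np.ndarray:
    """Rao score-test p-values for adding each candidate to the current model.

    The null model is fitted once; each candidate's score statistic uses the
    null fitted probabilities, so the sweep over a 15-variable panel costs a
    single logistic fit plus linear algebra.
    """
    y = table[outcome].to_numpy(dtype=float)
    X0 = _design(table, current)
    fit = _quick_logit(X0, y)
    p = fit["p"]
    W = p * (1 - p)
    C = table[list(candidates)].to_numpy(dtype=float)      # (n, c)
    U = C.T @ (y - p)                                      # (c,)
    XtWX = (X0 * W[:, None]).T @ X0 + 1e-10 * np.eye(X0.shape[1])
    XtWC = (X0 * W[:, None]).T @ C                         # (k, c)
    V = np.einsum("nc,nc->c", C * W[:, None], C) \
        - np.einsum("kc,kc->c", XtWC, np.linalg.solve(XtWX, XtWC))
    pvals = np.ones(len(candidates))
    ok = V > 0
    pvals[ok] = stats.chi2.sf(U[ok] ** 2 / V[ok], df=1)
    return pvals


def score_test_add(table: pd.DataFrame, current: list[str], candidate: str,
                   outcome: str) -> float:
    """Score-test p-value for adding one predictor to the current model."""
    return float(_score_tests(table, current, [candidate], outcome)[0])


def _quick_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> dict:
    """Plain Newton logistic fit used inside selection loops (no inference frills)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1 / (1 + np.exp(-eta))
        W = p * (1 - p)
        H = (X * W[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1 / (1 + np.exp(-eta))
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X + 1e-10 * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return {"beta": beta, "se": se, "p": p}


def forward_select(table: pd.DataFrame, predictors: list[str], outcome: str,
                   p_in: float = 0.05, p_out: float = 0.10) -> list[str]:
    """Stepwise forward selection with backward pruning.

    Repeatedly adds the candidate with the smallest score-test p below
    ``p_in`` (ties break by predictor order), then removes any included
    predictor whose Wald p exceeds ``p_out``, until a fixed point.  May return
    an empty set.  Requires complete data (run after imputation).
    """
    selected: list[str] = []
    y = table[outcome].to_numpy(dtype=float)
    seen: set[tuple[str, ...]] = set()
    while True:
        state = tuple(selected)
        if state in seen:
            break  # stepwise cycle (can occur under separation): stop
        seen.add(state)
        candidates = [v for v in predictors if v not in selected]
        if not candidates:
            break
        pvals = _score_tests(table, selected, candidates, outcome)
        best = int(np.argmin(pvals))
        if not pvals[best] < p_in:
            break
        selected.append(candidates[best])
        # backward sweep by Wald tests
        while selected:
            fit = _quick_logit(_design(table, selected), y)
            if np.any(np.abs(fit["beta"]) > 15):
                break  # separation: Wald p-values are meaningless, keep the model
            with np.errstate(divide="ignore", invalid="ignore"):
                z = fit["beta"][1:] / fit["se"][1:]
            wald_p = 2 * stats.norm.sf(np.abs(z))
            worst = int(np.argmax(wald_p))
            if wald_p[worst] > p_out:
                selected.pop(worst)
            else:
                break
    return selected


# -- multiple imputation -----------------------------------------------------

def multiple_impute(table: pd.DataFrame, n_imputations: int = 500, seed: int = 0,
                    exclude_from_models: tuple[str, ...] = (),
                    skip_columns: tuple[str, ...] = (),
                    n_sweeps: int = 5) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation.

    Each incomplete column is imputed from a regression on all other columns
    (minus ``exclude_from_models``): normal linear draws with parameter
    uncertainty for continuous columns, Bernoulli draws from a logistic fit
    for binary ones.  WFNS and RMS, when present, must be complete — they are
    the missing-at-random conditioning scores and enter every model.  With no
    missing values the input is returned unchanged (``n_imputations`` copies).
    """
    for v in ("WFNS", "RMS"):
        if v in table.columns and table[v].isna().any():
            raise ValueError(f"{v} must be complete: it anchors the MAR assumption")
    numeric = list(table.select_dtypes(include=[np.number, bool]).columns)
    incomplete = [c for c in numeric
                  if c not in skip_columns and table[c].isna().any()]
    for c in incomplete:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is 100% missing; cannot impute")
    if not incomplete:
        return [table.copy() for _ in range(n_imputations)]

    # numeric working matrix; column bookkeeping done once for all imputations
    M0 = table[numeric].to_numpy(dtype=float, copy=True)
    col_idx = {c: j for j, c in enumerate(numeric)}
    plan = []
    for c in incomplete:
        j = col_idx[c]
        miss = np.isnan(M0[:, j])
        others = [col_idx[o] for o in numeric
                  if o != c and o not in exclude_from_models and o not in skip_columns]
        binary = set(pd.unique(table[c].dropna())) <= {0, 1, 0.0, 1.0, True, False}
        plan.append((j, miss, np.array(others, int), binary))
    fill = np.nanmean(M0, axis=0)

    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_imputations)]
    out = []
    for rng in rngs:
        M = M0.copy()
        for j, miss, _, _ in plan:
            M[miss, j] = fill[j]
        for _ in range(n_sweeps):
            for j, miss, others, binary in plan:
                X = np.column_stack([np.ones(M.shape[0]), M[:, others]])
                X_obs, X_mis = X[~miss], X[miss]
                y_obs = M0[~miss, j]
                if binary:
                    fit = _quick_logit(X_obs, y_obs)
                    cov = np.diag(fit["se"] ** 2) + 1e-12 * np.eye(X.shape[1])
                    beta = fit["beta"] + np.linalg.cholesky(cov) @ rng.standard_normal(X.shape[1])
                    p = 1 / (1 + np.exp(-np.clip(X_mis @ beta, -30, 30)))
                    M[miss, j] = (rng.random(int(miss.sum())) < p).astype(float)
                else:
                    XtX = X_obs.T @ X_obs + 1e-10 * np.eye(X.shape[1])
                    beta_hat = np.linalg.solve(XtX, X_obs.T @ y_obs)
                    resid = y_obs - X_obs @ beta_hat
                    dof = max(X_obs.shape[0] - X.shape[1], 1)
                    sigma2 = float(resid @ resid) / dof
                    cov = sigma2 * np.linalg.inv(XtX) + 1e-12 * np.eye(X.shape[1])
                    beta = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(X.shape[1])
                    M[miss, j] = X_mis @ beta + rng.normal(0, np.sqrt(sigma2),
                                                           int(miss.sum()))
        df = table.copy()
        df[numeric] = M
        out.append(df)
    return out


def pool_rubin(estimates: np.ndarray, variances: np.ndarray) -> tuple[float, float]:
    """Rubin's rules: pooled estimate and total variance across imputations."""
    estimates = np.asarray(estimates, float)
    variances = np.asarray(variances, float)
    m = estimates.size
    qbar = float(estimates.mean())
    ubar = float(variances.mean())
    b = float(estimates.var(ddof=1)) if m > 1 else 0.0
    return qbar, ubar + (1 + 1 / m) * b


# -- ROC / AUC ---------------------------------------------------------------

def _auc_mannwhitney(y: np.ndarray, scores: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both outcome classes")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(y: np.ndarray, scores: np.ndarray) -> float:
    """DeLong variance of a single AUC via placement values."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    n1, n0 = pos.size, neg.size
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n0 for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / n1 for q in neg])
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return float(s10 / n1 + s01 / n0)


def roc_result(y: np.ndarray, scores: np.ndarray,
               ci_method: str = "delong") -> ROCResult:
    """AUC with a 95% CI by the DeLong (default) or Hanley-McNeil variance."""
    y = np.asarray(y, float)
    scores = np.asarray(scores, float)
    auc = _auc_mannwhitney(y, scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    if ci_method == "delong":
        var = _delong_variance(y, scores)
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
               + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    else:
        raise ValueError(f"unknown AUC CI method {ci_method!r}")
    half = _Z95 * np.sqrt(max(var, 0.0))
    return ROCResult(auc=auc, ci_low=max(0.0, auc - half),
                     ci_high=min(1.0, auc + half), n=y.size,
                     probabilities=scores)


def loo_auc(table: pd.DataFrame, predictors: list[str], outcome: str,
            n_imputations: int = 20, seed: int = 0, p_in: float = 0.05,
            p_out: float = 0.10, ci_method: str = "delong") -> ROCResult:
    """Leave-one-out AUC with per-fold imputation and variable selection.

    For each patient: the patient is held out; the fold (training rows plus
    the held-out row's predictors, never its outcome) is imputed
    ``n_imputations`` times; forward selection and a logistic fit run per
    completed table; the held-out probability is the mean across imputations
    (an empty selection yields the intercept-only event rate).  The AUC is
    computed over the stored probabilities with a 95% CI from ``ci_method``.
    Folds that would lose all events or all non-events are skipped with a
    warning.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 patients for leave-one-out")
    y_all = table[outcome].to_numpy(dtype=float)
    if len(np.unique(y_all[~np.isnan(y_all)])) < 2:
        raise ValueError("outcome must contain both classes")
    seeds = np.random.SeedSequence(seed).spawn(len(table))
    probs = np.full(len(table), np.nan)
    for i, (idx, fold_seed) in enumerate(zip(table.index, seeds)):
        train = table.drop(index=idx)
        y_train = train[outcome].to_numpy(dtype=float)
        if len(np.unique(y_train)) < 2:
            logger.warning("fold %s lost one outcome class; skipped", idx)
            continue
        fold = table.copy()
        fold.loc[idx, outcome] = np.nan  # held-out outcome never informs imputation
        completed = multiple_impute(fold, n_imputations,
                                    seed=int(fold_seed.generate_state(1)[0] % 2**31),
                                    exclude_from_models=(outcome,),
                                    skip_columns=(outcome,))
        fold_probs = []
        for comp in completed:
            comp_train = comp.drop(index=idx)
            comp_train[outcome] = y_train
            chosen = forward_select(comp_train, predictors, outcome, p_in, p_out)
            fit = _quick_logit(_design(comp_train, chosen),
                               comp_train[outcome].to_numpy(float))
            x_test = np.concatenate([[1.0], comp.loc[idx, chosen].to_numpy(float)])
            eta = float(np.clip(x_test @ fit["beta"], -30, 30))
            fold_probs.append(1 / (1 + np.exp(-eta)))
        probs[i] = float(np.mean(fold_probs))
    keep = ~np.isnan(probs)
    return roc_result(y_all[keep], probs[keep], ci_method)


def report_percent(numerator: float, denominator: float) -> float:
    """Percentage to one decimal, round-half-up (clinical-table convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# -- descriptive tests -------------------------------------------------------

def pearson_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table without continuity correction."""
    tbl = np.array([[a, b], [c, d]], dtype=float)
    if np.any(tbl < 0) or tbl.sum() == 0:
        raise ValueError("counts must be >= 0 with a positive total")
    if np.any(tbl.sum(axis=0) == 0) or np.any(tbl.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
    return float(chi2), float(p)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, otherwise
    the tie-corrected normal approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling; two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def detectable_effect_size_ttest(n1: int, n2: int, alpha: float = 0.05,
                                 power: float = 0.80) -> float:
    """Smallest Cohen's d detectable by a two-sided two-sample t-test.

    Power uses the exact noncentral-t distribution with noncentrality
    ``d * sqrt(n1 n2 / (n1 + n2))`` and ``n1 + n2 - 2`` degrees of freedom;
    the threshold d is found by bisection.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    df = n1 + n2 - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)

    def achieved_power(d: float) -> float:
        ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
        p = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
        return 1.0 if np.isnan(p) else p  # nct underflows at very large ncp

    lo, hi = 1e-6, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if achieved_power(mid) >= power:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-10:
            break
    return float(hi)
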