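"""Differential item functioning by ordinal logistic regression.

For each item three nested proportional-odds models are fit on the item's
ordinal response: M1 (theta only), M2 (theta + group), M3 (theta + group +
theta x group). Overall DIF is the likelihood-ratio test of M1 vs M3;
uniform and non-uniform components are M1 vs M2 and M2 vs M3. Magnitude
is McFadden's pseudo-R-squared change between M1 and M3, with the 0.035
"salient" cutoff conventional in this literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from premcat.databank import ResponseMatrix
from premcat.calibration import ThetaEstimate

logger = logging.getLogger(__name__)


@dataclass
class DifResult:
    item_id: str
    grouping: str
    chi2_overall: float
    df_overall: int
    p_overall: float
    chi2_uniform: float
    df_uniform: int
    p_uniform: float
    chi2_nonuniform: float
    df_nonuniform: int
    p_nonuniform: float
    delta_r2: float
    flag: str  # "none" | "negligible" | "salient" | "untestable"
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "item_id", "grouping", "chi2_overall", "df_overall", "p_overall",
            "chi2_uniform", "df_uniform", "p_uniform", "chi2_nonuniform",
            "df_nonuniform", "p_nonuniform", "delta_r2", "flag", "note")}


# ---------------------------------------------------------------------------
# Proportional-odds (cumulative logit) maximum likelihood
# ---------------------------------------------------------------------------

def _polr_loglik_grad(params, X, y, m):
    """Log-likelihood and gradient of the proportional-odds model.

    params = (alpha_1..alpha_m, beta); P(y<=k) = sigmoid(alpha_{k+1} - X beta).
    """
    alpha = params[:m]
    beta = params[m:]
    eta = X @ beta if beta.size else np.zeros(len(y))
    lo = np.where(y > 0, alpha[np.clip(y - 1, 0, m - 1)] - eta, -np.inf)
    hi = np.where(y < m, alpha[np.clip(y, 0, m - 1)] - eta, np.inf)
    Flo = _sigmoid(lo)
    Fhi = _sigmoid(hi)
    p = np.clip(Fhi - Flo, 1e-300, None)
    ll = float(np.log(p).sum())

    dlo = np.where(np.isfinite(lo), Flo * (1 - Flo), 0.0)
    dhi = np.where(np.isfinite(hi), Fhi * (1 - Fhi), 0.0)
    grad = np.zeros_like(params)
    # cutpoint derivatives
    for k in range(m):
        contrib = np.where(y == k, dhi, 0.0) - np.where(y == k + 1, dlo, 0.0)
        grad[k] = float((contrib / p).sum())
    if beta.size:
        g_eta = (dlo - dhi) / p  # d ll / d eta
        grad[m:] = X.T @ g_eta
    return ll, grad


def _sigmoid(x):
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_proportional_odds(X, y, max_iter: int = 200, tol: float = 1e-9):
    """Fit a cumulative-logit proportional-odds model by Newton-Raphson
    with step-halving (Hessian from finite differences of the analytic
    gradient). ``y`` must hold contiguous codes 0..m.

    Returns (params, log-likelihood, converged flag).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    m = int(y.max())
    if m < 1:
        raise ValueError("response is constant")
    # start: marginal cumulative logits, zero slopes
    props = np.array([(y <= k).mean() for k in range(m)])
    props = np.clip(props, 1e-3, 1 - 1e-3)
    alpha0 = np.log(props / (1 - props))
    alpha0 = np.maximum.accumulate(alpha0 + 1e-6 * np.arange(m))
    params = np.concatenate([alpha0, np.zeros(X.shape[1])])

    ll, grad = _polr_loglik_grad(params, X, y, m)
    for _ in range(max_iter):
        # numerical Hessian from analytic gradients
        npar = len(params)
        H = np.empty((npar, npar))
        eps = 1e-5
        for j in range(npar):
            pj = params.copy()
            pj[j] += eps
            _, gj = _polr_loglik_grad(pj, X, y, m)
            H[:, j] = (gj - grad) / eps
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        step = -step  # ascend
        if not np.all(np.isfinite(step)):
            return params, ll, False
        # step-halving: require an LL improvement and ordered cutpoints
        improved = False
        for _half in range(30):
            cand = params + step
            if np.all(np.diff(cand[:m]) > 0) or m == 1:
                ll_new, grad_new = _polr_loglik_grad(cand, X, y, m)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    improved = True
                    break
            step *= 0.5
        if not improved:
            return params, ll, False
        delta = float(np.max(np.abs(cand - params)))
        params, ll, grad = cand, ll_new, grad_new
        if delta < 1e-8 or np.max(np.abs(grad)) < tol * (1 + abs(ll)):
            return params, ll, True
    return params, ll, False


# ---------------------------------------------------------------------------
# DIF analysis
# ---------------------------------------------------------------------------

def _group_indicators(groups):
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("grouping has a single level")
    cols = np.column_stack([(np.asarray(groups) == lv).astype(float)
                            for lv in levels[1:]])
    return cols, levels


def dif_olr(data: ResponseMatrix, grouping: str, thetas,
            alpha: float = 0.01, r2_threshold: float = 0.035,
            min_group_n: int = 25) -> list:
    """Ordinal-logistic-regression DIF screen for one grouping covariate.

    Fits the three nested models per item and flags overall DIF at
    ``p < alpha`` (LRT M1 vs M3); significant items are "negligible" when
    McFadden's delta R-squared (M1 to M3, against the intercept-only null)
    stays below ``r2_threshold`` and "salient" otherwise. Non-converged
    fits are reported as "untestable", never raised.
    """
    if grouping not in data.covariates.columns:
        raise ValueError(f"unknown grouping covariate {grouping!r}")
    th = np.array([t.theta if isinstance(t, ThetaEstimate) else float(t)
                   for t in thetas])
    groups_all = data.covariates[grouping].astype(str).to_numpy()
    g_dummy_all, levels = _group_indicators(groups_all)
    for lv in levels:
        n_lv = int((groups_all == lv).sum())
        if n_lv < min_group_n:
            logger.warning("grouping %s level %r has only %d respondents",
                           grouping, lv, n_lv)
    results = []
    for j, iid in enumerate(data.item_ids):
        col = data.values[:, j]
        obs = ~np.isnan(col)
        y = col[obs].astype(int)
        # re-index to contiguous codes (categories may be unobserved)
        uniq = np.unique(y)
        y = np.searchsorted(uniq, y)
        if y.max() < 1:
            results.append(_untestable(iid, grouping, "constant item"))
            continue
        t = th[obs][:, None]
        g = g_dummy_all[obs]
        X1 = t
        X2 = np.hstack([t, g])
        X3 = np.hstack([t, g, t * g])
        try:
            _, ll0, c0 = fit_proportional_odds(np.empty((len(y), 0)), y)
            _, ll1, c1 = fit_proportional_odds(X1, y)
            _, ll2, c2 = fit_proportional_odds(X2, y)
            _, ll3, c3 = fit_proportional_odds(X3, y)
        except (ValueError, FloatingPointError) as exc:
            results.append(_untestable(iid, grouping, str(exc)))
            continue
        if not (c0 and c1 and c2 and c3):
            results.append(_untestable(iid, grouping, "non-convergence"))
            continue
        if not (ll1 <= ll2 + 1e-6 and ll2 <= ll3 + 1e-6):
            results.append(_untestable(iid, grouping, "nesting violated (numerical)"))
            continue
        ngrp = g.shape[1]
        chi_o = max(0.0, 2.0 * (ll3 - ll1))
        chi_u = max(0.0, 2.0 * (ll2 - ll1))
        chi_n = max(0.0, 2.0 * (ll3 - ll2))
        df_u = df_n = ngrp
        df_o = 2 * ngrp
        p_o = float(chi2.sf(chi_o, df_o))
        p_u = float(chi2.sf(chi_u, df_u))
        p_n = float(chi2.sf(chi_n, df_n))
        d_r2 = max(-1e-10, (ll3 - ll1) / (-ll0)) if ll0 != 0 else 0.0
        if p_o < alpha:
            flag = "negligible" if d_r2 < r2_threshold else "salient"
        else:
            flag = "none"
        results.append(DifResult(
            item_id=iid, grouping=grouping,
            chi2_overall=chi_o, df_overall=df_o, p_overall=p_o,
            chi2_uniform=chi_u, df_uniform=df_u, p_uniform=p_u,
            chi2_nonuniform=chi_n, df_nonuniform=df_n, p_nonuniform=p_n,
            delta_r2=float(d_r2), flag=flag))
    return results


def _untestable(iid, grouping, note):
    nan = float("nan")
    return DifResult(item_id=iid, grouping=grouping,
                     chi2_overall=nan, df_overall=0, p_overall=nan,
                     chi2_uniform=nan, df_uniform=0, p_uniform=nan,
                     chi2_nonuniform=nan, df_nonuniform=0, p_nonuniform=nan,
                     delta_r2=nan, flag="untestable", note=note)


def dif_summary(results_by_grouping: dict) -> dict:
    """Tabulate DIF flags per grouping and overall.

    ``results_by_grouping`` maps grouping name -> list of DifResult.
    """
    per_grouping = {}
    total_tests = 0
    total_flagged = 0
    for grouping, results in results_by_grouping.items():
        flagged = [r for r in results if r.flag in ("negligible", "salient")]
        per_grouping[grouping] = {
            "n_tests": len(results),
            "n_flagged": len(flagged),
            "n_salient": sum(1 for r in results if r.flag == "salient"),
            "n_untestable": sum(1 for r in results if r.flag == "untestable"),
            "flagged_items": [r.item_id for r in flagged],
        }
        total_tests += len(results)
        total_flagged += len(flagged)
    return {
        "per_grouping": per_grouping,
        "n_tests_total": total_tests,
        "n_flagged_total": total_flagged,
        "results": [r.to_dict() for rs in results_by_grouping.values() for r in rs],
    }
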