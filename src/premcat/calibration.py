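"""GPCM/PCM calibration, EAP scoring, item fit and information curves.

The generalized partial credit model gives category probabilities

    P_k(theta) = exp(sum_{v<=k} a (theta - b_v)) / sum_c exp(sum_{v<=c} a (theta - b_v))

with the empty sum equal to 0. Items are calibrated by marginal maximum
likelihood with an EM algorithm over a fixed quadrature grid carrying a
standard-normal prior; the partial credit model (PCM) is the same model
with a single common discrimination estimated for all items. Latent
scores are Bayesian expected a posteriori (EAP) means on the same grid,
reported with the posterior SD as standard error and on a 0-100 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from premcat.databank import GpcmItem, ItemBank, ResponseMatrix, ScoreTransform

logger = logging.getLogger(__name__)

A_MAX = 10.0  # discriminations diverging past this are clamped and flagged


@dataclass(frozen=True)
class QuadratureGrid:
    """Quadrature lattice with normalized N(0,1) prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    @classmethod
    def default(cls, n_nodes: int = 61, lo: float = -6.0, hi: float = 6.0) -> "QuadratureGrid":
        nodes = np.linspace(lo, hi, n_nodes)
        w = norm.pdf(nodes)
        return cls(nodes=nodes, weights=w / w.sum())


@dataclass
class FitSummary:
    """Marginal-likelihood fit of a calibrated model."""

    log_likelihood: float
    n_params: int
    n_respondents: int
    converged: bool
    n_cycles: int
    flagged_items: list = field(default_factory=list)
    lrt: dict = None  # {"chi2":, "df":, "p":} vs a nested model, if computed

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(self.n_respondents)

    def to_dict(self) -> dict:
        d = {
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "n_respondents": self.n_respondents,
            "AIC": self.aic,
            "BIC": self.bic,
            "converged": self.converged,
            "n_cycles": self.n_cycles,
            "flagged_items": self.flagged_items,
        }
        if self.lrt is not None:
            d["lrt"] = self.lrt
        return d


@dataclass
class ThetaEstimate:
    """EAP latent score with posterior SD and 0-100 transformed value."""

    theta: float
    se: float
    score_0_100: float
    n_items_used: int


@dataclass
class ItemFit:
    """Per-item infit (information-weighted) and outfit mean squares."""

    infit: dict
    outfit: dict
    low_n_items: list = field(default_factory=list)


@dataclass
class InformationCurve:
    """Item and test Fisher information evaluated on a theta grid."""

    grid: np.ndarray
    item_information: dict  # item_id -> array over grid
    test_information: np.ndarray

    def share_in(self, lo: float, hi: float) -> float:
        """Percentage of total test information in [lo, hi] (trapezoid)."""
        total = np.trapezoid(self.test_information, self.grid)
        mask = (self.grid >= lo) & (self.grid <= hi)
        part = np.trapezoid(self.test_information[mask], self.grid[mask])
        return float(100.0 * part / total)


# ---------------------------------------------------------------------------
# GPCM probabilities
# ---------------------------------------------------------------------------

def _gpcm_logits(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category logits s_k(theta), shape (n_categories, len(theta))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    m = len(b)
    k = np.arange(m + 1)[:, None]
    cumb = np.concatenate([[0.0], np.cumsum(b)])[:, None]
    return a * (k * theta[None, :] - cumb)


def gpcm_prob(item: GpcmItem, theta) -> np.ndarray:
    """Category probabilities P_k(theta) under the GPCM.

    Stabilized with log-sum-exp; returns shape (n_categories,) for scalar
    theta, else (n_categories, len(theta)).
    """
    scalar = np.isscalar(theta) or np.ndim(theta) == 0
    s = _gpcm_logits(item.a, np.asarray(item.b), theta)
    p = np.exp(s - logsumexp(s, axis=0, keepdims=True))
    return p[:, 0] if scalar else p


def _prob_from_params(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    s = _gpcm_logits(a, b, nodes)
    return np.exp(s - logsumexp(s, axis=0, keepdims=True))


def expected_score(item: GpcmItem, theta) -> np.ndarray:
    """E[K | theta] for an item (the item characteristic curve)."""
    p = gpcm_prob(item, np.atleast_1d(theta))
    k = np.arange(item.n_categories)[:, None]
    out = (k * p).sum(axis=0)
    return out if np.ndim(theta) else float(out[0])


def score_variance(item: GpcmItem, theta) -> np.ndarray:
    """Var[K | theta] for an item."""
    p = gpcm_prob(item, np.atleast_1d(theta))
    k = np.arange(item.n_categories)[:, None]
    ex = (k * p).sum(axis=0)
    ex2 = (k**2 * p).sum(axis=0)
    out = ex2 - ex**2
    return out if np.ndim(theta) else float(out[0])


# ---------------------------------------------------------------------------
# MML-EM calibration
# ---------------------------------------------------------------------------

def _item_ell_grad(params, r, nodes, pcm_a=None):
    """Negative expected complete-data log-likelihood and gradient for one item.

    ``r`` is the (n_categories x Q) table of expected counts per category
    and node. If ``pcm_a`` is given, params are the thresholds only.
    """
    if pcm_a is None:
        a, b = params[0], params[1:]
    else:
        a, b = pcm_a, params
    m = len(b)
    p = _prob_from_params(a, b, nodes)  # (m+1, Q)
    logp = np.log(np.clip(p, 1e-300, None))
    f = float((r * logp).sum())

    k = np.arange(m + 1)[:, None]
    cumb = np.concatenate([[0.0], np.cumsum(b)])[:, None]
    Rq = r.sum(axis=0)  # (Q,)
    grads = []
    if pcm_a is None:
        dsk_da = k * nodes[None, :] - cumb  # (m+1, Q)
        g_a = (r * dsk_da).sum() - (Rq * (p * dsk_da).sum(axis=0)).sum()
        grads.append(g_a)
    for j in range(1, m + 1):
        ind = (k >= j).astype(float)  # (m+1, 1)
        dsk_db = -a * ind
        g_b = (r * dsk_db).sum() - (Rq * (p * dsk_db).sum(axis=0)).sum()
        grads.append(g_b)
    return -f, -np.asarray(grads)


def _initial_thresholds(col: np.ndarray, m: int) -> np.ndarray:
    """Spread initial thresholds from the observed cumulative proportions."""
    obs = col[~np.isnan(col)]
    props = np.array([(obs <= k).mean() for k in range(m)])
    return np.clip(norm.ppf(np.clip(props, 0.02, 0.98)), -3.0, 3.0)


def fit_gpcm(data: ResponseMatrix, grid: QuadratureGrid = None, pcm: bool = False,
             max_cycles: int = 500, tol: float = 1e-4,
             transform: ScoreTransform = None, ll_trace: list = None):
    """Calibrate a GPCM (or PCM) item bank by marginal maximum likelihood.

    E-step: each respondent's posterior over the quadrature nodes, with
    missing responses skipped in the likelihood product. M-step: per-item
    quasi-Newton maximization of the expected complete-data log-likelihood;
    under ``pcm=True`` all items share one common estimated discrimination,
    updated by a one-dimensional search each cycle.

    Returns ``(ItemBank, FitSummary)``. Non-convergence within
    ``max_cycles`` is reported in the summary, never silent.
    """
    if grid is None:
        grid = QuadratureGrid.default()
    n, p_items = data.values.shape
    if n < 50:
        raise ValueError("calibration needs at least 50 respondents")
    if n < 200:
        logger.warning("calibration with n = %d (< 200): estimates may be unstable", n)
    for j, iid in enumerate(data.item_ids):
        col = data.values[:, j]
        obs = col[~np.isnan(col)]
        if np.unique(obs).size < 2:
            raise ValueError(f"item {iid!r} has fewer than 2 observed categories")

    nodes, logw = grid.nodes, np.log(grid.weights)
    Q = len(nodes)
    x = data.values  # float with NaN
    ms = [m - 1 for m in data.n_categories]  # steps per item

    a = np.ones(p_items)
    b = [_initial_thresholds(x[:, j], ms[j]) for j in range(p_items)]

    # index arrays per item for fast E-step accumulation
    obs_idx = [np.flatnonzero(~np.isnan(x[:, j])) for j in range(p_items)]
    obs_codes = [x[obs_idx[j], j].astype(int) for j in range(p_items)]

    def marginal_ll_matrix():
        ll = np.zeros((n, Q))
        for j in range(p_items):
            logp = np.log(np.clip(_prob_from_params(a[j], b[j], nodes), 1e-300, None))
            ll[obs_idx[j]] += logp[obs_codes[j], :]
        return ll

    converged = False
    n_cycles = 0
    ll_marg = -np.inf
    for cycle in range(1, max_cycles + 1):
        n_cycles = cycle
        ll = marginal_ll_matrix() + logw[None, :]
        ll_marg = float(logsumexp(ll, axis=1).sum())
        if ll_trace is not None:
            ll_trace.append(ll_marg)
        post = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))  # (n, Q)

        old = np.concatenate([a] + [bj for bj in b])
        # expected category-by-node counts per item
        r_tabs = []
        for j in range(p_items):
            r = np.zeros((ms[j] + 1, Q))
            np.add.at(r, obs_codes[j], post[obs_idx[j]])
            r_tabs.append(r)

        if not pcm:
            for j in range(p_items):
                x0 = np.concatenate([[a[j]], b[j]])
                res = minimize(_item_ell_grad, x0, args=(r_tabs[j], nodes), jac=True,
                               method="L-BFGS-B",
                               bounds=[(0.05, A_MAX)] + [(-8.0, 8.0)] * ms[j])
                a[j], b[j] = res.x[0], res.x[1:]
        else:
            for j in range(p_items):
                res = minimize(_item_ell_grad, b[j], args=(r_tabs[j], nodes, a[j]),
                               jac=True, method="L-BFGS-B", bounds=[(-8.0, 8.0)] * ms[j])
                b[j] = res.x

            def common_neg_ell(av):
                return sum(_item_ell_grad(b[j], r_tabs[j], nodes, pcm_a=av)[0]
                           for j in range(p_items))

            sa = minimize_scalar(common_neg_ell, bounds=(0.05, A_MAX), method="bounded",
                                 options={"xatol": 1e-6})
            a[:] = sa.x

        new = np.concatenate([a] + [bj for bj in b])
        if np.max(np.abs(new - old)) < tol:
            converged = True
            break

    # final marginal LL at converged parameters
    ll = marginal_ll_matrix() + logw[None, :]
    ll_marg = float(logsumexp(ll, axis=1).sum())

    flagged = []
    for j, iid in enumerate(data.item_ids):
        if a[j] >= A_MAX - 1e-9:
            flagged.append({"item_id": iid, "reason": f"discrimination clamped at {A_MAX}"})
    if not converged:
        logger.warning("EM did not converge in %d cycles (max |delta| >= %g)", max_cycles, tol)

    items = [GpcmItem(item_id=data.item_ids[j], a=float(a[j]), b=tuple(b[j]))
             for j in range(p_items)]
    bank = ItemBank(items=items, transform=transform or ScoreTransform(),
                    metadata={"model": "pcm" if pcm else "gpcm"})
    n_params = (1 + sum(ms)) if pcm else (p_items + sum(ms))
    summary = FitSummary(log_likelihood=ll_marg, n_params=n_params, n_respondents=n,
                         converged=converged, n_cycles=n_cycles, flagged_items=flagged)
    return bank, summary


def likelihood_ratio_test(full: FitSummary, restricted: FitSummary) -> dict:
    """LRT of a restricted model (e.g. PCM) against the nesting full model."""
    chi2_stat = max(0.0, -2.0 * (restricted.log_likelihood - full.log_likelihood))
    df = full.n_params - restricted.n_params
    p = float(chi2.sf(chi2_stat, df)) if df > 0 else float("nan")
    return {"chi2": float(chi2_stat), "df": int(df), "p": p}


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def eap_score(responses, bank: ItemBank, grid: QuadratureGrid = None) -> ThetaEstimate:
    """Bayesian EAP estimate of theta from one respondent's responses.

    ``responses`` maps item_id -> code, or is a sequence aligned with the
    bank (NaN/None = missing). With no responses the prior mean and SD are
    returned.
    """
    if grid is None:
        grid = QuadratureGrid.default()
    if isinstance(responses, dict):
        resp = [responses.get(it.item_id, np.nan) for it in bank.items]
    else:
        resp = list(responses)
        if len(resp) != len(bank):
            raise ValueError("response vector length must match bank size")
    log_post = np.log(grid.weights).copy()
    n_used = 0
    for it, r in zip(bank.items, resp):
        if r is None or (isinstance(r, float) and np.isnan(r)):
            continue
        r = int(r)
        if not (0 <= r < it.n_categories):
            raise ValueError(f"response {r} out of range for item {it.item_id!r}")
        logp = np.log(np.clip(_prob_from_params(it.a, np.asarray(it.b), grid.nodes),
                              1e-300, None))
        log_post += logp[r, :]
        n_used += 1
    w = np.exp(log_post - logsumexp(log_post))
    theta = float(np.sum(w * grid.nodes))
    var = float(np.sum(w * grid.nodes**2) - theta**2)
    se = float(np.sqrt(max(var, 1e-12)))
    return ThetaEstimate(theta=theta, se=se, score_0_100=bank.transform.apply(theta),
                         n_items_used=n_used)


def eap_score_matrix(data: ResponseMatrix, bank: ItemBank,
                     grid: QuadratureGrid = None) -> list:
    """EAP estimates for every respondent of a response matrix (vectorized)."""
    if grid is None:
        grid = QuadratureGrid.default()
    col_of = {iid: j for j, iid in enumerate(data.item_ids)}
    n = data.n_respondents
    log_post = np.tile(np.log(grid.weights), (n, 1))
    n_used = np.zeros(n, dtype=int)
    for it in bank.items:
        j = col_of[it.item_id]
        col = data.values[:, j]
        obs = np.flatnonzero(~np.isnan(col))
        logp = np.log(np.clip(_prob_from_params(it.a, np.asarray(it.b), grid.nodes),
                              1e-300, None))
        log_post[obs] += logp[col[obs].astype(int), :]
        n_used[obs] += 1
    w = np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))
    theta = w @ grid.nodes
    var = w @ grid.nodes**2 - theta**2
    se = np.sqrt(np.clip(var, 1e-12, None))
    return [ThetaEstimate(theta=float(t), se=float(s),
                          score_0_100=bank.transform.apply(t), n_items_used=int(k))
            for t, s, k in zip(theta, se, n_used)]


# ---------------------------------------------------------------------------
# Item fit
# ---------------------------------------------------------------------------

def infit_outfit(data: ResponseMatrix, bank: ItemBank, thetas) -> ItemFit:
    """Infit/outfit mean squares with plug-in EAP theta estimates.

    infit_i = sum_n (x_ni - E_ni)^2 / sum_n W_ni (information-weighted);
    outfit_i = mean_n (x_ni - E_ni)^2 / W_ni. Missing cells are excluded.
    """
    th = np.array([t.theta if isinstance(t, ThetaEstimate) else float(t) for t in thetas])
    col_of = {iid: j for j, iid in enumerate(data.item_ids)}
    infit, outfit, low_n = {}, {}, []
    for it in bank.items:
        col = data.values[:, col_of[it.item_id]]
        obs = ~np.isnan(col)
        if obs.sum() < 10:
            low_n.append(it.item_id)
        e = expected_score(it, th[obs])
        w = np.clip(score_variance(it, th[obs]), 1e-12, None)
        sq = (col[obs] - e) ** 2
        infit[it.item_id] = float(sq.sum() / w.sum())
        outfit[it.item_id] = float(np.mean(sq / w))
    if low_n:
        logger.warning("item fit computed on < 10 respondents for: %s", ", ".join(low_n))
    return ItemFit(infit=infit, outfit=outfit, low_n_items=low_n)


# ---------------------------------------------------------------------------
# Information
# ---------------------------------------------------------------------------

def item_information(item: GpcmItem, theta) -> np.ndarray:
    """Fisher information I_i(theta) = a^2 * Var[K | theta]."""
    return item.a**2 * score_variance(item, theta)


def information(bank: ItemBank, grid=None) -> InformationCurve:
    """Item and test information on a theta grid (default 241 pts on [-6, 6])."""
    if grid is None:
        grid = np.linspace(-6.0, 6.0, 241)
    grid = np.asarray(grid, dtype=float)
    per_item = {it.item_id: item_information(it, grid) for it in bank.items}
    total = np.sum(list(per_item.values()), axis=0)
    return InformationCurve(grid=grid, item_information=per_item, test_information=total)


def transform_score(theta: float, transform: ScoreTransform = None) -> float:
    """Map theta to the 0-100 reporting scale (affine then clip)."""
    return (transform or ScoreTransform()).apply(theta)
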