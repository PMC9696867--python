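"""IRT-assumption diagnostics: unidimensionality, local independence,
monotonicity.

Unidimensionality is judged from the eigenvalue spectrum of the
polychoric correlation matrix (first/second eigenvalue ratio), permutation
parallel analysis, and bifactor indices (omega hierarchical and explained
common variance) from a Schmid-Leiman orthogonalization of an oblique
minres EFA. Local independence uses Yen's Q3 residual correlations with
plug-in EAP scores; monotonicity uses rest-score curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from premcat._factors import minres_efa, promax, schmid_leiman
from premcat.databank import ItemBank, ResponseMatrix
from premcat.calibration import ThetaEstimate, expected_score

logger = logging.getLogger(__name__)


@dataclass
class DimensionalityReport:
    eigenvalues: np.ndarray
    first_second_ratio: float
    omega_h: float
    omega_group: list
    ecv_general: float
    ecv_group: list
    general_loadings: np.ndarray
    group_loadings: np.ndarray
    item_ids: list
    heywood_items: list = field(default_factory=list)
    parallel_n_factors: int = None

    def to_dict(self) -> dict:
        return {
            "eigenvalues": np.asarray(self.eigenvalues).tolist(),
            "first_second_ratio": self.first_second_ratio,
            "parallel_n_factors": self.parallel_n_factors,
            "omega_h": self.omega_h,
            "omega_group": list(self.omega_group),
            "ecv_general": self.ecv_general,
            "ecv_group": list(self.ecv_group),
            "item_ids": list(self.item_ids),
            "general_loadings": np.asarray(self.general_loadings).tolist(),
            "group_loadings": np.asarray(self.group_loadings).tolist(),
            "heywood_items": list(self.heywood_items),
        }


@dataclass
class LocalIndependenceReport:
    q3: pd.DataFrame
    max_abs_residual: float
    flagged_pairs: list  # (item_i, item_j, q3) with |q3| >= threshold
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "max_abs_residual": self.max_abs_residual,
            "flagged_pairs": [
                {"item_i": i, "item_j": j, "q3": v} for i, j, v in self.flagged_pairs
            ],
            "item_ids": list(self.q3.columns),
            "q3": np.round(self.q3.to_numpy(), 12).tolist(),
        }


@dataclass
class MonotonicityReport:
    bin_means: dict  # item_id -> list of rest-score-bin means (NaN = empty bin)
    violations: dict  # item_id -> count of adjacent decreases beyond tolerance
    max_violation: dict  # item_id -> largest decrease (0 if none)
    skipped_items: list
    tolerance: float

    @property
    def total_violations(self) -> int:
        return int(sum(self.violations.values()))

    def worst_item(self):
        if not self.max_violation:
            return None
        return max(self.max_violation, key=lambda k: self.max_violation[k])

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "total_violations": self.total_violations,
            "violations": self.violations,
            "max_violation": self.max_violation,
            "bin_means": {k: list(v) for k, v in self.bin_means.items()},
            "skipped_items": list(self.skipped_items),
        }


# ---------------------------------------------------------------------------
# Polychoric correlations
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def _bvn_cdf(h, k, rho):
    """Bivariate standard-normal CDF P(X<=h, Y<=k) by Gauss-Legendre
    quadrature of the correlation integral (vectorized over h, k)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)  # nodes on (0, rho)
    w = 0.5 * rho * _GL_WEIGHTS
    hh = h[..., None]
    kk = k[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.exp(
            -(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * (1.0 - r**2))
        ) / np.sqrt(1.0 - r**2)
    add = (integrand * w).sum(axis=-1) / (2.0 * np.pi)
    out = base + add
    # propagate infinite margins exactly
    out = np.where(np.isinf(h) & (h < 0), 0.0, out)
    out = np.where(np.isinf(k) & (k < 0), 0.0, out)
    out = np.where(np.isinf(h) & (h > 0), norm.cdf(k), out)
    out = np.where(np.isinf(k) & (k > 0), np.where(np.isinf(h) & (h > 0), 1.0,
                                                   norm.cdf(h)), out)
    return np.clip(out, 0.0, 1.0)


def _cell_probs(tau_r, tau_c, rho):
    """Rectangle probabilities of a two-way ordinal table under the
    bivariate-normal model with thresholds tau_r/tau_c (padded with inf)."""
    tr = np.concatenate([[-np.inf], tau_r, [np.inf]])
    tc = np.concatenate([[-np.inf], tau_c, [np.inf]])
    H, K = np.meshgrid(tr, tc, indexing="ij")
    F = _bvn_cdf(H, K, rho)
    return np.diff(np.diff(F, axis=0), axis=1)


def polychoric_rho(table: np.ndarray):
    """Two-stage ML polychoric correlation from a contingency table.

    Thresholds come from the marginals; rho maximizes the bivariate-normal
    likelihood by bounded univariate optimization. Empty marginal rows or
    columns are collapsed away first.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate table: fewer than 2 observed categories")
    n = table.sum()
    tau_r = norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    tau_c = norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)

    def nll(rho):
        p = np.clip(_cell_probs(tau_r, tau_c, rho), 1e-12, None)
        return -float((table * np.log(p)).sum())

    res = minimize_scalar(nll, bounds=(-0.9999, 0.9999), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def polychoric_matrix(data: ResponseMatrix) -> pd.DataFrame:
    """Pairwise two-stage ML polychoric correlation matrix.

    Degenerate pairs (an item constant on the pairwise-complete rows) fall
    back to the Pearson correlation with a warning.
    """
    if data.n_items < 2:
        raise ValueError("need at least 2 items")
    p = data.n_items
    R = np.eye(p)
    vals = data.values
    for i in range(p):
        for j in range(i + 1, p):
            both = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
            xi, xj = vals[both, i].astype(int), vals[both, j].astype(int)
            table = np.zeros((data.n_categories[i], data.n_categories[j]))
            np.add.at(table, (xi, xj), 1.0)
            try:
                R[i, j] = R[j, i] = polychoric_rho(table)
            except ValueError:
                pear = np.corrcoef(xi, xj)[0, 1] if xi.std() and xj.std() else 0.0
                logger.warning(
                    "polychoric degenerate for (%s, %s); Pearson fallback %.3f",
                    data.item_ids[i], data.item_ids[j], pear)
                R[i, j] = R[j, i] = pear
    return pd.DataFrame(R, index=data.item_ids, columns=data.item_ids)


# ---------------------------------------------------------------------------
# Eigen screen, parallel analysis, bifactor indices
# ---------------------------------------------------------------------------

def eigen_screen(corr) -> tuple:
    """Descending eigenvalues and the first/second-eigenvalue ratio.

    Small negative eigenvalues from non-PSD pairwise matrices are clipped
    to zero (logged)."""
    R = np.asarray(corr, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    vals = np.linalg.eigvalsh(R)[::-1]
    if vals[-1] < -1e-8:
        logger.info("smoothing: clipping negative eigenvalue %.3g to 0", vals[-1])
    vals = np.clip(vals, 0.0, None)
    ratio = float(vals[0] / vals[1]) if vals[1] > 0 else float("inf")
    return vals, ratio


def parallel_analysis(data: ResponseMatrix, n_reps: int = 100,
                      quantile: float = 0.95, seed: int = 0) -> int:
    """Permutation parallel analysis on Pearson correlations.

    Retains the number of observed eigenvalues exceeding the ``quantile``
    of the eigenvalue null distribution obtained from ``n_reps`` data sets
    in which every column is independently permuted (marginals preserved).
    """
    if n_reps < 10:
        raise ValueError("n_reps must be at least 10")
    rng = np.random.default_rng(seed)
    df = data.to_frame()
    obs = np.linalg.eigvalsh(df.corr(min_periods=3).to_numpy())[::-1]
    p = data.n_items
    null = np.empty((n_reps, p))
    vals = df.to_numpy()
    for r in range(n_reps):
        perm = np.column_stack([rng.permutation(vals[:, j]) for j in range(p)])
        null[r] = np.linalg.eigvalsh(pd.DataFrame(perm).corr(min_periods=3).to_numpy())[::-1]
    thresh = np.quantile(null, quantile, axis=0)
    keep = obs > thresh
    # sequential rule: stop at the first non-exceeding eigenvalue
    n_factors = 0
    for k in keep:
        if not k:
            break
        n_factors += 1
    return n_factors


def bifactor_indices(data: ResponseMatrix, n_group_factors: int = 2,
                     corr: pd.DataFrame = None,
                     parallel_kwargs: dict = None) -> DimensionalityReport:
    """Exploratory bifactor indices via Schmid-Leiman orthogonalization.

    An oblique (promax) minres EFA of the polychoric matrix with
    ``n_group_factors`` primaries is re-expressed as one general factor
    plus orthogonal group factors. Reports omega hierarchical, the
    analogous omega for each group factor, and the explained-common-variance
    split (percentages summing to 100).
    """
    if corr is None:
        corr = polychoric_matrix(data)
    R = corr.to_numpy()
    item_ids = list(corr.columns)
    if len(item_ids) < 3 * n_group_factors:
        logger.warning("fewer than 3 items per intended factor")
    eigenvalues, ratio = eigen_screen(R)

    L, psi = minres_efa(R, n_group_factors)
    pattern, Phi = promax(L)
    general, group = schmid_leiman(pattern, Phi)

    heywood = []
    comm = general**2 + (group**2).sum(axis=1)
    for idx in np.flatnonzero(comm > 1.0):
        heywood.append(item_ids[idx])
        scale = np.sqrt(1.0 / comm[idx])
        general[idx] *= scale
        group[idx, :] *= scale
    if heywood:
        logger.warning("Heywood case clipped for items: %s", ", ".join(heywood))

    comm = general**2 + (group**2).sum(axis=1)
    uniq = np.clip(1.0 - comm, 0.0, None)
    total_var = general.sum() ** 2 + sum(group[:, f].sum() ** 2
                                         for f in range(group.shape[1])) + uniq.sum()
    omega_h = float(general.sum() ** 2 / total_var)
    omega_group = [float(group[:, f].sum() ** 2 / total_var)
                   for f in range(group.shape[1])]
    common = float((general**2).sum() + (group**2).sum())
    ecv_general = float(100.0 * (general**2).sum() / common)
    ecv_group = [float(100.0 * (group[:, f] ** 2).sum() / common)
                 for f in range(group.shape[1])]

    pa = None
    if parallel_kwargs is not None:
        pa = parallel_analysis(data, **parallel_kwargs)
    return DimensionalityReport(
        eigenvalues=eigenvalues, first_second_ratio=ratio,
        omega_h=omega_h, omega_group=omega_group,
        ecv_general=ecv_general, ecv_group=ecv_group,
        general_loadings=general, group_loadings=group,
        item_ids=item_ids, heywood_items=heywood, parallel_n_factors=pa,
    )


# ---------------------------------------------------------------------------
# Local independence (Yen's Q3) and monotonicity
# ---------------------------------------------------------------------------

def q3_residuals(data: ResponseMatrix, bank: ItemBank, thetas,
                 threshold: float = 0.20) -> LocalIndependenceReport:
    """Yen's Q3: correlations of model residuals across item pairs.

    The residual for cell (n, i) is the observed code minus the expected
    GPCM score at the respondent's plug-in theta estimate; Q3 entries are
    pairwise-complete Pearson correlations of the residual columns. Pairs
    with fewer than 3 complete residuals are left missing (logged).
    """
    th = np.array([t.theta if isinstance(t, ThetaEstimate) else float(t)
                   for t in thetas])
    col_of = {iid: j for j, iid in enumerate(data.item_ids)}
    resid = np.full((data.n_respondents, len(bank)), np.nan)
    ids = bank.item_ids
    for jj, it in enumerate(bank.items):
        col = data.values[:, col_of[it.item_id]]
        obs = ~np.isnan(col)
        resid[obs, jj] = col[obs] - expected_score(it, th[obs])
    q3 = pd.DataFrame(resid, columns=ids).corr(min_periods=3)
    if q3.isna().to_numpy().any():
        logger.warning("Q3 undefined for some pairs (fewer than 3 complete residuals)")
    off = q3.to_numpy().copy()
    np.fill_diagonal(off, np.nan)
    max_abs = float(np.nanmax(np.abs(off))) if np.isfinite(off).any() else float("nan")
    flagged = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = off[i, j]
            if np.isfinite(v) and abs(v) >= threshold:
                flagged.append((ids[i], ids[j], float(v)))
    return LocalIndependenceReport(q3=q3, max_abs_residual=max_abs,
                                   flagged_pairs=flagged, threshold=threshold)


def monotonicity_check(data: ResponseMatrix, n_bins: int = 10,
                       tolerance: float = 0.05) -> MonotonicityReport:
    """Rest-score monotonicity: mean item score should not decrease across
    rest-score quantile bins by more than ``tolerance``.

    The rest score is the mean code over the respondent's other observed
    items, computed on the rows where the item itself is observed. Items
    with fewer than 2 non-empty bins (e.g. constant items) are skipped.
    """
    if data.n_respondents < n_bins * 10:
        logger.warning("monotonicity check with n = %d < %d: bins will be sparse",
                       data.n_respondents, n_bins * 10)
    df = data.to_frame()
    bin_means, violations, max_violation, skipped = {}, {}, {}, []
    for iid in data.item_ids:
        others = [c for c in data.item_ids if c != iid]
        rest = df[others].mean(axis=1)
        mask = df[iid].notna() & rest.notna()
        if df.loc[mask, iid].nunique() <= 1 or mask.sum() < 2 * n_bins:
            skipped.append(iid)
            continue
        try:
            bins = pd.qcut(rest[mask], q=n_bins, labels=False, duplicates="drop")
        except ValueError:
            skipped.append(iid)
            continue
        if bins.nunique() < 2:
            skipped.append(iid)
            continue
        means = df.loc[mask, iid].groupby(bins).mean()
        means = means.reindex(range(int(bins.max()) + 1))
        seq = means.dropna().to_numpy()
        drops = np.maximum(0.0, -(np.diff(seq)))
        violations[iid] = int((drops > tolerance).sum())
        max_violation[iid] = float(drops.max()) if drops.size else 0.0
        bin_means[iid] = means.to_numpy().tolist()
    if skipped:
        logger.warning("monotonicity skipped items: %s", ", ".join(skipped))
    return MonotonicityReport(bin_means=bin_means, violations=violations,
                              max_violation=max_violation, skipped_items=skipped,
                              tolerance=tolerance)
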