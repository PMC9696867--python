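"""Domain types and descriptive item screening for ordinal response banks.

Holds the three core containers (:class:`GpcmItem`, :class:`ItemBank`,
:class:`ResponseMatrix`), CSV/JSON I/O, the redundancy screen on inter-item
correlations, Cronbach's alpha, and sparse-category recoding.

Missing values ("not applicable", blank, ``NA``) are stored as ``NaN`` in a
float response array; all statistics document whether they use
pairwise-complete or listwise-complete data.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical 5-point Likert agreement labels, lowest to highest.
LIKERT_LABELS = [
    "strongly disagree",
    "disagree",
    "neither agree nor disagree",
    "agree",
    "strongly agree",
]

#: Case-insensitive cell contents treated as missing ("not applicable").
MISSING_TOKENS = {"", "na", "n/a", "nan", "not applicable"}

DEFAULT_TRANSFORM_OFFSET = 50.0
DEFAULT_TRANSFORM_SCALE = 12.5


@dataclass(frozen=True)
class GpcmItem:
    """One polytomous item under the generalized partial credit model.

    Parameters
    ----------
    item_id : str
        Unique label.
    a : float
        Discrimination (slope), strictly positive.
    b : tuple of float
        Step thresholds ``b_1..b_m``, one per boundary between adjacent
        categories. The GPCM does not require them to be ordered.
    """

    item_id: str
    a: float
    b: tuple

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"item {self.item_id!r}: discrimination must be > 0, got {self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) < 1:
            raise ValueError(f"item {self.item_id!r}: needs at least one step threshold")
        if not all(math.isfinite(x) for x in b):
            raise ValueError(f"item {self.item_id!r}: thresholds must be finite")
        object.__setattr__(self, "b", b)

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class ScoreTransform:
    """Affine map from the theta metric to a 0-100 reporting scale.

    ``score = clip(offset + scale * theta, 0, 100)``. The default anchors
    theta = -4 at 0 and theta = +4 at 100.
    """

    offset: float = DEFAULT_TRANSFORM_OFFSET
    scale: float = DEFAULT_TRANSFORM_SCALE

    def __post_init__(self):
        if not (self.scale > 0):
            raise ValueError("transform scale must be > 0 (monotone increasing)")

    def apply(self, theta: float) -> float:
        return float(np.clip(self.offset + self.scale * np.asarray(theta), 0.0, 100.0))


@dataclass
class ItemBank:
    """Ordered collection of GPCM items plus the scoring transform."""

    items: list
    transform: ScoreTransform = field(default_factory=ScoreTransform)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique in a bank")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> GpcmItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids) -> "ItemBank":
        keep = set(item_ids)
        return ItemBank(
            items=[it for it in self.items if it.item_id in keep],
            transform=self.transform,
            metadata=dict(self.metadata),
        )


@dataclass
class ResponseMatrix:
    """Respondents x items ordinal codes with missingness and covariates.

    ``values`` is a float array with codes ``0..m_i`` and ``NaN`` for
    missing / "not applicable". ``covariates`` is a DataFrame aligned on
    rows (may be empty).
    """

    values: np.ndarray
    item_ids: list
    covariates: pd.DataFrame = None
    n_categories: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (respondents x items)")
        if len(self.item_ids) != self.values.shape[1]:
            raise ValueError("item_ids length must match number of columns")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(self.values.shape[0]))
        if len(self.covariates) != self.values.shape[0]:
            raise ValueError("covariates must have one row per respondent")
        if self.n_categories is None:
            self.n_categories = []
            for j in range(self.values.shape[1]):
                col = self.values[:, j]
                obs = col[~np.isnan(col)]
                self.n_categories.append(int(obs.max()) + 1 if obs.size else 2)
        for j, m in enumerate(self.n_categories):
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            if obs.size and (obs.min() < 0 or obs.max() > m - 1 or np.any(obs != np.round(obs))):
                raise ValueError(
                    f"column {self.item_ids[j]!r}: codes must be integers in 0..{m - 1}"
                )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.item_ids)

    def subset_items(self, item_ids) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            values=self.values[:, idx],
            item_ids=list(item_ids),
            covariates=self.covariates.reset_index(drop=True),
            n_categories=[self.n_categories[i] for i in idx],
        )


@dataclass
class ScreeningReport:
    """Descriptive screen of an item set: distributions, floor/ceiling
    percentages, inter-item correlations, redundancy removals and alpha."""

    distributions: dict
    floor_pct: dict
    ceiling_pct: dict
    correlations: pd.DataFrame
    removed_items: list  # list of (item_id, reason) in removal order
    alpha: float
    n_listwise: int
    r_max: float
    correlation_type: str = "pearson"

    @property
    def surviving_items(self) -> list:
        removed = {r[0] for r in self.removed_items}
        return [i for i in self.correlations.columns if i not in removed]

    def to_dict(self) -> dict:
        return {
            "correlation_type": self.correlation_type,
            "r_max": self.r_max,
            "alpha": self.alpha,
            "n_listwise": self.n_listwise,
            "distributions": self.distributions,
            "floor_pct": self.floor_pct,
            "ceiling_pct": self.ceiling_pct,
            "removed_items": [{"item_id": i, "reason": r} for i, r in self.removed_items],
            "surviving_items": self.surviving_items,
            "correlations": {
                "item_ids": list(self.correlations.columns),
                "matrix": np.round(self.correlations.to_numpy(), 12).tolist(),
            },
        }


# ---------------------------------------------------------------------------
# CSV response I/O
# ---------------------------------------------------------------------------

def _parse_cell(raw, label_map, n_cat, row, col):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return np.nan
    s = str(raw).strip().lower()
    if s in MISSING_TOKENS:
        return np.nan
    if s in label_map:
        return float(label_map[s])
    try:
        v = float(s)
    except ValueError:
        raise ValueError(f"unknown category label {raw!r} at row {row}, column {col!r}") from None
    if v != round(v) or not (0 <= v <= n_cat - 1):
        raise ValueError(f"value {raw!r} out of range 0..{n_cat - 1} at row {row}, column {col!r}")
    return v


def read_responses(path, item_columns, covariate_columns=(), id_column=None,
                   n_categories=5, labels=None) -> ResponseMatrix:
    """Read a respondent-by-item CSV into a :class:`ResponseMatrix`.

    Item cells may be integer codes (0-based) or Likert agreement labels;
    "not applicable", ``NA`` and blank cells become missing. Covariate
    columns are carried through untouched.
    """
    labels = labels if labels is not None else LIKERT_LABELS
    label_map = {lab.lower(): k for k, lab in enumerate(labels)}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in list(item_columns) + list(covariate_columns):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if id_column is not None:
        ids = df[id_column].tolist()
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate respondent ids: {sorted(set(dup))}")
    values = np.empty((len(df), len(item_columns)))
    for j, col in enumerate(item_columns):
        for i, raw in enumerate(df[col]):
            values[i, j] = _parse_cell(raw, label_map, n_categories, i, col)
    cov = df[list(covariate_columns)].copy().reset_index(drop=True) if covariate_columns \
        else pd.DataFrame(index=range(len(df)))
    return ResponseMatrix(values=values, item_ids=list(item_columns), covariates=cov,
                          n_categories=[n_categories] * len(item_columns))


def write_responses(data: ResponseMatrix, path) -> None:
    """Write responses (and covariates) back to CSV; missing cells blank."""
    df = data.to_frame()
    out = df.where(df.notna(), "")
    out = out.apply(lambda c: c.map(lambda v: "" if v == "" else str(int(v))))
    out = pd.concat([out, data.covariates.reset_index(drop=True)], axis=1)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Item-bank JSON I/O
# ---------------------------------------------------------------------------

def write_bank(bank: ItemBank, path) -> None:
    payload = {
        "items": [
            {"id": it.item_id, "a": float(it.a), "b": [float(x) for x in it.b]}
            for it in bank.items
        ],
        "transform": {"offset": bank.transform.offset, "scale": bank.transform.scale},
        "metadata": bank.metadata,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_bank(path) -> ItemBank:
    with open(path) as fh:
        payload = json.load(fh)
    if "items" not in payload or not isinstance(payload["items"], list):
        raise ValueError(f"{path}: bank JSON must contain an 'items' list")
    items = []
    for rec in payload["items"]:
        try:
            items.append(GpcmItem(item_id=str(rec["id"]), a=float(rec["a"]),
                                  b=tuple(float(x) for x in rec["b"])))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed item record {rec!r}") from exc
    if "transform" in payload:
        tr = ScoreTransform(offset=float(payload["transform"]["offset"]),
                            scale=float(payload["transform"]["scale"]))
    else:
        tr = ScoreTransform()
        logger.warning(
            "bank %s has no 'transform'; using default 0-100 map (offset=%.1f, scale=%.2f)",
            path, tr.offset, tr.scale,
        )
    return ItemBank(items=items, transform=tr, metadata=payload.get("metadata", {}))


# ---------------------------------------------------------------------------
# Screening statistics
# ---------------------------------------------------------------------------

def screen_items(data: ResponseMatrix, r_max: float = 0.70,
                 min_pairs: int = 3) -> ScreeningReport:
    """Descriptive redundancy screen on pairwise-complete Pearson correlations.

    Items in pairs with ``r > r_max`` are removed iteratively: at each step
    the item participating in the largest number of violating pairs is
    dropped (ties broken by the smaller corrected item-total correlation,
    then by column order). Constant items are removed first with reason
    "zero variance". Screening the survivors again removes nothing.
    """
    if data.n_items < 2:
        raise ValueError("screening needs at least 2 items")
    df = data.to_frame()
    removed = []

    # distributions / floor / ceiling on all items
    distributions, floor_pct, ceiling_pct = {}, {}, {}
    for j, iid in enumerate(data.item_ids):
        col = df[iid].dropna()
        m = data.n_categories[j]
        counts = col.value_counts().reindex(range(m), fill_value=0).astype(int)
        distributions[iid] = counts.tolist()
        tot = max(len(col), 1)
        floor_pct[iid] = 100.0 * counts.iloc[0] / tot
        ceiling_pct[iid] = 100.0 * counts.iloc[-1] / tot

    for iid in data.item_ids:
        col = df[iid].dropna()
        if col.nunique() <= 1:
            removed.append((iid, "zero variance"))
    alive = [i for i in data.item_ids if i not in {r[0] for r in removed}]

    corr_full = df.corr(method="pearson", min_periods=min_pairs)

    def item_total_r(iid, current):
        others = [c for c in current if c != iid]
        total = df[others].sum(axis=1, min_count=1)
        mask = df[iid].notna() & total.notna()
        if mask.sum() < min_pairs or df.loc[mask, iid].std() == 0 or total[mask].std() == 0:
            return -np.inf
        return float(np.corrcoef(df.loc[mask, iid], total[mask])[0, 1])

    while len(alive) >= 2:
        sub = corr_full.loc[alive, alive]
        viol = (sub > r_max) & ~np.eye(len(alive), dtype=bool)
        counts = viol.sum(axis=1)
        if counts.max() == 0:
            break
        worst = counts.max()
        cands = [i for i in alive if counts[i] == worst]
        if len(cands) > 1:
            cands.sort(key=lambda i: (item_total_r(i, alive), alive.index(i)))
        drop = cands[0]
        partners = [j for j in alive if viol.loc[drop, j]]
        removed.append((drop, f"inter-item r > {r_max:.2f} with {', '.join(partners)}"))
        alive.remove(drop)

    try:
        alpha = cronbach_alpha(data.subset_items(alive)) if len(alive) >= 2 else float("nan")
    except ValueError:
        alpha = float("nan")
    n_listwise = int(df[alive].dropna().shape[0]) if alive else 0
    return ScreeningReport(
        distributions=distributions, floor_pct=floor_pct, ceiling_pct=ceiling_pct,
        correlations=corr_full, removed_items=removed, alpha=alpha,
        n_listwise=n_listwise, r_max=r_max,
    )


def cronbach_alpha(data: ResponseMatrix) -> float:
    """Cronbach's alpha on the listwise-complete subsample.

    alpha = k/(k-1) * (1 - sum(item variances) / var(total score)).
    """
    df = data.to_frame().dropna()
    k = data.n_items
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if df.empty:
        raise ValueError("no listwise-complete respondents")
    item_var = df.var(axis=0, ddof=1)
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero")
    logger.info("cronbach_alpha: listwise n = %d of %d", len(df), data.n_respondents)
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def recode_categories(data: ResponseMatrix, min_count: int = 10,
                      manual_map: dict = None):
    """Merge sparse response categories with an adjacent category.

    For each item, any category observed fewer than ``min_count`` times is
    merged with the adjacent category that has the fewer observations
    (ties merge downward); codes are re-indexed to stay contiguous from 0.
    A ``manual_map`` ({item_id: {old: new}}) overrides the rule per item.

    Returns ``(recoded ResponseMatrix, {item_id: {old_code: new_code}})``.
    """
    values = data.values.copy()
    recode_map = {}
    new_ncat = []
    for j, iid in enumerate(data.item_ids):
        m = data.n_categories[j]
        if manual_map and iid in manual_map:
            mapping = {int(k): int(v) for k, v in manual_map[iid].items()}
        else:
            # iterative merge: categories live as ordered groups of raw codes
            groups = [[k] for k in range(m)]

            def count_of(group, col=values[:, j]):
                return int(np.isin(col, group).sum())

            while True:
                counts = [count_of(g) for g in groups]
                order = sorted(range(len(groups)), key=lambda g: (counts[g], g))
                gi = order[0]
                if counts[gi] >= min_count:
                    break
                if len(groups) <= 2:
                    raise ValueError(
                        f"item {iid!r}: recoding would leave fewer than 2 categories"
                    )
                left = gi - 1 if gi > 0 else None
                right = gi + 1 if gi < len(groups) - 1 else None
                if left is None:
                    tgt = right
                elif right is None:
                    tgt = left
                else:
                    tgt = left if counts[left] <= counts[right] else right
                lo, hi = min(gi, tgt), max(gi, tgt)
                groups[lo] = groups[lo] + groups[hi]
                del groups[hi]
            mapping = {}
            for new_code, g in enumerate(groups):
                for old in g:
                    mapping[old] = new_code
        new_m = len(set(mapping.values()))
        if new_m < 2:
            raise ValueError(f"item {iid!r}: recoding would leave fewer than 2 categories")
        if sorted(set(mapping.values())) != list(range(new_m)):
            raise ValueError(f"item {iid!r}: recode map codes must be contiguous from 0")
        col = values[:, j]
        obs = ~np.isnan(col)
        col[obs] = [mapping[int(v)] for v in col[obs]]
        recode_map[iid] = mapping
        new_ncat.append(new_m)
    out = ResponseMatrix(values=values, item_ids=list(data.item_ids),
                         covariates=data.covariates.reset_index(drop=True),
                         n_categories=new_ncat)
    return out, recode_map
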