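"""Synthetic Likert-response generator with the structure the analysis assumes.

Responses are drawn from the GPCM category distribution at each
respondent's true theta ~ N(mean, sd), with missing-completely-at-random
cells, categorical covariates, and optional injected differential item
functioning (group-specific threshold shifts and discrimination
multipliers). A single integer seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from premcat.databank import GpcmItem, ItemBank, ResponseMatrix, ScoreTransform
from premcat.calibration import gpcm_prob


@dataclass(frozen=True)
class DifEffect:
    """Injected DIF: for respondents at ``level`` of ``covariate``, the
    item's thresholds shift by ``threshold_shift`` (uniform DIF) and its
    discrimination is multiplied by ``a_multiplier`` (non-uniform DIF)."""

    item_id: str
    covariate: str
    level: str
    threshold_shift: float = 0.0
    a_multiplier: float = 1.0


@dataclass
class SimulationDesign:
    """Full specification of one synthetic data set."""

    n_respondents: int
    bank: ItemBank
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    missing_rate: float = 0.0
    covariates: dict = field(default_factory=dict)  # name -> {level: proportion}
    dif_spec: list = field(default_factory=list)  # list of DifEffect
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for name, levels in self.covariates.items():
            tot = sum(levels.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"covariate {name!r}: proportions sum to {tot}, not 1")
        ids = set(self.bank.item_ids)
        for eff in self.dif_spec:
            if eff.item_id not in ids:
                raise ValueError(f"dif_spec names unknown item {eff.item_id!r}")
            if eff.covariate not in self.covariates:
                raise ValueError(f"dif_spec names unknown covariate {eff.covariate!r}")
            if eff.level not in self.covariates[eff.covariate]:
                raise ValueError(
                    f"dif_spec names unknown level {eff.level!r} of {eff.covariate!r}"
                )


def simulate_responses(design: SimulationDesign):
    """Draw a response matrix (and the true thetas) from a design.

    Returns ``(ResponseMatrix, numpy array of true theta)``. Identical
    seeds give identical output.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_respondents
    theta = rng.normal(design.theta_mean, design.theta_sd, size=n)

    cov = {}
    for name, levels in design.covariates.items():
        labs = list(levels.keys())
        probs = np.array([levels[k] for k in labs], dtype=float)
        cov[name] = rng.choice(labs, size=n, p=probs / probs.sum())
    covariates = pd.DataFrame(cov, index=range(n)) if cov else pd.DataFrame(index=range(n))

    dif_by_item = {}
    for eff in design.dif_spec:
        dif_by_item.setdefault(eff.item_id, []).append(eff)

    values = np.empty((n, len(design.bank)), dtype=float)
    for j, item in enumerate(design.bank.items):
        effs = dif_by_item.get(item.item_id, [])
        in_group = np.zeros(n, dtype=bool)
        item_g = item
        if effs:
            # respondents hit by any effect get the shifted item parameters
            for eff in effs:
                in_group |= covariates[eff.covariate].to_numpy() == eff.level
                item_g = GpcmItem(
                    item_id=item.item_id,
                    a=item_g.a * eff.a_multiplier,
                    b=tuple(np.asarray(item_g.b) + eff.threshold_shift),
                )
        u = rng.random(n)
        for params, mask in ((item, ~in_group), (item_g, in_group)):
            if not mask.any():
                continue
            p = gpcm_prob(params, theta[mask])  # (m+1, n_mask)
            cum = np.cumsum(p, axis=0)
            values[mask, j] = (u[mask][None, :] > cum).sum(axis=0)

    if design.missing_rate > 0:
        miss = rng.random(values.shape) < design.missing_rate
        values[miss] = np.nan

    data = ResponseMatrix(
        values=values,
        item_ids=design.bank.item_ids,
        covariates=covariates,
        n_categories=[it.n_categories for it in design.bank.items],
    )
    return data, theta


def random_bank(n_items: int, n_categories: int, rng,
                a_range=(1.0, 2.8), b_range=(-2.5, 1.5),
                transform: ScoreTransform = None, prefix: str = "I") -> ItemBank:
    """Bank with a ~ U(a_range) and sorted uniform step thresholds."""
    items = []
    for j in range(n_items):
        a = float(rng.uniform(*a_range))
        b = np.sort(rng.uniform(*b_range, size=n_categories - 1))
        items.append(GpcmItem(item_id=f"{prefix}{j + 1}", a=a, b=tuple(b)))
    return ItemBank(items=items, transform=transform or ScoreTransform())


def paper_like_design(seed: int = 0, n_respondents: int = 499, n_items: int = 19,
                      n_categories: int = 5, missing_rate: float = 0.0,
                      dif_spec=()) -> SimulationDesign:
    """Preset emulating the validation study's conditions.

    ~500 respondents answering a 19-item, 5-category bank with theta ~
    N(0,1); discriminations U(1.0, 2.8) and ordered step thresholds spread
    over [-2.5, 1.5], so test information concentrates in the central
    [-2, 2] range. Covariates mirror the study sample: sex ~50/50, age
    median-split, care setting 80/20 outpatient/inpatient, diagnosis
    53/26/21 schizophrenia/bipolar/depression.
    """
    rng = np.random.default_rng(seed)
    bank = random_bank(n_items, n_categories, rng)
    return SimulationDesign(
        n_respondents=n_respondents,
        bank=bank,
        missing_rate=missing_rate,
        covariates={
            "sex": {"male": 0.5, "female": 0.5},
            "age_group": {"<=40": 0.5, ">40": 0.5},
            "setting": {"outpatient": 0.8, "inpatient": 0.2},
            "diagnosis": {"schizophrenia": 0.53, "bipolar": 0.26, "depression": 0.21},
        },
        dif_spec=list(dif_spec),
        seed=int(seed),
    )


def simulate_redundant_dataset(seed: int = 0, n_respondents: int = 499,
                               n_base_items: int = 19, n_redundant: int = 6,
                               noise_sd: float = 0.3):
    """Simulate a bank carrying ``n_redundant`` planted near-copy items.

    Each copy duplicates one distinct base item's parameters and is drawn
    comonotonically with its source: the copy reuses the source's latent
    response quantile, evaluated at theta + N(0, noise_sd). The copies
    therefore correlate far above the 0.70 redundancy ceiling with their
    sources, while the 19 base items stay below it.

    The screened study bank is non-redundant by definition, so the fixture's
    only redundancy must be the planted copies: the base bank caps
    discriminations at 2.2 and is redrawn (deterministically under the
    seed) until no base pair exceeds a Pearson r of 0.70 in the realized
    sample — two strong items can otherwise cross the ceiling through the
    common trait alone.

    Returns ``(ResponseMatrix with 25 columns, true theta, copy item ids)``.
    """
    preset = paper_like_design(seed=seed, n_respondents=n_respondents,
                               n_items=n_base_items)
    rng_bank = np.random.default_rng(int(seed))
    for attempt in range(50):
        design = SimulationDesign(
            n_respondents=n_respondents,
            bank=random_bank(n_base_items, 5, rng_bank, a_range=(1.0, 2.2)),
            covariates=preset.covariates, seed=int(seed) + attempt * 7919)
        data, theta = simulate_responses(design)
        R = data.to_frame().corr().to_numpy()
        np.fill_diagonal(R, 0.0)
        if R.max() <= 0.70:
            break
    n = design.n_respondents
    rng = np.random.default_rng(int(seed) + 104729)
    sources = rng.choice(n_base_items, size=n_redundant, replace=False)
    extra_cols, extra_ids, extra_ncat = [], [], []
    for k, s in enumerate(sorted(sources)):
        item = design.bank.items[s]
        src_col = data.values[:, s].astype(int)
        # conditional quantile of the source draw: u | code=c ~ U(cum_{c-1}, cum_c)
        p_src = gpcm_prob(item, theta)  # (m+1, n)
        cum = np.cumsum(p_src, axis=0)
        lo = np.where(src_col > 0, np.take_along_axis(cum, (src_col - 1)[None, :],
                                                      axis=0)[0], 0.0)
        hi = np.take_along_axis(cum, src_col[None, :], axis=0)[0]
        u = lo + rng.random(n) * (hi - lo)
        theta_noisy = theta + rng.normal(0.0, noise_sd, size=n)
        cum_noisy = np.cumsum(gpcm_prob(item, theta_noisy), axis=0)
        copy = (u[None, :] > cum_noisy).sum(axis=0).astype(float)
        extra_cols.append(copy)
        extra_ids.append(f"R{k + 1}_{item.item_id}")
        extra_ncat.append(item.n_categories)
    values = np.column_stack([data.values] + extra_cols)
    out = ResponseMatrix(values=values, item_ids=data.item_ids + extra_ids,
                         covariates=data.covariates,
                         n_categories=data.n_categories + extra_ncat)
    return out, theta, extra_ids
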