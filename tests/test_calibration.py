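"""GPCM probabilities, EM calibration, EAP scoring, item fit, information."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from premcat.databank import GpcmItem, ItemBank, ScoreTransform
from premcat.calibration import (
    QuadratureGrid, eap_score, eap_score_matrix, expected_score, fit_gpcm,
    gpcm_prob, infit_outfit, information, item_information,
    likelihood_ratio_test, transform_score,
)
from premcat.simulate import paper_like_design, simulate_responses

from conftest import make_matrix


def brute_force_gpcm(a, b, theta):
    """Direct unstabilized evaluation of the GPCM category probabilities."""
    s = [0.0]
    for bv in b:
        s.append(s[-1] + a * (theta - bv))
    e = [math.exp(v) for v in s]
    return np.array(e) / sum(e)


class TestGpcmProb:
    def test_matches_brute_force(self):
        item = GpcmItem("X", 1.7, (-1.2, -0.4, 0.3, 1.1))
        assert np.allclose(gpcm_prob(item, 0.0),
                           brute_force_gpcm(1.7, item.b, 0.0), atol=1e-14)

    def test_two_category_symmetry_at_threshold(self):
        item = GpcmItem("X", 2.0, (0.7,))
        assert np.allclose(gpcm_prob(item, 0.7), [0.5, 0.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0.2, 3.0), st.lists(st.floats(-3, 3), min_size=1, max_size=4),
           st.floats(-6, 6))
    def test_probabilities_sum_to_one(self, a, b, theta):
        p = gpcm_prob(GpcmItem("X", a, tuple(b)), theta)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_no_overflow_at_extreme_logits(self):
        item = GpcmItem("X", 100.0, (-3.0, 0.0, 3.0))
        p = gpcm_prob(item, 7.0)  # |a * theta| = 700
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestEap:
    def test_empty_response_returns_prior(self, small_bank):
        est = eap_score({}, small_bank)
        assert est.theta == pytest.approx(0.0, abs=1e-6)
        assert est.se == pytest.approx(1.0, abs=1e-6)
        assert est.n_items_used == 0

    def test_all_top_above_all_bottom(self, study_design):
        bank = study_design.bank
        top = eap_score([it.n_categories - 1 for it in bank.items], bank)
        bottom = eap_score([0] * len(bank), bank)
        assert top.theta > bottom.theta
        assert top.se < 1.0 and bottom.se < 1.0

    def test_matches_dense_trapezoid_integration(self, small_bank):
        responses = {"A": 1, "B": 2, "C": 3}
        est = eap_score(responses, small_bank)
        # oracle: dense trapezoid integration of the posterior
        t = np.linspace(-6, 6, 10_001)
        from scipy.stats import norm
        post = norm.pdf(t)
        for iid, r in responses.items():
            item = small_bank.item(iid)
            post = post * np.array([gpcm_prob(item, ti)[r] for ti in t])
        post /= np.trapezoid(post, t)
        mean = np.trapezoid(t * post, t)
        sd = np.sqrt(np.trapezoid(t**2 * post, t) - mean**2)
        assert est.theta == pytest.approx(mean, abs=1e-4)
        assert est.se == pytest.approx(sd, abs=1e-4)

    def test_se_decreases_as_items_added(self, study_design):
        rng = np.random.default_rng(0)
        bank = study_design.bank
        for _ in range(100):
            k = rng.integers(1, 19)
            resp = {it.item_id: int(rng.integers(0, 5))
                    for it in rng.choice(bank.items, size=k, replace=False)}
            se_k = eap_score(resp, bank).se
            extra = next(it for it in bank.items if it.item_id not in resp)
            resp2 = dict(resp)
            resp2[extra.item_id] = 2
            assert eap_score(resp2, bank).se < se_k + 1e-9

    def test_matrix_scoring_agrees_with_per_respondent(self, study_design):
        data, _ = simulate_responses(study_design)
        ests = eap_score_matrix(data, study_design.bank)
        for i in (0, 100, 498):
            single = eap_score(dict(zip(data.item_ids, data.values[i])),
                               study_design.bank)
            assert ests[i].theta == pytest.approx(single.theta, abs=1e-10)
            assert ests[i].se == pytest.approx(single.se, abs=1e-10)

    def test_out_of_range_response_errors(self, small_bank):
        with pytest.raises(ValueError, match="out of range"):
            eap_score({"A": 5}, small_bank)


class TestEmCalibration:
    def test_marginal_ll_nondecreasing_and_identities(self):
        design = paper_like_design(seed=2, n_respondents=300, n_items=6)
        data, _ = simulate_responses(design)
        trace = []
        bank, fit = fit_gpcm(data, ll_trace=trace)
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-6)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.n_params)
        assert fit.bic == pytest.approx(
            -2 * fit.log_likelihood + fit.n_params * np.log(fit.n_respondents))

    def test_gpcm_ll_dominates_pcm(self):
        design = paper_like_design(seed=6, n_respondents=300, n_items=6)
        data, _ = simulate_responses(design)
        _, fit_g = fit_gpcm(data)
        bank_p, fit_p = fit_gpcm(data, pcm=True)
        assert fit_g.log_likelihood >= fit_p.log_likelihood - 1e-6
        # PCM constrains to one common discrimination
        a_vals = {round(it.a, 10) for it in bank_p.items}
        assert len(a_vals) == 1
        lrt = likelihood_ratio_test(fit_g, fit_p)
        assert lrt["chi2"] >= 0
        assert lrt["df"] == 5
        assert 0 <= lrt["p"] <= 1

    def test_missing_responses_are_skipped(self):
        design = paper_like_design(seed=12, n_respondents=400, n_items=5,
                                   missing_rate=0.15)
        data, _ = simulate_responses(design)
        bank, fit = fit_gpcm(data)
        assert fit.converged
        assert all(0.05 < it.a < 10 for it in bank.items)

    def test_small_sample_errors(self):
        design = paper_like_design(seed=0, n_respondents=30, n_items=4)
        data, _ = simulate_responses(design)
        with pytest.raises(ValueError, match="at least 50"):
            fit_gpcm(data)


class TestItemFit:
    def test_null_data_infit_near_one(self, study_design, study_data,
                                      study_thetas):
        data, _ = study_data
        fits = infit_outfit(data, study_design.bank, study_thetas)
        vals = np.array(list(fits.infit.values()))
        assert np.mean((vals > 0.8) & (vals < 1.2)) >= 0.9

    def test_random_item_has_high_outfit(self, study_design, study_data):
        data, _ = study_data
        rng = np.random.default_rng(3)
        vals = data.values.copy()
        vals[:, 4] = rng.integers(0, 5, size=len(vals))
        noisy = make_matrix(vals, item_ids=data.item_ids)
        thetas = eap_score_matrix(noisy, study_design.bank)
        fits = infit_outfit(noisy, study_design.bank, thetas)
        assert fits.outfit[data.item_ids[4]] > 1.3

    def test_overfitted_deterministic_item_infit_below_one(self):
        # near-deterministic item: responses follow the model expectation
        design = paper_like_design(seed=13, n_respondents=400, n_items=4)
        data, theta = simulate_responses(design)
        sharp = GpcmItem("sharp", 6.0, (-1.0, -0.3, 0.4, 1.0))
        vals = np.column_stack([
            data.values,
            np.argmax(gpcm_prob(sharp, theta), axis=0).astype(float),
        ])
        aug = make_matrix(vals, item_ids=data.item_ids + ["sharp"])
        bank = ItemBank(design.bank.items + [sharp])
        thetas = eap_score_matrix(aug, bank)
        fits = infit_outfit(aug, bank, thetas)
        assert fits.infit["sharp"] < 1.0


class TestInformation:
    def test_tails_vanish(self, study_design):
        item = GpcmItem("X", 1.7, (-1.2, -0.4, 0.3, 1.1))
        curve = information(ItemBank([item]))
        arr = curve.item_information["X"]
        assert arr[0] < 1e-3 * arr.max() and arr[-1] < 1e-3 * arr.max()
        # weakly discriminating items (a ~ 1.2) decay like exp(-a|theta-b|)
        # and so carry a few percent of peak at the grid edge, no more
        full = information(study_design.bank)
        for a in full.item_information.values():
            assert a[0] < 0.05 * a.max() and a[-1] < 0.05 * a.max()

    def test_matches_fisher_information_oracle(self):
        # I(theta) = -E[d^2/dtheta^2 log P_K(theta)], by finite differences
        item = GpcmItem("X", 1.7, (-1.2, -0.4, 0.3, 1.1))
        for theta in (-1.0, 0.0, 0.8):
            h = 1e-4
            oracle = 0.0
            p0 = gpcm_prob(item, theta)
            for k in range(item.n_categories):
                lp = [math.log(gpcm_prob(item, theta + d)[k])
                      for d in (-h, 0.0, h)]
                d2 = (lp[0] - 2 * lp[1] + lp[2]) / h**2
                oracle -= p0[k] * d2
            assert item_information(item, theta) == pytest.approx(oracle, abs=1e-5)

    def test_test_information_is_sum_of_items(self, study_design):
        curve = information(study_design.bank)
        total = np.sum(list(curve.item_information.values()), axis=0)
        assert np.allclose(curve.test_information, total)

    def test_most_informative_item_has_high_a_central_thresholds(self):
        items = [
            GpcmItem("strong_central", 2.6, (-1.0, -0.3, 0.3, 1.0)),
            GpcmItem("weak_central", 1.1, (-1.0, -0.3, 0.3, 1.0)),
            GpcmItem("strong_offset", 2.6, (1.5, 2.0, 2.5, 3.0)),
        ]
        bank = ItemBank(items)
        curve = information(bank)
        areas = {iid: np.trapezoid(arr, curve.grid)
                 for iid, arr in curve.item_information.items()}
        center = {iid: float(np.interp(0.0, curve.grid, arr))
                  for iid, arr in curve.item_information.items()}
        assert max(center, key=center.get) == "strong_central"
        assert areas["strong_central"] > areas["weak_central"]

    def test_share_in_central_range_exceeds_half(self, study_design):
        curve = information(study_design.bank)
        assert curve.share_in(-2, 2) > 50.0


class TestTransform:
    @pytest.mark.parametrize("theta,expected", [(0.0, 50.0), (-4.0, 0.0),
                                                (4.0, 100.0), (6.0, 100.0),
                                                (-7.0, 0.0)])
    def test_default_map(self, theta, expected):
        assert transform_score(theta) == pytest.approx(expected)

    def test_monotone(self):
        t = ScoreTransform()
        xs = np.linspace(-5, 5, 41)
        ys = [t.apply(x) for x in xs]
        assert all(y2 >= y1 for y1, y2 in zip(ys, ys[1:]))
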