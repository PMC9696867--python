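"""Response/bank I/O, redundancy screening, alpha, and category recoding."""

import logging

import numpy as np
import pytest

from premcat.databank import (
    GpcmItem, ItemBank, ScoreTransform, cronbach_alpha, read_bank,
    read_responses, recode_categories, screen_items, write_bank,
)
from premcat.simulate import paper_like_design, simulate_redundant_dataset, \
    simulate_responses

from conftest import make_matrix


class TestResponseCsv:
    def _write(self, tmp_path, text):
        p = tmp_path / "r.csv"
        p.write_text(text)
        return p

    def test_codes_and_missing(self, tmp_path):
        p = self._write(tmp_path, "I1,I2\n0,4\nNA,2\n3,\n")
        data = read_responses(p, item_columns=["I1", "I2"])
        assert np.isnan(data.values[1, 0]) and np.isnan(data.values[2, 1])
        assert data.values[0, 1] == 4
        assert np.isnan(data.values).sum() == 2

    def test_likert_labels_map_to_codes(self, tmp_path):
        p = self._write(tmp_path, "I1\nstrongly agree\nStrongly Disagree\n"
                                  "not applicable\n")
        data = read_responses(p, item_columns=["I1"])
        assert data.values[0, 0] == 4
        assert data.values[1, 0] == 0
        assert np.isnan(data.values[2, 0])

    def test_out_of_range_code_errors(self, tmp_path):
        p = self._write(tmp_path, "I1\n7\n")
        with pytest.raises(ValueError, match="out of range"):
            read_responses(p, item_columns=["I1"])

    def test_unknown_label_names_row_and_column(self, tmp_path):
        p = self._write(tmp_path, "I1\nmaybe\n")
        with pytest.raises(ValueError, match=r"row 0, column 'I1'"):
            read_responses(p, item_columns=["I1"])

    def test_duplicate_ids_error(self, tmp_path):
        p = self._write(tmp_path, "pid,I1\nx,1\nx,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_responses(p, item_columns=["I1"], id_column="pid")

    def test_covariates_kept_untouched(self, tmp_path):
        p = self._write(tmp_path, "I1,sex\n2,female\n3,male\n")
        data = read_responses(p, item_columns=["I1"], covariate_columns=["sex"])
        assert list(data.covariates["sex"]) == ["female", "male"]


class TestBankJson:
    def test_round_trip_lossless(self, tmp_path):
        design = paper_like_design(seed=3)
        path = tmp_path / "bank.json"
        write_bank(design.bank, path)
        back = read_bank(path)
        assert back.item_ids == design.bank.item_ids
        for a, b in zip(design.bank.items, back.items):
            assert b.a == pytest.approx(a.a, rel=1e-12)
            assert np.allclose(b.b, a.b, rtol=1e-12)
        assert back.transform == design.bank.transform

    def test_negative_discrimination_rejected(self):
        with pytest.raises(ValueError, match="discrimination"):
            GpcmItem("A", -0.5, (0.0,))

    def test_malformed_bank_errors(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"items": [{"id": "A", "b": [0.1]}]}')
        with pytest.raises(ValueError, match="malformed"):
            read_bank(p)

    def test_missing_transform_defaults_with_warning(self, tmp_path, caplog):
        p = tmp_path / "b.json"
        p.write_text('{"items": [{"id": "A", "a": 1.0, "b": [0.0]}]}')
        with caplog.at_level(logging.WARNING, logger="premcat.databank"):
            bank = read_bank(p)
        assert bank.transform == ScoreTransform()
        assert any("transform" in rec.message for rec in caplog.records)

    def test_duplicate_item_ids_rejected(self):
        it = GpcmItem("A", 1.0, (0.0,))
        with pytest.raises(ValueError, match="unique"):
            ItemBank([it, it])


class TestScreening:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=200).astype(float)
        y = rng.integers(0, 5, size=200).astype(float)
        data = make_matrix(np.column_stack([x, x, y]))
        rep = screen_items(data)
        assert len(rep.removed_items) == 1
        assert rep.removed_items[0][0] in ("I1", "I2")
        assert "r > 0.70" in rep.removed_items[0][1]

    def test_planted_redundancy_removes_one_of_each_pair(self):
        # a 0.3-noise copy and its source are near-interchangeable, so the
        # screen must drop exactly one member of each planted pair
        data, _, copies = simulate_redundant_dataset(seed=11)
        rep = screen_items(data)
        removed = [i for i, _ in rep.removed_items]
        assert len(removed) == len(copies) == 6
        assert len(rep.surviving_items) == 19
        for copy in copies:
            source = copy.split("_", 1)[1]
            assert (copy in removed) != (source in removed)
        # brute-force confirmation: no surviving pair exceeds the ceiling
        sub = rep.correlations.loc[rep.surviving_items, rep.surviving_items]
        off = sub.to_numpy()[~np.eye(len(sub), dtype=bool)]
        assert np.nanmax(off) <= 0.70

    def test_independent_items_kept(self):
        rng = np.random.default_rng(1)
        data = make_matrix(rng.integers(0, 5, size=(300, 6)).astype(float))
        rep = screen_items(data)
        assert rep.removed_items == []

    def test_screening_idempotent(self):
        data, _, _ = simulate_redundant_dataset(seed=4)
        rep = screen_items(data)
        again = screen_items(data.subset_items(rep.surviving_items))
        assert again.removed_items == []

    def test_zero_variance_item_flagged(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 5, size=(100, 3)).astype(float)
        vals[:, 1] = 2.0
        rep = screen_items(make_matrix(vals))
        assert ("I2", "zero variance") in rep.removed_items

    def test_correlation_matrix_symmetric_unit_diagonal(self, study_data):
        data, _ = study_data
        rep = screen_items(data)
        R = rep.correlations.to_numpy()
        assert np.allclose(R, R.T, equal_nan=True)
        assert np.allclose(np.diag(R), 1.0)


class TestCronbachAlpha:
    def test_parallel_items_closed_form(self):
        # k items with equal variance v and covariance c:
        # alpha = k c / (v + (k-1) c)
        rng = np.random.default_rng(3)
        k, n = 6, 100000
        common = rng.standard_normal(n)
        vals = np.column_stack([common + rng.standard_normal(n) for _ in range(k)])
        data = make_matrix(np.clip(np.round(vals + 2), 0, 4))
        df = data.to_frame()
        cov = df.cov().to_numpy()
        v = np.diag(cov).mean()
        c = cov[~np.eye(k, dtype=bool)].mean()
        expected = k * c / (v + (k - 1) * c)
        assert cronbach_alpha(data) == pytest.approx(expected, abs=0.01)

    def test_matches_textbook_formula_on_simulated_bank(self, study_data):
        data, _ = study_data
        df = data.to_frame().dropna()
        k = data.n_items
        oracle = k / (k - 1) * (1 - df.var(ddof=1).sum() / df.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(data) == pytest.approx(oracle, abs=0.03)

    def test_reversing_an_item_decreases_alpha(self, study_data):
        data, _ = study_data
        a0 = cronbach_alpha(data)
        flipped = data.values.copy()
        flipped[:, 0] = 4 - flipped[:, 0]
        a1 = cronbach_alpha(make_matrix(flipped, item_ids=data.item_ids))
        assert a1 < a0

    def test_invariant_to_constant_shift_of_one_item(self, study_data):
        # shifting every code on one item by +2 leaves alpha unchanged
        data, _ = study_data
        shifted = data.values.copy()
        shifted[:, 3] += 2
        d2 = make_matrix(shifted, item_ids=data.item_ids,
                         n_categories=[7 if j == 3 else 5 for j in range(19)])
        assert cronbach_alpha(d2) == pytest.approx(cronbach_alpha(data), abs=1e-12)

    def test_zero_total_variance_errors(self):
        data = make_matrix(np.ones((10, 3)) * 2)
        with pytest.raises(ValueError):
            cronbach_alpha(data)


class TestRecode:
    def test_sparse_middle_category_merged(self):
        counts = [200, 150, 3, 80, 66]
        col = np.concatenate([np.full(c, k) for k, c in enumerate(counts)])
        data = make_matrix(col[:, None].astype(float))
        out, cmap = recode_categories(data, min_count=10)
        assert out.n_categories == [4]
        assert cmap["I1"][2] == cmap["I1"][3]  # merged with the sparser side
        obs = out.values[~np.isnan(out.values)]
        assert sorted(np.unique(obs)) == [0, 1, 2, 3]

    def test_identity_when_all_categories_frequent(self, study_data):
        data, _ = study_data
        out, cmap = recode_categories(data, min_count=5)
        for iid, mapping in cmap.items():
            if len(set(mapping.values())) == len(mapping):
                assert mapping == {k: k for k in mapping}
        # the study-like design has well-populated categories at n = 499
        assert np.nansum(np.abs(out.values - data.values)) == 0

    def test_collapse_below_two_categories_errors(self):
        col = np.array([0.0] * 99 + [1.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            recode_categories(make_matrix(col[:, None]), min_count=10)

    def test_manual_map_override(self):
        col = np.array([0, 1, 2, 3, 4] * 40, dtype=float)
        data = make_matrix(col[:, None])
        out, cmap = recode_categories(data, manual_map={"I1": {0: 0, 1: 0, 2: 1,
                                                               3: 1, 4: 2}})
        assert out.n_categories == [3]
        assert cmap["I1"] == {0: 0, 1: 0, 2: 1, 3: 1, 4: 2}

    def test_collapsing_dead_category_improves_aic(self):
        # an item whose category 2 is never reachable wastes one threshold
        from premcat.calibration import fit_gpcm
        design = paper_like_design(seed=9, n_respondents=400, n_items=5)
        data, _ = simulate_responses(design)
        # plant a dead category on item 0: codes >= 2 shifted up by one
        vals = data.values.copy()
        vals[:, 0] = np.where(vals[:, 0] >= 2, vals[:, 0] + 1, vals[:, 0])
        raw = make_matrix(vals, item_ids=data.item_ids,
                          n_categories=[6, 5, 5, 5, 5])
        collapsed, _ = recode_categories(raw, min_count=10)
        _, fit_raw = fit_gpcm(raw)
        _, fit_col = fit_gpcm(collapsed)
        assert fit_col.aic <= fit_raw.aic
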