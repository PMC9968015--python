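"""Selectivity scores, dye-dye correlation, and panel selection rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from optonose import (
    SensorPanel,
    DyeFormulation,
    dye_correlation_matrix,
    select_panel,
    selectivity_scores,
)
from optonose.response import ResponseVector, SensitivityMatrix
from optonose.screening import CorrelationResult, SelectivityScores, percentage_gains


def _matrix(values, dyes=None, gases=None):
    values = np.asarray(values, dtype=float)
    dyes = dyes or [f"D{i}" for i in range(values.shape[0])]
    gases = gases or [f"g{j}" for j in range(values.shape[1])]
    return SensitivityMatrix(
        dyes=dyes, gases=gases, values=values,
        replicate_counts=np.ones(values.shape, dtype=int),
    )


class TestSelectivityScores:
    def test_flat_dye_has_zero_deviations(self):
        s = selectivity_scores(_matrix([[10.0, 10.0, 10.0]]))
        assert np.allclose(s.deviations, 0)

    def test_single_peak_deviation(self):
        s = selectivity_scores(_matrix([[30.0, 0.0, 0.0]]))
        assert np.allclose(s.deviations, [[20.0, -10.0, -10.0]])

    @given(arrays(float, (5, 4), elements=st.floats(0, 100)))
    def test_row_sums_vanish(self, values):
        s = selectivity_scores(_matrix(values))
        assert np.allclose(s.deviations.sum(axis=1), 0, atol=1e-9)

    def test_missing_cells_listed(self):
        S = _matrix([[1.0, 2.0]])
        S.replicate_counts[0, 1] = 0
        with pytest.raises(ValueError, match="missing"):
            selectivity_scores(S)


def _response_set(X, panel):
    return [
        ResponseVector(panel_id=panel.panel_id, gas_id="g", concentration=1.0,
                       replicate=i, distances=row)
        for i, row in enumerate(X)
    ]


class TestCorrelation:
    def _panel(self, n):
        return SensorPanel("P1", tuple(DyeFormulation(f"D{i}") for i in range(n)))

    def test_identical_profiles_correlate_perfectly(self, rng):
        x = rng.uniform(0, 50, 10)
        panel = self._panel(2)
        res = dye_correlation_matrix(_response_set(np.c_[x, x], panel), panel)
        assert res.matrix[0, 1] == pytest.approx(1.0)

    def test_affine_negation_correlates_minus_one(self, rng):
        x = rng.uniform(0, 50, 10)
        panel = self._panel(2)
        res = dye_correlation_matrix(_response_set(np.c_[x, 100 - 2 * x], panel), panel)
        assert res.matrix[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_oracle(self, rng):
        X = rng.uniform(0, 50, (12, 4))
        panel = self._panel(4)
        res = dye_correlation_matrix(_response_set(X, panel), panel)
        n = X.shape[0]
        for i in range(4):
            for j in range(4):
                # explicit summation formula
                sx, sy = X[:, i].sum(), X[:, j].sum()
                sxy = (X[:, i] * X[:, j]).sum()
                sxx, syy = (X[:, i] ** 2).sum(), (X[:, j] ** 2).sum()
                r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
                assert res.matrix[i, j] == pytest.approx(r, abs=1e-9)
        assert np.allclose(res.matrix, res.matrix.T)
        assert np.allclose(np.diag(res.matrix), 1.0)

    def test_zero_variance_dye_flagged_not_propagated(self, rng):
        X = np.c_[rng.uniform(0, 50, 5), np.full(5, 7.0)]
        panel = self._panel(2)
        res = dye_correlation_matrix(_response_set(X, panel), panel)
        assert res.undefined_dyes == ["D1"]
        assert np.isnan(res.matrix[0, 1]) and res.matrix[1, 1] == 1.0

    def test_too_few_observations_rejected(self, rng):
        panel = self._panel(2)
        with pytest.raises(ValueError, match="at least 3"):
            dye_correlation_matrix(_response_set(rng.uniform(0, 1, (2, 2)), panel), panel)


def _scores(deviations, dyes, gases):
    return SelectivityScores(dyes=dyes, gases=gases, deviations=np.asarray(deviations, float))


def _no_corr(dyes):
    return CorrelationResult(dyes=dyes, matrix=np.eye(len(dyes)))


class TestSelectPanel:
    gases = ["hexenal", "water", "ethanol"]

    def test_top_target_dyes_selected_in_order(self):
        dyes = ["D1", "D2", "D3", "D4", "D5"]
        dev = [
            [9.0, -5.0, -4.0],
            [8.0, -5.0, -3.0],
            [7.0, -5.0, -2.0],
            [1.0, -2.0, 1.0],
            [0.5, -2.0, 1.5],
        ]
        sel = select_panel(_scores(dev, dyes, self.gases), _no_corr(dyes), "hexenal", "water")
        assert sel.selected[:3] == [("D1", "hexenal"), ("D2", "hexenal"), ("D3", "hexenal")]
        assert ("D5", "ethanol") in sel.selected

    def test_water_sensitive_dye_excluded_despite_high_sensitivity(self):
        # D1's top deviation is for water: excluded even though it ranks first
        # for ethanol among all dyes
        dyes = ["D1", "D2", "D3", "D4", "D5"]
        dev = [
            [-10.0, 30.0, 20.0],
            [6.0, -3.0, -3.0],
            [5.0, -3.0, -2.0],
            [4.0, -2.0, -2.0],
            [-1.0, -1.0, 2.0],
        ]
        sel = select_panel(_scores(dev, dyes, self.gases), _no_corr(dyes), "hexenal", "water")
        assert sel.excluded_water_sensitive == ["D1"]
        assert "D1" not in sel.selected_dyes
        assert ("D5", "ethanol") in sel.selected

    def test_duplicate_dye_excluded_by_correlation(self):
        dyes = ["A", "B", "Bdup", "C", "E"]
        dev = [
            [9.0, -5.0, -4.0],  # target pick
            [1.0, -3.0, 2.0],   # best ethanol
            [0.9, -3.0, 1.9],   # duplicate of B
            [0.5, -1.0, 0.5],
            [0.1, -0.2, 0.1],
        ]
        corr = np.eye(5)
        corr[1, 2] = corr[2, 1] = 1.0
        sel = select_panel(
            _scores(dev, dyes, self.gases),
            CorrelationResult(dyes=dyes, matrix=corr),
            "hexenal", "water", n_target_dyes=1, corr_threshold=0.95, panel_size=2,
        )
        assert ("B", "ethanol") in sel.selected
        # raise panel size so the duplicate would be reconsidered
        sel2 = select_panel(
            _scores(dev, dyes, self.gases),
            CorrelationResult(dyes=dyes, matrix=corr),
            "hexenal", "water", n_target_dyes=2, corr_threshold=0.95,
        )
        assert ("Bdup", "B", 1.0) in sel2.excluded_correlated
        assert "Bdup" not in sel2.selected_dyes

    def test_partial_panel_warns_instead_of_padding(self):
        dyes = ["A", "B"]
        dev = [[5.0, -3.0, -2.0], [4.0, -2.0, -2.0]]
        sel = select_panel(_scores(dev, dyes, self.gases), _no_corr(dyes), "hexenal", "water")
        assert sel.warning is not None
        assert len(sel.selected) == 2

    def test_raising_threshold_never_removes_prior_selection(self):
        dyes = ["A", "B", "Bdup", "C", "E"]
        dev = [
            [9.0, -5.0, -4.0],
            [1.0, -3.0, 2.0],
            [0.9, -3.0, 1.9],
            [0.5, -1.0, 0.5],
            [0.1, -0.2, 0.1],
        ]
        corr = np.eye(5)
        corr[1, 2] = corr[2, 1] = 0.97
        args = (_scores(dev, dyes, self.gases), CorrelationResult(dyes=dyes, matrix=corr))
        low = select_panel(*args, "hexenal", "water", corr_threshold=0.9)
        high = select_panel(*args, "hexenal", "water", corr_threshold=0.99)
        assert set(low.selected_dyes) <= set(high.selected_dyes)

    def test_selection_invariant_to_dye_input_order(self, rng):
        dyes = [f"D{i}" for i in range(6)]
        dev = rng.normal(0, 3, (6, 3))
        dev -= dev.mean(axis=1, keepdims=True)
        base = select_panel(_scores(dev, dyes, self.gases), _no_corr(dyes), "hexenal", "water")
        perm = rng.permutation(6)
        shuffled = select_panel(
            _scores(dev[perm], [dyes[i] for i in perm], self.gases),
            _no_corr([dyes[i] for i in perm]), "hexenal", "water",
        )
        assert base.selected == shuffled.selected


def test_percentage_gain_conventions_are_both_reported():
    S = _matrix([[30.0, 10.0, 20.0]])
    gains = percentage_gains(S)
    assert gains["above_average"][0, 0] == pytest.approx((30 - 20) / 20 * 100)
    assert gains["of_average"][0, 0] == pytest.approx(30 / 20 * 100)
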