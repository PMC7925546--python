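"""Response-matrix construction, the interaction index and its identities,
and cross-signal linear pattern prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaidgamma import (ContrastGrid, MatrixGroundTruth, ResponseMatrix,
                        additive_prediction, build_matrix,
                        generate_response_matrix, interaction_index,
                        linear_predict_pattern)


def _matrix(values, grid, **kw):
    return ResponseMatrix(np.asarray(values, dtype=float), grid, **kw)


class TestBuildMatrix:
    def test_single_trial_identity(self, grid, rng):
        vals = rng.uniform(1, 5, size=(1, 7, 7))
        mat = build_matrix(vals, grid)
        np.testing.assert_array_equal(mat.values, vals[0])

    def test_normalization_divides_by_maximum(self, grid, rng):
        vals = rng.uniform(1, 3, size=(4, 7, 7))
        vals[0, 3, 3] = 4.0
        raw = build_matrix(vals, grid)
        norm = build_matrix(vals, grid, normalize=True)
        np.testing.assert_allclose(norm.values, raw.values / raw.values.max())
        assert norm.values.max() == pytest.approx(1.0)

    def test_missing_condition_reported(self, grid):
        vals = np.ones((2, 7, 7))
        vals[:, 2, 3] = np.nan
        with pytest.raises(ValueError, match="no trials"):
            build_matrix(vals, grid)

    def test_cell_standard_error_matches_clt(self, grid):
        # CV 0.1 with 10 trials: sd of the cell mean is 0.1/sqrt(10) = 0.0316
        # of the true mean
        gt = MatrixGroundTruth(Rmax=1.0, c50=0.2, m1=2.0, m2=1.5, b=0.6,
                               R0=0.2, noise_cv=0.1, n_trials=10)
        cells = []
        ref = generate_response_matrix(
            MatrixGroundTruth(**{**gt.__dict__, "noise_cv": 0.0}), grid, seed=0)
        for seed in range(300):
            m = generate_response_matrix(gt, grid, seed=seed)
            cells.append(m.values[6, 6])
        rel_se = np.std(cells) / ref.values[6, 6]
        assert rel_se == pytest.approx(0.1 / np.sqrt(10), rel=0.15)


class TestInteractionIndex:
    def test_additive_matrix_gives_zero(self, grid, rng):
        # M1(c1,c2) = a(c1) + b(c2) - const satisfies the additive
        # prediction exactly, so the index vanishes
        a = np.sort(rng.uniform(1, 4, size=7))
        b = np.sort(rng.uniform(1, 4, size=7))
        vals = a[:, None] + b[None, :] - 0.7
        res = interaction_index(_matrix(vals, grid))
        assert res.index == pytest.approx(0.0, abs=1e-13)
        np.testing.assert_allclose(res.prediction, vals, rtol=1e-13)

    def test_half_prediction_gives_minus_two_thirds(self, grid, rng):
        a = np.sort(rng.uniform(1, 4, size=7))
        b = np.sort(rng.uniform(1, 4, size=7))
        vals = a[:, None] + b[None, :] - 0.7
        vals[1:, 1:] = 0.5 * vals[1:, 1:]   # plaid block at half its prediction
        assert interaction_index(_matrix(vals, grid)).index == pytest.approx(-2.0 / 3.0)

    def test_double_prediction_gives_plus_two_thirds(self, grid, rng):
        a = np.sort(rng.uniform(1, 4, size=7))
        vals = a[:, None] + a[None, :] - 0.9
        vals[1:, 1:] = 2.0 * vals[1:, 1:]
        assert interaction_index(_matrix(vals, grid)).index == pytest.approx(2.0 / 3.0)

    def test_scale_invariance_to_machine_precision(self, grid, rng):
        vals = rng.uniform(0.5, 5.0, size=(7, 7))
        base = interaction_index(_matrix(vals, grid)).index
        scaled = interaction_index(_matrix(1e3 * vals, grid)).index
        assert scaled == pytest.approx(base, rel=1e-14)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_index_bounded_when_both_sums_positive(self, seed):
        grid = ContrastGrid()
        vals = np.random.default_rng(seed).uniform(0.1, 10.0, size=(7, 7))
        res = interaction_index(_matrix(vals, grid))
        if res.prediction[1:, 1:].sum() > 0:  # bound holds when both sums are positive
            assert -2.0 < res.index < 2.0

    def test_caption_variant_differs_by_offset_handling(self, grid, rng):
        vals = rng.uniform(1.0, 5.0, size=(7, 7))
        methods = additive_prediction(vals, "methods")
        caption = additive_prediction(vals, "caption")
        np.testing.assert_allclose(caption - methods, vals[0, 0])

    def test_strong_normalization_yields_suppression(self, grid, rng):
        # denominator exponent at least the numerator's: the plaid block
        # falls below the additive prediction, giving a negative index
        neg = 0
        draws = 40
        for seed in range(draws):
            gt = MatrixGroundTruth(
                Rmax=1.0, c50=float(rng.uniform(0.1, 0.4)),
                m1=float(rng.uniform(1.2, 2.0)), m2=float(rng.uniform(2.0, 3.0)),
                b=float(rng.uniform(0.3, 0.7)), R0=0.02, noise_cv=0.1)
            mat = generate_response_matrix(gt, grid, seed=seed)
            neg += interaction_index(mat).index < 0
        assert neg >= 0.95 * draws

    def test_bootstrap_p_for_suppressed_site(self, grid):
        gt = MatrixGroundTruth(m1=1.5, m2=2.5, c50=0.2, b=0.5, R0=0.02,
                               noise_cv=0.1, n_trials=10)
        mat = generate_response_matrix(gt, grid, seed=0)
        res = interaction_index(mat, bootstrap_B=200, seed=1)
        assert res.p is not None and res.p < 0.05


class TestLinearPrediction:
    def test_exact_affine_relation_recovered(self, grid, rng):
        src = _matrix(rng.uniform(1, 5, size=(7, 7)), grid, signal="MUA")
        tgt = _matrix(2.0 * src.values + 1.0, grid, signal="LG")
        res = linear_predict_pattern(src, tgt)
        assert res.gof == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_independent_target_explains_nothing(self, grid, rng):
        gofs = []
        for _ in range(100):
            src = _matrix(rng.uniform(1, 5, size=(7, 7)), grid)
            tgt = _matrix(rng.uniform(1, 5, size=(7, 7)), grid)
            gofs.append(linear_predict_pattern(src, tgt).gof)
        assert np.mean(gofs) == pytest.approx(0.0, abs=0.05)

    def test_variance_fraction_decomposition(self, grid, rng):
        # target = source + orthogonalized residual carrying a known
        # fraction v of the target variance: gof is about 1 - v
        v = 0.3
        src_vals = rng.normal(3.0, 1.0, size=(7, 7))
        resid = rng.normal(0.0, 1.0, size=(7, 7))
        s = src_vals - src_vals.mean()
        resid = resid - resid.mean() - (resid.ravel() @ s.ravel()) / (s.ravel() @ s.ravel()) * s
        resid *= np.sqrt(v / (1 - v)) * s.std() / resid.std()
        tgt = _matrix(src_vals + resid, grid)
        res = linear_predict_pattern(_matrix(src_vals, grid), tgt)
        assert res.gof == pytest.approx(1.0 - v, abs=0.02)

    def test_constant_target_flagged(self, grid, rng):
        src = _matrix(rng.uniform(1, 5, size=(7, 7)), grid)
        with pytest.raises(ZeroDivisionError):
            linear_predict_pattern(src, _matrix(np.ones((7, 7)), grid))
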