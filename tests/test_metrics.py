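"""Temporal decomposition, item measures, order scores: oracles and laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episcale import (decompose, expanding_windows, item_measures,
                      order_score, score_association, score_recognition,
                      windowed_between_measures)
from episcale.metrics import FIXED4_WINDOWS, _closest_residuals


def grid_search_alignment(true, recalled, resolution=1e-4):
    """Independent brute-force oracle: find (shift, scale) applied to the
    recalled pattern that minimize the identity-correspondence RMSD to the
    true pattern, by iterative grid refinement down to ``resolution``."""
    true = np.asarray(true, float)
    rec = np.asarray(recalled, float)
    shift_c, scale_c = 0.0, 1.0
    shift_w, scale_w = 20.0, 3.0
    while max(shift_w, scale_w) > resolution / 4:
        shifts = shift_c + np.linspace(-shift_w, shift_w, 41)
        scales = np.maximum(scale_c + np.linspace(-scale_w, scale_w, 41), 1e-6)
        # aligned = scale * (rec - mean) + mean + shift, all combinations
        centered = rec - rec.mean()
        al = (scales[:, None, None] * centered[None, None, :]
              + rec.mean() + shifts[None, :, None])
        err = ((al - true[None, None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(err), err.shape)
        scale_c, shift_c = scales[i], shifts[j]
        shift_w /= 10.0
        scale_w /= 10.0
    return shift_c, scale_c


class TestDecompose:
    def test_identity_is_neutral(self):
        t = np.array([1.0, 2.3, 4.1, 7.0, 10.5])
        dec = decompose(t, t, bounds=(0, 16))
        assert dec.translation == pytest.approx(0.0)
        assert dec.scaling == pytest.approx(1.0)
        assert dec.pattern_score == pytest.approx(0.0, abs=1e-12)
        assert dec.scaling_compr == 0.0 and dec.scaling_exp == 0.0

    def test_pure_shift_absorbed_by_translation(self):
        t = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        dec = decompose(t, t + 1.2)
        assert abs(dec.translation) == pytest.approx(1.2)
        assert dec.scaling == pytest.approx(1.0)
        assert dec.pattern_score == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("b", [0.25, 0.5, 0.7, 1.0, 1.3, 2.0, 4.0])
    def test_affine_scale_law(self, b):
        """recalled = centroid + b (true - centroid) => scaling == b."""
        t = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        r = t.mean() + b * (t - t.mean())
        dec = decompose(t, r)
        assert dec.scaling == pytest.approx(b, abs=1e-12)
        assert dec.translation == pytest.approx(0.0, abs=1e-12)
        assert dec.pattern_score == pytest.approx(0.0, abs=1e-10)
        if b < 1:
            assert dec.scaling_compr == pytest.approx(1 - b)
            assert dec.scaling_exp == 0.0
        elif b > 1:
            assert dec.scaling_exp == pytest.approx(b - 1)
            assert dec.scaling_compr == 0.0

    def test_worked_case_matches_grid_oracle(self):
        t = (1.0, 2.0, 4.0, 7.0, 11.0)
        r = (1.1, 2.3, 3.6, 7.4, 10.6)
        shift, scale = grid_search_alignment(t, r)
        dec = decompose(t, r)
        # decompose reports translation = -(applied shift), scaling = 1/scale
        assert dec.translation == pytest.approx(-shift, abs=1e-3)
        assert dec.scaling == pytest.approx(1.0 / scale, abs=1e-3)

    def test_random_instances_match_grid_oracle(self, rng):
        for _ in range(200):
            t = np.sort(rng.uniform(0, 16, size=5))
            r = np.clip(t + rng.normal(0, 1.0, size=5), 0, 16)
            if np.std(r) < 1e-3:
                continue
            shift, scale = grid_search_alignment(t, r)
            dec = decompose(t, r)
            assert dec.translation == pytest.approx(-shift, abs=5e-3)
            assert dec.scaling == pytest.approx(1.0 / scale, rel=5e-3)

    @given(c=st.floats(-50, 50))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_shift_equivariance(self, c):
        t = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        r = np.array([1.4, 2.2, 3.9, 7.7, 10.2])
        a = decompose(t, r)
        b = decompose(t + c, r + c)
        assert b.translation == pytest.approx(a.translation, abs=1e-9)
        assert b.scaling == pytest.approx(a.scaling, rel=1e-9)
        assert b.pattern_score == pytest.approx(a.pattern_score, abs=1e-8)

    def test_nearest_matching_never_worse_than_identity(self, rng):
        for _ in range(200):
            t = np.sort(rng.uniform(0, 16, size=5))
            aligned = t + rng.normal(0, 2.0, size=5)
            res_near = _closest_residuals(aligned, t)
            assert np.sum(res_near**2) <= np.sum((aligned - t) ** 2) + 1e-12

    def test_noise_weakly_decreases_pattern_score(self, rng):
        t = np.sort(rng.uniform(0, 16, size=5))
        scores = []
        for sd in (0.0, 0.3, 1.0):
            vals = [decompose(t, t + rng.normal(0, sd, 5)).pattern_score
                    for _ in range(300)]
            scores.append(np.mean(vals))
        assert scores[0] >= scores[1] >= scores[2]

    def test_degenerate_zero_spread_flagged(self):
        t = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        dec = decompose(t, np.full(5, 5.0))
        assert dec.degenerate
        assert np.isnan(dec.scaling)
        assert dec.pattern_score <= 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            decompose([1.0], [1.0])
        with pytest.raises(ValueError):
            decompose([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            decompose([1, 2, 3], [1, 2, 99], bounds=(0, 16))


class TestItemMeasures:
    def test_identity(self):
        t = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        im = item_measures(t, t)
        np.testing.assert_allclose(im.item_translation, 0.0)
        np.testing.assert_allclose(im.item_scaling, 1.0)
        np.testing.assert_array_equal(im.order_deviation, 0)

    def test_halved_gaps_give_half_scaling(self):
        t = np.array([0.0, 2.0, 6.0])
        r = np.array([0.0, 1.0, 3.0])   # every local gap halved
        im = item_measures(t, r)
        np.testing.assert_allclose(im.item_scaling, 0.5)
        np.testing.assert_allclose(im.item_scaling_compr, 0.5)
        np.testing.assert_allclose(im.item_scaling_exp, 0.0)

    def test_worked_case_matches_enumeration(self):
        t = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        r = np.array([1.5, 2.2, 5.0, 6.5, 10.0])

        def min_gap(x, i):      # independent enumeration over sorted order
            others = np.sort(x)
            pos = int(np.where(others == x[i])[0][0])
            gaps = []
            if pos > 0:
                gaps.append(others[pos] - others[pos - 1])
            if pos < len(x) - 1:
                gaps.append(others[pos + 1] - others[pos])
            return min(gaps)

        im = item_measures(t, r)
        for i in range(5):
            assert im.item_translation[i] == pytest.approx(abs(r[i] - t[i]))
            assert im.item_scaling[i] == pytest.approx(
                min_gap(r, i) / min_gap(t, i))

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            item_measures([1.0], [2.0])


class TestOrderScore:
    def test_correct_order_zero(self):
        t = np.array([1.0, 3.0, 5.0, 8.0, 12.0])
        dev, mean = order_score(t, t + 0.2)
        assert mean == 0.0

    def test_presented_third_placed_first_scores_two(self):
        """An episode shown 3rd but placed 1st deviates by 2 positions."""
        true_pos = np.arange(1.0, 17.0)          # 16 episodes in true order
        recalled = true_pos.copy()
        # move episode 3 to the front, keeping all other orderings intact
        recalled[2] = 0.5
        dev, _ = order_score(true_pos, recalled)
        assert dev[2] == 2

    def test_full_reversal_of_five(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        dev, mean = order_score(t, t[::-1])
        np.testing.assert_array_equal(dev, [4, 2, 0, 2, 4])
        assert mean == pytest.approx(2.4)


class TestWindows:
    def test_identity_all_windows_neutral(self):
        t = np.linspace(10, 1500, 16)
        out = windowed_between_measures(t, t, FIXED4_WINDOWS)
        assert len(out) == 4
        for dec in out.values():
            assert dec.translation == pytest.approx(0.0)
            assert dec.scaling == pytest.approx(1.0)
            assert dec.pattern_score == pytest.approx(0.0, abs=1e-9)

    def test_expanding_window_count_is_twelve(self):
        wins = expanding_windows(16, start=5)
        assert len(wins) == 12
        assert wins[0] == (1, 5) and wins[-1] == (1, 16)

    def test_window_equals_manual_slice(self, rng):
        t = np.sort(rng.uniform(0, 1500, 16))
        r = np.clip(t + rng.normal(0, 30, 16), 0, 1600)
        out = windowed_between_measures(t, r, [(5, 8)])
        manual = decompose(t[4:8], r[4:8])
        assert out[(5, 8)].scaling == pytest.approx(manual.scaling)
        assert out[(5, 8)].pattern_score == pytest.approx(manual.pattern_score)

    def test_window_out_of_range_rejected(self):
        t = np.arange(16.0)
        with pytest.raises(ValueError):
            windowed_between_measures(t, t, [(0, 4)])
        with pytest.raises(ValueError):
            windowed_between_measures(t, t, [(13, 17)])


class TestRecognitionAssociation:
    def test_all_correct_selector_scores_five(self, rng):
        targets = list(range(100))
        lures = list(range(100, 150))
        counts = score_recognition(targets, targets, lures, rng=rng)
        assert counts.shape == (50,)
        assert np.all(counts == 5)

    def test_all_lure_selector_scores_zero(self, rng):
        targets = list(range(100))
        lures = list(range(100, 150))
        counts = score_recognition(lures, targets, lures, rng=rng)
        assert np.all(counts == 0)

    def test_mixed_selection_matches_hypergeometric_mean(self, rng):
        targets = list(range(20))
        lures = list(range(100, 110))
        counts = score_recognition(targets + lures, targets, lures,
                                   n_draws=4000, rng=rng)
        assert counts.mean() == pytest.approx(5 * 20 / 30, abs=0.08)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            score_recognition([], [1], [2])

    def test_association_scoring(self):
        truth = {(1, e): 100 + e for e in range(1, 17)}
        perfect = score_association(dict(truth), truth)
        assert perfect.correct.sum() == 16
        wrong = score_association({k: -1 for k in truth}, truth)
        assert wrong.correct.sum() == 0
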