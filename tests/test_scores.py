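"""Closed-form cardiac scores: SMFI, WMSI, infarct size, SHG, fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microvasc as mv
from microvasc.phantom import FlowSample
from microvasc.scores import SegmentScoreTable


class TestStandardizedMfi:
    def test_hand_arithmetic_case(self):
        """medians 500/100, FMO SD 50 → (500−100)/(2·50) = 4."""
        fmo = np.array([0.0, 100.0, 200.0])  # median 100, sd 100
        fmo = 100 + 50 * (fmo - 100) / 100   # rescale sd to 50
        sample = FlowSample(events_positive=[400.0, 500.0, 600.0],
                            events_fmo=list(fmo))
        assert mv.standardized_mfi(sample) == pytest.approx(4.0)

    def test_equal_medians_give_zero(self):
        s = FlowSample(events_positive=[99.0, 100.0, 101.0],
                       events_fmo=[90.0, 100.0, 110.0])
        assert mv.standardized_mfi(s) == 0.0

    def test_constant_fmo_raises(self):
        s = FlowSample(events_positive=[1.0, 2.0], events_fmo=[5.0, 5.0])
        with pytest.raises(ValueError, match="degenerate FMO"):
            mv.standardized_mfi(s)

    def test_literal_product_reading_available(self):
        s = FlowSample(events_positive=[400.0, 500.0, 600.0],
                       events_fmo=[50.0, 100.0, 150.0])
        sd = np.std([50.0, 100.0, 150.0], ddof=1)
        assert mv.standardized_mfi(s, literal=True) == pytest.approx(
            400.0 * 2 * sd)

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(-1e3, 1e3), scale=st.floats(0.1, 10))
    def test_shift_invariance_and_inverse_scaling(self, shift, scale):
        rng = np.random.default_rng(0)
        pos = rng.normal(300, 40, 500)
        fmo = rng.normal(100, 20, 500)
        base = mv.standardized_mfi(FlowSample(events_positive=pos,
                                              events_fmo=fmo))
        shifted = mv.standardized_mfi(FlowSample(events_positive=pos + shift,
                                                 events_fmo=fmo + shift))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        mu = fmo.mean()
        spread = mv.standardized_mfi(FlowSample(
            events_positive=pos, events_fmo=mu + scale * (fmo - mu)))
        # widening the FMO spread shrinks the score inversely (medians of
        # the scaled control stay near mu)
        assert spread == pytest.approx(
            (np.median(pos) - np.median(mu + scale * (fmo - mu)))
            / (2 * scale * np.std(fmo, ddof=1)), rel=1e-9)


class TestWmsiAndInfarctSize:
    @pytest.mark.parametrize("scores,expected", [
        ([1] * 12, 1.0),
        ([1] * 6 + [3] * 6, 2.0),
        ([1] * 11 + [4], 15 / 12),
    ])
    def test_wmsi_closed_forms(self, scores, expected):
        assert mv.wmsi(SegmentScoreTable(scores)) == pytest.approx(expected)

    @pytest.mark.parametrize("scores,expected", [
        ([1] * 12, 0.0),
        ([1] * 6 + [2, 3, 4, 2, 3, 4], 50.0),
        ([2] + [1] * 11, 100 / 12),
    ])
    def test_infarct_size_closed_forms(self, scores, expected):
        assert mv.echo_infarct_size(SegmentScoreTable(scores)) == \
            pytest.approx(expected)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            SegmentScoreTable([0] + [1] * 11)
        with pytest.raises(ValueError):
            SegmentScoreTable([1] * 11)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(1, 4), min_size=12, max_size=12),
           st.randoms(use_true_random=False))
    def test_permutation_invariance_and_bounds(self, scores, rnd):
        t = SegmentScoreTable(scores)
        shuffled = list(scores)
        rnd.shuffle(shuffled)
        t2 = SegmentScoreTable(shuffled)
        assert mv.wmsi(t) == pytest.approx(mv.wmsi(t2))
        assert mv.echo_infarct_size(t) == pytest.approx(
            mv.echo_infarct_size(t2))
        assert 1.0 <= mv.wmsi(t) <= 4.0
        assert 0.0 <= mv.echo_infarct_size(t) <= 100.0

    def test_score_table_csv_round_trip_both_layouts(self, tmp_path):
        t = SegmentScoreTable([1, 2, 3, 4, 1, 2, 3, 4, 1, 2, 3, 4])
        p = tmp_path / "scores.csv"
        t.to_csv(p)
        assert SegmentScoreTable.from_csv(p).scores == t.scores
        # bare 3×4 matrix layout
        import pandas as pd
        pd.DataFrame(t.as_matrix()).to_csv(tmp_path / "m.csv", index=False)
        assert SegmentScoreTable.from_csv(tmp_path / "m.csv").scores == t.scores


class TestShgMetrics:
    def test_definitional_fraction(self):
        img = np.zeros((10, 10))
        img[:3] = 200.0  # 30 % bright
        zone = np.ones((10, 10), bool)
        m = mv.shg_metrics(img, zone, threshold=100.0)
        assert m.pct_shg == pytest.approx(30.0)

    def test_moments_match_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 255, (64, 64)).astype(float)
        zone = rng.random((64, 64)) > 0.3
        m = mv.shg_metrics(img, zone, threshold=128.0)
        vals = img[zone]
        mu = vals.mean()
        cm = [np.mean((vals - mu) ** k) for k in (2, 3, 4)]
        assert m.skewness == pytest.approx(cm[1] / cm[0] ** 1.5, rel=1e-12)
        assert m.kurtosis == pytest.approx(cm[2] / cm[0] ** 2, rel=1e-12)
        assert m.excess_kurtosis == pytest.approx(m.kurtosis - 3.0)

    def test_symmetric_bimodal_has_zero_skewness(self):
        img = np.concatenate([np.full(500, 10.0),
                              np.full(500, 200.0)]).reshape(20, 50)
        m = mv.shg_metrics(img, np.ones_like(img, bool), threshold=100.0)
        assert m.skewness == pytest.approx(0.0, abs=1e-9)

    def test_constant_zone_flags_moments(self):
        img = np.full((8, 8), 7.0)
        m = mv.shg_metrics(img, np.ones((8, 8), bool), threshold=3.0)
        assert m.pct_shg == 100.0
        assert not m.moments_defined
        assert m.skewness is None and m.kurtosis is None

    def test_empty_zone_raises(self):
        with pytest.raises(ValueError, match="empty zone"):
            mv.shg_metrics(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestPositiveFraction:
    def test_area_mode(self):
        ref = np.ones((10, 10), bool)
        sig = np.zeros((10, 10), bool)
        sig[:5] = True
        assert mv.positive_fraction(sig, ref) == 50.0
        assert mv.positive_fraction(np.zeros_like(ref), ref) == 0.0

    def test_count_mode(self):
        ref = [f"cell{i}" for i in range(12)]
        assert mv.positive_fraction(["cell0", "cell5", "cell7"], ref,
                                    mode="count") == 25.0

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError, match="empty reference"):
            mv.positive_fraction(np.ones((4, 4), bool),
                                 np.zeros((4, 4), bool))
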