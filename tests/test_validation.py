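import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ternhmm as th
from ternhmm.validation import (AlignmentError, coverage_bin, event_coverage_multi,
                                validation_metrics, ValidationMetrics)

from oracles import rle_foraging_events


class TestConfusion:
    def test_perfect_agreement(self):
        c = th.confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_hand_count(self):
        c = th.confusion([1, 0, 1, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_accepts_string_labels(self):
        c = th.confusion(["foraging", "not_foraging"], ["foraging", "foraging"])
        assert (c.tp, c.fp) == (1, 1)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_cells_partition_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        c = th.confusion(rng.integers(0, 2, n), rng.integers(0, 2, n))
        assert c.total == n

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            th.confusion([1, 0], [1])


class TestPointMetrics:
    def test_ppv(self):
        assert th.ppv(th.ConfusionCounts(3, 1, 0, 0)) == pytest.approx(0.75)

    def test_tpr(self):
        assert th.tpr(th.ConfusionCounts(3, 0, 0, 0)) == pytest.approx(1.0)

    def test_npv(self):
        assert th.npv(th.ConfusionCounts(0, 0, 2, 8)) == pytest.approx(0.8)

    def test_zero_denominators_are_missing_not_zero(self):
        none_predicted_positive = th.ConfusionCounts(0, 0, 3, 5)
        assert np.isnan(th.ppv(none_predicted_positive))
        no_positives_observed = th.ConfusionCounts(0, 4, 0, 5)
        assert np.isnan(th.tpr(no_positives_observed))

    def test_f1_of_equal_inputs(self):
        assert th.f1(0.6, 0.6) == pytest.approx(0.6)

    def test_f1_zero_when_both_zero(self):
        assert th.f1(0.0, 0.0) == 0.0

    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_f1_between_min_and_max(self, p, t):
        val = th.f1(p, t)
        assert min(p, t) - 1e-12 <= val <= max(p, t) + 1e-12


class TestLogLoss:
    def test_perfect_confident_predictions(self):
        y = np.array([1, 0, 1, 1, 0])
        assert th.log_loss(y, y.astype(float)) <= 1e-11

    def test_coin_flip_is_ln_two(self):
        y = np.array([1, 0, 1, 0, 1, 1])
        assert th.log_loss(y, np.full(6, 0.5)) == pytest.approx(np.log(2), abs=1e-12)

    def test_single_point_closed_form(self):
        assert th.log_loss([1], [0.8]) == pytest.approx(-np.log(0.8), abs=1e-12)

    def test_minimised_at_prevalence_for_constant_predictor(self):
        rng = np.random.default_rng(8)
        y = (rng.random(500) < 0.23).astype(int)
        prev = y.mean()
        grid = np.linspace(0.01, 0.99, 99)
        losses = [th.log_loss(y, np.full_like(y, q, dtype=float)) for q in grid]
        best_q = grid[int(np.argmin(losses))]
        assert abs(best_q - prev) <= 0.011  # within one grid step


class TestEvents:
    def test_two_events(self):
        events = th.extract_foraging_events([1, 1, 0, 1])
        assert [(e.start_index, e.end_index) for e in events] == [(0, 1), (3, 3)]
        assert [e.duration_s for e in events] == [2.0, 1.0]

    def test_no_foraging_no_events(self):
        assert th.extract_foraging_events([0, 0, 0]) == []

    @given(st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_matches_rle_oracle(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(0, 2, int(rng.integers(1, 120)))
        got = [(e.start_index, e.end_index)
               for e in th.extract_foraging_events(obs)]
        assert got == rle_foraging_events(list(obs))

    def test_cadence_scales_duration(self):
        (event,) = th.extract_foraging_events([0, 1, 1, 0], cadence_s=2.0)
        assert event.duration_s == 4.0


class TestEventCoverage:
    def test_quarter_coverage_goes_to_upper_bin(self):
        # exactly 25% is NOT "less than 25%": it belongs to [25,50%)
        events = th.extract_foraging_events([1, 1, 1, 1])
        cov = th.event_coverage(events, [1, 0, 0, 0])
        assert cov.proportions == [0.25]
        assert cov.bins["[25,50%)"] == 1

    @pytest.mark.parametrize("p,label", [
        (0.0, "missed"), (0.1, "(0,25%)"), (0.25, "[25,50%)"), (0.49, "[25,50%)"),
        (0.5, "[50,75%)"), (0.75, "[75,100%]"), (1.0, "[75,100%]"),
    ])
    def test_bin_boundaries(self, p, label):
        assert coverage_bin(p) == label

    def test_missed_event_contributes_duration(self):
        obs = [1, 1, 1, 0, 1, 1]
        events = th.extract_foraging_events(obs, cadence_s=1.0)
        cov = th.event_coverage(events, [0, 0, 0, 0, 1, 1])
        assert cov.missed_count == 1
        assert cov.missed_durations_s == [3.0]
        assert cov.median_missed_duration_s == 3.0

    def test_perfect_decoding_all_top_bin(self):
        obs = np.array([0, 1, 1, 0, 1, 0, 1, 1, 1])
        events = th.extract_foraging_events(obs)
        cov = th.event_coverage(events, obs)
        assert cov.bins["[75,100%]"] == len(events)
        assert cov.missed_count == 0

    def test_invariant_to_changes_outside_windows(self):
        obs = np.array([0, 1, 1, 0, 0, 1, 0])
        events = th.extract_foraging_events(obs)
        dec_a = np.array([0, 1, 0, 0, 0, 1, 0])
        dec_b = dec_a.copy()
        dec_b[[0, 3, 4, 6]] = 1  # flip only outside event windows
        cov_a = th.event_coverage(events, dec_a)
        cov_b = th.event_coverage(events, dec_b)
        assert cov_a.proportions == cov_b.proportions


class FakeFit:
    """Minimal stand-in exposing the results interface select_model needs."""

    def __init__(self, model_id, decoded, probs, n_params, aic=0.0):
        self.spec = th.HMMSpec.from_model_id(model_id)
        self._decoded = decoded
        self._probs = probs
        self.n_params = n_params
        self.aic = aic
        self.llf = 0.0

    def decoded_foraging(self):
        return self._decoded

    def prob_foraging(self):
        return self._probs


class TestSelectModel:
    def _obs(self):
        return [np.array([1, 0, 1, 0, 1, 1, 0, 0])]

    def test_single_model_selected(self):
        obs = self._obs()
        fit = FakeFit(0, obs, [np.full(8, 0.8)], 11)
        sel = th.select_model([fit], obs)
        assert sel.best_model_id == 0 and len(sel.table) == 1

    def test_lowest_logloss_wins_regardless_of_aic(self):
        obs = self._obs()
        good = FakeFit(0, obs, [np.where(obs[0] == 1, 0.9, 0.1)], 11, aic=999.0)
        bad = FakeFit(6, obs, [np.full(8, 0.5)], 17, aic=-999.0)
        sel = th.select_model([good, bad], obs)
        assert sel.best_model_id == 0
        # chosen row attains the table's minimum log-loss
        assert sel.table["logloss"].min() == sel.table.iloc[0]["logloss"]

    def test_tie_broken_by_fewer_parameters(self):
        obs = self._obs()
        probs = [np.full(8, 0.5)]
        small = FakeFit(0, obs, probs, 11)
        big = FakeFit(3, obs, probs, 25)
        sel = th.select_model([big, small], obs)
        assert sel.best_model_id == 0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            th.select_model([], self._obs())


class TestPooledMetricsAndRoundTrip:
    def test_pooling_matches_manual_concatenation(self):
        obs = [np.array([1, 0, 1]), np.array([0, 0, 1, 1])]
        dec = [np.array([1, 1, 0]), np.array([0, 0, 1, 0])]
        q = [np.array([0.9, 0.6, 0.4]), np.array([0.1, 0.2, 0.8, 0.3])]
        m = validation_metrics(obs, dec, q)
        c = th.confusion(np.concatenate(obs), np.concatenate(dec))
        assert m.counts == c
        assert m.logloss == pytest.approx(
            th.log_loss(np.concatenate(obs), np.concatenate(q)))
        assert m.f1 == pytest.approx(th.f1(th.ppv(c), th.tpr(c)))

    def test_metrics_survive_csv_roundtrip(self, small_fit, small_series, tmp_path):
        import pandas as pd

        df = small_fit.decode()
        path = tmp_path / "decoded.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        obs = [s.behaviour for s in small_series]
        dec = small_fit.decoded_foraging()
        q = small_fit.prob_foraging()
        before = validation_metrics(obs, dec, q)
        grouped = back.groupby("track_id", sort=False)
        dec2 = [g["viterbi_state"].to_numpy() for _, g in grouped]
        # map state index to binary via the label column
        dec2 = [(g["label"] == "foraging").astype(int).to_numpy()
                for _, g in grouped]
        q2 = [g["prob_foraging"].to_numpy() for _, g in grouped]
        after = validation_metrics(obs, dec2, q2)
        assert after.counts == before.counts
        assert after.logloss == pytest.approx(before.logloss, abs=1e-9)
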