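"""Scoring must be linear, baseline-invariant and faithful to the generator."""

import numpy as np
import pytest

import trialvar as tv
from trialvar.data import EpochSet
from trialvar.scoring import (
    COMPONENT_WINDOWS,
    LocalizerTieError,
    ScoringWindow,
    baseline_adjust,
    collapsed_localizer,
    filter_min_trials,
    score_mean_amplitude,
)
from conftest import make_table


def _epochs_from_matrix(mat, sampling_rate_hz=250.0, epoch_start_ms=-200.0,
                        channel="Fz", pid="s1", event="standard", group="NP"):
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    n_samples = mat.shape[1]
    end = epoch_start_ms + (n_samples - 1) * 1000.0 / sampling_rate_hz
    return EpochSet(
        epochs={(pid, event): mat},
        trial_ids={(pid, event): np.arange(1, mat.shape[0] + 1)},
        groups={pid: group},
        sampling_rate_hz=sampling_rate_hz,
        epoch_start_ms=epoch_start_ms,
        epoch_end_ms=end,
        channel=channel,
    )


class TestBaselineAdjust:
    def test_constant_trial_goes_to_zero(self):
        ep = _epochs_from_matrix(np.full((3, 175), 3.0))
        out = baseline_adjust(ep)
        assert np.allclose(out.epochs[("s1", "standard")], 0.0)

    def test_step_trial_keeps_post_event_difference(self):
        t = _epochs_from_matrix(np.full((1, 175), 2.0))
        times = t.times_ms
        t.epochs[("s1", "standard")][0, times >= 0] = 7.0
        out = baseline_adjust(t)
        adj = out.epochs[("s1", "standard")][0]
        assert np.allclose(adj[times < 0], 0.0)
        assert np.allclose(adj[times >= 0], 5.0)

    def test_idempotence(self, rng):
        ep = _epochs_from_matrix(rng.normal(size=(6, 175)))
        once = baseline_adjust(ep)
        twice = baseline_adjust(once)
        assert np.allclose(
            once.epochs[("s1", "standard")], twice.epochs[("s1", "standard")]
        )

    def test_short_pre_event_segment_rejected(self):
        ep = _epochs_from_matrix(np.zeros((1, 100)), epoch_start_ms=-100.0)
        with pytest.raises(ValueError, match="100.0 ms of\npre-event|pre-event"):
            baseline_adjust(ep)


class TestMeanAmplitude:
    def test_flat_trial_scores_its_level(self):
        ep = _epochs_from_matrix(np.full((2, 175), 5.0))
        table = score_mean_amplitude(ep, ScoringWindow("w", 100, 300, "Fz"))
        assert np.allclose(table["amplitude"], 5.0)
        assert list(table["trial"]) == [1, 2]

    def test_matches_brute_force_sample_mean(self, rng):
        ep = _epochs_from_matrix(rng.normal(size=(5, 175)))
        w = ScoringWindow("w", 265, 315, "Fz")
        table = score_mean_amplitude(ep, w)
        t = ep.times_ms
        mask = (t >= 265) & (t < 315)  # half-open window
        expected = ep.epochs[("s1", "standard")][:, mask].mean(axis=1)
        assert np.allclose(table["amplitude"].to_numpy(), expected)

    def test_linear_ramp_scores_midpoint(self):
        # ramp 0->10 uV across the scored window
        ep = _epochs_from_matrix(np.zeros((1, 175)))
        t = ep.times_ms
        w = ScoringWindow("w", 0, 400, "Fz")
        mask = (t >= 0) & (t < 400)
        ramp = np.zeros_like(t)
        ramp[mask] = np.linspace(0, 10, mask.sum())
        ep.epochs[("s1", "standard")][0] = ramp
        score = score_mean_amplitude(ep, w)["amplitude"].iloc[0]
        assert score == pytest.approx(5.0, abs=10 / mask.sum())

    def test_scoring_is_linear(self, rng):
        x = rng.normal(size=175)
        y = rng.normal(size=175)
        a, b = 2.5, -1.25
        w = ScoringWindow("w", 100, 300, "Fz")

        def score(v):
            ep = _epochs_from_matrix(v)
            return score_mean_amplitude(ep, w)["amplitude"].iloc[0]

        assert score(a * x + b * y) == pytest.approx(a * score(x) + b * score(y))

    def test_baseline_then_score_commutes(self, rng):
        mat = rng.normal(size=(4, 175))
        ep = _epochs_from_matrix(mat)
        w = ScoringWindow("w", 100, 300, "Fz")
        scored_after = score_mean_amplitude(baseline_adjust(ep), w)["amplitude"]
        t = ep.times_ms
        base = mat[:, t < 0].mean(axis=1)
        scored_before = score_mean_amplitude(ep, w)["amplitude"] - base
        assert np.allclose(scored_after, scored_before)

    def test_generator_round_trip_exact_with_boxcar_and_no_noise(self):
        cfg = tv.GeneratorConfig(n_per_group=3, trials_per_condition=5, seed=6)
        wp = tv.WaveformParams(
            bump_shape="boxcar", bump_center_ms=290, bump_width_ms=150,
            noise_sd=0.0, baseline_level=2.0,
        )
        epochs, truth = tv.simulate_epochs(cfg, wp)
        w = ScoringWindow("w", 265, 315, "Fz")  # inside the boxcar
        table = score_mean_amplitude(baseline_adjust(epochs), w)
        merged = truth.merge(
            table, on=["participant_id", "group", "event", "trial"],
            suffixes=("_true", "_scored"),
        )
        assert len(merged) == len(truth)
        assert np.allclose(merged["amplitude_scored"], merged["amplitude_true"])

    def test_gaussian_bump_recovers_amplitudes_up_to_noise(self):
        cfg = tv.GeneratorConfig(n_per_group=4, trials_per_condition=20, seed=1)
        wp = tv.WaveformParams(noise_sd=0.1)
        epochs, truth = tv.simulate_epochs(cfg, wp)
        table = score_mean_amplitude(
            baseline_adjust(epochs), ScoringWindow("w", 265, 315, "Fz")
        )
        merged = truth.merge(
            table, on=["participant_id", "group", "event", "trial"],
            suffixes=("_true", "_scored"),
        )
        r = np.corrcoef(merged["amplitude_true"], merged["amplitude_scored"])[0, 1]
        assert r > 0.99

    def test_empty_window_and_wrong_channel_rejected(self):
        ep = _epochs_from_matrix(np.zeros((1, 175)))
        with pytest.raises(ValueError, match="channel"):
            score_mean_amplitude(ep, ScoringWindow("w", 100, 300, "Cz"))
        with pytest.raises(ValueError, match="no samples"):
            score_mean_amplitude(ep, ScoringWindow("w", 300.5, 301, "Fz"))


class TestCollapsedLocalizer:
    def _two_condition_epochs(self, peak_ms=290.0, amp=-3.0, n_pid=3):
        rate, start = 1000.0, -200.0  # 1 kHz grid: latencies land on integers
        n = 701
        t = start + np.arange(n)
        epochs, ids, groups = {}, {}, {}
        bump = amp * np.exp(-0.5 * ((t - peak_ms) / 20.0) ** 2)
        for i in range(n_pid):
            pid = f"s{i}"
            epochs[(pid, "standard")] = np.zeros((2, n))
            epochs[(pid, "deviant")] = np.tile(bump, (2, 1))
            ids[(pid, "standard")] = ids[(pid, "deviant")] = np.array([1, 2])
            groups[pid] = "NP"
        return EpochSet(epochs, ids, groups, rate, start, t[-1], "Fz")

    def test_injected_negative_peak_yields_published_window(self):
        ep = self._two_condition_epochs(peak_ms=290.0)
        w = collapsed_localizer(ep, (100, 400), "negative", 25.0)
        assert (w.window_start_ms, w.window_end_ms) == (265.0, 315.0)
        published = COMPONENT_WINDOWS["mmn_d"]
        assert (w.window_start_ms, w.window_end_ms) == (
            published.window_start_ms, published.window_end_ms,
        )

    def test_peak_matches_argmin_oracle(self):
        ep = self._two_condition_epochs(peak_ms=333.0)
        w = collapsed_localizer(ep, (100, 400), "negative", 25.0)
        diff = ep.epochs[("s0", "deviant")][0] - ep.epochs[("s0", "standard")][0]
        t = ep.times_ms
        mask = (t >= 100) & (t <= 400)
        oracle = t[mask][np.argmin(diff[mask])]
        assert w.window_start_ms == oracle - 25.0

    def test_two_equal_extrema_choose_earliest(self):
        ep = self._two_condition_epochs(peak_ms=250.0)
        # add an identical second dip later
        for pid in list(ep.groups):
            t = ep.times_ms
            ep.epochs[(pid, "deviant")] += (
                -3.0 * np.exp(-0.5 * ((t - 350.0) / 20.0) ** 2)
            )
        with pytest.warns(UserWarning, match="earliest"):
            w = collapsed_localizer(ep, (100, 400), "negative", 25.0)
        assert w.window_start_ms == 250.0 - 25.0

    def test_flat_wave_without_tie_break_errors(self):
        ep = self._two_condition_epochs(amp=0.0)
        with pytest.raises(LocalizerTieError):
            collapsed_localizer(ep, (100, 400), "negative", tie_break=None)

    def test_positive_search_on_negative_wave_warns(self):
        ep = self._two_condition_epochs(amp=-3.0)
        with pytest.warns(UserWarning, match="opposite sign"):
            w = collapsed_localizer(ep, (250, 330), "positive", 25.0)
        # extremum is the least-negative point in the window: an edge
        assert w.window_start_ms in (250.0 - 25.0, 330.0 - 25.0)


class TestMinTrialFilter:
    def test_registered_rule_on_known_counts(self):
        table = make_table({
            ("a", "NP", "standard"): 4, ("a", "NP", "deviant"): 50,
            ("b", "NP", "standard"): 5, ("b", "NP", "deviant"): 5,
            ("c", "patient", "standard"): 6, ("c", "patient", "deviant"): 3,
            ("d", "patient", "standard"): 10, ("d", "patient", "deviant"): 10,
        })
        kept, report = filter_min_trials(table, min_trials=5)
        assert sorted(kept["participant_id"].unique()) == ["b", "d"]
        assert sorted(report["participant_id"]) == ["a", "c"]
        row_a = report.set_index("participant_id").loc["a"]
        assert (row_a["n_standard"], row_a["n_deviant"]) == (4, 50)

    def test_missing_cell_counts_as_zero(self):
        table = make_table({
            ("a", "NP", "standard"): 8,
            ("b", "NP", "standard"): 8, ("b", "NP", "deviant"): 8,
        })
        kept, report = filter_min_trials(table, 5)
        assert list(kept["participant_id"].unique()) == ["b"]
        assert report.set_index("participant_id").loc["a", "n_deviant"] == 0

    def test_min_trials_one_keeps_everyone(self):
        table = make_table({
            ("a", "NP", "standard"): 1, ("a", "NP", "deviant"): 2,
            ("b", "NP", "standard"): 3, ("b", "NP", "deviant"): 1,
        })
        kept, report = filter_min_trials(table, 1)
        assert len(report) == 0
        assert len(kept) == len(table)

    def test_idempotent_and_monotone_in_threshold(self):
        table = make_table({
            (p, "NP", e): n
            for p, ns in {"a": (3, 9), "b": (6, 6), "c": (12, 4)}.items()
            for e, n in zip(("standard", "deviant"), ns)
        })
        kept5, _ = filter_min_trials(table, 5)
        again, _ = filter_min_trials(kept5, 5)
        assert kept5.equals(again)
        kept7, _ = filter_min_trials(table, 7)
        assert set(kept7["participant_id"]) <= set(kept5["participant_id"])
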