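"""Single-trial ERP scoring: baseline adjustment, time-window mean amplitude,
collapsed-localizer window selection, and the minimum-trial inclusion filter.

Conventions
-----------
* Windows are half-open on the sample grid: a sample at time t belongs to the
  window iff window_start_ms <= t < window_end_ms. This avoids double-counting
  endpoint samples shared by adjacent windows and makes scores bit-reproducible.
* Baseline adjustment uses the first 200 ms of the epoch (the pre-event
  segment), per trial.
* The collapsed localizer pools the condition-difference waveform across all
  participants with equal weight per participant (groups pooled), finds the
  extremum of the requested polarity, and returns a window of +/- half_width_ms
  around the extremum latency snapped to the sampling grid. Ties break to the
  earliest latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TRIAL_COLUMNS, EpochSet, validate_trial_table

__all__ = [
    "ScoringWindow",
    "COMPONENT_WINDOWS",
    "baseline_adjust",
    "score_mean_amplitude",
    "collapsed_localizer",
    "filter_min_trials",
    "LocalizerTieError",
]

BASELINE_MS = 200.0


class LocalizerTieError(ValueError):
    """Raised when the localizer grand average has no unique extremum and the
    tie-break rule is disabled."""


@dataclass(frozen=True)
class ScoringWindow:
    """A named mean-amplitude scoring window at a single channel."""

    component: str
    window_start_ms: float
    window_end_ms: float
    channel: str

    def __post_init__(self) -> None:
        if not self.window_start_ms < self.window_end_ms:
            raise ValueError("window_start_ms must be < window_end_ms")


#: Published scoring windows per component (ms, channel): MMN-D and MMN-F from
#: a collapsed localizer on the deviant-standard difference wave; P3a at Cz for
#: novel sounds; P3b at Pz for targets; ERN response-locked at FCz; RewP
#: feedback-locked at FCz.
COMPONENT_WINDOWS: dict[str, ScoringWindow] = {
    "mmn_d": ScoringWindow("mmn_d", 265.0, 315.0, "Fz"),
    "mmn_f": ScoringWindow("mmn_f", 175.0, 225.0, "Fz"),
    "p3a": ScoringWindow("p3a", 250.0, 450.0, "Cz"),
    "p3b": ScoringWindow("p3b", 300.0, 500.0, "Pz"),
    "ern": ScoringWindow("ern", 0.0, 100.0, "FCz"),
    "rewp": ScoringWindow("rewp", 250.0, 350.0, "FCz"),
}


def baseline_adjust(epochs: EpochSet, baseline_ms: float = BASELINE_MS) -> EpochSet:
    """Subtract each trial's mean over the first ``baseline_ms`` of the epoch.

    Idempotent: re-adjusting an adjusted set leaves it unchanged up to float
    round-off. Raises if the epoch provides less than ``baseline_ms`` of
    pre-event signal.
    """
    pre = -epochs.epoch_start_ms
    if pre + 1e-9 < baseline_ms:
        raise ValueError(
            f"epoch starts at {epochs.epoch_start_ms} ms: only {pre:.1f} ms of "
            f"pre-event signal, {baseline_ms:.1f} ms needed for baseline adjustment"
        )
    t = epochs.times_ms
    mask = t < epochs.epoch_start_ms + baseline_ms
    if not mask.any():
        raise ValueError("no samples fall inside the baseline segment")
    out = epochs.copy()
    for key, mat in out.epochs.items():
        out.epochs[key] = mat - mat[:, mask].mean(axis=1, keepdims=True)
    return out


def score_mean_amplitude(epochs: EpochSet, window: ScoringWindow) -> pd.DataFrame:
    """Score every trial as the mean amplitude inside the window.

    Returns a TrialTable (participant_id, group, event, trial, amplitude) with
    one row per trial. The window is half-open on the sample grid.
    """
    if window.channel != epochs.channel:
        raise ValueError(
            f"window channel {window.channel!r} does not match epoch channel "
            f"{epochs.channel!r}"
        )
    t = epochs.times_ms
    mask = (t >= window.window_start_ms) & (t < window.window_end_ms)
    if not mask.any():
        raise ValueError(
            f"no samples in window [{window.window_start_ms}, "
            f"{window.window_end_ms}) ms on the {epochs.sampling_rate_hz} Hz grid"
        )
    rows = []
    for (pid, event), mat in epochs.epochs.items():
        scores = mat[:, mask].mean(axis=1)
        ids = epochs.trial_ids[(pid, event)]
        group = epochs.groups[pid]
        rows.extend(
            (pid, group, event, int(tid), float(s)) for tid, s in zip(ids, scores)
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def collapsed_localizer(
    epochs: EpochSet,
    search_window: tuple[float, float],
    polarity: str = "negative",
    half_width_ms: float = 25.0,
    event_order: tuple[str, str] | None = None,
    tie_break: str | None = "earliest",
) -> ScoringWindow:
    """Select a scoring window from the grand-average difference wave.

    Averages the per-participant condition-difference waveform (second event
    minus first, each participant weighted equally and groups pooled), locates
    the extremum of the stated polarity inside ``search_window``, and returns a
    window of +/- ``half_width_ms`` around the extremum latency, snapped to the
    sampling grid.
    """
    if polarity not in {"negative", "positive"}:
        raise ValueError("polarity must be 'negative' or 'positive'")
    events = list(dict.fromkeys(e for _, e in epochs.epochs))  # appearance order
    if event_order is None:
        if len(events) != 2:
            raise ValueError(
                f"need exactly 2 events for a difference wave, found {events}"
            )
        event_order = (events[0], events[1])
    e0, e1 = event_order
    diffs = []
    for pid in sorted(epochs.groups):
        a, b = epochs.epochs.get((pid, e0)), epochs.epochs.get((pid, e1))
        if a is None or b is None:
            continue
        diffs.append(b.mean(axis=0) - a.mean(axis=0))
    if not diffs:
        raise ValueError("no participant has both conditions")
    grand = np.mean(diffs, axis=0)

    t = epochs.times_ms
    lo, hi = search_window
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(f"search window [{lo}, {hi}] ms contains no samples")
    seg, seg_t = grand[mask], t[mask]
    values = seg if polarity == "positive" else -seg
    best = values.max()
    ties = np.flatnonzero(np.isclose(values, best, rtol=0.0, atol=1e-12))
    if len(ties) > 1 and tie_break is None:
        raise LocalizerTieError(
            f"{len(ties)} equal extrema in the search window; no tie-break rule"
        )
    if len(ties) > 1:
        warnings.warn(
            f"{len(ties)} equal extrema in the search window; "
            "choosing the earliest latency",
            stacklevel=2,
        )
    peak_idx = int(ties[0])  # earliest
    peak_val = seg[peak_idx]
    if (polarity == "positive" and peak_val < 0) or (
        polarity == "negative" and peak_val > 0
    ):
        warnings.warn(
            f"{polarity} extremum has value {peak_val:.3g} of the opposite sign: "
            "the difference wave may not contain the expected component",
            stacklevel=2,
        )
    latency = float(seg_t[peak_idx])
    return ScoringWindow(
        component="localized",
        window_start_ms=latency - half_width_ms,
        window_end_ms=latency + half_width_ms,
        channel=epochs.channel,
    )


def filter_min_trials(
    table: pd.DataFrame, min_trials: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the registered trial-count inclusion rule.

    Participants with fewer than ``min_trials`` trials in ANY event cell
    (including an entirely missing cell) are removed. Returns the filtered
    table and an exclusion report with one row per excluded participant and
    per-cell counts.
    """
    validate_trial_table(table)
    events = list(pd.unique(table["event"]))
    counts = (
        table.groupby(["participant_id", "event"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=events, fill_value=0)
    )
    excluded_ids = counts.index[(counts < min_trials).any(axis=1)]
    report = counts.loc[excluded_ids].copy()
    report.columns = [f"n_{e}" for e in report.columns]
    report["min_trials"] = min_trials
    report = report.reset_index()
    kept = table[~table["participant_id"].isin(excluded_ids)].reset_index(drop=True)
    if kept.empty:
        warnings.warn(
            f"all participants excluded by the {min_trials}-trial rule", stacklevel=2
        )
    return kept, report
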