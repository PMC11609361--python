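"""Synthetic trial-level ERP data with location-scale generative structure.

The generator draws single-trial amplitudes from the same model family the
analysis assumes: a Gaussian likelihood whose mean and log residual SD are both
linear in event type, diagnostic group, and their interaction, with correlated
person-specific random intercepts and event slopes on both portions,

    y_ij ~ Normal(x_ij' beta + z_ij' u_i,  exp(x_ij' eta + z_ij' v_i)),
    (u_i, v_i) ~ MVN(0, diag(tau) * C * diag(tau)).

Treatment (dummy) coding is used throughout: the intercept is the reference
event in the never-psychotic ("NP") reference group, and the remaining three
coefficients are deviations (event, group, event x group).

Default parameter values mirror the magnitudes reported for duration-deviant
mismatch negativity in the study this package re-implements: a reference mean
of 1.63 uV, an event effect of about -2.6 uV, a within-person residual SD of
2.49 uV with small log-scale group/event effects, person SDs of ~1.3 uV for
the mean structure and ~0.27 log-SD units for the variance structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "WaveformParams",
    "EpochSet",
    "simulate_trial_table",
    "simulate_epochs",
    "validate_trial_table",
    "read_trial_table",
    "write_trial_table",
]

TRIAL_COLUMNS = ["participant_id", "group", "event", "trial", "amplitude"]


class ConfigError(ValueError):
    """Raised when a generator or model configuration violates its invariants."""


def _default_re_corr() -> np.ndarray:
    return np.eye(4)


@dataclass
class GeneratorConfig:
    """Configuration of the trial-level generative model.

    Parameters
    ----------
    n_per_group : participants per diagnostic group (two groups are generated).
    trials_per_condition : nominal trial count per event before dropout.
    dropout_rate : i.i.d. probability that a trial is deleted, emulating
        artifact rejection and producing unbalanced cells.
    beta : location fixed effects (intercept, event, group, event x group), uV.
    eta : scale fixed effects on the log-SD scale, same coding.
    tau_loc : SDs of the location random intercept and event slope, uV.
    tau_scale : SDs of the scale random intercept and event slope, log-SD units.
    re_corr : 4 x 4 correlation matrix of (loc icpt, loc event, sc icpt,
        sc event) random effects. Defaults to identity; the source study does
        not report random-effect correlations.
    seed : RNG seed; two runs with equal config are byte-identical.
    """

    n_per_group: int = 20
    trials_per_condition: int = 30
    dropout_rate: float = 0.1
    beta: tuple[float, ...] = (1.63, -2.61, 0.02, 0.46)
    eta: tuple[float, ...] = (float(np.log(2.49)), 0.01, 0.04, -0.02)
    tau_loc: tuple[float, float] = (1.34, 1.39)
    tau_scale: tuple[float, float] = (0.27, 0.02)
    re_corr: np.ndarray = field(default_factory=_default_re_corr)
    seed: int = 0
    group_labels: tuple[str, str] = ("NP", "patient")
    event_labels: tuple[str, str] = ("standard", "deviant")

    def __post_init__(self) -> None:
        self.re_corr = np.asarray(self.re_corr, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if len(self.beta) != 4 or len(self.eta) != 4:
            raise ConfigError("beta and eta must be 4-vectors")
        if any(t < 0 for t in self.tau_loc) or any(t < 0 for t in self.tau_scale):
            raise ConfigError("random-effect SDs must be nonnegative")
        C = self.re_corr
        if C.shape != (4, 4):
            raise ConfigError("re_corr must be 4 x 4")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ConfigError("re_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ConfigError("re_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ConfigError("re_corr must be positive semi-definite")

    @property
    def tau(self) -> np.ndarray:
        """SD vector over the four random effects, loc block then scale block."""
        return np.asarray(self.tau_loc + self.tau_scale, dtype=float)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        for key in ("beta", "eta", "tau_loc", "tau_scale", "group_labels", "event_labels"):
            if key in d:
                d[key] = tuple(d[key])
        if "re_corr" in d:
            d["re_corr"] = np.asarray(d["re_corr"], dtype=float)
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a YAML or JSON file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def simulate_trial_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """Simulate a long-format single-trial score table.

    Returns a DataFrame with columns participant_id, group, event, trial,
    amplitude. Trial indices are 1-based and unique within each
    (participant, event) cell; dropout leaves gaps, so cells are unbalanced.
    Each cell retains at least one trial.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    beta = np.asarray(cfg.beta, dtype=float)
    eta = np.asarray(cfg.eta, dtype=float)
    tau = cfg.tau
    cov = np.outer(tau, tau) * cfg.re_corr
    # sqrtm via eigendecomposition: tolerant of semi-definite (zero-tau) cases
    evals, evecs = np.linalg.eigh(cov)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))

    rows: list[tuple] = []
    pid = 0
    for g_idx, g_label in enumerate(cfg.group_labels):
        for _ in range(cfg.n_per_group):
            pid += 1
            pid_label = f"s{pid:04d}"
            b = root @ rng.standard_normal(4)  # (u0, u1, v0, v1)
            for e_idx, e_label in enumerate(cfg.event_labels):
                x = np.array([1.0, e_idx, g_idx, e_idx * g_idx])
                mu = x @ beta + b[0] + e_idx * b[1]
                sd = np.exp(x @ eta + b[2] + e_idx * b[3])
                amps = rng.normal(mu, sd, size=cfg.trials_per_condition)
                keep = rng.random(cfg.trials_per_condition) >= cfg.dropout_rate
                if not keep.any():
                    keep[0] = True  # every cell keeps >= 1 trial
                for t in np.flatnonzero(keep):
                    rows.append((pid_label, g_label, e_label, int(t) + 1, amps[t]))
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    table["amplitude"] = table["amplitude"].astype(float)
    return table


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the TrialTable contract and return the table unchanged.

    Requires the five canonical columns, at least one row per present
    (participant, event) cell, unique trial indices within cells, and a single
    group label per participant.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("trial table is empty")
    if not np.isfinite(table["amplitude"].to_numpy(dtype=float)).all():
        raise ValueError("trial table contains non-finite amplitudes")
    dup = table.duplicated(subset=["participant_id", "event", "trial"])
    if dup.any():
        raise ValueError("duplicate trial indices within a (participant, event) cell")
    n_groups = table.groupby("participant_id", observed=True)["group"].nunique()
    if (n_groups > 1).any():
        bad = n_groups[n_groups > 1].index.tolist()
        raise ValueError(f"participants with inconsistent group labels: {bad}")
    return table


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(table)
    table.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_trial_table(table)


@dataclass
class WaveformParams:
    """Shape of the toy single-channel epoch waveforms.

    Each trial is a constant baseline level plus a component bump (Gaussian or
    boxcar) whose height is the trial's generating amplitude, plus white noise.
    Times are in ms relative to event onset; the epoch must start before 0.
    """

    sampling_rate_hz: float = 250.0
    epoch_start_ms: float = -200.0
    epoch_end_ms: float = 500.0
    bump_center_ms: float = 290.0
    bump_width_ms: float = 40.0  # Gaussian SD, or half-width for boxcar
    bump_shape: str = "gaussian"  # "gaussian" | "boxcar"
    noise_sd: float = 0.1
    baseline_level: float = 0.0
    channel: str = "Fz"

    def validate(self) -> None:
        if self.epoch_start_ms >= 0 or self.epoch_end_ms <= 0:
            raise ConfigError("epoch must span event onset (start < 0 < end)")
        if not self.epoch_start_ms <= self.bump_center_ms <= self.epoch_end_ms:
            raise ConfigError(
                "bump centre lies outside the epoch: "
                f"{self.bump_center_ms} ms not in "
                f"[{self.epoch_start_ms}, {self.epoch_end_ms}] ms"
            )
        if self.bump_shape not in {"gaussian", "boxcar"}:
            raise ConfigError("bump_shape must be 'gaussian' or 'boxcar'")


@dataclass
class EpochSet:
    """Per (participant, condition) matrices of trials x time samples.

    All matrices share one sampling grid. ``epochs`` maps (participant_id,
    event) to a float array of shape (n_trials, n_samples); ``trial_ids`` maps
    the same keys to the 1-based trial indices of each row; ``groups`` maps
    participant_id to its group label.
    """

    epochs: dict[tuple[str, str], np.ndarray]
    trial_ids: dict[tuple[str, str], np.ndarray]
    groups: dict[str, str]
    sampling_rate_hz: float
    epoch_start_ms: float
    epoch_end_ms: float
    channel: str

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms; grid starts at epoch_start_ms."""
        step = 1000.0 / self.sampling_rate_hz
        n = next(iter(self.epochs.values())).shape[1]
        return self.epoch_start_ms + step * np.arange(n)

    def copy(self) -> "EpochSet":
        return EpochSet(
            epochs={k: v.copy() for k, v in self.epochs.items()},
            trial_ids={k: v.copy() for k, v in self.trial_ids.items()},
            groups=dict(self.groups),
            sampling_rate_hz=self.sampling_rate_hz,
            epoch_start_ms=self.epoch_start_ms,
            epoch_end_ms=self.epoch_end_ms,
            channel=self.channel,
        )

    def to_dir(self, path: str | Path) -> None:
        """Write per-cell CSV matrices plus a JSON sidecar with the metadata."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "epoch_start_ms": self.epoch_start_ms,
            "epoch_end_ms": self.epoch_end_ms,
            "channel": self.channel,
            "groups": self.groups,
            "cells": [],
        }
        for (pid, event), mat in self.epochs.items():
            fname = f"{pid}__{event}.csv"
            np.savetxt(path / fname, mat, delimiter=",")
            meta["cells"].append(
                {
                    "participant_id": pid,
                    "event": event,
                    "file": fname,
                    "trial_ids": [int(t) for t in self.trial_ids[(pid, event)]],
                }
            )
        (path / "epochs.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "EpochSet":
        path = Path(path)
        meta = json.loads((path / "epochs.json").read_text())
        epochs, trial_ids = {}, {}
        for cell in meta["cells"]:
            key = (cell["participant_id"], cell["event"])
            epochs[key] = np.atleast_2d(
                np.loadtxt(path / cell["file"], delimiter=",", ndmin=2)
            )
            trial_ids[key] = np.asarray(cell["trial_ids"], dtype=int)
        return cls(
            epochs=epochs,
            trial_ids=trial_ids,
            groups=dict(meta["groups"]),
            sampling_rate_hz=meta["sampling_rate_hz"],
            epoch_start_ms=meta["epoch_start_ms"],
            epoch_end_ms=meta["epoch_end_ms"],
            channel=meta["channel"],
        )


def simulate_epochs(
    cfg: GeneratorConfig,
    waveform_params: WaveformParams | None = None,
    trial_table: pd.DataFrame | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """Simulate toy epoched waveforms whose scores recover the trial table.

    Draws a trial table from ``cfg`` (or takes one) and renders each trial as
    baseline level + component bump scaled by the trial amplitude + white
    noise. Returns the EpochSet and the generating trial table, so round-trip
    tests can compare scored against generating amplitudes.
    """
    wp = waveform_params or WaveformParams()
    wp.validate()
    if trial_table is None:
        trial_table = simulate_trial_table(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7311]))
    step = 1000.0 / wp.sampling_rate_hz
    n_samples = int(np.floor((wp.epoch_end_ms - wp.epoch_start_ms) / step)) + 1
    t = wp.epoch_start_ms + step * np.arange(n_samples)
    if wp.bump_shape == "gaussian":
        shape = np.exp(-0.5 * ((t - wp.bump_center_ms) / wp.bump_width_ms) ** 2)
    else:
        shape = (
            (t >= wp.bump_center_ms - wp.bump_width_ms)
            & (t < wp.bump_center_ms + wp.bump_width_ms)
        ).astype(float)

    epochs: dict[tuple[str, str], np.ndarray] = {}
    trial_ids: dict[tuple[str, str], np.ndarray] = {}
    groups: dict[str, str] = {}
    for (pid, group, event), cell in trial_table.groupby(
        ["participant_id", "group", "event"], sort=False, observed=True
    ):
        amps = cell["amplitude"].to_numpy(dtype=float)
        noise = rng.normal(0.0, wp.noise_sd, size=(len(amps), n_samples))
        epochs[(pid, event)] = wp.baseline_level + amps[:, None] * shape[None, :] + noise
        trial_ids[(pid, event)] = cell["trial"].to_numpy(dtype=int)
        groups[pid] = group
    epoch_set = EpochSet(
        epochs=epochs,
        trial_ids=trial_ids,
        groups=groups,
        sampling_rate_hz=wp.sampling_rate_hz,
        epoch_start_ms=wp.epoch_start_ms,
        epoch_end_ms=wp.epoch_end_ms,
        channel=wp.channel,
    )
    return epoch_set, trial_table
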