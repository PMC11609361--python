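"""Psychometric characterization of single-trial score tables.

Generalizability-theory dependability of a trial-averaged score,

    E(rho; n) = sigma2_person / (sigma2_person + sigma2_residual / n),

estimated from a one-way random-effects decomposition (person as the random
facet, trials as the replication facet) that accommodates unbalanced trial
counts; the standardized measurement error (SME) of a cell, trial SD / sqrt(n);
and the pooled-summary descriptive tests used to compare groups (two-sample t
from means/SDs/ns, chi-square of independence from count tables).

Variance components are estimated by REML with an ANOVA (method-of-moments)
fallback and starting point; negative method-of-moments components are
truncated at zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import validate_trial_table

__all__ = [
    "VarianceComponents",
    "DependabilityCurve",
    "estimate_variance_components",
    "dependability",
    "dependability_curve",
    "min_trials_at_threshold",
    "sme",
    "sme_table",
    "pooled_t_from_stats",
    "chi2_independence",
    "descriptive_tests",
]


@dataclass
class VarianceComponents:
    """Person and residual variance components of a one-way random design."""

    sigma2_person: float
    sigma2_residual: float
    n_participants: int
    trial_counts: dict[str, int]
    method: str = "reml"

    def __post_init__(self) -> None:
        if self.sigma2_person < 0 or self.sigma2_residual < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class DependabilityCurve:
    """Dependability as a function of the number of trials averaged."""

    trial_counts: np.ndarray
    dependability: np.ndarray
    threshold: float
    min_trials_at_threshold: int | None


def _select_cell(table: pd.DataFrame, group=None, event=None) -> pd.DataFrame:
    sub = table
    if group is not None:
        sub = sub[sub["group"] == group]
    if event is not None:
        sub = sub[sub["event"] == event]
    if sub.empty:
        raise ValueError(f"no rows for group={group!r}, event={event!r}")
    return sub


def _anova_components(n_i: np.ndarray, ybar: np.ndarray, ssw: float):
    """Unbalanced one-way ANOVA (method-of-moments) estimator."""
    n = n_i.size
    N = float(n_i.sum())
    grand = float(np.sum(n_i * ybar) / N)
    ssb = float(np.sum(n_i * (ybar - grand) ** 2))
    sigma2_e = ssw / (N - n)
    n_tilde = (N - np.sum(n_i**2) / N) / (n - 1)
    sigma2_p = (ssb / (n - 1) - sigma2_e) / n_tilde
    return sigma2_p, sigma2_e


def _neg2_reml(sigma2_p: float, sigma2_e: float, n_i, ybar, ssw) -> float:
    """-2 x restricted log-likelihood of the one-way random-effects model."""
    n = n_i.size
    N = float(n_i.sum())
    v = sigma2_p + sigma2_e / n_i
    w = 1.0 / v
    mhat = float(np.sum(w * ybar) / np.sum(w))
    return float(
        (N - n) * np.log(sigma2_e)
        + ssw / sigma2_e
        + np.sum(np.log(v))
        + np.sum(w * (ybar - mhat) ** 2)
        + np.log(np.sum(w))
    )


def estimate_variance_components(
    table: pd.DataFrame,
    group: str | None = None,
    event: str | None = None,
    method: str = "reml",
) -> VarianceComponents:
    """Estimate person and residual variances for one group x event cell.

    Requires at least 2 participants and at least one participant with >= 2
    trials. ``method`` is "reml" (default; ANOVA start, boundary-checked) or
    "anova" (method of moments, negative estimates truncated at 0).
    """
    validate_trial_table(table)
    sub = _select_cell(table, group, event)
    g = sub.groupby("participant_id", observed=True)["amplitude"]
    n_i = g.size().to_numpy(dtype=float)
    ybar = g.mean().to_numpy(dtype=float)
    ids = list(g.size().index)
    if n_i.size < 2:
        raise ValueError("need at least 2 participants")
    if (n_i < 2).all():
        raise ValueError("all participants have a single trial: residual "
                         "variance is not identifiable")
    ssw = float(((sub["amplitude"] - g.transform("mean")) ** 2).sum())
    counts = dict(zip(ids, (int(c) for c in n_i)))
    if sub["amplitude"].var(ddof=0) == 0.0:  # all trials identical
        return VarianceComponents(0.0, 0.0, n_i.size, counts, method=method)

    sp_mom, se_mom = _anova_components(n_i, ybar, ssw)
    if method == "anova":
        if sp_mom < 0:
            warnings.warn(
                f"negative person variance estimate {sp_mom:.4g} truncated to 0",
                stacklevel=2,
            )
        return VarianceComponents(
            max(sp_mom, 0.0), max(se_mom, 0.0), n_i.size, counts, method="anova"
        )
    if method != "reml":
        raise ValueError("method must be 'reml' or 'anova'")

    se0 = max(se_mom, 1e-8)
    sp0 = max(sp_mom, 1e-3 * se0)

    def objective(x):
        return _neg2_reml(np.exp(x[0]), np.exp(x[1]), n_i, ybar, ssw)

    res = optimize.minimize(
        objective,
        x0=[np.log(sp0), np.log(se0)],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
    )
    sp, se = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    # boundary check: profile out sigma2_person = 0
    se_b = (ssw + float(np.sum(n_i * (ybar - np.sum(n_i * ybar) / n_i.sum()) ** 2))) / (
        n_i.sum() - 1
    )
    if not res.success or _neg2_reml(1e-300, se_b, n_i, ybar, ssw) < objective(res.x):
        warnings.warn("REML optimum on the boundary: person variance set to 0",
                      stacklevel=2)
        sp, se = 0.0, float(se_b)
    return VarianceComponents(sp, se, n_i.size, counts, method="reml")


def dependability(vc: VarianceComponents, n_trials: int | np.ndarray):
    """Generalizability coefficient of an n-trial average score.

    sigma2_p / (sigma2_p + sigma2_res / n); undefined when both components
    vanish.
    """
    n_trials = np.asarray(n_trials, dtype=float)
    if (n_trials < 1).any():
        raise ValueError("n_trials must be >= 1")
    if vc.sigma2_person == 0.0 and vc.sigma2_residual == 0.0:
        raise ValueError("dependability undefined: both variance components are 0")
    out = vc.sigma2_person / (vc.sigma2_person + vc.sigma2_residual / n_trials)
    return float(out) if out.ndim == 0 else out


def min_trials_at_threshold(
    vc: VarianceComponents, threshold: float = 0.7, max_trials: int = 10_000
) -> int | None:
    """Smallest integer trial count whose dependability reaches the threshold.

    The asymptote is sigma2_p / (sigma2_p + 0) = 1 for positive person
    variance; returns None when the threshold is unreachable (sigma2_p = 0 or
    not reached by ``max_trials``).
    """
    if vc.sigma2_person == 0.0:
        return None
    if vc.sigma2_residual == 0.0:
        return 1
    # dependability >= threshold  <=>  n >= threshold/(1-threshold) * ratio
    ratio = vc.sigma2_residual / vc.sigma2_person
    n = int(np.ceil(threshold / (1.0 - threshold) * ratio - 1e-12))
    n = max(n, 1)
    return n if n <= max_trials else None


def dependability_curve(
    vc: VarianceComponents, max_trials: int = 100, threshold: float = 0.7
) -> DependabilityCurve:
    counts = np.arange(1, max_trials + 1)
    return DependabilityCurve(
        trial_counts=counts,
        dependability=dependability(vc, counts),
        threshold=threshold,
        min_trials_at_threshold=min_trials_at_threshold(vc, threshold),
    )


def sme(table: pd.DataFrame, participant: str, event: str) -> float:
    """Standardized measurement error of one participant x event cell (uV):
    the SD of single-trial scores divided by sqrt(trial count)."""
    sub = table[
        (table["participant_id"] == participant) & (table["event"] == event)
    ]
    n = len(sub)
    if n < 2:
        raise ValueError(
            f"SME needs >= 2 trials; participant {participant!r} has {n} "
            f"for event {event!r}"
        )
    return float(sub["amplitude"].std(ddof=1) / np.sqrt(n))


def sme_table(table: pd.DataFrame) -> pd.DataFrame:
    """SME for every (participant, event) cell with >= 2 trials."""
    validate_trial_table(table)
    g = table.groupby(["participant_id", "group", "event"], observed=True)[
        "amplitude"
    ]
    out = g.agg(n="size", sd=lambda x: x.std(ddof=1)).reset_index()
    out = out[out["n"] >= 2].reset_index(drop=True)
    out["sme"] = out["sd"] / np.sqrt(out["n"])
    return out


def pooled_t_from_stats(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sample pooled-variance t test from summary statistics.

    Returns (t, df, p). Reproduces published descriptive comparisons computed
    from table means and SDs.
    """
    if sd1 == 0 and sd2 == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(t), int(n1 + n2 - 2), float(p)


def chi2_independence(counts) -> tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction) from a
    contingency table of counts. Returns (chi2, df, p)."""
    counts = np.asarray(counts, dtype=float)
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def descriptive_tests(
    *,
    means: tuple[float, float] | None = None,
    sds: tuple[float, float] | None = None,
    ns: tuple[int, int] | None = None,
    counts=None,
) -> dict:
    """Convenience wrapper: pooled t from (means, sds, ns) and/or chi-square
    from a count table; returns a dict of (statistic, df, p) triples."""
    out = {}
    if means is not None:
        t, df, p = pooled_t_from_stats(
            means[0], sds[0], ns[0], means[1], sds[1], ns[1]
        )
        out["t"] = {"statistic": t, "df": df, "p": p}
    if counts is not None:
        c, df, p = chi2_independence(counts)
        out["chi2"] = {"statistic": c, "df": df, "p": p}
    if not out:
        raise ValueError("provide summary means/sds/ns and/or a count table")
    return out
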