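"""Bayesian mixed-effects location-scale models (MELSM) for single-trial scores.

Model
-----
For trial j of participant i,

    y_ij ~ Normal(mu_ij, sigma_ij)
    mu_ij        = x_ij' beta + z_ij' u_i          (location portion)
    log sigma_ij = w_ij' eta  + z_ij' v_i          (scale portion)
    (u_i, v_i)   ~ MVN(0, diag(tau) Omega diag(tau))

with treatment-coded fixed effects (reference: first event, "NP" group) for
event type, diagnostic group and their interaction on both portions, and
correlated random intercepts and event slopes on both portions. Setting the
scale portion to a lone intercept with no random effects gives the classical
homoscedastic ("location-only") multilevel model.

Estimation is full MCMC (adaptive HMC on the joint posterior with analytic
gradients and a non-centered random-effect parameterization). Priors are
weakly informative and configurable: Normal(centred, 10 uV) on location fixed
effects, Normal(centred, 1) on log-SD scale fixed effects, half-Student-t(3,
2.5) on random-effect SDs, and an LKJ(2) prior on the random-effect
correlation Cholesky factor. Intercept priors are centred at the sample mean
(location) and log sample SD (scale) so the defaults are scale-aware.

Point estimates are posterior medians; intervals are 95% equal-tailed credible
intervals, and "excludes zero" on a 95% CrI is the registered decision
criterion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import validate_trial_table
from .sampler import hmc_sample

__all__ = [
    "PriorConfig",
    "MelsmSpec",
    "MELSM",
    "MELSMResults",
    "ContrastResult",
    "HypothesisDecision",
    "summarize",
    "percent_change_in_sd",
    "decide_hypothesis",
]

_LOG2PI = math.log(2.0 * math.pi)


def _core_numpy(y, X, W, Zloc, Zsc, pid, beta, eta, B, k1, k2):
    """Likelihood, its fixed-effect gradients, and the per-participant
    random-effect gradient accumulator G. Returns (ok, loglik, gb, ge, G)."""
    n = B.shape[0]
    mu = X @ beta + (Zloc * B[pid, :k1]).sum(axis=1)
    s = W @ eta
    if k2:
        s = s + (Zsc * B[pid, k1:]).sum(axis=1)
    if np.abs(s).max() > 40.0:
        return False, 0.0, None, None, None
    inv_var = np.exp(-2.0 * s)
    r = y - mu
    loglik = -0.5 * y.size * _LOG2PI - s.sum() - 0.5 * float(r @ (r * inv_var))
    g_mu = r * inv_var
    g_s = r * g_mu - 1.0
    gb = X.T @ g_mu
    ge = W.T @ g_s
    G = np.empty((n, k1 + k2))
    for c in range(k1):
        G[:, c] = np.bincount(pid, weights=g_mu * Zloc[:, c], minlength=n)
    for c in range(k2):
        G[:, k1 + c] = np.bincount(pid, weights=g_s * Zsc[:, c], minlength=n)
    return True, loglik, gb, ge, G


try:  # jitted core: same arithmetic, single pass over observations
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _core_numba(y, X, W, Zloc, Zsc, pid, beta, eta, B, k1, k2):  # pragma: no cover
        N = y.shape[0]
        p = beta.shape[0]
        q = eta.shape[0]
        n = B.shape[0]
        gb = np.zeros(p)
        ge = np.zeros(q)
        G = np.zeros((n, k1 + k2))
        loglik = -0.5 * N * _LOG2PI
        for i in range(N):
            pi = pid[i]
            mu = 0.0
            for j in range(p):
                mu += X[i, j] * beta[j]
            for c in range(k1):
                mu += Zloc[i, c] * B[pi, c]
            s = 0.0
            for j in range(q):
                s += W[i, j] * eta[j]
            for c in range(k2):
                s += Zsc[i, c] * B[pi, k1 + c]
            if s > 40.0 or s < -40.0:
                return False, 0.0, gb, ge, G
            iv = math.exp(-2.0 * s)
            r = y[i] - mu
            loglik += -s - 0.5 * r * r * iv
            gm = r * iv
            gs = r * gm - 1.0
            for j in range(p):
                gb[j] += X[i, j] * gm
            for j in range(q):
                ge[j] += W[i, j] * gs
            for c in range(k1):
                G[pi, c] += Zloc[i, c] * gm
            for c in range(k2):
                G[pi, k1 + c] += Zsc[i, c] * gs
        return True, loglik, gb, ge, G

    _core = _core_numba
except Exception:  # pragma: no cover - numba is an optional accelerator
    _core = _core_numpy


# --------------------------------------------------------------------------
# specification
# --------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Weakly informative default priors for the MELSM blocks."""

    beta_sd: float = 10.0  # uV, location fixed effects
    eta_sd: float = 1.0  # log-SD units, scale fixed effects
    tau_df: float = 3.0  # half-Student-t df on random-effect SDs
    tau_scale: float = 2.5  # half-Student-t scale
    lkj_eta: float = 2.0  # mild concentration toward independence


@dataclass
class MelsmSpec:
    """Design of the location and scale linear predictors.

    Terms are drawn from {"1", "event", "group", "event:group", "cov",
    "event:cov"}; "cov" refers to a continuous covariate column (standardized
    to zero mean / unit SD before entry), used by the symptom models. Random
    effects are per-participant terms from {"1", "event"} on each portion; an
    empty ``re_scale`` plus a lone-intercept scale design gives the
    location-only model.
    """

    location: tuple[str, ...] = ("1", "event", "group", "event:group")
    scale: tuple[str, ...] = ("1", "event", "group", "event:group")
    re_location: tuple[str, ...] = ("1", "event")
    re_scale: tuple[str, ...] = ("1", "event")
    covariate: str | None = None
    priors: PriorConfig = field(default_factory=PriorConfig)

    @classmethod
    def location_scale(cls, covariate: str | None = None) -> "MelsmSpec":
        """The full registered model: event, group and interaction on both
        portions (or event, covariate and event x covariate for symptom
        models)."""
        if covariate is None:
            return cls()
        terms = ("1", "event", "cov", "event:cov")
        return cls(location=terms, scale=terms, covariate=covariate)

    @classmethod
    def location_only(cls) -> "MelsmSpec":
        """Homoscedastic comparison model: constant residual SD."""
        return cls(scale=("1",), re_scale=())

    def validate(self) -> None:
        valid = {"1", "event", "group", "event:group", "cov", "event:cov"}
        for side in (self.location, self.scale):
            bad = set(side) - valid
            if bad:
                raise ValueError(f"unknown design terms: {sorted(bad)}")
            if "1" not in side:
                raise ValueError("both portions must include an intercept ('1')")
        for side in (self.re_location, self.re_scale):
            if set(side) - {"1", "event"}:
                raise ValueError("random-effect terms must be '1' or 'event'")
        if not self.re_location:
            raise ValueError("at least a location random intercept is required")
        uses_cov = any(
            "cov" in t for t in self.location + self.scale
        )
        if uses_cov and self.covariate is None:
            raise ValueError("design uses 'cov' but no covariate column named")


# --------------------------------------------------------------------------
# hyper-parameter block: SDs + correlation Cholesky with priors
# --------------------------------------------------------------------------


def _corr_chol_py(y: np.ndarray, k: int, lkj_eta: float) -> tuple[np.ndarray, float]:
    """Correlation Cholesky factor from canonical partial correlations.

    ``y`` holds the k(k-1)/2 unconstrained entries (tanh-transformed to
    partial correlations). Returns (L, LKJ log density + log |Jacobian| of the
    transform).
    """
    L = np.zeros((k, k))
    L[0, 0] = 1.0
    lp = 0.0
    idx = 0
    for i in range(1, k):
        rem = 1.0
        row = L[i]
        for j in range(i):
            x = math.tanh(y[idx])
            # numerically degenerate correlations are treated as divergences
            if 1.0 - x * x <= 0.0 or rem <= 1e-300:
                return L, -np.inf
            lij = x * math.sqrt(rem)
            row[j] = lij
            # Jacobian: d x/d y = 1 - x^2 and d L_ij/d x_ij = sqrt(rem)
            lp += math.log1p(-x * x) + 0.5 * math.log(rem)
            rem -= lij * lij
            idx += 1
        rem = max(rem, 1e-300)
        row[i] = math.sqrt(rem)
        # LKJ-Cholesky density term for row i (1-based): (k - i + 2 eta - 2)
        lp += (k - (i + 1) + 2.0 * (lkj_eta - 1.0)) * math.log(row[i])
    return L, lp


try:
    _corr_chol = _numba.njit(cache=True)(_corr_chol_py)
    _corr_chol(np.zeros(6), 4, 2.0)  # compile eagerly; falls back on failure
except Exception:  # pragma: no cover
    _corr_chol = _corr_chol_py


def _tau_logprior(tau: np.ndarray, log_tau: np.ndarray, pr: PriorConfig) -> float:
    """half-Student-t(df, scale) on tau plus the exp-transform Jacobian."""
    return float(
        np.sum(
            -0.5 * (pr.tau_df + 1.0) * np.log1p(tau**2 / (pr.tau_df * pr.tau_scale**2))
            + log_tau
        )
    )


def _hyper_block(h: np.ndarray, k: int, pr: PriorConfig) -> tuple[np.ndarray, float]:
    """Map unconstrained hypers to the scaled Cholesky factor L_full.

    ``h`` is [log tau_1..k, y_1..k(k-1)/2]. Returns (L_full, log prior +
    log |Jacobian|): half-t on each tau and LKJ on the correlation factor.
    """
    log_tau = h[:k]
    tau = np.exp(log_tau)
    lp = _tau_logprior(tau, log_tau, pr)
    if k == 1:
        return tau.reshape(1, 1), lp
    L, lp_corr = _corr_chol(h[k:], k, pr.lkj_eta)
    return tau[:, None] * L, lp + lp_corr


# --------------------------------------------------------------------------
# design construction
# --------------------------------------------------------------------------


def _term_column(
    term: str, event: np.ndarray, group: np.ndarray, cov: np.ndarray | None
) -> np.ndarray:
    if term == "1":
        return np.ones_like(event, dtype=float)
    if term == "event":
        return event.astype(float)
    if term == "group":
        return group.astype(float)
    if term == "event:group":
        return (event * group).astype(float)
    if term == "cov":
        return cov
    if term == "event:cov":
        return event * cov
    raise ValueError(f"unknown term {term!r}")


def _term_name(term: str, event_label: str, group_label: str, covariate) -> str:
    return {
        "1": "Intercept",
        "event": f"event[{event_label}]",
        "group": f"group[{group_label}]",
        "event:group": f"event[{event_label}]:group[{group_label}]",
        "cov": str(covariate),
        "event:cov": f"event[{event_label}]:{covariate}",
    }[term]


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


class MELSM:
    """Mixed-effects location-scale model bound to a trial table.

    Parameters
    ----------
    table : long-format trial table (participant_id, group, event, trial,
        amplitude).
    spec : MelsmSpec, defaults to the full location-scale design.
    event_order : optional (reference, deviation) event labels; defaults to
        order of first appearance in the table.
    group_order : optional (reference, deviation) group labels; defaults to
        ("NP", other) when an "NP" label is present, else order of appearance.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        spec: MelsmSpec | None = None,
        event_order: Sequence[str] | None = None,
        group_order: Sequence[str] | None = None,
    ):
        self.spec = spec or MelsmSpec.location_scale()
        self.spec.validate()
        validate_trial_table(table)
        self.table = table.reset_index(drop=True)

        events = list(pd.unique(self.table["event"]))
        groups = list(pd.unique(self.table["group"]))
        if event_order is None:
            event_order = events
        if group_order is None:
            group_order = (
                ["NP"] + [g for g in groups if g != "NP"]
                if "NP" in groups
                else groups
            )
        if set(events) - set(event_order) or set(groups) - set(group_order):
            raise ValueError("event_order/group_order do not cover the table labels")
        self.event_order = tuple(event_order)
        self.group_order = tuple(group_order)

        needs_group = any(
            "group" in t for t in self.spec.location + self.spec.scale
        )
        if needs_group:
            per_group = self.table.groupby("group", observed=True)[
                "participant_id"
            ].nunique()
            if len(per_group) < 2 or (per_group < 2).any():
                raise ValueError(
                    "need at least 2 participants in each of 2 groups, got "
                    f"{per_group.to_dict()}"
                )

        ev = self.table["event"].map({e: i for i, e in enumerate(self.event_order)})
        gr = self.table["group"].map({g: i for i, g in enumerate(self.group_order)})
        if len(self.event_order) > 2 or len(self.group_order) > 2:
            raise ValueError("binary event and group factors are required")
        event = ev.to_numpy(dtype=float)
        group = gr.to_numpy(dtype=float)

        cov = None
        self.covariate_center = self.covariate_scale = None
        if self.spec.covariate is not None:
            if self.spec.covariate not in self.table.columns:
                raise ValueError(f"covariate column {self.spec.covariate!r} missing")
            raw = self.table[self.spec.covariate].to_numpy(dtype=float)
            self.covariate_center = float(raw.mean())
            self.covariate_scale = float(raw.std(ddof=0)) or 1.0
            cov = (raw - self.covariate_center) / self.covariate_scale

        ev1, gr1 = self.event_order[-1], self.group_order[-1]
        self.y = self.table["amplitude"].to_numpy(dtype=float)
        self.X = np.column_stack(
            [_term_column(t, event, group, cov) for t in self.spec.location]
        )
        self.W = np.column_stack(
            [_term_column(t, event, group, cov) for t in self.spec.scale]
        )
        self.loc_names = [
            _term_name(t, ev1, gr1, self.spec.covariate) for t in self.spec.location
        ]
        self.scale_names = [
            _term_name(t, ev1, gr1, self.spec.covariate) for t in self.spec.scale
        ]
        self.Zloc = np.column_stack(
            [_term_column(t, event, group, cov) for t in self.spec.re_location]
        )
        self.Zsc = (
            np.column_stack(
                [_term_column(t, event, group, cov) for t in self.spec.re_scale]
            )
            if self.spec.re_scale
            else np.empty((len(self.y), 0))
        )
        self.re_names = [
            f"loc:{_term_name(t, ev1, gr1, None)}" for t in self.spec.re_location
        ] + [f"scale:{_term_name(t, ev1, gr1, None)}" for t in self.spec.re_scale]

        pids = pd.unique(self.table["participant_id"])
        self.participants = list(pids)
        pid_index = {p: i for i, p in enumerate(pids)}
        self.pid = self.table["participant_id"].map(pid_index).to_numpy(dtype=np.int64)
        self.n_participants = len(pids)
        self.n_obs = len(self.y)

        # prior centres: sample mean for the location intercept, log sample SD
        # for the scale intercept, zero elsewhere
        pr = self.spec.priors
        self._b0 = np.zeros(self.X.shape[1])
        self._b0[self.spec.location.index("1")] = self.y.mean()
        self._e0 = np.zeros(self.W.shape[1])
        self._e0[self.spec.scale.index("1")] = math.log(self.y.std(ddof=0) + 1e-12)
        self._bsd = pr.beta_sd
        self._esd = pr.eta_sd

        self._k1 = self.Zloc.shape[1]
        self._k2 = self.Zsc.shape[1]
        self._k = self._k1 + self._k2
        self._m = self._k * (self._k - 1) // 2
        self._p = self.X.shape[1]
        self._q = self.W.shape[1]
        self.n_params = (
            self._p + self._q + self.n_participants * self._k + self._k + self._m
        )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "MELSM":
        return cls(table, **kwargs)

    # -- parameter vector layout ------------------------------------------
    def _unpack(self, theta: np.ndarray):
        p, q, n, k = self._p, self._q, self.n_participants, self._k
        beta = theta[:p]
        eta = theta[p : p + q]
        Z = theta[p + q : p + q + n * k].reshape(n, k)
        h = theta[p + q + n * k :]
        return beta, eta, Z, h

    def _predictors(self, beta, eta, Z, h):
        Lfull, lp_hyper = _hyper_block(h, self._k, self.spec.priors)
        B = Z @ Lfull.T
        mu = self.X @ beta + (self.Zloc * B[self.pid, : self._k1]).sum(axis=1)
        s = self.W @ eta
        if self._k2:
            s = s + (self.Zsc * B[self.pid, self._k1 :]).sum(axis=1)
        return Lfull, lp_hyper, B, mu, s

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log posterior and its gradient (non-centered parameterization)."""
        beta, eta, Z, h = self._unpack(theta)
        k = self._k
        pr = self.spec.priors
        log_tau = h[:k]
        tau = np.exp(log_tau)
        lp_hyper = _tau_logprior(tau, log_tau, pr)
        if k > 1:
            Lcorr, lp_corr = _corr_chol(h[k:], k, pr.lkj_eta)
            Lfull = tau[:, None] * Lcorr
            lp_hyper += lp_corr
        else:
            Lfull = tau.reshape(1, 1)
        if not np.isfinite(lp_hyper):
            return -np.inf, np.zeros_like(theta)
        B = Z @ Lfull.T
        ok, loglik, gb, ge, G = _core(
            self.y, self.X, self.W, self.Zloc, self.Zsc, self.pid,
            beta, eta, B, self._k1, self._k2,
        )
        if not ok:  # exp overflow guard; treated as divergence
            return -np.inf, np.zeros_like(theta)
        db = (beta - self._b0) / self._bsd
        de = (eta - self._e0) / self._esd
        logp = (
            loglik
            + lp_hyper
            - 0.5 * float(db @ db)
            - 0.5 * float((Z * Z).sum())
            - 0.5 * float(de @ de)
        )
        if not np.isfinite(logp):
            return -np.inf, np.zeros_like(theta)

        grad_beta = gb - db / self._bsd
        grad_eta = ge - de / self._esd
        grad_Z = G @ Lfull - Z
        Gl = G.T @ Z  # d loglik / d L_full

        # hyper block: analytic in log tau; the few correlation parameters by
        # forward differences on the small composite scalar, reusing the base
        # Cholesky evaluated above
        grad_h = np.empty(h.size)
        grad_h[:k] = (
            (Gl * Lfull).sum(axis=1)
            + 1.0
            - (pr.tau_df + 1.0) * tau**2 / (pr.tau_df * pr.tau_scale**2 + tau**2)
        )
        if self._m:
            Gl_tau = Gl * tau[:, None]
            base = (Gl_tau * Lcorr).sum() + lp_corr
            y = h[k:]
            step = 1e-7
            for j in range(self._m):
                yp = y.copy()
                yp[j] += step
                Lp, lpp = _corr_chol(yp, k, pr.lkj_eta)
                grad_h[k + j] = ((Gl_tau * Lp).sum() + lpp - base) / step

        grad = np.concatenate(
            [grad_beta, grad_eta, grad_Z.ravel(), grad_h]
        )
        return logp, grad

    def _initial_point(self, rng: np.random.Generator) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        sd = max(float(resid.std(ddof=0)), 1e-3)
        eta = np.zeros(self._q)
        eta[self.spec.scale.index("1")] = math.log(sd)
        person_means = np.bincount(
            self.pid, weights=resid, minlength=self.n_participants
        ) / np.bincount(self.pid, minlength=self.n_participants)
        tau0 = np.full(self._k, 0.1)
        tau0[0] = max(float(person_means.std(ddof=0)), 0.1)
        theta = np.concatenate(
            [
                beta,
                eta,
                0.1 * rng.standard_normal(self.n_participants * self._k),
                np.log(tau0),
                np.zeros(self._m),
            ]
        )
        jitter = 0.05 * rng.standard_normal(theta.size)
        jitter[: self._p + self._q] *= sd  # keep fixed-effect jitter on data scale
        return theta + jitter

    def _decode(self, theta: np.ndarray):
        beta, eta, Z, h = self._unpack(theta)
        Lfull, _, B, mu, s = self._predictors(beta, eta, Z, h)
        tau = np.exp(h[: self._k])
        Lcorr = Lfull / tau[:, None]
        corr = Lcorr @ Lcorr.T
        r = self.y - mu
        ll = -0.5 * _LOG2PI - s - 0.5 * r * r * np.exp(-2.0 * s)
        return beta, eta, tau, corr, B, ll

    def fit(
        self,
        draws: int = 500,
        warmup: int = 500,
        chains: int = 2,
        seed: int = 0,
        target_accept: float = 0.7,
        trajectory_length: float = 6.0,
        max_leapfrog: int = 256,
        store_loglik: bool = True,
    ) -> "MELSMResults":
        """Sample the posterior; returns a results object.

        Runs ``chains`` independent adaptive-HMC chains (chains >= 2 so that
        split R-hat is meaningful) and attaches convergence warnings when
        R-hat > 1.01 or bulk ESS < 400 for any reported parameter.
        """
        if chains < 2:
            raise ValueError("at least 2 chains are required")
        seq = np.random.SeedSequence(seed)
        chain_draws = np.empty((chains, draws, self.n_params))
        energies = np.empty((chains, draws))
        n_div = 0
        for c, child in enumerate(seq.spawn(chains)):
            rng = np.random.default_rng(child)
            init = self._initial_point(rng)
            d, stats = hmc_sample(
                self.logp_grad,
                init,
                n_warmup=warmup,
                n_draws=draws,
                rng=rng,
                target_accept=target_accept,
                trajectory_length=trajectory_length,
                max_leapfrog=max_leapfrog,
            )
            chain_draws[c] = d
            energies[c] = stats.energy
            n_div += stats.n_divergent
        return MELSMResults(
            self, chain_draws, energies, n_div, store_loglik=store_loglik
        )


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------


@dataclass
class ContrastResult:
    """Posterior summary of a scalar functional of the parameters."""

    name: str
    posterior_median: float
    cri_low: float
    cri_high: float
    excludes_zero: bool
    scale_percent_change: float | None = None

    def __post_init__(self) -> None:
        if not self.cri_low <= self.posterior_median <= self.cri_high:
            raise ValueError("median must lie inside the credible interval")
        if self.excludes_zero != (not self.cri_low <= 0.0 <= self.cri_high):
            raise ValueError("excludes_zero inconsistent with the interval")


def summarize(
    draws: np.ndarray,
    name: str = "functional",
    functional: Callable[[np.ndarray], np.ndarray] | None = None,
    scale_portion: bool = False,
) -> ContrastResult:
    """Median and 95% equal-tailed CrI of a (function of) posterior draws.

    ``draws`` is a 1-d array of pooled post-warmup draws, or anything
    ``functional`` maps to one. Percentiles use linear interpolation.
    """
    values = np.asarray(functional(draws) if functional is not None else draws)
    values = values.ravel().astype(float)
    if values.size == 0 or not np.isfinite(values).all():
        raise ValueError("draws must be a non-empty finite array")
    med = float(np.median(values))
    lo, hi = (float(v) for v in np.percentile(values, [2.5, 97.5]))
    return ContrastResult(
        name=name,
        posterior_median=med,
        cri_low=lo,
        cri_high=hi,
        excludes_zero=not (lo <= 0.0 <= hi),
        scale_percent_change=percent_change_in_sd(med) if scale_portion else None,
    )


def percent_change_in_sd(eta_contrast):
    """Back-transform a log-SD contrast to a signed percent change in SD.

    100 * (exp(eta) - 1): e.g. -0.02 -> -1.98 ("about 2% less variable"),
    ln 2 -> +100 (doubling).
    """
    return 100.0 * np.expm1(eta_contrast)


class MELSMResults:
    """Posterior draws, diagnostics and derived summaries of a MELSM fit."""

    def __init__(self, model: MELSM, chain_draws, energies, n_divergent, store_loglik):
        self.model = model
        self.spec = model.spec
        self.n_divergent = int(n_divergent)
        chains, draws, _ = chain_draws.shape
        k, n = model._k, model.n_participants
        self._beta = np.empty((chains, draws, model._p))
        self._eta = np.empty((chains, draws, model._q))
        self._tau = np.empty((chains, draws, k))
        self._corr = np.empty((chains, draws, k, k))
        self._u = np.empty((chains, draws, n, k))
        self._loglik = (
            np.empty((chains, draws, model.n_obs), dtype=np.float32)
            if store_loglik
            else None
        )
        for c in range(chains):
            for d in range(draws):
                beta, eta, tau, corr, B, ll = model._decode(chain_draws[c, d])
                self._beta[c, d] = beta
                self._eta[c, d] = eta
                self._tau[c, d] = tau
                self._corr[c, d] = corr
                self._u[c, d] = B
                if store_loglik:
                    self._loglik[c, d] = ll
        self._energy = energies
        self._idata = None
        self.convergence_warnings: list[str] = []
        self._check_convergence()

    # -- draws access ------------------------------------------------------
    @property
    def idata(self):
        """ArviZ InferenceData view (posterior, sample_stats, log_likelihood)."""
        if self._idata is None:
            import arviz as az

            m = self.model
            posterior = {"beta": self._beta, "eta": self._eta, "tau": self._tau,
                         "re_corr": self._corr, "u": self._u}
            dims = {
                "beta": ["loc_coef"],
                "eta": ["scale_coef"],
                "tau": ["re_term"],
                "re_corr": ["re_term", "re_term_"],
                "u": ["participant", "re_term"],
            }
            coords = {
                "loc_coef": m.loc_names,
                "scale_coef": m.scale_names,
                "re_term": m.re_names,
                "re_term_": m.re_names,
                "participant": m.participants,
            }
            kwargs = dict(
                posterior=posterior,
                sample_stats={"energy": self._energy},
                coords=coords,
                dims=dims,
            )
            if self._loglik is not None:
                kwargs["log_likelihood"] = {"y": self._loglik.astype(float)}
                kwargs["dims"]["y"] = ["obs"]
                kwargs["coords"]["obs"] = np.arange(self.model.n_obs)
            self._idata = az.from_dict(**kwargs)
        return self._idata

    def _coef_draws(self, portion: str, name: str) -> np.ndarray:
        """Pooled draws (chains flattened) of one fixed-effect coefficient."""
        if portion == "location":
            names, arr = self.model.loc_names, self._beta
        elif portion == "scale":
            names, arr = self.model.scale_names, self._eta
        else:
            raise ValueError("portion must be 'location' or 'scale'")
        if name not in names:
            raise KeyError(f"{name!r} not among {portion} coefficients {names}")
        return arr[:, :, names.index(name)].ravel()

    def pointwise_loglik(self) -> np.ndarray:
        """Pointwise log-likelihood matrix, (pooled draw) x observation."""
        if self._loglik is None:
            raise ValueError("fit was run with store_loglik=False")
        c, d, n = self._loglik.shape
        return self._loglik.reshape(c * d, n).astype(float)

    # -- diagnostics -------------------------------------------------------
    def _check_convergence(self) -> None:
        import arviz as az

        for label, arr in (("beta", self._beta), ("eta", self._eta),
                           ("tau", self._tau)):
            for j in range(arr.shape[2]):
                x = arr[:, :, j]
                rhat = float(az.rhat(az.convert_to_dataset(x[:, :, None]))["x"].max())
                ess = float(
                    az.ess(az.convert_to_dataset(x[:, :, None]), method="bulk")[
                        "x"
                    ].min()
                )
                if rhat > 1.01:
                    self.convergence_warnings.append(
                        f"R-hat {rhat:.3f} > 1.01 for {label}[{j}]"
                    )
                if ess < 400:
                    self.convergence_warnings.append(
                        f"bulk ESS {ess:.0f} < 400 for {label}[{j}]"
                    )
        if self.n_divergent:
            self.convergence_warnings.append(
                f"{self.n_divergent} divergent transitions after warmup"
            )
        if self.convergence_warnings:
            warnings.warn(
                "convergence diagnostics flagged: "
                + "; ".join(self.convergence_warnings),
                stacklevel=3,
            )

    # -- summaries ---------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior medians, SDs and 95% CrIs for fixed effects and
        random-effect SDs, in the layout of the published coefficient tables."""
        import arviz as az

        rows = []
        blocks = [
            ("location", self.model.loc_names, self._beta),
            ("scale", self.model.scale_names, self._eta),
            ("random_sd", self.model.re_names, self._tau),
        ]
        for portion, names, arr in blocks:
            for j, nm in enumerate(names):
                x = arr[:, :, j]
                flat = x.ravel()
                ds = az.convert_to_dataset(x[:, :, None])
                rows.append(
                    {
                        "portion": portion,
                        "parameter": nm,
                        "median": float(np.median(flat)),
                        "sd": float(flat.std(ddof=1)),
                        "cri_2.5": float(np.percentile(flat, 2.5)),
                        "cri_97.5": float(np.percentile(flat, 97.5)),
                        "rhat": float(az.rhat(ds)["x"].max()),
                        "ess_bulk": float(az.ess(ds, method="bulk")["x"].min()),
                    }
                )
        return pd.DataFrame(rows)

    def contrast(
        self, portion: str, weights: dict[str, float], name: str | None = None
    ) -> ContrastResult:
        """Posterior summary of a linear combination of fixed effects."""
        total = None
        for coef, w in weights.items():
            d = w * self._coef_draws(portion, coef)
            total = d if total is None else total + d
        label = name or " + ".join(f"{w:+g}*{c}" for c, w in weights.items())
        return summarize(total, name=label, scale_portion=(portion == "scale"))

    def group_contrasts(self, portion: str = "scale") -> dict[str, ContrastResult]:
        """Patient-minus-NP contrasts per event plus their difference.

        Mirrors the pairwise-contrast table: the reference-event contrast is
        the group coefficient, the other event's contrast adds the
        interaction, and the difference-score contrast is the interaction
        itself.
        """
        m = self.model
        ev1, gr1 = m.event_order[-1], m.group_order[-1]
        g = f"group[{gr1}]"
        ix = f"event[{ev1}]:group[{gr1}]"
        return {
            m.event_order[0]: self.contrast(portion, {g: 1.0}, name=m.event_order[0]),
            m.event_order[1]: self.contrast(
                portion, {g: 1.0, ix: 1.0}, name=m.event_order[1]
            ),
            "difference": self.contrast(portion, {ix: 1.0}, name="difference"),
        }

    def loo(self):
        """PSIS-LOO of this fit (see trialvar.model_comparison)."""
        from .model_comparison import psis_loo

        return psis_loo(self.pointwise_loglik())

    def decide(self, predicted: str = "higher") -> "HypothesisDecision":
        """Apply the registered CrI decision rule to this fit's scale portion."""
        by_event = self.group_contrasts("scale")
        e0, e1 = self.model.event_order
        g = f"group[{self.model.group_order[-1]}]"
        ix = f"event[{e1}]:group[{self.model.group_order[-1]}]"
        return decide_hypothesis(
            group=self.contrast("scale", {g: 1.0}, name="group"),
            interaction=self.contrast("scale", {ix: 1.0}, name="event:group"),
            event_contrasts=(by_event[e0], by_event[e1]),
            predicted=predicted,
        )


# --------------------------------------------------------------------------
# registered decision rules
# --------------------------------------------------------------------------


@dataclass
class HypothesisDecision:
    """Outcome of the registered per-component hypothesis rule."""

    predicted: str
    verdict: str  # "supported" | "not supported" | "opposite"
    reasons: list[str]
    contrasts: dict[str, ContrastResult]


def decide_hypothesis(
    group: ContrastResult,
    interaction: ContrastResult,
    event_contrasts: tuple[ContrastResult, ContrastResult],
    predicted: str = "higher",
) -> HypothesisDecision:
    """Apply the registered credible-interval decision rules.

    For components predicted to show higher patient variability, the
    hypothesis is supported when (1) the 95% CrI of the group coefficient on
    the scale portion excludes zero with patients more variable, and/or (2)
    the CrI of the event x group coefficient excludes zero, patients are more
    variable for one event, and the groups are comparable for the other. The
    inverted rule applies to a component predicted null (RewP): support
    requires BOTH CrIs to contain zero. A scale effect excluded from zero in
    the direction of *less* patient variability yields "opposite".
    """
    if predicted not in {"higher", "null"}:
        raise ValueError("predicted must be 'higher' or 'null'")
    e0, e1 = event_contrasts
    contrasts = {
        "group": group,
        "interaction": interaction,
        e0.name: e0,
        e1.name: e1,
    }
    reasons: list[str] = []

    if predicted == "null":
        if not group.excludes_zero and not interaction.excludes_zero:
            verdict = "supported"
            reasons.append("both scale CrIs contain zero, as predicted")
        else:
            verdict = "not supported"
            reasons.append("a scale CrI excludes zero despite the null prediction")
        return HypothesisDecision(predicted, verdict, reasons, contrasts)

    rule1 = group.excludes_zero and group.posterior_median > 0
    one_up_other_flat = (
        e0.excludes_zero and e0.posterior_median > 0 and not e1.excludes_zero
    ) or (e1.excludes_zero and e1.posterior_median > 0 and not e0.excludes_zero)
    rule2 = interaction.excludes_zero and one_up_other_flat
    if rule1:
        reasons.append("group scale CrI excludes zero with patients more variable")
    if rule2:
        reasons.append(
            "event x group scale CrI excludes zero with patients more variable "
            "for one event and comparable for the other"
        )
    if rule1 or rule2:
        return HypothesisDecision(predicted, "supported", reasons, contrasts)

    opposite = (group.excludes_zero and group.posterior_median < 0) or (
        interaction.excludes_zero and interaction.posterior_median < 0
    )
    if opposite:
        reasons.append(
            "a scale CrI excludes zero in the direction of LESS patient "
            "variability: opposite of the predicted pattern"
        )
        return HypothesisDecision(predicted, "opposite", reasons, contrasts)
    reasons.append("no scale CrI excludes zero in the predicted pattern")
    return HypothesisDecision(predicted, "not supported", reasons, contrasts)
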