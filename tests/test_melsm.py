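"""Posterior correctness of the location-scale model and its decision rules."""

import warnings

import numpy as np
import pytest

import trialvar as tv
from trialvar.melsm import (
    MELSM,
    ContrastResult,
    MelsmSpec,
    decide_hypothesis,
    percent_change_in_sd,
    summarize,
)


def _quiet_fit(model, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(**kwargs)


def _cr(lo, hi, name="c"):
    med = 0.5 * (lo + hi)
    return ContrastResult(name, med, lo, hi, not (lo <= 0.0 <= hi))


# --------------------------------------------------------------------------
# log posterior and designs
# --------------------------------------------------------------------------


@pytest.mark.parametrize("spec", [MelsmSpec.location_scale(), MelsmSpec.location_only()])
def test_gradient_matches_finite_differences(spec, rng):
    t = tv.simulate_trial_table(
        tv.GeneratorConfig(n_per_group=5, trials_per_condition=8, seed=3)
    )
    m = MELSM(t, spec)
    theta = m._initial_point(rng)
    lp, grad = m.logp_grad(theta)
    assert np.isfinite(lp)
    eps = 1e-6
    for j in rng.choice(theta.size, size=min(30, theta.size), replace=False):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += eps
        tm[j] -= eps
        fd = (m.logp_grad(tp)[0] - m.logp_grad(tm)[0]) / (2 * eps)
        assert grad[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_design_uses_treatment_coding_with_np_reference(small_table):
    m = MELSM(small_table)
    assert m.group_order[0] == "NP"
    assert m.loc_names == [
        "Intercept", "event[deviant]", "group[patient]",
        "event[deviant]:group[patient]",
    ]
    # reference cell rows have only the intercept active
    ref = (small_table["group"] == "NP") & (small_table["event"] == "standard")
    assert np.allclose(m.X[ref.to_numpy()], [1.0, 0.0, 0.0, 0.0])


def test_model_preconditions():
    t = tv.simulate_trial_table(tv.GeneratorConfig(n_per_group=1, seed=0))
    with pytest.raises(ValueError, match="at least 2 participants"):
        MELSM(t)
    t2 = tv.simulate_trial_table(tv.GeneratorConfig(n_per_group=4, seed=0))
    with pytest.raises(ValueError, match="covariate"):
        MELSM(t2, MelsmSpec.location_scale(covariate="bprs"))
    m = MELSM(t2)
    with pytest.raises(ValueError, match="2 chains"):
        m.fit(chains=1, draws=10, warmup=10)


def test_covariate_is_standardized_before_entry(small_table):
    t = small_table.copy()
    rng = np.random.default_rng(0)
    sym = {p: rng.normal(50, 10) for p in t["participant_id"].unique()}
    t["symptom"] = t["participant_id"].map(sym)
    m = MELSM(t, MelsmSpec.location_scale(covariate="symptom"))
    j = m.loc_names.index("symptom")
    col = m.X[:, j]
    assert abs(col.mean()) < 1e-10
    assert np.isclose(col.std(ddof=0), t["symptom"].std(ddof=0) / m.covariate_scale)


# --------------------------------------------------------------------------
# posterior oracles
# --------------------------------------------------------------------------


def test_location_estimates_match_ols_without_random_effects():
    # no random effects, constant scale: fixed effects are the OLS solution
    cfg = tv.GeneratorConfig(
        n_per_group=15, trials_per_condition=25, dropout_rate=0.0,
        beta=(1.63, -2.61, 0.5, 0.4), eta=(float(np.log(2.49)), 0, 0, 0),
        tau_loc=(0, 0), tau_scale=(0, 0), seed=11,
    )
    t = tv.simulate_trial_table(cfg)
    m = MELSM(t)
    res = _quiet_fit(m, draws=300, warmup=300, chains=2, seed=1)
    ols = np.linalg.lstsq(m.X, m.y, rcond=None)[0]
    s = res.summary().set_index(["portion", "parameter"])
    for j, name in enumerate(m.loc_names):
        row = s.loc[("location", name)]
        mcse = row["sd"] / np.sqrt(max(row["ess_bulk"], 4))
        assert row["median"] == pytest.approx(ols[j], abs=3 * mcse + 0.02)


def test_homoscedastic_reduction_matches_mixedlm_reml():
    # location-only fit vs restricted maximum likelihood (statsmodels MixedLM)
    import statsmodels.formula.api as smf

    cfg = tv.GeneratorConfig(
        n_per_group=20, trials_per_condition=20, dropout_rate=0.0,
        eta=(float(np.log(2.0)), 0, 0, 0), tau_loc=(1.5, 1.0), tau_scale=(0, 0),
        seed=21,
    )
    t = tv.simulate_trial_table(cfg).copy()
    t["ev"] = (t["event"] == "deviant").astype(float)
    t["gr"] = (t["group"] == "patient").astype(float)
    mlm = smf.mixedlm(
        "amplitude ~ ev * gr", t, groups=t["participant_id"], re_formula="~ev"
    ).fit(reml=True)
    res = _quiet_fit(
        MELSM(t, MelsmSpec.location_only()), draws=300, warmup=300, chains=2, seed=2
    )
    s = res.summary().set_index(["portion", "parameter"])
    pairs = {
        "Intercept": "Intercept", "ev": "event[deviant]", "gr": "group[patient]",
        "ev:gr": "event[deviant]:group[patient]",
    }
    for sm_name, our_name in pairs.items():
        assert s.loc[("location", our_name), "median"] == pytest.approx(
            mlm.params[sm_name], abs=2.0 * mlm.bse[sm_name]
        )
    # residual SD and random-intercept SD agree with REML point estimates
    eta0 = res._coef_draws("scale", "Intercept")
    assert np.exp(np.median(eta0)) == pytest.approx(
        np.sqrt(mlm.scale), rel=0.05
    )
    tau0 = res._tau[:, :, 0].ravel()
    assert np.median(tau0) == pytest.approx(
        np.sqrt(mlm.cov_re.iloc[0, 0]), rel=0.2
    )


def test_location_scale_separation_under_shift_and_scaling():
    cfg = tv.GeneratorConfig(n_per_group=10, trials_per_condition=10, seed=31)
    t = tv.simulate_trial_table(cfg)
    base = _quiet_fit(MELSM(t), draws=250, warmup=250, chains=2, seed=3)

    shifted = t.copy()
    shifted["amplitude"] += 7.0
    res_shift = _quiet_fit(MELSM(shifted), draws=250, warmup=250, chains=2, seed=3)
    sb = base.summary().set_index(["portion", "parameter"])
    ss = res_shift.summary().set_index(["portion", "parameter"])
    tol = 4 * sb["sd"] / np.sqrt(50) + 0.02
    # scale coefficients unchanged; location intercept shifts by the constant
    for name in base.model.scale_names:
        assert ss.loc[("scale", name), "median"] == pytest.approx(
            sb.loc[("scale", name), "median"], abs=tol.loc[("scale", name)]
        )
    assert ss.loc[("location", "Intercept"), "median"] == pytest.approx(
        sb.loc[("location", "Intercept"), "median"] + 7.0,
        abs=tol.loc[("location", "Intercept")],
    )

    scaled = t.copy()
    c = 3.0
    scaled["amplitude"] *= c
    res_scale = _quiet_fit(MELSM(scaled), draws=250, warmup=250, chains=2, seed=3)
    sc = res_scale.summary().set_index(["portion", "parameter"])
    assert sc.loc[("scale", "Intercept"), "median"] == pytest.approx(
        sb.loc[("scale", "Intercept"), "median"] + np.log(c), abs=0.06
    )
    for name in base.model.loc_names:
        assert sc.loc[("location", name), "median"] == pytest.approx(
            c * sb.loc[("location", name), "median"],
            abs=c * tol.loc[("location", name)],
        )


# --------------------------------------------------------------------------
# summaries and transforms
# --------------------------------------------------------------------------


def test_summarize_percentiles_match_brute_force():
    r = summarize(np.arange(1.0, 101.0))
    assert r.posterior_median == 50.5
    assert r.cri_low == pytest.approx(3.475)
    assert r.cri_high == pytest.approx(97.525)
    assert r.excludes_zero


def test_summarize_constant_draws():
    r = summarize(np.full(500, 2.5))
    assert (r.posterior_median, r.cri_low, r.cri_high) == (2.5, 2.5, 2.5)
    assert r.excludes_zero
    r0 = summarize(np.zeros(500))
    assert not r0.excludes_zero


def test_difference_contrast_equals_drawwise_difference(small_fit):
    # the difference-score group contrast must equal the drawwise difference
    # of the two event-specific group contrasts
    by_event = small_fit.group_contrasts("scale")
    g = small_fit._coef_draws("scale", "group[patient]")
    ix = small_fit._coef_draws("scale", "event[deviant]:group[patient]")
    drawwise = summarize((g + ix) - g, name="diff", scale_portion=True)
    assert by_event["difference"].posterior_median == pytest.approx(
        drawwise.posterior_median
    )
    assert by_event["difference"].cri_low == pytest.approx(drawwise.cri_low)
    assert by_event["standard"].posterior_median == pytest.approx(
        float(np.median(g))
    )


def test_contrast_result_invariants_enforced():
    with pytest.raises(ValueError, match="inside the credible interval"):
        ContrastResult("bad", 5.0, -1.0, 1.0, False)
    with pytest.raises(ValueError, match="excludes_zero"):
        ContrastResult("bad", 0.5, -1.0, 1.0, True)


def test_unknown_coefficient_rejected(small_fit):
    with pytest.raises(KeyError):
        small_fit.contrast("scale", {"group[alien]": 1.0})


def test_percent_change_in_sd_values():
    assert percent_change_in_sd(-0.02) == pytest.approx(-1.9801, abs=1e-3)
    assert percent_change_in_sd(0.0) == 0.0
    assert percent_change_in_sd(np.log(2.0)) == pytest.approx(100.0)


# --------------------------------------------------------------------------
# registered decision rules
# --------------------------------------------------------------------------


def test_mmn_d_pattern_reads_opposite():
    # group CrIs contain zero but the difference contrast excludes zero with
    # patients LESS variable
    d = decide_hypothesis(
        group=_cr(-0.02, 0.10),
        interaction=_cr(-0.03, -0.004),
        event_contrasts=(_cr(-0.02, 0.10, "standard"), _cr(-0.04, 0.08, "deviant")),
        predicted="higher",
    )
    assert d.verdict == "opposite"


def test_rewp_null_prediction_supported_when_both_contain_zero():
    d = decide_hypothesis(
        group=_cr(-0.07, 0.08),
        interaction=_cr(-0.07, 0.06),
        event_contrasts=(_cr(-0.07, 0.08, "loss"), _cr(-0.08, 0.07, "gain")),
        predicted="null",
    )
    assert d.verdict == "supported"
    d2 = decide_hypothesis(
        group=_cr(0.01, 0.08),
        interaction=_cr(-0.07, 0.06),
        event_contrasts=(_cr(0.01, 0.08, "loss"), _cr(-0.08, 0.07, "gain")),
        predicted="null",
    )
    assert d2.verdict == "not supported"


def test_ern_all_containing_zero_not_supported():
    d = decide_hypothesis(
        group=_cr(-0.11, 0.09),
        interaction=_cr(-0.05, 0.05),
        event_contrasts=(_cr(-0.11, 0.09, "correct"), _cr(-0.11, 0.08, "error")),
        predicted="higher",
    )
    assert d.verdict == "not supported"


def test_higher_prediction_supported_via_group_or_interaction():
    via_group = decide_hypothesis(
        group=_cr(0.02, 0.12),
        interaction=_cr(-0.05, 0.05),
        event_contrasts=(_cr(0.02, 0.12, "standard"), _cr(-0.01, 0.13, "deviant")),
        predicted="higher",
    )
    assert via_group.verdict == "supported"
    via_interaction = decide_hypothesis(
        group=_cr(-0.03, 0.06),
        interaction=_cr(0.01, 0.09),
        event_contrasts=(_cr(-0.03, 0.06, "standard"), _cr(0.02, 0.12, "deviant")),
        predicted="higher",
    )
    assert via_interaction.verdict == "supported"
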