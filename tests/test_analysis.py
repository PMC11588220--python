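"""Preference statistics, t-tests and mixed models against independent oracles."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from melgram.analysis import (
    DegenerateTestError,
    compare_models,
    fit_accent_glmm,
    fit_ic_glmm,
    one_sample_t,
    paired_t,
    preference_differences,
)
from melgram.grammar import default_grammar
from melgram.simulate import SimConfig, simulate_cohort

SPEC = default_grammar()


def _fca_rows(pid, records):
    """records: (ic_condition, contour, choice) triples."""
    return [{"participant_id": pid, "musician": False, "phase": "fc_accent",
             "ic_condition": ic, "contour": c, "order": 0, "choice": y}
            for ic, c, y in records]


# ---------------------------------------------------------------------------
# preference differences

def test_delta_ic_arithmetic():
    rows = _fca_rows(1, [("high", "peak", 1)] * 6 + [("high", "peak", 0)] * 2
                     + [("low", "valley", 1)] * 4 + [("low", "valley", 0)] * 4)
    prefs = preference_differences(pd.DataFrame(rows))
    assert prefs.table.loc[1, "delta_ic"] == pytest.approx(25.0)


def test_all_accented_chosen_gives_zero_deltas():
    rows = _fca_rows(1, [("high", "peak", 1), ("low", "valley", 1),
                         ("high", "ascending", 1), ("low", "descending", 1)])
    prefs = preference_differences(pd.DataFrame(rows))
    assert prefs.table.loc[1, "delta_ic"] == 0.0
    assert prefs.table.loc[1, "delta_peak"] == 0.0


def test_four_participant_fixture_matches_hand_tabulation():
    # spreadsheet-style hand counts for four participants
    data = {
        1: [("high", "peak", 1), ("high", "valley", 0), ("low", "peak", 1), ("low", "valley", 1)],
        2: [("high", "peak", 0), ("high", "valley", 0), ("low", "peak", 1), ("low", "valley", 0)],
        3: [("high", "ascending", 1), ("high", "peak", 1), ("low", "descending", 0), ("low", "valley", 0)],
        4: [("high", "peak", 1), ("high", "peak", 1), ("low", "peak", 0), ("low", "peak", 0)],
    }
    rows = [r for pid, recs in data.items() for r in _fca_rows(pid, recs)]
    prefs = preference_differences(pd.DataFrame(rows))
    # participant 1: high 50%, low 100%; peak 100%, nonpeak 50%
    assert prefs.table.loc[1, "delta_ic"] == pytest.approx(-50.0)
    assert prefs.table.loc[1, "delta_peak"] == pytest.approx(50.0)
    # participant 2: high 0%, low 50%; peak 50%, nonpeak 0%
    assert prefs.table.loc[2, "delta_ic"] == pytest.approx(-50.0)
    assert prefs.table.loc[2, "delta_peak"] == pytest.approx(50.0)
    # participant 3: high 100%, low 0%; peak 100%, nonpeak 1/3
    assert prefs.table.loc[3, "delta_ic"] == pytest.approx(100.0)
    assert prefs.table.loc[3, "delta_peak"] == pytest.approx(100.0 - 100.0 / 3)
    # participant 4: all peak items -> nonpeak stratum empty, flagged NaN
    assert math.isnan(prefs.table.loc[4, "delta_peak"])
    assert prefs.excluded_peak == 1
    assert len(prefs.delta_peak) == 3


# ---------------------------------------------------------------------------
# t-tests

def test_zero_variance_deltas_raise():
    with pytest.raises(DegenerateTestError):
        one_sample_t(np.array([1.0, 1.0, 1.0, 1.0]))


def test_symmetric_deltas_give_t_zero_p_one():
    res = one_sample_t(np.array([2.0, -2.0, 2.0, -2.0]))
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_one_sample_t_closed_form():
    # mean 3, sd sqrt(2.5): t = 3 / (sqrt(2.5)/sqrt(5)) = 4.242640687...
    res = one_sample_t(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    assert res.t == pytest.approx(3 / (np.sqrt(2.5) / np.sqrt(5)), abs=1e-10)
    assert res.df == 4


def test_paired_t_matches_textbook_formula():
    ratings = pd.DataFrame(
        [{"participant_id": p, "variant": v, "rating": r}
         for p, (g, a) in enumerate([(6, 4), (5, 5.0 - 1e-9), (7, 3), (6, 2)])
         for v, r in (("grammatical", g), ("agrammatical", a))]
    )
    res = paired_t(ratings)
    d = np.array([2.0, 1e-9, 4.0, 4.0])
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert res.t == pytest.approx(t_expected, abs=1e-10)
    assert res.df == 3


# ---------------------------------------------------------------------------
# GLMMs

@pytest.fixture(scope="module")
def effect_cohort():
    cfg = SimConfig(n_participants=80, beta_peak=0.8, beta_ic=0.0, sigma_u=0.5, seed=31)
    choices, _ = simulate_cohort(SPEC, cfg, phases=("fc_accent", "fc_ic"))
    return choices


def test_accent_glmm_recovers_peak_and_null_ic(effect_cohort):
    fit = fit_accent_glmm(effect_cohort)
    assert fit.converged
    peak = fit.params.loc["contour[peak]"]
    assert peak["ci_low"] > 0  # generating value 0.8
    ic = fit.params.loc["high_ic"]
    assert ic["ci_low"] < 0 < ic["ci_high"]  # generating value 0


def test_glmm_with_no_heterogeneity_matches_pooled_logistic():
    cfg = SimConfig(n_participants=50, beta_peak=0.8, sigma_u=0.0, seed=32)
    choices, _ = simulate_cohort(SPEC, cfg, phases=("fc_accent",))
    fit = fit_accent_glmm(choices)
    assert fit.sigma_u < 0.1
    fca = choices[choices["phase"] == "fc_accent"]
    X = pd.DataFrame({
        "intercept": 1.0,
        "contour[ascending]": (fca["contour"] == "ascending").astype(float),
        "contour[peak]": (fca["contour"] == "peak").astype(float),
        "contour[valley]": (fca["contour"] == "valley").astype(float),
        "high_ic": (fca["ic_condition"] == "high").astype(float),
        "musician": fca["musician"].astype(float),
    })
    X["high_ic:musician"] = X["high_ic"] * X["musician"]
    pooled = sm.GLM(fca["choice"].to_numpy(), X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.params["estimate"], pooled.params, atol=0.05)


def test_ic_glmm_accent_recovery():
    cfg = SimConfig(n_participants=60, gamma_accent=1.0, sigma_u=0.4, seed=33)
    choices, _ = simulate_cohort(SPEC, cfg, phases=("fc_ic",))
    fit = fit_ic_glmm(choices)
    acc = fit.params.loc["accented"]
    assert acc["ci_low"] > 0
    null_cfg = SimConfig(n_participants=60, gamma_accent=0.0, sigma_u=0.4, seed=34)
    null_choices, _ = simulate_cohort(SPEC, null_cfg, phases=("fc_ic",))
    null_fit = fit_ic_glmm(null_choices)
    acc0 = null_fit.params.loc["accented"]
    assert acc0["ci_low"] < 0 < acc0["ci_high"]


def test_ic_glmm_requires_records():
    with pytest.raises(ValueError):
        fit_ic_glmm(pd.DataFrame({"phase": []}))


def test_glmm_agrees_with_lme4(tmp_path, effect_cohort):
    """lme4::glmer (adaptive quadrature) is the independent mixed-model oracle."""
    fca = effect_cohort[effect_cohort["phase"] == "fc_accent"]
    csv = tmp_path / "fca.csv"
    fca.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$contour <- factor(d$contour, levels=c("descending","ascending","peak","valley"))
        d$high_ic <- as.numeric(d$ic_condition == "high")
        d$mus <- as.numeric(d$musician == "True")
        m <- glmer(choice ~ contour + high_ic + mus + high_ic:mus + (1|participant_id),
                   data=d, family=binomial, nAGQ=25)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), BIC(m), sep="\\n")
    """))
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
    vals = [float(x) for x in out.stdout.split()]
    fit = fit_accent_glmm(effect_cohort)
    np.testing.assert_allclose(fit.params["estimate"], vals[:7], atol=2e-3)
    assert fit.sigma_u == pytest.approx(vals[7], abs=5e-3)
    assert fit.loglik == pytest.approx(vals[8], abs=1e-3)
    assert fit.bic == pytest.approx(vals[9], abs=1e-2)


# ---------------------------------------------------------------------------
# model comparison

def test_identical_models_compare_to_null(effect_cohort):
    fit = fit_ic_glmm(effect_cohort)
    res = compare_models(fit, fit)
    assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 0


def test_dropping_the_four_level_contour_costs_three_df(effect_cohort):
    full = fit_accent_glmm(effect_cohort)
    res = compare_models(full, fit_accent_glmm(effect_cohort, drop=("contour",)))
    assert res.df == 3


def test_lrt_mirrors_generating_effects(effect_cohort):
    """Dropping the real contour effect hurts; dropping the null IC does not."""
    full = fit_accent_glmm(effect_cohort)
    no_contour = compare_models(full, fit_accent_glmm(effect_cohort, drop=("contour",)))
    no_ic = compare_models(full, fit_accent_glmm(effect_cohort, drop=("ic",)))
    assert no_contour.p < 0.01
    assert no_ic.p > 0.05


def test_non_nested_models_rejected(effect_cohort):
    accent = fit_accent_glmm(effect_cohort)
    ic = fit_ic_glmm(effect_cohort)
    with pytest.raises(ValueError):
        compare_models(accent, ic)
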