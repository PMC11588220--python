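"""Statistical pipeline for the forced-choice and rating data.

Mirrors the behavioural analysis: per-participant preference differences in
percentage points with one-sample t-tests, a paired t-test on similarity
ratings, binomial mixed-effects models (random participant intercept) for
both forced-choice tasks, and likelihood-ratio / BIC comparison of nested
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GlmmFit, fit_binomial_glmm

__all__ = [
    "PreferenceSummary",
    "TTestResult",
    "ModelComparison",
    "preference_differences",
    "one_sample_t",
    "paired_t",
    "rating_means_by_variant",
    "fit_accent_glmm",
    "fit_ic_glmm",
    "compare_models",
]

CONTOUR_LEVELS = ("descending", "ascending", "peak", "valley")  # reference first


class DegenerateTestError(ValueError):
    """Raised when a t-test is requested on zero-variance data."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_difference: float
    n: int


@dataclass(frozen=True)
class PreferenceSummary:
    """Per-participant stratified accent-choice percentages and differences."""

    table: pd.DataFrame  # one row per participant
    excluded_ic: int  # participants lacking an IC stratum
    excluded_peak: int

    @property
    def delta_ic(self) -> np.ndarray:
        return self.table["delta_ic"].dropna().to_numpy()

    @property
    def delta_peak(self) -> np.ndarray:
        return self.table["delta_peak"].dropna().to_numpy()


@dataclass(frozen=True)
class ModelComparison:
    chi2: float
    df: int
    p: float
    delta_bic: float  # BIC(reduced) - BIC(full)


# ---------------------------------------------------------------------------
# preference differences and t-tests

def preference_differences(choices: pd.DataFrame) -> PreferenceSummary:
    """Stratified accent-choice percentages per participant.

    From the accent-preference task: % accented chosen within high-IC and
    low-IC items (difference ``delta_ic`` = high - low) and within peak and
    non-peak items (``delta_peak`` = peak - non-peak), in percentage points.
    Participants with an empty stratum get NaN in the corresponding
    difference and are counted as excluded for that test, never zero-filled.
    """
    fca = choices[choices["phase"] == "fc_accent"]
    if fca.empty:
        raise ValueError("no accent-preference records in the choice table")
    rows = []
    for pid, sub in fca.groupby("participant_id"):
        def pct(mask: pd.Series) -> float:
            return 100.0 * sub.loc[mask, "choice"].mean() if mask.any() else np.nan

        hi = pct(sub["ic_condition"] == "high")
        lo = pct(sub["ic_condition"] == "low")
        pk = pct(sub["contour"] == "peak")
        npk = pct(sub["contour"] != "peak")
        rows.append({
            "participant_id": pid,
            "pct_accented_high_ic": hi, "pct_accented_low_ic": lo,
            "pct_accented_peak": pk, "pct_accented_nonpeak": npk,
            "delta_ic": hi - lo, "delta_peak": pk - npk,
        })
    table = pd.DataFrame(rows).set_index("participant_id")
    excl_ic = int(table["delta_ic"].isna().sum())
    excl_peak = int(table["delta_peak"].isna().sum())
    if excl_ic or excl_peak:
        warnings.warn(
            f"excluding participants with empty strata: {excl_ic} (IC), {excl_peak} (peak)",
            stacklevel=2,
        )
    return PreferenceSummary(table=table, excluded_ic=excl_ic, excluded_peak=excl_peak)


def one_sample_t(deltas: np.ndarray) -> TTestResult:
    """Two-sided one-sample t-test of the mean difference against zero."""
    x = np.asarray(deltas, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise DegenerateTestError("need at least two observations")
    if np.ptp(x) == 0:
        raise DegenerateTestError("zero variance in the differences")
    res = stats.ttest_1samp(x, 0.0)
    return TTestResult(t=float(res.statistic), df=len(x) - 1,
                       p=float(res.pvalue), mean_difference=float(x.mean()), n=len(x))


def rating_means_by_variant(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean similarity rating for each melody variant."""
    wide = (ratings.groupby(["participant_id", "variant"])["rating"].mean()
            .unstack("variant"))
    missing = wide.isna().any(axis=1)
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} participants without both variants",
                      stacklevel=2)
    return wide.dropna()


def paired_t(ratings: pd.DataFrame) -> TTestResult:
    """Within-participant t-test: grammatical vs agrammatical mean ratings."""
    wide = rating_means_by_variant(ratings)
    diff = (wide["grammatical"] - wide["agrammatical"]).to_numpy()
    if len(diff) < 2:
        raise DegenerateTestError("need at least two participants")
    if np.ptp(diff) == 0:
        raise DegenerateTestError("zero variance in the paired differences")
    res = stats.ttest_rel(wide["grammatical"], wide["agrammatical"])
    return TTestResult(t=float(res.statistic), df=len(diff) - 1,
                       p=float(res.pvalue), mean_difference=float(diff.mean()), n=len(diff))


# ---------------------------------------------------------------------------
# mixed models

def _accent_design(fca: pd.DataFrame, *, drop: tuple[str, ...] = ()) -> pd.DataFrame:
    """Design matrix for the accent-preference model.

    Treatment coding with 'descending' as the contour reference level;
    fixed effects: contour (3 dummies), high IC, musician, IC x musician.
    ``drop`` removes whole conceptual terms for reduced models.
    """
    X = pd.DataFrame({"intercept": np.ones(len(fca))}, index=fca.index)
    if "contour" not in drop:
        for lvl in CONTOUR_LEVELS[1:]:
            X[f"contour[{lvl}]"] = (fca["contour"] == lvl).astype(float)
    if "ic" not in drop:
        X["high_ic"] = (fca["ic_condition"] == "high").astype(float)
    if "musicianship" not in drop:
        X["musician"] = fca["musician"].astype(float)
    if "ic" not in drop and "musicianship" not in drop and "ic_x_musician" not in drop:
        X["high_ic:musician"] = X["high_ic"] * X["musician"]
    return X


def fit_accent_glmm(choices: pd.DataFrame, *, drop: tuple[str, ...] = ()) -> GlmmFit:
    """Binomial GLMM for the accent-preference task.

    Response: chose the accented member.  Fixed effects: melodic contour
    (categorical, reference = descending), IC condition, musicianship and
    the IC x musicianship interaction; random intercept per participant.
    ``drop`` fits a reduced model without the named terms.
    """
    fca = choices[choices["phase"] == "fc_accent"]
    if fca.empty:
        raise ValueError("no accent-preference records")
    if fca["participant_id"].nunique() < 2:
        raise ValueError("need at least two participants")
    if fca["ic_condition"].nunique() < 2 and "ic" not in drop:
        raise ValueError("both IC levels must be present")
    if fca["contour"].nunique() < 2 and "contour" not in drop:
        raise ValueError("need at least two contour classes")
    X = _accent_design(fca, drop=drop)
    label = "choice(accented) ~ " + " + ".join(X.columns) + " + (1 | participant)"
    return fit_binomial_glmm(fca["choice"].to_numpy(), X,
                             fca["participant_id"].to_numpy(), formula=label)


def _ic_design(fci: pd.DataFrame, *, drop: tuple[str, ...] = ()) -> pd.DataFrame:
    X = pd.DataFrame({"intercept": np.ones(len(fci))}, index=fci.index)
    if "accent" not in drop:
        X["accented"] = fci["accented"].astype(float)
    if "musicianship" not in drop:
        X["musician"] = fci["musician"].astype(float)
    if "accent" not in drop and "musicianship" not in drop and "accent_x_musician" not in drop:
        X["accented:musician"] = X["accented"] * X["musician"]
    return X


def fit_ic_glmm(choices: pd.DataFrame, *, drop: tuple[str, ...] = ()) -> GlmmFit:
    """Binomial GLMM for the IC-preference task.

    Response: chose the high-IC member.  Fixed effects: target-note accent,
    musicianship and their interaction; random intercept per participant.
    """
    fci = choices[choices["phase"] == "fc_ic"]
    if fci.empty:
        raise ValueError("no IC-preference records")
    if fci["participant_id"].nunique() < 2:
        raise ValueError("need at least two participants")
    X = _ic_design(fci, drop=drop)
    label = "choice(high_ic) ~ " + " + ".join(X.columns) + " + (1 | participant)"
    return fit_binomial_glmm(fci["choice"].to_numpy(), X,
                             fci["participant_id"].to_numpy(), formula=label)


def compare_models(full: GlmmFit, reduced: GlmmFit) -> ModelComparison:
    """Likelihood-ratio test of nested fits on the same data, plus delta-BIC.

    chi2 = 2 (loglik_full - loglik_reduced), df = difference in parameter
    count; small negative chi2 from optimiser tolerance is clipped to zero.
    """
    if set(reduced.fixed_terms) - set(full.fixed_terms):
        raise ValueError("models are not nested: reduced has terms absent from full")
    if reduced.nobs != full.nobs:
        raise ValueError("models were fit on different data")
    df = full.k_params - reduced.k_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -1e-6 * max(1.0, abs(full.loglik)):
        warnings.warn(f"reduced model out-fit the full model (chi2 = {chi2:.4g}); "
                      "check convergence", stacklevel=2)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return ModelComparison(chi2=chi2, df=df, p=p,
                           delta_bic=float(reduced.bic - full.bic))
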