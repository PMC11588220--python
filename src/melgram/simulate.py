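"""Synthetic participant responses with the structure the analysis assumes.

Participants are modelled with a shared fixed-effect structure plus a
zero-mean normal random intercept ``u`` (SD ``sigma_u``):

* similarity ratings (grammar-learning trials) are a participant baseline
  plus a grammaticality gap ``delta`` and Gaussian noise, rounded and
  clamped to the 1-7 scale;
* forced choices are Bernoulli draws whose log-odds are a linear predictor
  over the trial covariates -- for accent-preference items the probability
  of choosing the *accented* member, for IC-preference items the probability
  of choosing the *high-IC* member.

The default scenario encodes a positive peak-contour effect with null IC
and musicianship effects, the ground truth used for parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .experiment import Trial, TrialSchedule, build_full_schedule
from .grammar import GrammarSpec

__all__ = [
    "ParticipantProfile",
    "SimConfig",
    "simulate_similarity_rating",
    "simulate_liking_rating",
    "simulate_forced_choice",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ParticipantProfile:
    id: int
    musician: bool
    random_intercept: float  # u ~ N(0, sigma_u^2), shared across that person's choices
    grammar_sensitivity: float = 1.5  # mean rating gap grammatical - agrammatical
    rating_base: float = 4.0
    rating_noise_sd: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Cohort and effect-size configuration.

    ``beta_*`` parameterise the accent-preference choice (log-odds of
    choosing the accented member); ``gamma_*`` the IC-preference choice
    (log-odds of choosing the high-IC member).  The defaults encode the
    scenario the analyses are validated against: a real peak-contour effect
    and null IC/musicianship effects.
    """

    n_participants: int = 78
    musician_fraction: float = 0.5
    # accent-preference model
    beta0: float = 0.0
    beta_peak: float = 0.5
    beta_ic: float = 0.0
    beta_mus: float = 0.0
    beta_ic_mus: float = 0.0
    # IC-preference model
    gamma0: float = 0.0
    gamma_accent: float = 0.0
    gamma_mus: float = 0.0
    gamma_accent_mus: float = 0.0
    sigma_u: float = 0.5
    grammar_sensitivity: float = 1.5
    rating_noise_sd: float = 1.0
    liking_drift_per_trial: float = 0.0  # optional linear drift hook; feeds no analysis
    seed: int = 0

    def validate(self) -> None:
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")
        if not (0 <= self.musician_fraction <= 1):
            raise ValueError("musician_fraction must be in [0,1]")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_similarity_rating(
    profile: ParticipantProfile,
    trial: Trial,
    rng: np.random.Generator,
) -> int:
    """One 1-7 similarity rating for a grammar-learning trial.

    rating = round(clamp(base + u + delta * 1[grammatical] + noise, 1, 7)).
    """
    if trial.kind != "learning":
        raise ValueError(f"expected a learning trial, got {trial.kind}")
    grammatical = trial.info["variant"] == "grammatical"
    x = (profile.rating_base + profile.random_intercept
         + profile.grammar_sensitivity * grammatical
         + (rng.normal(0.0, profile.rating_noise_sd) if profile.rating_noise_sd > 0 else 0.0))
    return int(round(min(7.0, max(1.0, x))))


def simulate_liking_rating(
    profile: ParticipantProfile,
    trial_index: int,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> int:
    """One 1-7 liking rating for an exposure liking trial.

    Baseline plus the participant intercept, optional linear drift over the
    course of the exposure phase, and rating noise.  These ratings enter no
    analysis; the hook exists so exposure-phase engagement data can be
    emulated when a study needs it.
    """
    x = (profile.rating_base + profile.random_intercept
         + cfg.liking_drift_per_trial * trial_index
         + (rng.normal(0.0, profile.rating_noise_sd) if profile.rating_noise_sd > 0 else 0.0))
    return int(round(min(7.0, max(1.0, x))))


def simulate_forced_choice(
    profile: ParticipantProfile,
    item: Trial,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict:
    """One binary forced choice with all covariates recorded.

    For ``fc_accent`` items the recorded ``choice`` is 1 when the accented
    member is chosen; for ``fc_ic`` items, 1 when the high-IC member is.
    """
    u = profile.random_intercept
    mus = float(profile.musician)
    if item.kind == "fc_accent":
        peak = float(item.info["contour"] == "peak")
        high = float(item.info["ic_condition"] == "high")
        eta = (cfg.beta0 + cfg.beta_peak * peak + cfg.beta_ic * high
               + cfg.beta_mus * mus + cfg.beta_ic_mus * high * mus + u)
        choice = int(rng.random() < _logistic(eta))
        return {
            "participant_id": profile.id, "musician": profile.musician,
            "phase": "fc_accent", "ic_condition": item.info["ic_condition"],
            "contour": item.info["contour"],
            "order": item.info["accented_position"], "choice": choice,
        }
    if item.kind == "fc_ic":
        acc = float(item.info["accented"])
        eta = (cfg.gamma0 + cfg.gamma_accent * acc + cfg.gamma_mus * mus
               + cfg.gamma_accent_mus * acc * mus + u)
        choice = int(rng.random() < _logistic(eta))
        return {
            "participant_id": profile.id, "musician": profile.musician,
            "phase": "fc_ic", "accented": bool(item.info["accented"]),
            "contour_high": item.info["contour_high"],
            "order": item.info["high_position"], "choice": choice,
        }
    raise ValueError(f"expected a forced-choice trial, got {item.kind}")


def _make_profiles(cfg: SimConfig, rng: np.random.Generator) -> list[ParticipantProfile]:
    n = cfg.n_participants
    n_mus = int(round(cfg.musician_fraction * n))
    musician = np.zeros(n, dtype=bool)
    musician[:n_mus] = True
    rng.shuffle(musician)
    u = rng.normal(0.0, cfg.sigma_u, size=n) if cfg.sigma_u > 0 else np.zeros(n)
    return [
        ParticipantProfile(
            id=i, musician=bool(musician[i]), random_intercept=float(u[i]),
            grammar_sensitivity=cfg.grammar_sensitivity,
            rating_noise_sd=cfg.rating_noise_sd,
        )
        for i in range(n)
    ]


def simulate_cohort(
    spec: GrammarSpec,
    cfg: SimConfig,
    *,
    schedule_builder: Callable[[GrammarSpec, int], TrialSchedule] | None = None,
    phases: tuple[str, ...] = ("learning", "fc_accent", "fc_ic"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: (choice table, rating table), both long format.

    Each participant gets an independently built schedule (participant seeds
    are spawned from ``cfg.seed``) and responds to its learning and
    forced-choice phases.  ``schedule_builder`` defaults to the standard
    protocol builder; restricting ``phases`` skips the others entirely,
    which keeps null-calibration studies cheap.
    """
    cfg.validate()
    if cfg.n_participants == 0:
        warnings.warn("simulating an empty cohort", stacklevel=2)
        return pd.DataFrame(), pd.DataFrame()
    master = np.random.SeedSequence(cfg.seed)
    response_rng = np.random.default_rng(master.spawn(1)[0])
    profiles = _make_profiles(cfg, response_rng)
    schedule_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(cfg.n_participants)]

    if schedule_builder is None:
        def schedule_builder(spec_, seed_):
            return _phase_subset_schedule(spec_, seed_, phases)

    choices: list[dict] = []
    ratings: list[dict] = []
    for prof, sched_seed in zip(profiles, schedule_seeds):
        schedule = schedule_builder(spec, sched_seed)
        for ph in phases:
            for i, trial in enumerate(schedule.phases.get(ph, ())):
                if trial.kind == "learning":
                    r = simulate_similarity_rating(prof, trial, response_rng)
                    ratings.append({
                        "participant_id": prof.id, "musician": prof.musician,
                        "item_id": f"{ph}_{i}", "variant": trial.info["variant"],
                        "rating": r,
                    })
                elif trial.kind in ("fc_accent", "fc_ic"):
                    rec = simulate_forced_choice(prof, trial, cfg, response_rng)
                    rec["item_id"] = f"{ph}_{i}"
                    choices.append(rec)
    return pd.DataFrame(choices), pd.DataFrame(ratings)


def _phase_subset_schedule(spec: GrammarSpec, seed: int, phases: tuple[str, ...]) -> TrialSchedule:
    """Build only the phases a simulation consumes.

    Responses are never collected during exposure, so the exposure phase is
    not assembled here; the learning test draws its grammatical items from a
    just-big-enough pool of exposure-grammar melodies instead.  Use
    :func:`melgram.experiment.build_full_schedule` (via ``schedule_builder``)
    when the complete protocol matters.
    """
    from .experiment import (build_accent_preference_test, build_ic_preference_test,
                             build_learning_test)
    from .grammar import generate_exposure_melody

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: dict[str, tuple[Trial, ...]] = {}
    stimuli = {}
    if "learning" in phases:
        pool = [generate_exposure_melody(spec, rng) for _ in range(8)]
        t, s = build_learning_test(spec, rng, pool)
        out["learning"] = t
        stimuli.update(s)
    if "fc_accent" in phases:
        t, s = build_accent_preference_test(spec, rng)
        out["fc_accent"] = t
        stimuli.update(s)
    if "fc_ic" in phases:
        t, s = build_ic_preference_test(spec, rng)
        out["fc_ic"] = t
        stimuli.update(s)
    return TrialSchedule(phases=out, stimuli=stimuli, tonic_condition=0, seed=seed)
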