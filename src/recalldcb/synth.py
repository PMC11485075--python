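"""Synthetic cohort generator.

Emulates the structure of a longitudinal memory-aging cohort: item-level
word-recall responses (10 words, three immediate tasks with shuffled
presentation orders, one delayed task), demographic covariates, a
polygenic hazard score, Clinical Dementia Rating (CDR) at baseline and
at 36 months, and a known ground truth for every participant so that
parameter- and pipeline-recovery experiments are possible.

Covariate moments and the marginal counts (baseline CDR composition,
decliner fraction 61/330, logistic decline slope -14.94 on the true
recall-ability score M) follow the cohort this package's analyses are
designed around.  The per-participant encoding/retrieval probabilities
are drawn from independent logit-normal distributions with a mild
negative age trend; their base values and spread were calibrated once
so that the cohort mean of N_avg is about 0.431 and the recall-ability
average M_avg has mean about 0.53 with SD about 0.083.
(Under the route-attributed definition of M1/M2/M3 used here, M_avg is
mathematically bounded above by 2/3, so cohort-level M means quoted for
proprietary recombinations of the same parameters are not attainable;
see the methods note.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from recalldcb.model import (
    PARAM_NAMES,
    SCORE_NAMES,
    PositionEffects,
    scores_from_arrays,
    simulate_patterns,
)

__all__ = ["CohortConfig", "generate_cohort", "permute_positions", "priors_from_config"]


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_participants: int = 330
    n_words: int = 10
    rng_seed: int = 0

    # covariates
    age_mean: float = 71.4
    age_sd: float = 7.2
    male_fraction: float = 184 / 330
    education_mean: float = 16.333
    education_sd: float = 2.636
    phs_mean: float = 0.339
    phs_sd: float = 0.779

    # baseline CDR composition
    cdr_baseline_levels: tuple = (0.0, 0.5, 1.0)
    cdr_baseline_probs: tuple = (29 / 330, 300 / 330, 1 / 330)

    # latent parameter distribution (logit scale): base probabilities,
    # shared ability factor, unique noise, age trend per year
    dcb_base_probs: tuple = (0.56, 0.62, 0.52, 0.04, 0.85, 0.95, 0.95)
    dcb_shared_sd: float = 0.0
    dcb_unique_sd: float = 1.28
    age_logit_slope: float = -0.015

    # decline model: logit P(decline) = b0 + slope*M_true + phs_slope*(PHS-mean);
    # b0 is solved at generation time so the expected decliner fraction
    # matches decline_rate
    decline_slope: float = -14.94
    decline_rate: float = 61 / 330
    phs_decline_slope: float = 0.3

    # CDR transition shape
    decline_steps: tuple = (0.5, 1.0, 1.5)
    decline_step_probs: tuple = (0.64, 0.30, 0.06)
    reversion_prob: float = 0.13  # non-decliner 0.5 -> 0 at follow-up

    list_ids: tuple = ("A", "B", "C")

    def validate(self) -> None:
        if self.n_participants < 0 or self.n_words < 1:
            raise ValueError("n_participants must be >= 0 and n_words >= 1")
        for name, probs in (
            ("cdr_baseline_probs", self.cdr_baseline_probs),
            ("decline_step_probs", self.decline_step_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"{name} must be a probability vector")
        if self.age_sd <= 0 or self.education_sd <= 0 or self.phs_sd <= 0:
            raise ValueError("covariate SDs must be positive")
        if not (0.0 <= self.decline_rate <= 1.0):
            raise ValueError("decline_rate must be a probability")
        if any(not (0.0 < p < 1.0) for p in self.dcb_base_probs):
            raise ValueError("dcb_base_probs must lie strictly in (0, 1)")


def permute_positions(
    n_words: int, n_tasks: int, rng: np.random.Generator
) -> np.ndarray:
    """Presentation positions, shape (n_words, n_tasks); each task's
    column is an independent uniform permutation of 1..n_words."""
    return np.stack(
        [rng.permutation(n_words) + 1 for _ in range(n_tasks)], axis=1
    )


def _empty_tables() -> tuple:
    recall = pd.DataFrame(
        columns=[
            "participant_id", "word_id", "list_id", "pos1", "pos2", "pos3",
            "recall_ifr1", "recall_ifr2", "recall_ifr3", "recall_dfr",
        ]
    )
    participants = pd.DataFrame(
        columns=["participant_id", "age", "sex", "education", "phs",
                 "cdr_baseline", "cdr_36m"]
    )
    truth = pd.DataFrame(
        columns=["participant_id", *PARAM_NAMES, *SCORE_NAMES,
                 "p_decline", "decline"]
    )
    return recall, participants, truth


def generate_cohort(
    config: CohortConfig | None = None,
    effects: PositionEffects | None = None,
) -> tuple:
    """Draw a complete synthetic cohort.

    Returns ``(recall_df, participants_df, truth_df)``: the item-level
    recall table, the covariate table, and the ground truth (true
    parameters, true scores, decline probability and indicator).
    Deterministic given ``config.rng_seed``.
    """
    config = config or CohortConfig()
    config.validate()
    effects = effects if effects is not None else PositionEffects()
    n = config.n_participants
    if n == 0:
        return _empty_tables()
    rng = np.random.default_rng(config.rng_seed)

    pids = [f"P{i + 1:04d}" for i in range(n)]
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 55.0, 95.0)
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    education = np.clip(
        np.round(rng.normal(config.education_mean, config.education_sd, n)), 6, 20
    ).astype(int)
    phs = rng.normal(config.phs_mean, config.phs_sd, n)
    cdr_baseline = rng.choice(
        config.cdr_baseline_levels, size=n, p=config.cdr_baseline_probs
    )

    mu = logit(np.asarray(config.dcb_base_probs))
    theta = (
        mu
        + config.age_logit_slope * (age - config.age_mean)[:, None]
        + config.dcb_shared_sd * rng.standard_normal((n, 1))
        + config.dcb_unique_sd * rng.standard_normal((n, 7))
    )
    params = expit(theta)
    scores = scores_from_arrays(params)
    m_true = scores[:, 5]

    # solve the decline-model intercept so the expected decliner
    # fraction matches the configured rate for this realized cohort
    lin = config.decline_slope * m_true + config.phs_decline_slope * (
        phs - config.phs_mean
    )
    if config.decline_rate <= 0.0:
        p_decline = np.zeros(n)
    elif config.decline_rate >= 1.0:
        p_decline = np.ones(n)
    else:
        b0 = brentq(
            lambda b: expit(b + lin).mean() - config.decline_rate, -100.0, 100.0
        )
        p_decline = expit(b0 + lin)
    decline = rng.random(n) < p_decline

    steps = rng.choice(config.decline_steps, size=n, p=config.decline_step_probs)
    revert = (rng.random(n) < config.reversion_prob) & (cdr_baseline >= 0.5)
    cdr_36m = np.where(
        decline,
        np.minimum(cdr_baseline + steps, 3.0),
        np.where(revert, cdr_baseline - 0.5, cdr_baseline),
    )

    list_ids = [config.list_ids[i % len(config.list_ids)] for i in range(n)]
    recall_rows = []
    for i in range(n):
        positions = permute_positions(config.n_words, 3, rng)
        offs = np.array(
            [
                [effects.offset(list_ids[i], positions[w, t]) for t in range(3)]
                for w in range(config.n_words)
            ]
        )
        recalls = simulate_patterns(params[i], config.n_words, rng, offsets=offs)
        for w in range(config.n_words):
            recall_rows.append(
                (
                    pids[i], f"W{w + 1:02d}", list_ids[i],
                    *positions[w].tolist(), *recalls[w].tolist(),
                )
            )
    recall_df = pd.DataFrame(
        recall_rows,
        columns=[
            "participant_id", "word_id", "list_id", "pos1", "pos2", "pos3",
            "recall_ifr1", "recall_ifr2", "recall_ifr3", "recall_dfr",
        ],
    )
    participants_df = pd.DataFrame(
        {
            "participant_id": pids,
            "age": np.round(age, 1),
            "sex": sex,
            "education": education,
            "phs": np.round(phs, 4),
            "cdr_baseline": cdr_baseline,
            "cdr_36m": cdr_36m,
        }
    )
    truth_df = pd.DataFrame(
        {
            "participant_id": pids,
            **{name: params[:, k] for k, name in enumerate(PARAM_NAMES)},
            **{name: scores[:, k] for k, name in enumerate(SCORE_NAMES)},
            "p_decline": p_decline,
            "decline": decline.astype(int),
        }
    )
    return recall_df, participants_df, truth_df


def priors_from_config(
    config: CohortConfig | None = None,
    n_draws: int = 4000,
    seed: int = 12345,
):
    """Group priors matching the generator's own parameter distribution.

    For each demographic stratum a Beta is moment-matched (per
    parameter) to a Monte-Carlo sample drawn at the stratum's
    representative age (60/70/80 for the three bands).  This is the
    natural "oracle" prior for recovery experiments: it encodes the
    population the cohort was actually drawn from, playing the role the
    population-level demographic priors play for real assessments.
    """
    from recalldcb.inference import DEFAULT_GROUP, PriorSpec

    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    mu = logit(np.asarray(config.dcb_base_probs))

    def match(rep_age: float) -> dict:
        theta = (
            mu
            + config.age_logit_slope * (rep_age - config.age_mean)
            + config.dcb_shared_sd * rng.standard_normal((n_draws, 1))
            + config.dcb_unique_sd * rng.standard_normal((n_draws, 7))
        )
        p = expit(theta)
        m = p.mean(axis=0)
        v = np.minimum(np.maximum(p.var(axis=0), 1e-6), m * (1 - m) * 0.999)
        nu = m * (1 - m) / v - 1.0
        a = np.clip(m * nu, 0.5, 500.0)
        b = np.clip((1 - m) * nu, 0.5, 500.0)
        return {n_: (float(a[k]), float(b[k])) for k, n_ in enumerate(PARAM_NAMES)}

    groups = {DEFAULT_GROUP: match(config.age_mean)}
    for band, rep in (("age<65", 60.0), ("age65-75", 70.0), ("age>75", 80.0)):
        entry = match(rep)
        for sex in ("M", "F"):
            for edu in ("edu<16", "edu16+"):
                groups[f"{band}|{sex}|{edu}"] = entry
    return PriorSpec(groups)
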