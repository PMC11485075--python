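"""Hierarchical Bayesian estimation of recall-model parameters.

Each participant's seven encoding/retrieval probabilities are updated
independently against a demographic-group Beta prior using the observed
word-level recall patterns (the exact multinomial-processing-tree
likelihood), via adaptive random-walk Metropolis on the logit scale.
Derived recall-ability scores (M1..M3 and the averages N, R, M) are
computed per retained draw so that their posterior summaries propagate
parameter uncertainty.

Group priors are either supplied by the user (see
:class:`PriorSpec`) or estimated from a calibration cohort by
empirical-Bayes moment matching (:func:`estimate_group_priors`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from recalldcb._sampler import MCMCConfig, sample_posterior_batch
from recalldcb.model import (
    PARAM_NAMES,
    SCORE_NAMES,
    PositionEffects,
    RecallSequence,
    scores_from_arrays,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "PriorSpec",
    "DEFAULT_GROUP",
    "QUANTITY_NAMES",
    "demographic_group",
    "fit_participant",
    "fit_cohort",
    "estimate_group_priors",
]

DEFAULT_GROUP = "default"

#: Every quantity summarized by a fit: the 7 parameters + 6 derived scores.
QUANTITY_NAMES = PARAM_NAMES + SCORE_NAMES

_RHAT_FLAG = 1.05


def demographic_group(age: float, sex: str, education: float) -> str:
    """Demographic stratum label: age band x sex x education band.

    Bands: age <65 / 65-75 / >75 years; education <16 / >=16 years.
    """
    if age < 65:
        band = "age<65"
    elif age <= 75:
        band = "age65-75"
    else:
        band = "age>75"
    sex = str(sex).strip().upper()[:1]
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be M or F, got {sex!r}")
    edu = "edu<16" if education < 16 else "edu16+"
    return f"{band}|{sex}|{edu}"


@dataclass
class PriorSpec:
    """Beta(a, b) priors for the seven parameters, per demographic group.

    ``groups`` maps a group label to a mapping ``parameter -> (a, b)``.
    A group named :data:`DEFAULT_GROUP` must exist; participants whose
    group is missing fall back to it (with a warning at fit time).
    """

    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if DEFAULT_GROUP not in self.groups:
            raise ValueError(f"PriorSpec must define a {DEFAULT_GROUP!r} group")
        for group, entry in self.groups.items():
            missing = set(PARAM_NAMES) - set(entry)
            if missing:
                raise ValueError(f"group {group!r} lacks priors for {sorted(missing)}")
            for name in PARAM_NAMES:
                a, b = entry[name]
                if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
                    raise ValueError(
                        f"invalid Beta({a}, {b}) for {group!r}/{name}"
                    )

    @classmethod
    def flat(cls) -> "PriorSpec":
        """Uniform Beta(1, 1) priors for every parameter."""
        return cls({DEFAULT_GROUP: {n: (1.0, 1.0) for n in PARAM_NAMES}})

    def entry(self, group: str) -> Mapping:
        return self.groups.get(group, self.groups[DEFAULT_GROUP])

    def arrays(self, group: str) -> tuple:
        entry = self.entry(group)
        a = np.array([entry[n][0] for n in PARAM_NAMES], dtype=float)
        b = np.array([entry[n][1] for n in PARAM_NAMES], dtype=float)
        return a, b


def _prior_arrays(prior) -> tuple:
    """Accept a PriorSpec group entry (mapping) or an (a, b) array pair."""
    if isinstance(prior, Mapping):
        a = np.array([prior[n][0] for n in PARAM_NAMES], dtype=float)
        b = np.array([prior[n][1] for n in PARAM_NAMES], dtype=float)
        return a, b
    a, b = prior
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def _sequences_to_arrays(
    sequences: Sequence[RecallSequence], effects: PositionEffects, n_words: int
) -> tuple:
    recalls = np.zeros((n_words, 4))
    offsets = np.zeros((n_words, 3))
    mask = np.zeros(n_words, dtype=bool)
    for i, seq in enumerate(sequences):
        recalls[i] = seq.recalls
        offsets[i] = effects.for_sequence(seq)
        mask[i] = True
    return recalls, offsets, mask


def _summarize(draws: np.ndarray) -> tuple:
    """Summaries for draws of shape (chains, kept, P, 7).

    Returns (quantity draws (C, K, P, 13), summary arrays dict).
    """
    scores = scores_from_arrays(draws)
    quantities = np.concatenate([draws, scores], axis=-1)
    mean = quantities.mean(axis=(0, 1))
    sd = quantities.std(axis=(0, 1), ddof=1)
    lo, hi = np.percentile(quantities, [2.5, 97.5], axis=(0, 1))
    ds = az.convert_to_dataset(quantities)
    ess = np.asarray(az.ess(ds)["x"])
    if quantities.shape[0] >= 2:
        rhat = np.asarray(az.rhat(ds)["x"])
    else:
        rhat = np.full(mean.shape, np.nan)
    return quantities, {
        "mean": mean, "sd": sd, "lo": lo, "hi": hi, "ess": ess, "rhat": rhat,
    }


def fit_participant(
    sequences: Sequence[RecallSequence],
    prior,
    effects: PositionEffects | None = None,
    config: MCMCConfig | None = None,
    prior_only: bool = False,
) -> pd.DataFrame:
    """Posterior summary for one participant.

    Returns a frame indexed by quantity (N1..R3, M1..M3, N_avg, R_avg,
    M_avg) with posterior mean, SD, central 95% credible interval,
    effective sample size and split-chain R-hat.  ``prior_only=True``
    ignores the data and samples the prior (useful for calibration
    checks); otherwise at least one sequence is required.
    """
    config = config or MCMCConfig()
    effects = effects if effects is not None else PositionEffects()
    if not prior_only and len(sequences) == 0:
        raise ValueError("no recall sequences supplied (use prior_only=True "
                         "to sample the prior)")
    if prior_only:
        sequences = []
    n_words = len(sequences)
    recalls, offsets, mask = _sequences_to_arrays(sequences, effects, n_words)
    a, b = _prior_arrays(prior)
    draws = sample_posterior_batch(
        recalls[None], offsets[None], mask[None], a[None], b[None], config
    )
    _, s = _summarize(draws)
    return pd.DataFrame(
        {
            "mean": s["mean"][0],
            "sd": s["sd"][0],
            "ci_lower": s["lo"][0],
            "ci_upper": s["hi"][0],
            "ess": s["ess"][0],
            "rhat": s["rhat"][0],
        },
        index=list(QUANTITY_NAMES),
    )


def fit_cohort(
    recall_df: pd.DataFrame,
    participants_df: pd.DataFrame,
    priors: PriorSpec | None = None,
    effects: PositionEffects | None = None,
    config: MCMCConfig | None = None,
) -> pd.DataFrame:
    """Posterior-mean biomarkers for every participant in a cohort.

    ``recall_df`` is the item-level table; ``participants_df`` supplies
    age/sex/education for the demographic-group prior lookup.  Returns
    one row per participant with the posterior mean, SD and 95%
    credible bounds of each quantity, plus the worst R-hat across
    quantities and a convergence flag (R-hat > 1.05).
    """
    priors = priors or PriorSpec.flat()
    effects = effects if effects is not None else PositionEffects()
    config = config or MCMCConfig()
    from recalldcb.io import to_sequences  # late import: io depends on model only

    by_participant = to_sequences(recall_df)
    pids = sorted(by_participant)
    if not pids:
        columns = ["participant_id", "group", "n_words", "max_rhat", "converged"]
        for q in QUANTITY_NAMES:
            columns += [q, f"{q}_sd", f"{q}_lo", f"{q}_hi"]
        return pd.DataFrame(columns=columns)

    demo = participants_df.set_index("participant_id")
    groups = []
    for pid in pids:
        if pid not in demo.index:
            logger.warning("participant %s missing from covariate table; "
                           "using default-group prior", pid)
            groups.append(DEFAULT_GROUP)
            continue
        row = demo.loc[pid]
        group = demographic_group(row["age"], row["sex"], row["education"])
        if group not in priors.groups and len(priors.groups) > 1:
            logger.warning("no prior for group %s (participant %s); "
                           "falling back to default", group, pid)
        groups.append(group)

    n_words = max(len(by_participant[pid]) for pid in pids)
    n_part = len(pids)
    recalls = np.zeros((n_part, n_words, 4))
    offsets = np.zeros((n_part, n_words, 3))
    mask = np.zeros((n_part, n_words), dtype=bool)
    prior_a = np.zeros((n_part, 7))
    prior_b = np.zeros((n_part, 7))
    for i, pid in enumerate(pids):
        r, o, m = _sequences_to_arrays(by_participant[pid], effects, n_words)
        recalls[i], offsets[i], mask[i] = r, o, m
        prior_a[i], prior_b[i] = priors.arrays(groups[i])

    draws = sample_posterior_batch(recalls, offsets, mask, prior_a, prior_b, config)
    _, s = _summarize(draws)
    max_rhat = (
        np.nanmax(s["rhat"], axis=1) if config.chains >= 2
        else np.full(n_part, np.nan)
    )
    out = {
        "participant_id": pids,
        "group": groups,
        "n_words": mask.sum(axis=1).astype(int),
    }
    for k, q in enumerate(QUANTITY_NAMES):
        out[q] = s["mean"][:, k]
        out[f"{q}_sd"] = s["sd"][:, k]
        out[f"{q}_lo"] = s["lo"][:, k]
        out[f"{q}_hi"] = s["hi"][:, k]
    out["max_rhat"] = max_rhat
    out["converged"] = ~(max_rhat > _RHAT_FLAG)
    result = pd.DataFrame(out)
    n_flag = int((~result["converged"]).sum())
    logger.info(
        "fit_cohort: %d participants, worst R-hat %.3f, %d flagged (>%.2f)",
        n_part, float(np.nanmax(max_rhat)) if n_part else float("nan"),
        n_flag, _RHAT_FLAG,
    )
    return result


def estimate_group_priors(
    recall_df: pd.DataFrame,
    participants_df: pd.DataFrame,
    effects: PositionEffects | None = None,
    config: MCMCConfig | None = None,
    min_group_size: int = 2,
    clip: tuple = (0.5, 500.0),
) -> PriorSpec:
    """Empirical-Bayes group priors from a calibration cohort.

    Each participant is first fit under flat Beta(1, 1) priors; within
    every demographic group with at least ``min_group_size`` members a
    Beta(a, b) is moment-matched to the spread of posterior means, with
    a and b clipped to ``clip``.  Smaller groups are merged into the
    default group, which is always estimated from the whole cohort.
    """
    if len(participants_df) == 0:
        raise ValueError("empty calibration cohort")
    config = config or MCMCConfig(chains=2, iterations=1200, burn_in=600)
    fits = fit_cohort(recall_df, participants_df, PriorSpec.flat(), effects, config)
    if len(fits) == 0:
        raise ValueError("calibration cohort has no recall data")
    means = fits[list(PARAM_NAMES)].to_numpy()

    def match(block: np.ndarray) -> dict:
        m = np.clip(block.mean(axis=0), 1e-3, 1 - 1e-3)
        v = np.maximum(block.var(axis=0, ddof=1) if len(block) > 1 else
                       np.zeros(7), 1e-6)
        v = np.minimum(v, m * (1 - m) * 0.999)
        nu = m * (1 - m) / v - 1.0
        a = np.clip(m * nu, *clip)
        b = np.clip((1 - m) * nu, *clip)
        return {n: (float(a[k]), float(b[k])) for k, n in enumerate(PARAM_NAMES)}

    groups = {DEFAULT_GROUP: match(means)}
    for group, sub in fits.groupby("group"):
        if group == DEFAULT_GROUP:
            continue
        if len(sub) < min_group_size:
            logger.warning(
                "group %s has %d participant(s) (<%d); merged into default",
                group, len(sub), min_group_size,
            )
            continue
        groups[group] = match(sub[list(PARAM_NAMES)].to_numpy())
    return PriorSpec(groups)
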