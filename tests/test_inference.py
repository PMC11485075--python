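"""Bayesian estimation: priors, determinism, calibration, recovery."""

import logging

import numpy as np
import pandas as pd
import pytest

from recalldcb.inference import (
    MCMCConfig,
    PriorSpec,
    demographic_group,
    estimate_group_priors,
    fit_cohort,
    fit_participant,
)
from recalldcb.model import PARAM_NAMES, RecallSequence
from recalldcb.synth import CohortConfig, generate_cohort, priors_from_config


def informative_prior(a=5.0, b=5.0):
    return {n: (a, b) for n in PARAM_NAMES}


def some_sequences(rng, n_words=10, p=0.6):
    return [
        RecallSequence(
            f"W{w}", "A", tuple(rng.permutation(n_words)[:3] + 1),
            tuple(rng.integers(0, 2, 4)),
            list_length=n_words,
        )
        for w in range(n_words)
    ]


class TestGrouping:
    @pytest.mark.parametrize(
        "age, sex, edu, expected",
        [
            (60, "M", 12, "age<65|M|edu<16"),
            (70, "female", 16, "age65-75|F|edu16+"),
            (80, "F", 18, "age>75|F|edu16+"),
        ],
    )
    def test_group_labels(self, age, sex, edu, expected):
        assert demographic_group(age, sex, edu) == expected

    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError):
            demographic_group(70, "?", 16)

    def test_prior_spec_requires_default_group(self):
        with pytest.raises(ValueError, match="default"):
            PriorSpec({"age<65|M|edu<16": informative_prior()})
        with pytest.raises(ValueError):
            PriorSpec({"default": {n: (0.0, 1.0) for n in PARAM_NAMES}})


class TestFitParticipant:
    def test_zero_sequences_rejected(self, light_mcmc):
        with pytest.raises(ValueError, match="prior_only"):
            fit_participant([], informative_prior(), config=light_mcmc)

    def test_prior_only_posterior_matches_beta_moments(self):
        """With no data the posterior must reproduce the Beta prior."""
        config = MCMCConfig(chains=2, iterations=3000, burn_in=500, seed=8)
        summary = fit_participant(
            [], informative_prior(5, 5), config=config, prior_only=True
        )
        for name in PARAM_NAMES:
            assert summary.loc[name, "mean"] == pytest.approx(0.5, abs=0.03)
            assert summary.loc[name, "sd"] == pytest.approx(
                np.sqrt(0.25 / 11), abs=0.03
            )

    def test_summary_structure_and_bounds(self, rng, light_mcmc):
        summary = fit_participant(
            some_sequences(rng), informative_prior(), config=light_mcmc
        )
        assert list(summary.index[:7]) == list(PARAM_NAMES)
        assert ((summary["mean"] >= 0) & (summary["mean"] <= 1)).all()
        assert (summary["ci_lower"] <= summary["ci_upper"]).all()
        assert (summary["ess"] > 0).all()

    def test_seed_determinism(self, rng, light_mcmc):
        seqs = some_sequences(rng)
        a = fit_participant(seqs, informative_prior(), config=light_mcmc)
        b = fit_participant(seqs, informative_prior(), config=light_mcmc)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_config_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_participant(
                some_sequences(rng), informative_prior(),
                config=MCMCConfig(iterations=0),
            )


class TestFitCohort:
    def test_empty_cohort(self, light_mcmc):
        recall_df, parts_df, _ = generate_cohort(CohortConfig(n_participants=0))
        out = fit_cohort(recall_df, parts_df, config=light_mcmc)
        assert len(out) == 0

    def test_identical_participants_get_identical_rows(self, light_mcmc):
        recall_df, parts_df, _ = generate_cohort(
            CohortConfig(n_participants=1, rng_seed=4)
        )
        twin_recall = recall_df.copy()
        twin_recall["participant_id"] = "P9999"
        twin_parts = parts_df.copy()
        twin_parts["participant_id"] = "P9999"
        recall2 = pd.concat([recall_df, twin_recall], ignore_index=True)
        parts2 = pd.concat([parts_df, twin_parts], ignore_index=True)
        out = fit_cohort(recall2, parts2, config=light_mcmc)
        a = out[out.participant_id == parts_df.participant_id[0]].iloc[0]
        b = out[out.participant_id == "P9999"].iloc[0]
        cols = [c for c in out.columns if c not in ("participant_id",)]
        assert a[cols].tolist() == b[cols].tolist()

    def test_missing_covariates_fall_back_to_default_group(
        self, light_mcmc, caplog
    ):
        recall_df, parts_df, _ = generate_cohort(
            CohortConfig(n_participants=2, rng_seed=4)
        )
        with caplog.at_level(logging.WARNING, logger="recalldcb.inference"):
            out = fit_cohort(
                recall_df, parts_df.iloc[:1],
                priors_from_config(CohortConfig()), config=light_mcmc,
            )
        assert "default" in caplog.text
        assert len(out) == 2

    def test_group_recovery_correlation(self):
        """Posterior-mean M_avg must track the true per-participant
        recall ability on a 50-participant cohort."""
        cfg = CohortConfig(n_participants=50, rng_seed=13)
        recall_df, parts_df, truth_df = generate_cohort(cfg)
        fits = fit_cohort(
            recall_df, parts_df, priors_from_config(cfg),
            config=MCMCConfig(chains=2, iterations=1000, burn_in=500, seed=5),
        )
        merged = fits.merge(truth_df, on="participant_id",
                            suffixes=("_est", "_true"))
        r = np.corrcoef(merged["M_avg_est"], merged["M_avg_true"])[0, 1]
        assert r >= 0.8


class TestCalibration:
    def test_posterior_contracts_with_more_words(self):
        """Posterior SD of M_avg must shrink as words per assessment
        grow 5 -> 10 -> 20 (averaged over participants)."""
        sds = []
        for n_words, seed in ((5, 1), (10, 2), (20, 3)):
            cfg = CohortConfig(n_participants=8, n_words=n_words, rng_seed=seed)
            recall_df, parts_df, _ = generate_cohort(cfg)
            fits = fit_cohort(
                recall_df, parts_df, priors_from_config(cfg),
                config=MCMCConfig(chains=2, iterations=900, burn_in=450, seed=7),
            )
            sds.append(fits["M_avg_sd"].mean())
        assert sds[0] > sds[1] > sds[2]

    def test_truth_centered_priors_cover_truth(self):
        """With priors matching the generating distribution, the 95%
        intervals must cover the true parameters for most of the 7
        parameters on average (small-sample simulation check)."""
        cfg = CohortConfig(n_participants=25, rng_seed=31)
        recall_df, parts_df, truth_df = generate_cohort(cfg)
        fits = fit_cohort(
            recall_df, parts_df, priors_from_config(cfg),
            config=MCMCConfig(chains=2, iterations=1000, burn_in=500, seed=9),
        )
        merged = fits.merge(truth_df, on="participant_id",
                            suffixes=("_est", "_true"))
        covered = np.zeros(len(merged))
        for q in PARAM_NAMES:
            covered += (
                (merged[f"{q}_lo"] <= merged[f"{q}_true"])
                & (merged[f"{q}_true"] <= merged[f"{q}_hi"])
            ).to_numpy()
        assert covered.mean() >= 6.0


class TestGroupPriors:
    def test_empty_calibration_cohort_rejected(self):
        recall_df, parts_df, _ = generate_cohort(CohortConfig(n_participants=0))
        with pytest.raises(ValueError):
            estimate_group_priors(recall_df, parts_df)

    def test_identical_participants_concentrate_the_prior(self, light_mcmc):
        recall_df, parts_df, _ = generate_cohort(
            CohortConfig(n_participants=1, rng_seed=2)
        )
        frames_r, frames_p = [], []
        for k in range(4):
            r = recall_df.copy()
            p = parts_df.copy()
            r["participant_id"] = f"P{k:04d}"
            p["participant_id"] = f"P{k:04d}"
            frames_r.append(r)
            frames_p.append(p)
        spec = estimate_group_priors(
            pd.concat(frames_r, ignore_index=True),
            pd.concat(frames_p, ignore_index=True),
            config=light_mcmc,
        )
        a, b = spec.arrays("default")
        # identical inputs -> tiny spread of posterior means -> large a+b
        assert (a + b).min() > 50

    def test_planted_group_difference_recovered(self):
        """Two demographic strata generated with different recall
        ability must yield group priors ordered the same way."""
        frames_r, frames_p = [], []
        for band, ages, base, seed in (
            ("young", 58.0, 0.80, 5),
            ("old", 82.0, 0.30, 6),
        ):
            cfg = CohortConfig(
                n_participants=8,
                rng_seed=seed,
                age_mean=ages,
                age_sd=1.0,
                age_logit_slope=0.0,
                dcb_base_probs=(base,) * 7,
                dcb_unique_sd=0.4,
            )
            r, p, _ = generate_cohort(cfg)
            r["participant_id"] = band + r["participant_id"]
            p["participant_id"] = band + p["participant_id"]
            frames_r.append(r)
            frames_p.append(p)
        spec = estimate_group_priors(
            pd.concat(frames_r, ignore_index=True),
            pd.concat(frames_p, ignore_index=True),
            config=MCMCConfig(chains=2, iterations=800, burn_in=400, seed=1),
        )
        young = [g for g in spec.groups if g.startswith("age<65")]
        old = [g for g in spec.groups if g.startswith("age>75")]
        assert young and old

        def prior_mean(group):
            a, b = spec.arrays(group)
            return (a / (a + b)).mean()

        assert min(prior_mean(g) for g in young) > max(prior_mean(g) for g in old)

    def test_small_groups_merged_into_default(self, light_mcmc, caplog):
        cfg = CohortConfig(n_participants=5, rng_seed=11, age_mean=60, age_sd=0.5)
        recall_df, parts_df, _ = generate_cohort(cfg)
        # push one participant into a singleton stratum
        parts_df.loc[parts_df.index[0], "age"] = 85.0
        with caplog.at_level(logging.WARNING, logger="recalldcb.inference"):
            spec = estimate_group_priors(recall_df, parts_df, config=light_mcmc)
        assert "merged into default" in caplog.text
        assert not any(g.startswith("age>75") for g in spec.groups)
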