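"""Adaptive component-wise random-walk Metropolis on logit-transformed
parameters, batched over participants and chains.

Each participant's posterior is independent given their group prior, so
the whole cohort is updated in lock-step: the state is a matrix of
logits with one row per (participant, chain) and one column per
parameter, and every likelihood evaluation is a single vectorized
forward pass over all rows and words.

Randomness is organised so that results are reproducible and
independent of how participants are batched: every (participant, chain)
row draws from its own stream keyed by ``(seed, participant_key,
chain)``, where ``participant_key`` is a stable hash of that
participant's data and prior.  Two participants with identical data and
priors therefore produce identical chains under the same seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from recalldcb.model import forward_likelihoods

_TINY = 1e-300
_SLAB = 250  # iterations of pre-drawn randoms held in memory at once


@dataclass
class MCMCConfig:
    """Sampler settings: ``iterations`` is the total per chain, of which
    the first ``burn_in`` are discarded (and used for scale adaptation
    when ``adapt`` is on)."""

    chains: int = 4
    iterations: int = 2000
    burn_in: int = 1000
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.234
    initial_scale: float = 0.5

    def validate(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.iterations <= 0 or self.burn_in < 0:
            raise ValueError("iteration counts must be positive")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")


def participant_key(recalls: np.ndarray, offsets: np.ndarray,
                    prior_a: np.ndarray, prior_b: np.ndarray) -> int:
    """Stable 32-bit key for one participant's data + prior."""
    h = hashlib.sha256()
    for arr in (recalls, offsets, prior_a, prior_b):
        h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
    return int.from_bytes(h.digest()[:4], "little")


def sample_posterior_batch(
    recalls: np.ndarray,
    offsets: np.ndarray,
    mask: np.ndarray,
    prior_a: np.ndarray,
    prior_b: np.ndarray,
    config: MCMCConfig,
) -> np.ndarray:
    """Posterior draws for a batch of independent participants.

    Parameters
    ----------
    recalls, offsets, mask
        ``(P, W, 4)`` binary patterns, ``(P, W, 3)`` logit offsets and a
        ``(P, W)`` boolean word mask (False pads ragged word counts; an
        all-False row is a prior-only fit).
    prior_a, prior_b
        ``(P, 7)`` Beta prior parameters per participant.

    Returns
    -------
    Draws on the probability scale, shape ``(chains, kept, P, 7)``.
    """
    config.validate()
    recalls = np.asarray(recalls, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    prior_a = np.asarray(prior_a, dtype=float)
    prior_b = np.asarray(prior_b, dtype=float)
    n_part, n_words = mask.shape
    if np.any(prior_a <= 0) or np.any(prior_b <= 0):
        raise ValueError("Beta prior parameters must be positive")

    chains = config.chains
    rows = chains * n_part
    part_of_row = np.tile(np.arange(n_part), chains)
    keys = [
        participant_key(recalls[p], offsets[p], prior_a[p], prior_b[p])
        for p in range(n_part)
    ]
    gens = [
        np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed,
                                   spawn_key=(keys[p], c))
        )
        for c in range(chains)
        for p in range(n_part)
    ]

    rec_r = recalls[part_of_row]
    off_r = offsets[part_of_row]
    mask_r = mask[part_of_row].astype(float)
    a_r = prior_a[part_of_row]
    b_r = prior_b[part_of_row]

    def loglik(p_params: np.ndarray) -> np.ndarray:
        if n_words == 0:
            return np.zeros(rows)
        lik = forward_likelihoods(p_params[:, None, :], rec_r, off_r)
        return (np.log(np.maximum(lik, _TINY)) * mask_r).sum(axis=1)

    def logprior_cols(theta: np.ndarray) -> np.ndarray:
        # Beta(a, b) on the probability scale plus the logit Jacobian
        return -a_r * np.logaddexp(0.0, -theta) - b_r * np.logaddexp(0.0, theta)

    prior_mean = np.clip(a_r / (a_r + b_r), 0.02, 0.98)
    init_jitter = np.stack([g.standard_normal(7) for g in gens])
    theta = logit(prior_mean) + 0.2 * init_jitter
    p_cur = expit(theta)
    ll_cur = loglik(p_cur)
    lp_cur = logprior_cols(theta)

    scales = np.full((rows, 7), config.initial_scale)
    kept = config.iterations - config.burn_in
    draws = np.empty((kept, rows, 7))

    it = 0
    while it < config.iterations:
        slab = min(_SLAB, config.iterations - it)
        normals = np.stack([g.standard_normal((slab, 7)) for g in gens])
        unifs = np.stack([g.random((slab, 7)) for g in gens])
        for s in range(slab):
            for j in range(7):
                theta_j = theta[:, j] + scales[:, j] * normals[:, s, j]
                p_prop = p_cur.copy()
                p_prop[:, j] = expit(theta_j)
                ll_prop = loglik(p_prop)
                lp_j = (
                    -a_r[:, j] * np.logaddexp(0.0, -theta_j)
                    - b_r[:, j] * np.logaddexp(0.0, theta_j)
                )
                log_alpha = ll_prop - ll_cur + lp_j - lp_cur[:, j]
                accept = np.log(unifs[:, s, j]) < log_alpha
                theta[accept, j] = theta_j[accept]
                p_cur[accept, j] = p_prop[accept, j]
                ll_cur = np.where(accept, ll_prop, ll_cur)
                lp_cur[accept, j] = lp_j[accept]
                if config.adapt and it < config.burn_in:
                    gamma = (it + 10.0) ** -0.6
                    scales[:, j] *= np.exp(
                        gamma * (accept.astype(float) - config.target_accept)
                    )
            if it >= config.burn_in:
                draws[it - config.burn_in] = p_cur
            it += 1
    return (
        draws.reshape(kept, chains, n_part, 7).transpose(1, 0, 2, 3).copy()
    )
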