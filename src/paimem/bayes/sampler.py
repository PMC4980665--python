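"""Blocked adaptive Metropolis-within-Gibbs machinery.

All three hierarchical models in this package share a structure that a simple
random-walk sampler exploits well: a handful of shared parameters, plus
*conditionally independent* blocks (per-category deflections, per-subject
effects) whose components can be proposed and accepted/rejected jointly in one
vectorized likelihood pass, because the per-datum log likelihood factorizes
over the groups a component touches.

Proposal scales adapt per component toward a target acceptance rate during the
adaptation/burn-in phase (Robbins-Monro on the log scale) and are frozen
afterwards, so retained draws come from a valid Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MCMCConfig", "AdaptiveScales", "run_chains", "half_t_logpdf"]

TARGET_ACCEPT = 0.44  # componentwise random-walk optimum
ADAPT_RATE = 0.05


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout. Defaults are the test-scale settings; ``paper_scale``
    mirrors the published run lengths (5 chains, thinning 5, 60k draws)."""

    chains: int = 4
    draws: int = 5000
    burn_in: int = 2000
    adapt_steps: int = 1000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("chains", "draws", "burn_in", "adapt_steps", "thinning"):
            if getattr(self, name) < (1 if name in ("chains", "draws", "thinning") else 0):
                raise ValueError(f"{name} must be positive")

    @classmethod
    def paper_scale(cls, draws: int = 60_000, seed: int = 0) -> "MCMCConfig":
        return cls(chains=5, draws=draws, burn_in=2000, adapt_steps=1000,
                   thinning=5, seed=seed)

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


@dataclass
class AdaptiveScales:
    """Per-component random-walk scales with Robbins-Monro adaptation."""

    log_scale: np.ndarray
    frozen: bool = False

    @classmethod
    def of(cls, size: int, initial: float = 0.2) -> "AdaptiveScales":
        return cls(log_scale=np.full(size, np.log(initial)))

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted: np.ndarray) -> None:
        if not self.frozen:
            self.log_scale += ADAPT_RATE * (
                np.asarray(accepted, dtype=float) - TARGET_ACCEPT
            )
            np.clip(self.log_scale, -12.0, 6.0, out=self.log_scale)


def half_t_logpdf(x, df: float = 4.0, scale: float = 10.0):
    """Log density of the folded Student-t on x > 0 (vague scale prior)."""
    x = np.asarray(x, dtype=float)
    from scipy.stats import t as student_t

    return np.where(
        x > 0, student_t.logpdf(x, df, scale=scale) + np.log(2.0), -np.inf
    )


def run_chains(single_chain, config: MCMCConfig) -> dict[str, np.ndarray]:
    """Run independent chains and stack each quantity as (chains, draws, ...).

    ``single_chain(rng, n_keep, thin, n_warm)`` must return a dict of arrays
    whose leading dimension is the number of retained draws.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    n_warm = config.adapt_steps + config.burn_in
    per_chain = [
        single_chain(np.random.default_rng(s), config.draws, config.thinning, n_warm)
        for s in seeds
    ]
    return {
        key: np.stack([c[key] for c in per_chain]) for key in per_chain[0]
    }
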