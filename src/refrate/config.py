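"""Shared MCMC configuration."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MCMCConfig:
    """Run-length and tuning settings for a Metropolis-within-Gibbs sampler.

    Attributes
    ----------
    iterations : total number of MCMC iterations, burn-in included.
    burn_in : iterations discarded before any draw is retained.
    thinning : keep every ``thinning``-th post-burn-in draw.
    proposal_scale : initial random-walk step size (adapted during burn-in).
    adapt : adapt proposal scales toward target acceptance during burn-in.
    seed : seed for the sampler's random generator.
    """

    iterations: int = 20_000
    burn_in: int = 10_000
    thinning: int = 10
    proposal_scale: float = 0.1
    adapt: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.iterations <= self.burn_in:
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning
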