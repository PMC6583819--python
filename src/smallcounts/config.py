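"""Shared MCMC settings."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml


@dataclass
class MCMCConfig:
    """Sampler settings shared by the Poisson-gamma and spatial models.

    ``draws`` is the number of retained draws per chain after burn-in and
    thinning.  Metropolis step sizes are tuned toward a 44% acceptance rate
    during burn-in only (Robbins-Monro), then frozen to preserve detailed
    balance.
    """

    chains: int = 2
    burnin: int = 5000
    draws: int = 10000
    thin: int = 1
    seed: int = 0
    target_accept: float = 0.44
    adapt: bool = True
    init_step: float = 0.5

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.burnin < 0:
            raise ValueError("burnin must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "MCMCConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)
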