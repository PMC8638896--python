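"""Shared builders for small, fast model instances."""

from __future__ import annotations

import numpy as np
import pytest

from assemblysim.model import ModelParameters


def single_species_params(C: float = 1.0, m: float = 0.05, I: float = 1.0,
                          secretion_fraction: float = 0.0) -> ModelParameters:
    """One species, one resource, F = G = 1."""
    return ModelParameters(
        consumption=np.array([[C]]),
        stoichiometry=np.array([[[1.0]]]),
        symbionts=np.zeros((1, 1), dtype=bool),
        death_rate=m,
        symbiont_halfsat=0.01,
        conc_halfsat=1.0,
        transfer_rate=1.0,
        supply_conc=np.array([I]),
        specialization=np.array([0]),
        conc_specialization_enabled=False,
        secretion_fraction=secretion_fraction,
    )


def random_params(S: int = 6, M: int = 4, seed: int = 0,
                  n_essential: int = 2,
                  secretion_fraction: float = 0.8,
                  conc_enabled: bool = True) -> ModelParameters:
    """Random valid instance for property checks."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(size=(S, M))
    C = raw / raw.sum(axis=1, keepdims=True)
    g = rng.gamma(1.0, size=(S, M, M))
    D = g / g.sum(axis=1, keepdims=True)
    E = np.zeros((S, S), dtype=bool)
    f = rng.integers(M, size=S)
    for i in range(S):
        pool = np.flatnonzero(np.arange(S) != i)
        E[i, rng.choice(pool, size=min(n_essential, pool.size),
                        replace=False)] = True
    I = np.zeros(M)
    I[0] = 1.0
    return ModelParameters(
        consumption=C, stoichiometry=D, symbionts=E,
        death_rate=0.05, symbiont_halfsat=0.01,
        conc_halfsat=np.full(S, 100.0), transfer_rate=1.0,
        supply_conc=I, specialization=f,
        conc_specialization_enabled=conc_enabled,
        secretion_fraction=secretion_fraction,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
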