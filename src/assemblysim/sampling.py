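"""Monte Carlo sampling of community parameter sets and initial conditions.

Each ensemble draws ``n_param_sets`` independent parameterisations (uptake
matrix ``C``, stoichiometric tensor ``D``, essential-symbiont network ``E``)
and, for each, ``n_replicates`` initial biomass vectors.  Replicates within a
parameter set share ``C``, ``D`` and ``E`` exactly and differ only in the
initial biomass, the protocol probe for assembly stochasticity.

Seeding uses a ``numpy.random.SeedSequence`` hierarchy: the master seed spawns
one stream per parameter set, and each of those spawns a parameter stream plus
one stream per replicate.  Changing ``n_replicates`` therefore never changes
which parameter sets are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "EnsembleSpec",
    "CommunityBlueprint",
    "sample_consumption_matrix",
    "sample_stoichiometric_tensor",
    "sample_symbiont_network",
    "sample_initial_biomass",
    "build_parameters",
]


@dataclass
class EnsembleSpec:
    """Replicate/parameter-set counts and sampling-distribution settings.

    Defaults are the study conditions: 100 parameter resamplings x 10
    replicates, initial biomass Uniform(0.01, 1), specialised uptake rate
    Normal(mu=0.4, sigma=0.01), 10 essential symbionts per species.
    """

    n_param_sets: int = 100
    n_replicates: int = 10
    init_biomass_range: tuple[float, float] = (0.01, 1.0)
    seed: int = 0
    mu: float = 0.4
    sigma: float = 0.01
    n_essential: int | Literal["all"] = 10

    def __post_init__(self) -> None:
        if self.n_param_sets < 1:
            raise ValueError("n_param_sets must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("similarity needs pairs: n_replicates >= 2")
        low, high = self.init_biomass_range
        if not (0 < low < high):
            raise ValueError("init_biomass_range must satisfy 0 < low < high")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class CommunityBlueprint:
    """Community structure: who specialises for what, and the supply.

    Two layouts are used:

    * ``uniform`` — ``specialists_per_resource`` species per each of
      ``n_resources`` resources; no concentration specialisation (``G = 1``).
    * ``concentration_adapted`` — the supplied resource has ``n_high``
      specialists adapted to a high concentration (``L_high``) and ``n_low``
      adapted to a low one (``L_low``); every other resource has
      ``specialists_per_resource`` specialists.
    """

    layout: Literal["uniform", "concentration_adapted"] = "uniform"
    n_resources: int = 10
    specialists_per_resource: int = 10
    n_high: int = 45
    n_low: int = 5
    L_high: float = 100.0
    L_low: float = 1.0
    supply_conc_value: float = 100.0
    supplied_resource: int = 0
    death_rate: float = 0.05
    symbiont_halfsat: float = 0.01
    transfer_rate: float = 1.0
    dirichlet_concentration: float = 1.0
    secretion_fraction: float = 0.8
    init_resources: Literal["supply", "zero"] = "supply"

    def __post_init__(self) -> None:
        if self.n_resources < 1:
            raise ValueError("n_resources must be >= 1")
        if self.layout == "uniform":
            if self.specialists_per_resource < 1:
                raise ValueError("specialists_per_resource must be >= 1")
        elif self.layout == "concentration_adapted":
            if self.n_high < 1 or self.n_low < 1:
                raise ValueError("n_high and n_low must be >= 1")
        else:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.supply_conc_value <= 0:
            raise ValueError("supply_conc_value must be positive")
        if not 0 <= self.supplied_resource < self.n_resources:
            raise ValueError("supplied_resource out of range")

    @classmethod
    def uniform(cls, specialists_per_resource: int = 10,
                **kw) -> "CommunityBlueprint":
        # order-1 supply keeps the uniform community in the bounded regime
        # where uptake can balance the death rate (see docs/methods.md)
        kw.setdefault("supply_conc_value", 1.0)
        return cls(layout="uniform",
                   specialists_per_resource=specialists_per_resource, **kw)

    @classmethod
    def concentration_adapted(cls, adapted: Literal["high", "low"],
                              supply_conc_value: float,
                              **kw) -> "CommunityBlueprint":
        """Community adapted to a high or low supply concentration.

        ``adapted="high"`` gives the 45-high/5-low split for the supplied
        resource; ``"low"`` the mirror 5-high/45-low split.
        """
        n_high, n_low = (45, 5) if adapted == "high" else (5, 45)
        return cls(layout="concentration_adapted", n_high=n_high, n_low=n_low,
                   supply_conc_value=supply_conc_value, **kw)

    # -- derived structure ----------------------------------------------
    @property
    def n_species(self) -> int:
        if self.layout == "uniform":
            return self.specialists_per_resource * self.n_resources
        return (self.n_high + self.n_low
                + self.specialists_per_resource * (self.n_resources - 1))

    @property
    def specialization(self) -> np.ndarray:
        """Length-S resource assignment; supplied-resource specialists first."""
        a = self.supplied_resource
        others = [r for r in range(self.n_resources) if r != a]
        if self.layout == "uniform":
            head = [a] * self.specialists_per_resource
        else:
            head = [a] * (self.n_high + self.n_low)
        tail = [r for r in others
                for _ in range(self.specialists_per_resource)]
        return np.array(head + tail, dtype=int)

    @property
    def conc_halfsat(self) -> np.ndarray:
        """Adapted concentration L per species (1 for unspecialised roles)."""
        L = np.ones(self.n_species)
        if self.layout == "concentration_adapted":
            L[:self.n_high] = self.L_high
            L[self.n_high:self.n_high + self.n_low] = self.L_low
        return L

    @property
    def supply_conc(self) -> np.ndarray:
        I = np.zeros(self.n_resources)
        I[self.supplied_resource] = self.supply_conc_value
        return I

    @property
    def conc_specialization_enabled(self) -> bool:
        return self.layout == "concentration_adapted"

    def initial_resources(self) -> np.ndarray:
        if self.init_resources == "supply":
            return self.supply_conc.copy()
        return np.zeros(self.n_resources)


def sample_consumption_matrix(blueprint: CommunityBlueprint, mu: float,
                              sigma: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Draw the uptake matrix ``C`` per the specialisation rule.

    The specialised entry ``C[i, f_i]`` is Normal(mu, sigma^2) truncated to
    [0, 1] by resampling; the remaining entries are Uniform(0, 1) draws
    rescaled so every row sums to 1.
    """
    S, M = blueprint.n_species, blueprint.n_resources
    f = blueprint.specialization
    spec = rng.normal(mu, sigma, size=S)
    bad = (spec < 0) | (spec > 1)
    while np.any(bad):  # truncation by resampling; negligible mass at defaults
        spec[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = (spec < 0) | (spec > 1)
    rows = np.arange(S)
    if M == 1:
        return np.ones((S, 1))
    raw = rng.uniform(0.0, 1.0, size=(S, M))
    raw[rows, f] = 0.0
    totals = raw.sum(axis=1)
    while np.any(totals == 0):  # probability-zero guard
        redo = totals == 0
        raw[redo] = rng.uniform(0.0, 1.0, size=(int(redo.sum()), M))
        raw[rows[redo], f[redo]] = 0.0
        totals = raw.sum(axis=1)
    C = (1.0 - spec)[:, None] * raw / totals[:, None]
    C[rows, f] = spec
    return C


def sample_stoichiometric_tensor(blueprint: CommunityBlueprint,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw per-species stoichiometric matrices with flat-Dirichlet columns.

    Each column ``D^i[:, b]`` is uniform on the M-simplex (Dirichlet with
    concentration ``blueprint.dirichlet_concentration``); a species may
    secrete any resource, including its own specialised one.
    """
    S, M = blueprint.n_species, blueprint.n_resources
    g = rng.gamma(blueprint.dirichlet_concentration, size=(S, M, M))
    return g / g.sum(axis=1, keepdims=True)


def sample_symbiont_network(blueprint: CommunityBlueprint,
                            n_essential: int | Literal["all"],
                            rng: np.random.Generator) -> np.ndarray:
    """Draw the essential-symbiont network ``E``.

    Each species' essential partners are drawn without replacement from the
    pool of species specialised for *other* resources (never itself).
    ``n_essential="all"`` marks the entire pool essential; 0 gives the empty
    network.
    """
    S = blueprint.n_species
    f = blueprint.specialization
    E = np.zeros((S, S), dtype=bool)
    if n_essential == 0:
        return E
    for i in range(S):
        pool = np.flatnonzero(f != f[i])
        if n_essential == "all":
            E[i, pool] = True
            continue
        if n_essential > pool.size:
            raise ValueError(
                f"species {i} needs {n_essential} essential symbionts but "
                f"only {pool.size} other-resource specialists exist")
        E[i, rng.choice(pool, size=n_essential, replace=False)] = True
    return E


def sample_initial_biomass(n_species: int, init_range: tuple[float, float],
                           rng: np.random.Generator) -> np.ndarray:
    """I.i.d. Uniform initial biomass (study protocol: U(0.01, 1))."""
    low, high = init_range
    if not (0 < low < high):
        raise ValueError("init range must satisfy 0 < low < high")
    return rng.uniform(low, high, size=n_species)


def build_parameters(blueprint: CommunityBlueprint, spec: EnsembleSpec,
                     rng: np.random.Generator):
    """Sample one full :class:`~assemblysim.model.ModelParameters` draw."""
    from .model import ModelParameters

    C = sample_consumption_matrix(blueprint, spec.mu, spec.sigma, rng)
    D = sample_stoichiometric_tensor(blueprint, rng)
    E = sample_symbiont_network(blueprint, spec.n_essential, rng)
    return ModelParameters(
        consumption=C,
        stoichiometry=D,
        symbionts=E,
        death_rate=blueprint.death_rate,
        symbiont_halfsat=blueprint.symbiont_halfsat,
        conc_halfsat=blueprint.conc_halfsat,
        transfer_rate=blueprint.transfer_rate,
        supply_conc=blueprint.supply_conc,
        specialization=blueprint.specialization,
        conc_specialization_enabled=blueprint.conc_specialization_enabled,
        secretion_fraction=blueprint.secretion_fraction,
    )
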