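"""Consumer-resource dynamics with essential-symbiont gating and cross-feeding.

The community model is a MacArthur-type consumer-resource system: species
(guilds) grow by taking up explicit resource pools and secrete transformed
resources (metabolic byproducts) that other species can consume.  Two
saturating factors modulate uptake:

* ``F_i = s_i / (K_i + s_i)`` — essential-symbiont gating, where ``s_i`` is
  the summed biomass of the species essential for species *i*.  When the
  essential partners are scarce, species *i* cannot metabolise.
* ``G_{i,alpha} = 4 I L / (L + I)^2`` — specialisation for a supplied resource
  concentration, peaking at 1 when the supply concentration ``I`` matches the
  species' adapted concentration ``L``.

The governing equations are

    dN_i/dt = sum_a F_i G_ia C_ia R_a N_i - m_i N_i
    dR_a/dt = H_a - sum_i F_i G_ia C_ia R_a N_i
              + sum_{b,i} F_i G_ib D^i_ab C_ib R_b N_i

with chemostat supply/washout ``H_a = (I_a - R_a) / tau_a`` applied to every
resource (``I_a = 0`` off the supplied resource, so byproducts wash out).
``C`` is the per-species uptake-rate matrix and ``D^i`` the per-species
stoichiometric matrix: ``D^i[a, b]`` is the fraction of species *i*'s uptake
flux of resource *b* secreted as resource *a*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParameters",
    "CommunityState",
    "symbiont_activity",
    "concentration_specialization",
    "derivatives",
]

_SIMPLEX_TOL = 1e-9


@dataclass
class ModelParameters:
    """Full parameterisation of one community instance.

    Parameters
    ----------
    consumption
        ``(S, M)`` uptake-rate matrix ``C``; each row lies on the M-simplex.
    stoichiometry
        ``(S, M, M)`` per-species stoichiometric matrices ``D^i``;
        ``stoichiometry[i, a, b]`` is the fraction of species *i*'s uptake of
        resource *b* secreted as resource *a*.  Each column (fixed ``b``)
        sums to 1.
    symbionts
        ``(S, S)`` boolean matrix ``E``; ``E[i, j]`` is True iff species *j*
        is essential for species *i*.  The diagonal must be False.
    death_rate
        Length-``S`` per-capita death/dormancy rate ``m`` (study-scale 0.05).
    symbiont_halfsat
        Length-``S`` half-saturation ``K`` of the essential-symbiont factor.
    conc_halfsat
        Length-``S`` adapted supply concentration ``L``; only read for
        species specialised for the supplied resource when concentration
        specialisation is enabled.
    transfer_rate
        Length-``M`` chemostat transfer rate ``tau``.
    supply_conc
        Length-``M`` supply concentrations ``I``; exactly one positive entry.
    specialization
        Length-``S`` integer map ``f``; ``f[i]`` is the resource species *i*
        is specialised for.
    conc_specialization_enabled
        When False, ``G`` is identically 1 (the uniform-community setting).
    byproduct_literal_reading
        Sensitivity switch for the secretion term.  Default (False) converts
        consumed resource ``b`` into secreted resource ``a`` via
        ``sum_{b,i} F_i G_ib D^i_ab C_ib R_b N_i``; True evaluates the
        alternative index placement ``sum_{b,i} F_i G_ia D^i_ab C_ia R_a N_i``.
    secretion_fraction
        Fraction ``l`` of consumed flux re-secreted as byproducts (the
        byproduct term is scaled by ``l``).  At the default 1.0 secretion
        exactly balances consumption, total resources are pinned at the
        supply total, and no bounded steady state exists at realistic supply;
        the ensemble experiments use the leakage value 0.8 standard in the
        cross-feeding literature, which drains resources as biomass grows and
        bounds the dynamics (see docs/methods.md).
    """

    consumption: np.ndarray
    stoichiometry: np.ndarray
    symbionts: np.ndarray
    death_rate: np.ndarray
    symbiont_halfsat: np.ndarray
    conc_halfsat: np.ndarray
    transfer_rate: np.ndarray
    supply_conc: np.ndarray
    specialization: np.ndarray
    conc_specialization_enabled: bool = True
    byproduct_literal_reading: bool = False
    secretion_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.consumption = np.asarray(self.consumption, dtype=float)
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.symbionts = np.asarray(self.symbionts, dtype=bool)
        S, M = self.consumption.shape
        for name in ("death_rate", "symbiont_halfsat", "conc_halfsat"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (S,)).copy())
        self.transfer_rate = np.broadcast_to(
            np.asarray(self.transfer_rate, dtype=float), (M,)).copy()
        self.supply_conc = np.asarray(self.supply_conc, dtype=float)
        self.specialization = np.asarray(self.specialization, dtype=int)
        self.validate()

    # -- dimensions ------------------------------------------------------
    @property
    def n_species(self) -> int:
        return self.consumption.shape[0]

    @property
    def n_resources(self) -> int:
        return self.consumption.shape[1]

    @property
    def supplied_resource(self) -> int:
        """Index of the single supplied resource."""
        return int(np.argmax(self.supply_conc > 0))

    def validate(self) -> None:
        S, M = self.consumption.shape
        if self.stoichiometry.shape != (S, M, M):
            raise ValueError(f"stoichiometry must be {(S, M, M)}, "
                             f"got {self.stoichiometry.shape}")
        if self.symbionts.shape != (S, S):
            raise ValueError("symbionts must be square S x S")
        if self.supply_conc.shape != (M,):
            raise ValueError("supply_conc must have length M")
        if self.specialization.shape != (S,):
            raise ValueError("specialization must have length S")
        if np.any(self.consumption < 0) or np.any(self.consumption > 1):
            raise ValueError("consumption entries must lie in [0, 1]")
        if not np.allclose(self.consumption.sum(axis=1), 1.0,
                           atol=_SIMPLEX_TOL):
            raise ValueError("each consumption row must sum to 1")
        if np.any(self.stoichiometry < 0):
            raise ValueError("stoichiometry entries must be non-negative")
        colsums = self.stoichiometry.sum(axis=1)
        # a column may sum to 0 (resource secreted by nobody), else to 1
        if not np.all((np.abs(colsums - 1.0) < _SIMPLEX_TOL)
                      | (np.abs(colsums) < _SIMPLEX_TOL)):
            raise ValueError("each stoichiometry column must sum to 1 (or 0)")
        if not 0.0 <= self.secretion_fraction <= 1.0:
            raise ValueError("secretion_fraction must lie in [0, 1]")
        if np.any(np.diag(self.symbionts)):
            raise ValueError("no species may be its own essential symbiont")
        if np.count_nonzero(self.supply_conc > 0) != 1:
            raise ValueError("exactly one supply_conc entry must be positive")
        for name in ("death_rate", "symbiont_halfsat", "conc_halfsat",
                     "transfer_rate"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if np.any(self.specialization < 0) or np.any(self.specialization >= M):
            raise ValueError("specialization indices out of range")

    # -- serialisation ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialise to a JSON document (for run manifests / replay)."""
        doc = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
               for k, v in asdict(self).items()}
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelParameters":
        p = Path(str(source))
        doc = json.loads(p.read_text() if p.is_file() else str(source))
        arrays = {k: np.asarray(v) for k, v in doc.items()
                  if isinstance(v, list)}
        flags = {k: v for k, v in doc.items() if not isinstance(v, list)}
        return cls(**arrays, **flags)


@dataclass
class CommunityState:
    """Biomass vector ``N`` and resource vector ``R`` at one time point."""

    biomass: np.ndarray
    resources: np.ndarray

    def __post_init__(self) -> None:
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.resources = np.asarray(self.resources, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, v in (("biomass", self.biomass),
                        ("resources", self.resources)):
            if v.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(v < 0):
                raise ValueError(f"{name} contains negative entries")


def symbiont_activity(biomass: np.ndarray,
                      params: ModelParameters) -> np.ndarray:
    """Essential-symbiont gating factor ``F_i = s_i / (K_i + s_i)``.

    ``s_i`` is the summed biomass of species *i*'s essential partners.  A
    species with an empty essential set is ungated (``F_i = 1``), so the
    no-symbiont control reduces to plain consumer-resource dynamics.
    """
    biomass = np.asarray(biomass, dtype=float)
    if biomass.shape != (params.n_species,):
        raise ValueError("biomass length does not match parameter dimension")
    if np.any(biomass < 0):
        raise ValueError("biomass must be non-negative")
    s = params.symbionts @ biomass
    F = np.where(params.symbionts.any(axis=1),
                 s / (params.symbiont_halfsat + s), 1.0)
    return F


def concentration_specialization(params: ModelParameters) -> np.ndarray:
    """Concentration-specialisation matrix ``G`` in ``(0, 1]``.

    ``G[i, a] = 4 I_a L_i / (L_i + I_a)^2`` only for species specialised for
    the supplied resource, at the supplied-resource column; all other entries
    are 1.  ``G`` depends on the constant supply concentration, not on the
    dynamic resource level, so it is computed once per simulation.
    """
    S, M = params.n_species, params.n_resources
    G = np.ones((S, M))
    if not params.conc_specialization_enabled:
        return G
    a = params.supplied_resource
    I = params.supply_conc[a]
    if I <= 0:
        raise ValueError("supplied concentration must be positive")
    on_supplied = params.specialization == a
    L = params.conc_halfsat[on_supplied]
    G[on_supplied, a] = 4.0 * I * L / (L + I) ** 2
    return G


def derivatives(state: CommunityState,
                params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives ``(dN, dR)`` of the community system.

    Pure function of state and parameters.  Negative or non-finite state
    entries are rejected; the ODE driver applies its own positivity guard
    before calling the vectorised right-hand side.
    """
    state.validate()
    G = concentration_specialization(params)
    dN, dR = _rhs(state.biomass, state.resources, params, G)
    return dN, dR


def jacobian(N: np.ndarray, R: np.ndarray, params: ModelParameters,
             G: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the stacked system d(N, R)/dt.

    Used by the implicit solver; only the default byproduct-term reading is
    supported (the literal-reading switch falls back to finite differences).
    """
    if params.byproduct_literal_reading:
        raise NotImplementedError("analytic Jacobian requires the default "
                                  "byproduct-term reading")
    S, M = params.n_species, params.n_resources
    E = params.symbionts
    K = params.symbiont_halfsat
    s = E @ N
    nonempty = E.any(axis=1)
    F = np.where(nonempty, s / (K + s), 1.0)
    W = np.where(nonempty, K / (K + s) ** 2, 0.0)   # dF_i/ds_i
    GC = G * params.consumption
    u = GC @ R                                      # per-unit uptake rate
    FN = F * N
    phi = FN[:, None] * GC                          # dN_i / dR_a
    l = params.secretion_fraction
    v = l * np.einsum("iab,ib->ia", params.stoichiometry, GC * R[None, :])
    q = v - GC * R[None, :]                         # net resource conversion

    J = np.zeros((S + M, S + M))
    NuW = N * u * W
    J[:S, :S] = NuW[:, None] * E
    J[np.arange(S), np.arange(S)] += F * u - params.death_rate
    J[:S, S:] = phi
    NW = N * W
    J[S:, :S] = (F[None, :] * q.T) + q.T @ (NW[:, None] * E)
    D2 = l * np.einsum("i,iab,ib->ab", FN, params.stoichiometry, GC)
    D2[np.arange(M), np.arange(M)] -= (1.0 / params.transfer_rate
                                       + phi.sum(axis=0))
    J[S:, S:] = D2
    return J


def _rhs(N: np.ndarray, R: np.ndarray, params: ModelParameters,
         G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised right-hand side; ``G`` precomputed by the caller."""
    F = symbiont_activity(np.maximum(N, 0.0), params)
    # per-species, per-resource uptake flux F_i G_ia C_ia R_a N_i
    flux = (F * N)[:, None] * G * params.consumption * R[None, :]
    dN = flux.sum(axis=1) - params.death_rate * N
    H = (params.supply_conc - R) / params.transfer_rate
    l = params.secretion_fraction
    if params.byproduct_literal_reading:
        # alternative index placement: secretion proportional to uptake at
        # the secreted resource itself
        secretion = flux * params.stoichiometry.sum(axis=2)
        dR = H - flux.sum(axis=0) + l * secretion.sum(axis=0)
    else:
        secretion = np.einsum("iab,ib->a", params.stoichiometry, flux)
        dR = H - flux.sum(axis=0) + l * secretion
    return dN, dR
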