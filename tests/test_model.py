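"""Unit and property tests for the dynamical-system core."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assemblysim.model import (CommunityState, ModelParameters,
                               concentration_specialization, derivatives,
                               jacobian, symbiont_activity, _rhs)
from conftest import random_params, single_species_params


# ---------------------------------------------------------------- F factor
def _two_species(E):
    return ModelParameters(
        consumption=np.full((2, 2), 0.5),
        stoichiometry=np.tile(np.eye(2), (2, 1, 1)),
        symbionts=E,
        death_rate=0.05, symbiont_halfsat=0.01, conc_halfsat=1.0,
        transfer_rate=1.0, supply_conc=np.array([1.0, 0.0]),
        specialization=np.array([0, 1]),
        conc_specialization_enabled=False)


def test_symbiont_activity_zero_partner_biomass():
    p = _two_species(np.array([[False, True], [False, False]]))
    F = symbiont_activity(np.array([5.0, 0.0]), p)
    assert F[0] == 0.0          # non-empty essential set, partners extinct
    assert F[1] == 1.0          # empty essential set is ungated


def test_symbiont_activity_half_saturation():
    p = _two_species(np.array([[False, True], [False, False]]))
    F = symbiont_activity(np.array([0.0, 0.01]), p)   # s = K = 0.01
    assert F[0] == pytest.approx(0.5)


def test_symbiont_activity_empty_set_is_one():
    p = _two_species(np.zeros((2, 2), dtype=bool))
    assert np.all(symbiont_activity(np.array([3.0, 7.0]), p) == 1.0)


def test_symbiont_activity_length_mismatch():
    p = _two_species(np.zeros((2, 2), dtype=bool))
    with pytest.raises(ValueError):
        symbiont_activity(np.ones(3), p)


@given(st.floats(0.0, 1e3), st.floats(0.0, 10.0))
def test_symbiont_activity_monotone_in_partner_biomass(b, delta):
    p = _two_species(np.array([[False, True], [False, False]]))
    F1 = symbiont_activity(np.array([1.0, b]), p)[0]
    F2 = symbiont_activity(np.array([1.0, b + delta]), p)[0]
    assert F2 >= F1
    assert 0.0 <= F1 <= 1.0


# ---------------------------------------------------------------- G factor
def _conc_params(I, L):
    return ModelParameters(
        consumption=np.full((2, 2), 0.5),
        stoichiometry=np.tile(np.eye(2), (2, 1, 1)),
        symbionts=np.zeros((2, 2), dtype=bool),
        death_rate=0.05, symbiont_halfsat=0.01,
        conc_halfsat=np.array([L, L]),
        transfer_rate=1.0, supply_conc=np.array([I, 0.0]),
        specialization=np.array([0, 1]),
        conc_specialization_enabled=True)


def test_G_peak_at_matching_concentration():
    G = concentration_specialization(_conc_params(I=100.0, L=100.0))
    assert G[0, 0] == pytest.approx(1.0)


def test_G_high_supply_low_adapted():
    G = concentration_specialization(_conc_params(I=100.0, L=1.0))
    assert G[0, 0] == pytest.approx(400.0 / 10201.0)
    # only the supplied column of supplied-resource specialists is modified
    assert G[0, 1] == 1.0 and np.all(G[1] == 1.0)


def test_G_disabled_is_all_ones():
    p = _conc_params(I=100.0, L=1.0)
    p.conc_specialization_enabled = False
    assert np.all(concentration_specialization(p) == 1.0)


@given(st.floats(1e-3, 1e4), st.floats(1e-3, 1e4))
def test_G_in_unit_interval_peak_iff_match(I, L):
    G00 = concentration_specialization(_conc_params(I=I, L=L))[0, 0]
    assert 0.0 < G00 <= 1.0
    if abs(I - L) > 1e-6 * (I + L):   # below this, 1 - G underflows
        assert G00 < 1.0


# ------------------------------------------------------------- derivatives
def test_derivatives_hand_example():
    # one species, one resource, F=G=C=1, R=2, N=3, m=0.05
    p = single_species_params(C=1.0, m=0.05, I=1.0)
    dN, _ = derivatives(CommunityState(np.array([3.0]), np.array([2.0])), p)
    assert dN[0] == pytest.approx(2.0 * 3.0 - 0.05 * 3.0)  # 5.85


def test_derivatives_supply_equilibrium_without_consumers():
    p = single_species_params(I=7.0)
    dN, dR = derivatives(CommunityState(np.array([0.0]), np.array([7.0])), p)
    assert dN[0] == 0.0
    assert dR[0] == pytest.approx(0.0)


def test_derivatives_zero_biomass_leaves_only_supply():
    p = random_params(seed=3)
    R = np.full(p.n_resources, 0.3)
    dN, dR = derivatives(
        CommunityState(np.zeros(p.n_species), R), p)
    assert np.all(dN == 0.0)
    H = (p.supply_conc - R) / p.transfer_rate
    np.testing.assert_allclose(dR, H)


def test_derivatives_linear_in_biomass_when_ungated():
    p = random_params(seed=5, n_essential=0)
    rng = np.random.default_rng(0)
    N = rng.uniform(0.1, 1.0, p.n_species)
    R = rng.uniform(0.1, 1.0, p.n_resources)
    H = (p.supply_conc - R) / p.transfer_rate
    d1N, d1R = derivatives(CommunityState(N, R), p)
    d2N, d2R = derivatives(CommunityState(2 * N, R), p)
    np.testing.assert_allclose(d2N, 2 * d1N, rtol=1e-12)
    np.testing.assert_allclose(d2R - H, 2 * (d1R - H), rtol=1e-12)


def test_flux_balance_with_zero_stoichiometry():
    p = random_params(seed=7)
    p.stoichiometry = np.zeros_like(p.stoichiometry)
    rng = np.random.default_rng(1)
    N = rng.uniform(0.1, 1.0, p.n_species)
    R = rng.uniform(0.1, 1.0, p.n_resources)
    dN, dR = derivatives(CommunityState(N, R), p)
    H = (p.supply_conc - R) / p.transfer_rate
    consumed = (H - dR).sum()            # total flux out of resources
    grown = (dN + p.death_rate * N).sum()  # total flux into biomass
    assert consumed == pytest.approx(grown, rel=1e-12)


def test_derivatives_pure_and_rejects_bad_state():
    p = random_params(seed=11)
    N = np.linspace(0.1, 1.0, p.n_species)
    R = np.linspace(0.2, 0.9, p.n_resources)
    a = derivatives(CommunityState(N, R), p)
    b = derivatives(CommunityState(N.copy(), R.copy()), p)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    with pytest.raises(ValueError):
        CommunityState(N * -1.0, R)
    with pytest.raises(ValueError):
        CommunityState(np.full_like(N, np.nan), R)


def test_literal_reading_differs_but_same_growth():
    p = random_params(seed=13)
    N = np.linspace(0.1, 1.0, p.n_species)
    R = np.linspace(0.2, 0.9, p.n_resources)
    dN, dR = derivatives(CommunityState(N, R), p)
    p.byproduct_literal_reading = True
    dN2, dR2 = derivatives(CommunityState(N, R), p)
    np.testing.assert_allclose(dN2, dN)     # growth term unchanged
    assert not np.allclose(dR2, dR)         # secretion placement differs


# ---------------------------------------------------------------- Jacobian
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_jacobian_matches_finite_differences(seed):
    p = random_params(S=6, M=4, seed=seed)
    rng = np.random.default_rng(seed + 100)
    N = rng.uniform(0.1, 1.0, p.n_species)
    R = rng.uniform(0.1, 1.0, p.n_resources)
    G = concentration_specialization(p)
    J = jacobian(N, R, p, G)
    y0 = np.concatenate([N, R])
    eps = 1e-7
    for k in range(y0.size):
        yp, ym = y0.copy(), y0.copy()
        yp[k] += eps
        ym[k] -= eps
        fp = np.concatenate(_rhs(yp[:6], yp[6:], p, G))
        fm = np.concatenate(_rhs(ym[:6], ym[6:], p, G))
        np.testing.assert_allclose(J[:, k], (fp - fm) / (2 * eps),
                                   rtol=2e-4, atol=1e-7)


# -------------------------------------------------------------- validation
def test_parameter_validation_errors():
    p = random_params(seed=17)
    bad = p.consumption.copy()
    bad[0, 0] += 0.5
    with pytest.raises(ValueError, match="sum to 1"):
        ModelParameters(**{**_kw(p), "consumption": bad})
    badD = p.stoichiometry.copy()
    badD[0, :, 0] *= 0.5
    with pytest.raises(ValueError, match="stoichiometry column"):
        ModelParameters(**{**_kw(p), "stoichiometry": badD})
    badE = p.symbionts.copy()
    badE[0, 0] = True
    with pytest.raises(ValueError, match="own essential"):
        ModelParameters(**{**_kw(p), "symbionts": badE})
    badI = p.supply_conc.copy()
    badI[1] = 1.0
    with pytest.raises(ValueError, match="exactly one"):
        ModelParameters(**{**_kw(p), "supply_conc": badI})
    with pytest.raises(ValueError, match="positive"):
        ModelParameters(**{**_kw(p), "death_rate": 0.0})


def _kw(p):
    return {
        "consumption": p.consumption, "stoichiometry": p.stoichiometry,
        "symbionts": p.symbionts, "death_rate": p.death_rate,
        "symbiont_halfsat": p.symbiont_halfsat,
        "conc_halfsat": p.conc_halfsat, "transfer_rate": p.transfer_rate,
        "supply_conc": p.supply_conc, "specialization": p.specialization,
        "conc_specialization_enabled": p.conc_specialization_enabled,
        "secretion_fraction": p.secretion_fraction,
    }


def test_parameters_json_round_trip(tmp_path):
    p = random_params(seed=19)
    path = tmp_path / "params.json"
    p.to_json(path)
    q = ModelParameters.from_json(path)
    np.testing.assert_array_equal(p.consumption, q.consumption)
    np.testing.assert_array_equal(p.stoichiometry, q.stoichiometry)
    np.testing.assert_array_equal(p.symbionts, q.symbionts)
    assert q.secretion_fraction == p.secretion_fraction
    assert q.conc_specialization_enabled == p.conc_specialization_enabled
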