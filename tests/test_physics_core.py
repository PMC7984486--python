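"""Electron density, effective atomic numbers, kV CT model and Bethe SPR."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from redcal.physics_core import (
    AVOGADRO,
    DEFAULT_KV_FIT,
    KvFitParameters,
    ProtonBeam,
    beta_squared,
    effective_atomic_numbers,
    electrons_per_gram,
    kv_hu_scale,
    ln_i_water,
    mean_excitation,
    proton_spr,
    relative_electron_density,
)
from redcal.tissue_db import ELEMENTS, Tissue

# Literal (Z, A, I) constants for independent brute-force oracles.
ZAI = {
    "H": (1, 1.008, 19.2), "C": (6, 12.011, 78.0), "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0), "Na": (11, 22.98976928, 149.0), "Mg": (12, 24.305, 156.0),
    "P": (15, 30.973761998, 173.0), "S": (16, 32.06, 180.0), "Cl": (17, 35.45, 174.0),
    "K": (19, 39.0983, 190.0), "Ca": (20, 40.078, 191.0), "Fe": (26, 55.845, 286.0),
    "I": (53, 126.90447, 491.0),
}


def brute_force_ng_per_mol(weights):
    """Independent per-element summation of electrons per gram (mol e-/g)."""
    return math.fsum(w / 100.0 * ZAI[s][0] / ZAI[s][1] for s, w in weights.items())


# ---------------------------------------------------------------------------
# electrons per gram and RED
# ---------------------------------------------------------------------------

def test_electrons_per_gram_water(water):
    # Hand oracle: 0.1119*(1/1.008) + 0.8881*(8/15.999) ~ 0.5551 mol e-/g
    assert electrons_per_gram(water.weights) / AVOGADRO == pytest.approx(0.5551, abs=2e-4)


def test_electrons_per_gram_pure_hydrogen():
    t = Tissue("pure H", "soft", 1.0, {"H": 100.0})
    assert electrons_per_gram(t.weights) / AVOGADRO == pytest.approx(1 / 1.008, rel=1e-12)


def test_electrons_per_gram_matches_brute_force_on_all_rows(reference_set):
    for t in reference_set:
        expected = AVOGADRO * brute_force_ng_per_mol(t.weights)
        assert electrons_per_gram(t.weights) == pytest.approx(expected, rel=1e-12)


def test_red_of_water_is_one(water):
    assert relative_electron_density(water) == pytest.approx(1.0, rel=1e-14)


def test_red_of_adipose(reference_set):
    # Oracle: brute-force sum over the 7 nonzero Adipose elements gives
    # 0.55578 mol e-/g, so RED = 0.95 * 0.55578 / 0.55509 = 0.9512.
    t = reference_set["Adipose"]
    expected = 0.95 * brute_force_ng_per_mol(t.weights) / 0.5550930
    assert relative_electron_density(t) == pytest.approx(expected, rel=1e-6)
    assert relative_electron_density(t) == pytest.approx(0.9512, abs=0.0005)


def test_red_linear_in_density(reference_set):
    t = reference_set["Muscle"]
    doubled = Tissue("dense muscle", t.category, 2 * t.rho, dict(t.weights))
    assert relative_electron_density(doubled) == pytest.approx(
        2 * relative_electron_density(t), rel=1e-14
    )


# ---------------------------------------------------------------------------
# effective atomic numbers
# ---------------------------------------------------------------------------

def test_effective_atomic_numbers_water(water):
    # Oracle: electron fractions lambda_H = 0.2000, lambda_O = 0.8000
    lam_h = 0.1119 * 1 / 1.008 / 0.5551
    lam_o = 1 - lam_h
    zt = (lam_h * 1**3.62 + lam_o * 8**3.62) ** (1 / 3.62)
    zh = (lam_h * 1**1.86 + lam_o * 8**1.86) ** (1 / 1.86)
    got_t, got_h = effective_atomic_numbers(water.weights)
    assert got_t == pytest.approx(zt, abs=0.01)
    assert got_h == pytest.approx(zh, abs=0.01)
    assert got_t == pytest.approx(7.52, abs=0.01)
    assert got_h == pytest.approx(7.12, abs=0.01)


def test_effective_atomic_numbers_single_element():
    t = Tissue("pure O", "soft", 1.0, {"O": 100.0})
    zt, zh = effective_atomic_numbers(t.weights)
    assert zt == pytest.approx(8.0, rel=1e-12)
    assert zh == pytest.approx(8.0, rel=1e-12)


@st.composite
def compositions(draw):
    symbols = draw(st.sets(st.sampled_from(sorted(ZAI)), min_size=1, max_size=6))
    raw = {s: draw(st.floats(0.01, 100.0)) for s in symbols}
    total = sum(raw.values())
    return {s: 100.0 * v / total for s, v in raw.items()}


@settings(max_examples=100, derandomize=True, deadline=None)
@given(compositions())
def test_power_mean_inequality_any_composition(weights):
    zt, zh = effective_atomic_numbers(weights)
    assert zh <= zt + 1e-12
    assert 1.0 - 1e-12 <= zh and zt <= 53.0 + 1e-12


@settings(max_examples=100, derandomize=True, deadline=None)
@given(compositions())
def test_mean_excitation_bounded_by_elements(weights):
    im = math.exp(mean_excitation(weights))
    i_vals = [ZAI[s][2] for s in weights]
    assert min(i_vals) - 1e-9 <= im <= max(i_vals) + 1e-9


# ---------------------------------------------------------------------------
# kV CT model
# ---------------------------------------------------------------------------

def test_hu_scale_water_close_to_1000(water):
    assert kv_hu_scale(water, DEFAULT_KV_FIT) == pytest.approx(1000.0, rel=3e-3)


def test_hu_scale_proportional_to_red(water):
    # Compton-only limit: HU_scale = 1000 * RED for any composition.
    fit = KvFitParameters(A=0.0, B=0.0, C=1000.0)
    t = Tissue("half water", "soft", 0.5, dict(water.weights))
    assert kv_hu_scale(t, fit) == pytest.approx(
        1000.0 * relative_electron_density(t), rel=1e-12
    )
    assert kv_hu_scale(water, fit) == pytest.approx(1000.0, rel=1e-12)


def test_kv_fit_validation():
    with pytest.raises(ValueError):
        KvFitParameters(A=0.01, B=0.1, C=0.0)
    with pytest.raises(ValueError):
        KvFitParameters(A=-0.01, B=0.1, C=1000.0)


# ---------------------------------------------------------------------------
# mean excitation energy
# ---------------------------------------------------------------------------

def test_mean_excitation_water(water):
    # Oracle: exp((0.1110*ln 19.2 + 0.4441*ln 95)/0.5551) ~ 69 eV
    assert math.exp(mean_excitation(water.weights)) == pytest.approx(69.0, abs=0.5)


def test_mean_excitation_single_element():
    t = Tissue("pure C", "soft", 1.0, {"C": 100.0})
    assert math.exp(mean_excitation(t.weights)) == pytest.approx(78.0, rel=1e-12)


# ---------------------------------------------------------------------------
# proton kinematics and SPR
# ---------------------------------------------------------------------------

def test_beta_squared_at_175_mev():
    # Oracle: 1 - (938.272 / 1113.272)^2
    assert beta_squared(175.0) == pytest.approx(1 - (938.272 / 1113.272) ** 2, rel=1e-12)
    assert beta_squared(175.0) == pytest.approx(0.290, abs=0.001)


def test_beta_squared_monotone_and_bounded():
    energies = [1.0, 10.0, 100.0, 175.0, 250.0, 1000.0]
    vals = [beta_squared(t) for t in energies]
    assert all(0 < v < 1 for v in vals)
    assert vals == sorted(vals)


def test_beta_squared_rejects_nonpositive_energy():
    with pytest.raises(ValueError):
        beta_squared(0.0)
    with pytest.raises(ValueError):
        beta_squared(-5.0)


def test_spr_water_is_exactly_one(water, beam):
    assert proton_spr(water, beam) == 1.0


def test_spr_adipose_hand_oracle(reference_set, beam):
    """Direct scalar evaluation of the Bethe ratio, independent of the code."""
    t = reference_set["Adipose"]
    b2 = 1 - (938.272 / (175.0 + 938.272)) ** 2
    ng = brute_force_ng_per_mol(t.weights)
    ln_im = math.fsum(
        w / 100 * ZAI[s][0] / ZAI[s][1] * math.log(ZAI[s][2]) for s, w in t.weights.items()
    ) / ng
    wat = {"H": 2 * 1.008 / 18.015 * 100, "O": 15.999 / 18.015 * 100}
    ng_w = brute_force_ng_per_mol(wat)
    ln_iw = math.fsum(
        w / 100 * ZAI[s][0] / ZAI[s][1] * math.log(ZAI[s][2]) for s, w in wat.items()
    ) / ng_w
    red = 0.95 * ng / ng_w
    k = math.log(2 * 0.511e6 * b2 / (1 - b2))
    expected = red * (k - ln_im - b2) / (k - ln_iw - b2)
    assert proton_spr(t, beam) == pytest.approx(expected, rel=1e-5)


def test_spr_common_iw_rescaling_is_multiplicative(reference_set, beam):
    """Replacing I_w by c*I_w rescales every SPR by one common factor."""
    lnIw = ln_i_water("bragg_additivity")
    c = 78.0 / math.exp(lnIw)
    ratios = set()
    for t in list(reference_set)[:6]:
        r = proton_spr(t, beam, lnIw=lnIw + math.log(c)) / proton_spr(t, beam, lnIw=lnIw)
        ratios.add(round(r, 12))
    assert len(ratios) == 1


def test_ln_i_water_modes():
    assert math.exp(ln_i_water("bragg_additivity")) == pytest.approx(69.0, abs=0.5)
    assert math.exp(ln_i_water("fixed", 78.0)) == pytest.approx(78.0, rel=1e-12)
    with pytest.raises(ValueError):
        ln_i_water("nonsense")
    with pytest.raises(ValueError):
        ln_i_water("fixed", -1.0)
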