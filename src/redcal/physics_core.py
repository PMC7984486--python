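"""First-principles CT-number and proton stopping-power physics.

The stoichiometric calibration method rests on four closed-form
relations between a material's composition and its imaging/dosimetric
behaviour:

* electrons per gram             ``N_g = N_A * sum_i (w_i/100) Z_i / A_i``
* relative electron density      ``RED = rho N_g / (rho_w N_w)``
* scaled kV CT number            ``HU_scale = RED * (A Ztilde^3.62 + B Zhat^1.86 + C)``
* proton stopping-power ratio    ``SPR = RED * L(I_m) / L(I_w)`` with the
  stopping number ``L(I) = ln(2 m_e c^2 beta^2 / (I (1 - beta^2))) - beta^2``

``Ztilde`` and ``Zhat`` are power means of atomic number over electron
fractions (exponents 3.62 and 1.86, the photoelectric and coherent
scattering sensitivities); ``A, B, C`` are scanner- and energy-specific
fit constants.  ``I_m`` is the mean excitation energy of the mixture
combined by Bragg additivity; the water value ``I_w`` may be computed
the same way (default, which makes SPR(water) = 1 exactly) or fixed to
a tabulated value — the choice provably cancels out of all deviation
statistics downstream.

All quantities are kept in double precision; nothing is rounded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from scipy.constants import Avogadro

from .tissue_db import ELEMENTS, Tissue, water_reference

__all__ = [
    "AVOGADRO",
    "M_E_C2_MEV",
    "M_P_C2_MEV",
    "PHOTOELECTRIC_EXPONENT",
    "COHERENT_EXPONENT",
    "DEFAULT_KV_FIT",
    "DEFAULT_PROTON_ENERGY_MEV",
    "KvFitParameters",
    "ProtonBeam",
    "DerivedQuantities",
    "electrons_per_gram",
    "relative_electron_density",
    "effective_atomic_numbers",
    "kv_hu_scale",
    "mean_excitation",
    "ln_i_water",
    "beta_squared",
    "proton_spr",
    "derived_quantities",
]

AVOGADRO = Avogadro  # 1/mol
M_E_C2_MEV = 0.511  # electron rest energy
M_P_C2_MEV = 938.272  # proton rest energy

#: Fixed exponents of the parametric kV CT-number model (photoelectric
#: and coherent-scattering terms).  These are physical constants of the
#: model, not fit parameters.
PHOTOELECTRIC_EXPONENT = 3.62
COHERENT_EXPONENT = 1.86

#: Default proton kinetic energy (MeV) for SPR evaluation.  A mid-range
#: therapeutic energy; deviation statistics are insensitive to the choice
#: (see the energy-robustness property in the test suite).
DEFAULT_PROTON_ENERGY_MEV = 175.0


@dataclass(frozen=True)
class KvFitParameters:
    """Scanner-specific constants (A, B, C) of the kV CT-number model.

    The three terms scale the photoelectric, coherent-scatter and
    Compton contributions respectively.
    """

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("Compton coefficient C must be positive")
        if self.A < 0 or self.B < 0:
            raise ValueError("A and B must be non-negative")


#: Fit constants determined for a 120 kVp scan of a CIRS 062M electron
#: density phantom; used as the package default.
DEFAULT_KV_FIT = KvFitParameters(A=1.995e-2, B=1.899e-1, C=9.640e2)


def beta_squared(T: float) -> float:
    """Relativistic beta^2 of a proton with kinetic energy ``T`` (MeV)."""
    if T <= 0:
        raise ValueError(f"proton kinetic energy must be positive, got {T}")
    gamma_inv = M_P_C2_MEV / (T + M_P_C2_MEV)
    return 1.0 - gamma_inv * gamma_inv


@dataclass(frozen=True)
class ProtonBeam:
    """Monoenergetic proton beam: kinetic energy and derived beta^2."""

    T: float  # MeV
    beta_sq: float
    m_e_c2: float = M_E_C2_MEV

    @classmethod
    def from_energy(cls, T: float = DEFAULT_PROTON_ENERGY_MEV) -> "ProtonBeam":
        return cls(T=T, beta_sq=beta_squared(T))

    def __post_init__(self) -> None:
        if not 0.0 < self.beta_sq < 1.0:
            raise ValueError(f"beta^2 must be in (0, 1), got {self.beta_sq}")


@dataclass(frozen=True)
class DerivedQuantities:
    """All per-tissue physics outputs in one record."""

    Ng: float  # electrons per gram (absolute, 1/g)
    RED: float
    Z_tilde: float
    Z_hat: float
    lnIm: float  # ln(I_m / eV)
    HU_scale: float
    SPR: float


def electrons_per_gram(weights: Mapping[str, float]) -> float:
    """Electrons per gram, ``N_A * sum (w_i/100) Z_i / A_i`` (units 1/g).

    ``weights`` must be percentage weights summing to 100.
    """
    total = 0.0
    for sym, w in weights.items():
        el = ELEMENTS[sym]
        total += (w / 100.0) * el.Z / el.A_w
    return AVOGADRO * total


# Water constants are fixed by the registry; compute once.
_WATER = water_reference()
WATER_NG = electrons_per_gram(_WATER.weights)


def relative_electron_density(tissue: Tissue) -> float:
    """RED = rho N_g / (rho_w N_w), electrons per volume relative to water."""
    return tissue.rho * electrons_per_gram(tissue.weights) / (_WATER.rho * WATER_NG)


def effective_atomic_numbers(weights: Mapping[str, float]) -> tuple[float, float]:
    """Photoelectric and coherent effective atomic numbers (Ztilde, Zhat).

    Power means of Z over electron fractions ``lambda_i = N_gi / N_g``
    with exponents 3.62 and 1.86.  By the power-mean inequality
    ``Zhat <= Ztilde`` always.
    """
    lam = []
    zs = []
    for sym, w in weights.items():
        el = ELEMENTS[sym]
        lam.append((w / 100.0) * el.Z / el.A_w)
        zs.append(float(el.Z))
    norm = math.fsum(lam)
    z_tilde = math.fsum(
        l / norm * z**PHOTOELECTRIC_EXPONENT for l, z in zip(lam, zs)
    ) ** (1.0 / PHOTOELECTRIC_EXPONENT)
    z_hat = math.fsum(
        l / norm * z**COHERENT_EXPONENT for l, z in zip(lam, zs)
    ) ** (1.0 / COHERENT_EXPONENT)
    return z_tilde, z_hat


def kv_hu_scale(tissue: Tissue, fit: KvFitParameters = DEFAULT_KV_FIT) -> float:
    """Scaled kV CT number, ``RED * (A Ztilde^3.62 + B Zhat^1.86 + C)``.

    ``HU_scale`` is the CT number plus 1000, so water reads ~1000 and
    vacuum 0.
    """
    red = relative_electron_density(tissue)
    z_tilde, z_hat = effective_atomic_numbers(tissue.weights)
    return red * (
        fit.A * z_tilde**PHOTOELECTRIC_EXPONENT
        + fit.B * z_hat**COHERENT_EXPONENT
        + fit.C
    )


def mean_excitation(weights: Mapping[str, float]) -> float:
    """ln of the mean excitation energy (eV) by Bragg additivity.

    ``ln I_m = sum (w_i Z_i / A_i) ln I_i / sum (w_i Z_i / A_i)``.
    """
    num = 0.0
    den = 0.0
    for sym, w in weights.items():
        el = ELEMENTS[sym]
        f = (w / 100.0) * el.Z / el.A_w
        num += f * math.log(el.I)
        den += f
    return num / den


#: ln(I_w/eV) from Bragg additivity over water's own composition (~69 eV).
LN_I_WATER_BRAGG = mean_excitation(_WATER.weights)


def ln_i_water(mode: str = "bragg_additivity", fixed_value_eV: float = 78.0) -> float:
    """ln(I_w/eV) under the selected convention.

    ``"bragg_additivity"`` (default) combines the elemental values over
    water's own composition, which makes SPR(water) = 1 exactly and is
    internally consistent with how tissue I_m is computed.  ``"fixed"``
    uses ``fixed_value_eV`` instead.  Deviation statistics downstream are
    invariant to this choice.
    """
    if mode == "bragg_additivity":
        return LN_I_WATER_BRAGG
    if mode == "fixed":
        if fixed_value_eV <= 0:
            raise ValueError("fixed I_w must be positive")
        return math.log(fixed_value_eV)
    raise ValueError(f"unknown I_w mode {mode!r}")


def _stopping_number(ln_i: float, beam: ProtonBeam) -> float:
    """Bethe stopping number ``ln(2 m_e c^2 beta^2 / (I (1-beta^2))) - beta^2``.

    ``ln_i`` is ln(I/eV); the electron rest energy is converted to eV.
    """
    b2 = beam.beta_sq
    return math.log(2.0 * beam.m_e_c2 * 1e6 * b2 / (1.0 - b2)) - ln_i - b2


def proton_spr(
    tissue: Tissue,
    beam: ProtonBeam | None = None,
    lnIw: float | None = None,
) -> float:
    """Proton stopping-power ratio relative to water.

    ``SPR = RED * L(I_m) / L(I_w)`` with the Bethe stopping number L.
    ``lnIw`` defaults to the Bragg-additivity water value.
    """
    beam = beam or ProtonBeam.from_energy()
    if lnIw is None:
        lnIw = LN_I_WATER_BRAGG
    num = _stopping_number(mean_excitation(tissue.weights), beam)
    den = _stopping_number(lnIw, beam)
    if num <= 0 or den <= 0:
        raise ValueError(
            f"{tissue.name}: non-positive stopping number at beta^2={beam.beta_sq}"
        )
    return relative_electron_density(tissue) * num / den


def derived_quantities(
    tissue: Tissue,
    fit: KvFitParameters = DEFAULT_KV_FIT,
    beam: ProtonBeam | None = None,
    lnIw: float | None = None,
) -> DerivedQuantities:
    """Compute every per-tissue physics quantity in one pass."""
    beam = beam or ProtonBeam.from_energy()
    ng = electrons_per_gram(tissue.weights)
    red = tissue.rho * ng / (_WATER.rho * WATER_NG)
    z_tilde, z_hat = effective_atomic_numbers(tissue.weights)
    ln_im = mean_excitation(tissue.weights)
    hu = red * (
        fit.A * z_tilde**PHOTOELECTRIC_EXPONENT
        + fit.B * z_hat**COHERENT_EXPONENT
        + fit.C
    )
    if lnIw is None:
        lnIw = LN_I_WATER_BRAGG
    spr = red * _stopping_number(ln_im, beam) / _stopping_number(lnIw, beam)
    return DerivedQuantities(
        Ng=ng, RED=red, Z_tilde=z_tilde, Z_hat=z_hat, lnIm=ln_im, HU_scale=hu, SPR=spr
    )
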