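"""Single-energy narrow-beam attenuation and the kV vs MV linearity test.

A CT number is, at its core, a linear attenuation coefficient relative
to water: ``HU_scale = 1000 * mu / mu_water``.  For a monoenergetic
pencil beam the narrow-beam (unscattered-photon) attenuation
coefficient of a mixture follows the elemental mixture rule

    mu = rho * sum_i (w_i / 100) * (mu/rho)_i,

with total mass attenuation coefficients that include coherent
scattering, since a coherently scattered photon has interacted and so
leaves the unscattered count.  This closed form is exactly the
expectation of counting surviving photons through a slab (Beer-Lambert);
a small Bernoulli survival simulator is provided to verify that
equivalence.

The physics question addressed here: a kV beam (60 keV effective
energy for a 120 kVp spectrum) has substantial photoelectric and
coherent contributions that depend on atomic number, while a MV beam
(0.8 MeV, representative of a 2.5 MV imaging beam) is almost purely
Compton and therefore tracks electron density alone.  Fitting HU_scale
against RED per tissue category quantifies this: the MV fit is linear
to four decimal places of R^2 while the kV fit is visibly degraded,
especially for fat tissues.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tissue_db import BEAM_ENERGIES_MEV, CATEGORIES, ELEMENTS, Tissue, TissueSet, water_reference

__all__ = [
    "PhotonBeam",
    "AttenuationResult",
    "KV_BEAM",
    "MV_BEAM",
    "linear_attenuation",
    "hu_from_mu",
    "attenuation_table",
    "linearity_comparison",
    "simulate_survival_fraction",
    "interpolate_mu_rho",
]


@dataclass(frozen=True)
class PhotonBeam:
    """A monoenergetic photon beam identified by label and energy (MeV)."""

    label: str  # "kV" or "MV"
    energy: float

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("photon energy must be positive")
        if self.label not in BEAM_ENERGIES_MEV:
            raise ValueError(f"no attenuation table for beam label {self.label!r}")


KV_BEAM = PhotonBeam("kV", BEAM_ENERGIES_MEV["kV"])
MV_BEAM = PhotonBeam("MV", BEAM_ENERGIES_MEV["MV"])


@dataclass(frozen=True)
class AttenuationResult:
    """Linear attenuation of one tissue and its scaled CT number."""

    tissue_name: str
    mu: float  # cm^-1
    mu_water: float  # cm^-1
    hu_scale: float


def _mu_rho(symbol: str, beam: PhotonBeam) -> float:
    el = ELEMENTS[symbol]
    tab_energy = BEAM_ENERGIES_MEV[beam.label]
    if math.isclose(beam.energy, tab_energy, rel_tol=1e-9):
        return el.mu_rho[beam.label]
    return interpolate_mu_rho(symbol, beam.energy)


def interpolate_mu_rho(symbol: str, energy: float) -> float:
    """Log-log interpolation of (mu/rho) between the two embedded energies.

    Provided for off-grid energies; the default beams use the embedded
    values directly.
    """
    el = ELEMENTS[symbol]
    e_lo, e_hi = BEAM_ENERGIES_MEV["kV"], BEAM_ENERGIES_MEV["MV"]
    mu_lo, mu_hi = el.mu_rho["kV"], el.mu_rho["MV"]
    t = (math.log(energy) - math.log(e_lo)) / (math.log(e_hi) - math.log(e_lo))
    return math.exp(math.log(mu_lo) + t * (math.log(mu_hi) - math.log(mu_lo)))


def linear_attenuation(tissue: Tissue, beam: PhotonBeam) -> float:
    """Mixture-rule linear attenuation coefficient mu (cm^-1)."""
    return tissue.rho * math.fsum(
        (w / 100.0) * _mu_rho(sym, beam) for sym, w in tissue.weights.items()
    )


def hu_from_mu(mu: float, mu_water: float) -> float:
    """Scaled CT number ``1000 + 1000 * (mu - mu_water) / mu_water``."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    # grouped so mu == mu_water yields exactly 1000
    return 1000.0 * (mu / mu_water)


def attenuation_table(tissues: TissueSet, beam: PhotonBeam) -> list[AttenuationResult]:
    """Attenuation and CT number of every tissue under one beam."""
    mu_w = linear_attenuation(water_reference(), beam)
    return [
        AttenuationResult(t.name, mu := linear_attenuation(t, beam), mu_w, hu_from_mu(mu, mu_w))
        for t in tissues
    ]


def linearity_comparison(
    tissues: TissueSet,
    beams: Sequence[PhotonBeam] = (KV_BEAM, MV_BEAM),
) -> pd.DataFrame:
    """Per-beam, per-category linear fit of HU_scale against RED.

    Returns a DataFrame indexed by (beam label, category) with slope,
    intercept, the unrounded R^2 and R^2 rounded to 4 decimals.
    Requires >= 3 tissues per category for a meaningful R^2.
    """
    from .physics_core import relative_electron_density

    rows = []
    for beam in beams:
        results = {r.tissue_name: r for r in attenuation_table(tissues, beam)}
        for cat in CATEGORIES:
            members = tissues.by_category(cat)
            if len(members) < 3:
                raise ValueError(f"category {cat!r} has {len(members)} tissues; need >= 3")
            red = np.array([relative_electron_density(t) for t in members])
            hu = np.array([results[t.name].hu_scale for t in members])
            fit = stats.linregress(red, hu)
            r2 = float(fit.rvalue**2)
            rows.append(
                {
                    "beam": beam.label,
                    "energy_MeV": beam.energy,
                    "category": cat,
                    "slope": float(fit.slope),
                    "intercept": float(fit.intercept),
                    "r_squared": r2,
                    "r_squared_4dp": round(r2, 4),
                    "n_points": len(members),
                }
            )
    return pd.DataFrame(rows).set_index(["beam", "category"])


def comparison_to_json(comparison: pd.DataFrame, path: str | Path | None = None) -> str:
    """Serialize a linearity comparison table to JSON."""
    payload = comparison.reset_index().to_dict(orient="records")
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def simulate_survival_fraction(
    mu: float, thickness_cm: float, n_photons: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte Carlo estimate of mu from Bernoulli photon survival.

    Each photon survives a slab of ``thickness_cm`` unscattered with
    probability ``exp(-mu * t)``; the estimator ``-ln(k/n)/t`` recovers
    mu.  Returns (mu_hat, standard_error).  This is the stochastic
    counterpart whose expectation the mixture rule computes analytically.
    """
    p = math.exp(-mu * thickness_cm)
    k = rng.binomial(n_photons, p)
    if k == 0:
        raise RuntimeError("no surviving photons; reduce thickness or mu")
    frac = k / n_photons
    mu_hat = -math.log(frac) / thickness_cm
    se = math.sqrt((1.0 - frac) / (n_photons * frac)) / thickness_cm
    return mu_hat, se
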