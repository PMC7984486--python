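"""Element constants and the reference human-tissue table.

The package works with 13 chemical elements (H, C, N, O, Na, Mg, P, S,
Cl, K, Ca, Fe, I) that together cover every material in the reference
human-tissue compilation: 32 tissues grouped into fat, non-fat soft and
bone categories, each described by a mass density (g/cm^3) and elemental
percentage weights.

Element constants carried here:

* ``Z`` — atomic number,
* ``A_w`` — atomic weight (g/mol, IUPAC 2021 standard values),
* ``I`` — mean excitation energy (eV, ICRU-37 values as tabulated in
  the Geant4 physics reference manual),
* ``mu_rho`` — narrow-beam total mass attenuation coefficients
  (cm^2/g, coherent scattering included) at the two imaging energies
  used by :mod:`redcal.beam_attenuation`, keyed by beam label.

Tissue tables can be read from and written to a simple CSV dialect
(``name,category,density,H,...,I``); weights are renormalized to sum to
exactly 100 on load, since all downstream physics assumes proper mass
fractions.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Element",
    "Tissue",
    "TissueSet",
    "ELEMENTS",
    "ELEMENT_ORDER",
    "CATEGORIES",
    "BEAM_ENERGIES_MEV",
    "load_tissue_table",
    "write_tissue_table",
    "water_reference",
    "export_element_registry",
]

#: Tissue categories, in display order.
CATEGORIES = ("fat", "soft", "bone")

#: Column order of the tissue CSV dialect (after name, category, density).
ELEMENT_ORDER = ("H", "C", "N", "O", "Ca", "P", "Na", "Mg", "S", "Cl", "K", "Fe", "I")

#: Photon energies (MeV) at which mass attenuation coefficients are embedded,
#: keyed by beam label: a 120 kVp spectrum is represented by its ~60 keV
#: effective energy, a 2.5 MV imaging beam by its ~0.8 MeV average energy.
BEAM_ENERGIES_MEV = {"kV": 0.060, "MV": 0.800}

# Maximum tolerated deviation of a raw weight row from 100% before it is
# rejected (the published rows sum to 99.9-100.1 due to rounding).
WEIGHT_SUM_TOLERANCE = 0.5


@dataclass(frozen=True)
class Element:
    """Immutable physical constants for one chemical element."""

    symbol: str
    Z: int
    A_w: float  # g/mol
    I: float  # mean excitation energy, eV
    mu_rho: Mapping[str, float]  # beam label -> mass attenuation coeff, cm^2/g

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"{self.symbol}: atomic number must be >= 1")
        if self.A_w <= 0 or self.I <= 0:
            raise ValueError(f"{self.symbol}: A_w and I must be positive")
        if any(v <= 0 for v in self.mu_rho.values()):
            raise ValueError(f"{self.symbol}: mass attenuation coefficients must be positive")


def _el(symbol: str, Z: int, A_w: float, I: float, mu_kv: float, mu_mv: float) -> Element:
    return Element(symbol, Z, A_w, I, {"kV": mu_kv, "MV": mu_mv})


#: Registry of the 13 supported elements.  Mass attenuation coefficients are
#: narrow-beam totals (photoelectric + incoherent + coherent) from standard
#: photon cross-section tabulations at 60 keV and 0.8 MeV.
ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in (
        _el("H", 1, 1.008, 19.2, 0.3255, 0.1405),
        _el("C", 6, 12.011, 78.0, 0.1753, 0.0707),
        _el("N", 7, 14.007, 82.0, 0.1775, 0.0708),
        _el("O", 8, 15.999, 95.0, 0.1906, 0.0708),
        _el("Na", 11, 22.98976928, 149.0, 0.2263, 0.0676),
        _el("Mg", 12, 24.305, 156.0, 0.2530, 0.0696),
        _el("P", 15, 30.973761998, 173.0, 0.3402, 0.0683),
        _el("S", 16, 32.06, 180.0, 0.3900, 0.0704),
        _el("Cl", 17, 35.45, 174.0, 0.4200, 0.0676),
        _el("K", 19, 39.0983, 190.0, 0.5496, 0.0685),
        _el("Ca", 20, 40.078, 191.0, 0.6390, 0.0704),
        _el("Fe", 26, 55.845, 286.0, 1.2050, 0.0659),
        _el("I", 53, 126.90447, 491.0, 8.5100, 0.0616),
    )
}


@dataclass(frozen=True)
class Tissue:
    """A named material: category, mass density and elemental composition.

    Parameters
    ----------
    name
        Unique identifier.
    category
        One of ``"fat"``, ``"soft"``, ``"bone"`` (or ``"water"`` for the
        normalizing medium, which never enters category fits).
    rho
        Mass density in g/cm^3.
    weights
        Mapping element symbol -> percentage weight.  Stored normalized so
        the weights sum to exactly 100.
    """

    name: str
    category: str
    rho: float
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"{self.name}: density must be positive, got {self.rho}")
        unknown = set(self.weights) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"{self.name}: unknown element symbol(s) {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError(f"{self.name}: negative weight")
        total = math.fsum(self.weights.values())
        if abs(total - 100.0) > WEIGHT_SUM_TOLERANCE:
            raise ValueError(
                f"{self.name}: weights sum to {total:.3f}, more than "
                f"{WEIGHT_SUM_TOLERANCE} away from 100"
            )
        # Renormalize multiplicatively so downstream formulas see proper
        # mass fractions; drop zero entries for sparse iteration.  The
        # float residual of the rescaling is folded into the largest
        # weight so the stored sum is exactly 100.0, which makes
        # normalization idempotent (re-wrapping a normalized composition
        # reproduces it bit-exactly).
        norm = {s: 100.0 * w / total for s, w in self.weights.items() if w > 0}
        largest = max(norm, key=norm.get)
        norm[largest] += 100.0 - math.fsum(norm.values())
        object.__setattr__(self, "weights", norm)

    def nonzero_elements(self) -> tuple[str, ...]:
        return tuple(s for s in ELEMENT_ORDER if self.weights.get(s, 0.0) > 0)


@dataclass
class TissueSet:
    """Ordered collection of tissues with a provenance label."""

    tissues: list[Tissue]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [t.name for t in self.tissues]
        if len(names) != len(set(names)):
            raise ValueError("duplicate tissue names in set")

    def __iter__(self) -> Iterator[Tissue]:
        return iter(self.tissues)

    def __len__(self) -> int:
        return len(self.tissues)

    def __getitem__(self, name: str) -> Tissue:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    def by_category(self, category: str) -> list[Tissue]:
        return [t for t in self.tissues if t.category == category]

    def category_counts(self) -> dict[str, int]:
        return {c: len(self.by_category(c)) for c in CATEGORIES}


# ---------------------------------------------------------------------------
# Reference human tissues: density (g/cm^3) and percentage weights of
# H, C, N, O, Ca, P, Na, Mg, S, Cl, K, Fe, I (ELEMENT_ORDER).
# 32 tissues: 3 fat, 18 non-fat soft, 11 bone.
# ---------------------------------------------------------------------------
_REFERENCE_ROWS: tuple[tuple[str, str, float, tuple[float, ...]], ...] = (
    ("Adipose", "fat", 0.95, (11.4, 59.8, 0.7, 27.8, 0, 0, 0.1, 0, 0.1, 0.1, 0, 0, 0)),
    ("Yellow marrow", "fat", 0.98, (11.5, 64.4, 0.7, 23.1, 0, 0, 0.1, 0, 0.1, 0.1, 0, 0, 0)),
    ("Red marrow", "fat", 1.03, (10.5, 41.4, 3.4, 43.9, 0, 0.1, 0, 0, 0.2, 0.2, 0.2, 0.1, 0)),
    ("Lung (inflated)", "soft", 0.26, (10.3, 10.5, 3.1, 74.9, 0, 0.2, 0.2, 0, 0.3, 0.3, 0.2, 0, 0)),
    ("GI tract", "soft", 1.03, (10.6, 11.5, 2.2, 75.1, 0, 0.1, 0.1, 0, 0.1, 0.2, 0.1, 0, 0)),
    ("Lymph", "soft", 1.03, (10.8, 4.1, 1.1, 83.2, 0, 0, 0.3, 0, 0.1, 0.4, 0, 0, 0)),
    ("Brain", "soft", 1.04, (10.7, 14.5, 2.2, 71.2, 0, 0.4, 0.2, 0, 0.2, 0.3, 0.3, 0, 0)),
    ("Pancreas", "soft", 1.04, (10.6, 16.9, 2.2, 69.4, 0, 0.2, 0.2, 0, 0.1, 0.2, 0.2, 0, 0)),
    ("Testis", "soft", 1.04, (10.6, 9.9, 2.0, 76.6, 0, 0.1, 0.2, 0, 0.2, 0.2, 0.2, 0, 0)),
    ("Kidney", "soft", 1.05, (10.3, 13.2, 3.0, 72.4, 0.1, 0.2, 0.2, 0, 0.2, 0.2, 0.2, 0, 0)),
    ("Lung (deflated)", "soft", 1.05, (10.3, 10.5, 3.1, 74.9, 0, 0.2, 0.2, 0, 0.3, 0.3, 0.2, 0, 0)),
    ("Muscle", "soft", 1.05, (10.2, 14.3, 3.4, 71.0, 0, 0.2, 0.1, 0, 0.3, 0.1, 0.4, 0, 0)),
    ("Ovary", "soft", 1.05, (10.5, 9.3, 2.4, 76.8, 0, 0.2, 0.2, 0, 0.2, 0.2, 0.2, 0, 0)),
    ("Thyroid", "soft", 1.05, (10.4, 11.9, 2.4, 74.5, 0, 0.1, 0.2, 0, 0.1, 0.2, 0.1, 0, 0.1)),
    ("Blood", "soft", 1.06, (10.2, 11.0, 3.3, 74.5, 0, 0.1, 0.1, 0, 0.2, 0.3, 0.2, 0.1, 0)),
    ("Heart", "soft", 1.06, (10.3, 12.1, 3.2, 73.4, 0, 0.1, 0.1, 0, 0.2, 0.3, 0.2, 0.1, 0)),
    ("Liver", "soft", 1.06, (10.2, 13.9, 3.0, 71.6, 0, 0.3, 0.2, 0, 0.3, 0.2, 0.3, 0, 0)),
    ("Spleen", "soft", 1.06, (10.3, 11.3, 3.2, 74.1, 0, 0.3, 0.1, 0, 0.2, 0.2, 0.3, 0, 0)),
    ("Eye lens", "soft", 1.07, (9.6, 19.5, 5.7, 64.6, 0, 0.1, 0.1, 0, 0.3, 0.1, 0, 0, 0)),
    ("Skin", "soft", 1.09, (10.0, 20.4, 4.2, 64.5, 0, 0.1, 0.2, 0, 0.2, 0.3, 0.1, 0, 0)),
    ("Cartilage", "soft", 1.10, (9.6, 9.9, 2.2, 74.4, 0, 2.2, 0.5, 0, 0.9, 0.3, 0, 0, 0)),
    ("Skeleton-spongiosa", "bone", 1.18, (8.5, 40.4, 2.8, 36.7, 7.4, 3.4, 0.1, 0.1, 0.2, 0.2, 0.1, 0.1, 0)),
    ("Skeleton-sacrum", "bone", 1.29, (7.4, 30.2, 3.7, 43.8, 9.8, 4.5, 0, 0.1, 0.2, 0.1, 0.1, 0.1, 0)),
    ("Skeleton-femur", "bone", 1.33, (7.0, 34.5, 2.8, 36.8, 12.9, 5.5, 0.1, 0.1, 0.2, 0.1, 0, 0, 0)),
    ("Skeleton-vertebra (L3)", "bone", 1.33, (7.0, 28.7, 3.8, 43.7, 11.1, 5.1, 0, 0.1, 0.2, 0.1, 0.1, 0.1, 0)),
    ("Skeleton-ribs (2-6)", "bone", 1.41, (6.4, 26.3, 3.9, 43.6, 13.1, 6.0, 0.1, 0.1, 0.3, 0.1, 0.1, 0, 0)),
    ("Skeleton-vertebra (C4)", "bone", 1.42, (6.3, 26.1, 3.9, 43.5, 13.3, 6.1, 0.1, 0.1, 0.3, 0.1, 0.1, 0.1, 0)),
    ("Skeleton-humerus", "bone", 1.46, (6.0, 31.4, 3.1, 36.9, 15.2, 7.0, 0.1, 0.1, 0.2, 0, 0, 0, 0)),
    ("Skeleton-ribs (10)", "bone", 1.52, (5.6, 23.5, 4.0, 43.4, 15.6, 7.2, 0.1, 0.1, 0.3, 0.1, 0.1, 0, 0)),
    ("Skeleton-cranium", "bone", 1.61, (5.0, 21.2, 4.0, 43.5, 17.6, 8.1, 0.1, 0.2, 0.3, 0, 0, 0, 0)),
    ("Skeleton-mandible", "bone", 1.68, (4.6, 19.9, 4.1, 43.5, 18.7, 8.6, 0.1, 0.2, 0.3, 0, 0, 0, 0)),
    ("Skeleton-cortical bone", "bone", 1.92, (3.4, 15.5, 4.2, 43.5, 22.5, 10.3, 0.1, 0.2, 0.3, 0, 0, 0, 0)),
)

BUILTIN_TABLES = ("icrp23_reference",)


def _builtin_reference_set() -> TissueSet:
    tissues = [
        Tissue(name, cat, rho, dict(zip(ELEMENT_ORDER, w)))
        for name, cat, rho, w in _REFERENCE_ROWS
    ]
    return TissueSet(tissues, provenance="icrp23_reference (builtin)")


def water_reference() -> Tissue:
    """Water, the normalizing medium: rho = 1 g/cm^3, H2O mass fractions.

    Weights are derived from the atomic weights in the registry
    (2*A_H / (2*A_H + A_O) and A_O / (2*A_H + A_O), scaled to percent),
    so electron-density and stopping-power ratios normalize to water
    self-consistently.
    """
    a_h = ELEMENTS["H"].A_w
    a_o = ELEMENTS["O"].A_w
    m = 2.0 * a_h + a_o
    return Tissue("Water", "water", 1.0, {"H": 200.0 * a_h / m, "O": 100.0 * a_o / m})


def load_tissue_table(path_or_builtin: str | Path) -> TissueSet:
    """Load a tissue table from a builtin name or a CSV file.

    The CSV dialect has header ``name,category,density,H,C,N,O,Ca,P,Na,
    Mg,S,Cl,K,Fe,I``; missing element columns are treated as weight 0.
    Each row is validated (positive density, known elements, weight sum
    within 0.5 of 100) and weights are renormalized to sum to exactly 100.

    Parameters
    ----------
    path_or_builtin
        Either a builtin table name (``"icrp23_reference"``) or a path to
        a CSV file.

    Returns
    -------
    TissueSet
    """
    if isinstance(path_or_builtin, str) and path_or_builtin in BUILTIN_TABLES:
        return _builtin_reference_set()
    path = Path(path_or_builtin)
    if not path.exists():
        raise FileNotFoundError(
            f"{path_or_builtin!r} is neither a builtin table {BUILTIN_TABLES} nor an existing file"
        )
    with path.open(newline="", encoding="utf-8") as fh:
        return _parse_tissue_csv(fh, provenance=str(path))


def _parse_tissue_csv(fh: io.TextIOBase, provenance: str) -> TissueSet:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None or "density" not in reader.fieldnames:
        raise ValueError(f"{provenance}: missing header with a 'density' column")
    unknown_cols = set(reader.fieldnames) - {"name", "category", "density", "parent", "index"} - set(ELEMENTS)
    if unknown_cols:
        raise ValueError(f"{provenance}: unknown element column(s) {sorted(unknown_cols)}")
    tissues = []
    for i, row in enumerate(reader, start=2):
        name = row.get("name") or f"row{i}"
        try:
            rho = float(row["density"])
            weights = {
                sym: float(row[sym]) for sym in ELEMENTS if row.get(sym) not in (None, "")
            }
        except ValueError as exc:
            raise ValueError(f"{provenance} row {i} ({name}): non-numeric field: {exc}") from exc
        tissues.append(Tissue(name, row.get("category", "soft"), rho, weights))
    return TissueSet(tissues, provenance=provenance)


def write_tissue_table(tissues: Iterable[Tissue], path: str | Path) -> None:
    """Write tissues to the CSV dialect; floats use round-trip formatting."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "category", "density", *ELEMENT_ORDER])
        for t in tissues:
            writer.writerow(
                [t.name, t.category, format(t.rho, ".17g")]
                + [format(t.weights.get(s, 0.0), ".17g") for s in ELEMENT_ORDER]
            )


def export_element_registry(path: str | Path) -> None:
    """Dump the element registry to JSON for auditability."""
    payload = {
        sym: {
            "Z": e.Z,
            "atomic_weight_g_per_mol": e.A_w,
            "mean_excitation_energy_eV": e.I,
            "mass_attenuation_cm2_per_g": dict(e.mu_rho),
            "beam_energies_MeV": BEAM_ENERGIES_MEV,
        }
        for sym, e in ELEMENTS.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
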