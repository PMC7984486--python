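"""Gaussian composition perturbation: the synthetic-tissue generator.

Real patients' tissues deviate from the reference compositions.  To
emulate that, each reference tissue spawns ``n_per_tissue`` simulated
tissues: every nonzero elemental percentage weight is drawn
independently from a Gaussian centred on its nominal value with a
standard deviation equal to ``rel_sigma`` times the nominal value
(default 5%, a literature-informed scale of inter-subject composition
variability), after which the weight vector is renormalized to sum to
100%.  Elements absent from the parent stay absent (sigma of zero is
zero), and mass density is NOT resampled — the generator isolates the
effect of composition variation alone, so a simulated tissue's RED
changes only through its electrons per gram.

Randomness is reproducible at two levels: a run-level seed, and
per-parent substreams derived deterministically from (seed, parent
name), so any single tissue's draws can be regenerated in isolation.

At ``rel_sigma = 0.05`` a negative draw is a > 20-sigma event and never
occurs; for robustness at extreme settings any negative draw is clamped
to zero before renormalization and counted on the output record.
"""

from __future__ import annotations

import csv
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .tissue_db import ELEMENT_ORDER, Tissue, TissueSet

__all__ = [
    "SimulationConfig",
    "SimulatedTissue",
    "simulate_tissues",
    "simulate_all",
    "write_simulated_table",
]

#: Relative standard deviation of elemental weights used in the study
#: conditions (5% of nominal).
DEFAULT_REL_SIGMA = 0.05
#: Simulated tissues per reference tissue under the study conditions.
DEFAULT_N_PER_TISSUE = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the composition-perturbation generator."""

    n_per_tissue: int = DEFAULT_N_PER_TISSUE
    rel_sigma: float = DEFAULT_REL_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_tissue < 1:
            raise ValueError("n_per_tissue must be >= 1")
        if not 0.0 <= self.rel_sigma < 1.0:
            raise ValueError("rel_sigma must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedTissue:
    """One perturbed draw: parent name, sample index, perturbed tissue."""

    parent: str
    index: int
    tissue: Tissue
    n_clamped: int = 0  # negative draws clamped to zero (diagnostic)


def _parent_rng(seed: int, parent_name: str) -> np.random.Generator:
    """Deterministic substream for one parent tissue.

    Keyed by (seed, CRC-32 of the parent name) so a single tissue's
    draw set is reproducible without generating the whole run.
    """
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(parent_name.encode("utf-8"))))
    )


def simulate_tissues(parent: Tissue, config: SimulationConfig) -> list[SimulatedTissue]:
    """Draw ``config.n_per_tissue`` perturbed copies of ``parent``.

    Each nonzero weight ~ Normal(nominal, rel_sigma * nominal),
    independently per element; the vector is then renormalized to 100%.
    Density and category are copied from the parent.
    """
    rng = _parent_rng(config.seed, parent.name)
    symbols = parent.nonzero_elements()
    nominal = np.array([parent.weights[s] for s in symbols])
    if config.rel_sigma == 0.0:
        # degenerate distribution: every sample is the parent, bit-exactly
        return [
            SimulatedTissue(
                parent.name,
                i,
                Tissue(f"{parent.name}#{i}", parent.category, parent.rho, dict(parent.weights)),
            )
            for i in range(config.n_per_tissue)
        ]
    draws = rng.normal(nominal, config.rel_sigma * nominal, size=(config.n_per_tissue, len(symbols)))
    clamped_per_row = (draws < 0).sum(axis=1)
    draws = np.clip(draws, 0.0, None)
    draws *= 100.0 / draws.sum(axis=1, keepdims=True)
    out = []
    for i in range(config.n_per_tissue):
        weights = dict(zip(symbols, draws[i]))
        tissue = Tissue(f"{parent.name}#{i}", parent.category, parent.rho, weights)
        out.append(SimulatedTissue(parent.name, i, tissue, int(clamped_per_row[i])))
    return out


def simulate_all(tissues: TissueSet, config: SimulationConfig) -> list[SimulatedTissue]:
    """Concatenate ``simulate_tissues`` over the set, in table order."""
    out: list[SimulatedTissue] = []
    for parent in tissues:
        out.extend(simulate_tissues(parent, config))
    return out


def write_simulated_table(simulated: Iterable[SimulatedTissue], path: str | Path) -> None:
    """Export simulated tissues to the tissue CSV dialect + parent,index."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "category", "density", *ELEMENT_ORDER, "parent", "index"])
        for s in simulated:
            t = s.tissue
            writer.writerow(
                [t.name, t.category, format(t.rho, ".17g")]
                + [format(t.weights.get(sym, 0.0), ".17g") for sym in ELEMENT_ORDER]
                + [s.parent, s.index]
            )
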