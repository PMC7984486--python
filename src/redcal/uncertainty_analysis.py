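"""Systematic / statistical / total uncertainty of RED-based estimation.

For every tissue the target quantity (scaled kV CT number or proton
SPR) is known two ways: the ground truth computed from the exact
elemental composition, and the calibration-curve estimate obtained from
RED alone.  The percentage deviation ``100 * (estimate - truth) / truth``
measures the error a composition-blind clinical workflow makes.

Three summary statistics follow:

* **systematic** uncertainty — the standard deviation of the percentage
  deviations across the *reference* tissues (fixed, catalogued
  compositions);
* **statistical** uncertainty — the standard deviation of the residual
  deviations of the *simulated* tissues after subtracting each parent
  reference tissue's own deviation (removing the systematic part);
* **total** uncertainty — the root sum of squares of the two.

Each is reported per tissue category (fat / soft / bone) and pooled
over all tissues, together with the maximum absolute deviation.
Standard deviations use the n-1 (sample) convention by default and are
taken about the mean of the pooled set; a population-variance variant
is exposed for sensitivity checks.  Nothing is rounded until report
formatting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationCurve,
    TARGETS,
    build_calibration_curve,
    evaluate_curve,
)
from .physics_core import (
    DEFAULT_KV_FIT,
    KvFitParameters,
    ProtonBeam,
    kv_hu_scale,
    proton_spr,
    relative_electron_density,
)
from .tissue_db import CATEGORIES, Tissue, TissueSet, load_tissue_table
from .tissue_simulator import SimulatedTissue, SimulationConfig, simulate_all

__all__ = [
    "DeviationRecord",
    "UncertaintyReport",
    "ReportBundle",
    "percent_deviation",
    "reference_deviations",
    "simulated_deviations",
    "systematic_uncertainty",
    "statistical_uncertainty",
    "total_uncertainty",
    "build_report",
    "histogram_data",
]

#: Report row labels: the three categories plus the pooled row.
REPORT_ROWS = (*CATEGORIES, "all")


@dataclass(frozen=True)
class DeviationRecord:
    """Ground truth vs curve estimate for one tissue and one quantity."""

    tissue_name: str
    parent: str  # parent reference tissue (self for reference tissues)
    category: str
    quantity: str  # "HU_scale" or "SPR"
    truth: float
    estimate: float
    pct_dev: float

    def __post_init__(self) -> None:
        if self.truth <= 0:
            raise ValueError(f"{self.tissue_name}: non-positive ground truth")


def percent_deviation(truth: float, estimate: float) -> float:
    """``100 * (estimate - truth) / truth``; errors on zero truth."""
    if truth == 0:
        raise ZeroDivisionError("percentage deviation undefined for zero ground truth")
    return 100.0 * (estimate - truth) / truth


def _truth_value(
    tissue: Tissue,
    quantity: str,
    fit: KvFitParameters,
    beam: ProtonBeam,
    lnIw: float | None,
) -> float:
    if quantity == "HU_scale":
        return kv_hu_scale(tissue, fit)
    return proton_spr(tissue, beam, lnIw=lnIw)


def reference_deviations(
    tissues: TissueSet,
    curve: CalibrationCurve,
    fit: KvFitParameters = DEFAULT_KV_FIT,
    beam: ProtonBeam | None = None,
    lnIw: float | None = None,
) -> list[DeviationRecord]:
    """Deviation records for the reference tissues against ``curve``."""
    beam = beam or ProtonBeam.from_energy()
    records = []
    for t in tissues:
        truth = _truth_value(t, curve.target, fit, beam, lnIw)
        est = evaluate_curve(curve, relative_electron_density(t), t.category)
        records.append(
            DeviationRecord(t.name, t.name, t.category, curve.target, truth, est,
                            percent_deviation(truth, est))
        )
    return records


def simulated_deviations(
    simulated: Sequence[SimulatedTissue],
    curve: CalibrationCurve,
    fit: KvFitParameters = DEFAULT_KV_FIT,
    beam: ProtonBeam | None = None,
    lnIw: float | None = None,
) -> list[DeviationRecord]:
    """Deviation records for simulated tissues.

    Each simulated tissue is evaluated on its parent's category segment;
    the perturbation never reassigns category.
    """
    beam = beam or ProtonBeam.from_energy()
    records = []
    for s in simulated:
        t = s.tissue
        truth = _truth_value(t, curve.target, fit, beam, lnIw)
        est = evaluate_curve(curve, relative_electron_density(t), t.category)
        records.append(
            DeviationRecord(t.name, s.parent, t.category, curve.target, truth, est,
                            percent_deviation(truth, est))
        )
    return records


def _records_frame(records: Sequence[DeviationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue_name": [r.tissue_name for r in records],
            "parent": [r.parent for r in records],
            "category": [r.category for r in records],
            "quantity": [r.quantity for r in records],
            "truth": [r.truth for r in records],
            "estimate": [r.estimate for r in records],
            "pct_dev": [r.pct_dev for r in records],
        }
    )


def _sigma(values: np.ndarray, std_mode: str) -> float:
    ddof = 1 if std_mode == "sample" else 0
    if len(values) <= ddof:
        return 0.0
    return float(np.std(values, ddof=ddof))


def _per_category(values: np.ndarray, cats: np.ndarray, std_mode: str) -> dict[str, tuple[float, float]]:
    out = {}
    for row in REPORT_ROWS:
        mask = np.ones(len(values), bool) if row == "all" else cats == row
        if not mask.any():
            raise ValueError(f"no records in category {row!r}")
        v = values[mask]
        out[row] = (_sigma(v, std_mode), float(np.abs(v).max()))
    return out


def systematic_uncertainty(
    records: Sequence[DeviationRecord], std_mode: str = "sample"
) -> dict[str, tuple[float, float]]:
    """Per-category and pooled (sigma, max|dev|) over reference records."""
    values = np.array([r.pct_dev for r in records])
    cats = np.array([r.category for r in records])
    return _per_category(values, cats, std_mode)


def statistical_uncertainty(
    sim_records: Sequence[DeviationRecord],
    ref_records: Sequence[DeviationRecord],
    std_mode: str = "sample",
) -> dict[str, tuple[float, float]]:
    """Per-category and pooled (sigma, max|residual|) over simulated records.

    The residual of a simulated tissue is its percentage deviation minus
    its parent reference tissue's deviation, removing the systematic
    component so that only the perturbation-induced spread remains.
    """
    parent_dev = {r.tissue_name: r.pct_dev for r in ref_records}
    try:
        residuals = np.array([r.pct_dev - parent_dev[r.parent] for r in sim_records])
    except KeyError as exc:
        raise KeyError(f"simulated record has parent {exc} absent from reference records")
    cats = np.array([r.category for r in sim_records])
    return _per_category(residuals, cats, std_mode)


def total_uncertainty(systematic: float, statistical: float) -> float:
    """Root sum of squares of the two components (percent)."""
    if systematic < 0 or statistical < 0:
        raise ValueError("uncertainty components must be non-negative")
    return math.hypot(systematic, statistical)


@dataclass(frozen=True)
class UncertaintyReport:
    """Machine-readable uncertainty summary.

    Every field maps quantity ("HU_scale"/"SPR") -> row (category or
    "all") -> value in percent.
    """

    systematic_sigma: Mapping[str, Mapping[str, float]]
    statistical_sigma: Mapping[str, Mapping[str, float]]
    total_sigma: Mapping[str, Mapping[str, float]]
    max_abs_systematic: Mapping[str, Mapping[str, float]]
    max_abs_statistical: Mapping[str, Mapping[str, float]]

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Tabular layout: one row per category, columns (kind, quantity)."""
        cols = {}
        for kind, data in (
            ("systematic", self.systematic_sigma),
            ("statistical", self.statistical_sigma),
            ("total", self.total_sigma),
            ("max_abs_systematic", self.max_abs_systematic),
            ("max_abs_statistical", self.max_abs_statistical),
        ):
            for q in TARGETS:
                cols[(kind, q)] = [data[q][row] for row in REPORT_ROWS]
        frame = pd.DataFrame(cols, index=list(REPORT_ROWS))
        return frame.round(decimals) if decimals is not None else frame

    def to_csv(self, path: str | Path, decimals: int = 2) -> None:
        self.to_frame(decimals).to_csv(path)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "systematic_sigma_pct": {q: dict(v) for q, v in self.systematic_sigma.items()},
            "statistical_sigma_pct": {q: dict(v) for q, v in self.statistical_sigma.items()},
            "total_sigma_pct": {q: dict(v) for q, v in self.total_sigma.items()},
            "max_abs_systematic_pct": {q: dict(v) for q, v in self.max_abs_systematic.items()},
            "max_abs_statistical_pct": {q: dict(v) for q, v in self.max_abs_statistical.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


@dataclass
class ReportBundle:
    """Full pipeline output: the report plus the tables behind it."""

    report: UncertaintyReport
    curves: Mapping[str, CalibrationCurve]
    ref_deviations: pd.DataFrame  # per reference tissue, both quantities
    sim_residuals: pd.DataFrame  # per simulated tissue, with parent deviation removed


def build_report(
    fit: KvFitParameters = DEFAULT_KV_FIT,
    beam: ProtonBeam | None = None,
    config: SimulationConfig | None = None,
    tissues: TissueSet | None = None,
    lnIw: float | None = None,
    std_mode: str = "sample",
    with_intercept: bool = True,
) -> ReportBundle:
    """Run the whole chain: physics -> curves -> simulation -> statistics.

    Returns the uncertainty report plus per-tissue deviation tables (the
    data behind outlier attribution and residual histograms).
    """
    beam = beam or ProtonBeam.from_energy()
    config = config or SimulationConfig()
    tissues = tissues or load_tissue_table("icrp23_reference")
    simulated = simulate_all(tissues, config)

    sys_sigma: dict[str, dict[str, float]] = {}
    stat_sigma: dict[str, dict[str, float]] = {}
    tot_sigma: dict[str, dict[str, float]] = {}
    max_sys: dict[str, dict[str, float]] = {}
    max_stat: dict[str, dict[str, float]] = {}
    curves: dict[str, CalibrationCurve] = {}
    ref_frames = []
    sim_frames = []

    for quantity in TARGETS:
        curve = build_calibration_curve(
            tissues, quantity, fit=fit, beam=beam, lnIw=lnIw, with_intercept=with_intercept
        )
        curves[quantity] = curve
        ref_records = reference_deviations(tissues, curve, fit, beam, lnIw)
        sim_records = simulated_deviations(simulated, curve, fit, beam, lnIw)

        sys_stats = systematic_uncertainty(ref_records, std_mode)
        stat_stats = statistical_uncertainty(sim_records, ref_records, std_mode)
        sys_sigma[quantity] = {k: v[0] for k, v in sys_stats.items()}
        max_sys[quantity] = {k: v[1] for k, v in sys_stats.items()}
        stat_sigma[quantity] = {k: v[0] for k, v in stat_stats.items()}
        max_stat[quantity] = {k: v[1] for k, v in stat_stats.items()}
        tot_sigma[quantity] = {
            k: total_uncertainty(sys_sigma[quantity][k], stat_sigma[quantity][k])
            for k in REPORT_ROWS
        }

        ref_frames.append(_records_frame(ref_records))
        sim_frame = _records_frame(sim_records)
        parent_dev = {r.tissue_name: r.pct_dev for r in ref_records}
        sim_frame["residual"] = sim_frame["pct_dev"] - sim_frame["parent"].map(parent_dev)
        sim_frames.append(sim_frame)

    report = UncertaintyReport(sys_sigma, stat_sigma, tot_sigma, max_sys, max_stat)
    return ReportBundle(
        report=report,
        curves=curves,
        ref_deviations=pd.concat(ref_frames, ignore_index=True),
        sim_residuals=pd.concat(sim_frames, ignore_index=True),
    )


def histogram_data(
    bundle: ReportBundle, quantity: str, category: str, bins: int = 40
) -> pd.DataFrame:
    """Histogram of simulated residual deviations (bin edges and counts)."""
    frame = bundle.sim_residuals
    mask = frame["quantity"] == quantity
    if category != "all":
        mask &= frame["category"] == category
    counts, edges = np.histogram(frame.loc[mask, "residual"], bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
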