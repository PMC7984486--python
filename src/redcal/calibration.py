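"""Scanner fit and RED-based calibration curves.

Two distinct least-squares problems live here:

1. Determining the scanner constants (A, B, C) of the kV CT-number
   model from measured CT numbers of tissue-equivalent phantom inserts
   (``fit_kv_parameters``).  This is a three-regressor linear model with
   no intercept: ``HU_scale ~ RED*Ztilde^3.62 + RED*Zhat^1.86 + RED``.

2. Building the clinical calibration curves mapping RED to a target
   quantity — scaled kV CT number or proton SPR — by unweighted linear
   least squares fitted separately within each tissue category
   (``build_calibration_curve``).  Segmenting by category keeps each
   line over compositionally similar tissues; segments are not forced
   to be continuous across category boundaries.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .physics_core import (
    COHERENT_EXPONENT,
    PHOTOELECTRIC_EXPONENT,
    DEFAULT_KV_FIT,
    KvFitParameters,
    ProtonBeam,
    effective_atomic_numbers,
    kv_hu_scale,
    proton_spr,
    relative_electron_density,
)
from .tissue_db import CATEGORIES, Tissue, TissueSet

__all__ = [
    "SubstituteMeasurement",
    "LinearSegment",
    "CalibrationCurve",
    "fit_kv_parameters",
    "build_calibration_curve",
    "evaluate_curve",
    "curve_to_json",
    "curve_from_json",
    "load_substitute_measurements",
]

TARGETS = ("HU_scale", "SPR")


@dataclass(frozen=True)
class SubstituteMeasurement:
    """A phantom insert: vendor composition plus its measured CT number."""

    name: str
    tissue: Tissue
    hu_scale_measured: float  # HU + 1000

    def __post_init__(self) -> None:
        if self.hu_scale_measured <= 0:
            raise ValueError(f"{self.name}: measured HU_scale must be positive")


@dataclass(frozen=True)
class LinearSegment:
    """One category's line: target = slope * RED + intercept."""

    category: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a segment needs at least 2 points")
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-category linear maps from RED to ``HU_scale`` or ``SPR``."""

    target: str
    segments: Mapping[str, LinearSegment]

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}")
        missing = set(CATEGORIES) - set(self.segments)
        if missing:
            raise ValueError(f"curve missing categories: {sorted(missing)}")


class FitError(RuntimeError):
    """Raised when a least-squares problem is underdetermined."""


def fit_kv_parameters(
    measurements: Sequence[SubstituteMeasurement],
) -> tuple[KvFitParameters, np.ndarray]:
    """Determine (A, B, C) from measured substitute CT numbers.

    Ordinary least squares of ``hu_scale_measured`` on the regressors
    ``RED*Ztilde^3.62``, ``RED*Zhat^1.86`` and ``RED`` — the model has
    no intercept, mirroring its three physical interaction terms.

    Returns
    -------
    (KvFitParameters, residuals)
        The fitted constants and the per-measurement residuals
        (measured minus fitted HU_scale).
    """
    if len(measurements) < 3:
        raise FitError(f"need >= 3 measurements to fit 3 parameters, got {len(measurements)}")
    design = np.empty((len(measurements), 3))
    y = np.empty(len(measurements))
    for i, m in enumerate(measurements):
        red = relative_electron_density(m.tissue)
        z_tilde, z_hat = effective_atomic_numbers(m.tissue.weights)
        design[i] = (
            red * z_tilde**PHOTOELECTRIC_EXPONENT,
            red * z_hat**COHERENT_EXPONENT,
            red,
        )
        y[i] = m.hu_scale_measured
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise FitError("rank-deficient design: fewer than 3 independent compositions")
    return KvFitParameters(*coef), y - design @ coef


def _fit_segment(
    red: np.ndarray, target: np.ndarray, category: str, with_intercept: bool = True
) -> LinearSegment:
    if len(red) < 2:
        raise FitError(f"category {category!r} has {len(red)} tissue(s); need >= 2 to fit a line")
    if with_intercept:
        res = stats.linregress(red, target)
        slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    else:
        slope = float(np.dot(red, target) / np.dot(red, red))
        intercept = 0.0
        ss_res = float(np.sum((target - slope * red) ** 2))
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearSegment(category, float(slope), float(intercept), float(min(max(r2, 0.0), 1.0)), len(red))


def build_calibration_curve(
    tissues: TissueSet,
    target: str,
    fit: KvFitParameters = DEFAULT_KV_FIT,
    beam: ProtonBeam | None = None,
    lnIw: float | None = None,
    with_intercept: bool = True,
) -> CalibrationCurve:
    """Fit the per-category lines RED -> target over a reference set.

    ``target`` is ``"HU_scale"`` (computed from the exact composition via
    the parametric kV model with constants ``fit``) or ``"SPR"`` (Bethe
    ratio at the ``beam`` energy).  ``with_intercept=False`` forces lines
    through the origin, exposed for sensitivity checks only.
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}, got {target!r}")
    beam = beam or ProtonBeam.from_energy()
    segments = {}
    for cat in CATEGORIES:
        members = tissues.by_category(cat)
        red = np.array([relative_electron_density(t) for t in members])
        if target == "HU_scale":
            y = np.array([kv_hu_scale(t, fit) for t in members])
        else:
            y = np.array([proton_spr(t, beam, lnIw=lnIw) for t in members])
        segments[cat] = _fit_segment(red, y, cat, with_intercept)
    return CalibrationCurve(target=target, segments=segments)


def evaluate_curve(curve: CalibrationCurve, red: float, category: str) -> float:
    """Estimate the target at ``red`` using the ``category`` segment."""
    try:
        seg = curve.segments[category]
    except KeyError:
        raise KeyError(f"category {category!r} not in curve (has {sorted(curve.segments)})")
    return seg.slope * red + seg.intercept


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def curve_to_json(curve: CalibrationCurve, path: str | Path | None = None) -> str:
    """Serialize a curve to JSON; optionally write to ``path``."""
    payload = {
        "target": curve.target,
        "segments": [
            {
                "category": s.category,
                "slope": s.slope,
                "intercept": s.intercept,
                "r_squared": s.r_squared,
                "n_points": s.n_points,
            }
            for s in curve.segments.values()
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def curve_from_json(source: str | Path) -> CalibrationCurve:
    """Load a curve from a JSON string or file path."""
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    payload = json.loads(text)
    segments = {
        s["category"]: LinearSegment(
            s["category"], s["slope"], s["intercept"], s["r_squared"], s["n_points"]
        )
        for s in payload["segments"]
    }
    return CalibrationCurve(target=payload["target"], segments=segments)


def load_substitute_measurements(path: str | Path) -> list[SubstituteMeasurement]:
    """Read phantom-substitute measurements from CSV.

    Dialect: ``name,density,H,...,I,hu_scale_measured`` (element columns
    optional, in any order).  Substitutes carry no tissue category; they
    are tagged ``soft`` internally, which never enters the fit.
    """
    measurements = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            name = row.get("name") or f"row{i}"
            try:
                rho = float(row["density"])
                hu = float(row["hu_scale_measured"])
                weights = {
                    k: float(v)
                    for k, v in row.items()
                    if k not in ("name", "density", "hu_scale_measured", "category") and v
                }
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path} row {i} ({name}): bad field: {exc}") from exc
            tissue = Tissue(name, row.get("category", "soft"), rho, weights)
            measurements.append(SubstituteMeasurement(name, tissue, hu))
    return measurements
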