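"""Bioassay arithmetic: MTT viability normalisation, four-parameter
logistic (4PL) dose-response fitting with IC50 extraction, and flow
cytometry quadrant summaries.

Viability of a treated well is normalised against blank (medium only)
and untreated-control optical densities:

    viability % = (OD_treated - OD_blank) / (OD_control - OD_blank) * 100

The dose-response model is the 4PL on log dose,

    v(d) = lower + (upper - lower) / (1 + (d / ic50)^hill),

whose inflection dose is the *relative* IC50 (midpoint between the
fitted asymptotes).  An absolute-IC50 variant (the dose where the curve
crosses 50 % viability) is available by flag.  Noisy viabilities may
exceed 100 % or go below 0 %; no clamping is applied unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ViabilityMeasurement",
    "DoseResponseFit",
    "QuadrantCounts",
    "viability_pct",
    "four_param_logistic",
    "fit_ic50",
    "apoptosis_rate",
    "quadrant_percentages",
]


class ValidationError(ValueError):
    pass


class FitError(RuntimeError):
    """Dose-response fit failure; carries residual diagnostics."""

    def __init__(self, message: str, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class ViabilityMeasurement:
    """One treated/blank/control OD triple from a plate reader."""

    od_treated: float
    od_blank: float
    od_control: float

    def __post_init__(self) -> None:
        for v in (self.od_treated, self.od_blank, self.od_control):
            if not math.isfinite(v) or v < 0:
                raise ValidationError("optical densities must be finite and >= 0")


def viability_pct(m: ViabilityMeasurement) -> float:
    """Blank-corrected viability relative to the untreated control, in %."""
    denom = m.od_control - m.od_blank
    if denom == 0:
        raise ZeroDivisionError("control OD equals blank OD; viability undefined")
    return (m.od_treated - m.od_blank) / denom * 100.0


def four_param_logistic(dose, lower, upper, hill, ic50):
    """Decreasing 4PL: upper asymptote at low dose, lower at high dose."""
    dose = np.asarray(dose, dtype=float)
    return lower + (upper - lower) / (1.0 + (dose / ic50) ** hill)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters for one dose-response curve."""

    doses: np.ndarray
    viability_pct: np.ndarray
    lower: float
    upper: float
    hill: float
    ic50: float
    residual_se: float
    ic50_absolute: Optional[float] = None
    in_range: bool = True


def _absolute_ic50(lower: float, upper: float, hill: float, ic50: float) -> Optional[float]:
    # dose where the fitted curve crosses 50 % viability
    if not (min(lower, upper) < 50.0 < max(lower, upper)):
        return None
    ratio = (upper - lower) / (50.0 - lower) - 1.0
    if ratio <= 0:
        return None
    return ic50 * ratio ** (1.0 / hill)


def fit_ic50(
    doses: Sequence[float],
    viability: Sequence[float],
    seed: int = 0,
    max_nfev: int = 20_000,
) -> DoseResponseFit:
    """Least-squares 4PL fit; the IC50 is the fitted inflection dose.

    Requires >= 4 strictly increasing positive dose levels (replicates
    must be averaged per dose first).  The fit is deterministic for a
    given data set: the initial guess is derived from the data and the
    ``seed`` only labels the run.  A fitted IC50 outside
    [min dose / 10, max dose * 10] is flagged out-of-range rather than
    silently reported, since it means the plate did not bracket the
    transition (e.g. viability not decreasing over the tested range).
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.ndim != 1 or d.shape != v.shape:
        raise ValidationError("doses and viability must be 1-D and the same length")
    if len(d) < 4:
        raise ValidationError("a four-parameter fit needs at least 4 dose levels")
    if np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ValidationError("doses must be strictly positive and strictly increasing")

    lower0 = float(min(v.min(), 0.0))
    upper0 = float(max(v.max(), 100.0))
    # initial IC50: dose nearest the half-way response
    half = (lower0 + upper0) / 2.0
    ic50_0 = float(d[np.argmin(np.abs(v - half))])
    p0 = (lower0, upper0, 1.5, ic50_0)
    bounds = ([-50.0, 10.0, 0.05, d.min() / 100.0], [50.0, 250.0, 20.0, d.max() * 100.0])
    try:
        popt, _ = curve_fit(
            four_param_logistic, d, v, p0=p0, bounds=bounds, max_nfev=max_nfev
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}", residuals=v - four_param_logistic(d, *p0))
    lower, upper, hill, ic50 = (float(x) for x in popt)
    resid = v - four_param_logistic(d, *popt)
    dof = max(len(d) - 4, 1)
    fit = DoseResponseFit(
        doses=d,
        viability_pct=v,
        lower=lower,
        upper=upper,
        hill=hill,
        ic50=ic50,
        residual_se=float(np.sqrt(np.sum(resid**2) / dof)),
        ic50_absolute=_absolute_ic50(lower, upper, hill, ic50),
        in_range=bool(d.min() / 10.0 <= ic50 <= d.max() * 10.0),
    )
    return fit


@dataclass(frozen=True)
class QuadrantCounts:
    """Annexin-V / PI flow cytometry quadrant event counts."""

    viable: int
    early_apoptotic: int
    late_apoptotic: int
    necrotic: int

    def __post_init__(self) -> None:
        for c in (self.viable, self.early_apoptotic, self.late_apoptotic, self.necrotic):
            if c < 0:
                raise ValidationError("quadrant counts must be >= 0")

    @property
    def total(self) -> int:
        return self.viable + self.early_apoptotic + self.late_apoptotic + self.necrotic


def apoptosis_rate(q: QuadrantCounts) -> float:
    """Total apoptosis % = (early + late apoptotic) / all events * 100."""
    if q.total == 0:
        raise ValidationError("no events; apoptosis rate undefined")
    return (q.early_apoptotic + q.late_apoptotic) / q.total * 100.0


def quadrant_percentages(q: QuadrantCounts) -> dict:
    """Viable / apoptotic / necrotic percentages (sum to 100)."""
    if q.total == 0:
        raise ValidationError("no events; percentages undefined")
    return {
        "viable": q.viable / q.total * 100.0,
        "apoptotic": (q.early_apoptotic + q.late_apoptotic) / q.total * 100.0,
        "necrotic": q.necrotic / q.total * 100.0,
    }


def read_plate(path) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Read a plate TSV: rows ``dose<TAB>od1<TAB>od2...`` plus special
    rows with dose labels ``blank`` and ``control``.

    Returns (doses, mean treated ODs per dose, blank OD, control OD),
    replicate wells averaged.
    """
    doses, ods = [], []
    blank = control = None
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0].strip():
                continue
            vals = [float(x) for x in parts[1:] if x.strip()]
            label = parts[0].strip().lower()
            if label == "blank":
                blank = float(np.mean(vals))
            elif label == "control":
                control = float(np.mean(vals))
            else:
                doses.append(float(parts[0]))
                ods.append(float(np.mean(vals)))
    if blank is None or control is None:
        raise ValidationError("plate file must contain 'blank' and 'control' rows")
    return np.asarray(doses), np.asarray(ods), blank, control


def plate_viability(doses: np.ndarray, ods: np.ndarray, blank: float, control: float) -> np.ndarray:
    """Per-dose viability % from mean ODs."""
    return np.array(
        [viability_pct(ViabilityMeasurement(od, blank, control)) for od in ods]
    )
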