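"""MRM-based targeted quantification and method validation.

Calibration is ordinary least squares of peak area on concentration
(ng/mL), exactly as standard curves are built from serial dilutions of
mixed working solutions.  Sensitivity follows the S/N convention:
LOD = 3 sigma / slope and LOQ = 10 sigma / slope, with sigma the blank
noise standard deviation in area units.  Sample content in ug/g applies the
preparation arithmetic (weighed mass, extract volume, dilution factor), and
validation statistics (intra/inter-day precision, repeatability, spike
recovery) are relative standard deviations with the n-1 denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "SampleRecord",
    "QuantResult",
    "rsd",
    "fit_calibration",
    "estimate_lod_loq",
    "concentration_from_area",
    "content_from_concentration",
    "quantify_sample",
    "select_dilution",
    "precision_report",
    "recovery_report",
]


@dataclass
class CalibrationCurve:
    """A fitted linear calibration with its working range and sensitivity."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    points: Tuple[Tuple[float, float], ...]
    range_low: float
    range_high: float
    lod: Optional[float] = None
    loq: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")
        if self.lod is not None and self.loq is not None and self.loq < self.lod:
            raise ValueError("LOQ below LOD")


@dataclass
class SampleRecord:
    """One injected preparation: weighed mass, volume, dilution, areas."""

    sample_id: str
    role: str  # unknown | qc_low | qc_mid | qc_high | repeatability | recovery_base | recovery_spiked
    mass_mg: float
    volume_ml: float
    dilution: float
    areas: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mass_mg <= 0:
            raise ValueError("weighed mass must be positive")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass
class QuantResult:
    analyte: str
    concentration_ng_ml: float
    content_ug_g: float
    dilution: float
    flags: List[str] = field(default_factory=list)


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent, sd with n-1 denominator."""
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def fit_calibration(points: Sequence[Tuple[float, float]], analyte: str = "",
                    min_points: int = 5, weighting: str = "none") -> CalibrationCurve:
    """Least-squares calibration of area (y) on concentration (x).

    ``weighting`` is "none" (simple regression, the default), "1/x" or
    "1/x2".  Weighted fits are the usual remedy when the linear range spans
    orders of magnitude and the area noise is multiplicative: unweighted OLS
    lets the top calibrators' absolute scatter dominate the intercept, which
    ruins back-calculation near the LOQ.  Requires at least ``min_points``
    distinct concentrations.  A response with zero variance yields slope 0
    and R^2 = 0 (no explainable variance).
    """
    pts = [(float(x), float(y)) for x, y in points]
    concs = sorted({x for x, _ in pts})
    if len(concs) < min_points:
        raise ValueError(f"need >= {min_points} distinct concentrations, got {len(concs)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.var(x) == 0:
        raise ValueError("zero concentration variance")
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1.0 / x
    elif weighting == "1/x2":
        w = 1.0 / x ** 2
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")
    if np.any(~np.isfinite(w)):
        raise ValueError("weighted fit requires strictly positive concentrations")
    if np.var(y) == 0:
        slope, intercept, r2 = 0.0, float(y.mean()), 0.0
    else:
        sw = w.sum()
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        sxy = (w * (x - xbar) * (y - ybar)).sum()
        slope = float(sxy / sxx)
        intercept = float(ybar - slope * xbar)
        sse = (w * (y - intercept - slope * x) ** 2).sum()
        sst = (w * (y - ybar) ** 2).sum()
        r2 = float(max(0.0, min(1.0, 1.0 - sse / sst)))
    return CalibrationCurve(
        analyte=analyte, slope=slope, intercept=intercept, r_squared=r2,
        points=tuple(pts), range_low=min(concs), range_high=max(concs))


def estimate_lod_loq(noise_sd: float, slope: float) -> Tuple[float, float]:
    """LOD at S/N 3:1 and LOQ at S/N 10:1 from blank noise and slope."""
    if noise_sd <= 0 or slope <= 0:
        raise ValueError("noise_sd and slope must be positive")
    return 3.0 * noise_sd / slope, 10.0 * noise_sd / slope


def concentration_from_area(area: float, curve: CalibrationCurve) -> Tuple[float, List[str]]:
    """Back-calculate concentration; areas below the intercept floor at 0."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (area - curve.intercept) / curve.slope
    flags: List[str] = []
    if conc <= 0:
        conc = 0.0
        flags.append("below_loq")
    elif curve.loq is not None and conc < curve.loq:
        flags.append("below_loq")
    if conc > curve.range_high:
        flags.append("above_range")
    elif 0 < conc < curve.range_low:
        flags.append("below_range")
    return conc, flags


def content_from_concentration(conc_ng_ml: float, mass_mg: float,
                               volume_ml: float, dilution: float = 1.0) -> float:
    """ug/g content from extract concentration and preparation arithmetic.

    conc (ng/mL) x volume (mL) x dilution / mass (mg) = ng/mg = ug/g.
    """
    if mass_mg <= 0:
        raise ValueError("mass must be positive")
    return conc_ng_ml * volume_ml * dilution / mass_mg


def quantify_sample(record: SampleRecord,
                    curves: Mapping[str, CalibrationCurve]) -> List[QuantResult]:
    """Quantify every analyte of a single injected preparation."""
    results = []
    for analyte, area in record.areas.items():
        curve = curves.get(analyte)
        if curve is None:
            raise KeyError(f"no calibration curve for {analyte}")
        conc, flags = concentration_from_area(area, curve)
        content = content_from_concentration(conc, record.mass_mg, record.volume_ml,
                                             record.dilution)
        results.append(QuantResult(analyte, conc, content, record.dilution, flags))
    return results


def select_dilution(records: Sequence[SampleRecord],
                    curves: Mapping[str, CalibrationCurve]) -> Dict[str, QuantResult]:
    """Pick, per analyte, the dilution whose back-calculated concentration is
    inside the linear range; the least-diluted qualifying preparation wins.

    If no dilution is in range, the most-diluted result is returned with its
    range flag intact.
    """
    if not records:
        raise ValueError("no sample records")
    per_dilution = sorted(records, key=lambda r: r.dilution)
    chosen: Dict[str, QuantResult] = {}
    for rec in per_dilution:
        for res in quantify_sample(rec, curves):
            in_range = not any(f in ("above_range", "below_range", "below_loq")
                               for f in res.flags)
            if res.analyte not in chosen:
                chosen[res.analyte] = res
            else:
                prev = chosen[res.analyte]
                prev_in = not any(f in ("above_range", "below_range", "below_loq")
                                  for f in prev.flags)
                if in_range and not prev_in:
                    chosen[res.analyte] = res
                elif not prev_in and not in_range and "above_range" in prev.flags:
                    # keep escalating dilution while still above range
                    chosen[res.analyte] = res
    return chosen


def precision_report(qc: pd.DataFrame, intraday_day: Optional[int] = None) -> pd.DataFrame:
    """Intra- and inter-day precision RSDs per analyte and QC level.

    ``qc`` columns: analyte, level, day, area.  Intra-day RSD uses the
    replicates of one day (the first by default); inter-day pools all days.
    """
    required = {"analyte", "level", "day", "area"}
    if not required.issubset(qc.columns):
        raise ValueError(f"QC table needs columns {sorted(required)}")
    rows = []
    for (analyte, level), grp in qc.groupby(["analyte", "level"], sort=False):
        day = intraday_day if intraday_day is not None else grp["day"].min()
        within = grp.loc[grp["day"] == day, "area"]
        if len(within) < 3:
            raise ValueError(f"need >= 3 replicates per level ({analyte}/{level})")
        rows.append({
            "analyte": analyte,
            "level": level,
            "intra_day_rsd_pct": rsd(within),
            "inter_day_rsd_pct": rsd(grp["area"]),
            "n_intra": int(len(within)),
            "n_inter": int(len(grp)),
        })
    return pd.DataFrame(rows)


def recovery_report(base_content_ug_g: float,
                    spiked_found_ug: Sequence[float],
                    halved_mass_mg: Sequence[float],
                    added_ug: Sequence[float]) -> Tuple[float, float, List[float]]:
    """Spike recovery: (found - endogenous in the halved mass) / added x 100.

    The endogenous contribution scales with the actually weighed halved
    mass.  Returns (mean %, RSD %, per-replicate recoveries).
    """
    found = np.asarray(spiked_found_ug, dtype=float)
    masses = np.asarray(halved_mass_mg, dtype=float)
    added = np.asarray(added_ug, dtype=float)
    if not (len(found) == len(masses) == len(added)):
        raise ValueError("mismatched replicate arrays")
    if len(found) < 3:
        raise ValueError("need >= 3 spiked replicates")
    if np.any(added <= 0):
        raise ValueError("added amount must be positive")
    endogenous = base_content_ug_g * masses / 1000.0  # ug/g x g
    recoveries = (found - endogenous) / added * 100.0
    return float(recoveries.mean()), rsd(recoveries), recoveries.tolist()
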