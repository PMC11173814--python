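"""Non-target feature extraction and acceptance filtering.

A centroided LC-MS run is reduced to chromatographic features by linking
centroids across consecutive scans into m/z traces (tolerance 0.02 Da),
splitting each trace at its local maxima, and measuring per-peak apex
height, area, signal-to-noise and the A+1 isotope ratio.  Screened features
then pass or fail the acceptance gates: |ppm| <= 5, retention-time error
< 2 % against a reference when one exists, isotope-ratio error < 10 %, and
candidate score >= 70.

S/N is defined against a robust trace-local baseline: 1.4826 x the median
absolute deviation of the extracted-ion chromatogram outside detected peak
regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .formula_finder import FormulaCandidate

__all__ = [
    "Scan",
    "CentroidRun",
    "Feature",
    "ScreenConfig",
    "ScreenVerdict",
    "extract_features",
    "screen_feature",
]

#: mass difference between consecutive aggregated isotope peaks (~13C-12C)
ISOTOPE_SPACING = 1.003355


@dataclass
class Scan:
    """One centroided MS1 scan: retention time (min) and peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class CentroidRun:
    """An ordered centroided run of constant polarity, plus linked MS/MS."""

    polarity: str  # "+" or "-"
    scans: List[Scan]
    ms2: list = field(default_factory=list)  # FragmentSpectrum objects

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must increase strictly")


@dataclass
class Feature:
    """A screened LC-MS peak."""

    mz: float
    rt_apex: float
    height: float
    area: float
    snr: float
    isotope_ratio_a1: float
    n_scans: int
    is_isotope: bool = False


@dataclass
class ScreenConfig:
    """Extraction and acceptance thresholds (defaults follow the method)."""

    mz_tol: float = 0.02            # Da, trace linking / matching width
    rt_tol: float = 0.4             # min, library/standard RT window
    min_intensity: float = 50.0     # counts, absolute intensity gate
    min_snr: float = 3.0            # S/N gate (feature kept if either passes)
    ppm_tol: float = 5.0            # ppm, accurate-mass gate
    rt_rel_tol: float = 0.02        # fractional RT error vs expected RT
    isotope_ratio_tol: float = 0.10  # fractional isotope-ratio error gate
    score_min: float = 70.0         # formula score gate
    trace_min_intensity: float = 10.0  # counts, minimum to extend a trace
    rel_floor: float = 0.05         # peak boundary at this fraction of apex
    max_gap: int = 2                # scans a trace may skip before closing

    def __post_init__(self) -> None:
        for name in ("mz_tol", "rt_tol", "min_intensity", "min_snr", "ppm_tol",
                     "rt_rel_tol", "isotope_ratio_tol", "score_min",
                     "trace_min_intensity", "rel_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ScreenVerdict:
    """Pass/fail plus the outcome of each individual filter."""

    passed: bool
    checks: Dict[str, bool]
    reason: Optional[str]
    best: Optional[FormulaCandidate]


class _Trace:
    __slots__ = ("mz_weighted", "weight", "points", "last_scan")

    def __init__(self, scan_idx: int, mz: float, intensity: float):
        self.mz_weighted = mz * intensity
        self.weight = intensity
        self.points: List[Tuple[int, float, float]] = [(scan_idx, mz, intensity)]
        self.last_scan = scan_idx

    @property
    def mz(self) -> float:
        return self.mz_weighted / self.weight if self.weight > 0 else 0.0

    def add(self, scan_idx: int, mz: float, intensity: float) -> None:
        self.mz_weighted += mz * intensity
        self.weight += intensity
        self.points.append((scan_idx, mz, intensity))
        self.last_scan = scan_idx


def _build_traces(run: CentroidRun, cfg: ScreenConfig) -> List[_Trace]:
    active: List[_Trace] = []
    finished: List[_Trace] = []
    for i, scan in enumerate(run.scans):
        still_active: List[_Trace] = []
        for tr in active:
            if i - tr.last_scan > cfg.max_gap:
                finished.append(tr)
            else:
                still_active.append(tr)
        active = still_active
        if scan.mz.size:
            mask = scan.intensity >= cfg.trace_min_intensity
            mzs = scan.mz[mask]
            ints = scan.intensity[mask]
            # strongest centroids claim traces first
            taken = set()
            active_mz = np.array([tr.mz for tr in active])
            for j in np.argsort(-ints):
                mz_j, int_j = mzs[j], ints[j]
                tr_idx = None
                if active_mz.size:
                    k = int(np.argmin(np.abs(active_mz - mz_j)))
                    if abs(active_mz[k] - mz_j) <= cfg.mz_tol and k not in taken:
                        tr_idx = k
                if tr_idx is not None and active[tr_idx].last_scan < i:
                    active[tr_idx].add(i, mz_j, int_j)
                    taken.add(tr_idx)
                else:
                    active.append(_Trace(i, mz_j, int_j))
                    active_mz = np.append(active_mz, mz_j)
    finished.extend(active)
    return [tr for tr in finished if len(tr.points) >= 3]


def _cluster_traces(traces: List[_Trace], cfg: ScreenConfig) -> List[_Trace]:
    """Merge traces of the same m/z channel.

    Baseline flicker around the trace-extension threshold fragments a
    channel into several short traces; merging them restores one trace per
    channel so peak detection sees the whole chromatogram exactly once.
    """
    clusters: List[_Trace] = []
    for tr in sorted(traces, key=lambda t: -t.weight):
        target = None
        for cl in clusters:
            if abs(cl.mz - tr.mz) <= cfg.mz_tol * 0.5:
                target = cl
                break
        if target is None:
            merged = _Trace(tr.points[0][0], tr.points[0][1], tr.points[0][2])
            merged.mz_weighted = tr.mz_weighted
            merged.weight = tr.weight
            merged.points = list(tr.points)
            merged.last_scan = tr.last_scan
            clusters.append(merged)
        else:
            target.mz_weighted += tr.mz_weighted
            target.weight += tr.weight
            target.points.extend(tr.points)
            target.last_scan = max(target.last_scan, tr.last_scan)
    for cl in clusters:
        cl.points.sort()
    return clusters


def _trace_xic(trace: _Trace, run: CentroidRun, cfg: ScreenConfig) -> np.ndarray:
    """Full-run extracted-ion chromatogram at the trace's mean m/z."""
    center = trace.mz
    xic = np.zeros(len(run.scans))
    for i, scan in enumerate(run.scans):
        if not scan.mz.size:
            continue
        lo = np.searchsorted(scan.mz, center - cfg.mz_tol)
        hi = np.searchsorted(scan.mz, center + cfg.mz_tol)
        if hi > lo:
            xic[i] = float(scan.intensity[lo:hi].sum())
    return xic


def _robust_sigma(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def extract_features(run: CentroidRun, cfg: Optional[ScreenConfig] = None) -> List[Feature]:
    """Extract chromatographic features from a centroided run.

    Traces need >= 3 scans; each local maximum of a trace's XIC becomes a
    candidate feature, retained if apex height >= ``min_intensity`` OR
    S/N > ``min_snr``.  Features sitting one or two isotope spacings above a
    stronger co-eluting feature are flagged ``is_isotope``.
    """
    cfg = cfg or ScreenConfig()
    if len(run.scans) < 3:
        raise ValueError("run must contain at least 3 scans")
    rts = np.array([s.rt for s in run.scans])
    traces = _cluster_traces(_build_traces(run, cfg), cfg)

    features: List[Feature] = []
    feature_aux: List[Tuple[Feature, np.ndarray, int]] = []
    channel_xics: List[Tuple[float, np.ndarray]] = []
    for trace in traces:
        xic = _trace_xic(trace, run, cfg)
        channel_xics.append((trace.mz, xic))
        # light smoothing for peak detection suppresses single-scan noise spikes
        smooth = np.convolve(xic, np.ones(3) / 3.0, mode="same") if xic.size >= 3 else xic
        prelim = _robust_sigma(xic - np.median(xic))
        prominence = max(cfg.trace_min_intensity, 5.0 * prelim)
        peak_idx, props = find_peaks(smooth, prominence=prominence)
        if peak_idx.size == 0:
            continue
        spans: List[Tuple[int, int, int]] = []
        for p, lb, rb in zip(peak_idx, props["left_bases"], props["right_bases"]):
            floor = cfg.rel_floor * smooth[p]
            left = p
            while left > lb and smooth[left - 1] >= floor:
                left -= 1
            right = p
            while right < rb and smooth[right + 1] >= floor:
                right += 1
            spans.append((left, p, right))
        # robust noise from off-peak region shared by all peaks of this trace
        off_mask = np.ones_like(xic, dtype=bool)
        for left, _, right in spans:
            off_mask[max(0, left - 2):right + 3] = False
        off = xic[off_mask]
        sigma = _robust_sigma(off - np.median(off)) if off.size >= 5 else 0.0
        for left, p, right in spans:
            n_scans = right - left + 1
            if n_scans < 3:
                continue
            height = float(smooth[p])
            snr = height / sigma if sigma > 0 else float("inf")
            if not (height >= cfg.min_intensity or snr > cfg.min_snr):
                continue
            pts = [(s, m, i) for s, m, i in trace.points if left <= s <= right]
            if pts:
                w = np.array([i for _, _, i in pts])
                m = np.array([m for _, m, _ in pts])
                mz = float(np.average(m, weights=w)) if w.sum() > 0 else trace.mz
            else:
                mz = trace.mz
            area = float(np.trapezoid(xic[left:right + 1], rts[left:right + 1]))
            feature = Feature(
                mz=mz, rt_apex=float(rts[p]), height=height, area=area,
                snr=snr, isotope_ratio_a1=0.0, n_scans=n_scans,
            )
            features.append(feature)
            feature_aux.append((feature, xic, int(p)))

    # collapse residual duplicates (same channel, same apex region)
    features.sort(key=lambda f: (-f.height, -f.n_scans))
    unique: List[Feature] = []
    for f in features:
        if any(abs(f.mz - g.mz) <= cfg.mz_tol and abs(f.rt_apex - g.rt_apex) <= 0.1
               for g in unique):
            continue
        unique.append(f)
    features = unique

    # isotope-satellite bookkeeping: measure A+1 ratios and flag satellites.
    # The ratio is baseline-corrected (channel median) and averaged over the
    # apex +/- 1 scans so baseline offset and shot noise do not bias it.
    kept = {id(f) for f in features}

    def _channel_xic(center_mz: float) -> Optional[np.ndarray]:
        best = None
        for cmz, xic in channel_xics:
            d = abs(cmz - center_mz)
            if d <= cfg.mz_tol and (best is None or d < best[0]):
                best = (d, xic)
        return best[1] if best else None

    for f, xic, apex in feature_aux:
        if id(f) not in kept:
            continue
        sat = _channel_xic(f.mz + ISOTOPE_SPACING)
        if sat is None:
            continue
        lo, hi = max(0, apex - 1), min(len(xic), apex + 2)
        num = float(sat[lo:hi].mean() - np.median(sat))
        den = float(xic[lo:hi].mean() - np.median(xic))
        f.isotope_ratio_a1 = max(0.0, num / den) if den > 0 else 0.0

    by_height = sorted(features, key=lambda f: -f.height)
    for i, strong in enumerate(by_height):
        for weak in by_height[i + 1:]:
            if weak.is_isotope:
                continue
            for k in (1, 2):
                if (abs(weak.mz - (strong.mz + k * ISOTOPE_SPACING)) <= cfg.mz_tol
                        and abs(weak.rt_apex - strong.rt_apex) <= 0.1):
                    weak.is_isotope = True

    features.sort(key=lambda f: f.rt_apex)
    return features


def screen_feature(feature: Feature,
                   candidates: Sequence[FormulaCandidate],
                   expected_rt: Optional[float] = None,
                   cfg: Optional[ScreenConfig] = None) -> ScreenVerdict:
    """Apply the acceptance gates to a feature's best formula candidate."""
    cfg = cfg or ScreenConfig()
    if not candidates:
        return ScreenVerdict(False, {}, "no formula", None)
    best = candidates[0]
    checks = {
        "ppm": abs(best.ppm_error) <= cfg.ppm_tol,
        "rt": (expected_rt is None
               or abs(feature.rt_apex - expected_rt) / expected_rt < cfg.rt_rel_tol),
        "isotope": (best.isotope_ratio_error is None
                    or best.isotope_ratio_error < cfg.isotope_ratio_tol),
        "score": best.score >= cfg.score_min,
    }
    reason = next((name for name, ok in checks.items() if not ok), None)
    return ScreenVerdict(all(checks.values()), checks, reason, best)
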