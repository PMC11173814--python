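"""The three-step identification workflow and the quantification workflow.

Identification: non-target feature extraction and acceptance filtering
(screened), rule-based MS/MS interpretation plus spectral-library matching
(tentative), and retention-time + MS/MS agreement with authentic standards
(confirmed).  Quantification: calibration fitting, LOD/LOQ estimation from
blanks, two-dilution sample quantification with in-range selection, and the
validation report (precision, repeatability, recovery).
"""
from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    CandidateIdentification,
    FragmentSpectrum,
    StandardEntry,
    annotate_fragments,
    confirm_with_standard,
    is_flavonoid_like,
    library_match,
)
from .formula_finder import enumerate_formulas
from .chem import IsotopePattern, get_adduct
from .quantify import (
    CalibrationCurve,
    SampleRecord,
    estimate_lod_loq,
    fit_calibration,
    precision_report,
    recovery_report,
    rsd,
    select_dilution,
)
from .screening import CentroidRun, Feature, ScreenConfig, extract_features, screen_feature

logger = logging.getLogger(__name__)

__all__ = ["run_identification", "run_quantification"]


def _match_ms2(feature: Feature, ms2: Sequence[FragmentSpectrum],
               cfg: ScreenConfig) -> Optional[FragmentSpectrum]:
    best = None
    for spec in ms2:
        if abs(spec.precursor_mz - feature.mz) > cfg.mz_tol:
            continue
        if spec.rt is not None and abs(spec.rt - feature.rt_apex) > cfg.rt_tol:
            continue
        dt = abs((spec.rt or feature.rt_apex) - feature.rt_apex)
        if best is None or dt < best[0]:
            best = (dt, spec)
    return best[1] if best else None


def run_identification(runs: Sequence[CentroidRun],
                       library: Optional[Sequence[FragmentSpectrum]] = None,
                       standards: Optional[Sequence[StandardEntry]] = None,
                       cfg: Optional[ScreenConfig] = None,
                       bounds: Optional[Dict[str, Tuple[int, int]]] = None,
                       default_subclass: str = "isoflavone",
                       ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run the identification workflow over one or more centroided runs.

    Returns a per-feature report ordered by retention time and the summary
    tier counts.  ``n_tentative`` counts every feature that reached at least
    the tentative tier (confirmed features included).
    """
    cfg = cfg or ScreenConfig()
    library = list(library) if library else []
    standards = list(standards) if standards else []
    ref_spectra = {rec.name: rec for rec in library if rec.name}
    rows: List[Dict[str, object]] = []

    for run in runs:
        adduct = get_adduct("[M+H]+" if run.polarity == "+" else "[M-H]-")
        features = extract_features(run, cfg)
        for feature in features:
            if feature.is_isotope:
                continue
            pattern = None
            if feature.isotope_ratio_a1 > 0:
                pattern = IsotopePattern(((0.0, 1.0), (1.003355, feature.isotope_ratio_a1)))
            candidates = enumerate_formulas(feature.mz, adduct, cfg.ppm_tol,
                                            bounds, observed_pattern=pattern)
            verdict = screen_feature(feature, candidates, None, cfg)
            tier = "screened" if verdict.passed else "rejected"

            spectrum = _match_ms2(feature, run.ms2, cfg)
            cho = [c for c in candidates if c.is_cho]
            ann_candidate = cho[0] if cho else (candidates[0] if candidates else None)
            annotations = []
            if spectrum is not None and ann_candidate is not None:
                try:
                    annotations = annotate_fragments(
                        spectrum, ann_candidate.formula, subclass=default_subclass)
                except ValueError:
                    annotations = []
            flavo, flavo_reason = is_flavonoid_like(annotations)

            lib_name, lib_score = None, 0.0
            if spectrum is not None and library:
                hits = library_match(spectrum, library)
                if hits:
                    lib_name, lib_score = hits[0][0].name, hits[0][1]

            name = None
            if tier == "screened" and flavo:
                tier = "tentative"
                if lib_score >= cfg.score_min:
                    name = lib_name

            if tier == "tentative" and standards:
                cand_formulas = {c.formula for c in candidates}
                for std in standards:
                    if std.adduct != adduct.name or std.formula not in cand_formulas:
                        continue
                    ident = CandidateIdentification(formula=std.formula, tier=tier)
                    ident = confirm_with_standard(
                        ident, std, feature.rt_apex, spectrum,
                        ref_spectra.get(std.spectrum_id),
                        rt_tol=cfg.rt_tol, score_min=cfg.score_min)
                    if ident.tier == "confirmed":
                        tier = "confirmed"
                        name = std.name
                        break

            best = verdict.best
            rows.append({
                "rt_min": round(feature.rt_apex, 3),
                "mz": round(feature.mz, 4),
                "polarity": run.polarity,
                "tier": tier,
                "name": name,
                "formula": best.formula.hill() if best else None,
                "ppm_error": round(best.ppm_error, 1) if best else None,
                "isotope_ratio_error": (round(best.isotope_ratio_error, 4)
                                        if best and best.isotope_ratio_error is not None
                                        else None),
                "score": round(best.score, 1) if best else None,
                "library_hit": lib_name,
                "library_score": round(lib_score, 1),
                "flavonoid_like": flavo,
                "evidence": flavo_reason,
                "height": round(feature.height, 1),
                "snr": round(feature.snr, 1) if np.isfinite(feature.snr) else None,
            })

    report = pd.DataFrame(rows).sort_values("rt_min").reset_index(drop=True) \
        if rows else pd.DataFrame(columns=["rt_min", "mz", "polarity", "tier", "name"])
    tiers = report["tier"].tolist() if len(report) else []
    summary = {
        "n_features": len(tiers),
        "n_screened": sum(t in ("screened", "tentative", "confirmed") for t in tiers),
        "n_tentative": sum(t in ("tentative", "confirmed") for t in tiers),
        "n_confirmed": sum(t == "confirmed" for t in tiers),
    }
    logger.info("identification summary: %s", summary)
    return report, summary


def _records_from_df(df: pd.DataFrame, role: str) -> Dict[str, List[SampleRecord]]:
    """Group a long-format area table into SampleRecords keyed by sample id."""
    out: Dict[str, List[SampleRecord]] = {}
    for (sample_id, dilution), grp in df.groupby(["sample_id", "dilution"]):
        rec = SampleRecord(
            sample_id=str(sample_id), role=role,
            mass_mg=float(grp["mass_mg"].iloc[0]),
            volume_ml=float(grp["volume_ml"].iloc[0]),
            dilution=float(dilution),
            areas=dict(zip(grp["analyte"], grp["area"])))
        out.setdefault(str(sample_id), []).append(rec)
    return out


def run_quantification(dataset: Mapping[str, pd.DataFrame],
                       intraday_day: Optional[int] = None,
                       weighting: str = "1/x2",
                       ) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, CalibrationCurve]]:
    """Fit calibrations, quantify samples and assemble the validation report.

    ``dataset`` follows the layout of
    :func:`flavoscreen.synthetic.generate_quant_dataset` (calibration,
    blanks, qc, repeatability, recovery, samples tables).
    Returns (content table, validation table, fitted curves).

    Calibration defaults to 1/x^2 weighting because the linear ranges span
    about two orders of magnitude with multiplicative noise; pass
    ``weighting="none"`` for simple regression.
    """
    curves: Dict[str, CalibrationCurve] = {}
    for analyte, grp in dataset["calibration"].groupby("analyte"):
        curve = fit_calibration(list(zip(grp["conc_ng_ml"], grp["area"])),
                                analyte=analyte, weighting=weighting)
        blanks = dataset["blanks"]
        noise = blanks.loc[blanks["analyte"] == analyte, "area"]
        if len(noise) >= 3 and curve.slope > 0:
            noise_sd = float(noise.std(ddof=1))
            if noise_sd > 0:
                curve.lod, curve.loq = estimate_lod_loq(noise_sd, curve.slope)
        curves[analyte] = curve

    content_rows = []
    for sample_id, records in _records_from_df(dataset["samples"], "unknown").items():
        for analyte, res in select_dilution(records, curves).items():
            content_rows.append({
                "batch": sample_id, "analyte": analyte,
                "content_ug_g": res.content_ug_g,
                "dilution_used": res.dilution,
                "flags": ";".join(res.flags)})
    content = pd.DataFrame(content_rows).sort_values(["batch", "analyte"]).reset_index(drop=True)

    precision = precision_report(dataset["qc"], intraday_day=intraday_day)

    repeat_contents: Dict[str, List[float]] = {}
    for _, records in _records_from_df(dataset["repeatability"], "repeatability").items():
        for analyte, res in select_dilution(records, curves).items():
            repeat_contents.setdefault(analyte, []).append(res.content_ug_g)

    recovery_stats: Dict[str, Tuple[float, float]] = {}
    rec_df = dataset["recovery"]
    for analyte in curves:
        base_content = float(np.mean(repeat_contents.get(analyte, [np.nan])))
        found_ug, masses, added = [], [], []
        for _, records in _records_from_df(rec_df[rec_df["analyte"] == analyte],
                                           "recovery_spiked").items():
            res = select_dilution(records, curves)[analyte]
            mass = records[0].mass_mg
            found_ug.append(res.content_ug_g * mass / 1000.0)
            masses.append(mass)
            grp = rec_df[(rec_df["analyte"] == analyte)
                         & (rec_df["sample_id"] == records[0].sample_id)]
            added.append(float(grp["added_ug"].iloc[0]))
        if found_ug:
            mean_rec, rsd_rec, _ = recovery_report(base_content, found_ug, masses, added)
            recovery_stats[analyte] = (mean_rec, rsd_rec)

    validation_rows = []
    for analyte, curve in curves.items():
        prec = precision[precision["analyte"] == analyte].set_index("level")
        reps = repeat_contents.get(analyte, [])
        rec = recovery_stats.get(analyte, (np.nan, np.nan))
        validation_rows.append({
            "analyte": analyte,
            "slope": curve.slope,
            "intercept": curve.intercept,
            "r_squared": curve.r_squared,
            "range_low_ng_ml": curve.range_low,
            "range_high_ng_ml": curve.range_high,
            "lod_ng_ml": curve.lod,
            "loq_ng_ml": curve.loq,
            "intra_day_rsd_low": prec.loc["low", "intra_day_rsd_pct"],
            "intra_day_rsd_mid": prec.loc["mid", "intra_day_rsd_pct"],
            "intra_day_rsd_high": prec.loc["high", "intra_day_rsd_pct"],
            "inter_day_rsd_low": prec.loc["low", "inter_day_rsd_pct"],
            "inter_day_rsd_mid": prec.loc["mid", "inter_day_rsd_pct"],
            "inter_day_rsd_high": prec.loc["high", "inter_day_rsd_pct"],
            "repeatability_mean_ug_g": float(np.mean(reps)) if reps else np.nan,
            "repeatability_rsd_pct": rsd(reps) if len(reps) >= 2 else np.nan,
            "recovery_mean_pct": rec[0],
            "recovery_rsd_pct": rec[1],
        })
    validation = pd.DataFrame(validation_rows).sort_values("analyte").reset_index(drop=True)
    return content, validation, curves
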