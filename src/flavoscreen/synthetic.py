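"""Ground-truth synthetic data emulating the study's acquisitions.

Two kinds of datasets are generated, both fully determined by a seed:

* **LC-HRMS runs** for the 18-compound flavonoid panel: Gaussian elution
  profiles on a regular scan grid, per-scan m/z jitter (ppm-scale), isotope
  satellites from the aggregated isotope pattern, a noisy baseline in every
  occupied m/z channel, random noise centroids, and one MS/MS spectrum per
  compound synthesized from its known fragment list.
* **MRM quantification datasets**: calibration series spanning each
  analyte's linear range with multiplicative area noise, blank injections
  whose noise floor encodes the target LOD, low/mid/high QC replicates over
  several days, repeatability portions and 1:1 spike-recovery pairs built
  from known sample contents, plus two-dilution unknown samples.

The panel (masses, adducts, retention times, fragment lists, subclasses)
and the quantification truth (slopes, intercepts, linear ranges, LODs,
contents per batch) ship as packaged CSV data.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import FragmentSpectrum, StandardEntry
from .chem import Formula, adduct_mz, get_adduct, isotope_pattern
from .screening import CentroidRun, Scan

__all__ = [
    "PanelEntry",
    "GeneratorConfig",
    "load_panel",
    "load_calibration_truth",
    "load_sample_contents",
    "load_transitions",
    "generate_run",
    "generate_ms2_spectra",
    "build_reference_library",
    "standards_registry",
    "generate_quant_dataset",
    "CONFIRMED_STANDARDS",
]

#: The ten compounds identified against authentic standards.
CONFIRMED_STANDARDS = (
    "Glycitin", "Genistin", "Scutellarein", "Daidzein", "Glycitein",
    "Luteolin", "Genistein", "Kaempferol", "Formononetin", "Neobavaisoflavone",
)


@dataclass(frozen=True)
class PanelEntry:
    """One row of the screening panel."""

    number: int
    name: str
    rt: float
    mode_printed: str
    mode: str          # corrected adduct name ([M+H]+ or [M-H]-)
    formula: Formula
    theoretical_mz: float
    experimental_mz: float
    ppm_printed: float
    fragments: Tuple[float, ...]
    subclass: str
    abundance: float = 2000.0

    @property
    def polarity(self) -> str:
        return "+" if self.mode.endswith("+") else "-"


@dataclass
class GeneratorConfig:
    """Noise model and design parameters; a fixed seed fixes every output."""

    seed: int = 1
    mz_noise_ppm: float = 2.0        # per-scan centroid jitter (sigma)
    rt_jitter_min: float = 0.05      # per-compound apex jitter (sigma)
    peak_width_min: float = 0.08     # Gaussian elution sigma
    baseline_level: float = 10.0     # counts, channel baseline
    baseline_noise_sd: float = 5.0   # counts, channel noise (sigma)
    area_noise_cv: float = 0.02      # multiplicative CV on MRM peak areas
    scan_interval_min: float = 0.02
    n_noise_centroids: int = 10      # random centroids per scan
    calibration_levels: int = 10
    qc_days: int = 3
    qc_replicates: int = 6
    repeatability_n: int = 6
    recovery_n: int = 6
    sample_mass_mg: float = 150.0
    extract_volume_ml: float = 10.0
    dilution_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.area_noise_cv < 0:
            raise ValueError("area noise CV must be >= 0")


def load_panel() -> List[PanelEntry]:
    """The 18-compound flavonoid panel; unknown rows become 'unknown-<k>'.

    The one panel row whose printed ESI mode is inconsistent with its
    negative-mode fragmentation keeps the printed string in
    ``mode_printed`` while ``mode`` carries the corrected adduct.
    """
    path = resources.files("flavoscreen.data").joinpath("table1_panel.csv")
    out: List[PanelEntry] = []
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            printed = row["esi_mode_printed"]
            mode = printed.replace("−", "-")
            if mode == "[M-H]+":  # typo: negative-mode loss chemistry
                mode = "[M-H]-"
            number = int(row["number"])
            name = row["name"]
            if name.lower() == "unknown":
                name = f"unknown-{number}"
            out.append(PanelEntry(
                number=number, name=name, rt=float(row["rt_min"]),
                mode_printed=printed, mode=mode,
                formula=Formula.parse(row["formula"]),
                theoretical_mz=float(row["theoretical_mz"]),
                experimental_mz=float(row["experimental_mz"]),
                ppm_printed=float(row["error_ppm_printed"]),
                fragments=tuple(float(x) for x in row["fragments"].split(";")),
                subclass=row["subclass"]))
    return out


def load_calibration_truth() -> pd.DataFrame:
    path = resources.files("flavoscreen.data").joinpath("calibration_truth.csv")
    with path.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def load_sample_contents() -> pd.DataFrame:
    path = resources.files("flavoscreen.data").joinpath("sample_contents.csv")
    with path.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def load_transitions() -> pd.DataFrame:
    path = resources.files("flavoscreen.data").joinpath("mrm_transitions.csv")
    with path.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def _fragment_intensities(n: int, rng: Optional[np.random.Generator]) -> np.ndarray:
    """Rank-decaying fragment intensities; base peak is the first fragment
    (the aglycone ion for glycosides, whose high abundance is the hallmark
    of glycosidic cleavage)."""
    base = 1000.0 * np.exp(-0.4 * np.arange(n))
    if rng is not None:
        base = base * np.exp(rng.normal(0.0, 0.2, size=n))
        base[0] = max(base[0], base.max())  # keep the aglycone ion on top
    return base


def generate_ms2_spectra(panel: Sequence[PanelEntry],
                         cfg: GeneratorConfig,
                         rng: Optional[np.random.Generator] = None,
                         rt_true: Optional[Dict[int, float]] = None) -> List[FragmentSpectrum]:
    """One MS/MS spectrum per panel entry from its known fragment list."""
    spectra = []
    for entry in panel:
        mz = np.array(entry.fragments, dtype=float)
        inten = _fragment_intensities(mz.size, rng)
        if rng is not None:
            mz = mz * (1.0 + rng.normal(0.0, cfg.mz_noise_ppm * 1e-6, size=mz.size))
        rt = rt_true[entry.number] if rt_true else entry.rt
        spectra.append(FragmentSpectrum(
            precursor_mz=entry.theoretical_mz, polarity=entry.polarity,
            mz=mz, intensity=inten, rt=rt, name=entry.name))
    return spectra


def build_reference_library(panel: Sequence[PanelEntry]) -> List[FragmentSpectrum]:
    """Noise-free fixture spectral library (stand-in for public libraries)."""
    return generate_ms2_spectra(panel, GeneratorConfig(), rng=None, rt_true=None)


def standards_registry(panel: Sequence[PanelEntry]) -> List[StandardEntry]:
    """The ten authentic standards with their registered RTs and spectra."""
    return [StandardEntry(name=e.name, formula=e.formula, adduct=e.mode,
                          rt=e.rt, spectrum_id=e.name)
            for e in panel if e.name in CONFIRMED_STANDARDS]


def generate_run(panel: Sequence[PanelEntry],
                 cfg: Optional[GeneratorConfig] = None,
                 polarity: str = "+") -> Tuple[CentroidRun, pd.DataFrame]:
    """Synthesize a centroided LC-MS run for the panel entries of one polarity.

    Returns the run and a ground-truth table linking every planted compound
    to its true m/z, retention time and apex height.
    """
    cfg = cfg or GeneratorConfig()
    entries = [e for e in panel if e.polarity == polarity]
    rng = np.random.default_rng([cfg.seed, 0 if polarity == "+" else 1])
    keyset = {(round(e.theoretical_mz, 2), round(e.rt, 1)) for e in entries}
    if len(keyset) != len(entries):
        raise ValueError("panel entries overlap in (m/z, RT)")

    if entries:
        rt_lo = min(e.rt for e in entries) - 1.0
        rt_hi = max(e.rt for e in entries) + 1.0
    else:
        rt_lo, rt_hi = 0.0, 2.0
    rts = np.arange(rt_lo, rt_hi + cfg.scan_interval_min / 2, cfg.scan_interval_min)
    n_scans = rts.size

    # channels: center mz -> summed elution profile; isotope satellites
    # included.  Compounds sharing an m/z channel (isomers) share one
    # detector channel, hence one baseline, as on a real instrument.
    channel_map: Dict[float, np.ndarray] = {}
    truth_rows = []
    rt_true: Dict[int, float] = {}
    for entry in entries:
        apex_rt = entry.rt + rng.normal(0.0, cfg.rt_jitter_min)
        rt_true[entry.number] = apex_rt
        center = entry.theoretical_mz
        profile = entry.abundance * np.exp(
            -0.5 * ((rts - apex_rt) / cfg.peak_width_min) ** 2)
        pattern = isotope_pattern(entry.formula, 3)
        for offset, rel in pattern.peaks:
            key = round(center + offset, 5)
            if key in channel_map:
                channel_map[key] = channel_map[key] + profile * rel
            else:
                channel_map[key] = profile * rel
        truth_rows.append({
            "number": entry.number, "name": entry.name, "polarity": polarity,
            "mz_true": center, "rt_true": apex_rt, "height_true": entry.abundance,
            "formula": entry.formula.hill(), "subclass": entry.subclass,
        })

    channels = sorted(channel_map.items())
    scans: List[Scan] = []
    for i, rt in enumerate(rts):
        mz_list: List[float] = []
        int_list: List[float] = []
        for center, profile in channels:
            inten = profile[i] + cfg.baseline_level + rng.normal(0.0, cfg.baseline_noise_sd)
            if inten <= 0:
                continue
            jitter = rng.normal(0.0, cfg.mz_noise_ppm) * 1e-6
            mz_list.append(center * (1.0 + jitter))
            int_list.append(inten)
        if cfg.n_noise_centroids:
            noise_mz = rng.uniform(100.0, 1000.0, size=cfg.n_noise_centroids)
            noise_int = np.abs(rng.normal(cfg.baseline_level, cfg.baseline_noise_sd,
                                          size=cfg.n_noise_centroids))
            mz_list.extend(noise_mz.tolist())
            int_list.extend(noise_int.tolist())
        scans.append(Scan(rt=float(rt), mz=np.array(mz_list), intensity=np.array(int_list)))

    run = CentroidRun(polarity=polarity, scans=scans)
    run.ms2 = generate_ms2_spectra(entries, cfg, rng=rng, rt_true=rt_true)
    return run, pd.DataFrame(truth_rows)


def generate_quant_dataset(cfg: Optional[GeneratorConfig] = None,
                           analytes: Optional[Sequence[str]] = None,
                           repeatability_batch: str = "230110") -> Dict[str, pd.DataFrame]:
    """Synthesize the full MRM validation/quantification dataset.

    Truth (slopes, intercepts, linear ranges, LODs, contents) comes from the
    packaged tables; areas are perturbed multiplicatively at the configured
    CV, and blank noise is calibrated so the sigma-based estimate recovers
    the target LOD.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng([cfg.seed, 2])
    truth = load_calibration_truth()
    contents = load_sample_contents()
    if analytes is not None:
        truth = truth[truth["analyte"].isin(analytes)].reset_index(drop=True)
        contents = contents[contents["analyte"].isin(analytes)].reset_index(drop=True)

    def noisy(value: float) -> float:
        if cfg.area_noise_cv == 0:
            return float(value)
        return float(value * (1.0 + rng.normal(0.0, cfg.area_noise_cv)))

    def area_of(row: pd.Series, conc: float) -> float:
        return noisy(row["slope"] * conc + row["intercept"])

    cal_rows, blank_rows, qc_rows = [], [], []
    for _, row in truth.iterrows():
        concs = np.geomspace(row["range_low_ng_ml"], row["range_high_ng_ml"],
                             cfg.calibration_levels)
        for level, conc in enumerate(concs, start=1):
            cal_rows.append({"analyte": row["analyte"], "level": level,
                             "conc_ng_ml": float(conc),
                             "area": area_of(row, float(conc))})
        noise_sd = row["lod_ng_ml"] * row["slope"] / 3.0
        for rep in range(20):
            blank_rows.append({"analyte": row["analyte"], "rep": rep + 1,
                               "area": float(rng.normal(0.0, noise_sd))})
        qc_concs = {"low": row["range_low_ng_ml"] * 2.0,
                    "high": row["range_high_ng_ml"] * 0.8}
        qc_concs["mid"] = float(np.sqrt(qc_concs["low"] * qc_concs["high"]))
        for day in range(1, cfg.qc_days + 1):
            for rep in range(1, cfg.qc_replicates + 1):
                for level, conc in qc_concs.items():
                    qc_rows.append({"analyte": row["analyte"], "level": level,
                                    "day": day, "rep": rep, "conc_ng_ml": conc,
                                    "area": area_of(row, conc)})

    contents = contents.copy()
    contents["batch"] = contents["batch"].astype(str)
    lookup = contents.set_index(["batch", "analyte"])["content_ug_g"]

    def sample_areas(batch: str, mass_mg: float, dilution: float,
                     extra_ug: Optional[Dict[str, float]] = None) -> Dict[str, float]:
        areas = {}
        for _, row in truth.iterrows():
            analyte = row["analyte"]
            content = float(lookup.loc[(batch, analyte)])
            total_ug = content * mass_mg / 1000.0
            if extra_ug:
                total_ug += extra_ug.get(analyte, 0.0)
            conc = total_ug * 1000.0 / cfg.extract_volume_ml / dilution
            areas[analyte] = area_of(row, conc)
        return areas

    sample_rows = []
    for batch in sorted(contents["batch"].unique()):
        for dilution in (1.0, cfg.dilution_factor):
            areas = sample_areas(batch, cfg.sample_mass_mg, dilution)
            for analyte, area in areas.items():
                sample_rows.append({"sample_id": batch, "role": "unknown",
                                    "dilution": dilution,
                                    "mass_mg": cfg.sample_mass_mg,
                                    "volume_ml": cfg.extract_volume_ml,
                                    "analyte": analyte, "area": area})

    repeat_rows = []
    for rep in range(1, cfg.repeatability_n + 1):
        mass = cfg.sample_mass_mg
        for dilution in (1.0, cfg.dilution_factor):
            areas = sample_areas(repeatability_batch, mass, dilution)
            for analyte, area in areas.items():
                repeat_rows.append({"sample_id": f"{repeatability_batch}-rep{rep}",
                                    "rep": rep, "dilution": dilution,
                                    "mass_mg": mass, "volume_ml": cfg.extract_volume_ml,
                                    "analyte": analyte, "area": area})

    recovery_rows = []
    half_mass = cfg.sample_mass_mg / 2.0
    for rep in range(1, cfg.recovery_n + 1):
        added = {row["analyte"]: float(lookup.loc[(repeatability_batch, row["analyte"])])
                 * half_mass / 1000.0 for _, row in truth.iterrows()}  # 1:1 spike
        for dilution in (1.0, cfg.dilution_factor):
            areas = sample_areas(repeatability_batch, half_mass, dilution, extra_ug=added)
            for analyte, area in areas.items():
                recovery_rows.append({"sample_id": f"{repeatability_batch}-spike{rep}",
                                      "rep": rep, "dilution": dilution,
                                      "mass_mg": half_mass,
                                      "volume_ml": cfg.extract_volume_ml,
                                      "analyte": analyte, "area": area,
                                      "added_ug": added[analyte]})

    return {
        "calibration": pd.DataFrame(cal_rows),
        "blanks": pd.DataFrame(blank_rows),
        "qc": pd.DataFrame(qc_rows),
        "repeatability": pd.DataFrame(repeat_rows),
        "recovery": pd.DataFrame(recovery_rows),
        "samples": pd.DataFrame(sample_rows),
        "truth_calibration": truth,
        "truth_contents": contents,
    }
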