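"""File formats: centroid mzML, MGF, MSP, the line-oriented run format,
standards registries and feature tables.

mzML output is a minimal centroid document (64-bit float arrays, no
compression) that round-trips through pyteomics; MGF goes through pyteomics
directly.  MSP is the simple NIST text flavour (Name / PrecursorMZ /
Ion_mode / Num Peaks).
"""
from __future__ import annotations

import base64
import csv
import xml.etree.ElementTree as ET
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from pyteomics import mgf as _mgf

from .annotation import FragmentSpectrum, StandardEntry
from .chem import Formula
from .screening import CentroidRun, Feature, Scan

__all__ = [
    "write_mzml",
    "read_mzml",
    "write_mgf",
    "read_mgf",
    "write_msp",
    "read_msp",
    "write_run_tsv",
    "read_run_tsv",
    "write_standards_csv",
    "read_standards_csv",
    "features_to_rows",
]


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def _binary_array(values: np.ndarray, accession: str, name: str, unit: str) -> str:
    data = _b64(values)
    return (
        '<binaryDataArray encodedLength="{n}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="{acc}" name="{name}" value=""{unit}/>'
        '<binary>{data}</binary></binaryDataArray>'
    ).format(n=len(data), acc=accession, name=name, unit=unit, data=data)


def write_mzml(run: CentroidRun, path: str) -> None:
    """Write a centroided run (MS1 scans + linked MS2 spectra) as mzML."""
    polarity_cv = ('<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
                   if run.polarity == "+" else
                   '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>')
    unit_min = (' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"')
    spectra = []
    index = 0
    for scan in run.scans:
        spectra.append(
            '<spectrum index="{i}" id="scan={i}" defaultArrayLength="{n}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '{pol}'
            '<scanList count="1"><scan>'
            '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}"{unit}/>'
            '</scan></scanList>'
            '<binaryDataArrayList count="2">{mz}{inten}</binaryDataArrayList>'
            '</spectrum>'.format(
                i=index, n=scan.mz.size, pol=polarity_cv, rt=repr(float(scan.rt)),
                unit=unit_min,
                mz=_binary_array(scan.mz, "MS:1000514", "m/z array",
                                 ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'),
                inten=_binary_array(scan.intensity, "MS:1000515", "intensity array", "")))
        index += 1
    for spec in run.ms2:
        spectra.append(
            '<spectrum index="{i}" id="scan={i}" defaultArrayLength="{n}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            '{pol}'
            '<scanList count="1"><scan>'
            '<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}"{unit}/>'
            '</scan></scanList>'
            '<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
            '<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{pre}"/>'
            '</selectedIon></selectedIonList></precursor></precursorList>'
            '<binaryDataArrayList count="2">{mz}{inten}</binaryDataArrayList>'
            '</spectrum>'.format(
                i=index, n=spec.mz.size, pol=polarity_cv,
                rt=repr(float(spec.rt or 0.0)), unit=unit_min,
                pre=repr(float(spec.precursor_mz)),
                mz=_binary_array(spec.mz, "MS:1000514", "m/z array",
                                 ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'),
                inten=_binary_array(spec.intensity, "MS:1000515", "intensity array", "")))
        index += 1
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>'
        '</cvList>'
        '<run id="run1">'
        f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">'
        + "".join(spectra) +
        '</spectrumList></run></mzML>')
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(doc)


def read_mzml(path: str) -> CentroidRun:
    """Read a centroided mzML file back into a :class:`CentroidRun`.

    A thin namespace-aware reader keyed on the standard PSI-MS accessions
    (ms level, polarity, scan start time, selected ion m/z, binary array
    types); handles uncompressed 64- and 32-bit float arrays.
    """
    ns = {"m": "http://psi.hupo.org/ms/mzml"}
    tree = ET.parse(path)
    root = tree.getroot()
    scans: List[Scan] = []
    ms2: List[FragmentSpectrum] = []
    polarity = "+"

    def params(elem) -> Dict[str, str]:
        return {cv.get("accession"): cv.get("value", "")
                for cv in elem.findall("m:cvParam", ns)}

    for spectrum in root.iter("{http://psi.hupo.org/ms/mzml}spectrum"):
        p = params(spectrum)
        if "MS:1000129" in p:
            polarity = "-"
        elif "MS:1000130" in p:
            polarity = "+"
        ms_level = int(p.get("MS:1000511", "1"))
        rt = 0.0
        scan_list = spectrum.find("m:scanList", ns)
        if scan_list is not None:
            for scan_el in scan_list.findall("m:scan", ns):
                sp = params(scan_el)
                if "MS:1000016" in sp:
                    rt = float(sp["MS:1000016"])
        arrays: Dict[str, np.ndarray] = {}
        for array_el in spectrum.iter("{http://psi.hupo.org/ms/mzml}binaryDataArray"):
            ap = params(array_el)
            binary = array_el.find("m:binary", ns)
            raw = base64.b64decode(binary.text or "") if binary is not None else b""
            dtype = "<f4" if "MS:1000521" in ap else "<f8"
            values = np.frombuffer(raw, dtype=dtype).astype(float)
            if "MS:1000514" in ap:
                arrays["mz"] = values
            elif "MS:1000515" in ap:
                arrays["intensity"] = values
        mz = arrays.get("mz", np.array([]))
        inten = arrays.get("intensity", np.array([]))
        if ms_level == 1:
            scans.append(Scan(rt=rt, mz=mz, intensity=inten))
        else:
            pre = 0.0
            for ion in spectrum.iter("{http://psi.hupo.org/ms/mzml}selectedIon"):
                ip = params(ion)
                if "MS:1000744" in ip:
                    pre = float(ip["MS:1000744"])
            ms2.append(FragmentSpectrum(precursor_mz=pre, polarity=polarity,
                                        mz=mz, intensity=inten, rt=rt))
    run = CentroidRun(polarity=polarity, scans=scans)
    run.ms2 = ms2
    return run


def write_mgf(spectra: Sequence[FragmentSpectrum], path: str) -> None:
    entries = []
    for i, spec in enumerate(spectra):
        params = {"title": spec.name or f"spectrum_{i}", "pepmass": float(spec.precursor_mz)}
        if spec.rt is not None:
            params["rtinseconds"] = float(spec.rt) * 60.0
        params["ion_mode"] = "positive" if spec.polarity == "+" else "negative"
        entries.append({"m/z array": spec.mz, "intensity array": spec.intensity,
                        "params": params})
    _mgf.write(entries, output=path, file_mode="w")


def read_mgf(path: str, polarity: Optional[str] = None) -> List[FragmentSpectrum]:
    out = []
    with _mgf.MGF(path) as reader:
        for entry in reader:
            params = entry["params"]
            mode = str(params.get("ion_mode", "positive")).lower()
            pol = polarity or ("-" if mode.startswith("neg") else "+")
            rt = params.get("rtinseconds")
            pepmass = params["pepmass"]
            pre = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            out.append(FragmentSpectrum(
                precursor_mz=pre, polarity=pol,
                mz=np.asarray(entry["m/z array"], dtype=float),
                intensity=np.asarray(entry["intensity array"], dtype=float),
                rt=float(rt) / 60.0 if rt is not None else None,
                name=str(params.get("title")) if params.get("title") else None))
    return out


def write_msp(spectra: Sequence[FragmentSpectrum], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for spec in spectra:
            handle.write(f"Name: {spec.name or 'unknown'}\n")
            handle.write(f"PrecursorMZ: {spec.precursor_mz:.4f}\n")
            handle.write(f"Ion_mode: {'P' if spec.polarity == '+' else 'N'}\n")
            if spec.rt is not None:
                handle.write(f"RetentionTime: {spec.rt:.2f}\n")
            handle.write(f"Num Peaks: {spec.mz.size}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                handle.write(f"{mz:.4f} {inten:.1f}\n")
            handle.write("\n")


def read_msp(path: str) -> List[FragmentSpectrum]:
    spectra: List[FragmentSpectrum] = []
    fields: Dict[str, str] = {}
    peaks: List[Tuple[float, float]] = []
    n_expected = 0

    def flush() -> None:
        nonlocal fields, peaks, n_expected
        if fields:
            mz = np.array([p[0] for p in peaks])
            inten = np.array([p[1] for p in peaks])
            spectra.append(FragmentSpectrum(
                precursor_mz=float(fields.get("precursormz", "0") or 0),
                polarity="+" if fields.get("ion_mode", "P").upper().startswith("P") else "-",
                mz=mz, intensity=inten,
                rt=float(fields["retentiontime"]) if "retentiontime" in fields else None,
                name=fields.get("name")))
        fields, peaks, n_expected = {}, [], 0

    with open(path, "r", encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line:
                flush()
                continue
            if ":" in line and not line[0].isdigit():
                key, _, value = line.partition(":")
                key = key.strip().lower().replace(" ", "")
                value = value.strip()
                if key == "name" and fields:
                    flush()
                if key == "numpeaks":
                    n_expected = int(value)
                else:
                    fields[key] = value
            else:
                parts = line.replace(";", " ").split()
                if len(parts) >= 2:
                    peaks.append((float(parts[0]), float(parts[1])))
    flush()
    return spectra


def write_run_tsv(run: CentroidRun, path: str) -> None:
    """Line-oriented fixture format: SCAN header lines then mz/intensity rows."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"POLARITY\t{run.polarity}\n")
        for scan in run.scans:
            handle.write(f"SCAN\t{scan.rt:.6f}\t{scan.mz.size}\n")
            for mz, inten in zip(scan.mz, scan.intensity):
                handle.write(f"{mz:.6f}\t{inten:.3f}\n")


def read_run_tsv(path: str) -> CentroidRun:
    polarity = "+"
    scans: List[Scan] = []
    current: Optional[Tuple[float, List[float], List[float]]] = None
    with open(path, "r", encoding="utf-8") as handle:
        for raw in handle:
            parts = raw.rstrip("\n").split("\t")
            if parts[0] == "POLARITY":
                polarity = parts[1]
            elif parts[0] == "SCAN":
                if current is not None:
                    scans.append(Scan(current[0], np.array(current[1]), np.array(current[2])))
                current = (float(parts[1]), [], [])
            elif current is not None and len(parts) >= 2:
                current[1].append(float(parts[0]))
                current[2].append(float(parts[1]))
    if current is not None:
        scans.append(Scan(current[0], np.array(current[1]), np.array(current[2])))
    return CentroidRun(polarity=polarity, scans=scans)


def write_standards_csv(standards: Sequence[StandardEntry], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["name", "formula", "adduct", "rt_min", "spectrum_id"])
        for std in standards:
            writer.writerow([std.name, std.formula.hill(), std.adduct,
                             f"{std.rt:.2f}", std.spectrum_id])


def read_standards_csv(path: str) -> List[StandardEntry]:
    out = []
    with open(path, "r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            out.append(StandardEntry(
                name=row["name"], formula=Formula.parse(row["formula"]),
                adduct=row["adduct"].replace("−", "-"), rt=float(row["rt_min"]),
                spectrum_id=row["spectrum_id"]))
    return out


def features_to_rows(features: Sequence[Feature]) -> List[Dict[str, object]]:
    return [{
        "mz": round(f.mz, 4), "rt_min": round(f.rt_apex, 3),
        "height": round(f.height, 1), "area": round(f.area, 3),
        "snr": round(f.snr, 1) if np.isfinite(f.snr) else "inf",
        "isotope_ratio_a1": round(f.isotope_ratio_a1, 4),
        "n_scans": f.n_scans, "is_isotope": f.is_isotope,
    } for f in features]
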