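"""Elemental-mass arithmetic for small-molecule mass spectrometry.

Everything downstream (formula enumeration, screening filters, fragment
annotation, MRM parent ions) is built on the primitives here: molecular
formulas in Hill notation, monoisotopic masses from a versioned element
table, adduct m/z for singly charged electrospray ions, ppm mass errors,
ring-and-double-bond equivalents, and a coarse aggregated isotope pattern
(A, A+1, A+2 ...) sufficient for a 10 % isotope-ratio gate.

The element masses and isotope abundances are packaged as CSV data
(``data/elements.csv``) so that outputs are bit-stable across environments.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterator, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Formula",
    "FormulaError",
    "Adduct",
    "ADDUCTS",
    "get_adduct",
    "MassMeasurement",
    "IsotopePattern",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "rdbe",
    "isotope_pattern",
]

#: Mass of a proton in Da.  Used for [M+H]+ / [M-H]- adduct arithmetic; it is
#: equivalent to "hydrogen atom minus electron" to within 1e-8 Da.
PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990


class FormulaError(ValueError):
    """Raised for unparsable formulas, unknown elements or negative counts."""


def _load_element_table() -> Dict[str, List[Tuple[int, float, float]]]:
    table: Dict[str, List[Tuple[int, float, float]]] = {}
    path = resources.files("flavoscreen.data").joinpath("elements.csv")
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table.setdefault(row["element"], []).append(
                (int(row["nominal_offset"]), float(row["mass"]), float(row["abundance"]))
            )
    for isotopes in table.values():
        isotopes.sort()
    return table


#: element -> list of (nominal mass offset from the principal isotope,
#: isotopic mass in Da, natural abundance fraction)
ISOTOPES: Dict[str, List[Tuple[int, float, float]]] = _load_element_table()

#: element -> monoisotopic (principal isotope) mass in Da
MONOISOTOPIC: Dict[str, float] = {el: iso[0][1] for el, iso in ISOTOPES.items()}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _hill_order(counts: Mapping[str, int]) -> Tuple[Tuple[str, int], ...]:
    """Hill convention: C first, H second, remaining elements alphabetical.

    Without carbon, all elements are sorted alphabetically.
    """
    elements = [el for el, n in counts.items() if n > 0]
    if "C" in elements:
        rest = sorted(el for el in elements if el not in ("C", "H"))
        ordered = ["C"] + (["H"] if "H" in elements else []) + rest
    else:
        ordered = sorted(elements)
    return tuple((el, counts[el]) for el in ordered)


@dataclass(frozen=True)
class Formula(Mapping[str, int]):
    """An elemental composition with non-negative integer counts.

    Immutable and hashable; iteration and serialization follow Hill order so
    ``Formula.parse("C21H20O10").hill()`` round-trips.
    """

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kw: int):
        merged: Dict[str, int] = dict(counts or {})
        merged.update(kw)
        for el, n in merged.items():
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"negative or non-integer count for {el}: {n!r}")
        object.__setattr__(self, "counts", _hill_order(merged))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-notation string such as ``"C21H20O10"`` or ``"CO"``."""
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"unparsable formula: {text!r}")
            pos = match.end()
            el, digits = match.groups()
            if el not in ISOTOPES:
                raise FormulaError(f"unknown element symbol in {text!r}: {el!r}")
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        if pos != len(text):
            raise FormulaError(f"unparsable formula: {text!r}")
        return cls(counts)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        for symbol, n in self.counts:
            if symbol == el:
                return n
        raise KeyError(el)

    def __iter__(self) -> Iterator[str]:
        return (el for el, _ in self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts:
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts:
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise FormulaError(f"subtraction gives negative {el} count")
        return Formula(counts)

    def hill(self) -> str:
        return "".join(f"{el}{n if n > 1 else ''}" for el, n in self.counts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


@dataclass(frozen=True)
class Adduct:
    """An electrospray adduct: signed charge and mass shift relative to M."""

    name: str
    charge: int
    mass_delta: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")


ADDUCTS: Dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", +1, +PROTON_MASS),
    "[M-H]-": Adduct("[M-H]-", -1, -PROTON_MASS),
}


def get_adduct(name: str) -> Adduct:
    """Look up a supported adduct; tolerates the typographic minus sign."""
    key = name.replace("−", "-").replace(" ", "")
    try:
        return ADDUCTS[key]
    except KeyError:
        raise KeyError(f"unsupported adduct: {name!r} (supported: {sorted(ADDUCTS)})") from None


@dataclass(frozen=True)
class MassMeasurement:
    """A theoretical/experimental m/z pair with its signed ppm error."""

    mz_theoretical: float
    mz_experimental: float

    @property
    def ppm_error(self) -> float:
        return ppm_error(self.mz_theoretical, self.mz_experimental)


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated nominal-mass isotope pattern.

    ``peaks`` holds (m/z offset from the monoisotopic peak in Da, abundance
    relative to the monoisotopic peak).  The monoisotopic entry is (0.0, 1.0)
    and offsets increase strictly.
    """

    peaks: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("empty isotope pattern")
        offsets = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("isotope offsets must increase strictly")
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError("isotope abundances must be non-negative")

    @property
    def a1_ratio(self) -> float:
        """Abundance of the A+1 peak relative to A (0.0 if absent)."""
        for offset, rel in self.peaks:
            if 0.5 < offset < 1.5:
                return rel
        return 0.0

    @property
    def a2_ratio(self) -> float:
        for offset, rel in self.peaks:
            if 1.5 < offset < 2.5:
                return rel
        return 0.0


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of count x principal-isotope mass over all elements, in Da."""
    return float(sum(n * MONOISOTOPIC[el] for el, n in formula.counts))


def adduct_mz(formula: Formula, adduct: Adduct) -> float:
    """Theoretical m/z of ``formula`` under ``adduct`` (|charge| = 1 only).

    Full precision is retained; round to 4 decimals for report output.
    """
    if abs(adduct.charge) != 1:
        raise ValueError("only singly charged adducts are supported")
    return (monoisotopic_mass(formula) + adduct.mass_delta) / abs(adduct.charge)


def ppm_error(theoretical: float, experimental: float) -> float:
    """Signed relative mass error, (exp - theo) / theo x 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (experimental - theoretical) / theoretical * 1e6


def rdbe(formula: Formula) -> float:
    """Ring-and-double-bond equivalents, C - H/2 + N/2 + 1."""
    c = formula.get("C", 0)
    h = formula.get("H", 0)
    n = formula.get("N", 0)
    return c - h / 2.0 + n / 2.0 + 1.0


def _atom_distribution(element: str) -> Tuple[np.ndarray, np.ndarray]:
    """(probability, probability-weighted mass offset) per nominal bin."""
    isotopes = ISOTOPES[element]
    size = max(k for k, _, _ in isotopes) + 1
    prob = np.zeros(size)
    massw = np.zeros(size)
    base_mass = isotopes[0][1]
    total = sum(a for _, _, a in isotopes)
    for k, mass, abundance in isotopes:
        p = abundance / total
        prob[k] += p
        massw[k] += p * (mass - base_mass)
    return prob, massw


def _convolve(a: Tuple[np.ndarray, np.ndarray], b: Tuple[np.ndarray, np.ndarray],
              max_bins: int) -> Tuple[np.ndarray, np.ndarray]:
    pa, ma = a
    pb, mb = b
    prob = np.convolve(pa, pb)[:max_bins]
    # E[mass offset | bin] bookkeeping: weighted offsets add under convolution
    massw = (np.convolve(ma, pb) + np.convolve(pa, mb))[:max_bins]
    return prob, massw


def isotope_pattern(formula: Formula, n_peaks: int = 3,
                    min_abundance: float = 0.0) -> IsotopePattern:
    """Coarse aggregated isotope pattern (A, A+1, A+2, ...).

    Exact polynomial convolution of per-element isotope distributions on the
    nominal-mass grid; fine structure within a nominal bin is collapsed to the
    abundance-weighted mean mass offset.  ``min_abundance`` drops peaks below
    the given fraction of the monoisotopic peak (the monoisotopic peak itself
    is always kept).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    max_bins = n_peaks + 3
    dist: Tuple[np.ndarray, np.ndarray] = (np.array([1.0]), np.array([0.0]))
    for el, count in formula.counts:
        atom = _atom_distribution(el)
        for _ in range(count):
            dist = _convolve(dist, atom, max_bins)
    prob, massw = dist
    if prob[0] <= 0:
        raise ValueError("degenerate isotope distribution")
    peaks: List[Tuple[float, float]] = []
    for k in range(min(n_peaks, len(prob))):
        rel = prob[k] / prob[0]
        if k == 0:
            peaks.append((0.0, 1.0))
        elif rel >= max(min_abundance, 1e-9):
            peaks.append((massw[k] / prob[k], rel))
    return IsotopePattern(tuple(peaks))
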