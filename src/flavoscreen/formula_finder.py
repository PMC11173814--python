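"""Molecular-formula enumeration from accurate mass.

Candidate elemental compositions are enumerated exhaustively inside
per-element count bounds so that the neutral monoisotopic mass matches an
observed m/z (under a given adduct) within a ppm tolerance.  Chemically
implausible candidates (negative or huge RDBE, extreme H/C ratio) are
discarded and the survivors are ranked by a transparent 0-100 score that
penalises mass error and isotope-ratio error linearly:

    score = 100 * (0.5 * (1 - |ppm|/tol) + 0.5 * (1 - min(1, iso_err/0.10)))

The score replaces the vendor "formula finder score"; its only claim is that
it is monotone in both error terms and reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .chem import (
    Adduct,
    Formula,
    IsotopePattern,
    MONOISOTOPIC,
    isotope_pattern,
    rdbe,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "FormulaCandidate",
    "enumerate_formulas",
    "score_candidate",
]

#: Default search space covering the flavonoid (CHO) neighbourhood with room
#: for N and S analogues.
DEFAULT_BOUNDS: Dict[str, Tuple[int, int]] = {
    "C": (0, 40),
    "H": (0, 60),
    "N": (0, 5),
    "O": (0, 20),
    "S": (0, 2),
}

#: Chemical plausibility gates applied to every candidate.
RDBE_RANGE = (0.0, 40.0)
HC_RANGE = (0.2, 3.1)


@dataclass
class FormulaCandidate:
    """An enumerated formula with its evidence against the observation."""

    formula: Formula
    ppm_error: float
    rdbe: float
    isotope_ratio_error: Optional[float] = None  # fraction, e.g. 0.05 = 5 %
    score: float = 0.0
    theoretical_a1: float = field(default=0.0, repr=False)

    @property
    def is_cho(self) -> bool:
        return all(el in ("C", "H", "O") for el in self.formula)


def score_candidate(candidate: FormulaCandidate,
                    observed_pattern: Optional[IsotopePattern] = None,
                    tol_ppm: float = 5.0,
                    iso_tol: float = 0.10) -> float:
    """Deterministic 0-100 score; also fills ``isotope_ratio_error``.

    The isotope term compares the candidate's theoretical A+1/A ratio with
    the observed one as a relative error.  Without an observed pattern the
    isotope term takes full credit (no evidence, no penalty).
    """
    mass_term = max(0.0, 1.0 - abs(candidate.ppm_error) / tol_ppm)
    if observed_pattern is None:
        iso_err = 0.0
    else:
        theo = candidate.theoretical_a1 or isotope_pattern(candidate.formula, 2).a1_ratio
        obs = observed_pattern.a1_ratio
        iso_err = abs(obs - theo) / theo if theo > 0 else abs(obs - theo)
    candidate.isotope_ratio_error = iso_err
    iso_term = 1.0 - min(1.0, iso_err / iso_tol)
    candidate.score = 100.0 * (0.5 * mass_term + 0.5 * iso_term)
    return candidate.score


def enumerate_formulas(mz: float,
                       adduct: Adduct,
                       tol_ppm: float = 5.0,
                       bounds: Optional[Dict[str, Tuple[int, int]]] = None,
                       observed_pattern: Optional[IsotopePattern] = None,
                       iso_tol: float = 0.10) -> List[FormulaCandidate]:
    """Exhaustively enumerate formulas matching ``mz`` within ``tol_ppm``.

    Returns candidates sorted by score (descending), ties broken by smaller
    |ppm error| then lexicographic Hill string.  All elements except H are
    iterated with mass-bound pruning; the H count is solved directly from the
    mass remainder, which keeps the search exact but fast.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    bounds = dict(bounds or DEFAULT_BOUNDS)
    if not bounds or all(hi <= 0 for _, hi in bounds.values()):
        raise ValueError("empty element bounds")
    for el, (lo, hi) in bounds.items():
        if lo > hi or lo < 0:
            raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")

    charge = abs(adduct.charge)
    neutral_target = mz * charge - adduct.mass_delta
    tol_da = mz * tol_ppm * 1e-6 * charge
    h_lo, h_hi = bounds.get("H", (0, 0))
    m_h = MONOISOTOPIC["H"]
    heavy = [(el, bounds[el]) for el in bounds if el != "H"]
    # pruning: the largest mass any suffix (plus H) can still add
    max_tail = [h_hi * m_h]
    for el, (_, hi) in reversed(heavy):
        max_tail.insert(0, max_tail[0] + hi * MONOISOTOPIC[el])

    out: List[FormulaCandidate] = []

    def emit(counts: Dict[str, int], mass: float) -> None:
        remainder = neutral_target - mass
        h_guess = int(round(remainder / m_h))
        for h in (h_guess - 1, h_guess, h_guess + 1):
            if h < h_lo or h > h_hi:
                continue
            neutral = mass + h * m_h
            if abs(neutral - neutral_target) > tol_da:
                continue
            full = dict(counts)
            if h:
                full["H"] = h
            formula = Formula(full)
            dbe = rdbe(formula)
            if not (RDBE_RANGE[0] <= dbe <= RDBE_RANGE[1]):
                continue
            c = formula.get("C", 0)
            if c == 0 or not (HC_RANGE[0] <= h / c <= HC_RANGE[1]):
                continue
            ion_mz = (neutral + adduct.mass_delta) / charge
            out.append(FormulaCandidate(
                formula=formula,
                ppm_error=(ion_mz - mz) / mz * 1e6,
                rdbe=dbe,
                theoretical_a1=isotope_pattern(formula, 2).a1_ratio,
            ))

    def recurse(idx: int, counts: Dict[str, int], mass: float) -> None:
        if mass > neutral_target + tol_da:
            return
        if mass + max_tail[idx] < neutral_target - tol_da:
            return
        if idx == len(heavy):
            emit(counts, mass)
            return
        el, (lo, hi) = heavy[idx]
        m_el = MONOISOTOPIC[el]
        for n in range(lo, hi + 1):
            new_mass = mass + n * m_el
            if new_mass > neutral_target + tol_da:
                break
            if n:
                counts[el] = n
            recurse(idx + 1, counts, new_mass)
        counts.pop(el, None)

    recurse(0, {}, 0.0)
    for cand in out:
        score_candidate(cand, observed_pattern, tol_ppm=tol_ppm, iso_tol=iso_tol)
    out.sort(key=lambda c: (-c.score, abs(c.ppm_error), c.formula.hill()))
    return out
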