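"""Rule-based flavonoid MS/MS interpretation and spectral matching.

Flavonoid product-ion spectra are interpreted with a curated neutral-loss
table: glycosidic/acyl conjugate cleavages (hexose C6H10O5 and relatives)
release the aglycone ion Y0, and chains of small losses (CO, CO2, H2O, CH3,
OH, CHO, ketene, prenyl) explain the aglycone's further fragmentation.
Ring-cleavage (retro-Diels-Alder / cross-ring) fragments are supplied per
flavonoid subclass as data, not code.  Labels follow the glycoconjugate
nomenclature: [M+H]+/[M-H]- for the precursor, [Y0+H]+/[Y0-H]- for the
aglycone ion, loss chains appended (e.g. "[Y0-H-CO-OH]-"), and ring
cleavages as "[0,3B0]-".

Spectral library matching scores a square-root-intensity-weighted cosine
similarity on peaks greedily paired within an m/z tolerance, scaled to
0-100; 70 is the customary acceptance threshold.  Identification confidence
is tiered screened -> tentative (rules + library) -> confirmed (retention
time and MS/MS against an authentic standard).
"""
from __future__ import annotations

import csv
import logging
from collections import deque
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import (
    ELECTRON_MASS,
    Formula,
    FormulaError,
    adduct_mz,
    get_adduct,
    monoisotopic_mass,
    rdbe,
)

__all__ = [
    "FragmentSpectrum",
    "NeutralLossRule",
    "RingCleavageRule",
    "FragmentAnnotation",
    "CandidateIdentification",
    "StandardEntry",
    "load_loss_rules",
    "load_ring_rules",
    "annotate_fragments",
    "is_flavonoid_like",
    "spectral_cosine",
    "library_match",
    "confirm_with_standard",
]

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_TOL = 0.02  # Da
MAX_LOSS_DEPTH = 3


@dataclass
class FragmentSpectrum:
    """A product-ion spectrum with its precursor m/z and polarity."""

    precursor_mz: float
    polarity: str  # "+" or "-"
    mz: np.ndarray
    intensity: np.ndarray
    rt: Optional[float] = None
    collision_energy: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")
        order = np.argsort(self.mz)
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size and self.precursor_mz < self.mz.max() - DEFAULT_FRAGMENT_TOL:
            raise ValueError("fragment m/z above precursor m/z")

    @property
    def peaks(self) -> List[Tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass(frozen=True)
class NeutralLossRule:
    """A named neutral loss; ``kind`` is 'small' or 'conjugate'."""

    name: str
    formula: Formula
    kind: str

    @property
    def loss_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class RingCleavageRule:
    """A subclass-specific ring-cleavage fragment (RDA / cross-ring)."""

    subclass: str
    label: str
    formula: Formula
    polarity: str  # "positive" | "negative"


@dataclass
class FragmentAnnotation:
    """A fragment peak explained by a chain of rules."""

    fragment_mz: float
    label: str
    mass_error: float
    rule_chain: Tuple[str, ...]


@dataclass
class CandidateIdentification:
    """A compound hypothesis with its evidence tier."""

    formula: Formula
    tier: str = "screened"  # screened | tentative | confirmed
    name: Optional[str] = None
    evidence: Dict[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class StandardEntry:
    """A registered authentic standard used for tier-confirmed IDs."""

    name: str
    formula: Formula
    adduct: str
    rt: float
    spectrum_id: str


def load_loss_rules() -> List[NeutralLossRule]:
    path = resources.files("flavoscreen.data").joinpath("neutral_losses.csv")
    rules = []
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            rules.append(NeutralLossRule(row["name"], Formula.parse(row["formula"]), row["kind"]))
    return rules


def load_ring_rules() -> List[RingCleavageRule]:
    path = resources.files("flavoscreen.data").joinpath("ring_cleavage.csv")
    rules = []
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            rules.append(RingCleavageRule(
                row["subclass"], row["label"], Formula.parse(row["formula"]), row["polarity"]))
    return rules


_SUGAR_NAMES = ("hexose", "deoxyhexose", "pentose", "acetylhexose")


def _plausible_residue(formula: Formula) -> bool:
    """Is the composition left after a loss a credible flavonoid fragment?"""
    c = formula.get("C", 0)
    h = formula.get("H", 0)
    if c < 4 or h < 1:
        return False
    if h / c < 0.3 or h / c > 3.1:
        return False
    return rdbe(formula) >= 0


def _infer_aglycone(precursor_formula: Formula, rules: Sequence[NeutralLossRule]) -> bool:
    """A precursor that cannot shed a sugar residue is treated as an aglycone."""
    for rule in rules:
        if rule.name not in _SUGAR_NAMES:
            continue
        try:
            residue = precursor_formula - rule.formula
        except FormulaError:
            continue
        if _plausible_residue(residue):
            return False
    return True


@dataclass
class _Node:
    mz: float
    formula: Formula
    chain: Tuple[str, ...]
    small_chain: Tuple[str, ...]
    depth: int
    aglycone: bool


def _node_label(node: _Node, polarity: str) -> str:
    sign = polarity
    core = ("Y0+H" if node.aglycone else "M+H") if polarity == "+" else \
           ("Y0-H" if node.aglycone else "M-H")
    losses = "".join(f"-{name}" for name in node.small_chain)
    return f"[{core}{losses}]{sign}"


def annotate_fragments(spec: FragmentSpectrum,
                       precursor_formula: Formula,
                       rules: Optional[Sequence[NeutralLossRule]] = None,
                       tol: float = DEFAULT_FRAGMENT_TOL,
                       subclass: Optional[str] = None,
                       ring_rules: Optional[Sequence[RingCleavageRule]] = None,
                       is_aglycone: Optional[bool] = None,
                       max_depth: int = MAX_LOSS_DEPTH) -> List[FragmentAnnotation]:
    """Explain fragment peaks by neutral-loss chains and ring cleavages.

    Loss chains are applied breadth-first from the theoretical precursor ion
    down to ``max_depth`` losses; conjugate (glycosidic/acyl) cleavages are
    only allowed as the first step and relabel the product as the aglycone
    ion Y0.  Each experimental peak is assigned the reachable node within
    ``tol`` having the shortest chain, ties broken by smaller |mass error|.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    rules = list(rules) if rules is not None else load_loss_rules()
    adduct = get_adduct("[M+H]+" if spec.polarity == "+" else "[M-H]-")
    theo_mz = adduct_mz(precursor_formula, adduct)
    if abs(theo_mz - spec.precursor_mz) > 0.05:
        raise ValueError(
            f"precursor m/z {spec.precursor_mz:.4f} inconsistent with "
            f"{precursor_formula.hill()} {adduct.name} ({theo_mz:.4f})")
    if is_aglycone is None:
        is_aglycone = _infer_aglycone(precursor_formula, rules)

    small_rules = [r for r in rules if r.kind == "small"]
    conjugate_rules = [r for r in rules if r.kind == "conjugate"]
    rule_index = {r.name: i for i, r in enumerate(small_rules)}

    nodes: List[_Node] = []
    root = _Node(theo_mz, precursor_formula, (), (), 0, is_aglycone)

    # conjugate cleavages from the precursor release the aglycone ion
    y0_nodes: List[_Node] = []
    if not is_aglycone:
        for rule in conjugate_rules:
            try:
                residue = precursor_formula - rule.formula
            except FormulaError:
                continue
            if not _plausible_residue(residue):
                continue
            y0_nodes.append(_Node(
                root.mz - rule.loss_mass, residue, (rule.name,), (), 1, True))
    nodes.extend(y0_nodes)

    # small-loss chains from the precursor and from every aglycone node;
    # chains are generated as non-decreasing rule-index combinations so each
    # loss multiset appears once
    queue = deque([root] + y0_nodes)
    while queue:
        node = queue.popleft()
        if node.depth >= max_depth:
            continue
        start = rule_index[node.small_chain[-1]] if node.small_chain else 0
        for rule in small_rules[start:]:
            try:
                residue = node.formula - rule.formula
            except FormulaError:
                continue
            child_mz = node.mz - rule.loss_mass
            if child_mz < 40.0:
                continue
            child = _Node(child_mz, residue,
                          node.chain + (rule.name,),
                          node.small_chain + (rule.name,),
                          node.depth + 1, node.aglycone)
            nodes.append(child)
            queue.append(child)

    labelled: List[Tuple[float, str, Tuple[str, ...], int]] = [
        (n.mz, _node_label(n, spec.polarity), n.chain, n.depth) for n in nodes
    ]

    # data-driven ring-cleavage fragments for the compound subclass
    ring_rules = list(ring_rules) if ring_rules is not None else load_ring_rules()
    want = "positive" if spec.polarity == "+" else "negative"
    if subclass:
        for rrule in ring_rules:
            if rrule.subclass != subclass or rrule.polarity != want:
                continue
            ring_mz = monoisotopic_mass(rrule.formula) + (
                ELECTRON_MASS if spec.polarity == "-" else -ELECTRON_MASS)
            labelled.append((ring_mz, f"[{rrule.label}]{spec.polarity}",
                             (f"ring:{rrule.label}",), 1))

    annotations: List[FragmentAnnotation] = []
    for peak_mz in spec.mz:
        best = None
        for node_mz, label, chain, depth in labelled:
            err = peak_mz - node_mz
            if abs(err) > tol:
                continue
            key = (depth, abs(err))
            if best is None or key < best[0]:
                best = (key, label, err, chain)
        if best is not None:
            annotations.append(FragmentAnnotation(
                float(peak_mz), best[1], float(best[2]), tuple(best[3])))
    return annotations


def is_flavonoid_like(annotations: Sequence[FragmentAnnotation],
                      rules: Optional[Sequence[NeutralLossRule]] = None) -> Tuple[bool, str]:
    """Does the annotated fragmentation look like a flavonoid?

    Evidence, any of: a glycosidic/acyl conjugate cleavage; at least two
    distinct small losses (CO, CO2, H2O, CH3, OH, ...) in the loss chains; a
    ring-cleavage fragment.
    """
    rules = list(rules) if rules is not None else load_loss_rules()
    kinds = {r.name: r.kind for r in rules}
    conjugates: List[str] = []
    smalls: set = set()
    rings: List[str] = []
    for ann in annotations:
        for name in ann.rule_chain:
            if name.startswith("ring:"):
                rings.append(name[5:])
            elif kinds.get(name) == "conjugate":
                conjugates.append(name)
            elif kinds.get(name) == "small":
                smalls.add(name)
    if conjugates:
        return True, f"glycosidic/conjugate loss ({conjugates[0]})"
    if rings:
        return True, f"ring cleavage ({rings[0]})"
    if len(smalls) >= 2:
        return True, "small-loss chain (" + ", ".join(sorted(smalls)) + ")"
    return False, "no flavonoid cleavage evidence"


def spectral_cosine(a: FragmentSpectrum, b: FragmentSpectrum,
                    mz_tol: float = DEFAULT_FRAGMENT_TOL) -> float:
    """Square-root-intensity-weighted cosine similarity, 0-100.

    Peaks are paired greedily by smallest m/z difference within ``mz_tol``,
    one-to-one.  The score is symmetric.
    """
    if a.mz.size == 0 or b.mz.size == 0:
        return 0.0
    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            d = abs(mza - mzb)
            if d <= mz_tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    num = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        num += np.sqrt(a.intensity[i] * b.intensity[j])
    den = np.sqrt(a.intensity.sum()) * np.sqrt(b.intensity.sum())
    return float(100.0 * num / den) if den > 0 else 0.0


def library_match(spec: FragmentSpectrum,
                  library: Sequence[FragmentSpectrum],
                  mz_tol: float = DEFAULT_FRAGMENT_TOL) -> List[Tuple[FragmentSpectrum, float]]:
    """Score a query spectrum against every library record, best first."""
    if not library:
        raise ValueError("empty spectral library")
    scored = [(rec, spectral_cosine(spec, rec, mz_tol)) for rec in library]
    scored.sort(key=lambda t: -t[1])
    return scored


def confirm_with_standard(candidate: CandidateIdentification,
                          standard: StandardEntry,
                          rt_observed: float,
                          spec: Optional[FragmentSpectrum],
                          reference_spectrum: Optional[FragmentSpectrum],
                          rt_tol: float = 0.4,
                          score_min: float = 70.0) -> CandidateIdentification:
    """Promote a candidate to tier 'confirmed' on RT + MS/MS agreement."""
    if reference_spectrum is None:
        logger.warning("standard %s has no reference spectrum; tier unchanged", standard.name)
        return candidate
    rt_ok = abs(rt_observed - standard.rt) <= rt_tol
    score = spectral_cosine(spec, reference_spectrum) if spec is not None else 0.0
    if rt_ok and score >= score_min:
        evidence = dict(candidate.evidence)
        evidence.update({"standard": standard.name, "rt_delta": rt_observed - standard.rt,
                         "standard_score": score})
        return replace(candidate, tier="confirmed", name=standard.name, evidence=evidence)
    return candidate
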