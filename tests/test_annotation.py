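"""MS/MS rule annotation, library matching and standard confirmation."""
import numpy as np
import pytest
from matchms import Spectrum as MatchmsSpectrum
from matchms.similarity import CosineGreedy

from flavoscreen.annotation import (
    CandidateIdentification,
    FragmentSpectrum,
    StandardEntry,
    annotate_fragments,
    confirm_with_standard,
    is_flavonoid_like,
    library_match,
    load_loss_rules,
    spectral_cosine,
)
from flavoscreen.chem import Formula, adduct_mz, get_adduct, monoisotopic_mass
from flavoscreen.synthetic import GeneratorConfig, generate_ms2_spectra


def _spec(precursor, polarity, mz, intensity=None, **kw):
    mz = np.asarray(mz, dtype=float)
    if intensity is None:
        intensity = np.full(mz.size, 100.0)
    return FragmentSpectrum(precursor, polarity, mz, np.asarray(intensity, float), **kw)


def test_genistin_aglycone_ion_from_hexose_loss():
    """The 271.0595 fragment is the aglycone ion released by loss of a
    hexose residue, C6H10O5, nominal mass 162."""
    spec = _spec(433.1135, "+", [271.0595])
    anns = annotate_fragments(spec, Formula.parse("C21H20O10"))
    (ann,) = anns
    assert ann.label == "[Y0+H]+"
    assert ann.rule_chain == ("hexose",)
    rules = {r.name: r for r in load_loss_rules()}
    assert rules["hexose"].formula.hill() == "C6H10O5"
    assert round(rules["hexose"].loss_mass) == 162


def test_genistein_loss_chain_and_ring_cleavage_labels():
    spec = _spec(269.0458, "-", [241.0506, 224.0492, 133.0301])
    anns = {round(a.fragment_mz, 4): a
            for a in annotate_fragments(spec, Formula.parse("C15H10O5"),
                                        subclass="isoflavone")}
    assert anns[241.0506].label == "[Y0-H-CO]-"
    assert anns[224.0492].label == "[Y0-H-CO-OH]-"
    assert anns[224.0492].rule_chain == ("CO", "OH")
    assert anns[133.0301].label == "[0,3B0]-"


def test_empty_spectrum_annotates_to_nothing():
    spec = _spec(269.0456, "-", [])
    assert annotate_fragments(spec, Formula.parse("C15H10O5")) == []


def test_inconsistent_precursor_is_rejected():
    spec = _spec(275.0, "-", [241.0506])
    with pytest.raises(ValueError):
        annotate_fragments(spec, Formula.parse("C15H10O5"))


def test_fragment_above_precursor_violates_spectrum_invariant():
    with pytest.raises(ValueError):
        _spec(269.0456, "-", [300.0])


def test_annotations_respect_tolerance_and_precursor_mass(panel):
    """Every annotation's |mass error| <= tol; no assigned node exceeds the
    precursor m/z."""
    for entry in panel:
        spec = _spec(entry.theoretical_mz, entry.polarity, entry.fragments)
        anns = annotate_fragments(spec, entry.formula, subclass=entry.subclass)
        for ann in anns:
            assert abs(ann.mass_error) <= 0.02
            assert ann.fragment_mz < entry.theoretical_mz
            assert ann.rule_chain


def test_all_panel_rows_look_flavonoid_like(panel):
    """The printed fragment lists carry flavonoid cleavage evidence for all
    18 screened compounds."""
    for entry in panel:
        spec = _spec(entry.theoretical_mz, entry.polarity, entry.fragments)
        anns = annotate_fragments(spec, entry.formula, subclass=entry.subclass)
        verdict, reason = is_flavonoid_like(anns)
        assert verdict, f"{entry.name}: {reason}"


def test_alkane_like_spectrum_is_not_flavonoid_like():
    # CH2-ladder fragments never match the flavonoid loss table
    spec = _spec(283.2995, "+", [57.0699, 71.0855, 85.1012, 99.1168])
    anns = annotate_fragments(spec, Formula.parse("C20H42"))
    verdict, reason = is_flavonoid_like(anns)
    assert not verdict
    assert "no flavonoid" in reason


def test_library_self_match_is_perfect_and_disjoint_is_zero(library):
    spec = library[0]
    assert spectral_cosine(spec, spec) == pytest.approx(100.0)
    other = _spec(500.0, spec.polarity, [401.17, 415.33], [100.0, 50.0])
    assert spectral_cosine(spec, other) == 0.0


def test_library_match_ranks_true_compound_first(panel, library):
    queries = generate_ms2_spectra(panel, GeneratorConfig(seed=9),
                                   rng=np.random.default_rng(9))
    for query in queries:
        hits = library_match(query, library)
        assert hits[0][0].name == query.name
        assert hits[0][1] >= 70.0


def test_library_match_requires_records(library):
    with pytest.raises(ValueError):
        library_match(library[0], [])


def test_cosine_is_symmetric_and_matches_matchms():
    rng = np.random.default_rng(3)
    for _ in range(5):
        mza = np.sort(rng.uniform(100, 400, 10))
        mzb = np.sort(np.concatenate([mza[:5] + rng.normal(0, 0.005, 5),
                                      rng.uniform(100, 400, 6)]))
        a = _spec(450.0, "-", mza, rng.uniform(10, 1000, 10))
        b = _spec(450.0, "-", mzb, rng.uniform(10, 1000, 11))
        ours = spectral_cosine(a, b)
        assert ours == pytest.approx(spectral_cosine(b, a), abs=1e-9)
        ref = CosineGreedy(tolerance=0.02).pair(
            MatchmsSpectrum(mz=a.mz, intensities=np.sqrt(a.intensity), metadata={}),
            MatchmsSpectrum(mz=b.mz, intensities=np.sqrt(b.intensity), metadata={}))
        assert ours == pytest.approx(float(ref["score"]) * 100.0, abs=1e-6)


def _genistein_standard(panel, library):
    entry = next(e for e in panel if e.name == "Genistein")
    std = StandardEntry("Genistein", entry.formula, entry.mode, entry.rt, "Genistein")
    ref = next(rec for rec in library if rec.name == "Genistein")
    return entry, std, ref


def test_confirmation_requires_rt_and_spectral_agreement(panel, library):
    entry, std, ref = _genistein_standard(panel, library)
    candidate = CandidateIdentification(formula=entry.formula, tier="tentative")

    confirmed = confirm_with_standard(candidate, std, entry.rt + 0.1, ref, ref)
    assert confirmed.tier == "confirmed" and confirmed.name == "Genistein"

    rt_off = confirm_with_standard(candidate, std, entry.rt + 1.0, ref, ref)
    assert rt_off.tier == "tentative"

    poor_spec = _spec(entry.theoretical_mz, "-", [150.0, 180.0])
    low_score = confirm_with_standard(candidate, std, entry.rt, poor_spec, ref)
    assert low_score.tier == "tentative"


def test_missing_reference_spectrum_leaves_tier_unchanged(panel, library, caplog):
    entry, std, ref = _genistein_standard(panel, library)
    candidate = CandidateIdentification(formula=entry.formula, tier="tentative")
    with caplog.at_level("WARNING"):
        out = confirm_with_standard(candidate, std, entry.rt, ref, None)
    assert out.tier == "tentative"
    assert any("reference spectrum" in rec.message for rec in caplog.records)


def test_shortest_chain_wins_label_conflicts():
    # 241.0506 sits within tolerance of both a depth-1 CO loss (error
    # 0.0001) and a depth-1 CHO loss (error 0.008); smaller error wins.
    spec = _spec(269.0456, "-", [241.0506])
    (ann,) = annotate_fragments(spec, Formula.parse("C15H10O5"))
    assert ann.rule_chain == ("CO",)
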