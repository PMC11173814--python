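"""Feature extraction and acceptance filtering on synthetic chromatograms."""
import numpy as np
import pytest

from flavoscreen.chem import get_adduct, isotope_pattern
from flavoscreen.formula_finder import enumerate_formulas
from flavoscreen.screening import (
    CentroidRun,
    Feature,
    Scan,
    ScreenConfig,
    extract_features,
    screen_feature,
)
from flavoscreen.synthetic import GeneratorConfig, generate_run


def _gaussian_run(apex=1000.0, noise=5.0, baseline=10.0, mz=300.1234, seed=0):
    rng = np.random.default_rng(seed)
    scans = []
    for t in np.arange(0.0, 4.0, 0.02):
        inten = apex * np.exp(-0.5 * ((t - 2.0) / 0.08) ** 2)
        inten += baseline + rng.normal(0.0, noise)
        scans.append(Scan(rt=float(t), mz=np.array([mz]),
                          intensity=np.array([max(inten, 0.0)])))
    return CentroidRun("+", scans)


@pytest.mark.parametrize("seed", range(5))
def test_single_gaussian_peak_yields_one_feature_with_expected_snr(seed):
    feats = extract_features(_gaussian_run(seed=seed))
    assert len(feats) == 1
    f = feats[0]
    assert f.mz == pytest.approx(300.1234, abs=1e-3)
    assert f.rt_apex == pytest.approx(2.0, abs=0.06)
    # apex 1000 over MAD-based noise sigma 5 -> S/N about 200 (+-30 %)
    assert 140 < f.snr < 260
    assert f.n_scans >= 3


def test_all_zero_run_has_no_features():
    scans = [Scan(rt=t, mz=np.array([]), intensity=np.array([]))
             for t in np.arange(0.0, 1.0, 0.02)]
    assert extract_features(CentroidRun("+", scans)) == []


def test_short_run_is_rejected():
    scans = [Scan(rt=0.0, mz=np.array([100.0]), intensity=np.array([60.0])),
             Scan(rt=0.1, mz=np.array([100.0]), intensity=np.array([60.0]))]
    with pytest.raises(ValueError):
        extract_features(CentroidRun("+", scans))


def test_panel_run_recovers_every_planted_compound(panel):
    """Each planted compound yields a feature within 0.02 Da / 0.4 min."""
    for polarity in ("+", "-"):
        run, truth = generate_run(panel, GeneratorConfig(seed=11), polarity)
        feats = [f for f in extract_features(run) if not f.is_isotope]
        assert len(feats) >= len(truth)
        for _, row in truth.iterrows():
            matches = [f for f in feats
                       if abs(f.mz - row["mz_true"]) <= 0.02
                       and abs(f.rt_apex - row["rt_true"]) <= 0.4]
            assert matches, row["name"]


def test_screening_recall_on_generator_defaults(panel):
    """At default noise, >= 95 % of planted compounds pass the gates."""
    cfg = ScreenConfig()
    passed = total = 0
    for seed in range(1, 11):
        for polarity in ("+", "-"):
            run, truth = generate_run(panel, GeneratorConfig(seed=seed), polarity)
            adduct = get_adduct("[M+H]+" if polarity == "+" else "[M-H]-")
            feats = [f for f in extract_features(run, cfg) if not f.is_isotope]
            for _, row in truth.iterrows():
                total += 1
                match = min(feats, key=lambda f: abs(f.mz - row["mz_true"])
                            + abs(f.rt_apex - row["rt_true"]))
                from flavoscreen.chem import IsotopePattern
                pattern = None
                if match.isotope_ratio_a1 > 0:
                    pattern = IsotopePattern(((0.0, 1.0), (1.003355, match.isotope_ratio_a1)))
                cands = enumerate_formulas(match.mz, adduct, cfg.ppm_tol,
                                           observed_pattern=pattern)
                if screen_feature(match, cands, None, cfg).passed:
                    passed += 1
    assert passed / total >= 0.95


def test_feature_count_invariant_under_intensity_rescaling(panel):
    run, _ = generate_run(panel[:4], GeneratorConfig(seed=3), "+")
    base = extract_features(run, ScreenConfig())
    scaled_scans = [Scan(rt=s.rt, mz=s.mz.copy(), intensity=s.intensity * 10.0)
                    for s in run.scans]
    scaled = extract_features(CentroidRun("+", scaled_scans),
                              ScreenConfig(min_intensity=500.0,
                                           trace_min_intensity=100.0))
    assert len(scaled) == len(base)


def _feature(mz=433.1135, rt=11.3):
    return Feature(mz=mz, rt_apex=rt, height=2000.0, area=100.0, snr=100.0,
                   isotope_ratio_a1=0.0, n_scans=20)


def test_screen_feature_passes_small_ppm_error():
    cands = enumerate_formulas(433.1135, get_adduct("[M+H]+"), 5.0)
    cho = [c for c in cands if c.formula.hill() == "C21H20O10"]
    verdict = screen_feature(_feature(), cho, None, ScreenConfig())
    assert verdict.passed and verdict.checks["ppm"]
    assert abs(cho[0].ppm_error) == pytest.approx(1.4, abs=0.1)


def test_screen_feature_fails_on_ppm_and_rt_gates():
    cands = enumerate_formulas(433.1135, get_adduct("[M+H]+"), 8.0)
    bad = [c for c in cands if abs(c.ppm_error) > 5.0]
    assert bad
    verdict = screen_feature(_feature(), [bad[0]], None, ScreenConfig())
    assert not verdict.passed and verdict.reason == "ppm"

    good = [c for c in cands if c.formula.hill() == "C21H20O10"]
    verdict_rt = screen_feature(_feature(rt=11.3 * 1.05), good, 11.3, ScreenConfig())
    assert not verdict_rt.passed and verdict_rt.reason == "rt"


def test_screen_feature_without_candidates_reports_no_formula():
    verdict = screen_feature(_feature(), [], None, ScreenConfig())
    assert not verdict.passed and verdict.reason == "no formula"


def test_relaxing_tolerances_never_shrinks_pass_set(panel):
    """Monotonicity: every feature passing strict gates passes looser ones."""
    run, _ = generate_run(panel, GeneratorConfig(seed=5), "-")
    adduct = get_adduct("[M-H]-")
    feats = [f for f in extract_features(run) if not f.is_isotope]
    strict = ScreenConfig(ppm_tol=3.0, score_min=80.0, isotope_ratio_tol=0.05)
    loose = ScreenConfig(ppm_tol=5.0, score_min=70.0, isotope_ratio_tol=0.10)
    for f in feats:
        from flavoscreen.chem import IsotopePattern
        pattern = None
        if f.isotope_ratio_a1 > 0:
            pattern = IsotopePattern(((0.0, 1.0), (1.003355, f.isotope_ratio_a1)))
        strict_cands = enumerate_formulas(f.mz, adduct, strict.ppm_tol,
                                          observed_pattern=pattern, iso_tol=strict.isotope_ratio_tol)
        loose_cands = enumerate_formulas(f.mz, adduct, loose.ppm_tol,
                                         observed_pattern=pattern, iso_tol=loose.isotope_ratio_tol)
        if screen_feature(f, strict_cands, None, strict).passed:
            assert screen_feature(f, loose_cands, None, loose).passed


def test_isotope_satellites_are_flagged(panel):
    run, truth = generate_run(panel, GeneratorConfig(seed=2), "+")
    feats = extract_features(run)
    satellites = [f for f in feats if f.is_isotope]
    assert satellites
    mains = [f for f in feats if not f.is_isotope]
    for sat in satellites:
        assert any(abs(sat.mz - (m.mz + k * 1.003355)) <= 0.02
                   for m in mains for k in (1, 2))
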