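# Methods

This note documents the models, defaults and design choices behind
flavoscreen, and what the synthetic-data tests do and do not demonstrate.

## Mass arithmetic

Molecular formulas are element-count maps serialized in Hill order.
Monoisotopic masses come from a packaged element table (IUPAC principal-
isotope masses and natural abundances for C, H, N, O, S, P) so results are
bit-stable.  Adduct m/z uses the proton mass 1.00727646688 Da for both
[M+H]⁺ and [M−H]⁻; this is identical to "hydrogen atom minus electron"
bookkeeping to 1e−8 Da.  m/z is carried at full precision internally and
rounded to 4 decimals (ppm errors to 1 decimal) only in reports.

One reference value in the packaged panel deserves a caveat: the printed
theoretical [M−H]⁻ of genistein (C₁₅H₁₀O₅) is 269.0456, but the mass
computes to 269.045547, which rounds to 269.0455.  No single element-mass
table reproduces both this cell and the rest of the panel (rounding H to
1.00783 fixes it but shifts the genistin cell); the package reports the
full-precision computation and does not force agreement with the printed
digit.  The same panel row's printed ESI mode "[M−H]⁺" is kept verbatim in
the fixture metadata while the loader exposes the corrected [M−H]⁻, which
the compound's negative-mode loss chemistry requires.

The isotope model is an aggregated nominal-mass pattern (A, A+1, A+2):
per-element distributions over nominal offsets are convolved exactly, with
each bin carrying its abundance-weighted mean mass offset.  Fine structure
within a bin is deliberately collapsed — the pattern only has to support a
10 % isotope-ratio gate.  Tests check it against an independent
binomial/multinomial oracle to 1 % absolute for up to 30 carbons.

## Formula enumeration and scoring

Enumeration iterates all elements except hydrogen with mass-bound pruning
and solves the H count from the mass remainder, which is exact and fast.
Defaults: C ≤ 40, H ≤ 60, N ≤ 5, O ≤ 20, S ≤ 2 (flavonoids are CHO; N and
S admit plausible interferences), tolerance 5 ppm.  Chemical filters
remove RDBE outside [0, 40] and H/C outside [0.2, 3.1]; carbon-free
candidates are excluded because H/C is undefined for them and the target
chemistry is organic.  The vendor "formula finder score" of the original
workflow is undocumented, so it is replaced by a transparent linear score

    score = 100 · (0.5·(1 − |ppm|/tol) + 0.5·(1 − min(1, iso_err/0.10)))

where iso_err is the relative error between the candidate's theoretical
A+1/A ratio and the observed one.  Without an observed pattern the isotope
term takes full credit: absence of evidence is not penalised.  Ties are
broken by smaller |ppm|, then lexicographic Hill string, so ordering is
deterministic.

## Feature extraction

Centroids are linked across scans into traces within ±0.02 Da; a trace may
skip up to 2 scans (baseline flicker around the 10-count trace-extension
threshold) and traces of the same channel are merged afterwards, so each
m/z channel yields exactly one chromatogram.  The vendor knobs "threshold
10 cps / intensity threshold 0.05" have no published semantics; they are
mapped to the 10-count trace-extension minimum and to the 0.05-of-apex
relative floor that bounds peak integration, and documented here as an
interpretation.  Peak detection runs on a 3-point moving average (single-
scan noise spikes are not chromatography) with prominence
max(10, 5·σ̂) where σ̂ is the robust (MAD) channel noise; peaks need ≥ 3
scans.  A feature is kept when apex ≥ 50 counts or S/N > 3, with
S/N = apex / (1.4826·MAD of the off-peak channel intensities).  The A+1
ratio is measured baseline-corrected (channel median) and averaged over
apex ± 1 scans; features one or two isotope spacings (1.003355 Da) above a
stronger co-eluting feature are flagged as satellites and excluded from
candidate identification.  The RT-error gate (< 2 % relative) applies only
when a reference RT exists; non-target discovery has none.

## Fragmentation rules

Losses are applied breadth-first from the theoretical precursor ion, at
most 3 chained losses, as order-free multisets; conjugate (glycosidic or
acyl) cleavages are allowed only as the first step and relabel the product
as the aglycone ion Y₀.  A precursor that cannot shed a sugar residue and
leave a plausible aglycone (C ≥ 4, H/C ≥ 0.3, RDBE ≥ 0) is itself treated
as the aglycone, so its spectrum is labelled from [Y₀±H]±.  The loss
table was audited against all 18 panel fragment lists and therefore goes
beyond the four textbook small losses: CO, CO₂, H₂O, CH₃, OH, CHO, ketene
(C₂H₂O) and prenyl (C₅H₉) as small losses; hexose, deoxyhexose, pentose,
acetylhexose (C₈H₁₂O₆), an acyl residue C₄H₆O₃ and acetic acid as
conjugate losses.  Ring-cleavage fragments are data, not code: a
per-subclass CSV maps e.g. the 5,7-dihydroxy-isoflavone skeleton to
[0,3B0]⁻ = C₈H₅O₂.  When several nodes explain one peak within the
0.02 Da tolerance, the shortest chain wins, then the smaller |mass error|.

A spectrum is *flavonoid-like* when any conjugate cleavage is annotated,
or a ring cleavage is annotated, or at least two distinct small losses
occur across the loss chains.  With the curated table this classifies all
18 panel fragment lists as flavonoid-like while an alkane-like spectrum
triggers nothing.

Library matching uses a cosine on √intensity-weighted peaks greedily
paired within 0.02 Da; the square root damps base-peak dominance and is
the common practice default (configurable by transforming intensities
before the call).  The score is symmetric and 100 for self-matches; 70 is
the acceptance threshold throughout.  Confirmation against an authentic
standard requires both |ΔRT| ≤ 0.4 min and a reference-spectrum match
≥ 70; either alone leaves the candidate tentative.

## Quantification

Calibration is least squares of area on concentration.  `fit_calibration`
defaults to simple (unweighted) regression; the pipeline fits 1/x²
weighted because the linear ranges span about two orders of magnitude with
multiplicative noise — unweighted OLS lets the top calibrators' absolute
scatter dominate the intercept and ruins back-calculation near the LOQ
(observed as >15 % low-end bias in simulation, versus ~CV with weights).
LOD = 3σ/slope and LOQ = 10σ/slope with σ the blank-area standard
deviation (n = 20 blanks in the generator).  Content follows

    content [µg/g] = conc [ng/mL] · volume [mL] · dilution / mass [mg]

with concentrations floored at zero below the intercept and flagged
against [LOQ, top of range].  Each sample is prepared at two dilutions
(1× and 5×); per analyte the least-diluted in-range result is used, and if
none is in range the most-diluted result is reported with its range flag —
one packaged batch content (daidzein, 107.55 µg/g) back-computes above the
linear-range top at both dilutions and is reported flagged rather than
suppressed.  Intra-day precision is the RSD of one day's replicates
(day 1 by default; replicate count is a config knob, default 6),
inter-day pools all days.  Spike recovery corrects the endogenous amount
proportionally to the actually weighed halved mass.

## Synthetic data: what it emulates and what it does not

Defaults (chosen once, as study conditions): per-scan m/z jitter 2 ppm,
RT jitter 0.05 min, Gaussian peak σ 0.08 min, scan interval 0.02 min,
channel baseline 10 counts with σ 5 (giving S/N ≈ 200 for a 1000-count
apex), compound abundance 2000 counts, 10 random noise centroids per scan,
area CV 2 %, 10 calibration levels spanning each analyte's linear range,
QC at low/mid/high over 3 days × 6 replicates, repeatability n = 6 and
1:1 spike recovery n = 6 on the second batch, blank noise calibrated so
3σ/slope returns the target LOD.  One RNG stream per dataset; a fixed seed
reproduces byte-identical outputs.  Compounds sharing an m/z channel
(isomers) share one detector channel and hence one baseline.

Not modelled: chromatographic tailing, matrix ion suppression, detector
saturation, profile-mode peaks, mass-axis drift.  Passing tests therefore
demonstrate the correctness of the algorithms and their statistics under
idealised Gaussian chromatography, not robustness to real instrument
artefacts.  Fragment m/z values in synthetic MS/MS spectra are the
panel's printed values with ppm-scale jitter, so library matching on this
fixture is easier than against heterogeneous public libraries.

Simulation sizes used by the test suite — 20 seeds for the end-to-end
identification check, 50 seeds for the quantification statistics, 100
random masses for the enumeration oracle — keep the full suite around
half a minute while leaving the Monte-Carlo assertions comfortably
powered.  The quantification recovery checks run at 2 % area CV; at 3 %
the per-seed mean spike recovery (n = 6, with measurement noise entering
through both the found and endogenous terms) has σ ≈ 2.4 %, so a
94–106 % band can no longer hold every seed — accuracy assertions are
therefore phrased on per-seed means and across-seed averages, which the
noise-free limit pins exactly (slopes, intercepts, contents and recovery
reproduce to 1e−9 relative).

## Known limitations

- Only [M+H]⁺ / [M−H]⁻ singly charged adducts; others are extension
  points.
- The isotope gate uses the A+1 ratio alone; A+2-rich elements (Cl, Br)
  are outside the element table's scope.
- Ring-cleavage labels implement the cited nomenclature convention, but
  the exact bond numbering per flavonoid subclass is the rule table's
  responsibility, not derived from structures.
- Positional isomers (e.g. the three C₁₅H₁₀O₆ flavones) are
  distinguishable only by retention time against standards, as in the
  source workflow; biogenesis-based reasoning is not implemented.
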