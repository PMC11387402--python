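# Methods

## Lipid chemistry

Lipid classes are represented by linear sum-composition formula rules:
each element count is `a + b·n + c·d` in the total acyl carbons `n` and
total double bonds `d`. These rules are the unique compositions
consistent with the class backbone plus fatty-acyl condensation
(backbone + Σ CnH(2n−2d)O₂ − one H₂O per ester bond), e.g.
lysophosphatidylcholine C(n+8) H(2n+18−2d) N O₇ P from
glycerophosphocholine C₈H₂₀NO₆P, and are validated in the test suite
against that condensation oracle and against literature formulas of the
spiked internal standards (PC(14:0/14:0) = C₃₆H₇₂NO₈P, SM(d18:1/12:0) =
C₃₅H₇₁N₂O₆P, trimyristin C₄₅H₈₆O₆, …). For the sphingolipids (SM, Cer)
the double-bond count includes the sphingoid 4,5-ene.

Monoisotopic masses use CODATA/NIST atomic values (C 12, H 1.00782503,
O 15.99491462, N 14.00307400, P 30.97376163, Na 22.98976928,
D 2.01410178). Adduct m/z is (M + Δ)/|z| with electron-corrected shifts;
[M+H]⁺ adds the proton mass 1.00727647 Da. Deuterium labels (`D4-`,
`D7-`) substitute protium atoms, shifting mass by k·(m_D − m_H).

Default grids (configurable in `src/aldlipid/data/lipid_classes.yaml`):
1-radyl classes n ∈ [10, 30], 2-radyl [20, 60], 3-radyl [30, 80],
4-radyl (cardiolipin) [40, 80], d ∈ [0, 12]. Default adduct sets are
[M+H]⁺/[M+Na]⁺ for choline lipids, [M+NH₄]⁺/[M+Na]⁺ for neutral
glycerides and cholesterol esters, [M−H]⁻ (plus [M+HCOO]⁻ where
configured) for acidic phospholipids; the instrument method, not
chemistry, dictates these, so they are configuration, not fixed truth.
m/z is carried at full precision and reported to 4 decimals; comparisons
with unit-resolution MRM settings round to 2 decimals. The computed
[M+H]⁺ of D4-LPC(26:0) is 640.52, while triple-quadrupole methods
commonly print 640.50; no agreement is forced beyond 2-decimal rounding
of the unlabeled precursor.

## Annotation

Candidate identities are all catalog entries within a ppm window
(default 5 ppm, relative to the query m/z) and matching polarity, with
optional per-class retention-time windows. Exactly one hit is accepted
per feature: smallest |ppm error|, ties broken by adduct priority
([M+H]⁺ > [M+NH₄]⁺ > [M+Na]⁺ > [M−H]⁻ > [M+HCOO]⁻) then lexicographic
species name. Unmatched features are retained with an `accepted=False`
flag. Positional isomers (1-acyl vs 2-acyl LPC) share m/z and are
distinguished only by an optional isomer tag. Supplementary-style tables
keyed by lipid name bypass mass lookup; unparseable row labels go to a
rejects report.

## Semi-quantification

Abundance = (analyte area / class IS area) × (IS amount / plasma
volume). With the study's spike list (e.g. 0.5 nmol LPC(14:0) and
2.0 nmol PC(14:0/14:0) per 20 µL plasma) the base scale is nmol/µL
(≡ mmol/L); output is labeled A.U. with a configurable unit scale, since
per-class response factors are not calibrated. Because the analyte and
IS areas share the sample, any per-sample multiplicative response drift
cancels exactly. A missing or nonpositive IS area flags the (class,
sample) cell and propagates NaN — values are never zero-filled or
imputed. The targeted assays are isotope dilution: concentration =
area ratio × amount / volume; for LPC(26:0) the default spec is 0.01
nmol D4-LPC(26:0) per 10 µL plasma (10 µL of a 1 µmol/L spike), so an
area ratio of 0.072 sits at the 72 nmol/L healthy upper reference limit.
The exact plasma-equivalent IS concentration of that extraction protocol
is ambiguous in print, so it is exposed as configuration.

## Stratification

Males: CALD vs noCALD (all ages and > 55), AI vs noAI (all ages and
> 55), spinal-cord severity severe (EDSS > 6, any age) vs mild > 55
(EDSS ≤ 6). Age "> 55" is strict, EDSS exactly 6 is mild. Patients
without an EDSS score leave only the spinal-cord contrast, with a log
message. Females: among women strictly over 40, severe = EDSS > 6 by
default; an alternative "presence" rule (any spinal cord disease,
EDSS > 0) is selectable, since the clinical definition and the
figure-level EDSS cut coexist in the source material. Strata within one
contrast partition their eligible population; stratification is
deterministic and idempotent.

## Statistics

Per lipid and contrast: Shapiro–Wilk at α = 0.05 in each group routes to
Welch's t (both normal-looking) or Mann–Whitney U (otherwise; also
forced, with a warning, when a group has n < 3 or zero spread). The U
test uses the exact null for min(n) ≤ 8 without ties and the
tie-corrected normal approximation otherwise. Multi-group comparisons
use tie-corrected Kruskal–Wallis with hand-rolled Dunn z-tests on pooled
mean ranks (variance N(N+1)/12 − Σ(t³−t)/(12(N−1))), BH-adjusted within
the pairwise family. Fold change is the ratio of raw-scale group means
with the second group as reference — this convention reproduces the
published fold changes from the published group means to the printed
precision, which is the cross-validation that fixed it. BH (plus
Bonferroni and Holm, reported) is applied per contrast across all
testable lipids. Volcano labels use FC > 1.5 (or < 1/1.5) together with
BH-adjusted p < 0.05; the significance axis is the raw p, matching the
usual plot, while the counts use the adjusted p. Tests run on raw
abundances by default with a log2 toggle; PCA/PLS-DA always log2-
transform and center (PCA by full SVD; PLS-DA via NIPALS-based
`PLSRegression` on one-hot labels, 2 components). Constant lipid rows
are dropped from projections with a warning.

## Chain profiling

Per class, log₂ fold change is plotted against total acyl carbons and
smoothed by LOESS: tricube weights over the nearest ⌈span·n⌉ points,
local polynomial of degree 2, defaults span 0.75 — common smoother
defaults; only the curve family is fixed by the upstream convention.
Only chain length is smoothed; the saturation heatmap carries raw
per-(n, d) log₂FC values with no resmoothing. Two monotonicity
statistics are reported: Spearman of the fitted curve against the carbon
grid (descriptive; smoothing concentrates noise into few effective
degrees of freedom, so it is *not* null-calibrated) and Spearman of the
raw points against carbons (sd ≈ 1/√(n−1) under a null), which is the
one to use for inference-flavored checks.

## Synthetic data

The generator defines the study conditions used throughout the tests:

* **Rosters.** Deterministic rosters reproduce the stratification table
  exactly: 92 males (24 CALD / 68 noCALD with 21 over 55; 50 AI / 42
  noAI with 20 over 55; 17 mild > 55 / 15 severe) and 65 females (28
  mild / 26 severe among the 54 over 40), plus 12 healthy controls per
  sex.
* **Lipidome.** Baseline log2 abundances are Gaussian per class;
  patients add a planted effect log₂FC = β·max(0, n − n₀)·s(d) with
  s(d) = max(0, 1 − d/d_max) — the hinge mirrors the observation that
  elevation starts beyond ~20 carbons per acyl chain (n₀ = 20·radyl
  count) and shrinks with unsaturation. Default β = 0.15/carbon and
  multiplicative noise CV = 0.2, a typical plasma-lipidomics technical
  plus biological spread. The study-scale configuration plants the
  printed differential summary as ground truth: 1556 lipids across 12
  classes, the 421 highest hinge scores elevated (log₂FC ≥ 0.9), 45
  short polyunsaturated TG lowered (log₂FC = −1.2), the rest null.
* **Feature level.** Optionally each lipid becomes an LC-MS feature at
  its theoretical adduct m/z with Gaussian ppm jitter (default 1 ppm),
  areas scaled by a per-sample lognormal response factor shared with the
  IS areas, so the annotate → semi-quantify path must reproduce the
  abundances exactly up to one global factor.
* **XCI coupling.** LPC(26:0) = 85 + 400·x + ε with x ~ U(0, 1) the XCI
  fraction toward the variant allele and sd(ε) solved in closed form so
  the population Pearson r equals the 0.79 target:
  sd(ε) = slope·sd(x)·√(1/r² − 1).
* **Post-HCT decay.** C(t) = P + (C₀ − P)e^(−kt) with C₀ ~ N(435, 85²)
  nmol/L; P = 185.5 and k = 0.167/month are the closed-form solution of
  the printed mean trajectory 435 → 219 (12 mo) → 190 (24 mo), and
  per-patient lognormal effects keep the plateau strictly above the
  72 nmol/L healthy upper limit.
* **Targeted assays.** Lognormal samples around the printed per-stratum
  means (log-sd 0.32, consistent with the printed ranges), with an
  LPC–C26:0 Gaussian copula whose within-group correlation is solved
  analytically so the pooled latent correlation maps (Spearman =
  (6/π)·asin(ρ/2)) to the 0.7 target after accounting for the
  between-group collinearity of the configured means.

All randomness flows from a single seed through spawned
`SeedSequence` children; regeneration is bit-identical.

What the generator does *not* emulate: retention-time structure, adduct
multiplicity and in-source fragmentation, missingness/limit-of-detection
censoring, correlated lipid co-regulation, age/sex covariate effects,
and longitudinal within-patient correlation outside the HCT model.
Passing tests therefore demonstrate correctness of the computations and
calibration under the assumed structure, not robustness to those
real-data complications.

## Numerical choices and degenerate inputs

* Catalog queries window on |m/z − q| ≤ q·tol·10⁻⁶ via binary search,
  verified equivalent to a linear scan.
* Welch with two constant equal groups returns (0, 1); Mann–Whitney on a
  fully constant pooled sample returns p = 1; correlations of constant
  vectors return NaN with a warning rather than raising mid-pipeline.
* BH/Holm/Bonferroni reject p outside [0, 1].
* LOESS needs ≥ degree + 2 distinct x; exactly coincident neighborhoods
  fall back to averaging the coincident points; fits with fewer than 3
  class members return an empty trend with a warning.
* Lipids with < 2 observed values in a group are excluded from that
  contrast only, logged; missing abundances are NaN, never 0.
* Fold change with a nonpositive reference mean is NaN, flagged.

## Test problem sizes

The default suite exercises the study-scale lipidome (1556 × 104) once,
the null calibration at 200 replicates of 300 lipids × 40 samples, XCI
calibration at 500 replicates of n = 28, and decay-rate recovery over 20
simulated cohorts of 12 patients; these sizes give stable Monte-Carlo
means (binomial/standard errors quoted in the tests) while keeping the
whole suite in the low minutes.

## Known limitations

* Formula rules cover the 16 configured diacyl/triacyl classes; ether
  (O-/P-) lipids and hydroxylated sphingolipid variants are parsed but
  not expanded.
* One accepted identity per feature; overlapping isobars within the
  ppm window are resolved by rank, not deconvolved.
* Semi-quantification assumes response factor 1 vs the class IS, which
  is why outputs are A.U.; only the isotope-dilution assays yield
  concentrations.
* PLS-DA scores are descriptive; no cross-validated classification or
  permutation testing of components.
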