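# Methods

This note documents the conventions, default parameters and design choices
behind each analysis stage, and what the synthetic generator does and does
not emulate.

## Units and ion metadata

All charge-based quantities are computed in milliequivalents per liter:
`meq/L = mg/L × |charge| / molar mass`, with fixed IUPAC molar masses
(K 39.098, Na 22.990, Ca 40.078, Mg 24.305, Cl 35.453, SO₄ 96.06,
HCO₃ 61.016, CO₃ 60.008, NO₃ 62.004 g/mol). A missing CO₃ column is treated
as 0 mg/L — appropriate for the near-neutral, HCO₃-dominated waters the
toolkit targets. Total hardness uses the CaCO₃-equivalent convention
TH = 2.497·Ca + 4.118·Mg (equivalently, 50.04 mg CaCO₃ per meq).

## QC and categorical splits

The charge balance error is the signed percentage imbalance between cation
(K, Na, Ca, Mg) and anion (Cl, SO₄, HCO₃, CO₃, NO₃) equivalents; |CBE| ≤ 5 %
is the acceptance band. Threshold classifiers are lower-bound inclusive on
the named range: TDS = 1000 mg/L is brackish, TH = 150 mg/L is hard, and
well depths fall in shallow [0, 20] m, middle (20, 50] m, deep > 50 m.
Exceedance screens (nitrate > 20 mg/L, HQ > 1) are strict.

Descriptive statistics use the sample (n−1) standard deviation — the
conventional choice for survey data — and report CV = SD/mean rounded to
two decimals.

## Facies and source attribution

- **Piper coordinates.** Cation fractions (Ca, Mg, Na+K) and anion fractions
  (HCO₃+CO₃, SO₄, Cl) as percent of their class meq totals. The diamond
  point is the intersection of the +60° ray from the cation ternary point
  and the +120° ray from the anion ternary point, on unit triangles
  separated by a 0.2-unit gap.
- **Shchukarev labels.** All ions holding ≥ 25 % of their class meq total
  (the classical inclusion threshold), anions before cations, each ordered
  by decreasing fraction; K is grouped with Na and CO₃ with HCO₃.
- **Gibbs regions.** The mechanism envelopes of the classical figure are
  drawn by eye in the literature; the defaults here are rectangular
  approximations (rock: TDS 70–1000 mg/L and ratio ≤ 0.7; precipitation:
  TDS < 70 and ratio ≥ 0.5; evaporation: TDS > 1000 and ratio ≥ 0.5;
  otherwise "outside", which in practice flags anthropogenically disturbed
  samples). The classification is advisory; the ratios themselves are the
  primary output. Ratios are computed on meq/L (configurable in principle
  to mg/L; the meq basis is the dominant convention).
- **Cation exchange.** CAI-I and CAI-II follow Schoeller's definitions.
  Both indices share the numerator Cl − (Na+K), so they agree in sign
  whenever defined; numerators within 1e-12 relative of zero are treated as
  balanced to avoid floating-point sign flips. The exchange-line slope is
  the OLS fit of (Mg+Ca−SO₄−HCO₃) on (Na+K−Cl); a slope near −1 indicates
  alternate cation adsorption.
- **Correlation screen.** Pearson r with two-sided p-values from the
  t-transform (n−2 df); stars mark p < 0.10 / 0.05 / 0.01. No
  multiple-testing correction is applied, matching common practice for
  exploratory hydrochemical matrices.

## Water quality index

The default weight/standard table covers pH, TDS, TH, Ca, Mg, Na, K, Cl,
SO₄, HCO₃ and NO₃ with integer weights {4,4,3,3,3,3,2,4,4,2,5}. Standards
follow the Chinese class-III groundwater limits where defined (pH 8.5 upper
bound, TDS 1000, TH 450, Na 200, Cl 250, SO₄ 250 mg/L, NO₃ 20 mg/L as
reported) and common drinking-water guideline values otherwise (Ca 75,
Mg 50, K 12, HCO₃ 250 mg/L). Nitrate carries the largest weight, consistent
with it being the dominant quality driver in agriculturally affected
aquifers. The table is entirely user-overridable.

pH needs a convention because a raw C/S ratio rewards acidic water: by
default its rating is |pH − 7| / (S_pH − 7), so neutral water scores 0 and
the rating reaches 1 at the permissible bound; a plain-ratio mode is
available. Parameters missing from a sample are dropped with the remaining
weights renormalized. Effective weights always sum to 100 % by
construction; for the degenerate all-zero water they fall back to the
relative weights.

## Irrigation suitability

SAR, %Na and RSC are computed exactly as defined above on meq/L. %Na is
reported as a percentage (×100). Band edges are lower-bound inclusive:
SAR <10/10–18/18–26/>26 and %Na <20/20–40/40–60/60–80/>80.

The Wilcox diagram's five regions are published only as a drawing; the
defaults here are straight-edge polygons (EC up to 1000/2000/3000/3500
µS/cm with %Na ceilings falling from 80/90/95/100 to 20/25/25/30) chosen to
respect the qualitative geometry. Better classes use strict interior
containment, so a boundary point falls to the more cautious class; points
outside all polygons are "unsuitable".

USSL salinity classes are C1 <250, C2 250–750, C3 750–2250, C4 >2250 µS/cm.
Sodium classes default to the fixed SAR bands above; a sloped mode
interpolates the S-boundaries linearly in log₁₀(EC) from (100 µS/cm:
10/18/26) to (5000 µS/cm: 2.5/6.5/11), approximating the original sloped
lines. When EC is unmeasured it is estimated as TDS/0.64 and flagged.

## Nitrate health risk

Default exposure parameters (all config-overridable), drawn from the
Chinese exposure-factors literature: RfD = 1.6 mg/(kg·day), EF = 365 d/a,
AT = ED × 365, and (IR L/d, BW kg, ED a) of infant (0.6, 9, 1), child
(1.0, 20, 10), teenager (1.4, 50, 8), adult (1.5, 60, 30). With these
defaults E reduces to C·IR/BW, so the group risk ordering is fixed by IR/BW
— infant > child > teenager > adult. Nitrate is used exactly as reported;
a `nitrate_basis="as_n"` option applies the 4.427 NO₃/N mass conversion for
datasets reported as nitrate-N. Reproducing any specific campaign's
absolute HQ values requires that campaign's own exposure table.

Monte Carlo propagation varies C, BW and IR as independent draws (no
copula): C lognormal moment-matched to the cohort's nitrate mean/SD, BW and
IR truncated-normal at ±15 % and ±20 % relative SD by default. Draws are
seeded (`numpy.random.default_rng`), negative draws are rejected and
resampled with a bounded retry budget, and a run with all three inputs
degenerate reproduces the deterministic dose chain bit for bit. Summaries
report mean, SD, the 5/25/50/75/95 percentiles and P(HQ > 1).

## Synthetic survey generator

The generator emulates a tropical-island groundwater campaign: right-skewed
major-ion concentrations (survey CVs of 0.75–1.61 imply right skew, hence
lognormal marginals for ions and TDS), pH truncated-normal within the
observed range [5.11, 9.37], a depth mix of 50/30/20 % shallow/middle/deep
wells uniform within (3.5–20 / 20–50 / 50–340 m), EC derived as TDS/0.646
(the fresh-groundwater conductance factor implied by the default targets),
and four dependence targets: Pearson r of 0.92 (Na–Cl), 0.78 (Ca–HCO₃),
0.70 (Mg–HCO₃) and 0.71 (NO₃–K).

Because the targets are *sample* statistics of a finite survey, the
generator matches them as sample statistics rather than population moments:

1. Latent standard normals are empirically whitened and recolored so their
   sample correlation equals the requested latent matrix exactly.
2. Marginal parameters are solved against the realized latent draws
   (Brent's method on the lognormal σ; a 2-d root solve for the truncated
   normal), making each sample mean and SD exact before repair.
3. Latent correlations start from the closed-form lognormal inversion
   r = (e^{ρσ₁σ₂} − 1)/√((e^{σ₁²} − 1)(e^{σ₂²} − 1)) (quadrature + secant
   for other margin pairs). Pinning unspecified pairs at zero can make the
   target set infeasible (two strong links to one analyte), so a
   constrained positive-definite completion holds the target entries and
   frees the unspecified ones.
4. A fixed-point loop (≤ 10 rounds) regenerates, applies charge-balance
   repair, measures the post-repair means/SDs/correlations and adjusts the
   pre-repair targets and latent entries until everything matches; this is
   what lets the *repaired* dataset still hit every target.

Charge-balance repair defaults to proportional mode — cations × s, anions
÷ s with s² = Σan(1+t)/(Σcat(1−t)), which moves a violating sample just
inside the tolerance band while preserving intra-class ion ratios and the
dependence structure. The classical single-ion convention (rescale Na or
Cl, whichever needs the smaller relative change) is available per sample
via `cbe_repair` and as `repair_mode="single_ion"`; it is not the bulk
default because re-deriving one ion from the charge budget of eight others
destroys the Na–Cl correlation the generator is required to reproduce.
Samples irreparable within nonnegativity are flagged and kept.

Below ~30 samples the generator falls back to plain population moment
matching (sample statistics are too noisy to pin down).

**What passing tests show — and don't.** The generator reproduces the
marginal moments, four correlations, charge balance, pH range and depth
structure of a real campaign, so downstream code is exercised on
realistically scaled, realistically skewed, QC-clean data. It does not
emulate spatial structure, geology- or depth-conditioned chemistry,
seawater-intrusion mixing, censored detection limits, or the full
correlation matrix of real data (unspecified pairs are only constrained to
feasibility, not to field values). Cohort-level results on synthetic data —
mean WQI, exceedance percentages, HQ means — are therefore properties of
the configured conditions, not estimates for any real aquifer.

## Numerical choices

- Moment inversions: lognormal σ² = ln(1 + (SD/mean)²); truncated-normal
  targets are rejected when the SD exceeds the uniform-distribution limit
  (b−a)/√12, with the analyte named in the error.
- Repair targets sit at 0.999 × tolerance so repaired samples survive a
  subsequent |CBE| ≤ tolerance check despite rounding.
- Undefined ratios (zero denominators) yield NaN flags, never exceptions,
  except where an entire construct is meaningless (zero ionic strength).
- Band classifiers are total: every finite input maps to exactly one class.
- Reproducibility: all randomness flows from `numpy.random.default_rng`
  seeds carried in the configs; identical config ⇒ byte-identical outputs.

## Problem sizes used in validation

The test suite validates generator recovery at n = 10,000 (3 % mean / 5 %
SD / ±0.05 correlation tolerances), oracle equivalence of the irrigation
indices on 1,000 random samples, WQI normalization over 1,000 random weight
tables, and Monte Carlo consistency at 10,000 iterations; the acceptance
script analyses the default 63-well survey and the same 10,000-sample
recovery check. The full suite runs in well under a minute on one CPU.

## Known limitations

- Wilcox/Gibbs region boundaries are documented approximations of figures
  that have no canonical algebraic form.
- The WQI weight table and exposure parameters are literature defaults;
  campaign-specific results require the campaign's own tables.
- The USSL sloped mode linearizes the S-boundaries in log EC.
- No carcinogenic (slope-factor) risk, dermal/inhalation pathways,
  industrial-use index, or geospatial interpolation.
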