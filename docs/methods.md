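# Methods

`guanofe` computes a nutrient mass budget: how much iron a chinstrap penguin
(*Pygoscelis antarcticus*) colony accumulates in its guano, what fraction of
that iron reaches the adjacent coastal water, how the budget scales to the
global population over a year, and how much phytoplankton primary production
the released iron could sustain in iron-limited (HNLC) Southern Ocean waters.
The pipeline is a chain of products and quotients of measured quantities;
the modelling content lies in which quantities enter, how their
uncertainties propagate, and which conservative assumptions bound the
result.

## Uncertain quantities and propagation

Every stage works on `UncertainQuantity` — a non-negative value, a standard
deviation and a unit tag. Units convert by exact rational factors
(1 t = 10³ kg = 10⁶ g, 1 m³ = 10³ L), so round-trip conversions are
identities, not approximations.

Two propagation rules are available for products/quotients of independent
factors:

- **first-order (default)**: relative variances add,
  `(σ/µ)² = Σ eᵢ² (σᵢ/µᵢ)²`. This is the delta method; it is exact for the
  value and a good sd approximation below ~20 % relative sd.
- **Monte-Carlo**: each factor is drawn from a normal truncated at zero
  (concentrations, counts and masses cannot be negative), default 10⁵ draws,
  default seed 20230411. Truncation shifts a factor's mean up by
  `(σ/µ)·φ(µ/σ)/Φ(µ/σ)`; at the guano-Fe relative sd of 47 % this is +1.9 %,
  and it is documented rather than corrected — the truncated distribution
  *is* the assumed sampling model. In the small-sd limit (≤5 % relative) the
  two rules agree within Monte-Carlo standard error, which the tests check
  at 1 % relative sd.

No covariance is tracked between stages: all printed ± values in the
reports assume independent factors. Report values are rounded
half-away-from-zero to conventional precision only at output time; internal
arithmetic is full double precision.

## Census

The colony splits into guano-rich zones (GRZ), where breeders cluster at
~0.52 ind m⁻², and outer zones (OZ) at ~0.028 ind m⁻². Only part of the
colony is photographed at detection-capable resolution; its zone counts give
per-class densities (pooled counts over pooled areas when several zones per
class are surveyed), which transfer to same-class unsurveyed zones
(`count = density × area`). Cross-class transfer is an error, not a warning
— GRZ and OZ densities differ by a factor ~20, so a silent mix-up would
dominate the budget. The colony total sums zone counts with sds combined in
quadrature under independence; the reference census's printed total
uncertainty (±907) is larger than the quadrature of its printed zone sds
(≈513), so total sds are reported as computed and not asserted against that
value. Counts stay real-valued internally and round to whole birds only in
reports.

Zone areas may be given in m² or as GeoJSON polygons in a projected metric
CRS (planar shoelace area via shapely). Degree coordinates are heuristically
rejected: a footprint inside the ±360 coordinate range that spans less than
0.1 units in both axes is almost certainly lon/lat (a genuine metric zone is
never sub-decimetre across; a genuine degree footprint of a colony zone
always is).

## Accumulation: two independent routes

**Volumetric**: the mapped GRZ guano layer (area × 2 cm representative
thickness, or a directly supplied volume) × wet density 1088.6 kg m⁻³ ×
dry-weight fraction w = 0.4 gives dry mass; × Fe concentration
3.0 ± 1.4 mg g⁻¹ gives the Fe pool.

**Individual-excretion**: census total × 84.4 g dry guano bird⁻¹ day⁻¹ ×
120 breeding days × the same Fe concentration. The excretion rate is already
dry mass, so w applies *only* in the volumetric route — the routes would
otherwise disagree by 2.5×.

For the reference colony the routes agree within 2.3 % (165.5 vs 169.4 t dry
guano); their pooled Fe mean (≈502 kg as computed; 506 kg from the printed
rounded pools) feeds the discharge stage. The Fe concentration's 47 %
relative sd dominates every downstream uncertainty.

## Discharge

The receiving water volume is a cuboid bounded by the turbidity plume:
4 × 10⁴ m² × 2 m mean depth = 8 × 10⁴ m³, at the sampled 0.324 mg Fe L⁻¹ →
25.92 kg Fe (no seawater-density correction; mg L⁻¹ → kg via 1 m³ = 10³ L).
Release efficiency is water inventory / colony pool; it is scale-invariant
and values above 1 (possible under user sensitivity settings, impossible for
a real snapshot) warn rather than fail.

Efficiency bounds combine both accumulation routes by intersecting their
±1 sd intervals: the low bound divides by the smallest value+sd among the
pools, the high bound by the largest value−sd — the pool range consistent
with both routes at once. With a single pool this degenerates to the pool's
own interval. If value−sd ≤ 0 for the binding pool the upper bound is
undefined and an error is raised.

## Annual budget

The year splits into a 120-day breeding season (colony-resident; a
conservative 10 % of produced Fe assumed washed to sea) and a 245-day
non-breeding season (at-sea foraging near the receding pack ice; 100 %
release assumed). Production in both periods is population × excretion rate
× days × Fe concentration. The default global population of 8.0 × 10⁶
individuals is derived by inverting the budget against a 24.5 t
breeding-season release at 10 % efficiency
(24.5 t / 0.10 / (84.4 g × 120 d × 3.0 mg g⁻¹) ≈ 8.06 × 10⁶); it is a
required config field, not a constant. The efficiency applies to Fe —
equivalently to guano, since the concentration is constant across periods.

## Iron-stimulated NPP

Released Fe R_Fe is reduced by photic-zone retention p and phytoplankton
bioavailability ε, converted to moles (M_Fe = 55.845 g mol⁻¹), then to fixed
carbon through the Fe:C requirement u = 3 µmol mol⁻¹
(M_C = 12.01 g mol⁻¹), per unit ocean area:

    P = R_Fe·p·ε / M_Fe,    NPP = P·M_C / (u·10⁻⁶·a)   [g C m⁻² yr⁻¹]

p and ε move together across min/base/max levels (0.25/0.5/0.75), giving
p·ε ∈ {0.0625, 0.25, 0.5625} — hence the exact max/base ratio of 2.25 and
min/base of 0.25; an independent p × ε grid is available behind
`full_cross`. Default areas: Southern Ocean 2 × 10¹³ m², Antarctic Peninsula
waters 4.5 × 10¹² m². All NPP outputs are labelled upper limits: light,
macronutrient co-limitation, mixing and export of the stimulated carbon are
outside the model. A configurable comparison converts other taxa's Fe inputs
(default: baleen whales at 1.2 × 10³ t yr⁻¹) through the same equations.

## Synthetic colonies

`synthetic_data.simulate_colony` draws zone mosaics (log-uniform areas,
3–20 × 10³ m² for GRZ and 0.5–2 × 10⁵ m² for OZ, matching field magnitudes),
true counts = class density × area, and observed counts with Gaussian error
truncated at zero, sd = 7 % of the true count (the detector-reported
159/2265). Half the zones per class are withheld from the survey to exercise
extrapolation. One colony-level true Fe concentration is drawn from the
truncated 3.0 ± 1.4 mg g⁻¹ distribution — the estimator always assumes the
distribution's mean, so the drawn value is exactly the between-colony
variability its ±1 sd interval claims to cover. The water concentration is
the exact inversion of the inventory arithmetic for a known release
fraction (default 0.052), so the discharge round trip is machine-exact by
construction.

What passing recovery tests show: the estimator chain is unbiased and its
nominal intervals have close-to-nominal (62–74 %) coverage *under this error
model*. They say nothing about detector bias on real imagery, spatial
density structure, or guano transport — all explicitly outside the
generator.

## Numerical and design choices

- Problem sizes: recovery tests use 200 replicate colonies (500 for the
  census-only check) — enough for ~0.3 % standard error on the release
  fraction while keeping the suite in seconds.
- Division by a zero-valued quantity raises; zero counts/areas short-circuit
  to exact zero pools rather than propagate 0/0.
- Strict configs: pydantic models with unknown keys rejected, validated
  before any computation; reruns of a fixed config are byte-identical.
- Each summary value carries the producing operation and an input hash for
  traceability.
- Known limitations: snapshot budget (no deposition/erosion dynamics, no
  seasonal release variation), no hydrodynamic plume model, independence
  assumed everywhere, single-species scope.
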