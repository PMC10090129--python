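# guanofe

Iron-export budgets for penguin colonies: from zone-level census counts and
guano geometry to colony Fe accumulation, coastal release efficiency, global
annual Fe flux, and iron-stimulated net primary production (NPP), with
uncertainty carried through every stage.

## The problem

Phytoplankton growth in high-nutrient, low-chlorophyll Southern Ocean waters
is iron-limited, and krill-feeding vertebrates recycle iron into the photic
zone through their excreta. Chinstrap penguins (*Pygoscelis antarcticus*)
concentrate enormous quantities of Fe-rich guano at their breeding colonies;
`guanofe` quantifies that flux for scientists studying biogenic nutrient
cycling. The budget chains five stages:

1. **Census** — detection counts in surveyed zones give densities for
   guano-rich zones (GRZ) and outer zones (OZ), extrapolated class-wise to
   unsurveyed zones: `C = Σ dᵢ·aᵢ`.
2. **Accumulation** — colony Fe by two independent routes, volumetric
   `g_Fe = w·Fe·a_GRZ·t·d_guano` and individual-excretion
   `g_Fe = Cp·Fe·e·d`, cross-checked against each other.
3. **Discharge** — Fe inventory of the coastal water cuboid under the
   colony's turbidity plume, and the release efficiency
   `η = m_water / m_pool` with bounds from both routes' uncertainties.
4. **Annual budget** — a two-period year (120 breeding days at 10 % release,
   245 at-sea days at 100 %) scaled to the global population.
5. **NPP** — the recycled-iron fertilization model
   `P = R_Fe·p·ε/M_Fe`, `NPP = P·M_C/(u·10⁻⁶·a)`, over retention ×
   bioavailability scenarios (upper limits).

Uncertainties propagate by the first-order independent-factor rule or by
zero-truncated Monte-Carlo sampling (see `docs/methods.md`).

## Worked example

The packaged configuration reproduces the published budget for the Vapour
Col rookery (Deception Island, South Shetland Islands):

```sh
guanofe replicate-paper -o out/
```

prints, among others:

```
census_total_ind                           16725 ± 671 ind
dry_guano_volumetric_t                     165.554 t
fe_pool_volumetric_kg                      496.663 ± 232 kg
dry_guano_census_t                         169.389 ± 6.8 t
fe_pool_census_kg                          508.167 ± 238 kg
fe_pool_mean_kg                            502.415 ± 166 kg
water_fe_kg                                25.92 kg
release_efficiency_pct                     5.15908 ± 1.71 %
release_efficiency_bounds_pct              3.558 – 9.595 %
breeding_release_t_per_yr                  24.3072 ± 11.3 t
total_release_t_per_yr                     520.579 ± 232 t
npp_base_southern_ocean_g_c_m2_yr          0.466481 ± 0.208 g/m2/yr (upper limit)
npp_base_baleen_whales_southern_ocean_g_c_m2_yr 1.0753 g/m2/yr (upper limit)
```

Reading: the colony holds ~16,725 birds whose guano accumulates ~500 kg of
iron over a breeding season (the two routes agree within 2.3 %); about 5.2 %
of it (bounds 3.6–9.6 %) sits in the adjacent water at the sampling
snapshot; scaled to 8 × 10⁶ birds the species releases ~521 t Fe yr⁻¹, which
could sustain up to ~0.47 g C m⁻² yr⁻¹ of primary production across the
Southern Ocean — roughly half the stimulation attributed to all baleen
whales (~1.08). The dominant uncertainty everywhere is the guano Fe
concentration (3.0 ± 1.4 mg g⁻¹).

The same pipeline runs on your own data:

```sh
guanofe run -c my_colony.yaml -o out/       # see src/guanofe/data/vapour_col.yaml
guanofe simulate --seed 7 -o sim/           # synthetic colony + ground truth
guanofe report -s out/summary.json
```

or from Python:

```python
from guanofe import run_pipeline, vapour_col_config
bundle = run_pipeline(vapour_col_config())
bundle.summary["total_release_t_per_yr"]["value"]   # 520.58
```

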