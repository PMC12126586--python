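# wetlandscape

Continental wetland surveys face three linked questions: where are the
wetlands and of what type, where is wetland patchiness colliding with human
population, and how much carbon is at stake if those wetlands are drained?
`wetlandscape` implements that analysis chain as a tested, reusable Python
package for landscape ecologists and remote-sensing practitioners:

1. **Mapping** — seasonal composites of optical reflectance (B2, B3, B4, B8,
   B11, B12) and dual-polarisation SAR backscatter (VV, VH) feed spectral
   indices — NDVI = (B8−B4)/(B8+B4), NDWI = (B3−B8)/(B3+B8),
   MNDWI = (B3−SWIR)/(B3+SWIR), tasseled-cap wetness, and the SAR pair
   Ndiff = (VH−VV)/(VH+VV), Nratio = VV/VH — into a per-climate-zone random
   forest (500 trees) that labels each cell marsh, mangrove, swamp,
   peatland, seasonal wetland, or non-wetland. Variables are screened by
   mean decrease impurity (MDI) over repeated fits; accuracy is assessed on
   a stratified 50/50 control-point split with overall accuracy, Cohen's
   kappa κ = (p₀ − pₑ)/(1 − pₑ), and per-class producer's/user's accuracy.
2. **Fragmentation × population** — contiguous same-class regions are
   labeled as fragments and counted per coarse grid cell (Frag_grid = Σᵢ
   Gridᵢ; a fragment touching k cells counts once in each). Fragment counts
   and gridded population are each rescaled by a fuzzy linear membership
   μ(x) = (x − min)/(max − min) and combined with the fuzzy AND (cellwise
   minimum) into the **Wetland Fragmentation and Population Index (WFPI)**
   ∈ [0, 1]; wetland area is then summed by threat class (heavy WFPI > 0.5,
   moderate 0.3–0.5).
3. **Carbon accounting** — per-(zone, type) stock = area[ha] × stock
   factor [t C ha⁻¹]; annual flux = Σ EF × area for a pristine/drained
   condition or for a six-level water-table code (−3: ≤ −70 cm … 2: > +40 cm
   ponding); CO₂ equivalents are carbon mass × 44/12. Factor tables are
   user-supplied configuration; the repo ships example tables with
   synthetic placeholder values only.

A seeded synthetic-data module generates truth maps with an exactly known
fragment inventory, class-conditional scenes, city-kernel population
surfaces and control points, so the full chain runs and is validated
without any downloads.

## Worked example

```bash
wetlandscape run-all --seed 1 --outdir run1
```

runs the whole chain on the default synthetic conditions (200×200 truth
raster at 50 m, five wetland classes plus background, 200 control points per
class, 2 km analysis grid) and prints, among other metrics:

```
running full pipeline (seed=1) → run1
OA=1.000 kappa=1.000 fragments=635
{
  "overall_accuracy": 1.0,
  "kappa": 1.0,
  "selected_variables": ["B8_wet", "TCWI_wet", ...],
  "n_fragments": 635,
  "oracle_n_fragments": 635,
  "wfpi_heavy_km2": 1.5924999999999772,
  "wfpi_moderate_km2": 8.994999999999875,
  "stock_tC": 1157800.0,
  "drained_tC_yr": 10513.875,
  ...
}
```

Reading: the forest recovers the synthetic truth perfectly (OA and kappa of
1.0 on held-out points — the generator's class signatures are 8 within-class
standard deviations apart, so this is the expected regime, not a typical
real-world accuracy); the production fragment labeler finds exactly the 635
fragments the generator's independent flood-fill oracle recorded; about
1.6 km² of wetland sits in cells where high fragmentation coincides with
high population (WFPI > 0.5); and with the example factor table the mapped
wetlands hold ≈1.16 Mt C, releasing ≈10.5 kt C yr⁻¹ if drained.

Every stage is also a library call (`wetlandscape.indices`,
`.classify`, `.fragmentation`, `.wfpi`, `.carbon_accounting`,
`.synthetic_data`) and a CLI verb (`simulate`, `composite`, `classify`,
`fragment`, `wfpi`, `carbon`); outputs are GeoTIFF/CSV/JSON with a hashed
run manifest, and a rerun with the same config and seed is bit-identical.

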