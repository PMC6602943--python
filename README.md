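# ahah — Access to Healthy Assets and Hazards

A tested, reusable implementation of the **AHAH composite index**: a
small-area summary of how accessible health-promoting assets (GP practices,
pharmacies, dentists, A&E hospitals, leisure centres, green space) and
health-negating hazards (fast food outlets, gambling outlets, off-licences,
tobacconists, pubs/bars/nightclubs, air pollution) are from each
neighbourhood. It is aimed at health-geography and public-health
researchers who want the full construction pipeline — routing, buffers,
zonal statistics, rank transforms — as ordinary, inspectable Python,
exercised end-to-end on seeded synthetic study regions so nothing depends
on proprietary retail, NHS or pollution data downloads.

## What it computes

For every postcode, the network distance (km) along a directed road graph
(one-way restrictions honoured) to the nearest facility of each of 10
service categories, plus the area (m²) of public green space intersecting a
900 m buffer around the postcode centroid. Postcode measures are averaged
(unweighted) into small statistical zones (LSOA/Data Zone analogues);
zone-mean NO₂, PM₁₀ and SO₂ come from 1×1 km rasters whose overlapping
cells are averaged per zone. The zone × 14 indicator table then becomes an
index in four steps:

1. **Orientation** — indicators are signed so larger always means less
   healthy (distance to hazards and green-space area are flipped).
2. **Rankit standardisation** — each indicator is mapped to standard-normal
   scores, `Φ⁻¹((r − ½)/N)` with ascending average ranks `r`.
3. **Domains** — equal-weight means form three domain scores (retail
   environment, health services, physical environment); each domain is
   ranked, scaled to `R = rank/N ∈ (0, 1]`, and transformed exponentially:

   ```
   X = −23 · ln(1 − R·(1 − e^(−100/23)))        X ∈ (0, 100]
   ```

   which emphasises the worst-ranked zones and stops a very poor domain
   being cancelled out by good ones.
4. **Index** — the three domain `X` scores are averaged with equal weights;
   ranks and deciles follow (decile 1 = most health-promoting; higher
   scores mean *less* healthy throughout).

The synthetic study region that feeds the pipeline has an urban core where
services **and** hazards co-cluster, a suburban ring, and a remote
periphery with more green space — the spatial regime in which suburban
zones come out healthiest, city cores suffer from hazards and pollution,
and remote areas from poor service access.

## Worked example

```bash
ahah run-all --out demo --seed 1
```

```
ahah region: 50 zones, 679 postcodes, 256 nodes
ahah access: 6790 rows
ahah environment: 679 green rows, 50 air rows
ahah index: 50 zones written
wrote index for 50 zones to demo (seed 1)
```

`demo/ahah_index.csv` starts:

```
zone_code,index_score,index_rank,index_decile,retail_X,retail_decile,health_X,health_decile,physical_X,physical_decile
Z000,21.903493,32,7,1.404153,1,54.902220,10,9.404105,4
Z001,15.366166,12,3,6.821126,3,35.856824,8,3.420547,2
```

Zone `Z000` ranks 32nd of 50 (decile 7, less healthy than most): it has the
best possible retail environment (`retail_X` 1.4 — far from fast food,
bookmakers and pubs) but the worst decile for health-service access, the
classic remote-periphery trade-off that the exponential transform refuses
to cancel away. At seed 1 the healthiest zone is `Z022`
(`index_score` 11.27, decile 1) and the least healthy `Z025` (66.82,
decile 10). The run also writes `ahah_components.csv` (14 raw measures +
14 deciles per zone), `diagnostics_correlations.csv`, the per-stage CSVs,
and the complete synthetic region (`region/`: edge list, postcode lookup,
GeoJSON layers, ESRI ASCII pollutant grids) plus `config_used.yaml`.

Every stage is also a library function (`generate_region`,
`nearest_facility_distances`, `greenspace_area`, `raster_zone_mean`,
`aggregate_postcodes`, `construct_index`, …) and a CLI verb (`simulate`,
`access`, `environment`, `aggregate`, `index`, `diagnostics`, `run-all`).

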