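# gdemapper

Desk-scale pipeline for mapping **groundwater-dependent ecosystems (GDEs)**
in drylands from multi-temporal satellite-style imagery, implemented end to
end over simulated landscapes with known ground truth.

GDEs — phreatophyte stands, springs, riparian corridors, wetlands — are
"blue or green islands" in a xeric matrix: because their roots reach the
water table, they stay green and moist through the dry season, run a few
degrees cooler than their surroundings, and transpire more water annually
than falls as precipitation. This package turns those signatures into a
classification pipeline:

1. **Analysis extent** — dryland climate classes (Köppen B and dry-summer
   Cs types), minus agriculture/urban/open water, minus pixels whose
   depth to groundwater (DTG) exceeds 30 m (beyond most phreatophyte
   rooting depths), with gap-filling rules for the DTG layer.
2. **Eleven predictors** — dry-season means and interannual coefficients
   of variation of NDVI, NDMI, NDWI and MSAVI; the annual
   transpiration/precipitation ratio ETaP (> 1 flags a groundwater
   subsidy); the compound topographic index CTI = ln(a / tan β); and a
   multi-scale land-surface-temperature (LST) spatial anomaly — each
   pixel's deviation from its 270 m / 2,700 m / 5,400 m neighbourhood
   means, averaged.
3. **Random forest** — 40 trees, 5 variables per split, minimum leaf 2,
   bag fraction 0.7, 3,010-node cap, trained on an 80/20 stratified split
   of labelled points. Per-pixel GDE probability is the fraction of tree
   votes; the binary map (GDE = 1, non-GDE = 2) uses either the 50%
   likelihood threshold or a dynamic threshold that maximises validation
   accuracy over a 0.00–1.00 sweep.
4. **Post hoc analyses** — GDE area density by block aggregation with
   geodesic cell areas; groundwater-storage anomaly decomposition
   (GWS = TWS − SM − SWE − canopy) and least-squares trends over
   April 2002–April 2022; area-weighted fractions of GDE area over
   declining storage, inside protected areas / policy jurisdictions, and
   over pastoral land; zonal means over polygon regions.

Real-world rasters at global scale are not required: the
`synthetic_scene` module generates landscapes with the statistical
structure above (plus clouds, QA dropouts, sensor noise and persistent
soil heterogeneity), so every stage is testable against planted truth.

## Worked example

```bash
python analysis/04_train_and_map.py --seed 1
```

trains the forest on 1,000 GDE + 1,000 non-GDE + 200 barren points from
the default 200×200 scene and prints (abridged):

```
"oob_error": 0.0,
"dynamic_threshold": 0.16,
"test": { "tp": 200, "fp": 0, "fn": 0, "tn": 240,
          "accuracy": 1.0, "precision": 1.0, "recall": 1.0 },
"pixel_truth_agreement": 0.9974,
"gde_area_km2": 3.05,
"analysed_area_km2": 15.97,
"gde_share_of_extent": 0.191

top predictors: etap (0.61), ndmi_mean (0.19), lst_anom (0.18)
```

Read: on held-out points the forest separates the planted classes
perfectly (the default scene's contrast of 2 is an easy regime — see
`docs/methods.md`); 99.7% of extent pixels agree with the planted truth
mask; mapped GDEs cover 3.05 km² = 19% of the 15.97 km² analysed extent
(the scene plants ~19% of its extent as GDE); and the two distinctive
groundwater signatures — ETaP and the LST anomaly — carry most of the
ensemble's importance alongside the moisture index.

The other drivers follow the same pattern: `01_simulate_scene.py`
(landscape composition), `02_build_extent.py` (masking cascade),
`03_compute_predictors.py` (per-layer class separation),
`05_posthoc_analyses.py` (storage trends, protection, pastoral overlap).
Each writes a small table under `results/`.

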