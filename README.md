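# elcgap — ecogeographical gap analysis for germplasm collections

`elcgap` helps genebank curators and plant-genetic-resources researchers
answer two questions about a crop wild relative: **which of the species'
adaptive scenarios are missing from the genebank**, and **which unconserved
populations should be collected first** — optionally targeting populations
likely to carry drought- and salinity-tolerance traits.

The workflow, per species:

1. **Occurrence QC** — parse MCPD-style passport/presence tables, remove
   imprecise external records (fewer than two declared decimals in both
   coordinates, missing locality, or UTM coarser than 1 × 1 km), score
   georeferencing quality 0–100 and keep records > 80, and clear spatial
   duplicates (occurrences < 1 km apart are one population).
2. **Variable selection** — extract environmental raster values at occurrence
   sites; per ecogeographical component (bioclimatic, edaphic, geophysic),
   rank variables by random-forest mean decrease in accuracy and drop
   redundant ones (|r| > 0.50, p < 0.05, among the top 15); keep the top
   3 + 3 + 2 plus latitude/longitude as extra geophysic variables.
3. **ELC map** — an Ecogeographical Land Characterization map: K-means per
   component over all land cells with the elbow rule (50% drop in the
   within-group sum of squares, at most 8 clusters), combined so each land
   cell's category is its (bioclimatic, edaphic, geophysic) cluster triple —
   a putative adaptive scenario.
4. **Gap analysis** — *spatial gaps*: external populations > 1 km from every
   accession; *priority ecogeographical gaps*: external populations whose ELC
   category holds no accession (collection ranks 1–4); representativeness
   percentages before and after hypothetical collecting.
5. **Predictive characterization (FIGS)** — among priority gaps, keep sites
   with Lang aridity index AI_L = annual precipitation / annual mean
   temperature < 40, then select per species the 20% with the highest topsoil
   salinity: the shortlist for drought/salinity-targeted collecting.

A synthetic-landscape generator (`elcgap.synthetic`) produces raster stacks
and occurrence tables with known ground truth — planted zones, correlated
variables, injected duplicates, degraded records, withheld categories — so
the entire chain is testable without downloading climate or occurrence data.

## Worked example

```python
from elcgap import (PipelineConfig, SpeciesSimParams, SyntheticLandscapeSpec,
                    run_pipeline)

config = PipelineConfig(
    output_dir="demo_out",
    synthetic=SyntheticLandscapeSpec(extent=(-4.0, 39.0, -3.5, 39.5),
                                     cell_size=1 / 120 * 3),
    species_sim=[SpeciesSimParams("Aegilops demo", n_accessions=40,
                                  n_external=200, withhold_most_arid=2,
                                  dup_fraction=0.1, degrade_fraction=0.1)],
    seed=7,
)
bundle = run_pipeline(config)
print(bundle.tables["gap_summary"].to_string(index=False))
print(bundle.tables["pc_trace"].to_string(index=False))
```

prints

```
      species  n_externals  n_spatial_gaps  n_priority_gaps priority_pct
Aegilops demo          177             164               44           25
        TOTAL          177             164               44         None

      species  n_arid  fraction  n_selected
Aegilops demo      44       0.2           9
```

Reading it: of 220 simulated external records, 177 survive QC (20 were
planted with degraded coordinates or missing locality, 23 are spatial
duplicates); 164 lie more than 1 km from every accession; 44 fall in ELC
categories with no conserved accession — here the two most arid categories,
which the simulation withheld from the accession sample. All 44 are arid
(AI_L < 40), and the 20% rule (round-half-up of 0.2 × 44) shortlists 9
populations with the highest topsoil salinity (`bundle.tables["pc_subset"]`
lists them with coordinates, Lang index and salinity).

The same run is available from the shell:

```sh
elcgap simulate --out bundle/ --seed 7 --species "Aegilops demo:40:200"
elcgap run --bundle bundle/ --out demo_out --seed 7
```

with stage-level subcommands (`qc`, `select-vars`, `elc`, `gaps`, `pc`) for
partial runs, or `elcgap run --config config.yml` for a YAML configuration.

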