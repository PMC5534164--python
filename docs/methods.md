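# Methods

`elcgap` implements an ecogeographical gap-analysis workflow for crop wild
relative (CWR) germplasm collections: given where a species is conserved
(genebank *accessions*) and where it has been observed (*external sources*
such as floristic databases), it identifies which of the species' adaptive
scenarios are missing from the genebank and which unconserved populations to
collect first, ending with a trait-targeted shortlist (drought/salinity) in
the FIGS (Focused Identification of Germplasm Strategy) tradition.

## Pipeline stages

### 1. Occurrence quality control (`elcgap.qc`)

Passport and presence records pass four ordered checks:

1. **Coordinates.** Records without parseable coordinates are set aside (never
   silently dropped). Coordinate precision is read from the *textual*
   representation — `"41.70"` declares two decimals even though the float is
   `41.7`.
2. **Precision filter** (external sources only). A record is removed iff its
   decimal-degree coordinates have fewer than two decimals in *both* latitude
   and longitude, or its locality description is empty, or it is UTM-encoded
   coarser than 1 × 1 km. Accessions are exempt: their coordinates come from
   collecting missions. The three removal conditions are OR-ed; a record
   precise in either coordinate survives the decimal rule.
3. **Quality score.** A 0–100 composite (equal-weight mean of sub-scores in
   [0, 1]): coordinate precision (declared decimals capped at 4, divided
   by 4; a resolution ladder for UTM), administrative agreement
   (point-in-polygon of the declared admin units against reference
   boundaries, full credit at the finest declared level and partial credit at
   coarser ones), and completeness of the site description (locality text plus
   the four admin fields). Without reference boundaries the admin sub-score is
   skipped and the remaining two averaged. The score is monotone: improving
   any sub-score never lowers the total. Only records scoring **strictly
   above 80** enter the analyses. The scorer is pluggable (`run_qc(...,
   scorer=...)`); any callable record → 0–100 can replace it, since downstream
   stages use only the thresholded value.
4. **Spatial dedup.** Within each species × source class, occurrences **less
   than 1 km** apart (great-circle, sphere radius 6371.0088 km) are treated as
   one population. A greedy scan in deterministic order (quality score
   descending, then record id) retains a record iff it is ≥ 1 km from every
   already-retained record; the highest-quality member of each cluster
   survives. The retained set is therefore pairwise ≥ 1 km and every removed
   record is < 1 km from a retained one — a contract that is order-checkable
   independently of the greedy order, and idempotent.

All report percentages are integers rounded **half-up**, the convention that
reproduces every printed percentage in published tables of this kind
(e.g. 1879/4850 → 39%, 0.2 × 103 → 21).

### 2. Variable selection (`elcgap.varsel`)

Environmental layers are sampled at each retained record's containing raster
cell (cells are half-open `[west, east) × [south, north)` intervals; records
on nodata or off-grid are excluded and listed). Within each ecogeographical
component (bioclimatic, edaphic, geophysic), variables are ranked by
random-forest importance and pruned of redundancy:

* **Ranking.** The published workflow ranks variables by random-forest mean
  decrease in accuracy but does not state the response variable. The default
  here pre-clusters the component's site matrix (z-standardized K-means, k by
  the same elbow rule as the maps, floored at 2), trains a 500-tree random
  forest to predict the cluster labels, and uses permutation importance
  (mean decrease in accuracy, 5 repetitions, seeded). An unsupervised
  real-vs-permuted-columns contrast was evaluated and rejected: independent
  per-column permutation preserves every marginal distribution, so a variable
  whose zonal structure is purely marginal (the canonical test case — one
  zone-structured variable next to i.i.d. noise) is undetectable by that
  contrast. The ranking function is isolated and swappable.
* **Pruning.** The ranking is truncated to its top 15; pairs are scanned in
  rank order and the lower-ranked member of any pair with |Pearson r| > 0.50
  and two-sided p < 0.05 (t statistic, n − 2 df) is dropped. A dropped
  variable cannot drop others, so the top variable of a component always
  survives, and the surviving set is pairwise unflagged in the scan sense.
* **Final set.** Top 3 bioclimatic + top 3 edaphic + top 2 geophysic
  survivors, plus cell-center latitude and longitude appended to the
  geophysic component so the map categories aggregate spatially. Components
  with fewer survivors contribute what they have, with a warning.

### 3. Ecogeographical Land Characterization map (`elcgap.elc`)

Each component is clustered over **all land cells** of the territory (the map
must cover the whole study area, not just occurrence sites). Variables are
z-standardized over land so mm, °C and dS/m contribute comparably. K-means
runs for k = 1..8 with 10 seeded restarts, keeping the best within-group sum
of squares (WSS); monotonicity of WSS in k is asserted, and a violation
aborts the run rather than silently accepting a bad fit. The number of
clusters is the **elbow rule**: the smallest n where the relative WSS drop
from n to n + 1 falls below 50% (zero WSS stops the scan; if every drop is
≥ 50% the cap of 8 applies).

The three component maps combine cell-wise: a land cell's ELC category is its
(bioclimatic, edaphic, geophysic) label triple; observed triples are numbered
1..C in lexicographic order, so legends are reproducible. Any component
nodata makes the cell nodata. Per-category cell counts and mean variable
values are tabulated. Records get the category of their containing cell;
nodata yields category 0 and exclusion from representativeness.

### 4. Gap analysis (`elcgap.gaps`)

* **Spatial gaps**: external records strictly more than 1 km from every
  accession of the species (strict >, mirroring the strict < of the
  duplicate rule). With zero accessions, every external is a spatial gap.
* **Ecogeographical gaps**: ELC categories holding at least one external
  record and zero accessions.
* **Priority ranks 1–10.** The published toolkit's scoring beyond its
  defining property is not public. The stand-in preserves exactly that
  property — **rank ≤ 4 if and only if the record's category is
  unrepresented** — and grades within it: unrepresented-category records get
  the quartile (1 = rarest) of their category's territory frequency among the
  unrepresented categories (ties share the lower rank); represented-category
  records get 5 + min(5, ⌊5 × accession share / external share⌋). Everything
  downstream depends only on the rank ≤ 4 property.
* **Representativeness**: current % = represented categories / total
  categories; improvement % = gap categories / total; both half-up integers.

### 5. Predictive characterization (`elcgap.predchar`)

Priority-gap populations are filtered toward drought/salinity tolerance:

* **Lang aridity index** AI_L = annual precipitation (mm) / annual mean
  temperature (°C), undefined (and excluded, with a warning) for T ≤ 0.
* **Arid filter**: AI_L strictly < 40.
* **Selection**: per species, the round-half-up 20% of arid sites with the
  highest topsoil salinity (dS/m); ties broken by lower AI_L (more arid
  first), then record id. Half-up is the unique integer rounding consistent
  with the published per-species count pairs (10→2, 103→21, 76→15, 26→5,
  8→2; total 45). Salinity is applied as the primary criterion with AI_L as
  tiebreak only: the published results sort and select by salinity after the
  AI_L < 40 filter, although the methods prose mentions both. The selection
  is scale-invariant in salinity.

## Synthetic landscapes (`elcgap.synthetic`)

The generator replaces the original study's rasters and database downloads
with landscapes of known truth:

* **Zones.** Per component, `true_k` contiguous zones: farthest-point seeds
  relaxed by 10 Lloyd iterations (a centroidal Voronoi tessellation). Balance
  matters: unrelaxed Voronoi patches can be so unequal in area that the 50%
  elbow criterion legitimately stops at k = 1, which tests a different thing
  than category recovery.
* **Zone means.** Per variable, a random permutation of stratified-jittered
  levels across the variable's range — every zone pair is separated in every
  variable, spacing is irregular (perfectly symmetric configurations sit
  exactly on the 50% elbow boundary), and recovery difficulty is governed by
  `noise_sd` alone (i.i.d. Gaussian cell noise). Designated
  `annual_precipitation` (mm/yr), `annual_mean_temperature` (°C) and
  `topsoil_salinity` (dS/m) layers use realistic ranges so the
  predictive-characterization stage is meaningful.
* **Blemishes.** Injected twins < 1 km from their source (spatial
  duplicates), records with coordinates truncated to one decimal and/or
  stripped locality (precision-filter bait), categories withheld from the
  accession sample (guaranteed ecogeographical gaps; optionally the most
  arid categories, the scenario the FIGS stage targets).
* **Not emulated:** realistic climate surfaces and spatial autocorrelation
  within zones, coastline/island geometry (the nodata "sea" is a margin),
  gazetteer errors, taxonomic misidentification. Passing tests demonstrate
  the algorithmic contracts, not performance on real Iberian data.

Default study conditions: 30 arc-second cells (1/120°), 37 + 16 + 4 variables
per component, 3 zones per component, noise_sd 0.5. Tests and the acceptance
script use smaller extents (36–70 cells per side, 2–10 variables per
component) so a full run stays in seconds; the algorithms are size-agnostic.

## Numerical and design choices

* One master seed fans out to per-stage seeds via a CRC32-keyed derivation,
  so any stage can be rerun in isolation and full reruns are byte-identical.
* Rasters are read and written as single-band ESRI ASCII grids (plain text,
  `repr`-precision floats, lossless round trip) plus a CSV manifest tagging
  each variable's component; occurrence tables are UTF-8 CSV with MCPD-style
  headers, coordinates kept as text.
* Ties everywhere are broken deterministically (importance then name;
  salinity then AI_L then record id; quality then record id).
* Degenerate inputs: constant variables are dropped from clustering with a
  warning (error if none remain); zero WSS stops the elbow scan; species
  lacking accessions or externals are skipped and logged; an aridity
  threshold of 0 is legal and yields an empty PC subset.

## Known limitations

* The quality score and the priority ranks 5–10 are documented stand-ins, not
  reimplementations of the original toolkit; only the thresholded quality
  (> 80) and the rank ≤ 4 property are relied upon.
* The headline figures of the original five-species Spanish study (e.g. its
  26–27-category national maps) require the real 57-layer raster stack and
  are out of scope; the package reproduces the study's arithmetic and its
  algorithmic contracts instead.
* Dedup and spatial-gap search are exact O(n·m) scans — ample for
  10⁴-record collections, not for continental-scale point sets.
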