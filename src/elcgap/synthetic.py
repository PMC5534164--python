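"""Synthetic environmental landscapes and occurrence tables with known truth.

The generator emulates the inputs of an ecogeographical gap analysis so the
whole pipeline can be exercised without downloading climate/soil rasters or
occurrence databases:

* a stack of gridded environmental variables in three ecogeographical
  components (bioclimatic, edaphic, geophysic) whose values are driven by a
  known zonation — contiguous Voronoi patches around well-spread seed cells,
  one independent zonation per component, each zone with its own mean vector
  plus i.i.d. Gaussian cell noise;
* designated ``annual_precipitation``, ``annual_mean_temperature`` and
  ``topsoil_salinity`` layers on realistic scales (mm/yr, °C, dS/m) so the
  aridity/salinity predictive-characterization stage has meaningful inputs;
* optional planted redundant variables built as noisy linear transforms of an
  existing layer with a prescribed Pearson correlation, to exercise the
  correlation-pruning stage;
* occurrence tables of genebank "accessions" and "external source"
  populations with the blemishes of real passport data: injected spatial
  duplicates (< 1 km twins), records with degraded coordinate precision or
  missing locality text, and categories deliberately withheld from the
  accession set so that known ecogeographical gaps exist.

A nodata "sea" margin surrounds every landscape so downstream stages must
handle cells without data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import EARTH_RADIUS_KM, round_half_up
from .grids import (
    COMPONENTS,
    EcoRasterStack,
    GridGeometry,
    read_stack,
    write_ascii_grid,
    write_stack,
)

#: CSV dialect for occurrence tables (MCPD-style passport columns).
OCCURRENCE_COLUMNS = [
    "SPECIES", "SOURCE_CLASS", "DECLATITUDE", "DECLONGITUDE", "COORD_SYSTEM",
    "UTM_RESOLUTION_M", "LOCALITY", "COUNTRY", "ADM1", "ADM2", "ADM3", "RECORD_ID",
]

#: Ground-truth sidecar columns carried next to the occurrence table.
TRUTH_COLUMNS = ["RECORD_ID", "TRUE_CATEGORY", "DUPLICATE_OF", "DEGRADED_PRECISION"]

_KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0


@dataclass
class SyntheticLandscapeSpec:
    """Parameters of a synthetic landscape.

    Defaults mirror a desk-scale version of a 30 arc-second national study:
    cell_size 1/120 degree, 37 bioclimatic + 16 edaphic + 4 geophysic
    variables, three environmental zones per component.
    """

    extent: tuple[float, float, float, float]  # (west, south, east, north)
    cell_size: float = 1.0 / 120.0
    n_vars: dict[str, int] = field(
        default_factory=lambda: {"bioclimatic": 37, "edaphic": 16, "geophysic": 4}
    )
    true_k: dict[str, int] = field(
        default_factory=lambda: {"bioclimatic": 3, "edaphic": 3, "geophysic": 3}
    )
    noise_sd: float = 0.5
    corr_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    sea_margin: int = 2
    seed: int = 0

    def validate(self) -> None:
        west, south, east, north = self.extent
        if not (east > west and north > south):
            raise ValueError("degenerate extent")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        n_rows = int(round((north - south) / self.cell_size))
        n_cols = int(round((east - west) / self.cell_size))
        if n_rows - 2 * self.sea_margin < 2 or n_cols - 2 * self.sea_margin < 2:
            raise ValueError("extent too small: no land cells after the sea margin")
        for comp in COMPONENTS:
            k = self.true_k.get(comp, 1)
            if not 1 <= k <= 8:
                raise ValueError(f"true_k for {comp} must be in 1..8")
        for _, _, r in self.corr_pairs:
            if abs(r) > 1:
                raise ValueError("target correlation must be within [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    geometry: GridGeometry
    component_labels: dict[str, np.ndarray]  # 1..k on land, 0 on sea
    category_raster: np.ndarray  # combined category, 1..C on land, 0 on sea
    redundant_vars: list[str]
    record_flags: pd.DataFrame | None = None  # filled by sample_occurrences

    @property
    def categories(self) -> set[int]:
        return set(np.unique(self.category_raster[self.category_raster > 0]).tolist())


def _variable_names(component: str, n: int) -> list[str]:
    """Variable names per component; designated layers come first."""
    named = {
        "bioclimatic": ["annual_precipitation", "annual_mean_temperature"],
        "edaphic": ["topsoil_salinity"],
        "geophysic": ["altitude", "slope", "northness", "eastness"],
    }[component]
    prefix = {"bioclimatic": "bio", "edaphic": "soil", "geophysic": "geo"}[component]
    names = named[:n]
    names += [f"{prefix}{i:02d}" for i in range(len(names) + 1, n + 1)]
    return names


# Zone-mean distribution and cell-noise scale for the designated layers;
# generic layers use N(0, 3) means with cell noise equal to spec.noise_sd.
_NAMED_SCALES = {
    "annual_precipitation": ((200.0, 1000.0), 100.0, 0.0),  # (mean range, noise scale, floor)
    "annual_mean_temperature": ((8.0, 18.0), 1.2, 0.5),
    "topsoil_salinity": ((0.1, 2.6), 0.25, 0.0),
    "altitude": ((50.0, 1500.0), 120.0, 0.0),
    "slope": ((1.0, 25.0), 2.0, 0.0),
}


def _zone_partition(land_rc: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Partition land cells into k contiguous, roughly equal-area zones.

    Greedy farthest-point seeds followed by Lloyd relaxation: the result is a
    centroidal Voronoi tessellation, the patchy-but-balanced geometry typical
    of environmental zonations. Returns the zone index (0..k-1) per land cell.
    """
    first = rng.integers(len(land_rc))
    chosen = [land_rc[first]]
    d2 = np.sum((land_rc - chosen[0]) ** 2, axis=1).astype(float)
    for _ in range(k - 1):
        idx = int(np.argmax(d2))
        chosen.append(land_rc[idx])
        d2 = np.minimum(d2, np.sum((land_rc - land_rc[idx]) ** 2, axis=1))
    seeds = np.array(chosen, dtype=float)
    zone = np.zeros(len(land_rc), dtype=int)
    for _ in range(10):
        d2 = np.sum((land_rc[:, None, :] - seeds[None, :, :]) ** 2, axis=2)
        zone = d2.argmin(axis=1)
        for j in range(k):
            members = land_rc[zone == j]
            if len(members):
                seeds[j] = members.mean(axis=0)
    return zone


def _combine_labels(label_arrays: list[np.ndarray]) -> np.ndarray:
    """Combine per-component labels into consecutive category ids.

    Ids are assigned 1..C to the observed (bio, edaphic, geophysic) triples in
    lexicographic order; any component nodata (0) makes the cell nodata.
    """
    stacked = np.stack(label_arrays, axis=-1)
    land = np.all(stacked > 0, axis=-1)
    out = np.zeros(stacked.shape[:2], dtype=int)
    triples = stacked[land]
    uniq = np.unique(triples, axis=0)  # lexicographic order
    lut = {tuple(t): i + 1 for i, t in enumerate(uniq)}
    out[land] = [lut[tuple(t)] for t in triples]
    return out


def generate_raster_stack(spec: SyntheticLandscapeSpec) -> tuple[EcoRasterStack, GroundTruth]:
    """Generate an environmental raster stack with a known zonation.

    Returns the stack and the ground truth (per-component zone labels, the
    combined true category raster, and the names of planted redundant
    variables). Identical spec + seed yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    west, south, east, north = spec.extent
    n_rows = int(round((north - south) / spec.cell_size))
    n_cols = int(round((east - west) / spec.cell_size))
    geometry = GridGeometry(west=west, north=north, cell_size=spec.cell_size,
                            n_rows=n_rows, n_cols=n_cols)

    land = np.zeros((n_rows, n_cols), dtype=bool)
    m = spec.sea_margin
    land[m:n_rows - m, m:n_cols - m] = True
    land_rc = np.argwhere(land)

    stack = EcoRasterStack(geometry=geometry)
    component_labels: dict[str, np.ndarray] = {}
    for comp in COMPONENTS:
        k = spec.true_k.get(comp, 1)
        zone_of_land = _zone_partition(land_rc, k, rng)  # 0..k-1
        labels = np.zeros((n_rows, n_cols), dtype=int)
        labels[land] = zone_of_land + 1
        component_labels[comp] = labels

        for name in _variable_names(comp, spec.n_vars.get(comp, 0)):
            # Zone means are a random permutation of stratified-jittered levels:
            # one level per stratum of the variable's range, displaced uniformly
            # within it, so every pair of zones is separated in every variable
            # (no two levels coincide) while the spacing stays irregular;
            # recoverability is then governed by noise_sd alone.
            if name in _NAMED_SCALES:
                (lo, hi), noise_scale, floor = _NAMED_SCALES[name]
                noise_sd = spec.noise_sd * noise_scale
            else:
                lo, hi, floor = -3.0, 3.0, None
                noise_sd = spec.noise_sd
            levels = lo + (hi - lo) * (np.arange(k) + rng.uniform(0.15, 0.85, k)) / k
            zone_means = rng.permutation(levels)
            values = np.full((n_rows, n_cols), np.nan)
            cell_values = zone_means[zone_of_land]
            if noise_sd > 0:
                cell_values = cell_values + rng.normal(0.0, noise_sd, size=len(land_rc))
            if floor is not None:
                cell_values = np.maximum(cell_values, floor)
            values[land] = cell_values
            stack.add_layer(name, values, comp)

    redundant: list[str] = []
    for partner, new_name, target_r in spec.corr_pairs:
        base = stack.layers[partner][land]
        z = (base - base.mean()) / base.std()
        eps = rng.normal(0.0, 1.0, size=len(z))
        mixed = target_r * z + math.sqrt(max(0.0, 1.0 - target_r**2)) * eps
        values = np.full((n_rows, n_cols), np.nan)
        values[land] = mixed
        stack.add_layer(new_name, values, stack.components[partner])
        redundant.append(new_name)

    category = _combine_labels([component_labels[c] for c in COMPONENTS])
    truth = GroundTruth(geometry=geometry, component_labels=component_labels,
                        category_raster=category, redundant_vars=redundant)
    return stack, truth


def _jittered_point(geometry: GridGeometry, row: int, col: int,
                    rng: np.random.Generator) -> tuple[float, float]:
    lat, lon = geometry.cell_center(row, col)
    half = 0.4 * geometry.cell_size
    return lat + rng.uniform(-half, half), lon + rng.uniform(-half, half)


def _admin_units(geometry: GridGeometry, row: int, col: int) -> tuple[str, str, str]:
    """Fake nested admin units from coarse positional bins."""
    adm1 = f"Province {row * 2 // max(geometry.n_rows, 1) + 2 * (col * 2 // max(geometry.n_cols, 1)) + 1}"
    adm2 = f"Comarca {row * 4 // max(geometry.n_rows, 1) + 4 * (col * 4 // max(geometry.n_cols, 1)) + 1}"
    adm3 = f"Municipio {row}-{col}"
    return adm1, adm2, adm3


def sample_occurrences(
    truth: GroundTruth,
    n_accessions: int,
    n_external: int,
    withheld_categories: set[int] | None = None,
    dup_fraction: float = 0.0,
    degrade_fraction: float = 0.0,
    seed: int = 0,
    species: str = "Aegilops synthetica",
) -> pd.DataFrame:
    """Sample an occurrence table of accessions and external-source records.

    Accessions never fall in ``withheld_categories``, so those categories are
    ecogeographical gaps by construction. ``dup_fraction`` of the records in
    each source class receive an injected twin < 1 km away; a
    ``degrade_fraction`` of external records get coordinates truncated to one
    decimal and/or their locality text removed (the defects the precision
    filter must catch). Also records the per-record ground truth on
    ``truth.record_flags``.
    """
    withheld = set(withheld_categories or ())
    unknown = withheld - truth.categories
    if unknown:
        raise ValueError(f"withheld categories not in the landscape: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    geometry = truth.geometry
    cat = truth.category_raster
    land_rc = np.argwhere(cat > 0)
    acc_pool = land_rc[~np.isin(cat[land_rc[:, 0], land_rc[:, 1]], sorted(withheld))] \
        if withheld else land_rc
    if n_accessions > len(acc_pool) or n_external > len(land_rc):
        raise ValueError("requested more occurrences than available land cells")

    rows: list[dict] = []
    flags: list[dict] = []

    def emit(rc: np.ndarray, n: int, source_class: str, prefix: str) -> list[int]:
        idx = rng.choice(len(rc), size=n, replace=False)
        emitted = []
        for i, j in enumerate(idx):
            row, col = rc[j]
            lat, lon = _jittered_point(geometry, row, col, rng)
            adm1, adm2, adm3 = _admin_units(geometry, row, col)
            rid = f"{prefix}{i + 1:05d}"
            rows.append({
                "SPECIES": species, "SOURCE_CLASS": source_class,
                "DECLATITUDE": f"{lat:.6f}", "DECLONGITUDE": f"{lon:.6f}",
                "COORD_SYSTEM": "DD", "UTM_RESOLUTION_M": "",
                "LOCALITY": f"near cell {row}-{col}", "COUNTRY": "Synthland",
                "ADM1": adm1, "ADM2": adm2, "ADM3": adm3, "RECORD_ID": rid,
            })
            flags.append({"RECORD_ID": rid, "TRUE_CATEGORY": int(cat[row, col]),
                          "DUPLICATE_OF": "", "DEGRADED_PRECISION": False})
            emitted.append(len(rows) - 1)
        return emitted

    acc_idx = emit(acc_pool, n_accessions, "accession", "ACC")
    ext_idx = emit(land_rc, n_external, "external", "EXT")

    # Injected twins < 1 km from their source record.
    for source_class, base_idx in (("accession", acc_idx), ("external", ext_idx)):
        n_dups = round_half_up(dup_fraction * len(base_idx))
        if n_dups == 0:
            continue
        for j in rng.choice(base_idx, size=n_dups, replace=False):
            src = rows[j]
            lat = float(src["DECLATITUDE"])
            lon = float(src["DECLONGITUDE"])
            dist_km = rng.uniform(0.15, 0.85)
            bearing = rng.uniform(0, 2 * math.pi)
            dlat = dist_km * math.cos(bearing) / _KM_PER_DEG
            dlon = dist_km * math.sin(bearing) / (_KM_PER_DEG * math.cos(math.radians(lat)))
            rid = src["RECORD_ID"] + "-DUP"
            twin = dict(src)
            twin.update({
                "DECLATITUDE": f"{lat + dlat:.6f}", "DECLONGITUDE": f"{lon + dlon:.6f}",
                "RECORD_ID": rid,
            })
            rows.append(twin)
            cell = geometry.cell_index(lat + dlat, lon + dlon)
            true_cat = int(cat[cell]) if cell is not None else 0
            flags.append({"RECORD_ID": rid, "TRUE_CATEGORY": true_cat,
                          "DUPLICATE_OF": src["RECORD_ID"], "DEGRADED_PRECISION": False})

    # Degraded external records: coarse coordinates and/or missing locality.
    n_degrade = round_half_up(degrade_fraction * len(ext_idx))
    if n_degrade:
        for j in rng.choice(ext_idx, size=n_degrade, replace=False):
            mode = rng.integers(3)
            if mode in (0, 2):
                rows[j]["DECLATITUDE"] = f"{float(rows[j]['DECLATITUDE']):.1f}"
                rows[j]["DECLONGITUDE"] = f"{float(rows[j]['DECLONGITUDE']):.1f}"
            if mode in (1, 2):
                rows[j]["LOCALITY"] = ""
            flags[j]["DEGRADED_PRECISION"] = True

    table = pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
    truth.record_flags = pd.DataFrame(flags, columns=TRUTH_COLUMNS)
    return table


def write_fixture_bundle(stack: EcoRasterStack, occurrences: pd.DataFrame,
                         directory, truth: GroundTruth | None = None) -> None:
    """Write a self-contained fixture: rasters, occurrence CSV, truth sidecar.

    Layers go to ``rasters/`` as ESRI ASCII grids with a manifest; occurrences
    to ``occurrences.csv``; when ground truth is given, the true category
    raster and per-record flags are written alongside. Everything round-trips
    losslessly through :func:`read_fixture_bundle`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(stack, directory / "rasters")
    occurrences.to_csv(directory / "occurrences.csv", index=False)
    if truth is not None:
        write_ascii_grid(directory / "true_categories.asc", truth.geometry,
                         np.where(truth.category_raster > 0,
                                  truth.category_raster.astype(float), np.nan))
        if truth.record_flags is not None:
            truth.record_flags.to_csv(directory / "record_truth.csv", index=False)


def read_fixture_bundle(directory):
    """Read back a fixture bundle; returns (stack, occurrences DataFrame)."""
    directory = Path(directory)
    stack = read_stack(directory / "rasters")
    occurrences = pd.read_csv(directory / "occurrences.csv", dtype=str,
                              keep_default_na=False)
    return stack, occurrences
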