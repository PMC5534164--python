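"""Ecogeographical Land Characterization (ELC) maps.

An ELC map partitions a territory into categories representing putative
adaptive scenarios of a species. Each of the three ecogeographical components
(bioclimatic, edaphic, geophysic) is clustered separately with K-means over
all land cells, the number of clusters per component is chosen with an
elbow rule on the within-group sum of squares (capped at 8), and the three
component maps are combined: every land cell's ELC category is the triple of
its component cluster labels, with observed triples numbered consecutively.

Variables are z-standardized over land cells before clustering so that mm of
rainfall, °C and dS/m contribute comparably to the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grids import EcoRasterStack, GridGeometry
from .qc import OccurrenceRecord

K_MAX = 8


def elbow_k(wss: list[float], k_max: int | None = None) -> int:
    """Choose the number of clusters by the 50%-drop elbow rule.

    ``wss[i]`` is the within-group sum of squares at k = i + 1. The chosen k
    is the smallest n with (WSS(n) - WSS(n+1)) / WSS(n) < 0.5; when WSS(n) is
    zero the drop is treated as zero (stop at n). If every consecutive drop is
    at least 50%, the cap ``k_max`` (defaults to the last k available) is
    returned.
    """
    if len(wss) < 2:
        raise ValueError("need WSS for at least two values of k")
    k_max = k_max or len(wss)
    for n in range(1, len(wss)):
        if wss[n - 1] <= 0:
            return n
        drop = (wss[n - 1] - wss[n]) / wss[n - 1]
        if drop < 0.5:
            return n
    return k_max


@dataclass
class ComponentClustering:
    """Fitted K-means zonation of one ecogeographical component."""

    component: str
    variables: list[str]
    standardization: dict[str, tuple[float, float]]  # variable -> (mean, sd)
    wss: list[float]  # indexed k = 1..k_max
    chosen_k: int
    centers: np.ndarray  # chosen_k x n_variables, standardized space
    labels: np.ndarray  # raster of labels 1..k on land, 0 on nodata
    geometry: GridGeometry = None


def cluster_component(stack: EcoRasterStack, variables: list[str], component: str,
                      k_max: int = K_MAX, seed: int = 0, n_restarts: int = 10,
                      ) -> ComponentClustering:
    """Cluster all land cells of one component with elbow-rule K-means.

    K-means is run for every k = 1..k_max with ``n_restarts`` seeded restarts,
    keeping the best within-group sum of squares; the monotonicity of WSS in k
    is asserted. Constant variables (sd = 0 over land) are dropped with a
    warning; an error is raised if none remain.
    """
    land = stack.land_mask
    if land.sum() < k_max:
        raise ValueError("fewer land cells than the maximum number of clusters")
    cols, kept, standardization = [], [], {}
    for name in variables:
        arr = stack.get_layer(name)[land]
        mean, sd = float(arr.mean()), float(arr.std())
        if sd == 0:
            warnings.warn(f"variable {name!r} is constant over land; dropped "
                          "from clustering", stacklevel=2)
            continue
        cols.append((arr - mean) / sd)
        kept.append(name)
        standardization[name] = (mean, sd)
    if not cols:
        raise ValueError(f"no non-constant variables left for component {component!r}")
    X = np.column_stack(cols)

    fits = []
    wss = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        fits.append(km)
        wss.append(float(km.inertia_))
    for a, b in zip(wss, wss[1:]):
        if b > a * (1 + 1e-9) + 1e-9:
            raise RuntimeError("within-group sum of squares increased with k; "
                               "increase the number of restarts")
    chosen = elbow_k(wss, k_max=k_max)
    best = fits[chosen - 1]
    labels = np.zeros(land.shape, dtype=int)
    labels[land] = best.labels_ + 1
    return ComponentClustering(component=component, variables=kept,
                               standardization=standardization, wss=wss,
                               chosen_k=chosen, centers=best.cluster_centers_,
                               labels=labels, geometry=stack.geometry)


@dataclass
class ELCMap:
    """Combined category raster plus its legend and per-category statistics."""

    geometry: GridGeometry
    categories: np.ndarray  # int raster, 1..C on land, 0 nodata
    legend: pd.DataFrame  # category, bioclimatic, edaphic, geophysic, cell_count
    stats: pd.DataFrame | None = None  # per-category mean variable values

    @property
    def n_categories(self) -> int:
        return len(self.legend)

    @property
    def territory_frequencies(self) -> pd.Series:
        """Share of land cells per category (sums to 1)."""
        counts = self.legend.set_index("category")["cell_count"]
        return counts / counts.sum()


def combine_components(bio: ComponentClustering, edaph: ComponentClustering,
                       geoph: ComponentClustering,
                       stack: EcoRasterStack | None = None) -> ELCMap:
    """Combine the three component zonations into ELC categories.

    A land cell's category is the (bioclimatic, edaphic, geophysic) label
    triple; observed triples get consecutive ids 1..C in lexicographic order.
    Cells where any component is nodata are nodata. When the stack is given,
    per-category mean variable values are tabulated as well.
    """
    parts = (bio, edaph, geoph)
    if len({c.labels.shape for c in parts}) != 1 or len({c.geometry for c in parts}) != 1:
        raise ValueError("component clusterings are not on the same grid")
    stacked = np.stack([c.labels for c in parts], axis=-1)
    land = np.all(stacked > 0, axis=-1)
    categories = np.zeros(land.shape, dtype=int)
    triples = stacked[land]
    uniq, inverse = np.unique(triples, axis=0, return_inverse=True)
    categories[land] = inverse + 1
    legend = pd.DataFrame(uniq, columns=["bioclimatic", "edaphic", "geophysic"])
    legend.insert(0, "category", np.arange(1, len(uniq) + 1))
    legend["cell_count"] = np.bincount(inverse, minlength=len(uniq))

    stats = None
    if stack is not None:
        var_rows = {}
        for name in stack.variables():
            values = stack.layers[name][land]
            ok = ~np.isnan(values)
            sums = np.bincount(inverse[ok], weights=values[ok], minlength=len(uniq))
            counts = np.bincount(inverse[ok], minlength=len(uniq))
            with np.errstate(invalid="ignore"):
                var_rows[name] = sums / counts
        stats = pd.DataFrame(var_rows, index=legend["category"]).rename_axis("category")

    return ELCMap(geometry=bio.geometry, categories=categories, legend=legend, stats=stats)


def assign_category(elc: ELCMap, records: list[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Assign every record the ELC category of its containing cell.

    Records outside the grid or on nodata cells get category 0 (unassigned)
    and are excluded from representativeness computations downstream; a
    warning names how many were unassigned.
    """
    unassigned = 0
    for rec in records:
        cell = elc.geometry.cell_index(rec.latitude, rec.longitude)
        rec.elc_category = int(elc.categories[cell]) if cell is not None else 0
        if rec.elc_category == 0:
            unassigned += 1
    if unassigned:
        warnings.warn(f"{unassigned} records fall on nodata cells or outside the "
                      "grid; their ELC category is 0", stacklevel=2)
    return records
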