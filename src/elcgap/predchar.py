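"""Predictive characterization by ecogeographical filtering.

Populations identified as priority ecogeographical gaps are filtered toward
sites likely to harbour drought- and salinity-tolerance traits: first by the
Lang aridity index AI_L = annual precipitation (mm) / annual mean temperature
(°C), keeping sites with AI_L < 40 (arid), then by selecting per species the
20% of arid sites with the highest topsoil salinity (dS/m). The result is the
predictive-characterization (PC) subset proposed for collecting missions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up
from .grids import EcoRasterStack
from .qc import OccurrenceRecord

ARIDITY_THRESHOLD = 40.0
SELECTION_FRACTION = 0.2

PRECIPITATION_VAR = "annual_precipitation"
TEMPERATURE_VAR = "annual_mean_temperature"
SALINITY_VAR = "topsoil_salinity"


def lang_aridity_index(precipitation_mm: float, temperature_c: float) -> float:
    """Lang aridity index: annual precipitation over annual mean temperature.

    Dimensionless (mm/°C); lower is more arid. Undefined (NaN) for
    non-positive mean temperature.
    """
    if temperature_c <= 0:
        return float("nan")
    return precipitation_mm / temperature_c


def climate_at_sites(stack: EcoRasterStack, records: list[OccurrenceRecord],
                     ) -> pd.DataFrame:
    """Annual precipitation, mean temperature, AI_L and salinity per record.

    Values come from the record's containing raster cell; records outside the
    grid or on nodata cells are omitted.
    """
    columns = ["record_id", "species", "latitude", "longitude", "province",
               "municipality", "annual_precipitation", "annual_mean_temperature",
               "lang_index", "topsoil_salinity"]
    rows = []
    for rec in records:
        cell = stack.geometry.cell_index(rec.latitude, rec.longitude)
        if cell is None:
            continue
        p = float(stack.layers[PRECIPITATION_VAR][cell])
        t = float(stack.layers[TEMPERATURE_VAR][cell])
        s = float(stack.layers[SALINITY_VAR][cell])
        if np.isnan(p) or np.isnan(t) or np.isnan(s):
            continue
        rows.append({
            "record_id": rec.record_id, "species": rec.species,
            "latitude": rec.latitude, "longitude": rec.longitude,
            "province": rec.adm1, "municipality": rec.adm3,
            "annual_precipitation": p, "annual_mean_temperature": t,
            "lang_index": lang_aridity_index(p, t), "topsoil_salinity": s,
        })
    return pd.DataFrame(rows, columns=columns)


def filter_arid(climate: pd.DataFrame, threshold: float = ARIDITY_THRESHOLD,
                ) -> pd.DataFrame:
    """Keep sites with Lang index strictly below the aridity threshold.

    Sites where the index is undefined (mean temperature <= 0) are excluded
    with a warning.
    """
    undefined = climate["lang_index"].isna()
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} sites have non-positive mean "
                      "temperature; Lang index undefined, excluded", stacklevel=2)
    return climate[~undefined & (climate["lang_index"] < threshold)].copy()


def select_count(n_arid: int, fraction: float = SELECTION_FRACTION) -> int:
    """Per-species PC subset size: the selection fraction of arid sites, half-up."""
    return round_half_up(fraction * n_arid)


@dataclass
class PCSubset:
    """Per-species predictive-characterization selection with its size trace."""

    arid: pd.DataFrame
    selected: pd.DataFrame
    trace: pd.DataFrame  # species, n_arid, fraction, n_selected


def select_top_salinity(arid: pd.DataFrame, fraction: float = SELECTION_FRACTION,
                        ) -> PCSubset:
    """Select, per species, the top-salinity fraction of arid priority gaps.

    Within each species, records are ordered by topsoil salinity descending,
    Lang index ascending (more arid first on ties), then record id; the first
    round_half_up(fraction x n_arid) are selected.
    """
    frames, trace = [], []
    for species, group in arid.groupby("species", sort=True):
        n_sel = select_count(len(group), fraction)
        ordered = group.sort_values(
            by=["topsoil_salinity", "lang_index", "record_id"],
            ascending=[False, True, True], kind="mergesort")
        frames.append(ordered.head(n_sel))
        trace.append({"species": species, "n_arid": len(group),
                      "fraction": fraction, "n_selected": n_sel})
    selected = pd.concat(frames, ignore_index=True) if frames else arid.iloc[0:0]
    return PCSubset(arid=arid, selected=selected,
                    trace=pd.DataFrame(trace, columns=["species", "n_arid",
                                                       "fraction", "n_selected"]))


def pc_report(subset: PCSubset) -> pd.DataFrame:
    """One row per selected population, sorted by salinity descending.

    The Lang index is printed as an integer (half-up) and salinity with one
    decimal, matching how such tables are conventionally published.
    """
    sel = subset.selected
    if sel.empty:
        return pd.DataFrame(columns=["species", "latitude", "longitude", "province",
                                     "municipality", "lang_index", "topsoil_salinity"])
    out = sel.sort_values(by=["topsoil_salinity", "lang_index", "record_id"],
                          ascending=[False, True, True], kind="mergesort")
    return pd.DataFrame({
        "species": out["species"],
        "latitude": out["latitude"],
        "longitude": out["longitude"],
        "province": out["province"],
        "municipality": out["municipality"],
        "lang_index": out["lang_index"].map(round_half_up),
        "topsoil_salinity": out["topsoil_salinity"].round(1),
    }).reset_index(drop=True)
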