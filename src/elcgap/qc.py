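"""Occurrence-record quality control.

Implements the pre-processing chain applied to germplasm passport and
floristic presence data before any spatial analysis:

1. records without usable coordinates are set aside;
2. external-source records with imprecise georeferencing are removed —
   decimal-degree coordinates with fewer than two decimals in both latitude
   and longitude, no locality description, or UTM coordinates coarser than
   1 x 1 km (genebank accessions are exempt: their coordinates come from
   collecting missions and are kept regardless);
3. intraspecific spatial duplicates are cleared within each source class:
   occurrences less than 1 km apart are treated as the same population and
   only the highest-quality record of each cluster is retained;
4. a 0-100 georeferencing-quality score is computed and only records
   scoring strictly above the threshold (default 80) enter the analyses.

The quality score here is a documented three-part stand-in (coordinate
precision, administrative-boundary agreement, locality completeness); the
published workflow used an external toolkit whose internal scoring is not
specified. The score is pluggable: any callable mapping a record to 0-100
can replace the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import EARTH_RADIUS_KM, pct

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = [
    "SPECIES", "SOURCE_CLASS", "DECLATITUDE", "DECLONGITUDE", "RECORD_ID",
]

#: Unicode minus / dash variants seen in published coordinate tables.
_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-", "—": "-"})


@dataclass
class OccurrenceRecord:
    """One population occurrence: a genebank accession or an external source."""

    record_id: str
    species: str
    source_class: str  # "accession" | "external"
    latitude: float | None = None
    longitude: float | None = None
    lat_text: str = ""
    lon_text: str = ""
    coord_system: str = "DD"  # "DD" | "UTM"
    utm_resolution_m: float | None = None
    locality: str = ""
    country: str = ""
    adm1: str = ""
    adm2: str = ""
    adm3: str = ""
    quality_score: float | None = None
    elc_category: int = 0  # 0 = unassigned / nodata

    @property
    def has_coordinates(self) -> bool:
        return (
            self.latitude is not None
            and self.longitude is not None
            and -90 <= self.latitude <= 90
            and -180 <= self.longitude <= 180
        )

    @property
    def decimal_counts(self) -> tuple[int, int]:
        """Decimal places declared in the textual coordinates (not the float)."""
        return _decimals(self.lat_text), _decimals(self.lon_text)


def _decimals(text: str) -> int:
    text = text.strip()
    if "." not in text:
        return 0
    return len(text.split(".", 1)[1].strip())


def _parse_coord(text: str) -> float | None:
    text = text.strip().translate(_MINUS_VARIANTS)
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return None


def parse_occurrences(path: str | Path) -> list[OccurrenceRecord]:
    """Parse an occurrence CSV into records.

    Coordinates are kept as text alongside the parsed floats so the declared
    decimal precision survives parsing. Rows with missing or unparseable
    coordinates become records with no coordinates (they are flagged during
    QC, never silently dropped).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[OccurrenceRecord]:
    """Build records from an occurrence table already in memory (all-text cells)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence file missing mandatory columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        get = lambda col: getattr(row, col, "") if col in df.columns else ""
        lat_text, lon_text = get("DECLATITUDE"), get("DECLONGITUDE")
        utm_res = _parse_coord(get("UTM_RESOLUTION_M"))
        records.append(OccurrenceRecord(
            record_id=get("RECORD_ID"),
            species=get("SPECIES"),
            source_class=get("SOURCE_CLASS").strip().lower(),
            latitude=_parse_coord(lat_text),
            longitude=_parse_coord(lon_text),
            lat_text=lat_text,
            lon_text=lon_text,
            coord_system=(get("COORD_SYSTEM").strip().upper() or "DD"),
            utm_resolution_m=utm_res,
            locality=get("LOCALITY").strip(),
            country=get("COUNTRY").strip(),
            adm1=get("ADM1").strip(),
            adm2=get("ADM2").strip(),
            adm3=get("ADM3").strip(),
        ))
    return records


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lat, lon) points (WGS84 sphere)."""
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def is_low_precision(record: OccurrenceRecord) -> bool:
    """The precision-filter removal rule for EXTERNAL records.

    Removed iff decimal-degree coordinates have fewer than two decimals in
    BOTH latitude and longitude, OR the locality description is empty, OR the
    coordinates are UTM with resolution coarser than 1 x 1 km. Accessions are
    never removed by this rule.
    """
    if record.source_class != "external":
        return False
    if not record.locality:
        return True
    if record.coord_system == "UTM":
        return record.utm_resolution_m is None or record.utm_resolution_m > 1000.0
    d_lat, d_lon = record.decimal_counts
    return d_lat < 2 and d_lon < 2


def dedup_spatial(records: list[OccurrenceRecord], threshold_km: float = 1.0,
                  ) -> tuple[list[OccurrenceRecord], list[OccurrenceRecord]]:
    """Clear spatial duplicates: occurrences < threshold apart are one population.

    Greedy scan in deterministic order (quality score descending, then record
    id ascending): a record is retained iff it lies at least ``threshold_km``
    from every already-retained record. Records exactly at the threshold are
    NOT duplicates (the duplicate rule is strict "< 1 km apart"). Returns
    (retained, removed). Intended to be called per species x source class.
    """
    order = sorted(records,
                   key=lambda r: (-(r.quality_score if r.quality_score is not None else 0.0),
                                  r.record_id))
    retained: list[OccurrenceRecord] = []
    removed: list[OccurrenceRecord] = []
    coords: list[tuple[float, float]] = []
    for rec in order:
        p = (rec.latitude, rec.longitude)
        if any(haversine_km(p, q) < threshold_km for q in coords):
            removed.append(rec)
        else:
            retained.append(rec)
            coords.append(p)
    return retained, removed


#: Fraction of full credit per coarser-than-declared admin match level.
_ADMIN_PARTIAL = {"country": 0.25, "adm1": 0.5, "adm2": 0.75, "adm3": 1.0}


def score_georeferencing_quality(record: OccurrenceRecord,
                                 admin_reference: dict | None = None) -> float:
    """Composite 0-100 georeferencing-quality score (three equal sub-scores).

    (i) coordinate precision: declared decimal count (min of lat/lon, capped
    at 4) / 4 for decimal degrees; a resolution ladder for UTM;
    (ii) administrative agreement: point-in-polygon check of the declared
    admin units against ``admin_reference`` — a mapping of
    ``(level, name) -> shapely geometry`` for levels country/adm1/adm2/adm3 —
    with full credit for a match at the finest declared level, partial credit
    for coarser matches, zero for a mismatch;
    (iii) completeness of the site description: locality text plus the four
    admin fields.

    Improving any sub-score never lowers the total. Without a reference
    boundary layer the admin sub-score is excluded and the other two are
    averaged (logged once per call site).
    """
    if not record.has_coordinates:
        return 0.0
    if record.coord_system == "UTM":
        res = record.utm_resolution_m or 1e6
        if res <= 1:
            precision = 1.0
        elif res <= 100:
            precision = 0.9
        elif res <= 1000:
            precision = 0.75
        elif res <= 10000:
            precision = 0.4
        else:
            precision = 0.1
    else:
        precision = min(min(record.decimal_counts), 4) / 4.0

    admin_fields = [record.country, record.adm1, record.adm2, record.adm3]
    completeness = 0.5 * bool(record.locality) + \
        0.5 * sum(bool(f) for f in admin_fields) / len(admin_fields)

    sub_scores = [precision, completeness]
    if admin_reference is not None:
        agreement = _admin_agreement(record, admin_reference)
        sub_scores.append(agreement)
    return 100.0 * float(np.mean(sub_scores))


def _admin_agreement(record: OccurrenceRecord, admin_reference: dict) -> float:
    """Credit of the finest declared admin level whose polygon contains the point.

    Full credit (1.0) for a municipality-level match, partial for matches only
    at coarser levels, 0 when every checkable declared unit disagrees with the
    coordinates (or none is checkable).
    """
    from shapely.geometry import Point

    point = Point(record.longitude, record.latitude)
    declared = [("country", record.country), ("adm1", record.adm1),
                ("adm2", record.adm2), ("adm3", record.adm3)]
    best = 0.0
    for level, name in declared:
        if not name:
            continue
        geom = admin_reference.get((level, name))
        if geom is not None and geom.covers(point):
            best = max(best, _ADMIN_PARTIAL[level])
    return best


@dataclass
class QCPartition:
    """Outcome of the QC chain: four disjoint buckets partitioning the input."""

    retained: list[OccurrenceRecord] = field(default_factory=list)
    removed_no_coords: list[OccurrenceRecord] = field(default_factory=list)
    removed_low_precision: list[OccurrenceRecord] = field(default_factory=list)
    removed_duplicates: list[OccurrenceRecord] = field(default_factory=list)
    quality_threshold: float = 80.0

    @property
    def retained_high_quality(self) -> list[OccurrenceRecord]:
        """Non-duplicated records scoring strictly above the threshold."""
        return [r for r in self.retained
                if r.quality_score is not None and r.quality_score > self.quality_threshold]

    @property
    def retained_low_quality(self) -> list[OccurrenceRecord]:
        return [r for r in self.retained
                if r.quality_score is None or r.quality_score <= self.quality_threshold]

    def all_records(self) -> list[OccurrenceRecord]:
        return (self.retained + self.removed_no_coords
                + self.removed_low_precision + self.removed_duplicates)


def run_qc(records: list[OccurrenceRecord], quality_threshold: float = 80.0,
           duplicate_km: float = 1.0, admin_reference: dict | None = None,
           scorer=score_georeferencing_quality) -> QCPartition:
    """Apply the full QC chain and return the partition of the input.

    Order of operations: missing coordinates -> precision filter (externals
    only) -> quality scoring -> spatial dedup per species x source class.
    The quality threshold does not remove records from the partition; the
    high/low split is exposed on the result so reports can show both counts.
    """
    part = QCPartition(quality_threshold=quality_threshold)
    if admin_reference is None and scorer is score_georeferencing_quality:
        logger.warning("no admin boundaries provided; the admin-agreement "
                       "sub-score of the quality score is skipped")
    candidates: list[OccurrenceRecord] = []
    for rec in records:
        if not rec.has_coordinates:
            part.removed_no_coords.append(rec)
        elif is_low_precision(rec):
            part.removed_low_precision.append(rec)
        else:
            candidates.append(rec)
    for rec in candidates:
        rec.quality_score = scorer(rec, admin_reference)
    groups: dict[tuple[str, str], list[OccurrenceRecord]] = {}
    for rec in candidates:
        groups.setdefault((rec.species, rec.source_class), []).append(rec)
    for key in sorted(groups):
        kept, dropped = dedup_spatial(groups[key], threshold_km=duplicate_km)
        part.retained.extend(kept)
        part.removed_duplicates.extend(dropped)
    return part


def qc_report(partition: QCPartition) -> pd.DataFrame:
    """Per species x source class summary of the QC chain.

    Columns mirror a standard collection-cleaning table: initial counts, the
    removed counts with integer percentages of the initial count (rounded
    half-up), and the non-duplicated records split at the quality threshold.
    """
    rows = []
    buckets = {
        "removed_low_accuracy": partition.removed_low_precision + partition.removed_no_coords,
        "removed_duplicates": partition.removed_duplicates,
        "retained_low_quality": partition.retained_low_quality,
        "retained_high_quality": partition.retained_high_quality,
    }
    keys = sorted({(r.species, r.source_class) for r in partition.all_records()})
    for species, source_class in keys:
        sel = lambda recs: sum(1 for r in recs
                               if r.species == species and r.source_class == source_class)
        initial = sel(partition.all_records())
        row = {"species": species, "source_class": source_class, "initial": initial}
        for name, bucket in buckets.items():
            n = sel(bucket)
            row[name] = n
            row[f"{name}_pct"] = pct(n, initial) if initial else 0
        rows.append(row)
    return pd.DataFrame(rows)
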