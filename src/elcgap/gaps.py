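"""Spatial and ecogeographical gap identification and collection priorities.

A *spatial gap* is an external-source population lying more than 1 km from
every conserved accession of the same species. An *ecogeographical gap* is an
ELC category where the species occurs (per external sources) but from which
the genebank network conserves no accession. External records are ranked
1-10 for collection priority; ranks 1-4 are reserved for records in
unrepresented categories ("priority ecogeographical gaps"), graded by how
rare their category is in the territory. The published toolkit's exact
scoring beyond that defining property is not public, so the rank layout here
is a documented stand-in that preserves it: rank <= 4 if and only if the
record's category holds no accession.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import pct
from .elc import ELCMap
from .qc import OccurrenceRecord


def spatial_gaps(externals: list[OccurrenceRecord], accessions: list[OccurrenceRecord],
                 threshold_km: float = 1.0) -> list[OccurrenceRecord]:
    """External records strictly more than ``threshold_km`` from every accession.

    With no accessions at all, every external record is a spatial gap.
    Distances are great-circle; the comparison is vectorized but equivalent to
    the all-pairs check.
    """
    if not accessions:
        return list(externals)
    acc_lat = np.radians([a.latitude for a in accessions])
    acc_lon = np.radians([a.longitude for a in accessions])
    from ._util import EARTH_RADIUS_KM

    out = []
    for rec in externals:
        lat, lon = math.radians(rec.latitude), math.radians(rec.longitude)
        h = (np.sin((acc_lat - lat) / 2) ** 2
             + math.cos(lat) * np.cos(acc_lat) * np.sin((acc_lon - lon) / 2) ** 2)
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))
        if float(d.min()) > threshold_km:
            out.append(rec)
    return out


@dataclass
class RepresentativenessTable:
    """Category bookkeeping for one species' representativeness analysis."""

    species: str
    total_categories: int
    represented: set[int]  # categories with >= 1 accession
    gap_categories: set[int]  # categories with externals but no accession
    territory_freq: pd.Series  # category -> share of land cells
    external_freq: pd.Series  # category -> share of external records
    accession_freq: pd.Series  # category -> share of accession records


def representativeness(elc: ELCMap, accessions: list[OccurrenceRecord],
                       externals: list[OccurrenceRecord],
                       species: str = "") -> RepresentativenessTable:
    """Classify ELC categories as represented or gaps for one species.

    Records with category 0 (nodata) are excluded. A gap category holds at
    least one external record and zero accessions.
    """
    acc_cats = [r.elc_category for r in accessions if r.elc_category > 0]
    ext_cats = [r.elc_category for r in externals if r.elc_category > 0]
    represented = set(acc_cats)
    gap = set(ext_cats) - represented

    def freq(cats: list[int]) -> pd.Series:
        s = pd.Series(cats, dtype=int).value_counts().sort_index()
        return s / s.sum() if len(s) else pd.Series(dtype=float)

    return RepresentativenessTable(
        species=species,
        total_categories=elc.n_categories,
        represented=represented,
        gap_categories=gap,
        territory_freq=elc.territory_frequencies,
        external_freq=freq(ext_cats),
        accession_freq=freq(acc_cats),
    )


@dataclass
class PriorityRankedRecord:
    record: OccurrenceRecord
    rank: int  # 1..10; 1-4 only for unrepresented categories

    @property
    def is_priority_gap(self) -> bool:
        return self.rank <= 4


def priority_rank(record: OccurrenceRecord, table: RepresentativenessTable,
                  ) -> PriorityRankedRecord:
    """Collection-priority rank (1 = collect first) for one external record.

    Records in unrepresented categories get ranks 1-4: the quartile of their
    category's territory frequency among the unrepresented categories, rarest
    first (ties share the lower rank). Records in represented categories get
    ranks 5-10, increasing with how over-represented the category already is
    in the accession set relative to the external set.
    """
    cat = record.elc_category
    if cat <= 0:
        raise ValueError("record has no ELC category; cannot rank")
    if cat in table.gap_categories or cat not in table.represented:
        freqs = sorted(float(table.territory_freq.get(c, 0.0))
                       for c in table.gap_categories)
        f = float(table.territory_freq.get(cat, 0.0))
        position = sum(1 for x in freqs if x < f)
        rank = 1 + (4 * position) // max(len(freqs), 1)
        return PriorityRankedRecord(record=record, rank=min(rank, 4))
    acc_share = float(table.accession_freq.get(cat, 0.0))
    ext_share = float(table.external_freq.get(cat, 0.0))
    ratio = acc_share / ext_share if ext_share > 0 else 5.0
    return PriorityRankedRecord(record=record, rank=5 + min(5, int(math.floor(5 * ratio))))


def improvement_stats(total_categories: int, represented_count: int,
                      gap_category_count: int) -> tuple[int, int]:
    """Current and potential-improvement representativeness percentages.

    Returns (current %, improvement %) of the category total, rounded half-up
    to integers: the share of categories already represented in the genebank
    network and the share that collecting the gaps would add.
    """
    if total_categories <= 0:
        raise ValueError("ELC map has no categories")
    if represented_count + gap_category_count > total_categories:
        raise ValueError("represented + gap categories exceed the category total")
    return (pct(represented_count, total_categories),
            pct(gap_category_count, total_categories))


@dataclass
class SpeciesGapAnalysis:
    """Per-species result: gaps, priorities, representativeness."""

    species: str
    table: RepresentativenessTable
    spatial_gap_records: list[OccurrenceRecord]
    ranked: list[PriorityRankedRecord]
    n_externals: int

    @property
    def priority_gaps(self) -> list[PriorityRankedRecord]:
        return [r for r in self.ranked if r.is_priority_gap]


def analyze_species(elc: ELCMap, accessions: list[OccurrenceRecord],
                    externals: list[OccurrenceRecord], species: str = "",
                    threshold_km: float = 1.0) -> SpeciesGapAnalysis:
    """Run the full gap analysis for one species (categories must be assigned)."""
    table = representativeness(elc, accessions, externals, species=species)
    gaps = spatial_gaps(externals, accessions, threshold_km=threshold_km)
    ranked = [priority_rank(r, table) for r in externals if r.elc_category > 0]
    return SpeciesGapAnalysis(species=species, table=table, spatial_gap_records=gaps,
                              ranked=ranked, n_externals=len(externals))


def gap_report(analyses: list[SpeciesGapAnalysis]) -> pd.DataFrame:
    """Summary table of spatial and priority ecogeographical gaps per species.

    One row per species plus a TOTAL row; the priority percentage is the
    integer share (half-up) of external records flagged as priority gaps.
    """
    rows = []
    for a in analyses:
        n_priority = len(a.priority_gaps)
        rows.append({
            "species": a.species,
            "n_externals": a.n_externals,
            "n_spatial_gaps": len(a.spatial_gap_records),
            "n_priority_gaps": n_priority,
            "priority_pct": pct(n_priority, a.n_externals) if a.n_externals else 0,
        })
    df = pd.DataFrame(rows)
    if len(df):
        total = {
            "species": "TOTAL",
            "n_externals": int(df["n_externals"].sum()),
            "n_spatial_gaps": int(df["n_spatial_gaps"].sum()),
            "n_priority_gaps": int(df["n_priority_gaps"].sum()),
            "priority_pct": None,
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df


def representativeness_report(analyses: list[SpeciesGapAnalysis]) -> pd.DataFrame:
    """Per-species category counts and representativeness percentages."""
    rows = []
    for a in analyses:
        t = a.table
        current, improvement = improvement_stats(
            t.total_categories, len(t.represented), len(t.gap_categories))
        rows.append({
            "species": a.species,
            "n_categories": t.total_categories,
            "n_represented": len(t.represented),
            "represented_pct": current,
            "n_spatial_gap_categories": len({r.elc_category
                                             for r in a.spatial_gap_records
                                             if r.elc_category > 0}),
            "n_priority_gap_categories": len(t.gap_categories),
            "improvement_pct": improvement,
        })
    return pd.DataFrame(rows)
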