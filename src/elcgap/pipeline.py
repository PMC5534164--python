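"""End-to-end orchestration of the gap-analysis workflow.

One configuration drives the whole chain per species: occurrence QC →
variable selection → ELC map → spatial/ecogeographical gaps and priorities →
predictive characterization. Inputs are either a fixture on disk (occurrence
CSV plus a raster directory) or a synthetic landscape specification; all
randomness derives from one master seed so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from ._util import derive_seed
from .elc import K_MAX, assign_category, cluster_component, combine_components
from .gaps import analyze_species, gap_report, representativeness_report
from .grids import COMPONENTS, read_stack, write_ascii_grid
from .predchar import (
    ARIDITY_THRESHOLD,
    SELECTION_FRACTION,
    climate_at_sites,
    filter_arid,
    pc_report,
    select_top_salinity,
)
from .qc import parse_occurrences, qc_report, records_from_frame, run_qc
from .synthetic import (
    SyntheticLandscapeSpec,
    generate_raster_stack,
    sample_occurrences,
)
from .varsel import (
    DEFAULT_COMPONENT_COUNTS,
    extract_values,
    prune_correlated,
    rank_importance,
    select_final,
)

logger = logging.getLogger(__name__)


@dataclass
class SpeciesSimParams:
    """How to simulate one species' occurrences on a synthetic landscape.

    ``withhold_most_arid`` withholds that many of the landscape's most arid
    categories (lowest Lang-index cells) from the accession set, planting
    exactly the kind of gap the predictive-characterization stage targets.
    """

    name: str
    n_accessions: int = 60
    n_external: int = 300
    withheld_categories: tuple[int, ...] = ()
    withhold_most_arid: int = 0
    dup_fraction: float = 0.1
    degrade_fraction: float = 0.1


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the workflow's standard values: quality score > 80,
    1 km duplicate/gap distance, |r| > 0.50 with p < 0.05 pruning among the
    top 15 variables, at most 8 clusters per component, Lang index < 40 and a
    20% salinity selection; 3 + 3 + 2 variables per component (plus lat/lon).
    """

    output_dir: str = "elcgap_output"
    occurrences_path: str | None = None
    rasters_dir: str | None = None
    admin_boundaries_path: str | None = None
    synthetic: SyntheticLandscapeSpec | None = None
    species_sim: list[SpeciesSimParams] = field(default_factory=list)
    quality_threshold: float = 80.0
    distance_km: float = 1.0
    r_threshold: float = 0.50
    alpha: float = 0.05
    top_n: int = 15
    k_max: int = K_MAX
    aridity_threshold: float = ARIDITY_THRESHOLD
    selection_fraction: float = SELECTION_FRACTION
    component_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_COUNTS))
    seed: int = 0


def validate_config(config: PipelineConfig) -> list[str]:
    """All configuration violations (empty list = valid). Never mutates."""
    errors = []
    for name in ("quality_threshold", "distance_km", "r_threshold", "alpha"):
        if getattr(config, name) <= 0:
            errors.append(f"{name} must be positive")
    # threshold 0 is a legal degenerate setting: it yields an empty PC subset
    if config.aridity_threshold < 0:
        errors.append("aridity_threshold must be non-negative")
    if not 0 < config.selection_fraction <= 1:
        errors.append("selection_fraction must be in (0, 1]")
    if config.top_n < 1:
        errors.append("top_n must be at least 1")
    if not 1 <= config.k_max <= 8:
        errors.append("k_max must be in 1..8")
    if set(config.component_counts) - set(COMPONENTS):
        errors.append("component_counts has unknown components")
    if any(v < 1 for v in config.component_counts.values()):
        errors.append("component_counts entries must be at least 1")
    if config.synthetic is None:
        if not config.occurrences_path or not config.rasters_dir:
            errors.append("either a synthetic spec or occurrences_path + rasters_dir "
                          "must be provided")
        else:
            for p in (config.occurrences_path, config.rasters_dir):
                if not Path(p).exists():
                    errors.append(f"input path does not exist: {p}")
    elif not config.species_sim:
        errors.append("synthetic mode needs at least one species_sim entry")
    return errors


@dataclass
class ReportBundle:
    """All output tables of one run plus the run log."""

    tables: dict[str, pd.DataFrame]
    elc_maps: dict[str, object]  # species -> ELCMap
    run_log: dict

    def write(self, directory: str | Path) -> Path:
        """Write every table as CSV, ELC rasters as ASCII grids, and the log."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(directory / f"{name}.csv", index=False)
        for species, elc in self.elc_maps.items():
            slug = species.replace(" ", "_").replace(".", "")
            write_ascii_grid(directory / f"elc_{slug}.asc", elc.geometry,
                             elc.categories.astype(float))
            elc.legend.to_csv(directory / f"elc_{slug}_legend.csv", index=False)
        with open(directory / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(self.run_log, fh, indent=2, default=str)
        return directory


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = config.synthetic
        spec.seed = derive_seed(config.seed, "landscape")
        stack, truth = generate_raster_stack(spec)
        frames = []
        for i, sp in enumerate(config.species_sim):
            withheld = set(sp.withheld_categories)
            if sp.withhold_most_arid:
                from .predchar import PRECIPITATION_VAR, TEMPERATURE_VAR

                ai = stack.layers[PRECIPITATION_VAR] / stack.layers[TEMPERATURE_VAR]
                arid_share = {
                    c: float((ai[truth.category_raster == c]
                              < config.aridity_threshold).mean())
                    for c in sorted(truth.categories)}
                ranked = sorted(arid_share, key=lambda c: -arid_share[c])
                withheld |= set(ranked[:sp.withhold_most_arid])
            frames.append(sample_occurrences(
                truth, sp.n_accessions, sp.n_external,
                withheld_categories=withheld,
                dup_fraction=sp.dup_fraction, degrade_fraction=sp.degrade_fraction,
                seed=derive_seed(config.seed, f"occurrences/{sp.name}"),
                species=sp.name))
        table = pd.concat(frames, ignore_index=True)
        return stack, records_from_frame(table), truth
    stack = read_stack(config.rasters_dir)
    records = parse_occurrences(config.occurrences_path)
    return stack, records, None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage for every species and bundle the reports.

    Species lacking either accessions or external records after QC are
    reported in the run log and skipped. Any stage failure is re-raised with
    the stage and species named.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    stack, records, _truth = _load_inputs(config)

    partition = run_qc(records, quality_threshold=config.quality_threshold,
                       duplicate_km=config.distance_km)
    tables: dict[str, pd.DataFrame] = {"qc": qc_report(partition)}
    clean = partition.retained_high_quality

    by_species: dict[str, dict[str, list]] = {}
    for rec in clean:
        groups = by_species.setdefault(rec.species, {"accession": [], "external": []})
        groups.setdefault(rec.source_class, []).append(rec)

    analyses = []
    selections = []
    elc_maps = {}
    pc_subsets = []
    skipped = []
    for species in sorted(by_species):
        groups = by_species[species]
        accessions = groups.get("accession", [])
        externals = groups.get("external", [])
        if not accessions or not externals:
            skipped.append(species)
            continue
        stage = "variable selection"
        try:
            matrix = extract_values(stack, accessions + externals)
            pruned = {}
            for comp in COMPONENTS:
                ranking = rank_importance(
                    matrix, comp, seed=derive_seed(config.seed, f"rank/{species}/{comp}"))
                pruned[comp] = prune_correlated(
                    ranking, matrix, top_n=config.top_n,
                    r_threshold=config.r_threshold, alpha=config.alpha)
            selection = select_final(pruned, counts=config.component_counts)
            sel_report = selection.report()
            sel_report.insert(0, "species", species)
            selections.append(sel_report)

            stage = "ELC map"
            clusterings = {
                comp: cluster_component(
                    stack, selection.by_component[comp], comp, k_max=config.k_max,
                    seed=derive_seed(config.seed, f"elc/{species}/{comp}"))
                for comp in COMPONENTS
            }
            elc = combine_components(clusterings["bioclimatic"], clusterings["edaphic"],
                                     clusterings["geophysic"], stack=stack)
            elc_maps[species] = elc
            assign_category(elc, accessions + externals)

            stage = "gap analysis"
            analysis = analyze_species(elc, accessions, externals, species=species,
                                       threshold_km=config.distance_km)
            analyses.append(analysis)

            stage = "predictive characterization"
            priority_records = [r.record for r in analysis.priority_gaps]
            climate = climate_at_sites(stack, priority_records)
            arid = (filter_arid(climate, threshold=config.aridity_threshold)
                    if len(climate) else climate)
            pc_subsets.append(select_top_salinity(arid, fraction=config.selection_fraction))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for species {species!r}: {exc}"
                               ) from exc

    tables["variable_selection"] = (pd.concat(selections, ignore_index=True)
                                    if selections else pd.DataFrame())
    tables["gap_summary"] = gap_report(analyses)
    tables["representativeness"] = representativeness_report(analyses)
    if pc_subsets:
        tables["pc_trace"] = pd.concat([s.trace for s in pc_subsets], ignore_index=True)
        merged_arid = pd.concat([s.arid for s in pc_subsets], ignore_index=True)
        merged_sel = pd.concat([s.selected for s in pc_subsets], ignore_index=True)
        from .predchar import PCSubset

        tables["pc_subset"] = pc_report(PCSubset(arid=merged_arid, selected=merged_sel,
                                                 trace=tables["pc_trace"]))
    else:
        tables["pc_trace"] = pd.DataFrame(columns=["species", "n_arid", "fraction",
                                                   "n_selected"])
        tables["pc_subset"] = pd.DataFrame()

    run_log = {
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("synthetic", "species_sim")},
        "species_analyzed": [a.species for a in analyses],
        "species_skipped": skipped,
    }
    bundle = ReportBundle(tables=tables, elc_maps=elc_maps, run_log=run_log)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
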