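"""Selection of ecogeographical variables at occurrence sites.

For each species, the environmental layers are sampled at the retained
occurrence sites and, within each ecogeographical component, variables are
ranked by random-forest importance and pruned of redundant (strongly
correlated) members. The final set — by default the top three bioclimatic,
three edaphic and two geophysic survivors, plus latitude and longitude as two
extra geophysic variables — feeds the land-characterization clustering.

The random-forest ranking targets the adaptive scenarios themselves: the
component's site matrix is pre-clustered (standardized K-means with the same
elbow rule used for the land-characterization maps), a random-forest
classifier is trained to predict the cluster labels, and importance is the
permutation importance (mean decrease in accuracy) of each variable in that
task. Variables that define the environmental zonation of the occurrence
sites rank high; structureless noise variables rank near zero. The ranking is
a stand-in isolated behind `rank_importance` and can be swapped for any
function with the same signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .grids import LATITUDE_VAR, LONGITUDE_VAR, EcoRasterStack
from .qc import OccurrenceRecord

logger = logging.getLogger(__name__)


@dataclass
class SiteVariableMatrix:
    """Environmental values at occurrence sites (rows = records, cols = variables)."""

    values: pd.DataFrame  # indexed by record_id
    components: dict[str, str]
    excluded: list[str] = field(default_factory=list)  # record ids off-grid / on nodata

    def component_frame(self, component: str) -> pd.DataFrame:
        cols = [v for v, c in self.components.items() if c == component]
        return self.values[cols]


def extract_values(stack: EcoRasterStack, records: list[OccurrenceRecord]) -> SiteVariableMatrix:
    """Sample every layer at each record's containing cell.

    Cells are half-open lat/lon intervals; records outside the grid or on a
    nodata cell are excluded from the matrix and listed on ``excluded``.
    """
    names = stack.variables()
    rows, index, excluded = [], [], []
    for rec in records:
        cell = stack.geometry.cell_index(rec.latitude, rec.longitude)
        if cell is None:
            excluded.append(rec.record_id)
            continue
        vec = [stack.layers[name][cell] for name in names]
        if any(np.isnan(v) for v in vec):
            excluded.append(rec.record_id)
            continue
        rows.append(vec)
        index.append(rec.record_id)
    values = pd.DataFrame(rows, index=index, columns=names)
    return SiteVariableMatrix(values=values, components=dict(stack.components),
                              excluded=excluded)


@dataclass
class ImportanceRanking:
    """Importance-ordered variables of one component, before/after pruning."""

    component: str
    ranking: list[tuple[str, float]]  # (variable, mean decrease in accuracy), descending
    pruned: list[str] = field(default_factory=list)  # survivors, still in rank order
    dropped_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (kept variable, dropped variable, Pearson r, p-value)

    @property
    def variables(self) -> list[str]:
        return [v for v, _ in self.ranking]


def rank_importance(matrix: SiteVariableMatrix, component: str, seed: int,
                    n_trees: int = 500, n_repeats: int = 5,
                    k_max: int = 8) -> ImportanceRanking:
    """Rank one component's variables by random-forest mean decrease in accuracy.

    The response is the environmental zonation of the sites themselves: rows
    are z-standardized and clustered with K-means (k chosen by the 50%-drop
    elbow rule up to ``k_max``, floored at 2 so a classification target always
    exists), a random forest predicts the cluster labels, and importance is
    the permutation importance averaged over ``n_repeats`` shuffles.
    Deterministic for a fixed seed; ties are broken by variable name so the
    ranking is a total order.
    """
    from sklearn.cluster import KMeans

    from .elc import elbow_k

    frame = matrix.component_frame(component)
    if frame.shape[1] < 2:
        raise ValueError(f"component {component!r} needs at least 2 variables")
    if frame.shape[0] < 20:
        raise ValueError("need at least 20 occurrence rows to rank variables")
    rng = np.random.default_rng(seed)
    X = frame.to_numpy(dtype=float)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    km_seed = int(rng.integers(2**31))
    k_max = min(k_max, len(Z) - 1)
    fits = [KMeans(n_clusters=k, n_init=5, random_state=km_seed).fit(Z)
            for k in range(1, k_max + 1)]
    k = max(elbow_k([float(f.inertia_) for f in fits], k_max=k_max), 2)
    y = fits[k - 1].labels_

    forest = RandomForestClassifier(n_estimators=n_trees,
                                    random_state=int(rng.integers(2**31)))
    forest.fit(Z, y)
    perm = permutation_importance(forest, Z, y, n_repeats=n_repeats,
                                  random_state=int(rng.integers(2**31)),
                                  scoring="accuracy")
    pairs = sorted(zip(frame.columns, perm.importances_mean),
                   key=lambda kv: (-kv[1], kv[0]))
    return ImportanceRanking(component=component, ranking=[(v, float(s)) for v, s in pairs])


def prune_correlated(ranking: ImportanceRanking, matrix: SiteVariableMatrix,
                     top_n: int = 15, r_threshold: float = 0.50,
                     alpha: float = 0.05) -> ImportanceRanking:
    """Drop redundant variables among the top of the ranking.

    The ranking is truncated to its ``top_n`` best variables, then pairs are
    scanned in rank order: when |Pearson r| exceeds the threshold with a
    two-sided p-value below ``alpha`` (t-test, n-2 df), the lower-ranked
    member is dropped. A dropped variable cannot later drop others, so the
    top-ranked variable always survives.
    """
    top = ranking.variables[:top_n]
    dropped: set[str] = set()
    pairs: list[tuple[str, str, float, float]] = []
    for i, vi in enumerate(top):
        if vi in dropped:
            continue
        for vj in top[i + 1:]:
            if vj in dropped:
                continue
            r, p = stats.pearsonr(matrix.values[vi], matrix.values[vj])
            if abs(r) > r_threshold and p < alpha:
                dropped.add(vj)
                pairs.append((vi, vj, float(r), float(p)))
    survivors = [v for v in top if v not in dropped]
    return ImportanceRanking(component=ranking.component, ranking=ranking.ranking,
                             pruned=survivors, dropped_pairs=pairs)


#: How many surviving variables each component contributes to the final set.
DEFAULT_COMPONENT_COUNTS = {"bioclimatic": 3, "edaphic": 3, "geophysic": 2}


@dataclass
class VariableSelection:
    """Final per-component variable choice used to build the land-characterization map."""

    by_component: dict[str, list[str]]

    def all_variables(self) -> list[str]:
        return [v for vars_ in self.by_component.values() for v in vars_]

    def report(self) -> pd.DataFrame:
        rows = [
            {"component": comp, "rank": i + 1, "variable": var}
            for comp, vars_ in self.by_component.items()
            for i, var in enumerate(vars_)
        ]
        return pd.DataFrame(rows)


def select_final(pruned: dict[str, ImportanceRanking],
                 counts: dict[str, int] | None = None) -> VariableSelection:
    """Take the top surviving variables per component and append lat/lon.

    Latitude and longitude of the cell centers join the geophysic component as
    two additional variables so the clustered categories aggregate spatially.
    Components with fewer survivors than requested contribute what they have
    (with a warning).
    """
    counts = counts or DEFAULT_COMPONENT_COUNTS
    chosen: dict[str, list[str]] = {}
    for comp, want in counts.items():
        survivors = pruned[comp].pruned or pruned[comp].variables
        if len(survivors) < want:
            warnings.warn(
                f"component {comp!r}: only {len(survivors)} variables survive "
                f"pruning, requested {want}", stacklevel=2)
        chosen[comp] = survivors[:want]
    chosen["geophysic"] = chosen.get("geophysic", []) + [LATITUDE_VAR, LONGITUDE_VAR]
    return VariableSelection(by_component=chosen)
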