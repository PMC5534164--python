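"""Elbow rule, per-component clustering, category combination and assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from elcgap.elc import (
    assign_category,
    cluster_component,
    combine_components,
    elbow_k,
)
from elcgap.grids import GridGeometry
from elcgap.qc import OccurrenceRecord


class TestElbowRule:
    @pytest.mark.parametrize("wss,expected", [
        ([100, 40, 25, 20], 2),     # 60% drop, then 37.5% < 50%
        ([100, 60], 1),             # first drop already below 50%
        ([100, 50, 25, 12.5], 4),   # every drop exactly 50% -> cap
        ([100, 0, 0], 2),           # zero WSS stops the scan
    ])
    def test_worked_examples(self, wss, expected):
        assert elbow_k(wss) == expected

    def test_needs_two_entries(self):
        with pytest.raises(ValueError):
            elbow_k([10.0])

    @settings(deadline=None)
    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=7))
    def test_chosen_k_satisfies_the_rule(self, drops):
        # build a non-increasing WSS curve from arbitrary drop fractions
        wss = [1000.0]
        for d in drops:
            wss.append(wss[-1] * (1 - d))
        k = elbow_k(wss)
        assert 1 <= k <= len(wss)
        if k < len(wss):
            assert (wss[k - 1] - wss[k]) / wss[k - 1] < 0.5
        for n in range(1, k):
            assert (wss[n - 1] - wss[n]) / wss[n - 1] >= 0.5


class TestClusterComponent:
    def test_zero_noise_recovers_truth_exactly(self, quiet_landscape):
        stack, truth = quiet_landscape
        for comp in ("bioclimatic", "edaphic", "geophysic"):
            cc = cluster_component(stack, stack.variables(comp), comp, seed=3)
            assert cc.chosen_k == 3
            land = stack.land_mask
            ari = adjusted_rand_score(truth.component_labels[comp][land],
                                      cc.labels[land])
            assert ari == pytest.approx(1.0)

    def test_wss_non_increasing(self, landscape):
        stack, _ = landscape
        cc = cluster_component(stack, stack.variables("edaphic"), "edaphic", seed=0)
        assert all(b <= a * (1 + 1e-9) for a, b in zip(cc.wss, cc.wss[1:]))

    def test_constant_variable_dropped_with_warning(self, landscape):
        stack, _ = landscape
        const = np.where(stack.land_mask, 5.0, np.nan)
        stack_vars = stack.variables("edaphic")
        stack.add_layer("flat", const, "edaphic")
        try:
            with pytest.warns(UserWarning, match="flat"):
                cc = cluster_component(stack, stack_vars + ["flat"], "edaphic", seed=0)
            assert "flat" not in cc.variables
        finally:
            del stack.layers["flat"], stack.components["flat"]

    def test_all_constant_is_an_error(self, landscape):
        stack, _ = landscape
        const = np.where(stack.land_mask, 5.0, np.nan)
        stack.add_layer("flat2", const, "edaphic")
        try:
            with pytest.warns(UserWarning):
                with pytest.raises(ValueError, match="no non-constant"):
                    cluster_component(stack, ["flat2"], "edaphic", seed=0)
        finally:
            del stack.layers["flat2"], stack.components["flat2"]

    def test_same_seed_identical_labels(self, landscape):
        stack, _ = landscape
        a = cluster_component(stack, stack.variables("bioclimatic"), "bioclimatic", seed=9)
        b = cluster_component(stack, stack.variables("bioclimatic"), "bioclimatic", seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)


def label_raster(values):
    return np.asarray(values, dtype=int)


def clustering_from_labels(labels, component):
    from elcgap.elc import ComponentClustering

    labels = label_raster(labels)
    k = int(labels.max())
    geometry = GridGeometry(west=0.0, north=float(labels.shape[0]), cell_size=1.0,
                            n_rows=labels.shape[0], n_cols=labels.shape[1])
    return ComponentClustering(component=component, variables=[], standardization={},
                               wss=[], chosen_k=k, centers=np.zeros((k, 1)),
                               labels=labels, geometry=geometry)


class TestCombine:
    def test_all_triples_realized_gives_27_categories(self):
        # 27 cells enumerating every (bio, edaph, geoph) triple with k = 3 each
        triples = [(b, e, g) for b in (1, 2, 3) for e in (1, 2, 3) for g in (1, 2, 3)]
        shape = (3, 9)
        bio = label_raster(np.array([t[0] for t in triples]).reshape(shape))
        ed = label_raster(np.array([t[1] for t in triples]).reshape(shape))
        geo = label_raster(np.array([t[2] for t in triples]).reshape(shape))
        elc = combine_components(clustering_from_labels(bio, "bioclimatic"),
                                 clustering_from_labels(ed, "edaphic"),
                                 clustering_from_labels(geo, "geophysic"))
        assert elc.n_categories == 27
        legend = elc.legend
        assert legend["category"].tolist() == list(range(1, 28))
        # lexicographic by (bio, edaph, geoph)
        assert legend.iloc[0][["bioclimatic", "edaphic", "geophysic"]].tolist() == [1, 1, 1]
        assert not legend.duplicated(["bioclimatic", "edaphic", "geophysic"]).any()

    def test_category_count_bounded_by_product_of_ks(self):
        bio = label_raster([[1, 2], [2, 1]])
        ones = label_raster([[1, 1], [1, 1]])
        elc = combine_components(clustering_from_labels(bio, "bioclimatic"),
                                 clustering_from_labels(ones, "edaphic"),
                                 clustering_from_labels(ones, "geophysic"))
        assert elc.n_categories <= 2

    def test_unrealized_triples_absent_and_nodata_propagates(self):
        bio = label_raster([[1, 2], [0, 1]])  # one nodata cell
        ed = label_raster([[1, 1], [1, 2]])
        geo = label_raster([[1, 1], [1, 1]])
        elc = combine_components(clustering_from_labels(bio, "bioclimatic"),
                                 clustering_from_labels(ed, "edaphic"),
                                 clustering_from_labels(geo, "geophysic"))
        assert elc.categories[1, 0] == 0
        observed = {tuple(r) for r in
                    elc.legend[["bioclimatic", "edaphic", "geophysic"]].to_numpy()}
        assert (2, 2, 1) not in observed  # realized by zero cells

    def test_grid_mismatch_rejected(self):
        a = clustering_from_labels([[1]], "bioclimatic")
        b = clustering_from_labels([[1, 1]], "edaphic")
        c = clustering_from_labels([[1]], "geophysic")
        with pytest.raises(ValueError, match="grid"):
            combine_components(a, b, c)


class TestAssignCategory:
    def test_assignment_matches_ground_truth_at_zero_noise(self, quiet_landscape):
        from elcgap.synthetic import sample_occurrences

        stack, truth = quiet_landscape
        clusterings = {c: cluster_component(stack, stack.variables(c), c, seed=1)
                       for c in ("bioclimatic", "edaphic", "geophysic")}
        elc = combine_components(clusterings["bioclimatic"], clusterings["edaphic"],
                                 clusterings["geophysic"])
        table = sample_occurrences(truth, 0, 80, seed=13)
        records = [
            OccurrenceRecord(record_id=r.RECORD_ID, species="s", source_class="external",
                             latitude=float(r.DECLATITUDE), longitude=float(r.DECLONGITUDE))
            for r in table.itertuples()
        ]
        assign_category(elc, records)
        truth_cat = truth.record_flags.set_index("RECORD_ID")["TRUE_CATEGORY"]
        # perfect recovery up to label permutation: the map record->assigned
        # category must be a bijection of the map record->true category
        pairs = {(truth_cat[r.record_id], r.elc_category) for r in records}
        assert len({a for a, _ in pairs}) == len(pairs)
        assert len({b for _, b in pairs}) == len(pairs)

    def test_sea_record_gets_category_zero_with_warning(self, quiet_landscape):
        stack, _ = quiet_landscape
        clustering = cluster_component(stack, stack.variables("edaphic"), "edaphic", seed=1)
        elc = combine_components(clustering, clustering, clustering)
        sea_lat, sea_lon = stack.geometry.cell_center(0, 0)
        rec = OccurrenceRecord(record_id="SEA", species="s", source_class="external",
                               latitude=sea_lat, longitude=sea_lon)
        with pytest.warns(UserWarning, match="nodata"):
            assign_category(elc, [rec])
        assert rec.elc_category == 0
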