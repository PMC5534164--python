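"""Occurrence parsing, precision filtering, dedup and quality scoring."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from elcgap._util import EARTH_RADIUS_KM, pct
from elcgap.qc import (
    OccurrenceRecord,
    dedup_spatial,
    haversine_km,
    is_low_precision,
    parse_occurrences,
    qc_report,
    run_qc,
    score_georeferencing_quality,
)

DATA = __file__.rsplit("/", 1)[0] + "/data"


def make_record(lat_text="41.700833", lon_text="-0.045000", source_class="external",
                **kwargs) -> OccurrenceRecord:
    defaults = dict(record_id="R1", species="Ae. test", locality="roadside",
                    country="Spain", adm1="Huesca", adm2="Comarca", adm3="Sigena")
    defaults.update(kwargs)
    return OccurrenceRecord(latitude=float(lat_text), longitude=float(lon_text),
                            lat_text=lat_text, lon_text=lon_text,
                            source_class=source_class, **defaults)


class TestParsing:
    def test_decimal_counts_come_from_text(self):
        rec = make_record("41.700833", "-0.045000")
        assert rec.decimal_counts == (6, 6)
        assert make_record("41.7", "-0.0").decimal_counts == (1, 1)
        assert make_record("41", "-0").decimal_counts == (0, 0)

    def test_published_survey_table_parses_fully(self):
        # A 45-row survey of Iberian Aegilops populations re-encoded as CSV.
        records = parse_occurrences(f"{DATA}/selected_sites.csv")
        assert len(records) == 45
        assert all(r.has_coordinates for r in records)
        assert records[0].decimal_counts == (6, 6)

    def test_unicode_minus_is_parsed(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "SPECIES,SOURCE_CLASS,DECLATITUDE,DECLONGITUDE,RECORD_ID\n"
            "Ae. t,external,41.700833,−0.045000,R1\n")
        (rec,) = parse_occurrences(path)
        assert rec.longitude == pytest.approx(-0.045)

    def test_empty_latitude_lands_in_no_coords_bucket(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text(
            "SPECIES,SOURCE_CLASS,DECLATITUDE,DECLONGITUDE,LOCALITY,RECORD_ID\n"
            "Ae. t,external,,-0.5,somewhere,R1\n")
        part = run_qc(parse_occurrences(path))
        assert [r.record_id for r in part.removed_no_coords] == ["R1"]

    def test_missing_mandatory_columns_named(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text("SPECIES,DECLATITUDE\nx,1\n")
        with pytest.raises(ValueError, match="DECLONGITUDE"):
            parse_occurrences(path)


class TestPrecisionFilter:
    @pytest.mark.parametrize("lat,lon,removed", [
        ("41.7", "-0.0", True),    # one decimal in both
        ("41.70", "-0.1", False),  # only one coordinate is coarse
        ("41", "-0", True),        # no decimals at all
        ("41.70", "-0.10", False),
    ])
    def test_decimal_rule_requires_both_coarse(self, lat, lon, removed):
        assert is_low_precision(make_record(lat, lon)) is removed

    def test_missing_locality_removes_external(self):
        assert is_low_precision(make_record(locality=""))

    def test_utm_coarser_than_1km_removed(self):
        rec = make_record(coord_system="UTM", utm_resolution_m=10_000)
        assert is_low_precision(rec)
        assert not is_low_precision(make_record(coord_system="UTM", utm_resolution_m=1000))

    def test_accessions_are_never_removed(self):
        rec = make_record("41.7", "-0.0", source_class="accession", locality="")
        assert not is_low_precision(rec)


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert haversine_km((40.0, -3.0), (40.0, -3.0)) == 0.0

    def test_one_degree_of_longitude_at_equator(self):
        expected = EARTH_RADIUS_KM * math.pi / 180  # closed-form arc length
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(expected)
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.1951, abs=1e-3)

    @settings(deadline=None)
    @given(st.tuples(st.floats(-80, 80), st.floats(-179, 179)),
           st.tuples(st.floats(-80, 80), st.floats(-179, 179)))
    def test_symmetric_and_nonnegative(self, a, b):
        assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))
        assert haversine_km(a, b) >= 0


def _random_records(rng, n, lat0=40.0, lon0=-3.0, spread_deg=0.05):
    out = []
    for i in range(n):
        out.append(make_record(
            f"{lat0 + rng.uniform(-spread_deg, spread_deg):.6f}",
            f"{lon0 + rng.uniform(-spread_deg, spread_deg):.6f}",
            record_id=f"R{i:04d}", quality_score=float(rng.integers(50, 100))))
    return out


class TestDedup:
    def test_higher_quality_of_close_pair_is_kept(self):
        a = make_record("40.000000", "-3.000000", record_id="A", quality_score=90)
        b = make_record("40.004000", "-3.000000", record_id="B", quality_score=95)
        retained, removed = dedup_spatial([a, b])
        assert [r.record_id for r in retained] == ["B"]
        assert [r.record_id for r in removed] == ["A"]

    def test_chain_keeps_the_endpoints(self):
        # A-B = B-C = 0.8 km, A-C = 1.6 km; equal quality; greedy scan by id
        # retains A, drops B (too close to A), then retains C.
        step = 0.8 / (EARTH_RADIUS_KM * math.pi / 180)
        recs = [make_record(f"{40 + i * step:.8f}", "-3.000000",
                            record_id=chr(65 + i), quality_score=90) for i in range(3)]
        retained, removed = dedup_spatial(recs)
        assert [r.record_id for r in retained] == ["A", "C"]
        assert [r.record_id for r in removed] == ["B"]

    def test_at_the_1km_threshold_both_retained(self):
        # duplicates are strictly "< 1 km apart": at the threshold nothing is removed
        step = 1.0 / (EARTH_RADIUS_KM * math.pi / 180)
        a = make_record("40.000000", "-3.000000", record_id="A", quality_score=90)
        b = make_record(f"{40 + step + 1e-9:.12f}", "-3.000000", record_id="B",
                        quality_score=90)
        assert haversine_km((a.latitude, a.longitude), (b.latitude, b.longitude)) >= 1.0
        retained, removed = dedup_spatial([a, b])
        assert len(retained) == 2 and not removed

    def test_contract_against_brute_force(self, rng):
        records = _random_records(rng, 400)
        retained, removed = dedup_spatial(records)
        pts = [(r.latitude, r.longitude) for r in retained]
        for i, p in enumerate(pts):
            for q in pts[i + 1:]:
                assert haversine_km(p, q) >= 1.0
        for r in removed:
            assert any(haversine_km((r.latitude, r.longitude), p) < 1.0 for p in pts)

    def test_idempotent(self, rng):
        records = _random_records(rng, 300)
        once, _ = dedup_spatial(records)
        twice, dropped = dedup_spatial(once)
        assert [r.record_id for r in twice] == [r.record_id for r in once]
        assert not dropped


class TestQualityScore:
    def test_perfect_record_scores_100(self):
        boundaries = {("adm3", "Sigena"): box(-1.0, 41.0, 1.0, 42.0)}
        rec = make_record("41.700833", "-0.045000")
        assert score_georeferencing_quality(rec, boundaries) == 100.0

    def test_wrong_province_caps_total_at_67(self):
        boundaries = {("adm1", "Huesca"): box(10.0, 50.0, 11.0, 51.0)}  # elsewhere
        rec = make_record("41.700833", "-0.045000", adm2="", adm3="")
        score = score_georeferencing_quality(rec, boundaries)
        assert score <= 67.0

    def test_degrading_precision_never_raises_score(self):
        for n_from in range(1, 7):
            for n_to in range(n_from):
                hi = make_record(f"41.{'1' * n_from}", f"-0.{'1' * n_from}")
                lo = make_record(f"41.{'1' * n_to}" if n_to else "41",
                                 f"-0.{'1' * n_to}" if n_to else "-0")
                assert (score_georeferencing_quality(lo, None)
                        <= score_georeferencing_quality(hi, None))

    def test_without_boundaries_two_subscores_average(self):
        rec = make_record("41.700833", "-0.045000")
        assert score_georeferencing_quality(rec, None) == 100.0
        bare = make_record("41.700833", "-0.045000", locality="",
                           country="", adm1="", adm2="", adm3="")
        assert score_georeferencing_quality(bare, None) == pytest.approx(50.0)


class TestReport:
    def test_partition_covers_every_record_once(self, landscape):
        from elcgap.qc import records_from_frame
        from elcgap.synthetic import sample_occurrences

        _, truth = landscape
        table = sample_occurrences(truth, 40, 200, dup_fraction=0.1,
                                   degrade_fraction=0.1, seed=8)
        records = records_from_frame(table)
        part = run_qc(records)
        ids = sorted(r.record_id for r in part.all_records())
        assert ids == sorted(r.record_id for r in records)
        buckets = [part.retained, part.removed_no_coords,
                   part.removed_low_precision, part.removed_duplicates]
        assert sum(len(b) for b in buckets) == len(records)

    @pytest.mark.parametrize("n,initial,expected", [
        (1879, 4850, 39),  # duplicate share of a large external dataset
        (13, 30, 43),      # low-accuracy share of a small one
        (0, 30, 0),
    ])
    def test_percentages_round_half_up(self, n, initial, expected):
        assert pct(n, initial) == expected

    def test_report_counts_sum_to_initial(self, landscape):
        from elcgap.qc import records_from_frame
        from elcgap.synthetic import sample_occurrences

        _, truth = landscape
        table = sample_occurrences(truth, 40, 200, dup_fraction=0.1,
                                   degrade_fraction=0.15, seed=9)
        part = run_qc(records_from_frame(table))
        report = qc_report(part)
        parts = report[["removed_low_accuracy", "removed_duplicates",
                        "retained_low_quality", "retained_high_quality"]].sum(axis=1)
        assert (parts == report["initial"]).all()
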