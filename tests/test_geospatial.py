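"""Record filtering, coordinate collapse, and spiderfy geometry."""

from __future__ import annotations

import math
import random
from datetime import date

import pytest

from qpcrmap import GeoCluster, cluster_points, filter_records, spiderfy
from qpcrmap.geospatial import spiderfy_offsets

from _oracles import brute_force_components, brute_force_filter
from conftest import make_record


def records_at(coords):
    return [
        make_record(well=f"A{i + 1}", lat=lat, lon=lon)
        for i, (lat, lon) in enumerate(coords)
    ]


class TestFilterRecords:
    @pytest.fixture()
    def mixed(self):
        return [
            make_record(well="A1", species="Salmo salar",
                        scope="multicellular organism", when=date(2020, 1, 5)),
            make_record(well="A2", species="Salmo salar",
                        scope="multicellular organism", when=date(2020, 6, 5)),
            make_record(well="A3", species="Frog virus 3", scope="virus",
                        when=date(2020, 3, 1)),
            make_record(well="A4", species="Esox lucius",
                        scope="multicellular organism", when=date(2019, 12, 31)),
        ]

    def test_no_filters_is_identity(self, mixed):
        assert filter_records(mixed) == mixed

    def test_species_filter(self, mixed):
        kept = filter_records(mixed, species=["Salmo salar"])
        assert [r.metadata.run_location for r in kept] == ["A1", "A2"]

    def test_conjunction_and_inclusive_dates(self, mixed):
        kept = filter_records(
            mixed,
            scope=["multicellular organism"],
            date_range=(date(2020, 1, 5), date(2020, 6, 5)),
        )
        assert [r.metadata.run_location for r in kept] == ["A1", "A2"]

    def test_reversed_range_rejected(self, mixed):
        with pytest.raises(ValueError):
            filter_records(mixed, date_range=(date(2021, 1, 1), date(2020, 1, 1)))

    def test_matches_row_scan_oracle(self):
        rng = random.Random(9)
        from conftest import random_record

        records = [random_record(rng, f"A{i}") for i in range(60)]
        cases = [
            (None, None, None),
            (["virus"], None, None),
            (None, ["Salmo salar", "Esox lucius"], None),
            (None, None, (date(2019, 6, 1), date(2020, 6, 1))),
            (["multicellular organism"], ["Salmo salar"],
             (date(2019, 1, 1), date(2020, 12, 31))),
        ]
        for scope, species, date_range in cases:
            assert filter_records(
                records, scope, species, date_range
            ) == brute_force_filter(records, scope, species, date_range)


class TestClusterPoints:
    def test_within_tolerance_collapses(self):
        clusters = cluster_points(records_at([(0, 0), (0.004, 0.004)]))
        assert len(clusters) == 1
        assert clusters[0].members == (0, 1)

    def test_beyond_tolerance_stays_apart(self):
        clusters = cluster_points(records_at([(0, 0), (0.006, 0)]))
        assert len(clusters) == 2

    def test_exact_tolerance_is_inclusive(self):
        assert len(cluster_points(records_at([(0, 0), (0.005, 0.005)]))) == 1

    def test_chain_links_transitively(self):
        clusters = cluster_points(records_at([(0, 0), (0.004, 0), (0.008, 0)]))
        assert len(clusters) == 1
        assert clusters[0].members == (0, 1, 2)

    def test_box_rule_not_euclidean(self):
        # Euclidean distance ~0.0064 > 0.005 but both axis deltas are 0.0045
        assert len(cluster_points(records_at([(0, 0), (0.0045, 0.0045)]))) == 1

    def test_centroid_is_member_mean(self):
        clusters = cluster_points(records_at([(0.001, 0.001), (0.003, 0.005)]))
        assert clusters[0].centroid == pytest.approx((0.002, 0.003))

    def test_partition_and_oracle_agreement(self):
        rng = random.Random(31)
        coords = [
            (rng.uniform(45.0, 45.03), rng.uniform(-78.03, -78.0)) for _ in range(150)
        ]
        clusters = cluster_points(records_at(coords))
        members = sorted(i for c in clusters for i in c.members)
        assert members == list(range(len(coords)))  # exact partition
        assert sorted(c.members for c in clusters) == brute_force_components(
            coords, 0.005
        )

    def test_permutation_invariance(self):
        rng = random.Random(7)
        coords = [
            (rng.uniform(0, 0.02), rng.uniform(0, 0.02)) for _ in range(40)
        ]
        base = cluster_points(records_at(coords))
        perm = list(range(len(coords)))
        rng.shuffle(perm)
        shuffled = cluster_points(records_at([coords[p] for p in perm]))
        as_coords = lambda cl: sorted(
            tuple(sorted(coords[i] for i in c.members)) for c in cl
        )
        shuffled_coords = sorted(
            tuple(sorted(coords[perm[i]] for i in c.members)) for c in shuffled
        )
        assert as_coords(base) == shuffled_coords

    def test_degenerate_tolerances(self):
        coords = [(0, 0), (0, 0), (1e-9, 0), (0.3, 0.3)]
        zero_tol = cluster_points(records_at(coords), tol_degrees=0.0)
        assert sorted(c.members for c in zero_tol) == [(0, 1), (2,), (3,)]
        assert len(cluster_points(records_at(coords), tol_degrees=1e9)) == 1


class TestSpiderfy:
    def test_singleton_stays_put(self):
        assert spiderfy_offsets(1) == ((0.0, 0.0),)

    def test_four_members_at_right_angles(self):
        offsets = spiderfy_offsets(4, radius_degrees=0.0008)
        expect = [(0.0008, 0.0), (0.0, 0.0008), (-0.0008, 0.0), (0.0, -0.0008)]
        for got, want in zip(offsets, expect):
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("n", range(2, 51))
    def test_offsets_balance_around_centroid(self, n):
        offsets = spiderfy_offsets(n)
        assert sum(o[0] for o in offsets) == pytest.approx(0.0, abs=1e-12)
        assert sum(o[1] for o in offsets) == pytest.approx(0.0, abs=1e-12)
        for o in offsets:
            assert math.hypot(*o) == pytest.approx(0.0008)

    def test_cluster_wrapper_uses_member_count(self):
        cluster = GeoCluster(members=(3, 5, 9), centroid=(0, 0), spider_offsets=())
        assert spiderfy(cluster) == spiderfy_offsets(3)
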