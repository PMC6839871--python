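import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pollinet import (
    bray_curtis_matrix,
    estimate_inflorescence_flowers,
    load_community,
    pollination_environment,
    validate_community,
    write_community,
)
from pollinet.errors import (
    DimensionMismatchError,
    DuplicateSpeciesError,
    NegativeCountError,
    UnknownSpeciesError,
)
from tests.conftest import make_community


def write_site(tmp_path, matrix_text, species_text):
    (tmp_path / "interactions.csv").write_text(matrix_text)
    (tmp_path / "species.csv").write_text(species_text)
    return tmp_path / "interactions.csv", tmp_path / "species.csv"


SPECIES_OK = (
    "species_id,guild,origin,family,flower_count\n"
    "p0,plant,native,Asteraceae,12\n"
    "p1,plant,alien,Amaranthaceae,30\n"
    "v0,visitor,not_applicable,,\n"
    "v1,visitor,not_applicable,,\n"
)


class TestLoadCommunity:
    def test_total_visits_and_order(self, tmp_path):
        paths = write_site(tmp_path, "plant_id,v0,v1\np0,3,1\np1,1,1\n", SPECIES_OK)
        c = load_community(*paths)
        assert c.total_visits == 6
        assert c.plant_ids == ["p0", "p1"] and c.visitor_ids == ["v0", "v1"]
        assert c.plants[1].origin == "alien"
        assert c.plants[0].flower_count == 12

    def test_unknown_visitor_column(self, tmp_path):
        paths = write_site(tmp_path, "plant_id,v0,v9\np0,3,1\np1,1,1\n", SPECIES_OK)
        with pytest.raises(UnknownSpeciesError):
            load_community(*paths)

    def test_empty_matrix_file(self, tmp_path):
        paths = write_site(tmp_path, "", SPECIES_OK)
        with pytest.raises(DimensionMismatchError):
            load_community(*paths)

    def test_negative_count_names_cell(self, tmp_path):
        paths = write_site(tmp_path, "plant_id,v0,v1\np0,3,-1\np1,1,1\n", SPECIES_OK)
        with pytest.raises(NegativeCountError, match="v1"):
            load_community(*paths)

    def test_duplicate_plant_row(self, tmp_path):
        paths = write_site(tmp_path, "plant_id,v0,v1\np0,3,1\np0,1,1\n", SPECIES_OK)
        with pytest.raises(DuplicateSpeciesError):
            load_community(*paths)

    def test_round_trip(self, tmp_path, demo_community):
        write_community(demo_community, tmp_path / "site")
        c = load_community(tmp_path / "site" / "interactions.csv",
                           tmp_path / "site" / "species.csv")
        assert np.array_equal(c.counts, demo_community.counts)
        assert c.plant_ids == demo_community.plant_ids
        assert c.visitor_ids == demo_community.visitor_ids
        assert [p.origin for p in c.plants] == [p.origin for p in demo_community.plants]
        assert [p.flower_count for p in c.plants] == \
            [p.flower_count for p in demo_community.plants]


class TestValidateCommunity:
    def test_well_formed(self, demo_community):
        assert validate_community(demo_community) == []

    def test_plant_origin_not_applicable(self, demo_community):
        demo_community.plants[0].origin = "not_applicable"
        violations = validate_community(demo_community)
        assert len(violations) == 1 and "p0" in violations[0]

    def test_negative_count_reported_with_cell(self, demo_community):
        demo_community.counts[0, 0] = -1
        violations = validate_community(demo_community)
        assert len(violations) == 1
        assert "p0" in violations[0] and "v0" in violations[0]


@pytest.mark.parametrize("mean_flowers, n_infl, expected", [
    (12.0, 10, 120),
    (0, 50, 0),
    (2.5, 3, 8),  # 7.5 rounds half-up
    (2.49, 3, 7),
])
def test_estimate_inflorescence_flowers(mean_flowers, n_infl, expected):
    assert estimate_inflorescence_flowers(mean_flowers, n_infl) == expected


def test_estimate_inflorescence_flowers_rejects_negative():
    with pytest.raises(ValueError):
        estimate_inflorescence_flowers(-1.0, 3)


class TestPollinationEnvironment:
    def test_richness_and_rate(self):
        c = make_community([[3, 0, 2]], flower_counts=[10])
        s = pollination_environment(c)
        assert s.richness[0] == 2
        assert s.visitation_rate[0] == pytest.approx(0.5)

    def test_unvisited_plant(self):
        c = make_community([[0, 0, 0]], flower_counts=[10])
        s = pollination_environment(c)
        assert s.richness[0] == 0 and s.visitation_rate[0] == 0.0

    def test_rate_scales_inversely_with_flowers(self):
        c = make_community([[5, 5], [5, 5]], flower_counts=[10, 100])
        s = pollination_environment(c)
        assert s.visitation_rate[0] == pytest.approx(10 * s.visitation_rate[1])

    def test_zero_flowers_gives_missing_rate(self):
        c = make_community([[3]], flower_counts=[0])
        s = pollination_environment(c)
        assert np.isnan(s.visitation_rate[0])

    def test_richness_bounded_by_visitor_count(self, synthetic_site):
        c, _ = synthetic_site
        s = pollination_environment(c)
        assert (s.richness <= len(c.visitors)).all()
        finite = s.visitation_rate[np.isfinite(s.visitation_rate)]
        assert (finite >= 0).all()


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis_matrix([[5, 2], [5, 2]])[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports(self):
        assert bray_curtis_matrix([[3, 0], [0, 4]])[0, 1] == pytest.approx(1.0)

    def test_formula_value(self):
        # 1 - 2*min_sum/total = 1 - 4/6
        assert bray_curtis_matrix([[3, 1], [1, 1]])[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis_matrix([[0, 0], [1, 2]])

    @given(arrays(np.float64, (4, 3),
                  elements=st.floats(0, 100, allow_nan=False)).filter(
                      lambda x: (x.sum(axis=1) > 0).all()))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_zero_diagonal_bounded(self, X):
        D = bray_curtis_matrix(X)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()
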