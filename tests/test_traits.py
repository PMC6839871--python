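import math

import numpy as np
import pandas as pd
import pytest

from pollinet import (
    GeneratorConfig,
    TraitTable,
    generate_site,
    gower_distance,
    gower_distance_matrix,
    group_similarity_summary,
    hexagon_coordinates,
    similarity_index,
)


def single_trait_table(values, trait_range=None):
    df = pd.DataFrame({"species_id": [f"s{i}" for i in range(len(values))],
                       "flower_height_mm": values})
    ranges = {"flower_height_mm": trait_range} if trait_range else {}
    return TraitTable(df, quantitative=("flower_height_mm",), ranges=ranges)


class TestGowerDistance:
    def test_identical_vectors(self):
        a = {"h": 3.0, "d": 5.0}
        assert gower_distance(a, a, {"h": 10.0, "d": 10.0}) == 0.0

    def test_opposite_extremes(self):
        assert gower_distance({"h": 0.0}, {"h": 10.0}, {"h": 10.0}) == 1.0

    def test_mixed_trait_mean(self):
        a = {"h": 10.0, "d": 5.0, "color": "white"}
        b = {"h": 20.0, "d": 5.0, "color": "white"}
        d = gower_distance(a, b, {"h": 20.0, "d": 10.0}, categorical=("color",))
        assert d == pytest.approx((0.5 + 0 + 0) / 3)

    def test_zero_range_trait_excluded(self):
        a, b = {"h": 1.0, "d": 3.0}, {"h": 2.0, "d": 3.0}
        assert gower_distance(a, b, {"h": 2.0, "d": 0.0}) == pytest.approx(0.5)

    def test_no_usable_trait_rejected(self):
        with pytest.raises(ValueError):
            gower_distance({"h": 1.0}, {"h": 2.0}, {"h": 0.0})

    def test_matrix_symmetric_bounded(self, synthetic_site):
        _, table = synthetic_site
        D = gower_distance_matrix(table)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1).all()


class TestSimilarityIndex:
    def test_identical_species(self):
        t = single_trait_table([5.0, 5.0, 5.0], trait_range=1.0)
        assert np.allclose(similarity_index(t), 1.0)

    def test_two_species_at_full_distance(self):
        t = single_trait_table([0.0, 10.0])
        assert np.allclose(similarity_index(t), 0.0)

    def test_three_species_mean_distances(self):
        # pairwise distances 0.2, 0.4, 0.6 -> each s_i = 1 - mean of its two
        t = single_trait_table([0.0, 2.0, 6.0], trait_range=10.0)
        assert np.allclose(similarity_index(t), [0.6, 0.7, 0.5])

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(single_trait_table([1.0]))

    def test_invariant_to_duplicating_all_traits(self, synthetic_site):
        _, table = synthetic_site
        df = table.data.copy()
        dup_cols = {f"{c}_dup": df[c] for c in table.quantitative}
        df2 = df.assign(**dup_cols)
        doubled = TraitTable(
            df2, quantitative=tuple(table.quantitative) + tuple(dup_cols),
        )
        assert np.allclose(similarity_index(doubled), similarity_index(table))


class TestGroupSimilarity:
    def test_all_native_community_lacks_alien_summary(self):
        t = single_trait_table([1.0, 2.0, 3.0])
        res = group_similarity_summary(t, {f"s{i}": "native" for i in range(3)})
        assert math.isnan(res.alien_mean) and not math.isnan(res.native_mean)

    def test_identical_species_mean_one_sd_zero(self):
        t = single_trait_table([4.0, 4.0, 4.0], trait_range=1.0)
        res = group_similarity_summary(
            t, {"s0": "native", "s1": "alien", "s2": "native"})
        assert res.mean == pytest.approx(1.0) and res.sd == pytest.approx(0.0)

    def test_origin_blind_traits_give_matching_group_means(self):
        cfg = GeneratorConfig(seed=21, delta=0.0)
        nat, ali = [], []
        for i in range(50):
            c, t = generate_site(cfg, i)
            res = group_similarity_summary(
                t, {p.species_id: p.origin for p in c.plants})
            nat.append(res.native_mean)
            ali.append(res.alien_mean)
        assert abs(np.nanmean(nat) - np.nanmean(ali)) < 0.05

    def test_missing_origin_rejected(self):
        t = single_trait_table([1.0, 2.0])
        with pytest.raises(ValueError):
            group_similarity_summary(t, {"s0": "native"})


class TestHexagonCoordinates:
    grid = np.linspace(300, 700, 81)

    def sensitivities(self):
        peaks = (350.0, 440.0, 540.0)
        return np.array([np.exp(-0.5 * ((self.grid - p) / 40.0) ** 2) for p in peaks])

    def test_background_stimulus_is_achromatic_center(self):
        bg = np.full_like(self.grid, 0.3)
        x, y = hexagon_coordinates(bg, self.sensitivities(),
                                   np.ones_like(self.grid), bg)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_green_stimulus_has_positive_x(self):
        bg = np.full_like(self.grid, 0.3)
        refl = bg + 0.5 * np.exp(-0.5 * ((self.grid - 540.0) / 30.0) ** 2)
        x, _ = hexagon_coordinates(refl, self.sensitivities(),
                                   np.ones_like(self.grid), bg)
        assert x > 0

    def test_invariant_to_illuminant_scaling(self):
        bg = np.full_like(self.grid, 0.3)
        refl = np.clip(bg + 0.2 * np.sin(self.grid / 50.0), 0.01, 1.0)
        ill = np.ones_like(self.grid)
        assert hexagon_coordinates(refl, self.sensitivities(), ill, bg) == \
            pytest.approx(hexagon_coordinates(refl, self.sensitivities(), 2 * ill, bg))

    def test_coordinates_inside_hexagon_bounds(self, rng):
        bg = np.full_like(self.grid, 0.3)
        for _ in range(20):
            refl = rng.uniform(0.01, 1.0, self.grid.shape)
            x, y = hexagon_coordinates(refl, self.sensitivities(),
                                       np.ones_like(self.grid), bg)
            assert abs(x) <= math.sqrt(3) / 2 and -1.0 <= y <= 1.0

    def test_grid_mismatch_rejected(self):
        bg = np.full_like(self.grid, 0.3)
        with pytest.raises(ValueError):
            hexagon_coordinates(bg[:-1], self.sensitivities(),
                                np.ones_like(self.grid), bg)
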