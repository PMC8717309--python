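"""Seed index formulas, germination statistics and predictor screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harelink import traits
from harelink.errors import (
    ExcludedSpeciesError,
    InvalidDimensionError,
    MissingTraitError,
    UndefinedCorrelationError,
    ValidationError,
)

dims = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


class TestIndexFormulas:
    @pytest.mark.parametrize(
        "length,width,expected",
        [(2.0, 1.0, 2.0), (1.0, 1.0, 1.0), (1.7, 1.7, 1.0)],
    )
    def test_eccentricity(self, length, width, expected):
        assert traits.eccentricity_index(length, width) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "l,w,h,expected", [(2, 1, 1, 1.5), (1, 1, 1, 1.0), (3, 1, 0.5, 4.0)]
    )
    def test_flatness(self, l, w, h, expected):
        assert traits.flatness_index(l, w, h) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "mass,volume,expected",
        [(10, 5, 2.0), (0.0002, 0.3805, 5.256e-4), (1, 1, 1.0)],
    )
    def test_density(self, mass, volume, expected):
        assert traits.seed_density(mass, volume) == pytest.approx(expected, rel=1e-3)

    def test_density_rounds_to_printed_value(self):
        # Achillea millefolium: 0.0002 mg / 0.3805 mm^3 prints as 0.0005
        assert round(traits.seed_density(0.0002, 0.3805), 4) == 0.0005

    @pytest.mark.parametrize(
        "l,w,h,expected", [(1, 1, 1, 0.0), (1, 0.5, 0.5, 1.0 / 18.0)]
    )
    def test_shape_variance(self, l, w, h, expected):
        assert traits.shape_variance(l, w, h) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "area,mass,expected", [(1.6695, 0.0001, 16695), (5.6116, 0.0002, 28058), (1, 1, 1)]
    )
    def test_area_mass_ratio(self, area, mass, expected):
        assert traits.area_mass_ratio(area, mass) == pytest.approx(expected)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidDimensionError):
            traits.eccentricity_index(0.0, 1.0)
        with pytest.raises(InvalidDimensionError):
            traits.seed_density(1.0, 0.0)
        with pytest.raises(MissingTraitError):
            traits.flatness_index(1.0, 1.0, None)
        with pytest.raises(MissingTraitError):
            traits.shape_variance(1.0, 1.0, None)

    @given(l=dims, w=dims)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_eccentricity_reciprocal(self, l, w):
        assert traits.eccentricity_index(l, w) * traits.eccentricity_index(w, l) == pytest.approx(1.0)

    @given(l=dims, w=dims, h=dims, k=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dimensionless_indices_scale_invariant(self, l, w, h, k):
        assert traits.flatness_index(k * l, k * w, k * h) == pytest.approx(
            traits.flatness_index(l, w, h)
        )
        assert traits.shape_variance(k * l, k * w, k * h) == pytest.approx(
            traits.shape_variance(l, w, h)
        )

    @given(l=dims, w=dims, h=dims)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_shape_variance_bounded_when_length_longest(self, l, w, h):
        length = max(l, w, h)
        others = sorted([l, w, h])[:2]
        vs = traits.shape_variance(length, others[1], others[0])
        assert vs <= traits.VS_UPPER_BOUND + 1e-12


class TestSurfaceArea:
    def test_sphere_exact(self):
        res = traits.surface_area(2, 2, 2)
        assert res.branch == "ellipsoid"
        assert res.area == pytest.approx(4 * math.pi, rel=1e-6)

    def test_cylinder_closed_form(self):
        res = traits.surface_area(4, 2, 2, vs_threshold=0.01, warn_dead_branch=False)
        assert res.branch == "cylinder"
        assert res.area == pytest.approx(10 * math.pi)

    def test_thomsen_vs_quadrature_prolate(self):
        t = traits.surface_area(4, 2, 2, ellipsoid="thomsen").area
        q = traits.surface_area(4, 2, 2, ellipsoid="quadrature").area
        assert t == pytest.approx(q, rel=0.012)

    def test_dead_branch_warning(self):
        traits._DEAD_BRANCH_WARNED = False
        with pytest.warns(UserWarning, match="cylinder branch"):
            traits.surface_area(3, 1, 1, vs_threshold=1.0)

    def test_cylinder_radius_rule(self):
        mean_r = traits.surface_area(4, 2, 1, vs_threshold=0.0,
                                     warn_dead_branch=False).area
        width_r = traits.surface_area(4, 2, 1, vs_threshold=0.0,
                                      cylinder_radius="width",
                                      warn_dead_branch=False).area
        r1, r2 = 0.75, 1.0
        assert mean_r == pytest.approx(2 * math.pi * r1 * (r1 + 4))
        assert width_r == pytest.approx(2 * math.pi * r2 * (r2 + 4))


class TestStandardizedGermination:
    @pytest.mark.parametrize(
        "feces,cap,fed,expected",
        [(15, 1, 685, 218.98), (0, 50, 800, 0.0), (29, 87, 700, 4.76)],
    )
    def test_values(self, feces, cap, fed, expected):
        assert traits.standardized_germination(feces, cap, fed) == pytest.approx(
            expected, abs=0.005
        )

    def test_zero_capacity_excluded(self):
        with pytest.raises(ExcludedSpeciesError):
            traits.standardized_germination(1, 0.0, 800)

    @given(feces=st.integers(min_value=0, max_value=500),
           scale=st.integers(min_value=1, max_value=4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linear_in_feces_count(self, feces, scale):
        base = traits.standardized_germination(feces, 50, 800)
        scaled = traits.standardized_germination(feces * scale, 50, 800)
        assert scaled == pytest.approx(base * scale)

    def test_equals_100_at_expected_germinable_count(self):
        # 60% capacity of 500 seeds -> 300 germinable; 300 seedlings -> 100%
        assert traits.standardized_germination(300, 60, 500) == pytest.approx(100.0)


class TestBuildTraitTable:
    def test_empty(self):
        assert len(traits.build_trait_table([])) == 0

    def test_complete_record_populates_all_indices(self):
        rec = traits.SeedTraitRecord(
            species="Testum plantum", seeds_fed=100, control_germ_pct=50,
            feces_germ=5, length=2.0, width=1.0, height=0.8, mass=0.5, volume=0.9,
        )
        row = traits.build_trait_table([rec]).iloc[0]
        for col in ("ei", "fi", "vs", "area", "density", "area_mass", "sgs"):
            assert np.isfinite(row[col]), col

    def test_duplicate_species_rejected(self):
        rec = traits.SeedTraitRecord("A b", 10, 50, 1)
        with pytest.raises(ValidationError, match="duplicate"):
            traits.build_trait_table([rec, rec])

    def test_missing_height_flagged_not_imputed(self):
        rec = traits.SeedTraitRecord(
            species="A b", seeds_fed=10, control_germ_pct=50, feces_germ=1,
            length=2.0, width=1.0, mass=0.1, volume=0.2,
        )
        row = traits.build_trait_table([rec]).iloc[0]
        assert row["height_missing"]
        assert np.isnan(row["fi"]) and np.isnan(row["vs"]) and np.isnan(row["area"])
        assert np.isfinite(row["ei"])


class TestCollinearityFilter:
    def test_identical_columns_keep_one(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        res = traits.collinearity_filter(df, ["a", "b"], priority=["a", "b"], log=False)
        assert res.retained == ["a"] and res.dropped == ["b"]

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.standard_normal((1000, 3)), columns=["a", "b", "c"])
        res = traits.collinearity_filter(df, ["a", "b", "c"], priority=[], log=False)
        assert res.retained == ["a", "b", "c"]

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(UndefinedCorrelationError):
            traits.collinearity_filter(df, ["a", "b"], log=False)

    def test_row_order_invariance(self, table1):
        sub = table1.dropna(subset=["sgs"])
        cols = ["density", "ei", "area", "fi", "mass", "volume", "area_mass"]
        r1 = traits.collinearity_filter(sub, cols)
        r2 = traits.collinearity_filter(sub.sample(frac=1, random_state=0), cols)
        assert r1.retained == r2.retained

    def test_fixture_screen_drops_correlated_block(self, table1):
        sub = table1.dropna(subset=["sgs"])
        cols = ["density", "ei", "area", "fi", "mass", "volume", "area_mass"]
        res = traits.collinearity_filter(sub, cols)
        assert set(res.dropped) >= {"fi", "mass", "volume"}
        assert {"density", "ei", "area"} <= set(res.retained)


class TestPca:
    def test_perfectly_correlated_pc1_explains_all(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        res = traits.pca_summary(df, ["a", "b"], log=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_data_equal_shares(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.standard_normal((2000, 3)), columns=list("abc"))
        res = traits.pca_summary(df, ["a", "b", "c"], log=False)
        assert np.allclose(res.explained_variance_ratio, 1 / 3, atol=0.05)

    def test_loadings_orthonormal_eigenvalues_ordered(self, table1):
        sub = table1.dropna(subset=["sgs"])
        res = traits.pca_summary(sub, ["density", "ei", "area"])
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(3), atol=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert (res.eigenvalues >= 0).all()
        assert res.eigenvalues.sum() == pytest.approx(3.0)


class TestGroupSummary:
    def test_single_species_group_is_its_sgs(self, table1):
        one = table1[table1["species"] == "Lythrum salicaria"]
        res = traits.group_summary(one, "neophyte")
        assert res["mean_sgs"].iloc[0] == pytest.approx(9.52)

    def test_na_policy_drop_vs_zero(self, table1):
        zero = traits.group_summary(table1, "neophyte", na_policy="zero")
        drop = traits.group_summary(table1, "neophyte", na_policy="drop")
        n_zero = zero["n"].sum()
        assert n_zero == 44 and drop["n"].sum() == 43  # Anthriscus has no SGS

    def test_unknown_exclusion_rejected(self, table1):
        with pytest.raises(ValidationError):
            traits.group_summary(table1, "neophyte", exclude=["Nonexistens plantae"])
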