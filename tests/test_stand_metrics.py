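"""Stand structure, allometric biomass and productivity metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from soilqualkit.stand import (
    cv_dbh,
    gini_dbh,
    npp,
    pbs,
    stand_biomass,
    summarize_stand,
    tree_biomass,
)
from soilqualkit.tables import AllometricCoef, PlotMeta, TreeInventory

dbh_lists = st.lists(
    st.floats(min_value=0.5, max_value=150.0, allow_nan=False), min_size=2, max_size=200
)


def _inventory(dbh, species="fir", broadleaf=False, height=10.0):
    n = len(dbh)
    return TreeInventory(
        pd.DataFrame(
            {
                "plot_id": ["p"] * n,
                "species": [species] * n,
                "is_broadleaf": [broadleaf] * n,
                "dbh": dbh,
                "height": [height] * n,
            }
        )
    )


class TestCV:
    @pytest.mark.parametrize(
        "dbh, expected",
        [([10, 10, 10], 0.0), ([10, 20, 30], 50.0)],  # sample sd 10 over mean 20
    )
    def test_examples(self, dbh, expected):
        assert cv_dbh(dbh) == pytest.approx(expected)

    @given(dbh_lists, st.floats(min_value=0.1, max_value=50))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, dbh, c):
        assert cv_dbh([c * x for x in dbh]) == pytest.approx(cv_dbh(dbh), abs=1e-8)

    def test_needs_two_trees(self):
        with pytest.raises(ValueError):
            cv_dbh([10.0])


class TestGini:
    @pytest.mark.parametrize("form", ["standard", "paper_literal"])
    def test_equal_dbhs_give_zero(self, form):
        assert gini_dbh([12, 12, 12, 12], form) == pytest.approx(0.0)

    def test_two_tree_examples(self):
        # standard: sum|xi-xj| / (2 n^2 mean) = 40 / 160
        assert gini_dbh([10, 30], "standard") == pytest.approx(0.25)
        # dispersion form: mean squared deviation 100 over mean 20
        assert gini_dbh([10, 30], "paper_literal") == pytest.approx(5.0)

    @given(dbh_lists)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_standard_matches_pairwise_oracle(self, dbh):
        """The sorted-form Gini equals the O(n^2) mean-absolute-difference
        definition."""
        x = np.asarray(dbh)
        brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * len(x) ** 2 * x.mean())
        assert gini_dbh(dbh, "standard") == pytest.approx(brute, abs=1e-10)

    @given(dbh_lists, st.floats(min_value=0.1, max_value=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_form_scaling_behaviour(self, dbh, c):
        g = gini_dbh(dbh, "standard")
        assert 0 <= g < 1
        assert gini_dbh([c * x for x in dbh], "standard") == pytest.approx(g, abs=1e-8)
        # the dispersion form is linear in the DBH scale (documented difference)
        assert gini_dbh([c * x for x in dbh], "paper_literal") == pytest.approx(
            c * gini_dbh(dbh, "paper_literal"), rel=1e-9
        )

    def test_unknown_form(self):
        with pytest.raises(ValueError, match="form"):
            gini_dbh([10, 20], "percent")


class TestBiomass:
    def test_identity_coefficients(self):
        assert tree_biomass(2, 3, AllometricCoef("x", 1, 1)) == pytest.approx(12.0)

    def test_direct_evaluation(self):
        w = tree_biomass(20, 15, AllometricCoef("x", 0.05, 0.9))
        assert w == pytest.approx(0.05 * (20**2 * 15) ** 0.9)
        assert w == pytest.approx(125.6, abs=0.5)

    def test_zero_exponent_returns_a(self):
        assert tree_biomass(37, 21, AllometricCoef("x", 4.2, 0.0)) == pytest.approx(4.2)

    def test_per_hectare_scaling(self, tiny_coefs):
        # one tree of exactly 600 kg in a 600 m^2 plot -> 10 t/ha
        coef = AllometricCoef("fir", 600.0, 0.0)
        inv = _inventory([15.0])
        assert stand_biomass(inv, {"fir": coef}, 600.0) == pytest.approx(10.0)

    def test_empty_inventory_zero(self, tiny_coefs):
        empty = TreeInventory(
            pd.DataFrame(columns=["plot_id", "species", "is_broadleaf", "dbh", "height"])
        )
        assert stand_biomass(empty, tiny_coefs, 600.0) == 0.0

    def test_additive_over_disjoint_inventories(self, tiny_inventory, tiny_coefs):
        half_a = TreeInventory(tiny_inventory.data.iloc[:2])
        half_b = TreeInventory(tiny_inventory.data.iloc[2:])
        assert stand_biomass(tiny_inventory, tiny_coefs, 600.0) == pytest.approx(
            stand_biomass(half_a, tiny_coefs, 600.0)
            + stand_biomass(half_b, tiny_coefs, 600.0)
        )

    def test_unknown_species_listed(self, tiny_inventory):
        with pytest.raises(KeyError, match="schima"):
            stand_biomass(tiny_inventory, {"fir": AllometricCoef("fir", 0.05, 0.9)}, 600)


class TestNppPbs:
    def test_npp_is_biomass_over_age(self):
        assert npp(20.0, 20.0) == pytest.approx(1.0)
        assert npp(274.18, 20.0) == pytest.approx(13.709)
        assert npp(0.0, 20.0) == 0.0
        with pytest.raises(ValueError):
            npp(10.0, 0.0)

    def test_pure_stands(self, tiny_coefs):
        assert pbs(_inventory([10, 12], "schima", True), tiny_coefs) == pytest.approx(100.0)
        assert pbs(_inventory([10, 12], "fir", False), tiny_coefs) == pytest.approx(0.0)

    def test_equal_biomass_split(self):
        # same coefficient and size for both trees -> equal biomass -> 50 %
        coefs = {"fir": AllometricCoef("fir", 0.05, 0.9),
                 "oak": AllometricCoef("oak", 0.05, 0.9)}
        inv = TreeInventory(
            pd.DataFrame(
                {"plot_id": ["p", "p"], "species": ["fir", "oak"],
                 "is_broadleaf": [False, True], "dbh": [20.0, 20.0],
                 "height": [15.0, 15.0]}
            )
        )
        assert pbs(inv, coefs) == pytest.approx(50.0)

    def test_empty_inventory_error(self, tiny_coefs):
        empty = TreeInventory(
            pd.DataFrame(columns=["plot_id", "species", "is_broadleaf", "dbh", "height"])
        )
        with pytest.raises(ValueError):
            pbs(empty, tiny_coefs)


class TestSummary:
    def test_summary_fields(self, tiny_inventory, tiny_coefs, tiny_meta):
        s = summarize_stand(tiny_inventory, tiny_coefs, tiny_meta)
        assert s.n_trees == 3
        assert s.mean_dbh == pytest.approx(20.0)
        assert 0 <= s.gini_d_standard < 1
        assert s.npp == pytest.approx(s.fb / 20.0)
        assert 0 <= s.pbs <= 100

    def test_pbs_invariant_to_plot_area(self, tiny_inventory, tiny_coefs):
        small = summarize_stand(tiny_inventory, tiny_coefs, PlotMeta("p1", "M", 300.0))
        large = summarize_stand(tiny_inventory, tiny_coefs, PlotMeta("p1", "M", 1200.0))
        assert small.pbs == pytest.approx(large.pbs)
        # biomass itself scales inversely with area
        assert small.fb == pytest.approx(4 * large.fb)
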