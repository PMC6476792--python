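"""Abundance, carbon-contribution, size and hyperdominance arithmetic."""

import numpy as np
import pandas as pd
import pytest

import funcrare as fr
from funcrare.community_structure import InventoryError


def make_inventory(counts: dict, dbh: float = 20.0) -> pd.DataFrame:
    rows = [("P1", f"{sp}{i}", sp, dbh) for sp, n in counts.items()
            for i in range(n)]
    return pd.DataFrame(rows, columns=["plot", "tree", "species", "dbh_cm"])


class TestRelativeAbundance:
    def test_hand_counts(self, toy_inventory):
        ra = fr.relative_abundance(toy_inventory)
        assert ra["A"] == 100.0
        assert ra["B"] == 50.0
        assert ra["C"] == 10.0

    def test_single_species(self):
        assert fr.relative_abundance(make_inventory({"A": 7}))["A"] == 100.0

    def test_tied_maximum(self):
        ra = fr.relative_abundance(make_inventory({"A": 4, "B": 4}))
        assert (ra == 100.0).all()

    def test_empty_inventory_errors(self):
        with pytest.raises(InventoryError):
            fr.relative_abundance(pd.DataFrame(
                columns=["plot", "tree", "species", "dbh_cm"]))


class TestAbundanceClasses:
    @pytest.mark.parametrize("ra,cls", [
        (100.0, "abundant"), (10.5, "abundant"),
        (10.0, "nonabundant"), (7.0, "nonabundant"), (5.0, "nonabundant"),
        (4.9, "rare"), (0.5, "rare"),
    ])
    def test_thresholds(self, ra, cls):
        assert fr.classify_abundance(ra)[0] == cls


class TestHeightModels:
    def test_power_form_hand_value(self):
        m = fr.HDModel("power", a=5.0, b=0.5)
        assert m.predict(25.0) == pytest.approx(25.0)

    def test_weibull_asymptote(self):
        m = fr.HDModel("weibull", a=40.0, b=1e6, c=1.0)
        assert m.predict(50.0) == pytest.approx(40.0)

    def test_monotone_in_dbh(self):
        for m in (fr.HDModel("power", a=3.5, b=0.55),
                  fr.HDModel("weibull", a=45.0, b=0.03, c=0.9)):
            d = np.linspace(10, 300, 200)
            assert np.all(np.diff(m.predict(d)) >= 0)

    def test_measured_height_takes_precedence(self):
        m = fr.HDModel("power", a=5.0, b=0.5)
        h = fr.estimate_height([25.0, 25.0], m, measured=[18.0, np.nan])
        assert h[0] == 18.0 and h[1] == pytest.approx(25.0)

    def test_nonpositive_parameters_error(self):
        with pytest.raises(ValueError):
            fr.HDModel("power", a=-1.0, b=0.5)

    def test_fit_recovers_power_law(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(10, 150, 200)
        h = 3.5 * d ** 0.55
        m = fr.fit_hd_model(d, h, form="power")
        assert m.a == pytest.approx(3.5, rel=1e-6)
        assert m.b == pytest.approx(0.55, rel=1e-6)


class TestTreeCarbon:
    def test_hand_value(self):
        agc = fr.tree_agc(30.0, 0.6, 25.0)
        assert agc == pytest.approx(0.5 * 0.0509 * 0.6 * 900 * 25)
        assert agc == pytest.approx(343.575)

    def test_linear_in_carbon_fraction(self):
        assert fr.tree_agc(30.0, 0.6, 25.0, carbon_fraction=1.0) == \
            pytest.approx(2 * fr.tree_agc(30.0, 0.6, 25.0))

    def test_strictly_increasing_in_each_argument(self):
        base = fr.tree_agc(30.0, 0.6, 25.0)
        assert fr.tree_agc(31.0, 0.6, 25.0) > base
        assert fr.tree_agc(30.0, 0.7, 25.0) > base
        assert fr.tree_agc(30.0, 0.6, 26.0) > base

    def test_nonpositive_input_errors(self):
        with pytest.raises(ValueError):
            fr.tree_agc(0.0, 0.6, 25.0)


class TestSpeciesContributions:
    def test_single_species_is_total(self):
        inv = make_inventory({"A": 3})
        wd = pd.Series({"A": 0.6})
        out = fr.species_agc_contribution(inv, wd, fr.HDModel())
        assert out["A"] == pytest.approx(100.0)

    def test_two_to_one_split(self):
        inv = make_inventory({"A": 2, "B": 1}, dbh=30.0)
        wd = pd.Series({"A": 0.6, "B": 0.6})
        out = fr.species_agc_contribution(inv, wd, fr.HDModel())
        assert out["A"] == pytest.approx(200 / 3)
        assert out["B"] == pytest.approx(100 / 3)

    def test_invariant_to_allometry_constants(self, toy_inventory):
        wd = pd.Series({"A": 0.5, "B": 0.6, "C": 0.7})
        a = fr.species_agc_contribution(toy_inventory, wd, fr.HDModel())
        b = fr.species_agc_contribution(toy_inventory, wd, fr.HDModel(),
                                        carbon_fraction=0.47, coefficient=0.11)
        pd.testing.assert_series_equal(a, b)

    def test_contributions_sum_to_100(self, small_community):
        inv, _, wd, _ = small_community
        out = fr.species_agc_contribution(inv, wd, fr.HDModel())
        assert out.sum() == pytest.approx(100.0, abs=1e-9)

    def test_missing_wood_density_errors_with_name(self, toy_inventory):
        wd = pd.Series({"A": 0.5, "B": 0.6})
        with pytest.raises(InventoryError, match="C"):
            fr.species_agc_contribution(toy_inventory, wd, fr.HDModel())


class TestMaxSize:
    def test_hand_values_and_large_flag(self):
        rows = [("P1", "t1", "A", 12.0), ("P1", "t2", "A", 45.0),
                ("P1", "t3", "A", 71.0), ("P1", "t4", "B", 10.0)]
        inv = pd.DataFrame(rows, columns=["plot", "tree", "species", "dbh_cm"])
        out = fr.max_dbh(inv)
        assert out.loc["A", "max_dbh_cm"] == 71.0 and bool(out.loc["A", "large"])
        assert out.loc["B", "max_dbh_cm"] == 10.0 and not out.loc["B", "large"]

    def test_permutation_invariant(self, toy_inventory):
        shuffled = toy_inventory.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(fr.max_dbh(toy_inventory),
                                      fr.max_dbh(shuffled))


class TestHyperdominance:
    def test_hand_enumeration(self):
        c = pd.Series({"A": 40.0, "B": 20.0, "C": 25.0, "D": 15.0})
        flags = fr.classify_hyperdominant(c)
        assert set(flags[flags].index) == {"A", "C"}

    def test_single_species(self):
        flags = fr.classify_hyperdominant(pd.Series({"A": 100.0}))
        assert flags["A"]

    def test_uniform_boundary_needs_three_of_four(self):
        # cumulative after two is exactly 50, not >50, so three are flagged
        c = pd.Series({s: 25.0 for s in "ABCD"})
        flags = fr.classify_hyperdominant(c)
        assert flags.sum() == 3
        assert set(flags[flags].index) == {"A", "B", "C"}  # id tie-break

    def test_minimal_prefix_property(self, small_community):
        inv, _, wd, _ = small_community
        contrib = fr.species_agc_contribution(inv, wd, fr.HDModel())
        flags = fr.classify_hyperdominant(contrib)
        hyper = contrib[flags].sort_values(ascending=False)
        assert hyper.sum() > 50.0
        assert hyper.sum() - hyper.iloc[-1] <= 50.0
        # no unflagged species outranks a flagged one
        assert contrib[~flags].max() <= hyper.min() + 1e-12


def test_full_stats_table_columns_and_sums(small_community):
    inv, _, wd, _ = small_community
    out = fr.community_stats(inv, wd, fr.HDModel())
    assert list(out.columns) == ["species", "n_stems", "rel_abund_pct",
                                 "agc_pct", "max_dbh_cm", "large", "class",
                                 "hyperdominant"]
    assert out["agc_pct"].sum() == pytest.approx(100.0, abs=1e-9)
    assert (out["rel_abund_pct"] == 100.0).sum() >= 1
    assert out["n_stems"].sum() == len(inv)


def test_abundance_agc_rank_correlation_positive(small_community):
    """With coupled abundance and size, stem counts and carbon align."""
    from scipy.stats import spearmanr
    inv, _, wd, _ = small_community
    out = fr.community_stats(inv, wd, fr.HDModel())
    rho, _ = spearmanr(out["rel_abund_pct"], out["agc_pct"])
    assert rho > 0


def test_census_threshold_enforced():
    inv = pd.DataFrame([("P1", "t1", "A", 9.5)],
                       columns=["plot", "tree", "species", "dbh_cm"])
    with pytest.raises(InventoryError):
        fr.relative_abundance(inv)
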