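"""Cohort life-table construction, identities and survivorship typing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hedgelife as hl
from hedgelife.lifetable import SurvivorshipType

# Published single-year life tables for the packaged study sample
# (x, lx, ndx, nqx, npx, nLx, Tx, ex, nmx), at printed rounding.
GOLDEN_MALE = [
    (0, 177, 43, 0.243, 0.757, 155.5, 460.5, 2.602, 0.277),
    (1, 134, 54, 0.403, 0.597, 107.0, 305.0, 2.276, 0.505),
    (2, 80, 23, 0.287, 0.713, 68.5, 198.0, 2.475, 0.336),
    (3, 57, 29, 0.509, 0.491, 42.5, 129.5, 2.272, 0.682),
    (4, 28, 6, 0.214, 0.786, 25.0, 87.0, 3.107, 0.240),
    (5, 22, 7, 0.318, 0.682, 18.5, 62.0, 2.818, 0.378),
    (6, 15, 8, 0.533, 0.467, 11.0, 43.5, 2.900, 0.727),
    (7, 7, 0, 0.000, 1.000, 7.0, 32.5, 4.643, 0.000),
    (8, 7, 0, 0.000, 1.000, 7.0, 25.5, 3.643, 0.000),
    (9, 7, 2, 0.286, 0.714, 6.0, 18.5, 2.643, 0.333),
    (10, 5, 2, 0.400, 0.600, 4.0, 12.5, 2.500, 0.500),
    (11, 3, 1, 0.333, 0.667, 2.5, 8.5, 2.833, 0.400),
    (12, 2, 0, 0.000, 1.000, 2.0, 6.0, 3.000, 0.000),
    (13, 2, 1, 0.500, 0.500, 1.5, 4.0, 2.000, 0.667),
    (14, 1, 0, 0.000, 1.000, 1.0, 2.5, 2.500, 0.000),
    (15, 1, 0, 0.000, 1.000, 1.0, 1.5, 1.500, 0.000),
    (16, 1, 1, 1.000, 0.000, 0.5, 0.5, 0.500, 2.000),
]
GOLDEN_FEMALE = [
    (0, 109, 39, 0.358, 0.642, 89.5, 231.5, 2.124, 0.436),
    (1, 70, 21, 0.300, 0.700, 59.5, 142.0, 2.029, 0.353),
    (2, 49, 15, 0.306, 0.694, 41.5, 82.5, 1.684, 0.361),
    (3, 34, 18, 0.529, 0.471, 25.0, 41.0, 1.206, 0.720),
    (4, 16, 9, 0.562, 0.438, 11.5, 16.0, 1.000, 0.783),
    (5, 7, 6, 0.857, 0.143, 4.0, 4.5, 0.643, 1.500),
    (6, 1, 1, 1.000, 0.000, 0.5, 0.5, 0.500, 2.000),
]


def assert_matches_golden(table, golden):
    # round() on builtin float is decimal-correct (0.2875 stored slightly
    # below the midpoint rounds to 0.287, as printed); numpy's scaled
    # rounding would land on 0.288.
    for x, lx, ndx, nqx, npx, nLx, Tx, ex, nmx in golden:
        row = table.row(x)
        assert row["lx"] == lx and row["ndx"] == ndx
        assert round(float(row["nqx"]), 3) == pytest.approx(nqx)
        assert round(float(row["npx"]), 3) == pytest.approx(npx)
        assert round(float(row["nLx"]), 1) == pytest.approx(nLx)
        assert round(float(row["Tx"]), 1) == pytest.approx(Tx)
        assert round(float(row["ex"]), 3) == pytest.approx(ex)
        assert round(float(row["nmx"]), 3) == pytest.approx(nmx)
        assert row["nax"] == 0.5


class TestGoldenTables:
    def test_male_table_reproduced(self, male_table):
        assert_matches_golden(male_table, GOLDEN_MALE)

    def test_female_table_reproduced(self, female_table):
        assert_matches_golden(female_table, GOLDEN_FEMALE)

    def test_terminal_row_is_missing(self, male_table):
        last = male_table.row(17)
        assert last["lx"] == 0 and last["Tx"] == 0
        assert np.isnan(last["nqx"]) and np.isnan(last["ex"]) and np.isnan(last["nmx"])

    def test_text_rendering_marks_missing_cells(self, male_table):
        lines = male_table.to_text().strip().splitlines()
        assert lines[0].split("\t") == ["x", "lx", "ndx", "nqx", "npx", "nLx",
                                        "Tx", "ex", "nmx", "nax"]
        assert lines[-1].split("\t") == ["17", "0", "0", "-", "-", "-", "0.0",
                                         "-", "-", "0.5"]


class TestDegenerateCohorts:
    def test_all_die_at_zero(self):
        lt = hl.build_life_table(hl.AgeCountTable("x", {0: 40}))
        row = lt.row(0)
        assert row["nqx"] == 1.0
        assert row["nLx"] == 20.0  # N/2 person-years under nax = 0.5
        assert row["ex"] == 0.5
        assert row["nmx"] == 2.0

    def test_empty_counts_error(self):
        with pytest.raises(ValueError, match="empty"):
            hl.build_life_table(hl.AgeCountTable("x", {}))

    def test_negative_counts_rejected_upstream(self):
        with pytest.raises(ValueError):
            hl.AgeCountTable("x", {0: -1})


class TestTrajectories:
    def test_survivorship_normalisation(self, male_table):
        s = hl.survivorship_curve(male_table)
        assert s.loc[0] == 1.0
        assert s.loc[4] == pytest.approx(28 / 177)
        assert s.loc[17] == 0.0
        assert (np.diff(s.to_numpy()) <= 0).all()
        assert ((s >= 0) & (s <= 1)).all()

    def test_hazard_values(self, male_table):
        h = hl.hazard_curve(male_table)
        assert round(h.loc[6], 3) == 0.727
        assert h.loc[7] == 0.0  # interval with zero deaths
        assert h.loc[16] == 2.0  # all remaining die: nmx = d / (0.5 d)
        assert np.isnan(h.loc[17])


class TestClassification:
    def test_female_increasing_risk_is_type_one(self, female_table):
        cls = female_table.classify()
        assert cls.survivorship_type is SurvivorshipType.TYPE_I
        assert cls.slope > 0 and cls.pvalue < 0.05

    def test_male_constant_risk_is_type_two(self, male_table):
        cls = male_table.classify()
        assert cls.survivorship_type is SurvivorshipType.TYPE_II
        assert cls.pvalue > 0.05

    def test_decreasing_hazard_is_type_three(self):
        # heavy juvenile mortality falling off steeply with age
        counts = hl.AgeCountTable("x", {0: 600, 1: 150, 2: 60, 3: 30, 4: 20,
                                        5: 15, 6: 10, 7: 8, 8: 7})
        cls = hl.classify_survivorship(hl.build_life_table(counts))
        assert cls.survivorship_type is SurvivorshipType.TYPE_III
        assert cls.slope < 0

    def test_too_few_intervals(self):
        lt = hl.build_life_table(hl.AgeCountTable("x", {0: 5, 1: 5}))
        with pytest.raises(ValueError, match="at least 3"):
            lt.classify()


count_tables = st.dictionaries(
    st.integers(0, 25), st.integers(0, 60), min_size=1, max_size=15
).filter(lambda c: sum(c.values()) > 0)


@given(counts=count_tables)
@settings(max_examples=200, deadline=None)
def test_life_table_identities(counts):
    """Structural identities hold for arbitrary count tables."""
    lt = hl.build_life_table(hl.AgeCountTable("h", counts))
    f = lt.frame
    assert f["ndx"].sum() == lt.l0
    assert (np.diff(f["lx"].to_numpy()) <= 0).all()
    assert f["lx"].iloc[-1] == 0
    alive = f["lx"] > 0
    np.testing.assert_allclose(
        f.loc[alive, "nqx"], f.loc[alive, "ndx"] / f.loc[alive, "lx"], rtol=1e-12
    )
    np.testing.assert_allclose(
        f.loc[alive, "nLx"], f.loc[alive, "lx"] - 0.5 * f.loc[alive, "ndx"],
        rtol=1e-12,
    )
    # Tx telescoping
    nLx = np.nan_to_num(f["nLx"].to_numpy())
    Tx = f["Tx"].to_numpy()
    np.testing.assert_allclose(Tx[:-1], Tx[1:] + nLx[:-1], rtol=1e-12, atol=1e-12)
    assert Tx[-1] == 0.0
    # nmx = nqx / (1 - 0.5 nqx) wherever defined
    ok = alive & f["nmx"].notna()
    np.testing.assert_allclose(
        f.loc[ok, "nmx"],
        f.loc[ok, "nqx"] / (1 - 0.5 * f.loc[ok, "nqx"]),
        rtol=1e-12, atol=1e-12,
    )
    assert (f.loc[alive, "ex"] >= 0).all()


@given(counts=count_tables)
@settings(max_examples=100, deadline=None)
def test_e0_equals_mean_years_lived(counts):
    """Brute-force oracle: with nax=0.5 every death at age x contributes
    x + 0.5 person-years, so e0 is the mean of (age + 0.5)."""
    table = hl.AgeCountTable("h", counts)
    lt = hl.build_life_table(table)
    oracle = sum((a + 0.5) * n for a, n in counts.items()) / table.n_total
    assert lt.row(0)["ex"] == pytest.approx(oracle, rel=1e-12)


def test_e0_matches_geometric_closed_form():
    """Constant death probability q=0.5 with exact dyadic counts: the table's
    e0 agrees with the analytic expectation of the truncated geometric law,
    evaluated by brute-force summation."""
    q, k = 0.5, 20
    counts = {x: 2 ** (k - 1 - x) for x in range(k)}
    counts[k] = 1  # the final survivor dies in the last interval
    lt = hl.build_life_table(hl.AgeCountTable("geom", counts))
    n = sum(counts.values())
    oracle = sum(counts[x] * (x + 0.5) for x in counts) / n
    brute = sum((x + 0.5) * q * (1 - q) ** x for x in range(k))
    brute += (k + 0.5) * (1 - q) ** k  # truncation mass
    assert lt.row(0)["ex"] == pytest.approx(oracle, rel=1e-12)
    assert lt.row(0)["ex"] == pytest.approx(brute, rel=1e-9)
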