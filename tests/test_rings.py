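"""Ring-width I/O, GLK cross-dating agreement and BAI conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dendrowue.rings import (
    BAISeries,
    RingWidthSeries,
    bai_from_widths,
    glk,
    read_rwl,
    series_summary,
    site_mean_bai,
    truncate_series,
    widths_from_bai,
    write_rwl,
)

widths_strategy = st.lists(
    st.floats(0.05, 9.0, allow_nan=False), min_size=1, max_size=60
).map(lambda w: np.round(np.asarray(w), 2))


def make(widths, first_year=1990, sid="T1", pith=0.0):
    return RingWidthSeries(sid, "SITE", first_year, np.asarray(widths, float), pith)


class TestBAI:
    def test_unit_widths_give_odd_multiples_of_pi(self):
        b = bai_from_widths(make([1.0, 1.0, 1.0]))
        np.testing.assert_allclose(b.bai, np.pi * np.array([1.0, 3.0, 5.0]))

    def test_pith_offset_substitution(self):
        # one 2.05 mm ring on a 10 mm core: pi*(12.05^2 - 10^2)
        b = bai_from_widths(make([2.05], pith=10.0))
        assert b.bai[0] == pytest.approx(np.pi * 45.2025)
        assert b.bai[0] == pytest.approx(142.01, abs=0.01)

    @given(widths_strategy)
    def test_total_basal_area_conservation(self, widths):
        b = bai_from_widths(make(widths))
        assert np.all(b.bai > 0)
        assert np.sum(b.bai) == pytest.approx(np.pi * np.sum(widths) ** 2, rel=1e-9)

    @given(widths_strategy)
    def test_widths_recoverable_from_radii(self, widths):
        b = bai_from_widths(make(widths))
        np.testing.assert_allclose(widths_from_bai(b), widths, atol=1e-9)

    def test_truncation_folds_early_growth_into_pith(self):
        s = make([1.0, 2.0, 3.0, 4.0], first_year=1990)
        full = bai_from_widths(s)
        t = truncate_series(s, 1992, 1993)
        assert t.pith_offset == pytest.approx(3.0)
        np.testing.assert_allclose(bai_from_widths(t).bai, full.bai[2:])
        assert truncate_series(s, 2000, 2010) is None


class TestGLK:
    def test_identical_monotone_series_agree_fully(self):
        s = make([1.0, 2.0, 3.0, 4.0])
        assert glk(s, s) == 1.0

    def test_antiphase_series_score_zero(self):
        a = make([1.0, 2.0, 1.0, 2.0, 1.0])
        b = make([2.0, 1.0, 2.0, 1.0, 2.0], sid="T2")
        assert glk(a, b) == 0.0

    def test_hand_scored_tie_example(self):
        # diffs (+,+,0,-) vs (+,-,+,-): scores 1, 0, 0.5, 1 -> 0.625
        a = make([1.0, 2.0, 3.0, 3.0, 2.0])
        b = make([1.0, 2.0, 1.0, 2.0, 1.0], sid="T2")
        assert glk(a, b) == pytest.approx(0.625)

    @given(widths_strategy.filter(lambda w: len(w) >= 3), st.floats(0.1, 5.0))
    def test_symmetry_and_shift_invariance(self, widths, shift):
        a = make(widths)
        b = make(np.asarray(widths) + shift, sid="T2")
        assert glk(a, b) == glk(b, a)
        # shifting one series leaves every first-difference sign unchanged
        assert glk(a, b) == pytest.approx(glk(a, a))

    def test_short_overlap_rejected(self):
        a = make([1.0, 2.0, 3.0], first_year=1990)
        b = make([1.0, 2.0, 3.0], first_year=1992, sid="T2")
        with pytest.raises(ValueError, match="overlap"):
            glk(a, b)


class TestRwlIO:
    def test_stop_marker_dialect_scaling(self, tmp_path):
        p = tmp_path / "x.rwl"
        p.write_text("TREE01  1990   100   200   999\n")
        (s,) = read_rwl(p)
        np.testing.assert_allclose(s.widths, [1.00, 2.00])
        assert s.first_year == 1990

    @pytest.mark.parametrize("precision", [0.01, 0.001])
    def test_round_trip_bit_exact(self, tmp_path, precision):
        rng = np.random.default_rng(3)
        series = [
            make(np.round(rng.uniform(0.1, 5.0, 27), 3 if precision == 0.001 else 2),
                 first_year=1987, sid=f"T{i}")
            for i in range(3)
        ]
        p = tmp_path / "rt.rwl"
        write_rwl(series, p, precision=precision)
        back = read_rwl(p)
        for a, b in zip(series, back):
            assert a.series_id == b.series_id
            assert a.first_year == b.first_year
            np.testing.assert_allclose(a.widths, b.widths, atol=1e-9)
        # a second pass reproduces the file byte for byte
        p2 = tmp_path / "rt2.rwl"
        write_rwl(back, p2, precision=precision)
        assert p.read_text() == p2.read_text()
        # the 0.001 dialect uses the -9999 stop marker
        if precision == 0.001:
            assert "-9999" in p.read_text()

    def test_hand_written_two_series_overlap(self, tmp_path):
        p = tmp_path / "two.rwl"
        p.write_text(
            "ALPHA   1998   100   110\n"
            "ALPHA   2000   120   130   999\n"
            "BETA    1999    90\n"
            "BETA    2000    95    85   999\n"
        )
        a, b = read_rwl(p)
        assert (a.first_year, a.last_year) == (1998, 2001)
        assert (b.first_year, b.last_year) == (1999, 2001)
        np.testing.assert_allclose(a.widths, [1.0, 1.1, 1.2, 1.3])

    def test_lossy_rounding_within_half_unit(self, tmp_path):
        s = make([1.234, 2.345])
        p = tmp_path / "lossy.rwl"
        write_rwl([s], p, precision=0.01)
        (back,) = read_rwl(p)
        assert np.max(np.abs(back.widths - s.widths)) <= 0.005 + 1e-12

    def test_bad_inputs_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_rwl([], tmp_path / "e.rwl")
        with pytest.raises(ValueError, match="8 characters"):
            RingWidthSeries("TOOLONGID", "S", 2000, np.array([1.0]))
        p = tmp_path / "gap.rwl"
        p.write_text("GAP     1990   100   110\nGAP     2010   120   999\n")
        with pytest.raises(ValueError, match="non-consecutive"):
            read_rwl(p)
        p2 = tmp_path / "nostop.rwl"
        p2.write_text("NOSTOP  1990   100   110\n")
        with pytest.raises(ValueError, match="stop marker"):
            read_rwl(p2)


class TestChronology:
    def test_single_tree_chronology_is_that_tree(self):
        b = bai_from_widths(make([1.0, 1.5, 2.0]))
        chron = site_mean_bai([b])
        np.testing.assert_allclose(chron.mean_value, b.bai)
        assert list(chron.sample_depth) == [1, 1, 1]

    def test_two_tree_mean_and_depth(self):
        b1 = BAISeries("A", "S", 2000, np.array([10.0]), np.array([1.0]))
        b2 = BAISeries("B", "S", 2000, np.array([20.0]), np.array([1.0]))
        chron = site_mean_bai([b1, b2])
        assert chron.mean_value[0] == pytest.approx(15.0)
        assert chron.sample_depth[0] == 2

    def test_staggered_depth_profile_matches_hand_count(self):
        trees = [
            bai_from_widths(make([1.0] * n, first_year=fy, sid=f"T{i}"))
            for i, (fy, n) in enumerate([(2000, 5), (2002, 3), (2003, 2)])
        ]
        chron = site_mean_bai(trees, min_depth=1)
        assert list(chron.years) == [2000, 2001, 2002, 2003, 2004]
        assert list(chron.sample_depth) == [1, 1, 2, 3, 3]
        chron2 = site_mean_bai(trees, min_depth=2)
        assert list(chron2.years) == [2002, 2003, 2004]

    def test_summary_of_constant_tree(self):
        df = series_summary([make([1.0] * 10)])
        row = df.iloc[0]
        assert row["trw_mean"] == pytest.approx(1.0)
        assert row["age_mean"] == 10

    def test_summary_grand_mean_over_trees(self):
        df = series_summary([make([1.0] * 5, sid="A"), make([2.0] * 8, sid="B")])
        assert df.iloc[0]["trw_mean"] == pytest.approx(1.5)
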