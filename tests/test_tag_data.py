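import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tagmove import (
    StudyFrame,
    TagDataset,
    lake_erie_dataset,
    lake_erie_frame,
    lake_erie_reporting_rates,
    read_age_length_sample,
    read_reporting_rates,
    read_tag_tables,
    write_age_length_sample,
    write_reporting_rates,
    write_tag_tables,
)
from tagmove.tag_data import AgeLengthSample


class TestStudyFrame:
    def test_rejects_non_contiguous_years(self):
        with pytest.raises(ValueError, match="contiguous"):
            StudyFrame((2009, 2011), ("A",), 2, ("L1",))

    def test_rejects_single_age_class(self):
        with pytest.raises(ValueError, match="age"):
            StudyFrame((2009,), ("A",), 1, ("L1",))

    def test_case_insensitive_region_lookup(self):
        f = StudyFrame((2009,), ("MU1", "MU2"), 2, ("L1",))
        assert f.region_index("mu2") == 1


class TestLakeErieFixture:
    def test_printed_totals(self):
        ds = lake_erie_dataset()
        assert ds.total_releases == 13_694
        assert ds.total_recoveries == 322
        assert ds.total_at_large == 13_372

    def test_release_split_between_basins(self):
        ds = lake_erie_dataset()
        f = ds.frame
        mu1 = ds.releases[:, f.region_index("MU1"), :].sum()
        mu2 = ds.releases[:, f.region_index("MU2"), :].sum()
        assert round(100 * mu1 / ds.total_releases) == 76
        assert round(100 * mu2 / ds.total_releases) == 24

    def test_printed_cells(self):
        ds = lake_erie_dataset()
        f = ds.frame
        i09 = f.year_index(2009)
        mu1 = f.region_index("MU1")
        # 40 fish tagged 2009/MU1 recovered 2009/MU1
        assert ds.recoveries[i09, mu1, 0, i09, mu1] == 40
        # 14 fish tagged 2011/MU2 recovered 2012/MU3
        assert ds.recoveries[
            f.year_index(2011), f.region_index("MU2"), 0,
            f.year_index(2012), f.region_index("MU3"),
        ] == 14
        assert ds.at_large[i09, mu1, 0] == 3483

    def test_no_releases_from_mu3(self):
        ds = lake_erie_dataset()
        assert ds.releases[:, ds.frame.region_index("MU3"), :].sum() == 0

    def test_reporting_rate_cells(self):
        rr = lake_erie_reporting_rates()
        f = rr.frame
        assert rr.lam[f.year_index(2009), f.region_index("MU1")] == 0.29
        assert rr.lam[f.year_index(2011), f.region_index("MU3")] == 0.25


class TestReaders:
    def test_round_trip_exact(self, tmp_path):
        ds = lake_erie_dataset()
        write_tag_tables(ds, tmp_path / "rel.csv", tmp_path / "rec.csv")
        back = read_tag_tables(tmp_path / "rel.csv", tmp_path / "rec.csv", ds.frame)
        np.testing.assert_array_equal(back.releases, ds.releases)
        np.testing.assert_array_equal(back.recoveries, ds.recoveries)
        np.testing.assert_array_equal(back.at_large, ds.at_large)

    def test_reporting_round_trip(self, tmp_path):
        rr = lake_erie_reporting_rates()
        write_reporting_rates(rr, tmp_path / "rr.csv")
        back = read_reporting_rates(tmp_path / "rr.csv", rr.frame)
        np.testing.assert_allclose(back.lam, rr.lam)

    def test_empty_recovery_file_means_all_at_large(self, tmp_path):
        f = StudyFrame((2009,), ("A",), 2, ("L1",))
        (tmp_path / "rel.csv").write_text(
            "tag_year,tag_region,length_class,count\n2009,A,L1,100\n"
        )
        (tmp_path / "rec.csv").write_text(
            "tag_year,tag_region,length_class,recovery_year,recovery_region,count\n"
        )
        ds = read_tag_tables(tmp_path / "rel.csv", tmp_path / "rec.csv", f)
        assert ds.at_large[0, 0, 0] == 100

    def test_duplicate_rows_are_summed(self, tmp_path):
        f = StudyFrame((2009,), ("A",), 2, ("L1",))
        (tmp_path / "rel.csv").write_text(
            "tag_year,tag_region,length_class,count\n2009,A,L1,3\n2009,A,L1,4\n"
        )
        (tmp_path / "rec.csv").write_text(
            "tag_year,tag_region,length_class,recovery_year,recovery_region,count\n"
        )
        ds = read_tag_tables(tmp_path / "rel.csv", tmp_path / "rec.csv", f)
        assert ds.releases[0, 0, 0] == 7

    @pytest.mark.parametrize(
        "rel_rows,rec_rows,msg",
        [
            ("2009,A,L1,-5\n", "", "negative"),
            ("2010,A,L1,10\n", "2010,A,L1,2009,A,1\n", "precedes"),
            ("2010,A,L1,10\n", "2009,A,L1,2009,A,1\n", "zero releases"),
        ],
    )
    def test_invalid_tables_rejected(self, tmp_path, rel_rows, rec_rows, msg):
        f = StudyFrame((2009, 2010), ("A",), 2, ("L1",))
        (tmp_path / "rel.csv").write_text(
            "tag_year,tag_region,length_class,count\n" + rel_rows
        )
        (tmp_path / "rec.csv").write_text(
            "tag_year,tag_region,length_class,recovery_year,recovery_region,count\n"
            + rec_rows
        )
        with pytest.raises(ValueError, match=msg):
            read_tag_tables(tmp_path / "rel.csv", tmp_path / "rec.csv", f)

    def test_missing_reporting_rate_cell_rejected(self, tmp_path):
        f = StudyFrame((2009,), ("A", "B"), 2, ("L1",))
        (tmp_path / "rr.csv").write_text("year,region,rate\n2009,A,0.5\n")
        with pytest.raises(ValueError, match="missing"):
            read_reporting_rates(tmp_path / "rr.csv", f)

    def test_out_of_range_rate_rejected(self, tmp_path):
        f = StudyFrame((2009,), ("A",), 2, ("L1",))
        (tmp_path / "rr.csv").write_text("year,region,rate\n2009,A,1.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_reporting_rates(tmp_path / "rr.csv", f)

    def test_age_length_reader_sums_and_bounds(self, tmp_path):
        f = StudyFrame((2009,), ("A",), 3, ("L1",))
        (tmp_path / "al.csv").write_text(
            "length_class,age,count\nL1,1,3\nL1,1,4\nL1,2,5\n"
        )
        s = read_age_length_sample(tmp_path / "al.csv", f)
        assert s.n[0, 0] == 7 and s.N[0] == 12
        (tmp_path / "bad.csv").write_text("length_class,age,count\nL1,9,1\n")
        with pytest.raises(ValueError, match="age"):
            read_age_length_sample(tmp_path / "bad.csv", f)

    def test_age_length_round_trip_and_empty_stratum(self, tmp_path):
        f = StudyFrame((2009,), ("A",), 3, ("L1", "L2"))
        s = AgeLengthSample(frame=f, n=np.array([[2, 0, 5], [0, 0, 0]]))
        assert s.N[1] == 0  # empty stratum accepted
        write_age_length_sample(s, tmp_path / "al.csv")
        back = read_age_length_sample(tmp_path / "al.csv", f)
        np.testing.assert_array_equal(back.n, s.n)


@settings(max_examples=25, deadline=None)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 1), st.integers(0, 50)),
        min_size=1, max_size=20,
    )
)
def test_at_large_identity_always_holds(data):
    """releases - sum(recoveries) = at_large for arbitrary valid tables."""
    f = StudyFrame((2000, 2001), ("A", "B"), 2, ("L1",))
    releases = np.zeros((2, 2, 1), dtype=int)
    recoveries = np.zeros((2, 2, 1, 2, 2), dtype=int)
    rng = np.random.default_rng(0)
    for ty, tk, n in data:
        releases[ty, tk, 0] += n + 5
        # scatter a few recoveries into legal cells
        for _ in range(min(n, 5)):
            fy = rng.integers(ty, 2)
            fk = rng.integers(0, 2)
            recoveries[ty, tk, 0, fy, fk] += 1
    ds = TagDataset(frame=f, releases=releases, recoveries=recoveries)
    np.testing.assert_array_equal(
        ds.at_large, ds.releases - ds.recoveries.sum(axis=(3, 4))
    )
    assert (ds.at_large >= 0).all()
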