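"""Survey loading, group aggregation and trend detection."""

import numpy as np
import pandas as pd
import pytest

from distinctfish.community import (
    group_site_year_metrics,
    load_env_table,
    load_survey_table,
    northsea_annual_totals,
    per_cell_trend,
    per_species_trend,
    spatial_mean_map,
)


def survey_frame(rows):
    return pd.DataFrame(
        rows, columns=["species", "cell_id", "lat", "lon", "year", "abundance_per_km2"]
    )


@pytest.fixture
def small_cube():
    rows = []
    for sp, base in [("q4a", 10.0), ("q4b", 5.0), ("q1a", 50.0)]:
        for cell, lat in [("c1", 52.0), ("c2", 55.0)]:
            for k, year in enumerate([1990, 1991, 1992, 1993]):
                rows.append(
                    [sp, cell, lat, 3.0, year, base * (1 + 0.5 * k)]
                )
    return survey_frame(rows)


MEMBER = {"q4a": "Q4", "q4b": "Q4", "q1a": "Q1"}


class TestLoaders:
    def test_survey_roundtrip(self, tmp_path, small_cube):
        p = tmp_path / "s.csv"
        small_cube.to_csv(p, index=False)
        df = load_survey_table(p)
        assert len(df) == len(small_cube)

    def test_duplicate_key_rejected(self, tmp_path):
        df = survey_frame(
            [["a", "c1", 52, 3, 1990, 1.0], ["a", "c1", 52, 3, 1990, 2.0]]
        )
        p = tmp_path / "s.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_survey_table(p)

    def test_negative_abundance_rejected(self, tmp_path):
        df = survey_frame([["a", "c1", 52, 3, 1990, -1.0]])
        p = tmp_path / "s.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match=">= 0"):
            load_survey_table(p)

    def test_env_duplicate_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "cell_id": ["c1", "c1"],
                "year": [1990, 1990],
                "sst_c": [10, 10],
                "sss_psu": [34, 34],
                "depth_m": [50, 50],
                "bstress": [0.5, 0.5],
                "pci": [2, 2],
                "effort_hours": [100, 100],
                "nao": [0, 0],
                "amo": [0, 0],
            }
        )
        p = tmp_path / "e.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_env_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        pd.DataFrame({"species": ["a"]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            load_survey_table(p)


class TestGroupMetrics:
    def test_richness_counts_positive_members_only(self):
        cube = survey_frame(
            [
                ["a", "c1", 52, 3, 1990, 10.0],
                ["b", "c1", 52, 3, 1990, 0.0],
                ["c", "c1", 52, 3, 1990, 5.0],
            ]
        )
        series = group_site_year_metrics(
            cube, {"a": "Q4", "b": "Q4", "c": "Q4"}, groups=("Q4",)
        )
        assert series.loc[0, "richness"] == 2
        assert series.loc[0, "total_abundance"] == 15.0

    def test_absent_group_reported_as_zero(self, small_cube):
        series = group_site_year_metrics(
            small_cube[small_cube["species"] != "q1a"], MEMBER
        )
        q1 = series[series["group"] == "Q1"]
        assert (q1["richness"] == 0).all()
        assert (q1["total_abundance"] == 0).all()

    def test_groups_do_not_leak(self, small_cube):
        series = group_site_year_metrics(small_cube, MEMBER)
        q4 = series[(series["group"] == "Q4") & (series["cell_id"] == "c1")]
        # only q4a + q4b, never the (much larger) q1a abundances
        assert q4["total_abundance"].max() == pytest.approx((10 + 5) * 2.5)

    def test_unassigned_species_ignored(self, small_cube):
        extra = pd.concat(
            [small_cube, survey_frame([["mystery", "c1", 52, 3, 1990, 999.0]])],
            ignore_index=True,
        )
        a = group_site_year_metrics(small_cube, MEMBER)
        b = group_site_year_metrics(extra, MEMBER)
        pd.testing.assert_frame_equal(a, b)

    def test_no_overlap_errors(self, small_cube):
        with pytest.raises(ValueError, match="no survey species"):
            group_site_year_metrics(small_cube, {"zzz": "Q4"})

    def test_group_totals_bounded_by_overall_total(self, small_cube):
        series = group_site_year_metrics(small_cube, MEMBER)
        per_cy = series.groupby(["cell_id", "year"])["total_abundance"].sum()
        overall = small_cube.groupby(["cell_id", "year"])["abundance_per_km2"].sum()
        aligned = per_cy.reindex(overall.index)
        assert (aligned <= overall + 1e-9).all()
        # membership covers every species here, so equality holds
        assert np.allclose(aligned, overall)


class TestAggregates:
    def test_spatial_mean_over_present_years(self):
        series = pd.DataFrame(
            {
                "group": ["Q4"] * 3,
                "cell_id": ["c1"] * 3,
                "year": [1990, 1991, 1992],
                "richness": [1, 2, 3],
                "total_abundance": [10.0, 20.0, 30.0],
            }
        )
        m = spatial_mean_map(series)
        assert m.loc[0, "mean_total_abundance"] == pytest.approx(20.0)
        assert m.loc[0, "n_years"] == 3

    def test_unequal_year_coverage(self):
        series = pd.DataFrame(
            {
                "group": ["Q4"] * 7,
                "cell_id": ["c1"] * 4 + ["c2"] * 3,
                "year": [1990, 1991, 1992, 1993, 1990, 1991, 1992],
                "richness": [1] * 7,
                "total_abundance": [1.0, 2.0, 3.0, 4.0, 6.0, 6.0, 6.0],
            }
        )
        m = spatial_mean_map(series).set_index("cell_id")
        assert m.loc["c1", "mean_total_abundance"] == pytest.approx(2.5)
        assert m.loc["c2", "mean_total_abundance"] == pytest.approx(6.0)

    def test_annual_totals_sum_cells_and_relabelling_invariance(self, small_cube):
        series = group_site_year_metrics(small_cube, MEMBER)
        annual = northsea_annual_totals(series)
        q4_1990 = annual[(annual["group"] == "Q4") & (annual["year"] == 1990)]
        assert q4_1990["total_abundance"].iloc[0] == pytest.approx(30.0)
        relabeled = series.copy()
        relabeled["cell_id"] = relabeled["cell_id"].map({"c1": "x9", "c2": "x1"})
        pd.testing.assert_frame_equal(annual, northsea_annual_totals(relabeled))


class TestTrends:
    def make_series(self, totals, group="Q4", cell="c1"):
        years = 1990 + np.arange(len(totals))
        return pd.DataFrame(
            {
                "group": group,
                "cell_id": cell,
                "year": years,
                "richness": 1,
                "total_abundance": totals,
            }
        )

    def test_monotone_series(self):
        up = per_cell_trend(self.make_series([1.0, 2.0, 3.0, 4.0]))
        assert up["rho"].iloc[0] == pytest.approx(1.0)
        down = per_cell_trend(self.make_series([4.0, 3.0, 2.0, 1.0]))
        assert down["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_series_missing_with_reason(self):
        out = per_cell_trend(self.make_series([2.0, 2.0, 2.0]))
        assert np.isnan(out["rho"].iloc[0])
        assert out["reason"].iloc[0] == "constant"

    def test_short_series_skipped(self):
        out = per_cell_trend(self.make_series([1.0, 2.0]))
        assert out.empty

    def test_rho_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(2)
        totals = rng.uniform(1, 100, size=12)
        raw = self.make_series(totals)
        squared = self.make_series(totals**2)
        assert per_cell_trend(raw)["rho"].iloc[0] == pytest.approx(
            per_cell_trend(squared)["rho"].iloc[0]
        )

    def test_per_species_summary_counts(self):
        rows = []
        series = {
            "up": [1, 2, 3, 4, 5],
            "up2": [1, 1, 2, 2, 3],
            "down": [5, 4, 3, 2, 1],
        }
        for sp, vals in series.items():
            for k, v in enumerate(vals):
                rows.append([sp, "c1", 52, 3, 1990 + k, float(v)])
        cube = survey_frame(rows)
        table, summary = per_species_trend(cube, list(series))
        assert summary["increased"] == 2
        assert summary["declined"] == 1

    def test_sparse_species_trend_missing(self):
        cube = survey_frame(
            [
                ["rare", "c1", 52, 3, 1990, 1.0],
                ["ok", "c1", 52, 3, 1990, 1.0],
                ["ok", "c1", 52, 3, 1991, 2.0],
                ["ok", "c1", 52, 3, 1992, 3.0],
            ]
        )
        table, summary = per_species_trend(cube, ["rare", "ok", "absent"])
        t = table.set_index("species")
        assert np.isnan(t.loc["rare", "rho"])
        assert np.isnan(t.loc["absent", "rho"])
        assert t.loc["ok", "rho"] == pytest.approx(1.0)
        assert summary == {"increased": 1, "declined": 0, "undefined": 2}
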