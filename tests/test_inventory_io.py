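"""Inventory parsing, recruit-cohort extraction, and community assembly."""

import numpy as np
import pandas as pd
import pytest

from recruits.inventory_io import (
    CensusGapError,
    DisturbanceTable,
    InventoryTable,
    SchemaError,
    cohort_members,
    extract_recruit_cohorts,
    predisturbance_community,
    read_inventory,
    survivor_ids,
    write_inventory,
)

from conftest import toy_inventory

DIST = DisturbanceTable(pd.DataFrame({"plot_id": ["P1"], "agb_lost_pct": [30.0]}))


def full_census_rows(records_by_tree, disturbance_year=2000, horizon=8, plot="P1"):
    """Fill every census year for each tree from a {tree: {year: dbh}} spec."""
    rows = []
    for tree, years in records_by_tree.items():
        for year, dbh in years.items():
            rows.append((tree, plot, year, dbh, "", f"sp_{tree}", True))
    # pad a bystander tree so every census year exists
    for year in range(disturbance_year - 1, disturbance_year + horizon + 1):
        rows.append(("pad", plot, year, 50.0, "", "sp_pad", True))
    return rows


class TestReadWrite:
    def test_round_trip(self, tmp_path, small_bundle):
        _, _, inv, _, _ = small_bundle
        path = tmp_path / "inv.csv"
        write_inventory(inv, path)
        back = read_inventory(path, disturbance_year=inv.disturbance_year)
        a = inv.records.reset_index(drop=True)
        b = back.records.reset_index(drop=True)
        assert len(a) == len(b)
        for col in ["tree_id", "year", "species", "alive"]:
            assert (a[col].astype(str).to_numpy() == b[col].astype(str).to_numpy()).all()
        assert np.allclose(a["dbh_cm"].astype(float), b["dbh_cm"].astype(float))

    def test_nonpositive_dbh_rejected(self, tmp_path, caplog):
        df = pd.DataFrame(
            {
                "tree_id": ["t1", "t2"],
                "plot_id": ["P1", "P1"],
                "year": [2000, 2000],
                "dbh_cm": [12.0, -1.0],
                "vernacular": ["", ""],
                "species": ["a", "b"],
                "alive": [True, True],
            }
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with caplog.at_level("WARNING"):
            inv = read_inventory(path, disturbance_year=2000)
        assert len(inv.records) == 1
        assert any("nonpositive DBH" in m for m in caplog.messages)

    def test_missing_column_is_schema_error(self, tmp_path):
        pd.DataFrame({"tree_id": ["t"]}).to_csv(tmp_path / "x.csv", index=False)
        with pytest.raises(SchemaError):
            read_inventory(tmp_path / "x.csv", disturbance_year=2000)

    def test_duplicate_tree_year_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            toy_inventory(
                [
                    ("t1", "P1", 2000, 12.0, "", "a", True),
                    ("t1", "P1", 2000, 12.1, "", "a", True),
                ]
            )


class TestCohorts:
    def test_threshold_crossing_counted(self):
        # crossing tree: 9.8 at T-2, 10.2 at T=5 -> in cohort 5
        y0 = 2000
        spec = {"cross": {y0 + 3: 9.8, y0 + 4: 9.9, y0 + 5: 10.2, y0 + 6: 10.4}}
        inv = toy_inventory(full_census_rows(spec, y0), disturbance_year=y0)
        cohorts = extract_recruit_cohorts(inv, DIST, horizon=8)
        c5 = next(c for c in cohorts if c.time == 5)
        assert c5.counts.get("sp_cross") == 1
        assert all("sp_cross" not in c.counts for c in cohorts if c.time != 5)

    def test_survivor_in_no_cohort(self):
        y0 = 2000
        spec = {"big": {y: 30.0 + 0.1 * (y - y0) for y in range(y0 - 1, y0 + 9)}}
        inv = toy_inventory(full_census_rows(spec, y0), disturbance_year=y0)
        cohorts = extract_recruit_cohorts(inv, DIST, horizon=8)
        assert all("sp_big" not in c.counts for c in cohorts)

    def test_recruit_then_death_counted_once(self):
        # recruited at T=5, dead by T=7: cohort 5 only
        y0 = 2000
        spec = {"ephemeral": {y0 + 4: 9.5, y0 + 5: 10.1, y0 + 6: 10.2}}
        rows = full_census_rows(spec, y0)
        rows.append(("ephemeral", "P1", y0 + 7, 10.2, "", "sp_ephemeral", False))
        inv = toy_inventory(rows, disturbance_year=y0)
        cohorts = extract_recruit_cohorts(inv, DIST, horizon=8)
        hits = [(c.time, c.counts["sp_ephemeral"]) for c in cohorts if "sp_ephemeral" in c.counts]
        assert hits == [(5, 1)]

    def test_five_tree_toy_matches_enumeration(self):
        """Brute-force membership on a 5-tree table, checked by hand."""
        y0 = 2000
        spec = {
            "a": {y0 + 3: 9.0, y0 + 5: 10.5, y0 + 7: 11.0},         # cohort 5
            "b": {y0 + 5: 9.0, y0 + 7: 10.2},                        # cohort 7
            "c": {y: 20.0 for y in range(y0 - 1, y0 + 9)},           # survivor
            "d": {y0 + 6: 9.9, y0 + 7: 9.95},                        # never crosses
            "e": {y0 + 7: 12.0},                                     # absent before, cohort 7
        }
        # fill intermediate census years for a and b so runs are contiguous
        spec["a"][y0 + 4] = 9.5
        spec["a"][y0 + 6] = 10.7
        spec["b"][y0 + 6] = 9.5
        spec["e"][y0 + 8] = 12.2
        spec["a"][y0 + 8] = 11.2
        inv = toy_inventory(full_census_rows(spec, y0), disturbance_year=y0)
        members = cohort_members(inv, horizon=8)
        got = {(r.time, r.tree_id) for r in members.itertuples() if r.tree_id != "pad"}
        assert got == {(5, "a"), (7, "b"), (7, "e")}

    def test_each_tree_recruits_at_most_once(self, small_bundle):
        _, _, inv, dist, truth = small_bundle
        members = cohort_members(inv)
        assert members["tree_id"].is_unique
        crossed = truth.trees["recruit_year"].notna().sum()
        assert len(members) <= crossed

    def test_survivor_exclusion_property(self, small_bundle):
        _, _, inv, _, _ = small_bundle
        members = cohort_members(inv)
        surv = set(survivor_ids(inv))
        assert not (set(members["tree_id"]) & surv)

    def test_census_gap_raises(self):
        y0 = 2000
        rows = [
            ("t", "P1", y, 15.0, "", "a", True)
            for y in range(y0 - 1, y0 + 9)
            if y != y0 + 4
        ]
        inv = toy_inventory(rows, disturbance_year=y0)
        with pytest.raises(CensusGapError, match="2004"):
            extract_recruit_cohorts(inv, DIST, horizon=8)

    def test_unresolved_species_rejected(self):
        y0 = 2000
        rows = full_census_rows({"u": {y0 + 4: 9.0, y0 + 5: 10.5}}, y0)
        rows = [
            (t, p, y, d, v, "UNRESOLVED" if t == "u" else s, a) for t, p, y, d, v, s, a in rows
        ]
        inv = toy_inventory(rows, disturbance_year=y0)
        with pytest.raises(ValueError, match="unresolved"):
            extract_recruit_cohorts(inv, DIST, horizon=8)


class TestPredisturbance:
    def test_threshold_filter(self):
        y0 = 2000
        rows = [
            ("t1", "P1", y0 - 1, 12.0, "", "a", True),
            ("t2", "P1", y0 - 1, 15.0, "", "a", True),
            ("t3", "P1", y0 - 1, 30.0, "", "b", True),
            ("t4", "P1", y0 - 1, 10.0, "", "c", True),
            ("t5", "P1", y0 - 1, 9.9, "", "d", True),
            ("t6", "P1", y0 - 1, 5.0, "", "e", True),
        ]
        pre = predisturbance_community(toy_inventory(rows, y0))["P1"]
        assert pre.counts == {"a": 2, "b": 1, "c": 1}
        assert pre.total == 4

    def test_no_predisturbance_census_errors(self):
        inv = toy_inventory([("t", "P1", 2005, 15.0, "", "a", True)], disturbance_year=2000)
        with pytest.raises(ValueError):
            predisturbance_community(inv)

    def test_matches_generator_initial_community(self, small_bundle):
        _, _, inv, _, truth = small_bundle
        pre = predisturbance_community(inv)
        initial = truth.trees[truth.trees["recruit_year"].isna()]
        for plot, comm in pre.items():
            expected = initial[initial["plot_id"] == plot]["species"].value_counts().to_dict()
            assert comm.counts == expected
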