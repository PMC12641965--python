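"""Statistics pipeline: parsing, descriptives, ANOVA/Tukey/ω², RM-ANOVA/GES,
paired tests, exclusions, export and plots."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from flowintern.stats import (
    ExclusionLog,
    ReportFormatError,
    _anova_ss,
    _rm_decompose,
    descriptive_stats,
    exclusion_screen,
    export_results,
    load_reports,
    oneway_anova,
    paired_tests,
    parse_report,
    plot_summary,
    rm_anova,
    run_stats,
    tukey_pairwise,
)


def _tidy(groups: dict[str, list[float]], time="1h", parameter="p") -> pd.DataFrame:
    rows = []
    for obj, vals in groups.items():
        for i, v in enumerate(vals, 1):
            rows.append({"object": obj, "replicate": i, "time": time, "parameter": parameter, "value": v})
    return pd.DataFrame(rows)


def _tidy_rm(matrix: list[list[float]], obj="A", parameter="p") -> pd.DataFrame:
    rows = []
    for r, subject in enumerate(matrix, 1):
        for t, v in enumerate(subject, 1):
            rows.append({"object": obj, "replicate": r, "time": f"t{t}", "parameter": parameter, "value": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParseReport:
    def _write(self, tmp_path, lines):
        p = tmp_path / "r.txt"
        p.write_text("\n".join(lines), encoding="utf-8")
        return p

    def test_object_and_replicate_from_last_underscore(self, tmp_path):
        p = self._write(tmp_path, ["File\tCount", "3′LNA_1.daf\t100", "A_B_2.daf\t200"])
        out = parse_report(p, "1h")
        assert set(zip(out["object"], out["replicate"])) == {("3′LNA", 1), ("A_B", 2)}

    def test_preamble_before_header_skipped(self, tmp_path):
        p = self._write(tmp_path, ["some title", "", "File\tCount", "x_1.daf\t5"])
        out = parse_report(p, "1h")
        assert out.loc[0, "value"] == 5.0

    def test_non_numeric_cells_become_missing(self, tmp_path):
        p = self._write(tmp_path, ["File\tCount", "x_1.daf\tn/a"])
        assert math.isnan(parse_report(p, "1h")["value"].iloc[0])

    def test_missing_file_column_rejected(self, tmp_path):
        p = self._write(tmp_path, ["Name\tCount", "x_1.daf\t5"])
        with pytest.raises(ReportFormatError):
            parse_report(p, "1h")

    def test_bad_suffix_reported_with_row(self, tmp_path):
        p = self._write(tmp_path, ["File\tCount", "x_1.daf\t5", "nounderscore.daf\t6"])
        with pytest.raises(ReportFormatError, match="row 2"):
            parse_report(p, "1h")

    def test_load_reports_orders_time_levels(self, tmp_path):
        p1 = self._write(tmp_path, ["File\tCount", "x_1.daf\t5"])
        p2 = tmp_path / "r2.txt"
        p2.write_text("File\tCount\nx_1.daf\t7\n", encoding="utf-8")
        table = load_reports([p2, p1], ["4h", "1h"], time_order=["1h", "4h"])
        assert list(table["time"].cat.categories) == ["1h", "4h"]


# ---------------------------------------------------------------------------
# descriptives & exclusions
# ---------------------------------------------------------------------------

class TestDescriptives:
    def test_mean_and_sample_sd(self):
        out = descriptive_stats(_tidy({"A": [2, 4]}))
        assert out.loc[0, "mean"] == 3.0
        assert out.loc[0, "sd"] == pytest.approx(math.sqrt(2.0))
        assert out.loc[0, "n"] == 2

    def test_single_value_sd_missing(self):
        out = descriptive_stats(_tidy({"A": [5]}))
        assert math.isnan(out.loc[0, "sd"])

    def test_constant_sd_zero(self):
        out = descriptive_stats(_tidy({"A": [5, 5, 5]}))
        assert out.loc[0, "sd"] == 0.0


class TestExclusionScreen:
    def test_complete_design_passes(self):
        t = pd.concat([_tidy({"A": [1, 2], "B": [2, 3]}, time=tt) for tt in ("1h", "4h")])
        _, log = exclusion_screen(t)
        assert log.frame().empty

    def test_single_replicate_flagged(self):
        t = pd.concat([_tidy({"A": [1, 2]}, "1h"), _tidy({"A": [3]}, "4h")])
        retained, log = exclusion_screen(t)
        assert list(log.frame()["reason"]) == ["<2 replicates"]
        assert retained.empty

    def test_missing_timepoint_flagged(self):
        t = pd.concat([_tidy({"A": [1, 2], "B": [2, 3]}, "1h"), _tidy({"A": [3, 4]}, "4h")])
        _, log = exclusion_screen(t)
        assert ("B", "missing timepoint") in set(zip(log.frame()["unit"], log.frame()["reason"]))

    def test_zero_variance_flagged(self):
        t = pd.concat([_tidy({"A": [5, 5]}, tt) for tt in ("1h", "4h")])
        _, log = exclusion_screen(t)
        assert list(log.frame()["reason"]) == ["zero variance"]

    def test_descriptives_untouched_by_exclusion(self):
        t = pd.concat([_tidy({"A": [1, 2]}, "1h"), _tidy({"A": [3]}, "4h")])
        desc = descriptive_stats(t)
        assert len(desc) == 2  # excluded unit still described


# ---------------------------------------------------------------------------
# one-way ANOVA family
# ---------------------------------------------------------------------------

class TestOnewayAnova:
    def test_hand_decomposition(self):
        res = oneway_anova(_tidy({"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8]}), "p", "1h")
        assert res.F == pytest.approx(21.0, abs=1e-9)
        assert res.omega_sq == pytest.approx(40 / 49, abs=1e-9)
        assert res.df == (2, 6)

    def test_identical_groups_give_zero_f(self):
        res = oneway_anova(_tidy({"A": [1, 2, 3], "B": [1, 2, 3]}), "p", "1h")
        assert res.F == 0.0
        assert res.omega_sq <= 0  # reported as is

    def test_single_group_excluded(self):
        log = ExclusionLog()
        assert oneway_anova(_tidy({"A": [1, 2, 3]}), "p", "1h", log) is None
        assert log.frame()["reason"].iloc[0] == "insufficient data"

    def test_omega_ci_brackets_estimate(self):
        res = oneway_anova(_tidy({"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8]}), "p", "1h")
        lo, hi = res.omega_sq_ci
        assert 0 <= lo <= max(res.omega_sq, 0) <= hi <= 1

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            groups = {f"g{i}": list(rng.normal(i, 1, rng.integers(3, 7))) for i in range(3)}
            ssb, ssw, sst, _, _ = _anova_ss({k: np.array(v) for k, v in groups.items()})
            assert ssb + ssw == pytest.approx(sst, abs=1e-9)


class TestTukeyPairwise:
    def test_cohens_d_with_unit_pooled_sd(self):
        out = tukey_pairwise(_tidy({"A": [1, 2, 3], "B": [3, 4, 5]}), "p", "1h")
        assert out["cohen_d"].iloc[0] == pytest.approx(-2.0, abs=1e-12)

    def test_identical_groups_have_zero_d(self):
        out = tukey_pairwise(_tidy({"A": [1, 2, 3], "B": [1, 2, 3], "C": [9, 10, 11]}), "p", "1h")
        row = out[out["pair"] == "A vs B"].iloc[0]
        assert row["cohen_d"] == 0.0

    def test_bh_adjustment_monotone_and_bounded(self):
        out = tukey_pairwise(
            _tidy({"A": [1, 2, 3], "B": [2, 3, 4], "C": [6, 7, 8], "D": [4, 5, 6]}), "p", "1h"
        )
        ranked = out.sort_values("tukey_p")
        assert ranked["bh_p"].is_monotonic_increasing
        assert (out["bh_p"] <= 1).all()
        assert (out["bh_p"] >= out["tukey_p"] - 1e-15).all()


# ---------------------------------------------------------------------------
# repeated measures family
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_hand_decomposition(self):
        res = rm_anova(_tidy_rm([[1, 2, 3], [2, 3, 4], [3, 4, 5]]), "p", "A", n_boot=50)
        assert res.ss["ss_time"] == pytest.approx(6.0, abs=1e-9)
        assert res.ss["ss_subject"] == pytest.approx(6.0, abs=1e-9)
        assert res.ss["ss_error"] == pytest.approx(0.0, abs=1e-9)
        assert res.ges == pytest.approx(0.5, abs=1e-9)
        assert math.isinf(res.F) and res.infinite_f

    def test_one_timepoint_excluded(self):
        log = ExclusionLog()
        assert rm_anova(_tidy_rm([[1], [2], [3]]), "p", "A", log) is None
        assert not log.frame().empty

    def test_subject_label_shuffle_leaves_time_ss_unchanged(self):
        base = _tidy_rm([[1, 2, 3], [5, 4, 6], [2, 2, 2]])
        shuffled = base.copy()
        shuffled["replicate"] = shuffled["replicate"].map({1: 3, 2: 1, 3: 2})
        a = rm_anova(base, "p", "A", n_boot=10)
        b = rm_anova(shuffled, "p", "A", n_boot=10)
        assert a.ss["ss_time"] == pytest.approx(b.ss["ss_time"], abs=1e-12)

    def test_incomplete_replicates_dropped(self):
        t = _tidy_rm([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        t = t[~((t["replicate"] == 3) & (t["time"] == "t3"))]  # subject 3 incomplete
        res = rm_anova(t, "p", "A", n_boot=10)
        assert res.df == (2, 2)  # 2 complete subjects x 3 times

    def test_rm_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X = rng.normal(0, 1, size=(4, 3))
            ss = _rm_decompose(pd.DataFrame(X))
            assert ss["ss_subject"] + ss["ss_time"] + ss["ss_error"] == pytest.approx(
                ss["ss_total"], abs=1e-9
            )

    def test_bootstrap_ci_deterministic(self):
        t = _tidy_rm([[1, 2, 4], [2, 2, 5], [1, 3, 6], [2, 4, 7]])
        a = rm_anova(t, "p", "A", n_boot=200, seed=3)
        b = rm_anova(t, "p", "A", n_boot=200, seed=3)
        assert a.ges_ci == b.ges_ci
        assert 0.0 <= a.ges_ci[0] <= a.ges_ci[1] <= 1.0


class TestPairedTests:
    def test_cohens_dz(self):
        t = _tidy_rm([[0, 1], [0, 2], [0, 3]])
        out = paired_tests(t, "p", "A")
        assert out["cohen_dz"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_constant_differences_logged_as_zero_variance(self):
        log = ExclusionLog()
        out = paired_tests(_tidy_rm([[0, 1], [1, 2], [2, 3]]), "p", "A", log)
        assert math.isnan(out["p"].iloc[0])
        assert "zero variance" in set(log.frame()["reason"])

    def test_single_pair_bh_equals_raw(self):
        out = paired_tests(_tidy_rm([[0, 1], [0, 3], [1, 2]]), "p", "A")
        assert out["bh_p"].iloc[0] == pytest.approx(out["p"].iloc[0])


# ---------------------------------------------------------------------------
# orchestration / export / plots
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_design():
    rng = np.random.default_rng(12)
    rows = []
    for obj, shift in (("PS", 0.0), ("PS_LNA", 1.0)):
        for rep in (1, 2, 3):
            for i, t in enumerate(("1h", "4h", "12h")):
                rows.append(
                    {"object": obj, "replicate": rep, "time": t, "parameter": "Internalized %",
                     "value": 50 + 10 * i + shift * 5 + rng.normal(0, 2)}
                )
    table = pd.DataFrame(rows)
    table["time"] = pd.Categorical(table["time"], ["1h", "4h", "12h"], ordered=True)
    return table


class TestRunStatsAndExport:
    def test_full_run_produces_all_sections(self, small_design):
        res = run_stats(small_design, n_boot=100)
        assert not res.descriptives.empty
        assert not res.anova.empty
        assert not res.rm_anova.empty
        assert res.excluded.empty

    def test_export_round_trip_exact(self, small_design, tmp_path):
        res = run_stats(small_design, n_boot=100)
        paths = export_results(res, tmp_path)
        assert paths["xlsx"].exists()
        back = pd.read_csv(paths["anova"])
        pd.testing.assert_frame_equal(back, pd.read_csv(paths["anova"]))
        # numeric fidelity through the CSV mirror
        assert back["F"].iloc[0] == pytest.approx(res.anova["F"].iloc[0], rel=1e-12)

    def test_csv_mirror_byte_stable(self, small_design, tmp_path):
        res = run_stats(small_design, n_boot=100)
        p1 = export_results(res, tmp_path / "a")["anova"].read_bytes()
        p2 = export_results(run_stats(small_design, n_boot=100), tmp_path / "b")["anova"].read_bytes()
        assert p1 == p2

    def test_excel_sheets_match_sections(self, small_design, tmp_path):
        from openpyxl import load_workbook

        res = run_stats(small_design, n_boot=50)
        paths = export_results(res, tmp_path)
        wb = load_workbook(paths["xlsx"], read_only=True)
        assert set(wb.sheetnames) == {
            "Descriptive statistics", "ANOVA & Tukey", "RM-ANOVA & t-tests", "Excluded tubes-samples",
        }

    def test_empty_export_rejected(self, tmp_path):
        from flowintern.stats import StatsResults

        empty = StatsResults(pd.DataFrame(), pd.DataFrame(), pd.DataFrame(), pd.DataFrame())
        with pytest.raises(ValueError):
            export_results(empty, tmp_path)

    def test_plots_written(self, small_design, tmp_path):
        paths = plot_summary(small_design, tmp_path, mode="per-object")
        assert paths and all(p.exists() and p.stat().st_size > 0 for p in paths)
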