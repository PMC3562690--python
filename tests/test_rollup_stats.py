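"""Protein roll-up, CV/QC reporting and differential statistics."""

import numpy as np
import pandas as pd
import pytest

from lfquant import rollup_stats
from lfquant.quantify import PeptideQuantMatrix
from lfquant.rollup_stats import (
    ProteinQuantMatrix,
    bin_cv_counts,
    compare_groups,
    fold_difference,
    frequency_report,
    protein_cv_report,
    qc_check,
    rollup_protein,
)
from lfquant.io_formats import IdentificationEvent


def _pep_matrix(areas: dict, protein_map):
    df = pd.DataFrame(areas).T
    df.index.name = "peptide_key"
    return PeptideQuantMatrix(df, protein_map)


def _design(runs, groups=None, roles=None, samples=None):
    n = len(runs)
    return pd.DataFrame(
        {
            "run_id": runs,
            "sample_id": samples or [f"s{i}" for i in range(n)],
            "group_id": groups or ["A"] * n,
            "replicate_role": roles or ["experimental"] * n,
        }
    )


class TestRollup:
    def test_sum_and_mean(self):
        m = _pep_matrix(
            {"a.2": {"r1": 100.0}, "b.2": {"r1": 200.0}},
            {"a.2": ("P1",), "b.2": ("P1",)},
        )
        assert rollup_protein(m, "sum").abundances.loc["P1", "r1"] == 300.0
        assert rollup_protein(m, "mean").abundances.loc["P1", "r1"] == 150.0

    def test_single_peptide_protein_identity(self):
        m = _pep_matrix({"a.2": {"r1": 123.0}}, {"a.2": ("P9",)})
        out = rollup_protein(m)
        assert out.abundances.loc["P9", "r1"] == 123.0
        assert out.n_peptides["P9"] == 1

    def test_shared_peptides_excluded(self):
        m = _pep_matrix(
            {"a.2": {"r1": 100.0}, "sh.2": {"r1": 999.0}},
            {"a.2": ("P1",), "sh.2": ("P1", "P2")},
        )
        out = rollup_protein(m)
        assert out.abundances.loc["P1", "r1"] == 100.0
        assert "P2" not in out.abundances.index

    def test_missing_cells_propagate_only_when_all_missing(self):
        m = _pep_matrix(
            {"a.2": {"r1": 100.0, "r2": np.nan}, "b.2": {"r1": 50.0, "r2": np.nan}},
            {"a.2": ("P1",), "b.2": ("P1",)},
        )
        out = rollup_protein(m)
        assert out.abundances.loc["P1", "r1"] == 150.0
        assert np.isnan(out.abundances.loc["P1", "r2"])


class TestCVReport:
    def test_identical_abundances_all_in_first_bin(self):
        ab = pd.DataFrame({"r1": [10.0, 5.0], "r2": [10.0, 5.0], "r3": [10.0, 5.0]},
                          index=["P1", "P2"])
        pm = ProteinQuantMatrix(ab, pd.Series(1, index=ab.index))
        rep = protein_cv_report(pm, _design(["r1", "r2", "r3"]))
        first = rep.bin_table.iloc[0]
        assert first["bin"] == "<=15" and first["count"] == 2 and first["percent"] == 100.0
        assert rep.mean_cv["A"] == 0.0

    def test_cv_50_lands_in_30_50_bin(self):
        ab = pd.DataFrame({"r1": [1.0], "r2": [2.0], "r3": [3.0]}, index=["P1"])
        pm = ProteinQuantMatrix(ab, pd.Series(1, index=ab.index))
        rep = protein_cv_report(pm, _design(["r1", "r2", "r3"]))
        tab = rep.bin_table.set_index("bin")
        assert tab.loc["(30,50]", "count"] == 1

    def test_bin_percentages_match_printed_precision(self):
        """Bin counts 772/99/102/38 of 1,011 give 76.4/9.8/10.1/3.8% and a
        cumulative 96.2% at or below 30% CV."""
        cvs = pd.Series(
            [10.0] * 772 + [18.0] * 99 + [25.0] * 102 + [40.0] * 38
        )
        tab = bin_cv_counts(cvs)
        assert tab["count"].tolist() == [772, 99, 102, 38, 0]
        assert tab["percent"].tolist() == [76.4, 9.8, 10.1, 3.8, 0.0]
        assert round(float(tab["percent"][:3].sum()), 1) == 96.3  # rounded parts
        cum = round(100.0 * (cvs <= 30.0).mean(), 1)
        assert cum == 96.2


class TestQC:
    def _pm(self, cvs, n_runs=2):
        # two QC runs with mean 100 and chosen CV: values 100 +/- cv/sqrt(2)
        rows = {}
        for i, cv in enumerate(cvs):
            d = cv / np.sqrt(2.0)
            rows[f"P{i}"] = {"q1": 100.0 + d, "q2": 100.0 - d}
        ab = pd.DataFrame(rows).T
        return ProteinQuantMatrix(ab, pd.Series(1, index=ab.index))

    def _qc_design(self):
        return _design(["q1", "q2"], groups=["QC", "QC"], roles=["qc", "qc"],
                       samples=["qc", "qc"])

    def test_zero_cv_passes(self):
        res = qc_check(self._pm([0.0, 0.0, 0.0]), self._qc_design())
        assert res.verdict == "pass" and res.pct_within_default == 100.0

    def test_cv26_fails_default_but_passes_lloq(self):
        res = qc_check(self._pm([26.0]), self._qc_design())
        assert res.pct_within_default == 0.0
        assert res.pct_within_lloq == 100.0

    def test_85_percent_below_min_fraction_09_fails(self):
        cvs = [10.0] * 85 + [40.0] * 15
        res = qc_check(self._pm(cvs), self._qc_design(), min_fraction_pass=0.9)
        assert res.pct_within_default == 85.0
        assert res.verdict == "fail"

    def test_no_qc_runs_not_evaluable(self):
        pm = self._pm([0.0])
        res = qc_check(pm, _design(["q1", "q2"]))  # experimental only
        assert res.verdict == "not evaluable"


class TestCompare:
    def _pm(self, a_vals, b_vals, n=4):
        rows = {}
        for i, (a, b) in enumerate(zip(a_vals, b_vals)):
            rows[f"P{i}"] = {
                **{f"A_{j}": a[j] for j in range(len(a))},
                **{f"B_{j}": b[j] for j in range(len(b))},
            }
        ab = pd.DataFrame(rows).T
        runs = list(ab.columns)
        design = _design(runs, groups=[r[0] for r in runs])
        return ProteinQuantMatrix(ab, pd.Series(1, index=ab.index)), design

    def test_identical_groups_null_result(self):
        pm, design = self._pm([[100.0, 100.0, 100.0]], [[100.0, 100.0, 100.0]])
        out = compare_groups(pm, design)
        assert out["log2fc"].iloc[0] == 0.0
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_twofold_change_detected(self):
        rng = np.random.default_rng(0)
        a = [(1e6 * rng.lognormal(0, 0.05, 5)).tolist() for _ in range(3)]
        b = [(2e6 * rng.lognormal(0, 0.05, 5)).tolist() for _ in range(3)]
        pm, design = self._pm(a, b)
        out = compare_groups(pm, design)
        assert out["log2fc"].between(0.8, 1.2).all()
        assert out["significant"].all()

    def test_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(1)
        a = [(1e6 * rng.lognormal(0, 0.2, 3)).tolist() for _ in range(40)]
        b = [(1e6 * rng.lognormal(0, 0.2, 3)).tolist() for _ in range(40)]
        pm, design = self._pm(a, b)
        out = compare_groups(pm, design).dropna(subset=["p"]).sort_values("p")
        assert out["q"].is_monotonic_increasing
        assert (out["q"] <= 1.0).all()
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_single_group_rejected(self):
        ab = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["P1"])
        pm = ProteinQuantMatrix(ab, pd.Series(1, index=ab.index))
        with pytest.raises(ValueError):
            compare_groups(pm, _design(["r1", "r2"]))

    def test_insufficient_observations_marked_untested(self):
        pm, design = self._pm([[100.0, np.nan, np.nan]], [[100.0, 110.0, 90.0]])
        out = compare_groups(pm, design)
        assert not out["tested"].iloc[0]
        assert np.isnan(out["q"].iloc[0])


def _ev(key, run):
    return IdentificationEvent(run, 1, 10.0, 500.0, 2, key, ("P1",), 0.95)


class TestFrequencyReport:
    def test_printed_percentages_from_counts(self):
        """1,883 singletons and 61 ever-present peptides out of 7,361 print
        as 25.6% and 0.8%."""
        events = []
        for i in range(1883):
            events.append(_ev(f"s{i}.2", "r1"))
        for i in range(61):
            events.extend(_ev(f"u{i}.2", f"r{j}") for j in range(35))
        for i in range(7361 - 1883 - 61):
            events.extend(_ev(f"m{i}.2", f"r{j}") for j in range(2))
        rep = frequency_report(events, 35)
        assert rep.loc[rep["n_injections_identified"] == 1, "percent"].iloc[0] == 25.6
        assert rep.loc[rep["n_injections_identified"] == 35, "percent"].iloc[0] == 0.8
        assert int(rep["n_peptides"].sum()) == 7361

    def test_all_peptides_everywhere(self):
        events = [_ev(f"p{i}.2", f"r{j}") for i in range(4) for j in range(5)]
        rep = frequency_report(events, 5)
        assert rep.loc[rep["n_injections_identified"] == 5, "percent"].iloc[0] == 100.0


class TestFoldDifference:
    def test_standard_peptide_spread(self):
        # identical amounts of different peptides can differ 7.45-fold in area
        assert fold_difference([6.63e7, 8.90e6]) == 7.45

    def test_equal_areas(self):
        assert fold_difference([5.0, 5.0]) == 1.0

    def test_simple_ratio(self):
        assert fold_difference([2.0, 8.0]) == 4.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fold_difference([0.0, 1.0])


def test_no_hidden_normalization_in_rollup():
    """Scaling one run's peptide areas by c scales only that run's protein
    column by c."""
    m = _pep_matrix(
        {
            "a.2": {"r1": 100.0, "r2": 110.0},
            "b.2": {"r1": 50.0, "r2": 55.0},
        },
        {"a.2": ("P1",), "b.2": ("P1",)},
    )
    base = rollup_protein(m).abundances
    scaled_areas = m.areas.copy()
    scaled_areas["r1"] *= 7.0
    scaled = rollup_protein(PeptideQuantMatrix(scaled_areas, m.protein_map)).abundances
    assert scaled["r1"].equals(base["r1"] * 7.0)
    assert scaled["r2"].equals(base["r2"])
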