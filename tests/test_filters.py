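"""The four peptide-qualification filters and their audit trail."""

import numpy as np
import pandas as pd
import pytest

from lfquant import alignment, filters, quantify
from lfquant.filters import (
    FilterConfig,
    apply_filters,
    correlation_filter,
    cv_filter,
    frequency_filter,
    retention_time_filter,
)
from lfquant.io_formats import IdentificationEvent
from lfquant.quantify import PeakBounds, PeptideQuantMatrix


def _ev(key, run, t=10.0):
    return IdentificationEvent(run, 1, t, 500.0, 2, key, ("P1",), 0.95)


def _matrix(areas: dict, protein_map=None, bounds=None):
    df = pd.DataFrame(areas).T
    df.index.name = "peptide_key"
    pmap = protein_map or {k: ("P1",) for k in df.index}
    return PeptideQuantMatrix(df, pmap, bounds or {})


def _design(runs, sample="s1", group="A"):
    return pd.DataFrame(
        {
            "run_id": runs,
            "sample_id": [sample] * len(runs),
            "group_id": [group] * len(runs),
            "replicate_role": ["experimental"] * len(runs),
        }
    )


class TestFrequency:
    def test_identified_everywhere_passes(self):
        events = [_ev("p.2", f"r{i}") for i in range(35)]
        assert frequency_filter(events, 35, 0.5)["p.2"]

    def test_singleton_fails_at_half(self):
        assert not frequency_filter([_ev("p.2", "r0")], 35, 0.5)["p.2"]

    def test_zero_threshold_is_vacuous(self):
        events = [_ev("a.2", "r0"), _ev("b.2", "r3")]
        assert frequency_filter(events, 35, 0.0).all()


class TestRetentionTime:
    def _with_deviations(self, devs):
        runs = [f"r{i}" for i in range(len(devs))]
        bounds = {
            ("p.2", r): PeakBounds(10.0 + d, 100.0, 9.0 + d, 11.0 + d)
            for r, d in zip(runs, devs)
        }
        matrix = _matrix({"p.2": {r: 100.0 for r in runs}}, bounds=bounds)
        cons = pd.DataFrame({"peptide_key": ["p.2"], "rt_min": [10.0]})
        return matrix, cons

    def test_tight_apexes_pass(self):
        m, c = self._with_deviations([0.1, -0.2, 0.15, 0.0])
        assert retention_time_filter(m, c, 1.5, 0.25)["p.2"]

    def test_half_outliers_fail(self):
        # 2 of 4 deviations exceed 1.5 min: 0.5 > 0.25 allowed fraction
        m, c = self._with_deviations([0.1, 0.2, 4.0, 5.0])
        assert not retention_time_filter(m, c, 1.5, 0.25)["p.2"]


class TestCV:
    def test_identical_replicates_pass(self):
        m = _matrix({"p.2": {"r1": 100.0, "r2": 100.0, "r3": 100.0}})
        assert cv_filter(m, _design(["r1", "r2", "r3"]), 30.0)["p.2"]

    def test_cv_50_fails_at_30(self):
        # sd 1, mean 2 -> CV 50%
        m = _matrix({"p.2": {"r1": 1.0, "r2": 2.0, "r3": 3.0}})
        assert not cv_filter(m, _design(["r1", "r2", "r3"]), 30.0)["p.2"]

    def test_standard_peptide_trio(self):
        """Replicate CVs like the three mass standards: ~15% and ~11% pass
        at a 30% bound while a ~63% CV peptide fails."""
        rng = np.random.default_rng(0)
        runs = [f"r{i}" for i in range(10)]
        areas = {}
        for key, cv in (("angIII.2", 0.15), ("fibB.2", 0.114), ("angI.2", 0.634)):
            vals = 1e6 * (1 + cv * rng.standard_normal(10))
            areas[key] = dict(zip(runs, np.clip(vals, 1e4, None)))
        m = _matrix(areas)
        got = cv_filter(m, _design(runs), 30.0)
        assert got["angIII.2"] and got["fibB.2"] and not got["angI.2"]

    def test_no_replicates_skips_filter(self):
        m = _matrix({"p.2": {"r1": 1.0, "r2": 100.0}})
        design = pd.DataFrame(
            {
                "run_id": ["r1", "r2"],
                "sample_id": ["s1", "s2"],  # distinct samples: no tech reps
                "group_id": ["A", "A"],
                "replicate_role": ["experimental", "experimental"],
            }
        )
        assert cv_filter(m, design, 30.0).all()


class TestCorrelation:
    runs = ["r1", "r2", "r3", "r4"]

    def _trio(self, flip=False):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        areas = {
            "a.2": dict(zip(self.runs, 100 * base)),
            "b.2": dict(zip(self.runs, 50 * base)),
            "c.2": dict(zip(self.runs, 10 * (base[::-1] if flip else base))),
        }
        return _matrix(areas)

    def test_identical_profiles_all_pass(self):
        got = correlation_filter(self._trio(), 0.5, 3)
        assert got.all()

    def test_anticorrelated_sibling_fails(self):
        # c.2 reversed: Pearson r = -1 against both siblings, median < 0.5
        got = correlation_filter(self._trio(flip=True), 0.5, 3)
        assert got["a.2"] and got["b.2"] and not got["c.2"]

    def test_small_proteins_pass_by_default(self):
        m = _matrix({"solo.2": dict(zip(self.runs, [1.0, 5.0, 2.0, 9.0]))})
        assert correlation_filter(m, 0.5, 3).all()


class TestApplyFilters:
    def _pipeline(self, experiment, config):
        cfg, (runs, events, design, truth) = experiment
        cons = alignment.align_events(events)
        matrix = quantify.build_peptide_matrix(runs, cons, events, design=design)
        return matrix, filters.apply_filters(matrix, events, design, cons, config), truth

    def test_vacuous_thresholds_keep_everything(self, misbehaved_experiment):
        vacuous = FilterConfig(
            min_id_fraction=0.0,
            rt_deviation_max=1e6,
            rt_outlier_fraction_max=1.0,
            cv_max=1e9,
            correlation_min=-1.0,
        )
        matrix, (filtered, report), _ = self._pipeline(misbehaved_experiment, vacuous)
        assert filtered.areas.shape == matrix.areas.shape
        assert report.summary["removed"] == 0

    def test_misidentified_singletons_all_removed_by_frequency(self, misbehaved_experiment):
        _, (filtered, report), truth = self._pipeline(misbehaved_experiment, FilterConfig())
        misid = set(truth.peptides.loc[truth.peptides["misid"], "peptide_key"])
        rows = report.table.set_index("peptide_key")
        present = [k for k in misid if k in rows.index]
        assert present, "simulation produced no misidentified peptides"
        assert (rows.loc[present, "status"] == "removed").all()
        assert rows.loc[present, "removal_reasons"].str.contains("frequency").all()

    def test_most_pattern_vi_peptides_flagged_by_rt_filter(self, misbehaved_experiment):
        _, (filtered, report), truth = self._pipeline(misbehaved_experiment, FilterConfig())
        info = truth.peptides.set_index("peptide_key")
        rows = report.table.set_index("peptide_key")
        vi = [
            k
            for k in rows.index
            if k in info.index and info.loc[k, "pattern"] == "vi" and not info.loc[k, "misid"]
        ]
        assert len(vi) >= 5
        flagged = rows.loc[vi, "removal_reasons"].str.contains("retention_time")
        assert flagged.mean() >= 0.9

    def test_tightening_cv_never_grows_retained_set(self, misbehaved_experiment):
        retained = []
        for cv_max in (50.0, 30.0, 15.0):
            _, (filtered, report), _ = self._pipeline(
                misbehaved_experiment, FilterConfig(cv_max=cv_max)
            )
            retained.append(set(report.retained()))
        assert retained[0] >= retained[1] >= retained[2]

    def test_multiple_reasons_recorded(self, misbehaved_experiment):
        strict = FilterConfig(min_id_fraction=1.0, rt_deviation_max=0.01,
                              rt_outlier_fraction_max=0.0, cv_max=0.5)
        _, (filtered, report), _ = self._pipeline(misbehaved_experiment, strict)
        n_reasons = report.table["removal_reasons"].str.count(";") + 1
        removed = report.table["status"] == "removed"
        assert (n_reasons[removed] >= 2).any()

    def test_shared_peptides_flagged(self, small_experiment):
        cfg, (runs, events, design, truth) = small_experiment
        cons = alignment.align_events(events)
        matrix = quantify.build_peptide_matrix(runs, cons, events, design=design)
        _, report = filters.apply_filters(matrix, events, design, cons, FilterConfig())
        truly_shared = set(truth.peptides.loc[truth.peptides["shared"], "peptide_key"])
        flagged = set(report.table.loc[report.table["shared"], "peptide_key"])
        assert flagged == truly_shared & set(matrix.peptide_keys)
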