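"""Protein roll-up, CV / QC reporting and group comparison — no normalization.

Qualified, non-shared peptide areas are combined (sum by default) into one
protein abundance per injection. Precision is reported as coefficients of
variation (CV = 100·sd/mean) binned the way bioanalytical assay-acceptance
reports present them, with the default acceptance bound at 25% CV and a
relaxed 30% bound at the lower limit of quantitation. Group differences use
a Welch t-test on log2 abundances with Benjamini-Hochberg correction.

No rescaling of any kind happens here or anywhere upstream: when no sound
normalization model exists, applying one only adds error, and instrument
health is instead established from QC injections analysed in the same batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import PeptideQuantMatrix

DEFAULT_CV_BINS = (15.0, 20.0, 30.0, 50.0)


@dataclass
class ProteinQuantMatrix:
    """Protein x injection abundances (NaN missing) with peptide counts."""

    abundances: pd.DataFrame
    n_peptides: pd.Series

    def __post_init__(self) -> None:
        self.abundances.index.name = "protein_id"
        if (self.n_peptides < 1).any():
            raise ValueError("every rolled-up protein needs >= 1 peptide")


@dataclass
class CVReport:
    """Per-group protein CV distribution in assay-acceptance style.

    ``bin_table`` has one row per (group, bin) with count and percent;
    ``mean_cv`` maps group → mean percent CV; ``cumulative_le`` maps group →
    percent of proteins at or below the named CV bound (default 30%).
    """

    bin_table: pd.DataFrame
    mean_cv: dict[str, float]
    cumulative_le: dict[str, float]
    cumulative_bound: float
    n_proteins: dict[str, int]


@dataclass
class QCResult:
    """Verdict from QC injections: percent of proteins within the default
    and LLOQ CV bounds, and pass/fail at ``min_fraction_pass``."""

    pct_within_default: float | None
    pct_within_lloq: float | None
    cv_pass: float
    cv_pass_lloq: float
    min_fraction_pass: float
    verdict: str  # "pass" | "fail" | "not evaluable"
    n_proteins: int = 0


def rollup_protein(
    matrix: PeptideQuantMatrix, method: str = "sum"
) -> ProteinQuantMatrix:
    """Combine qualified peptide areas into protein abundances.

    Shared peptides (multiple accessions) are excluded — they would couple
    unrelated proteins. A cell is missing only when no peptide of the
    protein has a value in that run; proteins left with zero usable peptides
    are dropped (and counted in the log).
    """
    if method not in ("sum", "mean"):
        raise ValueError(f"unknown roll-up method {method!r}")
    rows: dict[str, list[str]] = {}
    for pep in matrix.peptide_keys:
        prots = matrix.protein_map[pep]
        if len(prots) > 1:
            continue
        rows.setdefault(prots[0], []).append(pep)
    if not rows:
        raise ValueError("no non-shared peptides to roll up")
    out = {}
    n_pep = {}
    for prot in sorted(rows):
        sub = matrix.areas.loc[rows[prot]]
        agg = sub.sum(axis=0, min_count=1) if method == "sum" else sub.mean(axis=0)
        out[prot] = agg
        n_pep[prot] = len(rows[prot])
    abundances = pd.DataFrame(out).T
    abundances.index.name = "protein_id"
    return ProteinQuantMatrix(abundances, pd.Series(n_pep, name="n_peptides"))


def _cv_per_protein(abundances: pd.DataFrame, runs: list[str]) -> pd.Series:
    sub = abundances[runs]
    n = sub.notna().sum(axis=1)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    return cv.where((n >= 2) & (mean > 0))


def bin_cv_counts(
    cvs: pd.Series, bins: tuple[float, ...] = DEFAULT_CV_BINS
) -> pd.DataFrame:
    """Count proteins per CV bin: <=b1, (b1,b2], ..., >bk. Percentages are
    rounded to one decimal, as printed in assay-acceptance reports."""
    vals = cvs.dropna()
    edges = [-np.inf, *bins, np.inf]
    labels = [f"<={bins[0]:g}"]
    labels += [f"({bins[i]:g},{bins[i + 1]:g}]" for i in range(len(bins) - 1)]
    labels += [f">{bins[-1]:g}"]
    counts = pd.cut(vals, edges, labels=labels).value_counts().reindex(labels, fill_value=0)
    total = int(counts.sum())
    pct = (100.0 * counts / total).round(1) if total else counts * np.nan
    return pd.DataFrame({"bin": labels, "count": counts.values, "percent": pct.values})


def protein_cv_report(
    protein_matrix: ProteinQuantMatrix,
    design: pd.DataFrame,
    bins: tuple[float, ...] = DEFAULT_CV_BINS,
    cumulative_bound: float = 30.0,
    groups: list[str] | None = None,
) -> CVReport:
    """Per-group protein CVs, binned counts/percentages, mean CV and the
    cumulative percentage at or below ``cumulative_bound``.

    Groups with fewer than two runs are skipped with a warning. Missing
    cells are excluded; a protein needs >= 2 values in a group for a CV.
    """
    import logging

    log = logging.getLogger(__name__)
    use = design[design["replicate_role"].isin(["experimental", "qc"])]
    wanted = groups if groups is not None else list(dict.fromkeys(use["group_id"]))
    tables = []
    mean_cv: dict[str, float] = {}
    cum: dict[str, float] = {}
    n_prot: dict[str, int] = {}
    for g in wanted:
        runs = [
            r
            for r in use.loc[use["group_id"] == g, "run_id"]
            if r in protein_matrix.abundances.columns
        ]
        if len(runs) < 2:
            log.warning("protein_cv_report: group %r has < 2 runs; skipped", g)
            continue
        cvs = _cv_per_protein(protein_matrix.abundances, runs)
        tab = bin_cv_counts(cvs, bins)
        tab.insert(0, "group", g)
        tables.append(tab)
        ok = cvs.dropna()
        n_prot[g] = int(ok.size)
        mean_cv[g] = float(round(ok.mean(), 1)) if ok.size else float("nan")
        cum[g] = float(round(100.0 * (ok <= cumulative_bound).mean(), 1)) if ok.size else float("nan")
    if not tables:
        raise ValueError("no group with >= 2 runs; cannot build a CV report")
    return CVReport(
        bin_table=pd.concat(tables, ignore_index=True),
        mean_cv=mean_cv,
        cumulative_le=cum,
        cumulative_bound=cumulative_bound,
        n_proteins=n_prot,
    )


def qc_check(
    protein_matrix: ProteinQuantMatrix,
    design: pd.DataFrame,
    cv_pass: float = 25.0,
    cv_pass_lloq: float = 30.0,
    min_fraction_pass: float = 0.8,
) -> QCResult:
    """Assess instrument/run quality from QC injections.

    Per-protein CVs are computed over the runs flagged ``qc`` in the design;
    the batch passes when at least ``min_fraction_pass`` of proteins fall
    within ``cv_pass`` percent CV. The relaxed ``cv_pass_lloq`` bound is
    reported alongside. With fewer than two QC runs the result is an
    explicit "not evaluable", never a silent pass.
    """
    qc_runs = [
        r
        for r in design.loc[design["replicate_role"] == "qc", "run_id"]
        if r in protein_matrix.abundances.columns
    ]
    if len(qc_runs) < 2:
        return QCResult(None, None, cv_pass, cv_pass_lloq, min_fraction_pass, "not evaluable")
    cvs = _cv_per_protein(protein_matrix.abundances, qc_runs).dropna()
    if cvs.empty:
        return QCResult(None, None, cv_pass, cv_pass_lloq, min_fraction_pass, "not evaluable")
    pct_default = float(round(100.0 * (cvs <= cv_pass).mean(), 1))
    pct_lloq = float(round(100.0 * (cvs <= cv_pass_lloq).mean(), 1))
    verdict = "pass" if pct_default / 100.0 >= min_fraction_pass else "fail"
    return QCResult(pct_default, pct_lloq, cv_pass, cv_pass_lloq, min_fraction_pass, verdict, int(cvs.size))


def compare_groups(
    protein_matrix: ProteinQuantMatrix,
    design: pd.DataFrame,
    group_a: str | None = None,
    group_b: str | None = None,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Welch t-test on log2 protein abundances between two groups.

    Returns one row per protein: back-transformed group geometric means,
    log2 fold change (B over A), Welch t, p, Benjamini-Hochberg q, a
    ``tested`` flag (>= ``min_obs`` values per group required) and a
    ``significant`` flag (q < alpha and |log2FC| >= log2(fc_min)).
    """
    exp = design[design["replicate_role"] == "experimental"]
    groups = list(dict.fromkeys(exp["group_id"]))
    if group_a is None or group_b is None:
        if len(groups) < 2:
            raise ValueError("need at least two experimental groups to compare")
        if len(groups) > 2 and (group_a is None or group_b is None):
            raise ValueError(f"more than two groups present ({groups}); name the pair")
        group_a, group_b = groups[0], groups[1]
    runs_a = [r for r in exp.loc[exp["group_id"] == group_a, "run_id"] if r in protein_matrix.abundances.columns]
    runs_b = [r for r in exp.loc[exp["group_id"] == group_b, "run_id"] if r in protein_matrix.abundances.columns]
    if len(runs_a) < 2 or len(runs_b) < 2:
        raise ValueError("each compared group needs >= 2 runs")

    rows = []
    for prot, row in protein_matrix.abundances.iterrows():
        a = np.log2(row[runs_a].dropna().astype(float))
        b = np.log2(row[runs_b].dropna().astype(float))
        if len(a) < min_obs or len(b) < min_obs:
            rows.append((prot, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        log2fc = float(b.mean() - a.mean())
        var_a, var_b = a.var(ddof=1), b.var(ddof=1)
        if var_a == 0 and var_b == 0:
            # degenerate: identical replicate values; no evidence either way
            t, p = (0.0, 1.0) if log2fc == 0 else (np.inf * np.sign(log2fc), 0.0)
        else:
            t, p = sps.ttest_ind(b, a, equal_var=False)
        rows.append((prot, float(2 ** a.mean()), float(2 ** b.mean()), log2fc, float(t), float(p), True))
    out = pd.DataFrame(
        rows,
        columns=["protein_id", f"mean_{group_a}", f"mean_{group_b}", "log2fc", "t", "p", "tested"],
    )
    tested = out["tested"] & out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["significant"] = (
        tested
        & (out["q"] < alpha)
        & (out["log2fc"].abs() >= np.log2(max(fc_min, 1.0)))
    )
    return out


def frequency_report(events, n_injections: int) -> pd.DataFrame:
    """Identification-frequency histogram: for each k in [1, n_injections],
    the number and percent (one decimal) of peptides identified in exactly
    k injections."""
    if n_injections < 1:
        raise ValueError("n_injections must be >= 1")
    seen: dict[str, set[str]] = {}
    for e in events:
        seen.setdefault(e.peptide_key, set()).add(e.run_id)
    counts = pd.Series({k: len(v) for k, v in seen.items()})
    total = int(counts.size)
    hist = counts.value_counts().reindex(range(1, n_injections + 1), fill_value=0)
    return pd.DataFrame(
        {
            "n_injections_identified": hist.index,
            "n_peptides": hist.values,
            "percent": np.round(100.0 * hist.values / total, 1) if total else np.nan,
        }
    )


def fold_difference(areas) -> float:
    """Max/min ratio of a set of peak areas, rounded to two decimals —
    the spread identical amounts of different peptides can show."""
    vals = [float(a) for a in areas]
    if len(vals) < 2:
        raise ValueError("need at least two areas")
    if any(v <= 0 for v in vals):
        raise ValueError("areas must be > 0")
    return round(max(vals) / min(vals), 2)
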