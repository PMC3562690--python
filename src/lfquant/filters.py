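"""Peptide qualification: frequency, retention-time, CV and correlation filters.

Not every identified peptide can be used to quantify its protein: rarely
identified peptides may be misidentifications, peptides with erratic elution
never form a reliable peak, high technical-replicate CV marks poor
chromatographic behaviour, and a peptide whose profile disagrees with its
protein siblings is suspect (PTMs, sharing, carry-over). Eliminating such
peptides before roll-up matters more for accuracy than any normalization,
which this pipeline deliberately omits.

Filters run in the order frequency → retention time → CV → correlation; the
correlation filter is evaluated only among peptides surviving the first
three, so discordance is measured against already-plausible siblings. Every
failed filter is recorded per peptide in the audit report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError, IdentificationEvent
from .quantify import PeptideQuantMatrix

log = logging.getLogger(__name__)

REASONS = ("frequency", "retention_time", "cv", "correlation")


@dataclass
class FilterConfig:
    """Thresholds for the four qualification filters.

    The defaults are deliberate but not canonical — no clear cutoffs exist —
    and every one is meant to be tuned to the experiment at hand. ``cv_max``
    of 30% mirrors the relaxed quantitation acceptance bound used at the
    lower limit of quantitation.
    """

    min_id_fraction: float = 0.5  # of experimental injections
    rt_deviation_max: float = 1.5  # minutes from consensus RT
    rt_outlier_fraction_max: float = 0.25
    cv_max: float = 30.0  # percent, across technical replicates
    correlation_min: float = 0.5  # median Pearson r against siblings
    min_siblings_for_corr: int = 3

    def __post_init__(self) -> None:
        for name in ("min_id_fraction", "rt_outlier_fraction_max"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cv_max <= 0:
            raise ValueError("cv_max must be > 0")
        if not -1.0 <= self.correlation_min <= 1.0:
            raise ValueError("correlation_min must be in [-1, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown filter option(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class FilterReport:
    """Per-peptide audit trail plus per-reason summary counts."""

    table: pd.DataFrame  # peptide_key, status, removal_reasons, shared
    summary: dict[str, int] = field(default_factory=dict)

    def retained(self) -> list[str]:
        return list(self.table.loc[self.table["status"] == "retained", "peptide_key"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _experimental_runs(design: pd.DataFrame) -> list[str]:
    return list(design.loc[design["replicate_role"] == "experimental", "run_id"])


def frequency_filter(
    events: list[IdentificationEvent],
    n_injections: int,
    min_id_fraction: float,
    run_ids: set[str] | None = None,
) -> pd.Series:
    """Pass iff the peptide was identified in at least ``min_id_fraction``
    of the ``n_injections`` experimental injections.

    The more injections a peptide is identified in, the more confident one
    can be that it truly exists in all of them; a once-identified peptide
    may be a misidentification that would be quantified (wrongly) everywhere.
    """
    if n_injections < 1:
        raise ValueError("n_injections must be >= 1")
    seen: dict[str, set[str]] = {}
    for e in events:
        if run_ids is not None and e.run_id not in run_ids:
            continue
        seen.setdefault(e.peptide_key, set()).add(e.run_id)
    return pd.Series(
        {k: len(runs) / n_injections >= min_id_fraction for k, runs in sorted(seen.items())},
        dtype=bool,
    )


def retention_time_filter(
    matrix: PeptideQuantMatrix,
    consensus: pd.DataFrame,
    rt_deviation_max: float,
    rt_outlier_fraction_max: float,
) -> pd.Series:
    """Fail peptides whose elution strays from the consensus RT too often —
    the signature of indistinct, non-reproducible chromatography.

    Deviation per injection is measured at the XIC's bulk-signal time
    (PeakBounds.top_time, falling back to the integrated apex); injections
    where no peak was detectable at all count as discordant, since elution
    at the consensus time could not be confirmed there."""
    rt = dict(zip(consensus["peptide_key"], consensus["rt_min"]))
    out = {}
    for pep in matrix.peptide_keys:
        exceed = []
        for run in matrix.run_ids:
            b = matrix.bounds.get((pep, run))
            if b is None:
                exceed.append(True)
                continue
            where = b.top_time if b.top_time is not None else b.apex_time
            exceed.append(abs(where - rt[pep]) > rt_deviation_max)
        frac = float(np.mean(exceed)) if exceed else 1.0
        out[pep] = bool(frac <= rt_outlier_fraction_max)
    return pd.Series(out, dtype=bool)


def _replicate_groups(design: pd.DataFrame) -> dict[str, list[str]]:
    """sample_id → run_ids, for samples with >= 2 non-blank injections."""
    ok = design[design["replicate_role"].isin(["experimental", "qc"])]
    groups = ok.groupby("sample_id")["run_id"].apply(list).to_dict()
    return {s: r for s, r in groups.items() if len(r) >= 2}


def cv_filter(
    matrix: PeptideQuantMatrix, design: pd.DataFrame, cv_max: float
) -> pd.Series:
    """Fail peptides whose peak-area CV across technical replicates of any
    single sample exceeds ``cv_max`` percent.

    Only same-sample replicates enter the CV — differences between
    biological groups are signal, not noise. With no replicated samples the
    filter is skipped (all pass) with a warning.
    """
    reps = _replicate_groups(design)
    reps = {s: [r for r in runs if r in matrix.areas.columns] for s, runs in reps.items()}
    reps = {s: runs for s, runs in reps.items() if len(runs) >= 2}
    if not reps:
        log.warning("cv_filter: no technical replicates in design; filter skipped")
        return pd.Series(True, index=matrix.areas.index)
    out = pd.Series(True, index=matrix.areas.index)
    for _, runs in sorted(reps.items()):
        sub = matrix.areas[runs]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        bad = (n >= 2) & (mean > 0) & (cv > cv_max)
        out &= ~bad
    return out


def correlation_filter(
    matrix: PeptideQuantMatrix,
    correlation_min: float,
    min_siblings_for_corr: int = 3,
    candidates: list[str] | None = None,
) -> pd.Series:
    """Fail peptides whose abundance profile disagrees with their protein
    siblings (median pairwise Pearson r below ``correlation_min``).

    Applied only within proteins having at least ``min_siblings_for_corr``
    quantifiable peptides; pairs need >= 3 common non-missing injections.
    Peptides of small proteins, and shared peptides, pass by default.
    """
    keys = candidates if candidates is not None else matrix.peptide_keys
    out = pd.Series(True, index=pd.Index(keys))
    by_protein: dict[str, list[str]] = {}
    for pep in keys:
        prots = matrix.protein_map[pep]
        if len(prots) > 1:
            continue  # shared peptides are handled at roll-up, not here
        by_protein.setdefault(prots[0], []).append(pep)

    def median_r(pep: str, others: list[str]) -> float | None:
        a = matrix.areas.loc[pep]
        rs = []
        for other in others:
            if other == pep:
                continue
            b = matrix.areas.loc[other]
            common = a.notna() & b.notna()
            if common.sum() < 3:
                continue
            x, y = a[common], b[common]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                continue  # flat profiles carry no correlation information
            rs.append(float(np.corrcoef(x, y)[0, 1]))
        return float(np.median(rs)) if rs else None

    for _, peps in sorted(by_protein.items()):
        if len(peps) < min_siblings_for_corr:
            continue
        # greedy elimination: one discordant peptide drags its siblings'
        # median r down, so remove the worst offender and re-evaluate
        current = list(peps)
        while len(current) >= 2:
            med = {p: median_r(p, current) for p in current}
            below = {p: m for p, m in med.items() if m is not None and m < correlation_min}
            if not below:
                break
            worst = min(sorted(below), key=lambda p: below[p])
            out[worst] = False
            current.remove(worst)
    return out


def apply_filters(
    matrix: PeptideQuantMatrix,
    events: list[IdentificationEvent],
    design: pd.DataFrame,
    consensus: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[PeptideQuantMatrix, FilterReport]:
    """Run all four filters and return the filtered matrix plus the audit
    report.

    Frequency, RT and CV verdicts are recorded for every peptide (a peptide
    failing several filters lists every reason); the correlation filter is
    computed among survivors of the first three. Shared peptides stay in the
    matrix but are flagged for exclusion from protein roll-up.
    """
    config = config or FilterConfig()
    exp_runs = _experimental_runs(design)
    if not exp_runs:
        raise ConfigurationError("design table has no experimental runs")
    known = set(matrix.peptide_keys)
    cons_keys = set(consensus["peptide_key"])
    if not known <= cons_keys:
        raise ConfigurationError(
            f"matrix peptides missing from consensus: {sorted(known - cons_keys)[:3]}"
        )

    freq = frequency_filter(events, len(exp_runs), config.min_id_fraction, set(exp_runs))
    # peptides identified only in QC/blank runs have 0 experimental IDs
    freq = freq.reindex(matrix.areas.index, fill_value=config.min_id_fraction <= 0.0)
    rt_ok = retention_time_filter(
        matrix, consensus, config.rt_deviation_max, config.rt_outlier_fraction_max
    ).reindex(matrix.areas.index, fill_value=False)
    cv_ok = cv_filter(matrix, design, config.cv_max).reindex(matrix.areas.index, fill_value=True)

    survivors = [
        p for p in matrix.peptide_keys if freq[p] and rt_ok[p] and cv_ok[p]
    ]
    corr_ok = correlation_filter(
        matrix, config.correlation_min, config.min_siblings_for_corr, survivors
    ).reindex(matrix.areas.index, fill_value=True)

    rows = []
    shared = set(matrix.shared_peptides())
    for pep in matrix.peptide_keys:
        reasons = []
        if not freq[pep]:
            reasons.append("frequency")
        if not rt_ok[pep]:
            reasons.append("retention_time")
        if not cv_ok[pep]:
            reasons.append("cv")
        if pep in set(survivors) and not corr_ok[pep]:
            reasons.append("correlation")
        rows.append(
            (
                pep,
                "retained" if not reasons else "removed",
                ";".join(reasons),
                pep in shared,
            )
        )
    table = pd.DataFrame(rows, columns=["peptide_key", "status", "removal_reasons", "shared"])
    summary = {
        reason: int(table["removal_reasons"].str.contains(reason).sum())
        for reason in REASONS
    }
    summary["retained"] = int((table["status"] == "retained").sum())
    summary["removed"] = int((table["status"] == "removed").sum())
    report = FilterReport(table, summary)
    return matrix.subset(report.retained()), report
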