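"""Extracted-ion-chromatogram peak areas anchored at the consensus RT.

For every (peptide, injection) pair — including injections where the peptide
was never identified — an XIC is extracted around the aligned retention
time, the elution peak nearest the consensus RT is detected, and its area is
obtained by trapezoidal integration of the raw trace. No normalization is
applied anywhere: multiplying a run's intensities by c scales that run's
areas by exactly c.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, fields, asdict

import numpy as np
import pandas as pd

from .io_formats import ConfigurationError, IdentificationEvent, MSRun


@dataclass
class XIC:
    """Intensity-vs-time trace for one target m/z in one run."""

    run_id: str
    peptide_key: str
    target_mz: float
    tolerance: float
    tolerance_unit: str  # "da" | "ppm"
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("XIC times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("XIC intensities must be >= 0")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PeakBounds:
    """Bounds of the integrated peak.

    ``apex_time`` is the local maximum nearest the consensus RT (the peak
    that gets integrated); ``top_time`` is the time of the window's global
    intensity maximum — where the bulk of the signal eluted — which is what
    the retention-time qualification filter judges.
    """

    apex_time: float
    apex_intensity: float
    start_time: float
    end_time: float
    top_time: float | None = None

    def __post_init__(self) -> None:
        if not self.start_time <= self.apex_time <= self.end_time:
            raise ValueError("apex must lie within [start, end]")
        if self.apex_intensity <= 0:
            raise ValueError("apex intensity must be > 0")


@dataclass
class QuantParams:
    """XIC extraction / integration settings.

    ``tolerance=None`` picks the instrument-mode default: 0.5 Da in low_res
    mode (covering the ~0.3-0.9 Da precursor m/z spread seen on ion traps),
    10 ppm in high_res mode. The window of +/-3 min around the consensus RT
    matches typical LC retention drift.
    """

    tolerance: float | None = None
    tolerance_unit: str | None = None
    window: float = 3.0  # minutes, half-width
    smooth: bool = True  # 3-point moving average for apex finding only
    baseline_fraction: float = 0.01
    noise_floor: float = 0.0

    LOW_RES_DA = 0.5
    HIGH_RES_PPM = 10.0

    def resolve(self, mode: str) -> tuple[float, str]:
        if self.tolerance is not None:
            return self.tolerance, self.tolerance_unit or "da"
        if mode == "high_res":
            return self.HIGH_RES_PPM, "ppm"
        return self.LOW_RES_DA, "da"

    @classmethod
    def from_dict(cls, d: dict) -> "QuantParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown quantify option(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class PeptideQuantMatrix:
    """Peptide x injection peak areas (NaN = missing) with peak bounds and
    the peptide → protein accession map."""

    areas: pd.DataFrame
    protein_map: dict[str, tuple[str, ...]]
    bounds: dict[tuple[str, str], PeakBounds] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.areas.index.name = "peptide_key"
        vals = self.areas.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("peak areas must be >= 0")

    @property
    def peptide_keys(self) -> list[str]:
        return list(self.areas.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.areas.columns)

    def shared_peptides(self) -> list[str]:
        return [k for k, prots in self.protein_map.items() if len(prots) > 1]

    def subset(self, peptide_keys) -> "PeptideQuantMatrix":
        keys = [k for k in self.areas.index if k in set(peptide_keys)]
        return PeptideQuantMatrix(
            self.areas.loc[keys].copy(),
            {k: self.protein_map[k] for k in keys},
            {kr: b for kr, b in self.bounds.items() if kr[0] in set(keys)},
        )


def extract_xic(
    run: MSRun,
    target_mz: float,
    tolerance: float,
    rt: float,
    window: float,
    tolerance_unit: str = "da",
    peptide_key: str = "",
) -> XIC:
    """Sum MS1 intensity within an m/z tolerance of the target, for every
    scan inside [rt - window, rt + window]. Scans with no matching peak
    contribute 0; an RT window holding no scans yields an empty XIC."""
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if window <= 0:
        raise ValueError("window must be > 0")
    tol_da = tolerance if tolerance_unit == "da" else target_mz * tolerance * 1e-6
    lo, hi = target_mz - tol_da, target_mz + tol_da
    times, intens = [], []
    for scan in run.scans:
        if scan.time < rt - window or scan.time > rt + window:
            continue
        i0 = np.searchsorted(scan.mz, lo, side="left")
        i1 = np.searchsorted(scan.mz, hi, side="right")
        times.append(scan.time)
        intens.append(float(scan.intensity[i0:i1].sum()) if i1 > i0 else 0.0)
    return XIC(
        run.run_id, peptide_key, target_mz, tolerance, tolerance_unit,
        np.array(times), np.array(intens),
    )


def _smooth3(y: np.ndarray) -> np.ndarray:
    if y.size < 3:
        return y.astype(float)
    out = y.astype(float).copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    out[0] = (y[0] + y[1]) / 2.0
    out[-1] = (y[-2] + y[-1]) / 2.0
    return out


def detect_peak(
    xic: XIC,
    consensus_rt: float,
    smooth: bool = True,
    baseline_fraction: float = 0.01,
    noise_floor: float = 0.0,
) -> PeakBounds | None:
    """Locate the elution peak nearest the consensus RT.

    The apex is the local maximum of the (optionally 3-point smoothed) trace
    closest in time to ``consensus_rt``; peak boundaries walk outward on the
    raw trace until the intensity drops below
    ``max(baseline_fraction * apex, noise_floor)``, a local minimum is hit,
    or the trace ends. Returns None (missing) when no point exceeds the
    noise floor.
    """
    if len(xic) == 0:
        return None
    raw = xic.intensities
    if not np.any(raw > max(noise_floor, 0.0)):
        return None
    trace = _smooth3(raw) if smooth else raw.astype(float)

    n = trace.size
    maxima = []
    for i in range(n):
        left = trace[i - 1] if i > 0 else -np.inf
        right = trace[i + 1] if i < n - 1 else -np.inf
        if trace[i] >= left and trace[i] >= right:
            maxima.append(i)
    maxima = [i for i in maxima if raw[i] > max(noise_floor, 0.0)]
    if not maxima:
        return None
    apex = min(maxima, key=lambda i: (abs(xic.times[i] - consensus_rt), i))

    thr = max(baseline_fraction * raw[apex], noise_floor)

    def walk(i0: int, step: int) -> int:
        i = i0
        while True:
            j = i + step
            if j < 0 or j >= n:
                return i
            if raw[j] > raw[i]:
                return i  # local minimum
            i = j
            if raw[i] <= thr:
                return i
        # unreachable

    left = walk(apex, -1)
    right = walk(apex, +1)
    return PeakBounds(
        apex_time=float(xic.times[apex]),
        apex_intensity=float(raw[apex]),
        start_time=float(xic.times[left]),
        end_time=float(xic.times[right]),
        top_time=float(xic.times[int(np.argmax(raw))]),
    )


def integrate_area(xic: XIC, bounds: PeakBounds) -> float:
    """Trapezoidal integral of the raw intensities between the peak bounds.

    Integration always uses the unsmoothed trace (smoothing would bias
    areas). Exact additivity holds: splitting at any interior sample point
    and summing the parts reproduces the whole.
    """
    if len(xic) == 0:
        raise ValueError("cannot integrate an empty XIC")
    t = xic.times
    if bounds.start_time < t[0] or bounds.end_time > t[-1]:
        raise ValueError("integration bounds fall outside the XIC time span")
    i0 = int(np.searchsorted(t, bounds.start_time, side="left"))
    i1 = int(np.searchsorted(t, bounds.end_time, side="right")) - 1
    if i1 <= i0:
        return 0.0
    return float(np.trapezoid(xic.intensities[i0 : i1 + 1], t[i0 : i1 + 1]))


def peptide_target_mz(events: list[IdentificationEvent]) -> float:
    """Per-peptide target m/z: median of the event precursor m/z values
    (robust to occasional outlier m/z drift)."""
    return float(statistics.median(e.precursor_mz for e in events))


def build_peptide_matrix(
    runs: list[MSRun],
    consensus: pd.DataFrame,
    events: list[IdentificationEvent],
    params: QuantParams | None = None,
    design: pd.DataFrame | None = None,
) -> PeptideQuantMatrix:
    """Quantify every aligned peptide in every injection.

    A peptide identified in only one injection may well be present in all of
    them, so extraction is attempted for every (peptide, run) pair; cells
    where no peak rises above the noise floor stay missing.

    ``consensus`` is the table produced by :func:`lfquant.alignment.align_events`.
    When a design table is given, each of its non-blank runs must be present.
    """
    params = params or QuantParams()
    run_by_id = {r.run_id: r for r in runs}
    if design is not None:
        needed = design.loc[design["replicate_role"] != "blank", "run_id"]
        missing = [r for r in needed if r not in run_by_id]
        if missing:
            raise ConfigurationError(f"design references absent run(s): {missing}")
        run_ids = [r for r in needed if r in run_by_id]
    else:
        run_ids = [r.run_id for r in runs]

    ev_by_pep: dict[str, list[IdentificationEvent]] = {}
    for e in events:
        ev_by_pep.setdefault(e.peptide_key, []).append(e)

    peptides = list(consensus["peptide_key"])
    rts = dict(zip(consensus["peptide_key"], consensus["rt_min"]))
    missing_ev = [p for p in peptides if p not in ev_by_pep]
    if missing_ev:
        raise ConfigurationError(
            f"consensus table lists peptides without events: {missing_ev[:3]}..."
        )

    protein_map = {p: ev_by_pep[p][0].protein_ids for p in peptides}
    targets = {p: peptide_target_mz(ev_by_pep[p]) for p in peptides}

    area = np.full((len(peptides), len(run_ids)), np.nan)
    bounds: dict[tuple[str, str], PeakBounds] = {}
    for j, rid in enumerate(run_ids):
        run = run_by_id[rid]
        tol, unit = params.resolve(run.meta.get("mode", "low_res"))
        for i, pep in enumerate(peptides):
            xic = extract_xic(run, targets[pep], tol, rts[pep], params.window, unit, pep)
            pk = detect_peak(
                xic, rts[pep], params.smooth, params.baseline_fraction, params.noise_floor
            )
            if pk is None:
                continue
            bounds[(pep, rid)] = pk
            area[i, j] = integrate_area(xic, pk)

    areas = pd.DataFrame(area, index=pd.Index(peptides, name="peptide_key"), columns=run_ids)
    return PeptideQuantMatrix(areas, protein_map, bounds)
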