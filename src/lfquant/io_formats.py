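"""Readers and writers for LC-MS runs, PSM tables, design tables and matrices.

All retention times are minutes and all m/z values are Da throughout the
package. Two run dialects are supported: a line-oriented internal TSV format
(lossless round-trip, used by the simulator and the test-suite) and a
read-only subset of mzML restricted to centroided MS1 spectra.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violates the expected dialect (bad header, non-monotone times...)."""


class ConfigurationError(ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


#: required columns of a PSM table, in canonical order
PSM_COLUMNS = (
    "run_id",
    "scan_number",
    "scan_time_min",
    "precursor_mz",
    "charge",
    "peptide_key",
    "protein_ids",
    "confidence",
)

DESIGN_COLUMNS = ("run_id", "sample_id", "group_id", "replicate_role")
_ROLES = ("experimental", "qc", "blank")


@dataclass
class MS1Scan:
    """One centroided full-MS scan: parallel m/z / intensity arrays."""

    scan_number: int
    time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise FormatError(
                f"scan {self.scan_number}: mz and intensity must be 1-D arrays "
                f"of equal length"
            )
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            raise FormatError(f"scan {self.scan_number}: m/z values not ascending")
        if np.any(self.intensity < 0):
            raise FormatError(f"scan {self.scan_number}: negative intensity")


@dataclass
class MSRun:
    """One injection's MS1 scans in elution order plus free-form metadata.

    ``meta['mode']`` is ``"low_res"`` or ``"high_res"`` and selects the
    default XIC m/z tolerance downstream (0.5 Da vs 10 ppm).
    """

    run_id: str
    scans: list[MS1Scan]
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.array([s.time for s in self.scans])
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise FormatError(f"run {self.run_id}: scan times not strictly increasing")
        self.meta.setdefault("mode", "low_res")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans])


@dataclass(frozen=True)
class IdentificationEvent:
    """One MS/MS identification: the landmark unit of the alignment."""

    run_id: str
    scan_number: int
    scan_time: float  # minutes
    precursor_mz: float  # Da
    charge: int
    peptide_key: str  # sequence + modifications + charge
    protein_ids: tuple[str, ...]
    confidence: float  # in [0, 1], larger is better

    def __post_init__(self) -> None:
        if self.scan_time < 0:
            raise FormatError(f"negative scan time for {self.peptide_key}")
        if not self.peptide_key:
            raise FormatError("empty peptide_key")
        if not self.protein_ids:
            raise FormatError(f"{self.peptide_key}: no protein accession")


# ---------------------------------------------------------------------------
# internal run dialect
# ---------------------------------------------------------------------------

_MAGIC = "#LFQRUN\t1"


def write_run(run: MSRun, path: str | os.PathLike) -> None:
    """Write an MSRun in the internal TSV dialect (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        meta = ";".join(f"{k}={v}" for k, v in sorted(run.meta.items()))
        fh.write(f"#RUN\t{run.run_id}\t{meta}\n")
        for scan in run.scans:
            fh.write(f"#SCAN\t{scan.scan_number}\t{float(scan.time)!r}\n")
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{float(mz)!r}\t{float(inten)!r}\n")


def _read_internal(path: str | os.PathLike) -> MSRun:
    run_id = None
    meta: dict[str, str] = {}
    scans: list[MS1Scan] = []
    cur_num = cur_time = None
    mzs: list[float] = []
    intens: list[float] = []

    def flush() -> None:
        if cur_num is not None:
            scans.append(MS1Scan(cur_num, cur_time, np.array(mzs), np.array(intens)))

    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise FormatError(f"{path}: not an internal-format run file")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#RUN\t"):
                parts = line.split("\t")
                run_id = parts[1]
                if len(parts) > 2 and parts[2]:
                    meta = dict(kv.split("=", 1) for kv in parts[2].split(";"))
            elif line.startswith("#SCAN\t"):
                flush()
                _, num, t = line.split("\t")
                cur_num, cur_time = int(num), float(t)
                mzs, intens = [], []
            else:
                a, b = line.split("\t")
                mzs.append(float(a))
                intens.append(float(b))
    flush()
    if run_id is None:
        raise FormatError(f"{path}: missing #RUN header")
    return MSRun(run_id, scans, meta)


_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_binary(bda) -> np.ndarray:
    import base64
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    accs = {cv.get("accession") for cv in bda.iter(ns + "cvParam")}
    node = bda.find(ns + "binary")
    raw = base64.b64decode(node.text or "")
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str | os.PathLike) -> MSRun:
    """Minimal mzML reader: centroided MS1 spectra only.

    Handles 32/64-bit float arrays, optional zlib compression, and scan
    start times in minutes or seconds. MS2+ spectra are skipped (they carry
    no XIC signal).
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    scans: list[MS1Scan] = []
    for i, (_, spec) in enumerate(
        etree.iterparse(str(path), events=("end",), tag=ns + "spectrum")
    ):
        params = {cv.get("accession"): cv for cv in spec.iter(ns + "cvParam")}
        level = params.get(_ACC_MS_LEVEL)
        if level is not None and level.get("value") != "1":
            spec.clear()
            continue
        start = params.get(_ACC_SCAN_START)
        if start is None:
            raise FormatError(f"{path}: spectrum without scan start time")
        time_min = float(start.get("value"))
        if start.get("unitName") == "second":
            time_min /= 60.0
        arrays = {}
        for bda in spec.iter(ns + "binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(ns + "cvParam")}
            if _ACC_MZ_ARRAY in accs:
                arrays["mz"] = _decode_binary(bda)
            elif _ACC_INT_ARRAY in accs:
                arrays["intensity"] = _decode_binary(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError(f"{path}: MS1 spectrum missing m/z or intensity array")
        m = re.search(r"scan=(\d+)", spec.get("id", ""))
        number = int(m.group(1)) if m else int(spec.get("index", i)) + 1
        order = np.argsort(arrays["mz"], kind="stable")
        scans.append(
            MS1Scan(number, time_min, arrays["mz"][order], arrays["intensity"][order])
        )
        spec.clear()
    run_id = os.path.splitext(os.path.basename(str(path)))[0]
    return MSRun(run_id, scans, {"source": "mzml"})


def read_run(path: str | os.PathLike, format: str = "internal") -> MSRun:
    """Read one injection.

    Parameters
    ----------
    path
        Run file.
    format
        ``"internal"`` for the TSV dialect written by :func:`write_run`,
        ``"mzml"`` for the mzML subset (MS1 centroid spectra only; MS2
        spectra are skipped).
    """
    if not os.path.exists(path):
        raise OSError(f"run file not found: {path}")
    if format == "internal":
        return _read_internal(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown run format: {format!r}")


# ---------------------------------------------------------------------------
# PSM and design tables
# ---------------------------------------------------------------------------


def read_psm_table(
    path: str | os.PathLike, min_confidence: float = 0.0
) -> list[IdentificationEvent]:
    """Read a PSM TSV, drop rows below ``min_confidence`` and return events in
    canonical (peptide_key, run_id, scan_time) order."""
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "peptide_key": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: PSM table missing column(s) {missing}")
    df = df[df["confidence"] >= min_confidence]
    df = df.sort_values(["peptide_key", "run_id", "scan_time_min"], kind="stable")
    return [
        IdentificationEvent(
            run_id=row.run_id,
            scan_number=int(row.scan_number),
            scan_time=float(row.scan_time_min),
            precursor_mz=float(row.precursor_mz),
            charge=int(row.charge),
            peptide_key=row.peptide_key,
            protein_ids=tuple(str(row.protein_ids).split(";")),
            confidence=float(row.confidence),
        )
        for row in df.itertuples(index=False)
    ]


def write_psm_table(
    events: list[IdentificationEvent], path: str | os.PathLike
) -> None:
    rows = [
        (
            e.run_id,
            e.scan_number,
            repr(e.scan_time),
            repr(e.precursor_mz),
            e.charge,
            e.peptide_key,
            ";".join(e.protein_ids),
            repr(e.confidence),
        )
        for e in events
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_design_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the injection → sample → group design; validates roles and
    run_id uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: design table missing column(s) {missing}")
    return validate_design(df)


def validate_design(df: pd.DataFrame) -> pd.DataFrame:
    if df["run_id"].duplicated().any():
        dup = df.loc[df["run_id"].duplicated(), "run_id"].iloc[0]
        raise FormatError(f"design table: duplicate run_id {dup!r}")
    bad = set(df["replicate_role"]) - set(_ROLES)
    if bad:
        raise FormatError(f"design table: unknown replicate_role(s) {sorted(bad)}")
    if not (df["replicate_role"] == "experimental").any():
        raise FormatError("design table: no experimental injections")
    return df.reset_index(drop=True)


def write_design_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quantitation matrices
# ---------------------------------------------------------------------------


def write_matrix(matrix, path: str | os.PathLike) -> None:
    """Write a peptide or protein quantitation matrix as TSV.

    One row per key, one column per run_id; missing cells are empty fields.
    Accepts either a DataFrame or any object exposing a ``.areas`` /
    ``.abundances`` DataFrame (PeptideQuantMatrix, ProteinQuantMatrix).
    """
    df = getattr(matrix, "areas", None)
    if df is None:
        df = getattr(matrix, "abundances", None)
    if df is None:
        df = matrix
    if df.shape[0] == 0:
        raise ValueError("refusing to write an empty matrix")
    out = df.copy()
    out.index.name = out.index.name or "key"
    # repr() round-trips float64 exactly through the text format
    out = out.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t")


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)
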