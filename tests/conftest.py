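"""Shared fixtures: a hand-rolled tiny mzML writer and seeded simulated
experiments reused across module tests."""

from __future__ import annotations

import base64
import struct

import pytest

from lfquant.synthetic_data import (
    GroupSpec,
    IdProbModel,
    SimConfig,
    simulate_experiment,
)


def _b64(vals) -> str:
    return base64.b64encode(struct.pack("<%dd" % len(vals), *vals)).decode()


def _spectrum(idx: int, scan: int, ms_level: int, time_min: float, mz, inten) -> str:
    return f"""
    <spectrum index="{idx}" id="scan={scan}" defaultArrayLength="{len(mz)}">
      <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
      <scanList count="1">
        <scan>
          <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time_min}" unitAccession="UO:0000031" unitName="minute"/>
        </scan>
      </scanList>
      <binaryDataArrayList count="2">
        <binaryDataArray encodedLength="{len(_b64(mz))}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
          <binary>{_b64(mz)}</binary>
        </binaryDataArray>
        <binaryDataArray encodedLength="{len(_b64(inten))}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
          <binary>{_b64(inten)}</binary>
        </binaryDataArray>
      </binaryDataArrayList>
    </spectrum>"""


def write_tiny_mzml(path, spectra) -> None:
    """Write a synthetic minimal mzML file.

    ``spectra`` is a list of (scan_number, ms_level, time_min, mz, intensity).
    This is a test stand-in for instrument output, not a general writer.
    """
    body = "".join(
        _spectrum(i, scan, level, t, mz, inten)
        for i, (scan, level, t, mz, inten) in enumerate(spectra)
    )
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="tiny">
    <spectrumList count="{len(spectra)}">{body}
    </spectrumList>
  </run>
</mzML>"""
    with open(path, "w") as fh:
        fh.write(doc)


@pytest.fixture(scope="session")
def small_experiment():
    """Two-group experiment (5 proteins truly 2-fold changed) with QC
    injections; moderate noise; fixed seed."""
    cfg = SimConfig(
        n_proteins=10,
        peptides_per_protein=(2, 3),
        groups={
            "A": GroupSpec(n_samples=3),
            "B": GroupSpec(n_samples=3, fold_change=2.0, n_changed=5),
        },
        noise_cv=0.1,
        shared_peptide_fraction=0.1,
        seed=42,
    )
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Deterministic chromatography: pattern (i) only, no noise, no jitter."""
    cfg = SimConfig(
        n_proteins=6,
        peptides_per_protein=(2, 2),
        groups={"A": GroupSpec(n_samples=3)},
        pattern_mix={"i": 1.0, "ii": 0, "iii": 0, "iv": 0, "v": 0, "vi": 0},
        noise_cv=0.0,
        rt_jitter_sd=0.0,
        mz_jitter_sd=0.0,
        shared_peptide_fraction=0.0,
        n_qc_injections=0,
        id_prob_model=IdProbModel(intercept=6.0),  # everything gets identified
        seed=7,
    )
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def misbehaved_experiment():
    """Single-group experiment heavy in pattern-(vi) peptides plus
    misidentified singletons, with technical replicates for the CV filter."""
    cfg = SimConfig(
        n_proteins=20,
        peptides_per_protein=(2, 3),
        groups={"A": GroupSpec(n_samples=5, n_tech_reps=2)},
        pattern_mix={"i": 0.5, "ii": 0.0, "iii": 0.0, "iv": 0.0, "v": 0.0, "vi": 0.5},
        noise_cv=0.1,
        misid_fraction=0.15,
        shared_peptide_fraction=0.0,
        seed=11,
    )
    return cfg, simulate_experiment(cfg)
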