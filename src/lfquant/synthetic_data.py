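"""Simulator for multi-injection LC-MS/MS label-free experiments.

The generator produces MS1 runs, MS/MS identification events, a design table
and a ground-truth record, reproducing the acquisition phenomenology that
makes label-free quantitation hard:

* per-peptide retention drift across injections on the order of 3 min;
* six chromatographic elution patterns — (i) a single consistent peak,
  (ii) a single peak with injection-specific apex shifts, (iii) column
  overload with an early satellite, (iv) tight binding with a late satellite,
  (v) both satellites, (vi) poor chromatography: low, broad, multi-modal
  elution at indistinct time points that differ between injections;
* MS/MS sampling away from the elution apex under dynamic exclusion;
* identification probability that rises with abundance, so identification
  frequency across injections is strongly right-skewed (many peptides seen
  in only one injection);
* optionally, misidentified singleton peptides and peptides shared between
  proteins.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; a fixed config gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, fields

import numpy as np
import pandas as pd

from .io_formats import IdentificationEvent, MS1Scan, MSRun

PATTERNS = ("i", "ii", "iii", "iv", "v", "vi")

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _gauss(t: np.ndarray, area: float, mu: float, sigma: float) -> np.ndarray:
    return area / (sigma * _SQRT2PI) * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


@dataclass
class IdProbModel:
    """Logistic identification probability in log10 abundance.

    p = sigmoid(intercept + slope * (log10(area) - center)); only the
    qualitative effect — frequency heterogeneity across injections — matters
    downstream.
    """

    intercept: float = 0.5
    slope: float = 1.5
    center_log10_area: float = 6.0

    def prob(self, area: float) -> float:
        z = self.intercept + self.slope * (math.log10(max(area, 1e-12)) - self.center_log10_area)
        return 1.0 / (1.0 + math.exp(-z))


@dataclass
class GroupSpec:
    """One experimental group: n_samples biological samples, each injected
    n_tech_reps times; fold_change is applied to n_changed proteins
    (all proteins when None) relative to the base abundance."""

    n_samples: int = 5
    n_tech_reps: int = 1
    fold_change: float = 1.0
    n_changed: int | None = None


def _default_groups() -> dict[str, GroupSpec]:
    return {"A": GroupSpec(), "B": GroupSpec(fold_change=2.0)}


def _default_pattern_mix() -> dict[str, float]:
    # most peptides chromatograph well; a visible minority misbehaves
    return {"i": 0.55, "ii": 0.15, "iii": 0.08, "iv": 0.08, "v": 0.04, "vi": 0.10}


@dataclass
class SimConfig:
    """Parameters of one simulated experiment. Times in minutes, m/z in Da,
    areas in arbitrary units."""

    n_proteins: int = 20
    peptides_per_protein: tuple[int, int] = (2, 4)
    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    rt_jitter_sd: float = 0.75  # gives a ~3 min max-min spread over ~10 injections
    mz_jitter_sd: float = 0.15  # low-res precursor m/z reproducibility
    peak_width_range: tuple[float, float] = (0.08, 0.25)  # Gaussian sd, min
    pattern_mix: dict[str, float] = field(default_factory=_default_pattern_mix)
    id_prob_model: IdProbModel = field(default_factory=IdProbModel)
    noise_cv: float = 0.1  # multiplicative area noise per peptide-injection
    dynamic_exclusion_window: float = 0.5
    seed: int = 0
    # acquisition details
    cycle_time: float = 0.05  # MS1 cycle, min
    gradient_length: float = 30.0
    trigger_threshold: float = 1e4  # MS/MS trigger intensity
    select_prob: float = 0.7  # chance an eligible precursor wins MS/MS
    baseline_level: float = 0.0  # additive intensity on emitted peaks
    emit_threshold: float = 1.0  # profile intensity below this is not recorded
    # population
    area_log10_mean: float = 6.0
    area_log10_sd: float = 0.6
    bio_cv: float = 0.0  # biological sample-to-sample variation
    satellite_fraction: float = 0.2  # patterns (iii)-(v), per satellite
    satellite_offset: float = 2.0  # min between main apex and satellite
    misid_fraction: float = 0.0  # chance an identification gets a wrong key
    shared_peptide_fraction: float = 0.05
    n_qc_injections: int = 2
    confidence_range: tuple[float, float] = (0.9, 0.999)
    instrument_mode: str = "low_res"

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be an increasing range >= 1")
        if not self.groups:
            raise ValueError("at least one group is required")
        for name, g in self.groups.items():
            if g.n_samples < 1 or g.n_tech_reps < 1:
                raise ValueError(f"group {name}: counts must be >= 1")
            if g.n_changed is not None and not (0 <= g.n_changed <= self.n_proteins):
                raise ValueError(f"group {name}: n_changed out of range")
        if set(self.pattern_mix) - set(PATTERNS):
            raise ValueError(f"unknown pattern(s) {set(self.pattern_mix) - set(PATTERNS)}")
        tot = sum(self.pattern_mix.values())
        if abs(tot - 1.0) > 1e-9 or any(p < 0 for p in self.pattern_mix.values()):
            raise ValueError("pattern_mix must be a probability distribution")
        for name in ("noise_cv", "mz_jitter_sd", "rt_jitter_sd", "bio_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("select_prob", "misid_fraction", "shared_peptide_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dynamic_exclusion_window <= 0:
            raise ValueError("dynamic_exclusion_window must be > 0")
        if self.cycle_time <= 0 or self.gradient_length <= self.cycle_time:
            raise ValueError("invalid scan-cycle / gradient configuration")
        if not (0 < self.peak_width_range[0] <= self.peak_width_range[1]):
            raise ValueError("peak_width_range must be a positive increasing range")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulate option(s): {sorted(unknown)}")
        if "groups" in d:
            d["groups"] = {k: GroupSpec(**v) for k, v in d["groups"].items()}
        if "id_prob_model" in d:
            d["id_prob_model"] = IdProbModel(**d["id_prob_model"])
        for key in ("peptides_per_protein", "peak_width_range", "confidence_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """True state behind one simulated experiment.

    peptides : one row per peptide_key (protein_id, pattern, true_mz,
        base_area, width, base_rt, shared, misid).
    proteins : one row per protein with its per-group fold change columns.
    apex     : one row per (peptide_key, run_id) that was simulated, with the
        realized apex RT and the realized (noisy) total area.
    """

    peptides: pd.DataFrame
    proteins: pd.DataFrame
    apex: pd.DataFrame

    def write(self, directory) -> None:
        import os

        self.peptides.to_csv(os.path.join(directory, "truth_peptides.tsv"), sep="\t", index=False)
        self.proteins.to_csv(os.path.join(directory, "truth_proteins.tsv"), sep="\t", index=False)
        self.apex.to_csv(os.path.join(directory, "truth_apex.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# elution profiles
# ---------------------------------------------------------------------------


def profile_components(
    pattern: str,
    apex_rt: float,
    width: float,
    satellite_fraction: float = 0.2,
    satellite_offset: float = 2.0,
    vi_components: list[tuple[float, float, float]] | None = None,
) -> list[tuple[float, float, float]]:
    """Gaussian mixture (fraction, center, sigma) realizing one elution
    pattern; fractions sum to 1 so the profile integrates to base_area."""
    if pattern not in PATTERNS:
        raise ValueError(f"unknown elution pattern {pattern!r}; expected one of {PATTERNS}")
    f = satellite_fraction
    if pattern in ("i", "ii"):
        return [(1.0, apex_rt, width)]
    if pattern == "iii":  # overload: part elutes before the main peak
        return [(1.0 - f, apex_rt, width), (f, apex_rt - satellite_offset, width)]
    if pattern == "iv":  # tight binding: remainder elutes after the main peak
        return [(1.0 - f, apex_rt, width), (f, apex_rt + satellite_offset, width)]
    if pattern == "v":
        return [
            (1.0 - 2.0 * f, apex_rt, width),
            (f, apex_rt - satellite_offset, width),
            (f, apex_rt + satellite_offset, width),
        ]
    # pattern (vi): low, broad, multi-modal; callers normally supply
    # injection-specific components, the fallback spans 6 min
    if vi_components is not None:
        return list(vi_components)
    w = 3.0 * width
    third = 1.0 / 3.0
    return [(third, apex_rt - 3.0, w), (third, apex_rt, w), (third, apex_rt + 3.0, w)]


def elution_profile(
    pattern: str,
    base_area: float,
    apex_rt: float,
    width: float,
    t: np.ndarray | float,
    satellite_fraction: float = 0.2,
    satellite_offset: float = 2.0,
    vi_components: list[tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Intensity of one peptide's elution profile at time(s) ``t``.

    The profile integrates to ``base_area`` (fractions of the underlying
    Gaussian mixture sum to one). Pattern (ii) is the same single Gaussian as
    (i); its injection-specific apex shift is applied by the caller through
    ``apex_rt``.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    if base_area <= 0:
        raise ValueError("base_area must be > 0")
    comps = profile_components(
        pattern, apex_rt, width, satellite_fraction, satellite_offset, vi_components
    )
    tt = np.asarray(t, dtype=float)
    out = np.zeros_like(tt, dtype=float)
    for frac, mu, sigma in comps:
        out += _gauss(tt, frac * base_area, mu, sigma)
    return out


def sample_msms_events(
    times: np.ndarray,
    intensities: np.ndarray,
    dynamic_exclusion_window: float,
    rng: np.random.Generator,
    trigger_threshold: float,
    select_prob: float = 0.7,
) -> list[float]:
    """MS/MS scan times for one precursor under dynamic exclusion.

    Walking the MS1 trace in time order, the precursor is eligible wherever
    its intensity exceeds the trigger and it is not dynamically excluded;
    each eligible cycle it wins the MS/MS slot with probability
    ``select_prob`` (competition with co-eluting precursors). The first
    selection typically lands on the leading edge, and exclusion pushes
    repeats into the peak tail, so events are not apex-centred.
    """
    if dynamic_exclusion_window <= 0:
        raise ValueError("dynamic_exclusion_window must be > 0")
    if np.any(np.asarray(intensities) < 0):
        raise ValueError("profile must be nonnegative")
    out: list[float] = []
    last = -np.inf
    for t, inten in zip(times, intensities):
        if inten <= trigger_threshold:
            continue
        if t - last < dynamic_exclusion_window:
            continue
        if rng.random() < select_prob:
            out.append(float(t))
            last = t
    return out


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------


def _build_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for gname, g in config.groups.items():
        for s in range(1, g.n_samples + 1):
            for r in range(1, g.n_tech_reps + 1):
                rows.append(
                    (f"{gname}_s{s}_r{r}", f"{gname}_s{s}", gname, "experimental")
                )
    for i in range(1, config.n_qc_injections + 1):
        rows.append((f"QC_r{i}", "QC_pool", "QC", "qc"))
    return pd.DataFrame(rows, columns=["run_id", "sample_id", "group_id", "replicate_role"])


def simulate_experiment(
    config: SimConfig,
) -> tuple[list[MSRun], list[IdentificationEvent], pd.DataFrame, GroundTruth]:
    """Simulate a full multi-injection experiment.

    Returns (runs, identification events, design table, ground truth). Every
    event's peptide_key — including misidentified ones — appears in
    ``GroundTruth.peptides``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pat_names = list(PATTERNS)
    pat_probs = np.array([config.pattern_mix.get(p, 0.0) for p in pat_names])

    # --- protein and peptide population -----------------------------------
    protein_ids = [f"PROT{i + 1:04d}" for i in range(config.n_proteins)]
    group_names = list(config.groups)
    fc = {}
    for gi, gname in enumerate(group_names):
        g = config.groups[gname]
        col = np.ones(config.n_proteins)
        if gi > 0 and g.fold_change != 1.0:
            if g.n_changed is None:
                col[:] = g.fold_change
            else:
                idx = rng.choice(config.n_proteins, size=g.n_changed, replace=False)
                col[np.sort(idx)] = g.fold_change
        fc[gname] = col
    proteins = pd.DataFrame({"protein_id": protein_ids})
    for gname in group_names:
        proteins[f"fc_{gname}"] = fc[gname]

    lo, hi = config.peptides_per_protein
    pep_rows = []
    rt_lo, rt_hi = 0.12 * config.gradient_length, 0.88 * config.gradient_length
    for pi, prot in enumerate(protein_ids):
        n_pep = int(rng.integers(lo, hi + 1))
        for j in range(n_pep):
            key = f"PEP{len(pep_rows) + 1:05d}.2"
            pattern = pat_names[rng.choice(len(pat_names), p=pat_probs)]
            accessions = [prot]
            if config.n_proteins > 1 and rng.random() < config.shared_peptide_fraction:
                other = int(rng.integers(config.n_proteins - 1))
                if other >= pi:
                    other += 1
                accessions.append(protein_ids[other])
            pep_rows.append(
                {
                    "peptide_key": key,
                    "protein_id": prot,
                    "all_proteins": ";".join(accessions),
                    "pattern": pattern,
                    "true_mz": float(rng.uniform(400.0, 1200.0)),
                    "base_rt": float(rng.uniform(rt_lo, rt_hi)),
                    "width": float(rng.uniform(*config.peak_width_range)),
                    "base_area": float(10 ** rng.normal(config.area_log10_mean, config.area_log10_sd)),
                    "shared": len(accessions) > 1,
                    "misid": False,
                }
            )
    peptides = pd.DataFrame(pep_rows)
    n_pep = len(peptides)

    design = _build_design(config)
    grid = np.arange(0.0, config.gradient_length, config.cycle_time)

    # per-sample biological factors (same for technical replicates)
    bio = {}
    bio_sigma = math.sqrt(math.log(1 + config.bio_cv**2)) if config.bio_cv > 0 else 0.0
    for sample in design["sample_id"].unique():
        bio[sample] = (
            float(rng.lognormal(-0.5 * bio_sigma**2, bio_sigma)) if bio_sigma > 0 else 1.0
        )

    jitter_scale = {"i": 0.15, "ii": 1.5, "iii": 1.0, "iv": 1.0, "v": 1.0, "vi": 1.0}
    noise_sigma = math.sqrt(math.log(1 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    runs: list[MSRun] = []
    events: list[IdentificationEvent] = []
    apex_rows = []
    misid_rows = []
    misid_counter = 0

    pep_keys = peptides["peptide_key"].to_numpy()
    pep_prot = peptides["all_proteins"].to_numpy()
    pep_pattern = peptides["pattern"].to_numpy()
    pep_mz = peptides["true_mz"].to_numpy()
    pep_rt = peptides["base_rt"].to_numpy()
    pep_w = peptides["width"].to_numpy()
    pep_area = peptides["base_area"].to_numpy()
    prot_index = {p: i for i, p in enumerate(protein_ids)}

    for row in design.itertuples(index=False):
        gname = row.group_id
        fc_col = fc.get(gname)  # None for QC
        profile = np.zeros((n_pep, grid.size))
        mz_obs = np.empty(n_pep)
        area_obs = np.empty(n_pep)
        apex_obs = np.empty(n_pep)

        for p in range(n_pep):
            fold = 1.0 if fc_col is None else float(fc_col[prot_index[pep_prot[p].split(";")[0]]])
            area = pep_area[p] * fold * bio[row.sample_id]
            if noise_sigma > 0:
                area *= float(rng.lognormal(-0.5 * noise_sigma**2, noise_sigma))
            pattern = pep_pattern[p]
            shift = float(rng.normal(0.0, jitter_scale[pattern] * config.rt_jitter_sd))
            apex = pep_rt[p] + shift
            vi_comp = None
            if pattern == "vi":
                # indistinct elution: few sparse blobs, redrawn every injection
                k = int(rng.integers(2, 4))
                centers = apex + rng.uniform(-6.0, 6.0, size=k)
                sigmas = pep_w[p] * rng.uniform(1.5, 3.0, size=k)
                fracs = rng.dirichlet(np.ones(k))
                vi_comp = list(zip(fracs.tolist(), centers.tolist(), sigmas.tolist()))
                apex = float(centers[int(np.argmax(fracs))])
            mz_obs[p] = pep_mz[p] + float(rng.normal(0.0, config.mz_jitter_sd))
            area_obs[p] = area
            apex_obs[p] = apex
            profile[p] = elution_profile(
                pattern,
                area,
                pep_rt[p] + shift,
                pep_w[p],
                grid,
                satellite_fraction=config.satellite_fraction,
                satellite_offset=config.satellite_offset,
                vi_components=vi_comp,
            )

        # assemble MS1 scans (peaks sorted by m/z within each scan)
        scans = []
        for j in range(grid.size):
            mask = profile[:, j] > config.emit_threshold
            idx = np.nonzero(mask)[0]
            if idx.size:
                order = np.argsort(mz_obs[idx], kind="stable")
                sel = idx[order]
                inten = profile[sel, j]
                if config.baseline_level > 0:
                    inten = inten + config.baseline_level
                scans.append(MS1Scan(j + 1, float(grid[j]), mz_obs[sel], inten))
            else:
                scans.append(MS1Scan(j + 1, float(grid[j]), np.empty(0), np.empty(0)))
        runs.append(MSRun(row.run_id, scans, {"mode": config.instrument_mode}))

        # MS/MS identification events
        ev_num = 100000
        for p in range(n_pep):
            apex_rows.append(
                {
                    "peptide_key": pep_keys[p],
                    "run_id": row.run_id,
                    "apex_rt": apex_obs[p],
                    "true_area": area_obs[p],
                }
            )
            if rng.random() >= config.id_prob_model.prob(area_obs[p]):
                continue
            times = sample_msms_events(
                grid,
                profile[p],
                config.dynamic_exclusion_window,
                rng,
                config.trigger_threshold,
                config.select_prob,
            )
            if not times:
                continue
            key = pep_keys[p]
            prot_str = pep_prot[p]
            if config.misid_fraction > 0 and rng.random() < config.misid_fraction:
                misid_counter += 1
                key = f"MIS{misid_counter:05d}.2"
                prot_str = f"XMIS{misid_counter:05d}"
                misid_rows.append(
                    {
                        "peptide_key": key,
                        "protein_id": prot_str,
                        "all_proteins": prot_str,
                        "pattern": pep_pattern[p],
                        "true_mz": pep_mz[p],
                        "base_rt": pep_rt[p],
                        "width": pep_w[p],
                        "base_area": pep_area[p],
                        "shared": False,
                        "misid": True,
                    }
                )
            for t in times:
                ev_num += 1
                events.append(
                    IdentificationEvent(
                        run_id=row.run_id,
                        scan_number=ev_num,
                        scan_time=float(t + 0.5 * config.cycle_time),
                        precursor_mz=float(mz_obs[p]),
                        charge=2,
                        peptide_key=key,
                        protein_ids=tuple(prot_str.split(";")),
                        confidence=float(rng.uniform(*config.confidence_range)),
                    )
                )

    if misid_rows:
        peptides = pd.concat([peptides, pd.DataFrame(misid_rows)], ignore_index=True)
    truth = GroundTruth(peptides=peptides, proteins=proteins, apex=pd.DataFrame(apex_rows))
    return runs, events, design, truth


# ---------------------------------------------------------------------------
# direct protein-matrix simulation (for statistics-level checks)
# ---------------------------------------------------------------------------


def simulate_protein_matrix(
    n_proteins: int,
    n_per_group: int,
    fold_change: float = 1.0,
    n_changed: int = 0,
    noise_cv: float = 0.1,
    seed: int = 0,
    base_log10_mean: float = 6.0,
    base_log10_sd: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate a protein abundance matrix for two groups directly.

    Bypasses the chromatographic layer: each protein gets a lognormal base
    abundance, ``n_changed`` proteins get ``fold_change`` applied in group B,
    and every cell carries multiplicative lognormal noise of CV ``noise_cv``.
    Returns (abundances, design table, changed protein ids).
    """
    rng = np.random.default_rng(seed)
    prot = [f"PROT{i + 1:05d}" for i in range(n_proteins)]
    base = 10 ** rng.normal(base_log10_mean, base_log10_sd, size=n_proteins)
    changed = sorted(rng.choice(n_proteins, size=n_changed, replace=False).tolist())
    fc = np.ones(n_proteins)
    fc[changed] = fold_change
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0

    cols = {}
    design_rows = []
    for gname, gfc in (("A", np.ones(n_proteins)), ("B", fc)):
        for r in range(1, n_per_group + 1):
            run = f"{gname}_s{r}_r1"
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n_proteins) if sigma > 0 else 1.0
            cols[run] = base * gfc * noise
            design_rows.append((run, f"{gname}_s{r}", gname, "experimental"))
    abundances = pd.DataFrame(cols, index=pd.Index(prot, name="protein_id"))
    design = pd.DataFrame(design_rows, columns=["run_id", "sample_id", "group_id", "replicate_role"])
    return abundances, design, [prot[i] for i in changed]
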