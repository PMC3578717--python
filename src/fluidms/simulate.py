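"""Synthetic forensic-sample simulator: spectra plus ground truth.

Samples are described compositionally (proportions of matrix profiles, a
dilution factor, a spectrum budget, a noise model) and rendered into MGF
peak lists by: (1) drawing a source — a composed matrix weighted by
proportion x protein richness / dilution, fabric keratin, foreign shuffled
protein, or blank —, (2) drawing a protein by profile abundance and one of
its tryptic peptides by a length-window detectability weight, (3) emitting
the singly charged b/y ladder with m/z jitter and spurious peaks.
Precursors are restricted to the MS selection window (450-1650 m/z) and
fragments to the MS/MS acquisition range (50-2300 m/z); dynamic exclusion
is emulated as at most one spectrum per distinct modified peptide.

Protein-poor matrices (saliva, vaginal fluid) carry a small richness yield,
so at low proportion inside a protein-rich matrix (blood, semen) their
spectra are rarely drawn — the masking effect seen in mixed casework
samples emerges from this asymmetry rather than being scripted.

Abundance profiles are synthetic and live in an editable config
(``data/matrix_profiles.yaml``); nothing downstream depends on their
absolute values, only on the high/low richness ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .digest import (
    METHYLTHIO,
    DigestConfig,
    Peptide,
    digest_protein,
    enumerate_modified_forms,
    mz,
)
from .errors import ConfigError, InputError
from .panel import MarkerPanel, ProteinRecord
from .scoring import SpectrumRecord, theoretical_fragments

PRECURSOR_WINDOW = (450.0, 1650.0)
MSMS_RANGE = (50.0, 2300.0)
DETECTABLE_LENGTH = (7, 25)

TRUTH_COLUMNS = ("spectrum_id", "matrix", "accession", "peptide", "charge")


@dataclass(frozen=True)
class NoiseModel:
    fragment_jitter_sd: float = 0.02  # Da, on every emitted peak
    spurious_rate: float = 0.2  # spurious peaks per true peak (Poisson)
    foreign_fraction: float = 0.02  # weight of out-of-database shuffled protein
    keratin_level: float = 0.02  # weight of fabric keratin contamination


@dataclass(frozen=True)
class MatrixProfile:
    name: str
    matrix: str
    abundances: Mapping[str, float]
    richness: str  # high | low

    def __post_init__(self):
        if not self.abundances or not any(v > 0 for v in self.abundances.values()):
            raise ConfigError(f"profile {self.name!r}: needs a positive abundance")
        if any(v < 0 for v in self.abundances.values()):
            raise ConfigError(f"profile {self.name!r}: negative abundance")
        if self.richness not in ("high", "low"):
            raise ConfigError(f"profile {self.name!r}: richness must be high|low")


@dataclass(frozen=True)
class SampleSpec:
    composition: Mapping[str, float]  # profile name -> proportion (sum <= 1)
    dilution_factor: float = 1.0
    spectrum_budget: int = 400
    seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    dynamic_exclusion: bool = True

    def __post_init__(self):
        if any(v < 0 for v in self.composition.values()):
            raise ConfigError("composition proportions must be >= 0")
        if sum(self.composition.values()) > 1 + 1e-9:
            raise ConfigError("composition proportions must sum to <= 1")
        if self.dilution_factor < 1:
            raise ConfigError("dilution_factor must be >= 1")
        if self.spectrum_budget < 0:
            raise ConfigError("spectrum_budget must be >= 0")


def load_profiles() -> tuple[dict[str, MatrixProfile], dict[str, float]]:
    """Bundled profiles and the richness -> yield mapping."""
    path = Path(resources.files("fluidms") / "data" / "matrix_profiles.yaml")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    profiles = {
        name: MatrixProfile(name, spec["matrix"], spec["abundances"], spec["richness"])
        for name, spec in cfg["profiles"].items()
    }
    return profiles, dict(cfg["richness_yield"])


def _assign_charge(neutral: float, window: tuple = PRECURSOR_WINDOW) -> int | None:
    for z in (2, 3):
        if window[0] <= mz(neutral, z) <= window[1]:
            return z
    return None


def _detectable_peptides(record: ProteinRecord, digest_config: DigestConfig) -> list[tuple[Peptide, int, float]]:
    """(fixed-modified peptide, charge, weight) for peptides the instrument would pick."""
    out = []
    cfg = replace(digest_config, max_missed_cleavages=min(1, digest_config.max_missed_cleavages))
    for pep in digest_protein(record, cfg):
        if not (DETECTABLE_LENGTH[0] <= len(pep.sequence) <= DETECTABLE_LENGTH[1]):
            continue
        form = enumerate_modified_forms(pep, (METHYLTHIO,), cap=0)[0]
        z = _assign_charge(form.neutral_mass)
        if z is None:
            continue
        out.append((form, z, float(len(form.sequence))))
    return out


def _shuffled_records(panel: MarkerPanel, rng: np.random.Generator, n: int = 3) -> list[ProteinRecord]:
    """Out-of-database 'dirt' proteins: shuffles of marker sequences."""
    sources = sorted(panel.marker_records(), key=lambda r: r.accession)[:n]
    out = []
    for i, rec in enumerate(sources):
        seq = list(rec.sequence)
        rng.shuffle(seq)
        out.append(
            ProteinRecord(
                accession=f"DIRT{i}_SHUFFLE",
                name="shuffled dirt protein",
                species="",
                sequence="".join(seq),
                role="background",
            )
        )
    return out


def simulate_sample(
    spec: SampleSpec,
    panel: MarkerPanel,
    digest_config: DigestConfig | None = None,
    profiles: Mapping[str, MatrixProfile] | None = None,
    richness_yield: Mapping[str, float] | None = None,
) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """Render a sample spec into spectra and a per-spectrum ground-truth table."""
    digest_config = digest_config or DigestConfig()
    if profiles is None or richness_yield is None:
        bundled, yields = load_profiles()
        profiles = profiles or bundled
        richness_yield = richness_yield or yields
    unknown = set(spec.composition) - set(profiles)
    if unknown:
        raise InputError(f"composition names unknown profiles: {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)

    # source categories and weights
    sources: list[tuple[str, float, str, list[ProteinRecord], dict]] = []
    for name, prop in sorted(spec.composition.items()):
        prof = profiles[name]
        weight = prop * richness_yield[prof.richness] / spec.dilution_factor
        recs = [panel.records[a] for a in sorted(prof.abundances)]
        sources.append((name, weight, prof.matrix, recs, dict(prof.abundances)))
    contaminants = sorted(
        (r for r in panel.records.values() if r.role == "contaminant"),
        key=lambda r: r.accession,
    )
    if contaminants and spec.noise.keratin_level > 0:
        sources.append(
            ("keratin", spec.noise.keratin_level, "background", contaminants,
             {r.accession: 1.0 for r in contaminants})
        )
    if spec.noise.foreign_fraction > 0:
        foreign = _shuffled_records(panel, rng)
        sources.append(
            ("foreign", spec.noise.foreign_fraction, "background", foreign,
             {r.accession: 1.0 for r in foreign})
        )

    names = [s[0] for s in sources] + ["blank"]
    weights = np.array([s[1] for s in sources] + [1.0])
    weights = weights / weights.sum()
    by_name = {s[0]: s for s in sources}

    pools: dict[str, list] = {}  # accession -> detectable peptides
    spectra: list[SpectrumRecord] = []
    truth_rows: list[tuple] = []
    excluded: set = set()

    for attempt in range(spec.spectrum_budget):
        source = str(rng.choice(names, p=weights))
        if source == "blank":
            continue
        _name, _w, matrix, recs, abund = by_name[source]
        pvec = np.array([abund[r.accession] for r in recs], dtype=float)
        rec = recs[int(rng.choice(len(recs), p=pvec / pvec.sum()))]
        if rec.accession not in pools:
            pools[rec.accession] = _detectable_peptides(rec, digest_config)
        pool = pools[rec.accession]
        if not pool:
            continue
        wvec = np.array([w for _p, _z, w in pool])
        pep, z, _w2 = pool[int(rng.choice(len(pool), p=wvec / wvec.sum()))]
        key = (pep.sequence, pep.modifications)
        if spec.dynamic_exclusion and key in excluded:
            continue
        excluded.add(key)

        theo = theoretical_fragments(pep)
        frags = theo + rng.normal(0.0, spec.noise.fragment_jitter_sd, len(theo))
        frags = frags[(frags >= MSMS_RANGE[0]) & (frags <= MSMS_RANGE[1])]
        n_spurious = int(rng.poisson(spec.noise.spurious_rate * len(frags)))
        spurious = rng.uniform(MSMS_RANGE[0], MSMS_RANGE[1], n_spurious)
        peaks = np.concatenate([frags, spurious])
        inten = np.concatenate(
            [rng.uniform(100.0, 500.0, len(frags)), rng.uniform(20.0, 80.0, n_spurious)]
        )
        order = np.argsort(peaks)
        precursor = mz(pep.neutral_mass, z) + rng.normal(0.0, spec.noise.fragment_jitter_sd / z)

        spectrum_id = f"scan={len(spectra):05d}"
        spectra.append(
            SpectrumRecord(
                spectrum_id=spectrum_id,
                precursor_mz=float(precursor),
                charge=z,
                fragments=peaks[order],
                intensities=inten[order],
                acquisition_range=MSMS_RANGE,
            )
        )
        truth_rows.append((spectrum_id, matrix, rec.accession, pep.sequence, z))

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return spectra, truth


def simulate_null_spectra(
    candidate_masses: Sequence[float],
    n: int,
    seed: int,
    mean_peaks: float = 30.0,
    precursor_tol: float = 0.35,
    msms_range: tuple = MSMS_RANGE,
) -> list[SpectrumRecord]:
    """Spectra with uniformly random peaks, for scorer null-calibration.

    Precursors are placed within tolerance of random candidate masses so
    that searches produce candidates, while the peak lists carry no signal:
    exactly the uniform null the binomial score model assumes.  Searching
    these against any index must yield (super)uniform rank-1 p-values.
    """
    rng = np.random.default_rng(seed)
    masses = np.asarray(candidate_masses, dtype=float)
    out = []
    for i in range(n):
        m = float(rng.choice(masses)) + rng.uniform(-precursor_tol * 0.9, precursor_tol * 0.9)
        z = int(rng.choice([2, 3]))
        n_peaks = max(5, int(rng.poisson(mean_peaks)))
        peaks = np.sort(rng.uniform(msms_range[0], msms_range[1], n_peaks))
        out.append(
            SpectrumRecord(
                spectrum_id=f"null={i:05d}",
                precursor_mz=(m + z * 1.00727646688) / z,
                charge=z,
                fragments=peaks,
                acquisition_range=msms_range,
            )
        )
    return out


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def _called(report, matrix: str) -> bool:
    return matrix in {c.matrix for c in report.matrix_calls if c.tier != "none"}


def simulate_dilution_series(
    profile_name: str,
    factors: Sequence[float],
    replicates: int,
    seed: int,
    panel: MarkerPanel | None = None,
    spectrum_budget: int = 300,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Detection table over a dilution grid (full simulate->classify runs)."""
    from .panel import default_panel
    from .pipeline import RunConfig, analyze_spectra

    if replicates < 1 or any(f < 1 for f in factors):
        raise InputError("factors must be >= 1 and replicates >= 1")
    panel = panel or default_panel()
    profiles, yields = load_profiles()
    matrix = profiles[profile_name].matrix
    rows = []
    run = 0
    for factor in factors:
        for rep in range(replicates):
            spec = SampleSpec(
                {profile_name: 1.0},
                dilution_factor=factor,
                spectrum_budget=spectrum_budget,
                seed=_child_seed(seed, run),
                noise=noise or NoiseModel(),
            )
            run += 1
            spectra, _truth = simulate_sample(spec, panel, profiles=profiles, richness_yield=yields)
            report = analyze_spectra(spectra, panel, RunConfig(sample_id=f"dil{factor}:{rep}"))
            rows.append((factor, rep, _called(report, matrix)))
    return pd.DataFrame(rows, columns=["factor", "replicate", "detected"])


def simulate_mixture_grid(
    profile_a: str,
    profile_b: str,
    proportions: Sequence[float],
    seed: int,
    panel: MarkerPanel | None = None,
    spectrum_budget: int = 300,
    noise: NoiseModel | None = None,
) -> pd.DataFrame:
    """Per-proportion calls for two-matrix mixtures (proportion = share of a)."""
    from .panel import default_panel
    from .pipeline import RunConfig, analyze_spectra

    if profile_a == profile_b:
        raise InputError("mixture grid needs two distinct profiles")
    panel = panel or default_panel()
    profiles, yields = load_profiles()
    matrix_a, matrix_b = profiles[profile_a].matrix, profiles[profile_b].matrix
    rows = []
    for i, prop in enumerate(proportions):
        comp = {}
        if prop > 0:
            comp[profile_a] = float(prop)
        if prop < 1:
            comp[profile_b] = float(1 - prop)
        spec = SampleSpec(
            comp,
            spectrum_budget=spectrum_budget,
            seed=_child_seed(seed, i),
            noise=noise or NoiseModel(),
        )
        spectra, _truth = simulate_sample(spec, panel, profiles=profiles, richness_yield=yields)
        report = analyze_spectra(spectra, panel, RunConfig(sample_id=f"mix{prop}"))
        rows.append((prop, _called(report, matrix_a), _called(report, matrix_b)))
    return pd.DataFrame(rows, columns=["proportion_a", "called_a", "called_b"])
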