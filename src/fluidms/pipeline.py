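"""Full identification pipeline: digest -> index -> search -> infer -> classify."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .classify import (
    ABSENCE_CAVEAT,
    SampleReport,
    call_species,
    classify,
)
from .digest import DEFAULT_MODS, DigestConfig, build_peptide_index
from .errors import InputError
from .inference import InferenceConfig, infer_proteins
from .panel import MarkerPanel, default_panel
from .scoring import SearchConfig, SpectrumRecord, search_spectrum

log = logging.getLogger("fluidms")


@dataclass
class RunConfig:
    input_mgf: str | Path | None = None
    panel_path: str | Path | None = None  # None -> bundled default panel
    digest: DigestConfig = field(default_factory=DigestConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    sample_id: str = "sample"
    seed: int | None = None
    variable_mod_cap: int = 2

    def fingerprint(self) -> dict:
        return {
            "enzyme_mode": self.digest.enzyme_mode,
            "max_missed_cleavages": self.digest.max_missed_cleavages,
            "precursor_tol": self.search.precursor_tol,
            "fragment_tol": self.search.fragment_tol,
            "score_threshold": self.search.score_threshold,
            "p_threshold": self.search.p_threshold,
            "discovery_p_threshold": self.search.discovery_p_threshold,
            "mode": self.inference.mode,
            "seed": self.seed,
        }


def shared_index(panel: MarkerPanel, digest_config: DigestConfig, cap: int = 2):
    """Peptide index over all panel records, cached per panel instance."""
    cache = getattr(panel, "_index_cache", None)
    if cache is None:
        cache = {}
        panel._index_cache = cache
    key = (digest_config, cap)
    if key not in cache:
        cache[key] = build_peptide_index(
            panel.records.values(), digest_config, DEFAULT_MODS, cap=cap
        )
    return cache[key]


def analyze_spectra(
    spectra: Sequence[SpectrumRecord],
    panel: MarkerPanel,
    config: RunConfig | None = None,
) -> SampleReport:
    """Identify biological matrices in a set of MS/MS spectra."""
    config = config or RunConfig()
    index = shared_index(panel, config.digest, config.variable_mod_cap)
    log.info("indexed %d peptide forms from %d records", len(index), len(panel.records))

    psms = []
    for spectrum in spectra:
        psms.extend(search_spectrum(spectrum, index, config.search))
    log.info("searched %d spectra -> %d candidate PSMs", len(spectra), len(psms))

    species_map = {acc: rec.species for acc, rec in panel.records.items()}
    if psms:
        hits, sub = infer_proteins(
            psms, index.membership, config.inference, config.search, species_map
        )
    else:
        hits, sub = [], []
    log.info("retained %d protein hits (%d sub-threshold PSMs)", len(hits), len(sub))

    calls = classify(
        hits, panel, subthreshold_psms=sub, membership=index.membership,
        digest_config=config.digest,
    )
    species_calls = call_species(hits, panel, config.digest)
    fingerprint = dict(config.fingerprint(), panel_version=panel.version)
    return SampleReport(
        sample_id=config.sample_id,
        matrix_calls=calls,
        species_calls=species_calls,
        protein_table=hits,
        config_fingerprint=fingerprint,
        caveats=[ABSENCE_CAVEAT],
    )


def run_pipeline(config: RunConfig) -> SampleReport:
    """End-to-end run from an MGF file; 'no matrix found' is a success."""
    from .io import read_mgf  # local import keeps module load light

    if config.input_mgf is None:
        raise InputError("run_pipeline requires an input MGF path")
    panel = default_panel() if config.panel_path is None else _load_panel_path(config.panel_path)
    spectra = read_mgf(config.input_mgf)
    return analyze_spectra(spectra, panel, config)


def _load_panel_path(path) -> MarkerPanel:
    from .io import read_fasta
    from .panel import load_panel
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    fasta = cfg.get("fasta")
    if fasta is None:
        raise InputError(f"panel config {path} lacks a 'fasta' entry")
    fasta_path = Path(path).parent / fasta
    return load_panel(cfg, read_fasta(fasta_path))
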