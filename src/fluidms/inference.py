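"""Aggregate PSMs into protein hits and filter homologues (bold-red rule).

A peptide match is *red* when it is the top-ranked match for its spectrum.
Each distinct peptide is *bold* in exactly one protein: the highest-scoring
protein containing it, where provisional protein scores are the per-protein
sums of red PSM scores (one pass, ties broken by accession).  Only proteins
owning at least one bold *and* red match survive — this largely eliminates
homologues with lower coverage, whose peptides are all better explained by
a higher-scoring relative.

A protein's score is the sum of the scores of its assigned peptide matches;
the reported per-protein p-value is that of its best peptide (peptide
p-values do not combine into a protein-level probability).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InputError
from .scoring import PSM, SearchConfig


@dataclass
class ProteinHit:
    """Per-protein summary row: peptide count, summed score, best peptide p."""

    accession: str
    species: str = ""
    distinct_peptides: frozenset = frozenset()
    n_peptides: int = 0
    protein_score: float = 0.0
    best_peptide_p: float = 1.0
    has_bold_red: bool = False

    def __post_init__(self):
        self.distinct_peptides = frozenset(self.distinct_peptides)
        if self.distinct_peptides and self.n_peptides == 0:
            self.n_peptides = len(self.distinct_peptides)


@dataclass(frozen=True)
class InferenceConfig:
    mode: str = "standard"  # standard | discovery
    min_peptides_per_protein: int = 1

    def __post_init__(self):
        if self.mode not in ("standard", "discovery"):
            raise InputError(f"unknown inference mode {self.mode!r}")


@dataclass
class ThresholdedPSMs:
    accepted: list
    subthreshold: list


def flag_red(psms: Sequence[PSM]) -> list[PSM]:
    """Mark exactly the rank-1 PSM of each spectrum as red."""
    by_spectrum: dict[str, list[PSM]] = defaultdict(list)
    for m in psms:
        by_spectrum[m.spectrum_id].append(m)
    for spectrum_id, group in by_spectrum.items():
        top = [m for m in group if m.rank == 1]
        if len(top) != 1:
            raise InputError(
                f"spectrum {spectrum_id}: expected exactly one rank-1 PSM, found {len(top)}"
            )
        for m in group:
            m.red = m.rank == 1
    return list(psms)


def flag_bold(psms: Sequence[PSM], membership: Mapping[str, frozenset]) -> list[PSM]:
    """Assign each distinct peptide to its top-scoring containing protein.

    Provisional protein scores sum red PSM scores over every protein
    containing the peptide; proteins are ordered by descending provisional
    score, ties by ascending accession, and each peptide's PSMs become bold
    in (and are attributed to) the first protein of that order containing
    the peptide.
    """
    provisional: dict[str, float] = defaultdict(float)
    for m in psms:
        seq = m.peptide_sequence
        if seq not in membership or not membership[seq]:
            raise InputError(f"peptide {seq!r} is contained in no protein")
        if m.red:
            for acc in membership[seq]:
                provisional[acc] += m.score
    order = {
        acc: i
        for i, acc in enumerate(sorted(provisional, key=lambda a: (-provisional[a], a)))
    }
    for m in psms:
        parents = membership[m.peptide_sequence]
        ranked = sorted(parents, key=lambda a: (order.get(a, len(order)), a))
        m.assigned_protein = ranked[0] if ranked else None
        m.bold = m.assigned_protein is not None
    return list(psms)


def apply_thresholds(
    psms: Sequence[PSM],
    config: InferenceConfig = InferenceConfig(),
    search_config: SearchConfig = SearchConfig(),
) -> ThresholdedPSMs:
    """Split PSMs into accepted and sub-threshold pools (inclusive bounds).

    Standard mode accepts p <= 0.05 and score >= 41; discovery mode
    additionally requires p <= 0.01.  Sub-threshold matches are retained —
    they may later corroborate a confirmed matrix call but never create one.
    """
    p_cut = search_config.p_threshold
    if config.mode == "discovery":
        p_cut = min(p_cut, search_config.discovery_p_threshold)
    accepted, sub = [], []
    for m in psms:
        ok = m.p_value <= p_cut and m.score >= search_config.score_threshold
        (accepted if ok else sub).append(m)
    return ThresholdedPSMs(accepted, sub)


def summarize(
    psms: Sequence[PSM],
    membership: Mapping[str, frozenset],
    config: InferenceConfig = InferenceConfig(),
    species: Mapping[str, str] | None = None,
) -> list[ProteinHit]:
    """One hit per protein owning assigned red peptide matches, sorted by score.

    Only red matches (each spectrum's top match) contribute evidence, so a
    spectrum is never counted twice through its lower-ranked candidates.
    """
    hits: dict[str, ProteinHit] = {}
    for m in psms:
        acc = m.assigned_protein
        if acc is None or not m.red:
            continue
        hit = hits.get(acc)
        if hit is None:
            hit = hits[acc] = ProteinHit(acc, species=(species or {}).get(acc, ""))
        hit.distinct_peptides = hit.distinct_peptides | {m.peptide_sequence}
        hit.protein_score += m.score
        hit.best_peptide_p = min(hit.best_peptide_p, m.p_value)
        hit.has_bold_red = hit.has_bold_red or (m.bold and m.red)
    for hit in hits.values():
        hit.n_peptides = len(hit.distinct_peptides)
    out = [h for h in hits.values() if h.n_peptides >= config.min_peptides_per_protein]
    out.sort(key=lambda h: (-h.protein_score, h.accession))
    return out


def filter_bold_red(protein_hits: Iterable[ProteinHit]) -> list[ProteinHit]:
    """Retain exactly the proteins with at least one bold-red peptide match."""
    return [h for h in protein_hits if h.has_bold_red]


def infer_proteins(
    psms: Sequence[PSM],
    membership: Mapping[str, frozenset],
    config: InferenceConfig = InferenceConfig(),
    search_config: SearchConfig = SearchConfig(),
    species: Mapping[str, str] | None = None,
) -> tuple[list[ProteinHit], list[PSM]]:
    """Full chain red -> thresholds -> bold -> summarize -> bold-red filter.

    Returns the retained protein hits and the sub-threshold PSM pool.
    """
    flag_red(psms)
    pools = apply_thresholds(psms, config, search_config)
    if pools.accepted:
        flag_bold(pools.accepted, membership)
    hits = filter_bold_red(summarize(pools.accepted, membership, config, species))
    return hits, pools.subthreshold
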