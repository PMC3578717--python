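"""In-silico proteolysis and peptide mass computation.

Trypsin cleaves C-terminal to K or R; by convention (Keil rule) not when the
next residue is proline.  Peptides retaining internal cleavage sites are
"missed cleavage" products.  Semitryptic peptides keep exactly one
enzymatically consistent terminus (protein termini count as enzymatic) and
arise from in-source or biological truncation; they matter for dilute,
partially degraded matrices such as urine and feces.

All masses are monoisotopic.  Residue masses come from pyteomics'
standard table; modification deltas are fixed constants of the supported
chemistry: methylthio on cysteine (the MMTS alkylation of the digest
protocol, fixed), oxidation of methionine and deamidation of Asn/Gln
(common variable modifications).
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as _pmass

from .errors import ConfigError, InputError

RESIDUE_MASS: Mapping[str, float] = dict(_pmass.std_aa_mass)
WATER = 18.0105646863
PROTON = 1.00727646688

CANONICAL = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ModificationSpec:
    """A mass modification targeting a set of residues.

    ``kind`` is ``fixed`` (always applied to every matching residue) or
    ``variable`` (enumerated combinatorially).  ``max_per_peptide`` caps the
    number of variable sites considered; fixed modifications are uncapped.
    """

    name: str
    residues: frozenset
    delta_mass: float
    kind: str = "variable"
    max_per_peptide: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "residues", frozenset(self.residues))
        if self.kind not in ("fixed", "variable"):
            raise ConfigError(f"modification kind must be fixed|variable, got {self.kind!r}")
        if self.kind == "fixed" and self.max_per_peptide is not None:
            raise ConfigError("fixed modifications take no per-peptide cap")
        if not np.isfinite(self.delta_mass):
            raise ConfigError("modification delta mass must be finite")


METHYLTHIO = ModificationSpec("Methylthio", frozenset("C"), 45.98772, kind="fixed")
OXIDATION = ModificationSpec("Oxidation", frozenset("M"), 15.99491)
DEAMIDATION = ModificationSpec("Deamidation", frozenset("NQ"), 0.98402)

#: the modification set of the supported sample-preparation chemistry
DEFAULT_MODS = (METHYLTHIO, OXIDATION, DEAMIDATION)


@dataclass(frozen=True)
class DigestConfig:
    enzyme_mode: str = "tryptic"  # tryptic | semitryptic
    max_missed_cleavages: int = 2
    proline_rule: bool = True
    min_length: int = 1
    max_length: int = 60

    def __post_init__(self):
        if self.enzyme_mode not in ("tryptic", "semitryptic"):
            raise ConfigError(f"unknown enzyme mode {self.enzyme_mode!r}")
        if not (0 <= self.max_missed_cleavages <= 5):
            raise ConfigError("max_missed_cleavages must be in [0, 5]")
        if self.min_length > self.max_length:
            raise ConfigError("min_length must not exceed max_length")


@dataclass(frozen=True)
class Peptide:
    """A proteolysis product, optionally carrying modifications.

    ``start``/``end`` are 1-based inclusive coordinates in the parent;
    ``modifications`` is a sorted tuple of ``(position, ModificationSpec)``
    with 1-based positions inside the peptide.
    """

    sequence: str
    parent_accessions: frozenset = frozenset()
    start: int = 1
    end: int = 0
    missed_cleavages: int = 0
    modifications: tuple = ()

    def __post_init__(self):
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        object.__setattr__(self, "parent_accessions", frozenset(self.parent_accessions))
        object.__setattr__(
            self, "modifications", tuple(sorted(self.modifications, key=lambda m: (m[0], m[1].name)))
        )

    @property
    def neutral_mass(self) -> float:
        return neutral_mass(self)

    def mod_string(self) -> str:
        """Compact rendering like ``3:Oxidation;5:Deamidation`` ('.' if none)."""
        if not self.modifications:
            return "."
        return ";".join(f"{pos}:{spec.name}" for pos, spec in self.modifications)


def neutral_mass(peptide: Peptide | str) -> float:
    """Monoisotopic neutral mass: residue masses + water + modification deltas."""
    seq = peptide if isinstance(peptide, str) else peptide.sequence
    try:
        m = sum(RESIDUE_MASS[aa] for aa in seq) + WATER
    except KeyError as exc:
        raise InputError(f"unknown residue {exc.args[0]!r} in peptide {seq!r}") from exc
    if not isinstance(peptide, str):
        m += sum(spec.delta_mass for _pos, spec in peptide.modifications)
    return m


def mz(peptide: Peptide | float, charge: int) -> float:
    """m/z of the [M+zH]^z+ ion for a peptide or a raw neutral mass."""
    if charge < 1:
        raise InputError(f"charge must be >= 1, got {charge}")
    m = peptide if isinstance(peptide, (int, float)) else neutral_mass(peptide)
    return (m + charge * PROTON) / charge


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions i such that trypsin cuts between i and i+1."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            sites.append(i)
    return sites


def digest_protein(record, config: DigestConfig = DigestConfig()) -> list[Peptide]:
    """Digest a protein record (or bare sequence) into peptides.

    Tryptic mode emits every product bounded by cleavage sites / protein
    termini with at most ``max_missed_cleavages`` internal sites.
    Semitryptic mode additionally emits every sub-peptide with exactly one
    non-enzymatic terminus.  Output is sorted by (start, end) and respects
    the length bounds.
    """
    if isinstance(record, str):
        sequence, accession = record, ""
    else:
        sequence, accession = record.sequence, record.accession
    if not sequence:
        raise InputError("cannot digest an empty sequence")
    parents = frozenset({accession} if accession else ())

    sites = cleavage_sites(sequence, config.proline_rule)
    # boundaries as 0-based start offsets of segments, plus the sequence end
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    out: list[Peptide] = []
    seen: set[tuple[int, int]] = set()

    def emit(a: int, b: int, missed: int) -> None:
        if (a, b) in seen:
            return
        if not (config.min_length <= b - a <= config.max_length):
            return
        seen.add((a, b))
        out.append(
            Peptide(
                sequence[a:b],
                parent_accessions=parents,
                start=a + 1,
                end=b,
                missed_cleavages=missed,
            )
        )

    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + config.max_missed_cleavages, len(bounds))):
            emit(bounds[i], bounds[j], j - i - 1)

    if config.enzyme_mode == "semitryptic":
        site_set = set(bounds)
        sorted_sites = bounds
        for a in range(len(sequence)):
            for b in range(a + 1, len(sequence) + 1):
                a_enz, b_enz = a in site_set, b in site_set
                if a_enz == b_enz:  # fully tryptic handled above; fully non-tryptic excluded
                    continue
                lo = bisect.bisect_right(sorted_sites, a)
                hi = bisect.bisect_left(sorted_sites, b)
                missed = hi - lo  # enzymatic boundaries strictly inside (a, b)
                if missed <= config.max_missed_cleavages:
                    emit(a, b, missed)

    out.sort(key=lambda p: (p.start, p.end))
    return out


def enumerate_modified_forms(
    peptide: Peptide, mods: Sequence[ModificationSpec], cap: int = 4
) -> list[Peptide]:
    """All modified forms of a peptide under fixed + variable modifications.

    Fixed modifications are applied at every matching residue in every
    output.  Variable modifications are enumerated over matching sites, the
    first ``cap`` sites only (reading order), each site carrying either no
    modification or one of its applicable variable modifications.  The
    unmodified-variable form is always included.
    """
    if cap < 0:
        raise ConfigError("variable-site cap must be >= 0")
    fixed = [(i + 1, spec) for i, aa in enumerate(peptide.sequence)
             for spec in mods if spec.kind == "fixed" and aa in spec.residues]
    var_sites: list[tuple[int, list[ModificationSpec]]] = []
    for i, aa in enumerate(peptide.sequence):
        applicable = [spec for spec in mods if spec.kind == "variable" and aa in spec.residues]
        if applicable:
            var_sites.append((i + 1, applicable))
    var_sites = var_sites[:cap]

    forms: list[Peptide] = []
    choice_lists = [[None, *specs] for _pos, specs in var_sites]
    for combo in itertools.product(*choice_lists) if choice_lists else [()]:
        variable = [
            (pos, spec)
            for (pos, _specs), spec in zip(var_sites, combo)
            if spec is not None
        ]
        forms.append(
            Peptide(
                peptide.sequence,
                parent_accessions=peptide.parent_accessions,
                start=peptide.start,
                end=peptide.end,
                missed_cleavages=peptide.missed_cleavages,
                modifications=tuple(fixed) + tuple(variable),
            )
        )
    return forms


class PeptideIndex:
    """Mass-ordered index of modified peptide forms supporting tolerance queries."""

    def __init__(self, peptides: Iterable[Peptide]):
        merged: dict[tuple, Peptide] = {}
        for p in peptides:
            key = (p.sequence, tuple((pos, spec.name) for pos, spec in p.modifications))
            if key in merged:
                q = merged[key]
                merged[key] = Peptide(
                    q.sequence,
                    parent_accessions=q.parent_accessions | p.parent_accessions,
                    start=q.start,
                    end=q.end,
                    missed_cleavages=q.missed_cleavages,
                    modifications=q.modifications,
                )
            else:
                merged[key] = p
        self.peptides = sorted(merged.values(), key=lambda p: p.neutral_mass)
        self._masses = np.array([p.neutral_mass for p in self.peptides])

    def __len__(self) -> int:
        return len(self.peptides)

    def query(self, m: float, tol: float) -> list[Peptide]:
        lo = int(np.searchsorted(self._masses, m - tol, side="left"))
        hi = int(np.searchsorted(self._masses, m + tol, side="right"))
        return self.peptides[lo:hi]

    @property
    def membership(self) -> dict[str, frozenset]:
        """Mapping peptide sequence -> parent accessions (all modified forms merged)."""
        out: dict[str, set] = {}
        for p in self.peptides:
            out.setdefault(p.sequence, set()).update(p.parent_accessions)
        return {seq: frozenset(accs) for seq, accs in out.items()}


def build_peptide_index(
    records: Iterable,
    config: DigestConfig = DigestConfig(),
    mods: Sequence[ModificationSpec] = DEFAULT_MODS,
    cap: int = 2,
) -> PeptideIndex:
    """Digest all records and index every modified form by neutral mass."""
    records = list(records)
    if not records:
        raise InputError("cannot build an index from zero records")
    forms: list[Peptide] = []
    for rec in records:
        for pep in digest_protein(rec, config):
            forms.extend(enumerate_modified_forms(pep, mods, cap=cap))
    return PeptideIndex(forms)
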