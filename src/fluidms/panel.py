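"""Marker panel: protein records, per-matrix rules, discriminating peptides.

The panel encodes the biomarker decision logic for seven biological
matrices.  Most rules are *specific_sufficient*: observing any listed marker
identifies the matrix.  Urine and feces are *conditional*: their markers
(uromodulin/AMBP, immunoglobulins/albumin) also occur in blood serum, so
they only indicate the matrix when no hemoglobin is seen — and because some
genuine urine/feces samples yield no detectable protein at all, absence of
these markers never excludes the matrix.

Isoform/ortholog groups (salivary vs non-salivary alpha-amylase; hemoglobin
orthologs of human, bovine and canine blood) are resolved through
*discriminating peptides*: tryptic peptides unique to one group member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .digest import CANONICAL, DigestConfig, digest_protein
from .errors import ConfigError

MATRICES = ("blood", "semen", "vaginal_fluid", "saliva", "nasal_secretion", "urine", "feces")
ROLES = ("marker", "background", "contaminant")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    name: str = ""
    gene: str = ""
    species: str = ""
    sequence: str = ""
    role: str = "marker"

    def __post_init__(self):
        if not self.sequence:
            raise ConfigError(f"record {self.accession!r} has an empty sequence")
        bad = set(self.sequence) - CANONICAL
        if bad:
            raise ConfigError(
                f"record {self.accession!r} contains non-canonical residues {sorted(bad)}"
            )
        if self.role not in ROLES:
            raise ConfigError(f"record {self.accession!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class MarkerRule:
    """Decision rule for one biological matrix."""

    matrix: str
    marker_accessions: frozenset
    sufficiency: str = "specific_sufficient"  # specific_sufficient | conditional
    required_absent: frozenset = frozenset()
    absence_excludes: bool = True
    species_resolvable: bool = False
    #: markers whose specificity is too low to confirm the matrix on their own
    nonspecific: bool = False
    #: accessions usable only as extra support, never triggering the rule
    support_accessions: frozenset = frozenset()
    #: isoform group (in MarkerPanel.isoform_groups) that must be resolved by
    #: a marker-unique peptide before the rule fires on peptide-level evidence
    isoform_group: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "marker_accessions", frozenset(self.marker_accessions))
        object.__setattr__(self, "required_absent", frozenset(self.required_absent))
        object.__setattr__(self, "support_accessions", frozenset(self.support_accessions))


@dataclass(frozen=True)
class DiscriminatingPeptideSet:
    """Partition of a protein group's digest into member-unique and shared peptides."""

    group_name: str
    member_peptides: Mapping[str, frozenset]
    shared_peptides: frozenset


@dataclass
class MarkerPanel:
    rules: list = field(default_factory=list)
    records: dict = field(default_factory=dict)  # accession -> ProteinRecord
    isoform_groups: dict = field(default_factory=dict)  # name -> tuple of accessions
    aliases: dict = field(default_factory=dict)  # display alias -> tuple of accessions
    version: str = "default"

    def rule_for(self, matrix: str) -> MarkerRule | None:
        for rule in self.rules:
            if rule.matrix == matrix:
                return rule
        return None

    def marker_records(self) -> list[ProteinRecord]:
        return [r for r in self.records.values() if r.role == "marker"]

    def discriminating_sets(
        self, digest_config: DigestConfig | None = None
    ) -> dict[str, DiscriminatingPeptideSet]:
        """Discriminating peptides per isoform group (cached per digest config)."""
        cfg = digest_config or DigestConfig()
        cache = getattr(self, "_disc_cache", None)
        if cache is None:
            cache = {}
            self._disc_cache = cache
        if cfg not in cache:
            cache[cfg] = {
                name: find_discriminating_peptides([self.records[a] for a in accs], cfg)
                for name, accs in self.isoform_groups.items()
                if len(accs) >= 2
            }
            for name, disc in cache[cfg].items():
                object.__setattr__(disc, "group_name", name)
        return cache[cfg]


def find_discriminating_peptides(
    group: Sequence[ProteinRecord], digest_config: DigestConfig = DigestConfig()
) -> DiscriminatingPeptideSet:
    """Split the group's tryptic peptides into member-unique and shared sets.

    A peptide sequence is unique to a member when it occurs in that member's
    digest and in no other member's; peptides occurring in two or more
    members are shared.  Order of the group is irrelevant.
    """
    if len(group) < 2:
        raise ConfigError("discriminating peptides need at least two group members")
    digests = {
        rec.accession: frozenset(p.sequence for p in digest_protein(rec, digest_config))
        for rec in group
    }
    member: dict[str, frozenset] = {}
    for acc, peps in digests.items():
        others = frozenset().union(*(d for a, d in digests.items() if a != acc))
        member[acc] = peps - others
    counts: dict[str, int] = {}
    for peps in digests.values():
        for seq in peps:
            counts[seq] = counts.get(seq, 0) + 1
    shared = frozenset(seq for seq, n in counts.items() if n >= 2)
    return DiscriminatingPeptideSet("group", member, shared)


def validate_panel(panel: MarkerPanel, digest_config: DigestConfig | None = None) -> list[str]:
    """Diagnostics (empty iff the panel is internally consistent).

    Violations of hard invariants are prefixed ``error:``; soft findings
    (e.g. a species-resolvable group without discriminating peptides) are
    prefixed ``warning:``.
    """
    diags: list[str] = []
    seen_matrices: set[str] = set()
    known = set(panel.records)
    for rule in panel.rules:
        if rule.matrix in seen_matrices:
            diags.append(f"error: duplicate rule for matrix {rule.matrix!r}")
        seen_matrices.add(rule.matrix)
        if rule.matrix not in MATRICES:
            diags.append(f"error: rule {rule.matrix!r}: unknown matrix label")
        if not rule.marker_accessions:
            diags.append(f"error: rule {rule.matrix!r}: empty marker set")
        overlap = rule.marker_accessions & rule.required_absent
        if overlap:
            diags.append(
                f"error: rule {rule.matrix!r}: markers also listed as required_absent: "
                f"{sorted(overlap)}"
            )
        dangling = (rule.marker_accessions | rule.required_absent | rule.support_accessions) - known
        if dangling:
            diags.append(f"error: rule {rule.matrix!r}: unknown accessions {sorted(dangling)}")
        if rule.matrix in ("urine", "feces") and rule.absence_excludes:
            diags.append(
                f"error: rule {rule.matrix!r}: absence_excludes must be false "
                "(marker absence does not exclude this matrix)"
            )
        if rule.isoform_group and rule.isoform_group not in panel.isoform_groups:
            diags.append(f"error: rule {rule.matrix!r}: unknown isoform group {rule.isoform_group!r}")
    for name, accs in panel.isoform_groups.items():
        dangling = set(accs) - known
        if dangling:
            diags.append(f"error: group {name!r}: unknown accessions {sorted(dangling)}")
        elif len(accs) >= 2:
            disc = find_discriminating_peptides(
                [panel.records[a] for a in accs], digest_config or DigestConfig()
            )
            lacking = [a for a in accs if not disc.member_peptides[a]]
            if lacking:
                diags.append(
                    f"warning: group {name!r}: no discriminating peptides for {sorted(lacking)}"
                )
    for alias, accs in panel.aliases.items():
        dangling = set(accs) - known
        if dangling:
            diags.append(f"error: alias {alias!r}: unknown accessions {sorted(dangling)}")
    return diags


# ---------------------------------------------------------------------------
# panel configuration I/O

def _data_path(name: str) -> Path:
    return Path(resources.files("fluidms") / "data" / name)


def load_panel(config, fasta_source) -> MarkerPanel:
    """Build a validated panel from a config mapping/path and protein records.

    ``config`` is a mapping (or a YAML file path) with ``rules``, ``groups``
    and ``aliases`` sections; ``fasta_source`` is an iterable of
    ``ProteinRecord`` (unreferenced entries are retained as background
    context for search).  Raises ``ConfigError`` listing every dangling
    accession, and on duplicate matrix labels.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    records = {rec.accession: rec for rec in fasta_source}

    rules_cfg = config.get("rules") or {}
    if isinstance(rules_cfg, dict):
        items = list(rules_cfg.items())
    else:  # list form: [{"matrix": ..., ...}, ...] — may carry duplicates, caught below
        items = [(spec["matrix"], spec) for spec in rules_cfg]
    rules = []
    for matrix, spec in items:
        rules.append(
            MarkerRule(
                matrix=matrix,
                marker_accessions=frozenset(spec.get("markers", ())),
                sufficiency=spec.get("sufficiency", "specific_sufficient"),
                required_absent=frozenset(spec.get("required_absent", ())),
                absence_excludes=bool(spec.get("absence_excludes", True)),
                species_resolvable=bool(spec.get("species_resolvable", False)),
                nonspecific=bool(spec.get("nonspecific", False)),
                support_accessions=frozenset(spec.get("support", ())),
                isoform_group=spec.get("isoform_group"),
            )
        )
    panel = MarkerPanel(
        rules=rules,
        records=records,
        isoform_groups={k: tuple(v) for k, v in (config.get("groups") or {}).items()},
        aliases={k: tuple(v) for k, v in (config.get("aliases") or {}).items()},
        version=str(config.get("version", "custom")),
    )
    errors = [d for d in validate_panel(panel) if d.startswith("error:")]
    if errors:
        raise ConfigError("invalid panel configuration:\n" + "\n".join(errors))
    return panel


def panel_to_config(panel: MarkerPanel) -> dict:
    cfg: dict = {"version": panel.version, "rules": {}, "groups": {}, "aliases": {}}
    for rule in panel.rules:
        cfg["rules"][rule.matrix] = {
            "markers": sorted(rule.marker_accessions),
            "sufficiency": rule.sufficiency,
            "required_absent": sorted(rule.required_absent),
            "absence_excludes": rule.absence_excludes,
            "species_resolvable": rule.species_resolvable,
            "nonspecific": rule.nonspecific,
            "support": sorted(rule.support_accessions),
            "isoform_group": rule.isoform_group,
        }
    cfg["groups"] = {k: list(v) for k, v in panel.isoform_groups.items()}
    cfg["aliases"] = {k: list(v) for k, v in panel.aliases.items()}
    return cfg


def write_panel(panel: MarkerPanel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(panel_to_config(panel), fh, sort_keys=True)


def default_panel() -> MarkerPanel:
    """The shipped panel over the bundled synthetic marker FASTA."""
    from .io import read_fasta  # late import to avoid a cycle

    fasta = _data_path("markers_synthetic.fasta")
    config = _data_path("default_panel.yaml")
    for p in (fasta, config):
        if not p.exists():
            raise ConfigError(f"bundled panel fixture missing: {p}")
    panel = load_panel(config, read_fasta(fasta))
    panel.version = "default"
    return panel
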