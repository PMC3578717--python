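"""Matrix decision tree, species/isoform resolution, and sample reports.

The classifier maps a table of retained protein hits onto biological-matrix
calls.  Specific markers (hemoglobin, semenogelins, PAP, PSA, cornulin,
cornifins, involucrin, salivary amylase, plunc) are individually
sufficient; urine and feces markers fire only when no hemoglobin was seen,
because those markers also circulate in blood.  Multiple calls per sample
are expected — mixtures are the norm in casework.

Evidence tiers: ``confirmed`` (one above-threshold specific marker),
``corroborated`` (two or more distinct markers of the same matrix),
``suggestive`` (evidence short of an identification: sub-threshold marker
matches attached to an already-confirmed matrix, or non-specific-marker
patterns such as the immunoglobulin/albumin feces indication).

When protein hits carry peptide-level evidence, an amylase hit yields a
saliva call only if a peptide unique to the salivary isoform was observed;
hemoglobin species calls likewise rest on ortholog-discriminating peptides.
Hit tables entered by hand (accession-level only) are taken at face value,
as their isoforms were resolved by whoever produced the table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

from .digest import DigestConfig
from .errors import ConfigError, InputError
from .inference import ProteinHit
from .panel import DiscriminatingPeptideSet, MarkerPanel, validate_panel
from .scoring import PSM

TIERS = ("confirmed", "corroborated", "suggestive", "none")

ABSENCE_CAVEAT = (
    "absence of urine/feces markers does not exclude the presence of those matrices"
)
MENSTRUAL_CAVEAT = (
    "hemoglobin together with cornulin: consistent with menstrual blood "
    "(indistinguishable from a blood + vaginal fluid mixture)"
)
AMYLASE_CAVEAT = (
    "alpha-amylase detected without a salivary-isoform-specific peptide; "
    "saliva not called (amylase 2 occurs in semen and vaginal secretion)"
)
FECES_CAVEAT = (
    "immunoglobulins/albumin without hemoglobin indicate feces but are not "
    "specific; reported as feces-possible"
)


@dataclass
class MatrixCall:
    matrix: str
    tier: str
    supporting_markers: list = field(default_factory=list)  # (acc, n_pep, score, best_p)
    caveats: list = field(default_factory=list)


@dataclass
class SpeciesCall:
    group_name: str
    species: str  # binomial name or "ambiguous"
    observed_discriminating_peptides: frozenset = frozenset()
    n_shared_only: int = 0


@dataclass
class SampleReport:
    sample_id: str
    matrix_calls: list = field(default_factory=list)
    species_calls: list = field(default_factory=list)
    protein_table: list = field(default_factory=list)  # ProteinHit rows
    config_fingerprint: dict = field(default_factory=dict)
    caveats: list = field(default_factory=list)

    def called_matrices(self, tiers: tuple = ("confirmed", "corroborated")) -> set:
        return {c.matrix for c in self.matrix_calls if c.tier in tiers}


def _evidence(hit: ProteinHit) -> tuple:
    return (hit.accession, hit.n_peptides, hit.protein_score, hit.best_peptide_p)


def classify(
    protein_hits: Sequence[ProteinHit],
    panel: MarkerPanel,
    subthreshold_psms: Sequence[PSM] | None = None,
    membership: Mapping[str, frozenset] | None = None,
    digest_config: DigestConfig | None = None,
) -> list[MatrixCall]:
    """Apply every panel rule to the hit table; returns one call per matrix found.

    Empty evidence yields the single call ``none``.  Sub-threshold PSMs, if
    supplied, are attached as suggestive corroboration of confirmed calls
    (they never create a call on their own).
    """
    errors = [d for d in validate_panel(panel) if d.startswith("error:")]
    if errors:
        raise ConfigError("refusing to classify with an invalid panel:\n" + "\n".join(errors))

    hits = {h.accession: h for h in protein_hits}
    # contaminants (e.g. fabric keratins) are listed in reports but never classified
    hits = {
        acc: h
        for acc, h in hits.items()
        if acc not in panel.records or panel.records[acc].role != "contaminant"
    }
    disc = panel.discriminating_sets(digest_config) if panel.isoform_groups else {}

    calls: list[MatrixCall] = []
    for rule in panel.rules:
        found = [hits[a] for a in sorted(rule.marker_accessions) if a in hits]
        if rule.isoform_group:
            found = [h for h in found if _isoform_resolved(h, rule, disc)]
            unresolved = [
                hits[a]
                for a in sorted(rule.marker_accessions)
                if a in hits and hits[a] not in found
            ]
        else:
            unresolved = []
        if not found:
            if unresolved:
                calls.append(
                    MatrixCall(
                        rule.matrix,
                        "suggestive",
                        [_evidence(h) for h in unresolved],
                        [AMYLASE_CAVEAT],
                    )
                )
            continue
        if rule.required_absent and any(a in hits for a in rule.required_absent):
            continue
        tier = "corroborated" if len(found) >= 2 else "confirmed"
        caveats: list[str] = []
        if rule.nonspecific:
            tier = "suggestive"
            caveats.append(FECES_CAVEAT)
        support = [hits[a] for a in sorted(rule.support_accessions) if a in hits]
        calls.append(
            MatrixCall(rule.matrix, tier, [_evidence(h) for h in found + support], caveats)
        )

    # menstrual-blood consistency: hemoglobin together with cornulin
    blood = next((c for c in calls if c.matrix == "blood"), None)
    if blood is not None and any(
        acc in hits and panel.records.get(acc, None) and panel.records[acc].gene == "CRNN"
        for acc in hits
    ):
        blood.caveats.append(MENSTRUAL_CAVEAT)

    if not any(c.tier in ("confirmed", "corroborated", "suggestive") for c in calls):
        calls = [MatrixCall("none", "none", [], [ABSENCE_CAVEAT])]

    if subthreshold_psms:
        calls.extend(
            corroborating_evidence(subthreshold_psms, panel, calls, membership=membership)
        )
    return calls


def _isoform_resolved(hit: ProteinHit, rule, disc: Mapping[str, DiscriminatingPeptideSet]) -> bool:
    """Peptide-level hits must show a marker-unique peptide of the isoform group."""
    if not hit.distinct_peptides:  # accession-level table: already resolved upstream
        return True
    dset = disc.get(rule.isoform_group)
    if dset is None:
        return True
    unique = dset.member_peptides.get(hit.accession, frozenset())
    return bool(hit.distinct_peptides & unique)


def call_species(
    hits_or_psms: Iterable,
    panel: MarkerPanel,
    digest_config: DigestConfig | None = None,
) -> list[SpeciesCall]:
    """Resolve species per multi-species isoform group via discriminating peptides.

    Members with at least one observed member-unique peptide contribute a
    call for their species; unique evidence from several species yields one
    call per species (mixed-species samples are legitimate); shared-peptide
    evidence alone is ambiguous.  Accession-level hits (no peptides) count
    the accession's own species as evidence.
    """
    observed: dict[str, frozenset] = {}
    for item in hits_or_psms:
        if isinstance(item, ProteinHit):
            observed[item.accession] = observed.get(item.accession, frozenset()) | item.distinct_peptides
        elif isinstance(item, PSM):
            for acc in getattr(item.peptide, "parent_accessions", ()) or (
                [item.assigned_protein] if item.assigned_protein else []
            ):
                observed[acc] = observed.get(acc, frozenset()) | {item.peptide_sequence}

    calls: list[SpeciesCall] = []
    disc = panel.discriminating_sets(digest_config)
    for group_name, accs in panel.isoform_groups.items():
        species_of = {a: panel.records[a].species for a in accs}
        if len(set(species_of.values())) < 2:
            continue  # same-species isoform groups carry no species information
        dset = disc[group_name]
        evidence: dict[str, set] = {}
        n_shared = 0
        group_seen = False
        for acc in accs:
            if acc not in observed:
                continue
            group_seen = True
            peps = observed[acc]
            unique = peps & dset.member_peptides[acc]
            n_shared += len(peps & dset.shared_peptides)
            if unique or not peps:  # accession-level evidence: the record implies its species
                evidence.setdefault(species_of[acc], set()).update(unique)
        if not group_seen:
            continue
        if evidence:
            for species in sorted(evidence):
                calls.append(
                    SpeciesCall(group_name, species, frozenset(evidence[species]), n_shared)
                )
        else:
            calls.append(SpeciesCall(group_name, "ambiguous", frozenset(), n_shared))
    return calls


def corroborating_evidence(
    subthreshold_psms: Sequence[PSM],
    panel: MarkerPanel,
    confirmed_calls: Sequence[MatrixCall],
    membership: Mapping[str, frozenset] | None = None,
) -> list[MatrixCall]:
    """Suggestive annotations from sub-threshold marker matches.

    A sub-threshold match of a marker whose matrix already carries a
    confirmed/corroborated call is attached as a suggestive annotation; on
    its own it never creates a call.  Only informative top-of-spectrum
    matches qualify (red, positive score), and markers already supporting
    the call are not re-annotated.
    """
    confirmed = {c.matrix for c in confirmed_calls if c.tier in ("confirmed", "corroborated")}
    already = {
        (c.matrix, acc)
        for c in confirmed_calls
        if c.tier in ("confirmed", "corroborated")
        for acc, *_rest in c.supporting_markers
    }
    best: dict[tuple, PSM] = {}
    for m in subthreshold_psms:
        if not m.red or m.score <= 0:
            continue
        seq = m.peptide_sequence
        parents = set(getattr(m.peptide, "parent_accessions", ()) or ())
        if not parents and membership is not None:
            parents = set(membership.get(seq, ()))
        if not parents and m.assigned_protein:
            parents = {m.assigned_protein}
        for acc in parents:
            for rule in panel.rules:
                if acc in rule.marker_accessions and rule.matrix in confirmed:
                    key = (rule.matrix, acc)
                    if key in already:
                        continue
                    if key not in best or m.score > best[key].score:
                        best[key] = m
    out = []
    for (matrix, acc), m in sorted(best.items()):
        out.append(
            MatrixCall(
                matrix,
                "suggestive",
                [(acc, 1, m.score, m.p_value)],
                [f"sub-threshold match (score {m.score:g}, p {m.p_value:g}) "
                 f"corroborating the confirmed {matrix} call"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# report rendering

REPORT_COLUMNS = ("sample_id", "identification", "biomarker", "n_peptides",
                  "protein_score", "best_peptide_p")


def render_report(report: SampleReport, format: str = "json") -> str:
    """Serialize a report; ``json`` is canonical and round-trips losslessly."""
    if format == "json":
        payload = asdict(report)
        for call in payload["species_calls"]:
            call["observed_discriminating_peptides"] = sorted(
                call["observed_discriminating_peptides"]
            )
        for row in payload["protein_table"]:
            row["distinct_peptides"] = sorted(row["distinct_peptides"])
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        identification = (
            "+".join(sorted(report.called_matrices())) or "none"
        )
        rows = {h.accession: h for h in report.protein_table}
        emitted = set()
        for call in report.matrix_calls:
            for acc, n_pep, score, best_p in call.supporting_markers:
                if acc in emitted:
                    continue
                emitted.add(acc)
                lines.append(
                    "\t".join(
                        [report.sample_id, identification, acc, str(n_pep),
                         f"{score:g}", f"{best_p:g}"]
                    )
                )
        return "\n".join(lines) + "\n"
    raise InputError(f"unknown report format {format!r}")


def report_from_json(text: str) -> SampleReport:
    payload = json.loads(text)
    return SampleReport(
        sample_id=payload["sample_id"],
        matrix_calls=[
            MatrixCall(
                c["matrix"],
                c["tier"],
                [tuple(m) for m in c["supporting_markers"]],
                list(c["caveats"]),
            )
            for c in payload["matrix_calls"]
        ],
        species_calls=[
            SpeciesCall(
                c["group_name"],
                c["species"],
                frozenset(c["observed_discriminating_peptides"]),
                c["n_shared_only"],
            )
            for c in payload["species_calls"]
        ],
        protein_table=[
            ProteinHit(
                accession=r["accession"],
                species=r["species"],
                distinct_peptides=frozenset(r["distinct_peptides"]),
                n_peptides=r["n_peptides"],
                protein_score=r["protein_score"],
                best_peptide_p=r["best_peptide_p"],
                has_bold_red=r["has_bold_red"],
            )
            for r in payload["protein_table"]
        ],
        config_fingerprint=payload.get("config_fingerprint", {}),
        caveats=list(payload.get("caveats", [])),
    )
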