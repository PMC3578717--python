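"""Readers and writers: FASTA records, MGF peak lists, tabular hit reports.

FASTA headers follow the ``accession Name KEY=value`` convention, with
``GN`` (gene), ``OS`` (species, tolerating spaces around ``=`` as printed
in some reports) and the package-specific ``ROLE`` (marker | background |
contaminant).  MGF is read with pyteomics, which accepts the common charge
dialects ("2+", "+2", "2"); writing uses full-precision floats so files
produced here re-read to identical spectra.
"""

from __future__ import annotations

import re
import textwrap
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from pyteomics import mgf as _pmgf

from .digest import CANONICAL
from .errors import InputError
from .inference import ProteinHit
from .panel import ProteinRecord
from .scoring import PSM, SpectrumRecord

_KEY_RE = re.compile(r"\b([A-Z]{2,5})\s*=\s*")


def _header_line(path, accession: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [accession]:
                return i
    return 0


def parse_fasta_description(description: str) -> dict:
    """Split ``acc Name GN=.. OS = Homo sapiens ROLE=..`` into fields."""
    tokens = description.split(None, 1)
    accession = tokens[0]
    rest = tokens[1] if len(tokens) > 1 else ""
    keys = list(_KEY_RE.finditer(rest))
    name = rest[: keys[0].start()].strip() if keys else rest.strip()
    fields = {}
    for i, m in enumerate(keys):
        end = keys[i + 1].start() if i + 1 < len(keys) else len(rest)
        fields[m.group(1)] = rest[m.end(): end].strip()
    return {
        "accession": accession,
        "name": name,
        "gene": fields.get("GN", ""),
        "species": fields.get("OS", ""),
        "role": fields.get("ROLE", "marker").lower(),
    }


def read_fasta(path) -> list[ProteinRecord]:
    """Parse FASTA into ProteinRecords (order preserved, sequences uppercased)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = parse_fasta_description(rec.description)
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(
                f"{path}:{_header_line(path, meta['accession'])}: "
                f"record {meta['accession']!r} has no sequence"
            )
        bad = set(seq) - CANONICAL
        if bad:
            raise InputError(
                f"{path}:{_header_line(path, meta['accession'])}: "
                f"record {meta['accession']!r} contains illegal residues {sorted(bad)}"
            )
        records.append(ProteinRecord(sequence=seq, **meta))
    seen = set()
    for rec in records:
        if rec.accession in seen:
            raise InputError(f"{path}: duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.accession} {rec.name}"
            if rec.gene:
                header += f" GN={rec.gene}"
            if rec.species:
                header += f" OS={rec.species}"
            header += f" ROLE={rec.role}"
            fh.write(header + "\n")
            fh.write(textwrap.fill(rec.sequence, 60) + "\n")


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path) -> list[SpectrumRecord]:
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    spectra = []
    try:
        with _pmgf.MGF(str(path)) as reader:
            for i, spec in enumerate(reader):
                params = spec["params"]
                charge = int(params["charge"][0]) if "charge" in params else 2
                spectra.append(
                    SpectrumRecord(
                        spectrum_id=str(params.get("title", f"index={i}")),
                        precursor_mz=float(params["pepmass"][0]),
                        charge=abs(charge),
                        fragments=np.asarray(spec["m/z array"], dtype=float),
                        intensities=np.asarray(spec["intensity array"], dtype=float),
                    )
                )
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        if isinstance(exc, InputError):
            raise
        raise InputError(f"malformed MGF {path} near block {len(spectra)}: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[SpectrumRecord], path) -> None:
    """Write MGF with full-precision peaks (round-trips exactly through read_mgf)."""
    with open(path, "w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.spectrum_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz!r}\n")
            fh.write(f"CHARGE={spec.charge}+\n")
            inten = (
                spec.intensities
                if spec.intensities is not None
                else np.full(len(spec.fragments), 100.0)
            )
            for m, i in zip(spec.fragments, inten):
                fh.write(f"{float(m)!r} {float(i)!r}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# tabular reports

HIT_COLUMNS = ("sample_id", "accession", "n_peptides", "protein_score", "best_peptide_p")


def read_hit_table(path) -> dict[str, list[ProteinHit]]:
    """Accession-level protein-hit table (TSV) grouped by sample.

    Expected columns: sample_id, accession, n_peptides, protein_score,
    best_peptide_p.  Used for classification-only runs on hand-entered
    report tables.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: hit table lacks columns {sorted(missing)}")
    out: dict[str, list[ProteinHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample_id), []).append(
            ProteinHit(
                accession=str(row.accession),
                n_peptides=int(row.n_peptides),
                protein_score=float(row.protein_score),
                best_peptide_p=float(row.best_peptide_p),
                has_bold_red=True,
            )
        )
    return out


def write_hit_table(hits_by_sample: dict, path) -> None:
    rows = []
    for sample_id, hits in hits_by_sample.items():
        for h in hits:
            rows.append((sample_id, h.accession, h.n_peptides, h.protein_score, h.best_peptide_p))
    pd.DataFrame(rows, columns=list(HIT_COLUMNS)).to_csv(path, sep="\t", index=False)


PSM_COLUMNS = ("spectrum_id", "peptide", "mods", "charge", "matched", "total",
               "p_value", "score", "rank", "red", "bold", "assigned_protein")


def write_psm_table(psms: Sequence[PSM], path) -> None:
    rows = []
    for m in psms:
        mods = m.peptide.mod_string() if hasattr(m.peptide, "mod_string") else "."
        rows.append(
            (m.spectrum_id, m.peptide_sequence, mods, m.charge, m.matched_fragments,
             m.total_fragments, m.p_value, m.score, m.rank, m.red, m.bold,
             m.assigned_protein or ".")
        )
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)
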