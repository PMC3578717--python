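"""Generate the frozen synthetic marker FASTA bundled with the package.

The marker proteins needed by the default panel (hemoglobins of three
species, semenogelins, amylase isoforms, ...) are represented by SYNTHETIC
stand-in sequences: random tryptic-friendly proteins of roughly realistic
length, with ortholog/isoform pairs derived from a common base sequence by
point substitution so that they share many tryptic peptides while each
retains unique ones.  No sequence here is a real database entry; the
package's correctness is established on these stand-ins and on ad-hoc
sequences in the unit tests, never on provenance of real accessions.

Substitutions are restricted to residue pairs whose monoisotopic mass
difference — also after bridging by any supported modification delta
(methylthio on C, oxidation of M, deamidation of N/Q; e.g. F is
near-isobaric with oxidized M) — exceeds 1.5 Da, so that
single-substitution homolog peptides are never near-isobaric and
precursor-mass discrimination between group members stays decisive.

Run from the repository root:  python scripts/make_marker_fixtures.py
The output is committed and never regenerated at test time.
"""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
from pyteomics import mass as pmass

OUT = Path(__file__).resolve().parents[1] / "src" / "fluidms" / "data" / "markers_synthetic.fasta"

# residues used inside tryptic segments (K/R reserved as cleavage sites)
BODY = list("ACDEFGHILMNPQSTVWY")
MONO = dict(pmass.std_aa_mass)


def make_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein: M start, K/R roughly every 6-13 residues, no P after K/R."""
    seq = ["M"]
    while len(seq) < length:
        seg_len = int(rng.integers(5, 13))
        for j in range(seg_len):
            aa = str(rng.choice(BODY))
            while j == 0 and aa == "P":  # keep cleavage sites clean
                aa = str(rng.choice(BODY))
            seq.append(aa)
        seq.append(str(rng.choice(["K", "R"])))
    return "".join(seq[:length])


# modification deltas that can bridge a substitution mass gap: none,
# +/- oxidation (M), +/- deamidation (N/Q), +/- methylthio (fixed on C)
BRIDGES = [0.0, 15.99491, -15.99491, 0.98402, -0.98402, 45.98772, -45.98772]


def _mass_safe(old: str, new: str) -> bool:
    delta = MONO[new] - MONO[old]
    return all(abs(delta - b) > 1.5 for b in BRIDGES)


def mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Point-substitute non-K/R/P residues; substitutions stay mass-discriminable."""
    out = []
    for i, ch in enumerate(seq):
        if i == 0 or ch in "KRP" or rng.random() > rate:
            out.append(ch)
            continue
        cands = [a for a in BODY if a != ch and a != "P" and _mass_safe(ch, a)]
        out.append(str(rng.choice(cands)))
    return "".join(out)


def main() -> None:
    rng = np.random.default_rng(20120729)
    records: list[tuple[str, str, str]] = []  # (header, role, sequence)

    def add(acc, name, gene, species, role, seq):
        header = f"{acc} {name} (synthetic stand-in) GN={gene} OS={species} ROLE={role}"
        records.append((header, role, seq))

    # hemoglobin ortholog trio per subunit: shared base, independent substitutions
    hbb_base = make_protein(rng, 146)
    hba_base = make_protein(rng, 141)
    add("HBB_HUMAN", "Hemoglobin subunit beta", "HBB", "Homo sapiens", "marker", hbb_base)
    add("HBB_BOVIN", "Hemoglobin subunit beta", "HBB", "Bos taurus", "marker", mutate(hbb_base, rng, 0.10))
    add("HBB_CANFA", "Hemoglobin subunit beta", "HBB", "Canis familiaris", "marker", mutate(hbb_base, rng, 0.10))
    add("HBA_HUMAN", "Hemoglobin subunit alpha", "HBA1", "Homo sapiens", "marker", hba_base)
    add("HBA_BOVIN", "Hemoglobin subunit alpha", "HBA", "Bos taurus", "marker", mutate(hba_base, rng, 0.10))
    add("HBA_CANFA", "Hemoglobin subunit alpha", "HBA", "Canis familiaris", "marker", mutate(hba_base, rng, 0.10))

    # semen markers
    add("SEMG1_HUMAN", "Semenogelin-1", "SEMG1", "Homo sapiens", "marker", make_protein(rng, 300))
    add("SEMG2_HUMAN", "Semenogelin-2", "SEMG2", "Homo sapiens", "marker", make_protein(rng, 320))
    add("PAP_HUMAN", "Prostatic acid phosphatase", "ACPP", "Homo sapiens", "marker", make_protein(rng, 250))
    add("PSA_HUMAN", "Prostate-specific antigen", "KLK3", "Homo sapiens", "marker", make_protein(rng, 230))

    # vaginal-fluid markers (cornifin-A/B as a homologous pair)
    add("CORNU_HUMAN", "Cornulin", "CRNN", "Homo sapiens", "marker", make_protein(rng, 300))
    spr_base = make_protein(rng, 90)
    add("SPR1A_HUMAN", "Cornifin-A", "SPRR1A", "Homo sapiens", "marker", spr_base)
    add("SPR1B_HUMAN", "Cornifin-B", "SPRR1B", "Homo sapiens", "marker", mutate(spr_base, rng, 0.12))
    add("INVO_HUMAN", "Involucrin", "IVL", "Homo sapiens", "marker", make_protein(rng, 180))

    # amylase isoform pair: salivary vs the form seen in semen / vaginal fluid
    amy_base = make_protein(rng, 280)
    add("AMY1_HUMAN", "Alpha-amylase 1", "AMY1A", "Homo sapiens", "marker", amy_base)
    add("AMY2_HUMAN", "Alpha-amylase 2", "AMY2A", "Homo sapiens", "marker", mutate(amy_base, rng, 0.10))

    # nasal secretion
    add("PLUNC_HUMAN", "Palate lung and nasal epithelium protein", "BPIFA1", "Homo sapiens", "marker", make_protein(rng, 180))

    # non-specific markers (usable only inside conditional rules / as support)
    add("ALBU_HUMAN", "Serum albumin", "ALB", "Homo sapiens", "marker", make_protein(rng, 300))
    add("IGJ_HUMAN", "Immunoglobulin J chain", "JCHAIN", "Homo sapiens", "marker", make_protein(rng, 140))
    add("IGKC_HUMAN", "Immunoglobulin kappa constant", "IGKC", "Homo sapiens", "marker", make_protein(rng, 106))
    add("IGHA_HUMAN", "Immunoglobulin heavy constant alpha", "IGHA1", "Homo sapiens", "marker", make_protein(rng, 160))

    # urine markers
    add("UROM_HUMAN", "Uromodulin", "UMOD", "Homo sapiens", "marker", make_protein(rng, 300))
    add("AMBP_HUMAN", "Protein AMBP", "AMBP", "Homo sapiens", "marker", make_protein(rng, 200))

    # fabric-handling contaminants
    add("K2C1_HUMAN", "Keratin type II cytoskeletal 1", "KRT1", "Homo sapiens", "contaminant", make_protein(rng, 250))
    add("K1C10_HUMAN", "Keratin type I cytoskeletal 10", "KRT10", "Homo sapiens", "contaminant", make_protein(rng, 250))

    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as fh:
        for header, _role, seq in records:
            fh.write(f">{header}\n")
            fh.write(textwrap.fill(seq, 60) + "\n")
    print(f"wrote {len(records)} records to {OUT}")


if __name__ == "__main__":
    main()
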