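# fluidms

Mass-spectrometry-based identification of forensic body fluids.

Determining *what* a biological trace is — blood, semen, saliva, vaginal
fluid, nasal secretion, urine, feces — can matter as much in casework as
determining *whose* it is. Conventional presumptive tests (benzidine,
Phadebas, PSA strips) are destructive, single-matrix, and blind to
mixtures. Bottom-up proteomics on the supernatant of a swab extract avoids
all three problems: one LC-MS/MS run identifies the marker proteins of
every matrix present, resolves the donor species of blood through
hemoglobin ortholog peptides, and leaves the cell pellet untouched for DNA
typing.

`fluidms` implements that identification chain as a tested Python toolkit
for forensic and proteomics researchers:

- **in-silico digestion** — tryptic and semitryptic peptides, missed
  cleavages, fixed methylthio(C) and variable oxidation(M)/deamidation(NQ)
  modifications, monoisotopic masses;
- **peptide–spectrum matching** — candidate lookup at a 0.35 Da precursor
  tolerance, b/y fragment matching at 0.6 Da, and a binomial significance
  model (below);
- **protein inference** — the *bold-red* homologue filter: a match is
  *red* when it is the top match for its spectrum and *bold* in the
  highest-scoring protein containing its peptide; only proteins with at
  least one bold **and** red match survive;
- **matrix classification** — a biomarker decision tree with conditional
  rules (urine/feces markers count only in the absence of hemoglobin, and
  their absence never excludes the matrix), salivary-amylase isoform
  resolution, species calls from ortholog-discriminating peptides, and a
  corroboration tier for sub-threshold evidence;
- **a sample simulator** — compositional mixtures, dilution series,
  fabric keratin and dirt contamination, dynamic exclusion — so the whole
  chain can be exercised and benchmarked without instrument data.

## The score model

For a spectrum with `n_obs` observed peaks in an acquisition window of
width `W`, a theoretical fragment matches some peak by chance with
probability `q = n_obs · 2·tol / W` under a uniform null. Because CID
spectra carry complementary b/y pairs, evidence is counted per backbone
cleavage position: position *i* of an *L*-residue peptide is matched when
its b- or y-ion is matched, giving *n = L − 1* trials at null probability
`2q`. The peptide p-value is the binomial upper tail

&nbsp;&nbsp;&nbsp;&nbsp;`p = P(X ≥ k | n = L−1, 2q)`,&nbsp;&nbsp;
`score = −10·log₁₀(p)`  (capped at 400),

and a protein's score is the sum of its assigned peptide scores.
Identifications require `p ≤ 0.05` **and** `score ≥ 41` (both inclusive;
`p ≤ 0.01` in discovery mode). Sub-threshold marker matches are kept as
*suggestive* corroboration of already-confirmed matrices but never create
a call on their own.

The bundled marker sequences are synthetic stand-ins (see
`scripts/make_marker_fixtures.py`): homolog groups share a base sequence
with mass-discriminable point substitutions, so every ortholog retains
unique tryptic peptides. No result depends on real database entries.

## Worked example

Classify an accession-level protein-hit table (as produced by the pipeline
or entered from a report):

```sh
$ cat demo_hits.tsv
sample_id	accession	n_peptides	protein_score	best_peptide_p
stain_1	HBB_BOVIN	27	904	1.3e-07
stain_1	HBA_BOVIN	15	847	4.5e-14
stain_1	AMY1_HUMAN	3	160	3.1e-07

$ fluidms classify demo_hits.tsv --format tsv
sample_id	identification	biomarker	n_peptides	protein_score	best_peptide_p
stain_1	blood+saliva	HBA_BOVIN	15	847	4.5e-14
stain_1	blood+saliva	HBB_BOVIN	27	904	1.3e-07
stain_1	blood+saliva	AMY1_HUMAN	3	160	3.1e-07
```

The stain is called **blood + saliva**: the two bovine hemoglobin
subunits make the blood call *corroborated* (two distinct markers, best
peptide p = 4.5e-14), salivary alpha-amylase confirms saliva, and the
JSON report additionally carries the species call
`hemoglobin → Bos taurus` — the blood is bovine, the saliva human.

The full pipeline runs from a peak list instead:

```sh
fluidms simulate --spec sample.yaml --seed 7 --out-dir out/   # or real MGF
fluidms run out/sample.mgf --format json
```

`fluidms run` reports every matrix found (mixtures give multiple calls),
an exit code of 0 even when the answer is "none", and a config
fingerprint (tolerances, thresholds, panel version) in every report.

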