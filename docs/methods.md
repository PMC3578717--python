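# Methods

This note documents the models, parameter choices, and known limits of
`fluidms` — what each stage assumes, what the simulator does and does not
emulate, and therefore what passing tests do and do not establish about
real instrument data.

## Digestion

Trypsin cleaves C-terminal to K/R; the Keil proline restriction (no
cleavage before P) is **on** by default and configurable, since published
search settings rarely state it. Up to 2 missed cleavages are generated by
default. Semitryptic mode adds every peptide with exactly one enzymatic
terminus (protein termini count as enzymatic); it exists for degraded,
protein-poor matrices such as urine and feces, where in-source truncation
products carry much of the signal. Length bounds default to 1–60 residues.
Protein N-terminal methionine is not specially processed.

Masses are monoisotopic throughout (pyteomics residue table; water
18.010565, proton 1.007276). Modifications: methylthio +45.98772 Da fixed
on C (the MMTS alkylation of the digest chemistry), oxidation +15.99491 on
M and deamidation +0.98402 on N/Q as variable. Variable sites are
enumerated combinatorially over the first `cap` matching sites (default 4
for standalone enumeration; the search index uses 2) — a pure
tractability bound on the combinatorics; peptides with more sites keep
their first-`cap` forms.

## Peptide–spectrum matching

Candidates are all indexed modified peptide forms within ±0.35 Da of the
precursor-derived neutral mass (the spectrum's charge when known,
otherwise charges {2,3}). Fragments are singly charged b/y ladders —
dominant for 2+/3+ precursors under CID on Q-TOF instruments — matched
one-to-one within ±0.6 Da by a sorted greedy walk that attains the optimal
bipartite matching cardinality for points on a line.

**Null model.** With `n_obs` observed peaks in an acquisition window of
width `W` (default 50–2300 m/z), a single theoretical fragment lands
within `tol` of some peak with probability `q = min(1, n_obs·2·tol/W)`
under a uniform-peak null. Complementary b/y ions are not independent: for
a same-precursor-mass peptide, `b_i + y_{L−i}` is fixed, so a b-match at a
position makes the paired y-match nearly automatic. Counting both would
double-count evidence and inflate false identifications by orders of
magnitude (we measured a ~5% per-spectrum false-ID rate at score ≥ 41 for
out-of-database ladder spectra when fragments are counted independently).
Evidence is therefore counted per backbone cleavage position: `n = L − 1`
trials, a trial succeeds when either ion of that position matches, null
probability `min(1, 2q)`. The p-value is the exact binomial upper tail and
the score is `−10·log₁₀(p)`, capped at 400 to keep underflowing p-values
finite.

**Calibration scope.** Against its own null — spectra whose peaks are
uniform over the acquisition window — the model is slightly conservative
(one-to-one matching makes successes negatively dependent); decoy searches
of such spectra give ~3% of rank-1 matches at p ≤ 0.05 and an empirical
p-distribution dominated by uniform. Against *structured* negatives (a
real b/y ladder from a peptide absent from the database), p-values are
optimistic, because true peak density concentrates in the fragment span
rather than the full window. This is why two acceptance currencies exist
and are applied independently: `p ≤ 0.05` per peptide **and**
`score ≥ 41` (≈ p ≤ 7.9e−5). At the default thresholds the residual
false-identification rate for out-of-database ladder spectra is ~1e−4 per
candidate spectrum — visible as an occasional spurious single-peptide
protein in large simulations, the known weakness of one-peptide
identifications. The exact score↔p linkage used by commercial engines is
database-size dependent and deliberately not reconstructed; both
thresholds are exposed.

Intensities are read and carried but ignored by the scorer (match/no-match
only) — the simplest model consistent with score/p reporting.

## Protein inference (bold-red)

Per spectrum, the rank-1 match is *red* (ties broken by smaller absolute
precursor error, then sequence). After thresholding, provisional protein
scores are per-protein sums of red match scores; proteins are ordered by
that score (ties by accession) and each distinct peptide is assigned
*bold* to the first protein of the order containing it — one pass, no
re-scoring to a fixpoint, which keeps the assignment deterministic.
Summaries count only red matches (a spectrum never contributes twice);
protein score is the sum of assigned peptide scores and the reported
p-value is the best peptide's (peptide p-values do not combine to a
protein-level probability). Proteins without a bold red match are
dropped, which eliminates lower-coverage homologues whose peptides are
all better explained elsewhere. `min_peptides_per_protein` defaults to 1
because single-peptide marker identifications are operationally accepted
in this workflow.

## Decision tree

Specific markers are individually sufficient: hemoglobin α/β (blood, with
a species-resolvable ortholog group), semenogelin-1/2, prostatic acid
phosphatase and PSA (semen), cornulin / cornifin-A / cornifin-B /
involucrin (vaginal fluid), salivary alpha-amylase (saliva), plunc (nasal
secretion). Urine (uromodulin, AMBP) and feces (immunoglobulin J/κ/α
chains, albumin) are conditional: those proteins also circulate in blood,
so the rules fire only when no hemoglobin was seen, and — because genuine
urine/feces samples may yield no detectable protein — marker absence
never excludes either matrix (a caveat carried on every report).

Evidence tiers: *confirmed* (one above-threshold specific marker),
*corroborated* (≥ 2 distinct markers of one matrix), *suggestive*
(evidence short of an identification). Suggestive covers two situations
and is deliberately never counted as an identification: sub-threshold
marker matches attached to an already-confirmed matrix (only informative
top-of-spectrum matches qualify, and they never create a call), and
non-specific patterns — the feces rule always reports at most
"feces-possible" because immunoglobulins and albumin are poor markers, and
an amylase hit whose peptides cannot distinguish the salivary from the
non-salivary isoform yields a caveat instead of a saliva call.

Design choices on genuinely open points:

- **Menstrual blood** is reported as blood + vaginal fluid with a
  "consistent with menstrual blood" caveat rather than as a class of its
  own: hemoglobin-plus-cornulin cannot be separated from a blood/vaginal
  mixture.
- **Isoform trust in table mode.** Hand-entered accession-level hit
  tables carry no peptides; their amylase/hemoglobin rows are taken at
  face value, since isoforms were resolved by whatever produced the
  table. Peptide-level hits from the pipeline must show a group-unique
  peptide.
- **Species calls are per protein group**, not per sample — a sample may
  legitimately contain human and bovine blood; shared-peptide-only
  evidence is reported as *ambiguous*.
- **Contaminants** (fabric keratins) are listed in the protein table but
  never classified; a single-specific-marker call is accepted even at one
  peptide, consistent with operational reporting practice.

## Simulator

A sample spec is a composition over matrix profiles, a dilution factor, a
spectrum budget, a seed, and a noise model. Each spectrum draw picks a
source ∝ `proportion × richness-yield ÷ dilution` against fixed
contamination weights (fabric keratin 0.02, out-of-database shuffled
"dirt" protein 0.02) and a blank weight of 1.0 (so deep dilutions mostly
acquire nothing); then a protein ∝ its profile abundance; then a tryptic
peptide weighted by length within the 7–25-residue detectability window
(a crude, documented, non-physical proxy). Precursors must fall in the
450–1650 m/z selection window at charge 2 or 3; fragments are the singly
charged b/y ladder with Gaussian m/z jitter (σ = 0.02 Da) plus uniform
spurious peaks (0.2 per true peak) clipped to 50–2300 m/z. Dynamic
exclusion is emulated as one spectrum per distinct modified peptide. All
randomness flows from a single seeded generator; identical seeds give
byte-identical MGF output.

Abundance profiles are synthetic and editable
(`src/fluidms/data/matrix_profiles.yaml`); nothing downstream depends on
their absolute values, only on the ordering of richness classes:
protein-rich blood and semen carry yield 1.0, protein-poor saliva,
vaginal fluid and the rest 0.05. That 20-fold gap is what produces the
masking asymmetry (a poor matrix at 1% inside a rich one is mostly
missed; the reverse is mostly found) as an emergent property rather than
a scripted one.

Problem sizes in the shipped studies: 300–400 spectra per sample, 20
samples for mixture recovery, 50 seed-pairs for masking, a 10⁰–10⁶
dilution grid with 3 replicates — sizes at which every study runs in
seconds while the binomial uncertainties stay far smaller than the
effects measured.

**What the simulator does not emulate** — chromatography and retention
time, isotope envelopes, fragment charge states > 1, intensity structure,
co-isolation chimeras, real inter-donor variability of fluid proteomes,
and real homolog sequence structure (stand-in orthologs substitute ~10%
of residues with mass-discriminable exchanges; real orthologs can carry
near-isobaric substitutions such as F ↔ oxidized M, which would make
species discrimination harder than it is here). Passing the simulation
studies therefore demonstrates internal correctness and the qualitative
masking/dilution/species behavior of the method, not instrument-level
sensitivities; the bundled worked-example tables are label-level
regressions of published identifications, not re-acquisitions.

## Numerical conventions

Threshold boundaries are inclusive (`p ≤`, `score ≥`). Ranking ties break
by precursor error then sequence; bold ties by accession; all outputs are
invariant under permutation of inputs. Peptide masses reproduce to 1e-4
Da; the score cap is 400. TSV uses tabs with "." for missing values; JSON
is the canonical lossless report form and embeds the config fingerprint
(tolerances, thresholds, enzyme mode, panel version, seed) so reports
from different settings are distinguishable from metadata alone.
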