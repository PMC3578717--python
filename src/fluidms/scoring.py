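"""Probabilistic peptide-spectrum matching.

Candidate peptides are drawn from a mass index at the precursor tolerance,
their singly charged b/y fragment ladders are matched against the observed
peak list at the fragment tolerance, and each match is scored with a
binomial null model: if a spectrum shows ``n_obs`` peaks across an
acquisition window of width ``W``, a single theoretical fragment lands
within ``tol`` of some peak with probability ``q = min(1, n_obs * 2*tol/W)``
under a uniform null.  The p-value of observing ``k`` of ``n`` theoretical
fragments matched is the binomial upper tail ``P(X >= k | n, q)``; the
peptide score is ``-10*log10(p)`` (capped at 400).

Two acceptance currencies are used downstream: a per-peptide p-value
threshold (0.05; 0.01 in discovery mode) and a score threshold (41).  They
are applied independently — their exact linkage in commercial engines
depends on database size and is deliberately not reconstructed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .digest import PROTON, WATER, RESIDUE_MASS, Peptide, PeptideIndex, mz as peptide_mz
from .errors import InputError

SCORE_CAP = 400.0


@dataclass
class SpectrumRecord:
    spectrum_id: str
    precursor_mz: float
    charge: int
    fragments: np.ndarray
    intensities: np.ndarray | None = None
    acquisition_range: tuple = (50.0, 2300.0)

    def __post_init__(self):
        self.fragments = np.asarray(self.fragments, dtype=float)
        if self.intensities is not None:
            self.intensities = np.asarray(self.intensities, dtype=float)
        if self.charge < 1:
            raise InputError(f"spectrum {self.spectrum_id}: charge must be >= 1")


@dataclass(frozen=True)
class SearchConfig:
    precursor_tol: float = 0.35
    fragment_tol: float = 0.6
    charges: frozenset = frozenset({2, 3})
    series: tuple = ("b", "y")
    score_threshold: float = 41.0
    p_threshold: float = 0.05
    discovery_p_threshold: float = 0.01

    def __post_init__(self):
        object.__setattr__(self, "charges", frozenset(self.charges))
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise InputError("tolerances must be positive")
        for p in (self.p_threshold, self.discovery_p_threshold):
            if not (0 < p <= 1):
                raise InputError("p thresholds must lie in (0, 1]")


@dataclass
class PSM:
    """One scored spectrum-to-peptide assignment."""

    spectrum_id: str
    peptide: Peptide | str
    charge: int
    matched_fragments: int
    total_fragments: int
    per_fragment_prob: float
    p_value: float
    score: float
    precursor_delta: float = 0.0
    rank: int = 0
    red: bool = False
    bold: bool = False
    assigned_protein: str | None = None

    @property
    def peptide_sequence(self) -> str:
        return self.peptide if isinstance(self.peptide, str) else self.peptide.sequence


def theoretical_fragments(
    peptide: Peptide, series: tuple = ("b", "y"), fragment_charge: int = 1
) -> np.ndarray:
    """Sorted m/z of the requested fragment-ion ladders.

    b-ions are N-terminal prefixes (residues + proton); y-ions are
    C-terminal suffixes (residues + water + proton).  Modification deltas
    shift exactly the fragments containing the modified residue.
    """
    seq = peptide.sequence
    L = len(seq)
    if L < 2:
        raise InputError("fragments are defined for peptides of length >= 2")
    deltas = np.zeros(L)
    for pos, spec in peptide.modifications:
        deltas[pos - 1] += spec.delta_mass
    residue = np.array([RESIDUE_MASS[aa] for aa in seq]) + deltas
    prefix = np.cumsum(residue)
    out: list[np.ndarray] = []
    z = fragment_charge
    if "b" in series:
        out.append((prefix[:-1] + z * PROTON) / z)
    if "y" in series:
        suffix = prefix[-1] - prefix[:-1][::-1]  # residue sums of C-terminal 1..L-1 residues
        out.append((suffix + WATER + z * PROTON) / z)
    return np.sort(np.concatenate(out)) if out else np.array([])


def _matched_indices(observed: np.ndarray, theoretical: np.ndarray, tol: float) -> list[int]:
    """Indices of theoretical fragments claimed in an optimal one-to-one pairing.

    Both lists are walked in sorted order; for points on a line with a fixed
    tolerance this greedy pairing attains the optimum bipartite matching
    cardinality.
    """
    obs = np.sort(observed)
    theo = np.asarray(theoretical)
    i = j = 0
    matched: list[int] = []
    while i < len(obs) and j < len(theo):
        d = obs[i] - theo[j]
        if abs(d) <= tol:
            matched.append(j)
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return matched


def match_fragments(spectrum: SpectrumRecord | np.ndarray, theoretical: np.ndarray, tol: float) -> int:
    """Maximum number of one-to-one observed/theoretical pairs within ``tol``."""
    obs = spectrum.fragments if isinstance(spectrum, SpectrumRecord) else np.asarray(spectrum)
    return len(_matched_indices(obs, theoretical, tol))


def random_match_probability(n_observed: int, tol: float, acquisition_range: tuple) -> float:
    """Chance a theoretical fragment lands within ``tol`` of any observed peak."""
    low, high = acquisition_range
    if high <= low:
        raise InputError("acquisition range must have positive width")
    return min(1.0, n_observed * 2.0 * tol / (high - low))


def score_psm(k: int, n: int, q: float) -> tuple[float, float]:
    """Binomial upper-tail p-value and -10*log10 score for k of n matches."""
    if k > n:
        raise InputError(f"matched count {k} exceeds fragment count {n}")
    if k <= 0:
        return 1.0, 0.0
    p = float(stats.binom.sf(k - 1, n, q))
    p = min(1.0, max(p, 10 ** (-SCORE_CAP / 10.0)))
    score = min(SCORE_CAP, -10.0 * np.log10(p))
    return p, score


def matched_cleavage_positions(
    spectrum: SpectrumRecord, peptide: Peptide, config: SearchConfig
) -> tuple[int, int, float]:
    """Backbone-position evidence (k, n, q_position) for scoring one candidate.

    A CID spectrum of a same-mass peptide carries complementary b/y pairs
    whose m/z sum is fixed by the precursor, so b- and y-matches at one
    backbone position are strongly correlated and must not be counted as
    independent trials.  Evidence is therefore counted per cleavage
    position: position i (1..L-1) is matched when its b- or its y-ion is
    matched, giving n = L-1 trials with per-trial null probability
    min(1, 2q) (either of two fragments may match).
    """
    q = random_match_probability(
        len(spectrum.fragments), config.fragment_tol, spectrum.acquisition_range
    )
    L = len(peptide.sequence)
    positions: set[int] = set()
    if "b" in config.series:
        theo_b = theoretical_fragments(peptide, ("b",))
        for i in _matched_indices(spectrum.fragments, theo_b, config.fragment_tol):
            positions.add(i + 1)  # b_i covers the site after residue i
    if "y" in config.series:
        theo_y = theoretical_fragments(peptide, ("y",))  # ascending = suffix length 1..L-1
        for j in _matched_indices(spectrum.fragments, theo_y, config.fragment_tol):
            positions.add(L - (j + 1))  # y_j covers the site before the last j residues
    q_pos = min(1.0, len(config.series) * q)
    return len(positions), L - 1, q_pos


def search_spectrum(
    spectrum: SpectrumRecord, index: PeptideIndex, config: SearchConfig = SearchConfig()
) -> list[PSM]:
    """Score every index candidate within the precursor tolerance, ranked.

    Candidates are scored on backbone-position evidence (see
    ``matched_cleavage_positions``).  The spectrum's own charge is used when
    known, otherwise every allowed charge is tried.  Ties in score break by
    smaller absolute precursor mass error, then lexicographically by peptide
    sequence.
    """
    charges = [spectrum.charge] if spectrum.charge else sorted(config.charges)
    psms: list[PSM] = []
    seen: set = set()
    for z in charges:
        neutral = spectrum.precursor_mz * z - z * PROTON
        for cand in index.query(neutral, config.precursor_tol):
            if len(cand.sequence) < 2:  # no fragment ladder to match
                continue
            key = (cand.sequence, cand.modifications, z)
            if key in seen:
                continue
            seen.add(key)
            k, n, q_pos = matched_cleavage_positions(spectrum, cand, config)
            p, score = score_psm(k, n, q_pos)
            psms.append(
                PSM(
                    spectrum_id=spectrum.spectrum_id,
                    peptide=cand,
                    charge=z,
                    matched_fragments=k,
                    total_fragments=n,
                    per_fragment_prob=q_pos,
                    p_value=p,
                    score=score,
                    precursor_delta=cand.neutral_mass - neutral,
                )
            )
    psms.sort(key=lambda m: (-m.score, abs(m.precursor_delta), m.peptide_sequence))
    for r, m in enumerate(psms, start=1):
        m.rank = r
    return psms
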