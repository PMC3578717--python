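"""Red/bold flagging, thresholding, protein summaries, homologue filtering."""

import numpy as np
import pytest

from fluidms import (
    InferenceConfig,
    PSM,
    SearchConfig,
    apply_thresholds,
    filter_bold_red,
    flag_bold,
    flag_red,
    infer_proteins,
    summarize,
)
from fluidms.errors import InputError


def psm(spectrum_id, seq, score, rank=1, p=None, red=False):
    p = p if p is not None else 10 ** (-score / 10)
    return PSM(
        spectrum_id=spectrum_id,
        peptide=seq,
        charge=2,
        matched_fragments=5,
        total_fragments=10,
        per_fragment_prob=0.02,
        p_value=p,
        score=score,
        rank=rank,
        red=red,
    )


class TestFlagRed:
    def test_only_rank_one_is_red(self):
        psms = [psm("s1", "AAAK", 60, rank=1), psm("s1", "AACK", 40, rank=2),
                psm("s1", "AADK", 20, rank=3)]
        flag_red(psms)
        assert [m.red for m in psms] == [True, False, False]

    def test_one_red_per_spectrum(self):
        psms = [psm(f"s{i}", "AAAK", 60, rank=1) for i in range(5)]
        psms += [psm(f"s{i}", "AACK", 30, rank=2) for i in range(5)]
        flag_red(psms)
        assert sum(m.red for m in psms) == 5

    def test_duplicate_rank_one_rejected(self):
        psms = [psm("s1", "AAAK", 60, rank=1), psm("s1", "AACK", 60, rank=1)]
        with pytest.raises(InputError):
            flag_red(psms)

    def test_flags_invariant_under_permutation(self):
        rng = np.random.default_rng(31)
        psms = [psm(f"s{i%4}", f"PEP{j}K", 50 - j, rank=j % 3 + 1) for j, i in
                enumerate(rng.integers(0, 4, 12))]
        # ensure exactly one rank-1 per spectrum
        psms = [psm(f"s{i}", f"A{i}K", 50, rank=1) for i in range(4)] + [
            psm(f"s{i}", f"B{i}K", 30, rank=2) for i in range(4)
        ]
        flag_red(psms)
        reds = {(m.spectrum_id, m.peptide) for m in psms if m.red}
        shuffled = list(psms)
        rng.shuffle(shuffled)
        for m in shuffled:
            m.red = False
        flag_red(shuffled)
        assert {(m.spectrum_id, m.peptide) for m in shuffled if m.red} == reds


class TestFlagBold:
    def test_unique_peptide_bold_in_its_protein(self):
        psms = [psm("s1", "AAAK", 60, red=True)]
        flag_bold(psms, {"AAAK": frozenset({"P1"})})
        assert psms[0].bold and psms[0].assigned_protein == "P1"

    def test_shared_peptide_bold_in_higher_scoring_protein(self):
        psms = [
            psm("s1", "SHAREDK", 50, red=True),
            psm("s2", "UNIQUEK", 50, red=True),
        ]
        membership = {"SHAREDK": frozenset({"A", "B"}), "UNIQUEK": frozenset({"A"})}
        flag_bold(psms, membership)
        assert psms[0].assigned_protein == "A"  # A: 100 vs B: 50

    def test_peptide_without_protein_rejected(self):
        with pytest.raises(InputError):
            flag_bold([psm("s1", "ORPHANK", 50, red=True)], {"ORPHANK": frozenset()})

    def test_assignment_equals_max_container_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(100):
            n_prot = int(rng.integers(2, 6))
            n_pep = int(rng.integers(2, 10))
            membership = {}
            for j in range(n_pep):
                owners = rng.choice(n_prot, size=int(rng.integers(1, n_prot + 1)),
                                    replace=False)
                membership[f"PEP{j}"] = frozenset(f"P{o}" for o in owners)
            psms = [
                psm(f"s{j}", f"PEP{j}", float(rng.integers(10, 100)), red=True)
                for j in range(n_pep)
            ]
            flag_bold(psms, membership)
            # oracle: provisional score by definition, then max-scoring container
            provisional = {f"P{i}": 0.0 for i in range(n_prot)}
            for m in psms:
                for acc in membership[m.peptide]:
                    provisional[acc] += m.score
            for m in psms:
                best = max(
                    membership[m.peptide],
                    key=lambda a: (provisional[a], ), default=None,
                )
                # ties break by accession ascending
                top = sorted(
                    membership[m.peptide], key=lambda a: (-provisional[a], a)
                )[0]
                assert m.assigned_protein == top


class TestThresholds:
    def test_near_miss_goes_to_subthreshold_pool(self):
        pools = apply_thresholds([psm("s1", "PAPPEPK", 38, p=0.071, red=True)])
        assert pools.accepted == [] and len(pools.subthreshold) == 1

    def test_boundaries_are_inclusive(self):
        m = psm("s1", "EDGEK", 41.0, p=0.05, red=True)
        pools = apply_thresholds([m])
        assert pools.accepted == [m]

    def test_discovery_mode_accepts_a_subset(self):
        psms = [psm(f"s{i}", f"A{i}K", s, p=p, red=True)
                for i, (s, p) in enumerate([(80, 1e-8), (45, 0.03), (60, 0.008)])]
        std = apply_thresholds(psms, InferenceConfig("standard"))
        disc = apply_thresholds(psms, InferenceConfig("discovery"))
        assert set(id(m) for m in disc.accepted) <= set(id(m) for m in std.accepted)
        assert len(disc.accepted) == 2


class TestSummarizeAndFilter:
    def test_protein_score_is_sum_of_member_scores(self):
        psms = [psm("s1", "AAAK", 40, red=True), psm("s2", "CCCK", 60, red=True)]
        membership = {"AAAK": frozenset({"P"}), "CCCK": frozenset({"P"})}
        flag_bold(psms, membership)
        hits = summarize(psms, membership)
        assert len(hits) == 1
        assert hits[0].protein_score == 100
        assert hits[0].n_peptides == 2
        assert hits[0].best_peptide_p == min(m.p_value for m in psms)

    def test_nested_homologue_is_eliminated(self):
        # B's peptides are a strict subset of A's; A scores higher
        membership = {
            "AAAAK": frozenset({"A", "B"}),
            "CCCCK": frozenset({"A", "B"}),
            "DDDDK": frozenset({"A"}),
        }
        psms = [
            psm("s1", "AAAAK", 50, red=True),
            psm("s2", "CCCCK", 55, red=True),
            psm("s3", "DDDDK", 60, red=True),
        ]
        flag_bold(psms, membership)
        hits = filter_bold_red(summarize(psms, membership))
        assert [h.accession for h in hits] == ["A"]

    def test_filter_is_idempotent(self):
        membership = {"AAAAK": frozenset({"A"})}
        psms = [psm("s1", "AAAAK", 50, red=True)]
        flag_bold(psms, membership)
        hits = filter_bold_red(summarize(psms, membership))
        assert filter_bold_red(hits) == hits

    def test_homologue_elimination_on_random_nests(self):
        rng = np.random.default_rng(33)
        for _ in range(100):
            n_shared = int(rng.integers(1, 6))
            shared = [f"S{j}K" for j in range(n_shared)]
            extra = [f"E{j}K" for j in range(int(rng.integers(1, 4)))]
            membership = {s: frozenset({"BIG", "SUB"}) for s in shared}
            membership.update({e: frozenset({"BIG"}) for e in extra})
            psms = [
                psm(f"s{i}", seq, float(rng.integers(42, 100)), p=1e-6, red=True)
                for i, seq in enumerate(shared + extra)
            ]
            flag_bold(psms, membership)
            hits = filter_bold_red(summarize(psms, membership))
            assert "SUB" not in [h.accession for h in hits]

    def test_score_conservation(self):
        rng = np.random.default_rng(34)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            membership = {f"PEP{j}": frozenset({f"P{rng.integers(0, 3)}"}) for j in range(n)}
            psms = [psm(f"s{j}", f"PEP{j}", float(rng.integers(42, 100)), p=1e-6, red=True)
                    for j in range(n)]
            flag_bold(psms, membership)
            hits = summarize(psms, membership)
            # no peptide shared -> protein scores exactly partition the PSM scores
            assert sum(h.protein_score for h in hits) == pytest.approx(
                sum(m.score for m in psms)
            )

    def test_full_inference_is_permutation_invariant(self):
        rng = np.random.default_rng(35)
        membership = {
            "AAAAK": frozenset({"A", "B"}),
            "CCCCK": frozenset({"B"}),
            "DDDDK": frozenset({"A"}),
        }
        base = [
            psm("s1", "AAAAK", 80, p=1e-8, rank=1),
            psm("s2", "CCCCK", 50, p=1e-5, rank=1),
            psm("s3", "DDDDK", 70, p=1e-7, rank=1),
        ]
        hits0, _ = infer_proteins(base, membership)
        for _ in range(5):
            shuffled = list(base)
            rng.shuffle(shuffled)
            for m in shuffled:
                m.red = m.bold = False
                m.assigned_protein = None
            hits, _ = infer_proteins(shuffled, membership)
            assert [(h.accession, h.protein_score) for h in hits] == [
                (h.accession, h.protein_score) for h in hits0
            ]
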