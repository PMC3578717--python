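"""Decision tree behavior, species calls, corroboration, report rendering."""

import itertools

import pytest

from fluidms import (
    ProteinHit,
    PSM,
    SampleReport,
    call_species,
    classify,
    corroborating_evidence,
    render_report,
    report_from_json,
)
from fluidms.classify import AMYLASE_CAVEAT, MENSTRUAL_CAVEAT
from fluidms.errors import InputError


def hit(acc, n=3, score=200.0, p=1e-6, peptides=()):
    return ProteinHit(
        accession=acc, n_peptides=n, protein_score=score, best_peptide_p=p,
        distinct_peptides=frozenset(peptides), has_bold_red=True,
    )


def sub_psm(seq, score, p, parents):
    from fluidms.digest import Peptide

    return PSM(
        spectrum_id="sub1",
        peptide=Peptide(seq, parent_accessions=frozenset(parents)),
        charge=2, matched_fragments=2, total_fragments=10,
        per_fragment_prob=0.02, p_value=p, score=score, rank=1, red=True,
    )


def called(calls, tiers=("confirmed", "corroborated")):
    return sorted({c.matrix for c in calls if c.tier in tiers})


class TestDecisionTree:
    def test_four_semen_markers_corroborate_semen(self, panel):
        hits = [hit(a) for a in ("SEMG1_HUMAN", "SEMG2_HUMAN", "PAP_HUMAN", "PSA_HUMAN")]
        calls = classify(hits, panel)
        assert called(calls) == ["semen"]
        assert calls[0].tier == "corroborated"

    def test_no_hits_yields_none(self, panel):
        calls = classify([], panel)
        assert [c.matrix for c in calls] == ["none"]

    def test_bovine_blood_with_saliva(self, panel):
        hits = [hit("HBB_BOVIN"), hit("HBA_BOVIN"), hit("AMY1_HUMAN")]
        calls = classify(hits, panel)
        assert called(calls) == ["blood", "saliva"]
        species = call_species(hits, panel)
        assert [(s.group_name, s.species) for s in species] == [("hemoglobin", "Bos taurus")]

    def test_semen_with_vaginal_fluid(self, panel):
        hits = [hit(a) for a in
                ("SEMG2_HUMAN", "SEMG1_HUMAN", "CORNU_HUMAN", "PAP_HUMAN",
                 "SPR1B_HUMAN", "INVO_HUMAN")]
        assert called(classify(hits, panel)) == ["semen", "vaginal_fluid"]

    def test_urine_requires_absence_of_hemoglobin(self, panel):
        urine_only = [hit("UROM_HUMAN")]
        assert called(classify(urine_only, panel)) == ["urine"]
        with_blood = urine_only + [hit("HBB_HUMAN")]
        assert called(classify(with_blood, panel)) == ["blood"]

    def test_feces_pattern_is_suggestive_only(self, panel):
        hits = [hit("IGJ_HUMAN"), hit("IGKC_HUMAN"), hit("ALBU_HUMAN")]
        calls = classify(hits, panel)
        assert called(calls) == []
        feces = [c for c in calls if c.matrix == "feces"]
        assert feces and feces[0].tier == "suggestive"

    def test_menstrual_blood_caveat(self, panel):
        hits = [hit("HBB_HUMAN"), hit("HBA_HUMAN"), hit("CORNU_HUMAN")]
        calls = classify(hits, panel)
        assert called(calls) == ["blood", "vaginal_fluid"]
        blood = next(c for c in calls if c.matrix == "blood")
        assert MENSTRUAL_CAVEAT in blood.caveats

    def test_keratin_contaminants_are_ignored(self, panel):
        calls = classify([hit("K2C1_HUMAN"), hit("K1C10_HUMAN")], panel)
        assert [c.matrix for c in calls] == ["none"]

    def test_amylase_without_salivary_specific_peptide_not_called(self, panel):
        disc = panel.discriminating_sets()["amylase"]
        shared = sorted(disc.shared_peptides)[:3]
        calls = classify([hit("AMY1_HUMAN", peptides=shared)], panel)
        assert called(calls) == []
        assert any(AMYLASE_CAVEAT in c.caveats for c in calls)

    def test_amylase_with_salivary_specific_peptide_called(self, panel):
        disc = panel.discriminating_sets()["amylase"]
        unique = sorted(disc.member_peptides["AMY1_HUMAN"])[:2]
        calls = classify([hit("AMY1_HUMAN", peptides=unique)], panel)
        assert called(calls) == ["saliva"]

    def test_adding_markers_never_removes_calls_except_conditional(self, panel):
        base = [hit("SEMG1_HUMAN"), hit("UROM_HUMAN")]
        before = set(called(classify(base, panel)))
        assert before == {"semen", "urine"}
        for extra in ("CORNU_HUMAN", "PSA_HUMAN", "PLUNC_HUMAN"):
            after = set(called(classify(base + [hit(extra)], panel)))
            assert before <= after
        # hemoglobin retracts the conditional urine call, never the rest
        with_hb = set(called(classify(base + [hit("HBA_HUMAN")], panel)))
        assert "urine" not in with_hb and "semen" in with_hb and "blood" in with_hb

    def test_mixture_calls_are_union_of_pure_calls(self, panel):
        sets = {
            "blood": [hit("HBB_HUMAN"), hit("HBA_HUMAN")],
            "semen": [hit("SEMG1_HUMAN"), hit("PSA_HUMAN")],
            "vaginal_fluid": [hit("CORNU_HUMAN")],
        }
        for (ma, ha), (mb, hb) in itertools.combinations(sets.items(), 2):
            union = called(classify(ha + hb, panel))
            assert union == sorted({ma, mb})


class TestSpeciesCalls:
    def test_unique_bovine_peptides_call_bos_taurus(self, panel):
        disc = panel.discriminating_sets()["hemoglobin"]
        unique = sorted(disc.member_peptides["HBB_BOVIN"])[:2]
        hits = [hit("HBB_BOVIN", peptides=unique)]
        calls = [s for s in call_species(hits, panel) if s.group_name == "hemoglobin"]
        assert [s.species for s in calls] == ["Bos taurus"]

    def test_shared_peptides_only_is_ambiguous(self, panel):
        disc = panel.discriminating_sets()["hemoglobin"]
        shared = sorted(disc.shared_peptides)[:3]
        hits = [hit("HBB_HUMAN", peptides=shared)]
        calls = [s for s in call_species(hits, panel) if s.group_name == "hemoglobin"]
        assert [s.species for s in calls] == ["ambiguous"]
        assert calls[0].n_shared_only == len(shared)

    def test_canine_unique_peptides_call_canis_familiaris(self, panel):
        disc = panel.discriminating_sets()["hemoglobin"]
        unique = sorted(disc.member_peptides["HBB_CANFA"])[:1]
        hits = [hit("HBB_CANFA", peptides=unique)]
        calls = [s for s in call_species(hits, panel) if s.group_name == "hemoglobin"]
        assert [s.species for s in calls] == ["Canis familiaris"]

    def test_mixed_species_yield_one_call_each(self, panel):
        disc = panel.discriminating_sets()["hemoglobin"]
        hits = [
            hit("HBB_HUMAN", peptides=sorted(disc.member_peptides["HBB_HUMAN"])[:1]),
            hit("HBB_BOVIN", peptides=sorted(disc.member_peptides["HBB_BOVIN"])[:1]),
        ]
        calls = [s for s in call_species(hits, panel) if s.group_name == "hemoglobin"]
        assert sorted(s.species for s in calls) == ["Bos taurus", "Homo sapiens"]


class TestCorroboration:
    def test_subthreshold_pap_corroborates_confirmed_semen(self, panel):
        confirmed = classify([hit("SEMG1_HUMAN"), hit("SEMG2_HUMAN")], panel)
        annotations = corroborating_evidence(
            [sub_psm("QQQPAPK", 38.0, 0.071, {"PAP_HUMAN"})], panel, confirmed
        )
        assert len(annotations) == 1
        assert annotations[0].matrix == "semen"
        assert annotations[0].tier == "suggestive"
        assert annotations[0].supporting_markers[0][0] == "PAP_HUMAN"

    def test_subthreshold_marker_alone_creates_no_call(self, panel):
        calls = classify(
            [], panel, subthreshold_psms=[sub_psm("CORNUPEPK", 30.0, 0.2, {"CORNU_HUMAN"})]
        )
        assert [c.matrix for c in calls] == ["none"]

    def test_no_subthreshold_psms_no_annotations(self, panel):
        confirmed = classify([hit("SEMG1_HUMAN")], panel)
        assert corroborating_evidence([], panel, confirmed) == []


class TestReportRendering:
    def _report(self, panel):
        hits = [hit("SEMG1_HUMAN", peptides=("AAAK", "CCCK"))]
        return SampleReport(
            sample_id="demo",
            matrix_calls=classify(hits, panel),
            species_calls=call_species(hits, panel),
            protein_table=hits,
            config_fingerprint={"score_threshold": 41.0, "p_threshold": 0.05},
        )

    def test_json_round_trip(self, panel):
        report = self._report(panel)
        again = report_from_json(render_report(report, "json"))
        assert again == report

    def test_tsv_has_canonical_columns(self, panel):
        text = render_report(self._report(panel), "tsv")
        header = text.splitlines()[0].split("\t")
        assert header == ["sample_id", "identification", "biomarker", "n_peptides",
                          "protein_score", "best_peptide_p"]
        assert "SEMG1_HUMAN" in text

    def test_empty_report_renders_header_only(self):
        text = render_report(SampleReport(sample_id="empty"), "tsv")
        assert len(text.splitlines()) == 1

    def test_unknown_format_rejected(self, panel):
        with pytest.raises(InputError):
            render_report(self._report(panel), "xml")

    def test_fingerprint_distinguishes_configs(self, panel):
        a, b = self._report(panel), self._report(panel)
        b.config_fingerprint = {"score_threshold": 30.0, "p_threshold": 0.05}
        assert a.config_fingerprint != b.config_fingerprint
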