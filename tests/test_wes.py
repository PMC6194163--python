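"""Inheritance-model filter cascade, segregation and diagnosis."""

import itertools

import pytest

from mitotriage import (
    FamilySpec,
    MemberSpec,
    NuclearVariant,
    diagnose_family,
    dominant_candidates,
    effect_filter,
    frequency_filter,
    recessive_candidates,
    segregation_check,
)
from mitotriage.roh import ROHRegion

_ids = itertools.count()


def variant(gene="GENE1", chrom="1", pos=None, effect="nonsense", pop_af=0.001,
            inhouse=0.0, n_damaging=4, acmg=5, omim=False, mito=True):
    pos = pos if pos is not None else 1000 + next(_ids)
    return NuclearVariant(
        variant_id=f"{gene}:{pos}:A>T", gene=gene, chromosome=chrom, position=pos,
        ref="A", alt="T", effect=effect, population_af=pop_af, inhouse_af=inhouse,
        n_damaging=n_damaging, acmg_class=acmg, mitocarta=mito, omim_dominant=omim,
    )


def trio(fid="FX", strategy="B", consanguineous=False, n_affected=1, sex="m", subclinical=False):
    members = [
        MemberSpec(f"{fid}_P{i+1}", sex if i == 0 else "f", True, f"{fid}_FA", f"{fid}_MO")
        for i in range(n_affected)
    ] + [
        MemberSpec(f"{fid}_FA", "m", False, subclinical=subclinical),
        MemberSpec(f"{fid}_MO", "f", False),
    ]
    return FamilySpec(
        family_id=fid, strategy=strategy, consanguineous=consanguineous,
        n_affected=n_affected, group=1, mdc_score=6, members=tuple(members),
    )


def gts(v, **by_member):
    return {v.variant_id: by_member}


class TestFrequencyFilter:
    def test_annotated_threshold_strict(self):
        kept = frequency_filter([variant(pop_af=0.005), variant(pop_af=0.02), variant(pop_af=0.01)])
        assert [v.population_af for v in kept] == [0.005]

    def test_non_annotated_kept_unless_inhouse_common(self):
        kept = frequency_filter([variant(pop_af=None, inhouse=0.03), variant(pop_af=None, inhouse=0.07)])
        assert [v.inhouse_af for v in kept] == [0.03]
        assert frequency_filter([variant(pop_af=None, inhouse=0.05)])  # inclusive <=

    def test_empty_input(self):
        assert frequency_filter([]) == []

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            frequency_filter([], popmax=0.0)


class TestEffectFilter:
    def test_lof_always_kept_even_benign_predicted(self):
        assert len(effect_filter([variant(effect="frameshift", n_damaging=0)])) == 1

    def test_missense_needs_damaging_prediction(self):
        assert effect_filter([variant(effect="missense", n_damaging=0)]) == []
        assert len(effect_filter([variant(effect="missense", n_damaging=1)])) == 1

    def test_synonymous_removed(self):
        assert effect_filter([variant(effect="synonymous", n_damaging=4)]) == []

    def test_cascade_order_stable(self):
        pool = [
            variant(pop_af=0.3, effect="missense", n_damaging=2),
            variant(pop_af=0.001, effect="synonymous"),
            variant(pop_af=0.001, effect="nonsense"),
            variant(pop_af=None, inhouse=0.2, effect="frameshift"),
            variant(pop_af=0.002, effect="missense", n_damaging=0),
        ]
        fwd = effect_filter(frequency_filter(pool))
        rev = frequency_filter(effect_filter(pool))
        assert fwd == rev


class TestRecessiveCandidates:
    def test_ar_hom_with_carrier_parents(self):
        fam = trio(strategy="A", consanguineous=True)
        v = variant()
        g = gts(v, FX_P1="hom_alt", FX_FA="het", FX_MO="het")
        (cand,) = recessive_candidates(fam, [v], g)
        assert cand.mode == "AR_hom" and not cand.in_roh

    def test_roh_overlap_ranks_first(self):
        fam = trio(strategy="A", consanguineous=True)
        v_in = variant(gene="IN", chrom="4", pos=5_000_000)
        v_out = variant(gene="OUT", chrom="9", pos=5_000_000)
        g = {
            v_in.variant_id: dict(FX_P1="hom_alt", FX_FA="het", FX_MO="het"),
            v_out.variant_id: dict(FX_P1="hom_alt", FX_FA="het", FX_MO="het"),
        }
        roh = [ROHRegion("4", 1_000_000, 8_000_000)]
        cands = recessive_candidates(fam, [v_out, v_in], g, roh)
        assert [c.gene for c in cands] == ["IN", "OUT"]
        assert cands[0].in_roh and not cands[1].in_roh

    def test_comphet_in_trans(self):
        fam = trio()
        v1, v2 = variant(gene="G2"), variant(gene="G2")
        g = {
            v1.variant_id: dict(FX_P1="het", FX_FA="het", FX_MO="hom_ref"),
            v2.variant_id: dict(FX_P1="het", FX_FA="hom_ref", FX_MO="het"),
        }
        (cand,) = recessive_candidates(fam, [v1, v2], g)
        assert cand.mode == "AR_comphet" and not cand.unphasable

    def test_comphet_in_cis_rejected(self):
        fam = trio()
        v1, v2 = variant(gene="G2"), variant(gene="G2")
        g = {
            v1.variant_id: dict(FX_P1="het", FX_FA="hom_ref", FX_MO="het"),
            v2.variant_id: dict(FX_P1="het", FX_FA="hom_ref", FX_MO="het"),
        }
        assert recessive_candidates(fam, [v1, v2], g) == []

    def test_comphet_unphasable_retained_flagged(self):
        fam = trio()
        v1, v2 = variant(gene="G2"), variant(gene="G2")
        g = {
            v1.variant_id: dict(FX_P1="het", FX_FA="missing", FX_MO="missing"),
            v2.variant_id: dict(FX_P1="het", FX_FA="missing", FX_MO="missing"),
        }
        (cand,) = recessive_candidates(fam, [v1, v2], g)
        assert cand.unphasable

    def test_xlr_hemizygous_male(self):
        fam = trio(sex="m")
        v = variant(gene="XG", chrom="X")
        g = gts(v, FX_P1="hemi", FX_FA="hom_ref", FX_MO="het")
        (cand,) = recessive_candidates(fam, [v], g)
        assert cand.mode == "XLR"

    def test_xlr_requires_affected_male(self):
        fam = trio(sex="f")
        v = variant(gene="XG", chrom="X")
        g = gts(v, FX_P1="het", FX_FA="hom_ref", FX_MO="het")
        assert recessive_candidates(fam, [v], g) == []

    def test_hom_in_unaffected_parent_not_a_candidate(self):
        fam = trio()
        v = variant()
        g = gts(v, FX_P1="hom_alt", FX_FA="hom_alt", FX_MO="het")
        assert recessive_candidates(fam, [v], g) == []


class TestDominantCandidates:
    OMIM = frozenset({"ADGENE", "XDGENE"})

    def test_de_novo_flagged(self):
        fam = trio()
        v = variant(gene="ADGENE", omim=True)
        g = gts(v, FX_P1="het", FX_FA="hom_ref", FX_MO="hom_ref")
        (cand,) = dominant_candidates(fam, [v], g, self.OMIM)
        assert cand.mode == "AD" and cand.de_novo is True

    def test_panel_restriction(self):
        fam = trio()
        v = variant(gene="NOTINPANEL")
        g = gts(v, FX_P1="het", FX_FA="hom_ref", FX_MO="hom_ref")
        assert dominant_candidates(fam, [v], g, self.OMIM) == []

    def test_inherited_variant_retained_with_origin(self):
        fam = trio()
        v = variant(gene="ADGENE")
        g = gts(v, FX_P1="het", FX_FA="het", FX_MO="hom_ref")
        (cand,) = dominant_candidates(fam, [v], g, self.OMIM)
        assert cand.de_novo is False and cand.inherited_from == "FX_FA"

    def test_xld_de_novo_in_female(self):
        fam = trio(sex="f")
        v = variant(gene="XDGENE", chrom="X")
        g = gts(v, FX_P1="het", FX_FA="hom_ref", FX_MO="hom_ref")
        (cand,) = dominant_candidates(fam, [v], g, self.OMIM)
        assert cand.mode == "XLD" and cand.de_novo is True

    def test_missing_parents_leave_de_novo_unknown(self):
        members = (MemberSpec("FY_P1", "m", True),)
        fam = FamilySpec("FY", "B", False, 1, 1, 6, members, parents_available=False)
        v = variant(gene="ADGENE")
        g = gts(v, FY_P1="het")
        (cand,) = dominant_candidates(fam, [v], g, self.OMIM)
        assert cand.de_novo is None

    def test_strategy_a_rejected(self):
        fam = trio(strategy="A", n_affected=2)
        with pytest.raises(ValueError, match="strategy-B"):
            dominant_candidates(fam, [], {}, self.OMIM)


class TestSegregation:
    def test_ar_hom_unaffected_sib_hom_fails(self):
        fid = "FZ"
        members = (
            MemberSpec(f"{fid}_P1", "m", True, f"{fid}_FA", f"{fid}_MO"),
            MemberSpec(f"{fid}_S1", "f", False, f"{fid}_FA", f"{fid}_MO"),
            MemberSpec(f"{fid}_FA", "m", False),
            MemberSpec(f"{fid}_MO", "f", False),
        )
        fam = FamilySpec(fid, "A", True, 1, 1, 6, members)
        v = variant()
        from mitotriage import CandidateSet

        cand = CandidateSet("AR_hom", (v,), v.gene)
        ok = {v.variant_id: dict(FZ_P1="hom_alt", FZ_S1="het", FZ_FA="het", FZ_MO="het")}
        bad = {v.variant_id: dict(FZ_P1="hom_alt", FZ_S1="hom_alt", FZ_FA="het", FZ_MO="het")}
        assert segregation_check(cand, fam, ok)
        assert not segregation_check(cand, fam, bad)

    def test_ad_inherited_needs_subclinical_parent(self):
        from mitotriage import CandidateSet

        v = variant(gene="ADGENE")
        cand = CandidateSet("AD", (v,), v.gene, de_novo=False, inherited_from="FX_FA")
        g = gts(v, FX_P1="het", FX_FA="het", FX_MO="hom_ref")
        assert not segregation_check(cand, trio(), g)
        assert segregation_check(cand, trio(subclinical=True), g)


class TestDiagnosis:
    MITO = frozenset({"GENE1", "G2"})

    def test_multi_genic_family_reports_all_genes(self):
        fam = trio(strategy="A", consanguineous=True)
        v1, v2, v3 = variant(gene="GENE1"), variant(gene="G2"), variant(gene="G3")
        g = {}
        for v in (v1, v2, v3):
            g[v.variant_id] = dict(FX_P1="hom_alt", FX_FA="het", FX_MO="het")
        cands = recessive_candidates(fam, [v1, v2, v3], g)
        result = diagnose_family(fam, cands, g, self.MITO)
        assert result.solved and result.multi_genic
        assert sorted(result.genes) == ["G2", "G3", "GENE1"]
        assert dict(zip(result.genes, result.mitocarta_flags))["G3"] is False

    def test_class_three_candidate_is_vus_not_solved(self):
        fam = trio(strategy="A", consanguineous=True)
        v = variant(acmg=3)
        g = gts(v, FX_P1="hom_alt", FX_FA="het", FX_MO="het")
        cands = recessive_candidates(fam, [v], g)
        assert cands  # candidate exists ...
        assert not diagnose_family(fam, cands, g, self.MITO).solved  # ... but VUS

    def test_no_candidates_unsolved(self):
        fam = trio()
        result = diagnose_family(fam, [], {}, self.MITO)
        assert not result.solved and result.genes == ()
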