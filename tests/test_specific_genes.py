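"""Focal-unique gene calling, subpopulation partition and enrichment."""

import math

import pytest

from snpinet import (
    AnnotatedVariant,
    GeneClassification,
    VariantSite,
    classify_by_subpopulation,
    find_focal_specific_genes,
    run_specific_gene_analysis,
    term_enrichment,
)
from snpinet.alignments import GeneAlignment
from snpinet.population import SpecificGeneResult, hypergeom_enumeration_p
from snpinet.variants import PopulationCallSet


def _callset(name, sample_pops, sites_with_carriers):
    cs = PopulationCallSet(
        name=name, samples=list(sample_pops), population_of=dict(sample_pops)
    )
    for site, carriers in sites_with_carriers:
        cs.add_site(site, carriers)
    return cs


def _missense(pos, gene="G1", ppos=2, ref_aa="A", alt_aa="T", impact="MODERATE"):
    return AnnotatedVariant(
        site=VariantSite("chr1", pos, "G", "A", qual=100.0),
        effect_class="non_synonymous",
        impact=impact,
        gene_id=gene,
        protein_position=ppos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


ALN = {
    "G1": GeneAlignment(
        "G1", rows={"dog": "MAL", "cat": "MAL", "pig": "MAL"}, focal="dog"
    )
}


def _focal(carriers=("S_LT01",), pos=100):
    pops = {"S_LT01": "LT", "S_ST01": "ST", "S_NT01": "NT"}
    site = VariantSite("chr1", pos, "G", "A", qual=100.0)
    return _callset("focal", pops, [(site, carriers)])


def test_planted_unique_variant_is_called():
    av = _missense(100)
    res = find_focal_specific_genes([av], _focal(), [], ALN)
    assert res.gene_ids == {"G1"}
    assert res.genes["G1"] == [av]


def test_alt_in_comparison_breed_excludes_gene():
    av = _missense(100)
    comp = _callset(
        "breed", {"B1": "breed"},
        [(VariantSite("chr1", 100, "G", "A", qual=80.0), ["B1"])],
    )
    res = find_focal_specific_genes([av], _focal(), [comp], ALN)
    assert res.gene_ids == set()
    assert res.n_rejected["in_comparison_breed"] == 1


def test_low_impact_missense_excluded():
    av = _missense(100, impact="LOW")
    res = find_focal_specific_genes([av], _focal(), [], ALN)
    assert res.gene_ids == set()
    assert res.n_rejected["effect_or_impact"] == 1


def test_alt_residue_in_related_species_excludes_gene():
    aln = {
        "G1": GeneAlignment(
            "G1", rows={"dog": "MAL", "cat": "MTL", "pig": "MAL"}, focal="dog"
        )
    }
    res = find_focal_specific_genes([_missense(100)], _focal(), [], aln)
    assert res.gene_ids == set()
    assert res.n_rejected["in_related_species"] == 1


def test_alt_residue_in_species_snp_table_excludes_gene():
    aln = {
        "G1": GeneAlignment(
            "G1",
            rows={"dog": "MAL", "cat": "MAL"},
            focal="dog",
            alt_residues={("cat", 2): {"T"}},
        )
    }
    res = find_focal_specific_genes([_missense(100)], _focal(), [], aln)
    assert res.gene_ids == set()


def test_gap_column_makes_species_non_informative():
    aln = {
        "G1": GeneAlignment(
            "G1", rows={"dog": "MAL", "cat": "M-L"}, focal="dog"
        )
    }
    res = find_focal_specific_genes([_missense(100)], _focal(), [], aln)
    assert res.gene_ids == {"G1"}


def test_gene_without_alignment_is_unevaluable():
    res = find_focal_specific_genes([_missense(100)], _focal(), [], {})
    assert res.gene_ids == set()
    assert res.unevaluable_genes == {"G1"}


# -- subpopulation classification -------------------------------------


def _specific(genes):
    res = SpecificGeneResult()
    res.genes = genes
    return res


POPS = {
    "S_LT01": "LT", "S_LT02": "LT", "S_ST01": "ST",
    "S_NT01": "NT", "S_NT02": "NT",
}


def _focal_multi(sites_with_carriers):
    return _callset("focal", POPS, sites_with_carriers)


def test_tail_only_carriers_give_tail_specific():
    av = _missense(100)
    focal = _focal_multi([(av.site, ["S_LT01", "S_LT02"])])
    cls = classify_by_subpopulation(_specific({"G1": [av]}), focal)
    assert cls.tail_specific == {"G1"}
    assert not cls.common and not cls.non_tail_specific


def test_st_and_nt_variants_give_common():
    av1, av2 = _missense(100), _missense(200, ppos=3, ref_aa="L", alt_aa="V")
    focal = _focal_multi([(av1.site, ["S_ST01"]), (av2.site, ["S_NT01"])])
    cls = classify_by_subpopulation(_specific({"G1": [av1, av2]}), focal)
    assert cls.common == {"G1"}


def test_nt_only_carriers_give_non_tail_specific():
    av = _missense(100)
    focal = _focal_multi([(av.site, ["S_NT01", "S_NT02"])])
    cls = classify_by_subpopulation(_specific({"G1": [av]}), focal)
    assert cls.non_tail_specific == {"G1"}


def test_zero_carrier_supporting_variant_is_inconsistent():
    av = _missense(100)
    focal = _focal_multi([(av.site, [])])
    with pytest.raises(ValueError, match="no focal carriers"):
        classify_by_subpopulation(_specific({"G1": [av]}), focal)


def test_classification_sets_must_be_disjoint():
    with pytest.raises(ValueError, match="overlap"):
        GeneClassification(
            focal_specific={"G1", "G2"},
            tail_specific={"G1"},
            non_tail_specific={"G1"},
            common=set(),
        )


# -- end-to-end on the synthetic cohort --------------------------------


def test_each_decoy_type_is_excluded(cohort_sim, cohort_bundle):
    analysis = run_specific_gene_analysis(cohort_bundle)
    called = analysis.classification.focal_specific
    for gene, decoy_type in cohort_sim.truth.decoy_types.items():
        assert gene not in called, (gene, decoy_type)
    rejected = analysis.specific.n_rejected
    assert rejected["effect_or_impact"] >= 1  # low-impact decoys
    assert rejected["in_comparison_breed"] >= 1
    assert rejected["in_related_species"] >= 1


def test_partition_is_exhaustive_and_disjoint(cohort_bundle):
    analysis = run_specific_gene_analysis(cohort_bundle)
    cls = analysis.classification
    union = cls.tail_specific | cls.non_tail_specific | cls.common
    assert union == cls.focal_specific
    assert len(cls.tail_specific) + len(cls.non_tail_specific) + len(cls.common) == len(union)


# -- term enrichment ---------------------------------------------------


def test_foreground_equals_background_gives_p_one():
    genes = {f"G{i}" for i in range(8)}
    table = term_enrichment(genes, genes, {"T1": {"G0", "G1"}})
    assert table["raw_p"].iloc[0] == pytest.approx(1.0)


def test_closed_form_hypergeometric():
    background = {f"G{i}" for i in range(20)}
    term = {f"G{i}" for i in range(5)}
    table = term_enrichment(term, background, {"T1": term})
    assert table["raw_p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)


def test_bonferroni_arithmetic():
    background = {f"G{i}" for i in range(40)}
    terms = {f"T{i}": {f"G{j}" for j in range(i, i + 8)} for i in range(10)}
    table = term_enrichment({"G0", "G1", "G2"}, background, terms, alpha=0.05)
    expected = (table["raw_p"] * 10).clip(upper=1.0)
    assert (table["adj_p"] == expected).all()


def test_enrichment_input_validation():
    with pytest.raises(ValueError, match="background"):
        term_enrichment(set(), set(), {})
    with pytest.raises(ValueError, match="subset"):
        term_enrichment({"A"}, {"B"}, {})


def test_hypergeometric_matches_enumeration_small_backgrounds():
    from scipy.stats import hypergeom

    for N in range(2, 13):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    exact = hypergeom_enumeration_p(k, N, K, n)
                    sf = float(hypergeom.sf(k - 1, N, K, n))
                    assert sf == pytest.approx(exact, rel=1e-10, abs=1e-12)
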