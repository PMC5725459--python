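"""Hard filtering, codon-level effect classification, Ti/Tv and the
category table."""

import numpy as np
import pytest

from snpinet import (
    FilterThresholds,
    GeneModel,
    VariantSite,
    AnnotatedVariant,
    annotate_sites,
    classify_coding_effect,
    default_impact,
    hard_filter,
    tabulate_categories,
    ti_tv_ratio,
)


def _v(qual=100.0, qd=20.0, mq=55.0, fs=5.0, pos=100, ref="A", alt="G"):
    return VariantSite("chr1", pos, ref, alt, qual=qual, qd=qd, mq=mq, fs=fs)


# -- hard filter -------------------------------------------------------


def test_hard_filter_removes_low_qd_and_tallies():
    retained, tally = hard_filter([_v(qd=4.0), _v(pos=101)])
    assert len(retained) == 1
    assert tally.qd == 1 and tally.removed == 1 and tally.retained == 1


def test_hard_filter_boundaries_are_strict():
    boundary = _v(qd=5.0, mq=40.0, fs=200.0, qual=30.0)
    retained, tally = hard_filter([boundary])
    assert retained == [boundary]
    assert tally.removed == 0
    removed, tally2 = hard_filter([_v(qd=4.999)])
    assert removed == [] and tally2.qd == 1


def test_hard_filter_missing_stat_does_not_fire():
    v = VariantSite("chr1", 5, "A", "G", qual=100.0)  # no QD/MQ/FS
    retained, tally = hard_filter([v])
    assert retained == [v]
    assert (tally.qd, tally.mq, tally.fs) == (0, 0, 0)


def test_hard_filter_one_violation_each_clause():
    variants = (
        [_v(pos=i, qd=4.0) for i in range(3)]
        + [_v(pos=10 + i, mq=39.0) for i in range(3)]
        + [_v(pos=20 + i, fs=201.0) for i in range(3)]
        + [_v(pos=30 + i) for i in range(7)]
    )
    retained, tally = hard_filter(variants)
    assert len(retained) == 7
    assert (tally.qd, tally.mq, tally.fs, tally.qual) == (3, 3, 3, 0)


def test_hard_filter_order_independent():
    rng = np.random.default_rng(0)
    variants = [_v(pos=i, qd=float(rng.uniform(0, 10))) for i in range(40)]
    base, _ = hard_filter(variants)
    for _ in range(5):
        perm = list(variants)
        rng.shuffle(perm)
        shuffled, _ = hard_filter(perm)
        assert {v.key for v in shuffled} == {v.key for v in base}


def test_hard_filter_empty_input():
    retained, tally = hard_filter([])
    assert retained == [] and tally.removed == 0


def test_custom_thresholds():
    retained, _ = hard_filter([_v(qd=6.0)], FilterThresholds(qd=7.0))
    assert retained == []


# -- codon classification ----------------------------------------------

# single-exon plus-strand gene: CDS = ATG GCA CCT CTG (M A P L)
GENE_PLUS = GeneModel("Gp", "chr1", "+", ((101, 112),), 0, "Gp_P",
                      utrs=((71, 100), (113, 142)))
CDS = "ATGGCACCTCTG"


def test_ala_to_thr_missense():
    # codon GCA, G->A at codon position 1: ACA, Ala -> Thr
    v = VariantSite("chr1", 104, "G", "A")
    eff = classify_coding_effect(v, GENE_PLUS, CDS)
    assert eff == ("non_synonymous", "A", "T", 2)
    assert default_impact(eff) == "MODERATE"


def test_pro_to_ala_missense():
    # codon CCT, C->G at codon position 1: GCT, Pro -> Ala
    v = VariantSite("chr1", 107, "C", "G")
    eff = classify_coding_effect(v, GENE_PLUS, CDS)
    assert eff == ("non_synonymous", "P", "A", 3)


def test_third_position_synonymous():
    # codon CTG, G->A at position 3: CTA, Leu -> Leu
    v = VariantSite("chr1", 112, "G", "A")
    eff = classify_coding_effect(v, GENE_PLUS, CDS)
    assert eff.effect_class == "synonymous"
    assert eff.ref_aa == eff.alt_aa == "L"
    assert default_impact(eff) == "LOW"


def test_minus_strand_complements_before_substitution():
    # same CDS on the minus strand: genome shows the reverse complement,
    # so the GCA codon's G sits at genomic position 109 as base C
    gene = GeneModel("Gm", "chr1", "-", ((101, 112),), 0, "Gm_P")
    assert gene.genomic_to_cds_index(109) == 3
    v = VariantSite("chr1", 109, "C", "T")  # complement of G->A
    eff = classify_coding_effect(v, gene, CDS)
    assert eff == ("non_synonymous", "A", "T", 2)


def test_stop_gain_is_high_impact():
    # CTG -> TAG would need two changes; use TGG->TGA style: place codon TGG
    gene = GeneModel("Gs", "chr1", "+", ((11, 16),), 0)
    v = VariantSite("chr1", 16, "G", "A")  # TGG -> TGA = stop
    eff = classify_coding_effect(v, gene, "ATGTGG")
    assert eff.effect_class == "non_synonymous"
    assert eff.alt_aa == "*"
    assert default_impact(eff) == "HIGH"


def test_reference_mismatch_raises():
    v = VariantSite("chr1", 104, "C", "A")  # CDS has G at that spot
    with pytest.raises(ValueError, match="inconsistent"):
        classify_coding_effect(v, GENE_PLUS, CDS)


@pytest.mark.parametrize(
    "pos,expected",
    [
        (95, "UTR"),  # 5' UTR interval
        (130, "UTR"),  # 3' UTR interval
        (300, "intergenic"),
    ],
)
def test_noncoding_regions(pos, expected):
    v = VariantSite("chr1", pos, "A", "G")
    assert classify_coding_effect(v, GENE_PLUS, CDS).effect_class == expected


def test_splice_site_within_two_bp_of_exon_boundary():
    gene = GeneModel("Gi", "chr1", "+", ((101, 106), (201, 206)), 0)
    cds = "ATGGCACCTCTG"
    for pos, expected in [(107, "splice_site"), (108, "splice_site"),
                          (109, "intron"), (199, "splice_site"),
                          (150, "intron")]:
        v = VariantSite("chr1", pos, "A", "G")
        assert classify_coding_effect(v, gene, cds).effect_class == expected, pos


# -- category table ----------------------------------------------------


def _annotated(effect, impact="MODIFIER", **kw):
    return AnnotatedVariant(site=_v(**kw), effect_class=effect, impact=impact)


def test_uniform_toy_fractions():
    avs = [
        AnnotatedVariant(site=_v(pos=1), effect_class="non_synonymous",
                         impact="MODERATE", gene_id="G", protein_position=1,
                         ref_aa="A", alt_aa="T"),
        _annotated("splice_site", pos=2),
        _annotated("intron", pos=3),
        _annotated("intergenic", pos=4),
    ]
    table = tabulate_categories(avs)
    present = table[table["count"] > 0]
    assert (present["fraction"] == 0.25).all()
    assert table["fraction"].sum() == pytest.approx(1.0, abs=1e-12)


def test_empty_input_all_zero():
    table = tabulate_categories([])
    assert (table["count"] == 0).all()
    assert (table["fraction"] == 0.0).all()


def test_multi_gene_precedence_utr_over_intron():
    # site inside gene A's intron and gene B's UTR: counted as UTR
    gene_a = GeneModel("A", "chr1", "+", ((100, 111), (300, 311)), 0)
    gene_b = GeneModel("B", "chr1", "+", ((230, 241),), 0,
                       utrs=((200, 229), (242, 271)))
    cds = {"A": "ATGGCACCTCTGATGGCACCTCTG", "B": "ATGGCACCTCTG"}
    site = VariantSite("chr1", 210, "A", "G", qual=100.0)
    [av] = annotate_sites([site], [gene_a, gene_b], cds)
    assert av.effect_class == "UTR"
    assert av.gene_id == "B"


def test_precedence_matches_exhaustive_rank_oracle():
    """annotate_sites must always pick the most severe per-gene label;
    verify against a brute-force ranking of every per-gene effect."""
    order = ["non_synonymous", "synonymous", "splice_site", "UTR", "intron",
             "intergenic"]
    gene_a = GeneModel("A", "chr1", "+", ((100, 111), (300, 311)), 0,
                       utrs=((70, 99), (312, 341)))
    gene_b = GeneModel("B", "chr1", "+", ((230, 241),), 0,
                       utrs=((200, 229), (242, 271)))
    genes = [gene_a, gene_b]
    cds = {"A": "ATGGCACCTCTGATGGCACCTCTG", "B": "ATGGCACCTCTG"}
    for pos in range(60, 360, 7):
        site = VariantSite("chr1", pos, "A", "G", qual=100.0)
        try:
            [av] = annotate_sites([site], genes, cds)
        except ValueError:
            continue  # ref inconsistent with CDS at exonic spots; fine here
        per_gene = []
        for g in genes:
            try:
                per_gene.append(
                    classify_coding_effect(site, g, cds[g.gene_id]).effect_class
                )
            except ValueError:
                pass
        if per_gene:
            assert order.index(av.effect_class) == min(
                order.index(e) for e in per_gene
            )


# -- Ti/Tv -------------------------------------------------------------


def test_ti_tv_definition():
    pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]
    variants = [VariantSite("chr1", i + 1, r, a) for i, (r, a) in enumerate(pairs)]
    assert ti_tv_ratio(variants) == pytest.approx(2.0)


def test_ti_tv_single_transversion_is_zero():
    assert ti_tv_ratio([VariantSite("chr1", 1, "A", "C")]) == 0.0


def test_ti_tv_no_transversions_raises():
    with pytest.raises(ZeroDivisionError):
        ti_tv_ratio([VariantSite("chr1", 1, "A", "G")])
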