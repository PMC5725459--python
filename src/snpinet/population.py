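"""Population-level variant analysis.

This module carries the core screen of the pipeline: hard-filter the
SNP calls, classify effects and tabulate categories, compute Ti/Tv,
call genes whose high/moderate-impact missense alleles occur *only* in
the focal population (checked against comparison-breed call sets at the
same genomic position and against related-species residues at the
orthologous alignment column), partition those genes by the
subpopulation of their carriers (tail vs non-tail), and run a
hypergeometric term over-representation test with Bonferroni control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .alignments import GeneAlignment
from .config import FilterThresholds
from .genes import EFFECT_PRECEDENCE, GeneModel
from .variants import AnnotatedVariant, PopulationCallSet, VariantSite

logger = logging.getLogger(__name__)


# -- hard filtering ----------------------------------------------------


@dataclass
class FilterTally:
    """Per-clause removal counts.  A variant failing several clauses
    increments each of them; ``removed`` counts it once."""

    qd: int = 0
    mq: int = 0
    fs: int = 0
    qual: int = 0
    removed: int = 0
    retained: int = 0


def hard_filter(
    variants: Iterable[VariantSite],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantSite], FilterTally]:
    """Remove variants failing any hard-filter clause.

    A variant is removed iff QD < qd OR MQ < mq OR FS > fs OR
    QUAL < qual, all strict; a missing statistic never fires its clause.
    """
    thr = thresholds or FilterThresholds()
    tally = FilterTally()
    retained: list[VariantSite] = []
    for v in variants:
        fails = False
        if v.qd is not None and v.qd < thr.qd:
            tally.qd += 1
            fails = True
        if v.mq is not None and v.mq < thr.mq:
            tally.mq += 1
            fails = True
        if v.fs is not None and v.fs > thr.fs:
            tally.fs += 1
            fails = True
        if v.qual is not None and v.qual < thr.qual:
            tally.qual += 1
            fails = True
        if fails:
            tally.removed += 1
        else:
            tally.retained += 1
            retained.append(v)
    return retained, tally


# -- Ti/Tv and category accounting ------------------------------------

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ti_tv_ratio(variants: Sequence[VariantSite | AnnotatedVariant]) -> float:
    """Transition / transversion count ratio over ref->alt pairs.

    Computed without strand folding (A->G and T->C are both
    transitions).  Raises when the set contains no transversion.
    """
    ti = tv = 0
    for v in variants:
        site = v.site if isinstance(v, AnnotatedVariant) else v
        if (site.ref, site.alt) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        raise ZeroDivisionError("Ti/Tv undefined: no transversions in input")
    return ti / tv


def classify_region_multi(site: VariantSite, genes: Sequence[GeneModel]) -> str:
    """Region label for a site possibly overlapping several genes,
    resolved by severity precedence (exonic > splice > UTR > intron >
    intergenic).  Exonic labels still need codon classification; this
    returns 'exon' in that case."""
    order = ("exon", "splice_site", "UTR", "intron", "intergenic")
    best = "intergenic"
    for g in genes:
        if g.chrom != site.chrom:
            continue
        region = g.region_of(site.pos)
        if order.index(region) < order.index(best):
            best = region
    return best


def tabulate_categories(variants: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    """Count and fraction per effect category, fixed row order.

    Fractions sum to 1 (empty input reports all-zero fractions).
    """
    counts = {c: 0 for c in EFFECT_PRECEDENCE}
    for v in variants:
        counts[v.effect_class] += 1
    total = sum(counts.values())
    rows = [
        {
            "category": c,
            "count": counts[c],
            "fraction": counts[c] / total if total else 0.0,
        }
        for c in EFFECT_PRECEDENCE
    ]
    return pd.DataFrame(rows)


# -- focal-population-specific genes ----------------------------------


@dataclass
class SpecificGeneResult:
    """Genes with >= 1 focal-unique missense variant, with support."""

    genes: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    unevaluable_genes: set[str] = field(default_factory=set)
    n_rejected: dict[str, int] = field(default_factory=dict)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)


def _is_focal_unique(
    variant: AnnotatedVariant,
    focal: PopulationCallSet,
    comparisons: Sequence[PopulationCallSet],
    alignment: GeneAlignment,
    rejections: dict[str, int],
) -> bool:
    key = variant.key
    if variant.effect_class != "non_synonymous" or variant.impact not in (
        "HIGH",
        "MODERATE",
    ):
        rejections["effect_or_impact"] = rejections.get("effect_or_impact", 0) + 1
        return False
    if not focal.has_alt(key):
        rejections["no_focal_carrier"] = rejections.get("no_focal_carrier", 0) + 1
        return False
    for comp in comparisons:
        if comp.has_alt(key):
            rejections["in_comparison_breed"] = (
                rejections.get("in_comparison_breed", 0) + 1
            )
            return False
    column = alignment.column_of(variant.protein_position)
    for species in alignment.species:
        # gap columns leave the species non-informative
        if alignment.shows_residue(species, column, variant.alt_aa):
            rejections["in_related_species"] = (
                rejections.get("in_related_species", 0) + 1
            )
            return False
    return True


def find_focal_specific_genes(
    annotated_variants: Sequence[AnnotatedVariant],
    focal: PopulationCallSet,
    comparisons: Sequence[PopulationCallSet],
    alignments: Mapping[str, GeneAlignment],
) -> SpecificGeneResult:
    """Call genes carrying focal-population-unique missense alleles.

    A variant is focal-unique iff it is (a) non-synonymous with HIGH or
    MODERATE impact, (b) carried by >= 1 focal individual, (c) its alt
    allele is absent from every comparison call set at the same
    chrom:pos, and (d) its alternative residue is shown by no related
    species at the orthologous alignment column.  A gene is
    focal-specific iff it has >= 1 focal-unique variant; a gene with
    candidate variants but no alignment is flagged unevaluable and
    excluded.
    """
    result = SpecificGeneResult()
    for v in annotated_variants:
        if v.gene_id is None:
            continue
        if v.effect_class == "non_synonymous" and v.gene_id not in alignments:
            result.unevaluable_genes.add(v.gene_id)
            logger.warning("gene %s has no alignment; excluded as unevaluable", v.gene_id)
            continue
        if v.effect_class != "non_synonymous":
            continue
        if _is_focal_unique(v, focal, comparisons, alignments[v.gene_id], result.n_rejected):
            result.genes.setdefault(v.gene_id, []).append(v)
    result.genes = {g: vs for g, vs in result.genes.items() if g not in result.unevaluable_genes}
    return result


# -- subpopulation classification -------------------------------------


@dataclass
class GeneClassification:
    """Partition of the focal-specific genes by carrier subpopulation."""

    focal_specific: set[str]
    tail_specific: set[str]
    non_tail_specific: set[str]
    common: set[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sets = [self.tail_specific, self.non_tail_specific, self.common]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"classification sets overlap: {sorted(overlap)}")
            if not sets[i] <= self.focal_specific:
                raise ValueError("classified gene outside focal-specific set")


#: Default mapping from fine subpopulation labels to the tail/non-tail
#: dichotomy used for classification.
TAIL_GROUPS = {"LT": "tail", "ST": "tail", "NT": "non_tail"}


def classify_by_subpopulation(
    specific: SpecificGeneResult,
    focal: PopulationCallSet,
    tail_group_of: Mapping[str, str] | None = None,
) -> GeneClassification:
    """Split focal-specific genes into tail-specific, non-tail-specific
    and common sets by which subpopulations carry their unique alleles.

    A gene is tail-specific when all carriers of all its focal-unique
    variants are tail (long- or short-tail) individuals, non-tail-
    specific when all are non-tail, and common when both groups carry
    at least one of its variants.  A supporting variant with zero focal
    carriers contradicts focal-uniqueness and raises.
    """
    groups = tail_group_of or TAIL_GROUPS
    tail: set[str] = set()
    non_tail: set[str] = set()
    common: set[str] = set()
    for gene, variants in specific.genes.items():
        carried_groups: set[str] = set()
        for v in variants:
            carriers = focal.carriers_of(v.key)
            if not carriers:
                raise ValueError(
                    f"{gene} variant {v.key} has no focal carriers but was "
                    "called focal-unique"
                )
            for s in carriers:
                carried_groups.add(groups[focal.population_of[s]])
        if carried_groups == {"tail"}:
            tail.add(gene)
        elif carried_groups == {"non_tail"}:
            non_tail.add(gene)
        else:
            common.add(gene)
    return GeneClassification(
        focal_specific=specific.gene_ids,
        tail_specific=tail,
        non_tail_specific=non_tail,
        common=common,
    )


# -- term enrichment ---------------------------------------------------


def term_enrichment(
    foreground: set[str],
    background: set[str],
    term_map: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term, with
    Bonferroni adjustment over the number of tested terms.

    Columns: term, k (foreground hits), K (background term size),
    n (foreground size), N (background size), raw_p, adj_p, enriched.
    """
    if not background:
        raise ValueError("empty background gene set")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    N, n = len(background), len(foreground)
    n_terms = len(term_map)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & background
        K = len(members)
        k = len(members & foreground)
        raw_p = float(hypergeom.sf(k - 1, N, K, n))
        adj_p = min(1.0, raw_p * n_terms)
        rows.append(
            {
                "term": term,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "raw_p": raw_p,
                "adj_p": adj_p,
                "enriched": adj_p < alpha,
            }
        )
    return pd.DataFrame(rows)


def hypergeom_enumeration_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) by direct enumeration of
    counting outcomes; independent cross-check for small backgrounds."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total
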