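"""End-to-end orchestration.

Thin glue that loads a cohort bundle (generated or on disk), runs the
hard filter, annotates variants with the codon classifier (keeping any
externally supplied impact, as an effect-annotation tool would emit),
calls focal-specific genes, partitions them by subpopulation and, for
the interaction side, builds profiles, reconstructs ancestral states
and summarizes branch changes with randomization p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alignments import GeneAlignment, read_alignment_dir
from .config import RunConfig
from .evolution import (
    FitchResult,
    InteractionProfile,
    OrthologMap,
    PairKey,
    branch_change_summary,
    build_profiles,
    fitch_reconstruct,
    randomization_test,
    BranchChangeSummary,
)
from .genes import GeneModel, classify_coding_effect, default_impact, read_gene_models
from .networks import ScoredNetwork, read_edge_list
from .population import (
    GeneClassification,
    SpecificGeneResult,
    classify_by_subpopulation,
    find_focal_specific_genes,
    hard_filter,
)
from .trees import SpeciesTree
from .variants import (
    AnnotatedVariant,
    PopulationCallSet,
    SiteKey,
    VariantSite,
    read_vcf_cohort,
)


@dataclass
class CohortBundle:
    """A loaded cohort: call sets plus annotation resources."""

    focal: PopulationCallSet
    comparisons: list[PopulationCallSet]
    genes: list[GeneModel]
    cds: dict[str, str]
    alignments: dict[str, GeneAlignment]
    impact_overrides: dict[SiteKey, str]


def load_cohort(directory: str | Path) -> CohortBundle:
    """Read a cohort bundle written by :meth:`SimulatedCohort.write`."""
    directory = Path(directory)
    labels: dict[str, str] = {}
    with open(directory / "focal_samples.tsv") as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                sample, pop = line.rstrip("\n").split("\t")
                labels[sample] = pop
    focal = read_vcf_cohort(directory / "focal.vcf", labels, name="focal")
    comparisons = []
    for vcf_path in sorted((directory / "breeds").glob("*.vcf")):
        breed = vcf_path.stem
        # every breed sample belongs to that breed's population
        from cyvcf2 import VCF

        breed_labels = {s: breed for s in VCF(str(vcf_path)).samples}
        comparisons.append(read_vcf_cohort(vcf_path, breed_labels, name=breed))
    genes = read_gene_models(directory / "gene_models.tsv")
    cds: dict[str, str] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(directory / "cds.fasta"), "fasta"):
        cds[rec.id] = str(rec.seq)
    alignments = read_alignment_dir(directory / "alignments")
    impact_overrides = _read_impact_overrides(directory / "annotations.tsv")
    return CohortBundle(
        focal=focal,
        comparisons=comparisons,
        genes=genes,
        cds=cds,
        alignments=alignments,
        impact_overrides=impact_overrides,
    )


def _read_impact_overrides(path: Path) -> dict[SiteKey, str]:
    overrides: dict[SiteKey, str] = {}
    if not path.exists():
        return overrides
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            key = (
                fields[col["chrom"]],
                int(fields[col["pos"]]),
                fields[col["ref"]],
                fields[col["alt"]],
            )
            overrides[key] = fields[col["impact"]]
    return overrides


def annotate_sites(
    sites: Sequence[VariantSite],
    genes: Sequence[GeneModel],
    cds: Mapping[str, str],
    impact_overrides: Mapping[SiteKey, str] | None = None,
) -> list[AnnotatedVariant]:
    """Classify each site against the gene models.

    The best (most severe) effect over all overlapping genes wins.  An
    impact override — e.g. from an external annotation tool — replaces
    the classifier's default severity mapping for that site.
    """
    impact_overrides = impact_overrides or {}
    order = ("non_synonymous", "synonymous", "splice_site", "UTR", "intron",
             "intergenic")
    annotated: list[AnnotatedVariant] = []
    for site in sites:
        best: tuple[int, AnnotatedVariant] | None = None
        for gene in genes:
            if gene.chrom != site.chrom:
                continue
            effect = classify_coding_effect(site, gene, cds[gene.gene_id])
            impact = impact_overrides.get(site.key, default_impact(effect))
            in_gene = effect.effect_class != "intergenic"
            av = AnnotatedVariant(
                site=site,
                effect_class=effect.effect_class,
                impact=impact,
                gene_id=gene.gene_id if in_gene else None,
                protein_position=effect.protein_position,
                ref_aa=effect.ref_aa,
                alt_aa=effect.alt_aa,
            )
            rank = order.index(effect.effect_class)
            if best is None or rank < best[0]:
                best = (rank, av)
        if best is None:
            best = (
                len(order),
                AnnotatedVariant(site=site, effect_class="intergenic",
                                 impact="MODIFIER"),
            )
        annotated.append(best[1])
    return annotated


@dataclass
class SpecificGeneAnalysis:
    annotated: list[AnnotatedVariant]
    filter_tally: object
    specific: SpecificGeneResult
    classification: GeneClassification


def run_specific_gene_analysis(
    bundle: CohortBundle, config: RunConfig | None = None
) -> SpecificGeneAnalysis:
    """Hard-filter the focal calls, annotate them, call focal-specific
    genes against the comparison panel and alignments, and partition
    them by carrier subpopulation."""
    config = config or RunConfig()
    retained, tally = hard_filter(bundle.focal.sites, config.filter_thresholds)
    annotated = annotate_sites(
        retained, bundle.genes, bundle.cds, bundle.impact_overrides
    )
    specific = find_focal_specific_genes(
        annotated, bundle.focal, bundle.comparisons, bundle.alignments
    )
    classification = classify_by_subpopulation(specific, bundle.focal)
    return SpecificGeneAnalysis(
        annotated=annotated,
        filter_tally=tally,
        specific=specific,
        classification=classification,
    )


# -- interaction evolution side ---------------------------------------


@dataclass
class EvolutionAnalysis:
    profiles: dict[PairKey, InteractionProfile]
    reconstructions: dict[PairKey, FitchResult]
    summary: BranchChangeSummary


def run_evolution_analysis(
    pairs: Sequence[PairKey],
    tree: SpeciesTree,
    ortholog_map: OrthologMap,
    species_networks: Mapping[str, ScoredNetwork],
    species: Sequence[str],
    observed_pairs: Sequence[PairKey] | None = None,
    config: RunConfig | None = None,
    outgroup: str = "mouse",
    rng: np.random.Generator | int | None = None,
) -> EvolutionAnalysis:
    """Profile pairs across species, reconstruct ancestral states and
    summarize per-branch changes; when ``observed_pairs`` is given the
    summary and randomization test are restricted to that set against
    the full profiled universe."""
    config = config or RunConfig()
    profiles = build_profiles(
        pairs,
        species=[s for s in species if s != "dog"],
        ortholog_map=ortholog_map,
        species_networks=species_networks,
        focal_network=species_networks["dog"],
        min_score=config.string_score_threshold,
    )
    reconstructions = {
        pair: fitch_reconstruct(tree, prof.states, outgroup=outgroup)
        for pair, prof in profiles.items()
    }
    observed = [tuple(sorted(p)) for p in (observed_pairs or pairs)]
    observed_recon = {p: reconstructions[p] for p in observed}
    summary = branch_change_summary(tree, observed_recon)
    summary.randomization_p = randomization_test(
        observed,
        reconstructions,
        tree,
        n_randomizations=config.n_randomizations,
        rng=rng if rng is not None else config.rng_seed,
    )
    return EvolutionAnalysis(
        profiles=profiles, reconstructions=reconstructions, summary=summary
    )


def load_history(directory: str | Path):
    """Read a history bundle written by :meth:`SimulatedHistory.write`;
    returns (tree, pairs, species_networks, ortholog_map)."""
    directory = Path(directory)
    tree = SpeciesTree.read(directory / "species_tree.nwk")
    pairs: list[PairKey] = []
    with open(directory / "pairs.tsv") as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                a, b = line.rstrip("\n").split("\t")
                pairs.append((a, b))
    networks = {}
    for path in sorted(directory.glob("network_*.tsv")):
        networks[path.stem.removeprefix("network_")] = read_edge_list(path)
    omap = OrthologMap.read_tsv(directory / "orthologs.tsv")
    return tree, pairs, networks, omap
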