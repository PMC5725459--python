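"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here: multi-sample
VCFs for a focal dog cohort split into long-tail / short-tail /
non-tail subpopulations and for a panel of comparison breeds, gene
models with coding sequences, per-gene cross-species protein
alignments, STRING-like scored networks, ortholog tables and simulated
interaction histories on a species tree.  Generators plant a known
truth (focal-unique missense genes with a chosen subpopulation
partition; an excess of interaction gains on one branch) so each
downstream stage can be scored for exact recovery.

All randomness flows from one integer seed through a splittable
``numpy.random.SeedSequence``; the per-component child seeds are
recorded in the returned objects so any file can be regenerated.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .alignments import GeneAlignment, write_alignment_fasta, write_alt_residues
from .evolution import ABSENT, PRESENT, UNKNOWN, OrthologMap, PairKey
from .genes import (
    COMPLEMENT,
    CodingEffect,
    GeneModel,
    classify_coding_effect,
    default_impact,
    write_gene_models,
)
from .networks import ScoredNetwork
from .trees import SpeciesTree, default_species_tree
from .variants import AnnotatedVariant, SiteKey, VariantSite, write_vcf

BASES = ("A", "C", "G", "T")
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Comparison breed panel with per-breed sample counts (the 12-breed
#: panel used for the uniqueness screen, with its published sizes).
DEFAULT_BREED_PANEL: dict[str, int] = {
    "diqing_village": 10,
    "german_shepherd": 10,
    "kunming": 10,
    "lijiang_village": 10,
    "tibetan_mastiff": 10,
    "yingjiang_village": 10,
    "indian_village": 3,
    "lebanon_village": 1,
    "modern_european": 1,
    "namibia_village": 1,
    "portugal_village": 2,
    "vietnam_village": 2,
}

DEFAULT_RELATED_SPECIES = ("cat", "cow", "horse", "human", "mouse", "pig")

DECOY_TYPES = ("synonymous", "low_impact", "in_breed", "in_species")


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults mirror the focal study design: 7 long-tail, 5 short-tail
    and 10 non-tail individuals, a 12-breed comparison panel, six
    related species, and a target Ti/Tv of 2.05 for background sites.
    ``fraction_focal_unique_missense`` is the fraction of genes that
    receive a planted focal-unique missense SNP; every remaining gene
    becomes a decoy violating exactly one uniqueness condition.
    """

    n_long_tail: int = 7
    n_short_tail: int = 5
    n_non_tail: int = 10
    comparison_breeds: tuple[tuple[str, int], ...] = tuple(DEFAULT_BREED_PANEL.items())
    related_species: tuple[str, ...] = DEFAULT_RELATED_SPECIES
    n_genes: int = 60
    n_sites_per_gene: int = 4
    fraction_focal_unique_missense: float = 10 / 60
    ti_tv_target: float = 2.05
    n_lowqual_sites: int = 8
    #: relative sizes of the planted tail / non-tail / common classes
    subpop_class_weights: tuple[float, float, float] = (39.0, 20.0, 98.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_long_tail", "n_short_tail", "n_non_tail", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(size <= 0 for _, size in self.comparison_breeds):
            raise ValueError("breed sizes must be positive")
        if not 0.0 <= self.fraction_focal_unique_missense <= 1.0:
            raise ValueError("fraction_focal_unique_missense must be in [0, 1]")
        if self.n_planted_genes > self.n_genes:
            raise ValueError("more planted genes than genes")

    @property
    def n_planted_genes(self) -> int:
        return round(self.fraction_focal_unique_missense * self.n_genes)

    @property
    def focal_samples(self) -> dict[str, str]:
        samples: dict[str, str] = {}
        for i in range(self.n_long_tail):
            samples[f"S_LT{i + 1:02d}"] = "LT"
        for i in range(self.n_short_tail):
            samples[f"S_ST{i + 1:02d}"] = "ST"
        for i in range(self.n_non_tail):
            samples[f"S_NT{i + 1:02d}"] = "NT"
        return samples


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators for recovery tests."""

    focal_specific_genes: set[str] = field(default_factory=set)
    tail_specific: set[str] = field(default_factory=set)
    non_tail_specific: set[str] = field(default_factory=set)
    common: set[str] = field(default_factory=set)
    decoy_types: dict[str, str] = field(default_factory=dict)
    planted_gain_branch: str | None = None
    planted_pairs: list[PairKey] = field(default_factory=list)
    true_node_states: dict[PairKey, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        classed = [self.tail_specific, self.non_tail_specific, self.common]
        for i in range(3):
            for j in range(i + 1, 3):
                if classed[i] & classed[j]:
                    raise ValueError("planted class sets overlap")
            if not classed[i] <= self.focal_specific_genes:
                raise ValueError("planted class outside focal-specific set")

    def write_json(self, path: str | Path) -> None:
        data = {
            "focal_specific_genes": sorted(self.focal_specific_genes),
            "tail_specific": sorted(self.tail_specific),
            "non_tail_specific": sorted(self.non_tail_specific),
            "common": sorted(self.common),
            "decoy_types": dict(sorted(self.decoy_types.items())),
            "planted_gain_branch": self.planted_gain_branch,
            "planted_pairs": [list(p) for p in self.planted_pairs],
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


# -- substitution sampling --------------------------------------------


def sample_substitution(
    rng: np.random.Generator, ti_tv_target: float, ref: str | None = None
) -> tuple[str, str]:
    """Draw a ref -> alt substitution whose long-run Ti/Tv matches the
    target: each site is a transition with probability t / (1 + t)."""
    if ref is None:
        ref = BASES[rng.integers(4)]
    p_ti = ti_tv_target / (1.0 + ti_tv_target)
    if rng.random() < p_ti:
        return ref, TRANSITION_OF[ref]
    choices = [b for b in BASES if b != ref and b != TRANSITION_OF[ref]]
    return ref, choices[rng.integers(2)]


# -- gene construction -------------------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    non_stop = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in STOP_CODONS
    ]
    codons.append("ATG")
    for _ in range(n_codons - 1):
        codons.append(non_stop[rng.integers(len(non_stop))])
    return "".join(codons)


def _build_gene(
    rng: np.random.Generator, index: int, cursor: int
) -> tuple[GeneModel, str, int]:
    """One gene model plus its CDS; returns the advanced genome cursor."""
    gene_id = f"GENE{index + 1:04d}"
    n_codons = int(rng.integers(60, 91))
    cds = _random_cds(rng, n_codons)
    cds_len = len(cds)
    n_exons = int(rng.integers(1, 4))
    # split the CDS length into n_exons parts of >= 20 bp
    cuts = sorted(rng.choice(np.arange(20, cds_len - 20), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    lengths = np.diff([0, *cuts, cds_len]).astype(int)
    utr_len = 30
    utr5 = (cursor, cursor + utr_len - 1)
    pos = cursor + utr_len
    exons = []
    for li, length in enumerate(lengths):
        exons.append((pos, pos + int(length) - 1))
        pos += int(length)
        if li < len(lengths) - 1:
            pos += int(rng.integers(40, 120))  # intron
    utr3 = (pos, pos + utr_len - 1)
    pos += utr_len + int(rng.integers(150, 300))  # intergenic gap
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel(
        gene_id=gene_id,
        chrom="chr1",
        strand=strand,
        exons=tuple(exons),
        coding_frame_offset=0,
        protein_id=f"{gene_id}_P",
        utrs=(utr5, utr3),
    )
    return gene, cds, pos


def _coding_variant(
    rng: np.random.Generator,
    gene: GeneModel,
    cds: str,
    want: str,
    ti_tv_target: float,
    used_positions: set[int],
) -> tuple[VariantSite, CodingEffect]:
    """A single-base coding variant of the requested effect class,
    biased toward the transition/transversion target when possible."""
    p_ti = ti_tv_target / (1.0 + ti_tv_target)
    for _ in range(500):
        idx = int(rng.integers(3, gene.cds_length))  # keep the start codon
        pos = gene.cds_index_to_genomic(idx)
        if pos in used_positions:
            continue
        cds_ref = cds[idx]
        prefer_ti = rng.random() < p_ti
        alts = [b for b in BASES if b != cds_ref]
        rng.shuffle(alts)
        alts.sort(key=lambda b: (b != TRANSITION_OF[cds_ref]) if prefer_ti
                  else (b == TRANSITION_OF[cds_ref]))
        for cds_alt in alts:
            ref = cds_ref if gene.strand == "+" else COMPLEMENT[cds_ref]
            alt = cds_alt if gene.strand == "+" else COMPLEMENT[cds_alt]
            site = VariantSite(chrom=gene.chrom, pos=pos, ref=ref, alt=alt)
            effect = classify_coding_effect(site, gene, cds)
            if effect.effect_class == "non_synonymous" and "*" in (
                effect.ref_aa,
                effect.alt_aa,
            ):
                continue  # keep planted variants missense, not nonsense
            if effect.effect_class == want:
                used_positions.add(pos)
                return site, effect
    raise RuntimeError(f"could not place a {want} variant in {gene.gene_id}")


def _quality_stats(rng: np.random.Generator) -> dict[str, float]:
    return {
        "qual": float(rng.uniform(60, 600)),
        "qd": float(rng.uniform(10, 35)),
        "mq": float(rng.uniform(50, 60)),
        "fs": float(rng.uniform(0, 30)),
    }


# -- cohort simulation -------------------------------------------------


@dataclass
class SimulatedCohort:
    """All in-memory artifacts of one synthetic cohort."""

    spec: CohortSpec
    genes: list[GeneModel]
    cds: dict[str, str]
    focal_sites: list[VariantSite]
    focal_genotypes: dict[SiteKey, dict[str, int]]
    focal_samples: dict[str, str]
    breed_sites: dict[str, list[VariantSite]]
    breed_genotypes: dict[str, dict[SiteKey, dict[str, int]]]
    breed_samples: dict[str, list[str]]
    alignments: dict[str, GeneAlignment]
    annotations: list[AnnotatedVariant]
    truth: PlantedTruth
    child_seeds: dict[str, int]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(
            out / "focal.vcf",
            self.focal_sites,
            self.focal_genotypes,
            list(self.focal_samples),
        )
        labels = ["sample\tpopulation"]
        labels += [f"{s}\t{p}" for s, p in self.focal_samples.items()]
        (out / "focal_samples.tsv").write_text("\n".join(labels) + "\n")
        breed_dir = out / "breeds"
        breed_dir.mkdir(exist_ok=True)
        for breed, sites in self.breed_sites.items():
            write_vcf(
                breed_dir / f"{breed}.vcf",
                sites,
                self.breed_genotypes[breed],
                self.breed_samples[breed],
            )
        write_gene_models(self.genes, out / "gene_models.tsv")
        with open(out / "cds.fasta", "w") as fh:
            for gid in sorted(self.cds):
                fh.write(f">{gid}\n{self.cds[gid]}\n")
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for gid, aln in self.alignments.items():
            write_alignment_fasta(aln, aln_dir / f"{gid}.fasta")
        write_alt_residues(self.alignments, aln_dir / "alt_residues.tsv")
        self._write_annotations(out / "annotations.tsv")
        self.truth.write_json(out / "truth.json")
        (out / "manifest.json").write_text(
            json.dumps({"rng_seed": self.spec.rng_seed, "child_seeds": self.child_seeds},
                       indent=2) + "\n"
        )

    def _write_annotations(self, path: Path) -> None:
        lines = [
            "gene_id\tchrom\tpos\tref\talt\teffect_class\timpact\t"
            "protein_position\tref_aa\talt_aa"
        ]
        for av in self.annotations:
            s = av.site
            lines.append(
                f"{av.gene_id or '.'}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                f"{av.effect_class}\t{av.impact}\t{av.protein_position or '.'}\t"
                f"{av.ref_aa or '.'}\t{av.alt_aa or '.'}"
            )
        path.write_text("\n".join(lines) + "\n")


def _allocate_classes(n: int, weights: tuple[float, float, float]) -> tuple[int, int, int]:
    if n == 0:
        return 0, 0, 0
    total = sum(weights)
    raw = [w / total * n for w in weights]
    counts = [int(x) for x in raw]
    while sum(counts) < n:
        frac = [r - c for r, c in zip(raw, counts)]
        counts[frac.index(max(frac))] += 1
    return counts[0], counts[1], counts[2]


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full variant-analysis input bundle.

    Planted genes receive focal-unique HIGH/MODERATE missense SNPs
    whose carriers match the planted tail / non-tail / common class;
    every other gene is a decoy violating exactly one of the four
    uniqueness conditions.  Background non-coding sites follow the
    transition/transversion target in expectation.
    """
    seed_seq = np.random.SeedSequence(spec.rng_seed)
    children = seed_seq.spawn(6)
    child_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(
            ["genes", "planted", "decoys", "background", "alignments", "breeds"],
            children,
        )
    }
    rng_genes = np.random.default_rng(children[0])
    rng_planted = np.random.default_rng(children[1])
    rng_decoys = np.random.default_rng(children[2])
    rng_bg = np.random.default_rng(children[3])
    rng_aln = np.random.default_rng(children[4])
    rng_breeds = np.random.default_rng(children[5])

    # genes --------------------------------------------------------------
    genes: list[GeneModel] = []
    cds: dict[str, str] = {}
    cursor = 1000
    for i in range(spec.n_genes):
        gene, seq, cursor = _build_gene(rng_genes, i, cursor)
        genes.append(gene)
        cds[gene.gene_id] = seq
    gene_by_id = {g.gene_id: g for g in genes}

    focal_samples = spec.focal_samples
    tail_samples = [s for s, p in focal_samples.items() if p in ("LT", "ST")]
    nt_samples = [s for s, p in focal_samples.items() if p == "NT"]
    breed_samples = {
        breed: [f"B_{breed}_{i + 1:02d}" for i in range(size)]
        for breed, size in spec.comparison_breeds
    }

    truth = PlantedTruth()
    n_planted = spec.n_planted_genes
    n_tail, n_nt, n_common = _allocate_classes(n_planted, spec.subpop_class_weights)
    planted_ids = [g.gene_id for g in genes[:n_planted]]
    decoy_ids = [g.gene_id for g in genes[n_planted:]]
    truth.focal_specific_genes = set(planted_ids)
    truth.tail_specific = set(planted_ids[:n_tail])
    truth.non_tail_specific = set(planted_ids[n_tail : n_tail + n_nt])
    truth.common = set(planted_ids[n_tail + n_nt :])
    truth.validate()

    focal_sites: list[VariantSite] = []
    focal_genotypes: dict[SiteKey, dict[str, int]] = {}
    annotations: list[AnnotatedVariant] = []
    used_positions: set[int] = set()
    # (gene_id, protein_position) columns reserved so species rows never
    # accidentally show a focal alternative residue
    reserved_columns: dict[str, set[int]] = {g.gene_id: set() for g in genes}
    # deliberate cross-species hits for 'in_species' decoys
    species_hits: list[tuple[str, int, str]] = []  # gene, protein_pos, alt_aa
    breed_sites: dict[str, list[VariantSite]] = {b: [] for b in breed_samples}
    breed_genotypes: dict[str, dict[SiteKey, dict[str, int]]] = {
        b: {} for b in breed_samples
    }

    def _add_focal(site: VariantSite, carriers: list[str]) -> VariantSite:
        stats = _quality_stats(rng_planted)
        full = VariantSite(site.chrom, site.pos, site.ref, site.alt, **stats)
        focal_sites.append(full)
        focal_genotypes[full.key] = {
            s: int(1 + (rng_planted.random() < 0.3)) for s in carriers
        }
        return full

    def _carriers_for_class(cls: str, rng: np.random.Generator) -> list[str]:
        def pick(pool: list[str]) -> list[str]:
            k = int(rng.integers(1, min(4, len(pool)) + 1))
            return list(rng.choice(pool, size=k, replace=False))

        if cls == "tail":
            return pick(tail_samples)
        if cls == "non_tail":
            return pick(nt_samples)
        return pick(tail_samples) + pick(nt_samples)

    # planted focal-unique missense genes --------------------------------
    for gid in planted_ids:
        gene = gene_by_id[gid]
        if gid in truth.tail_specific:
            cls = "tail"
        elif gid in truth.non_tail_specific:
            cls = "non_tail"
        else:
            cls = "common"
        two_variant_common = cls == "common" and rng_planted.random() < 0.5
        if two_variant_common:
            plans = [("tail", None), ("non_tail", None)]
        else:
            plans = [(cls, None)]
        for sub_cls, _ in plans:
            site, effect = _coding_variant(
                rng_planted, gene, cds[gid], "non_synonymous", spec.ti_tv_target,
                used_positions,
            )
            carriers = _carriers_for_class(sub_cls, rng_planted)
            full = _add_focal(site, carriers)
            reserved_columns[gid].add(effect.protein_position)
            annotations.append(
                AnnotatedVariant(
                    site=full,
                    effect_class=effect.effect_class,
                    impact=default_impact(effect),
                    gene_id=gid,
                    protein_position=effect.protein_position,
                    ref_aa=effect.ref_aa,
                    alt_aa=effect.alt_aa,
                )
            )

    # decoy genes: each violates exactly one uniqueness condition --------
    breed_names = list(breed_samples)
    for i, gid in enumerate(decoy_ids):
        gene = gene_by_id[gid]
        decoy_type = DECOY_TYPES[i % len(DECOY_TYPES)]
        truth.decoy_types[gid] = decoy_type
        want = "synonymous" if decoy_type == "synonymous" else "non_synonymous"
        site, effect = _coding_variant(
            rng_decoys, gene, cds[gid], want, spec.ti_tv_target, used_positions
        )
        carriers = _carriers_for_class(
            ("tail", "non_tail", "common")[i % 3], rng_decoys
        )
        full = _add_focal(site, carriers)
        impact = default_impact(effect)
        if decoy_type == "low_impact":
            impact = "LOW"
        if effect.protein_position is not None:
            reserved_columns[gid].add(effect.protein_position)
        annotations.append(
            AnnotatedVariant(
                site=full,
                effect_class=effect.effect_class,
                impact=impact,
                gene_id=gid,
                protein_position=effect.protein_position,
                ref_aa=effect.ref_aa,
                alt_aa=effect.alt_aa,
            )
        )
        if decoy_type == "in_breed":
            breed = breed_names[int(rng_decoys.integers(len(breed_names)))]
            bsite = VariantSite(
                full.chrom, full.pos, full.ref, full.alt, **_quality_stats(rng_decoys)
            )
            breed_sites[breed].append(bsite)
            carrier = breed_samples[breed][
                int(rng_decoys.integers(len(breed_samples[breed])))
            ]
            breed_genotypes[breed][bsite.key] = {carrier: 1}
        elif decoy_type == "in_species":
            species_hits.append((gid, effect.protein_position, effect.alt_aa))

    # background non-coding sites (Ti/Tv target, category variety) ------
    lowqual_left = spec.n_lowqual_sites
    lowqual_clauses = itertools.cycle(["qd", "mq", "fs", "qual"])
    all_focal = list(focal_samples)
    for gene in genes:
        lo, hi = gene.span
        candidates = {
            "intron": [
                p
                for p in range(lo, hi + 1)
                if gene.region_of(p) == "intron"
            ],
            "splice_site": [
                p
                for p in range(lo, hi + 1)
                if gene.region_of(p) == "splice_site"
            ],
            "UTR": [p for s, e in gene.utrs for p in range(s, e + 1)],
            "intergenic": list(range(hi + 45, hi + 75)),
        }
        kinds = ["intron", "UTR", "intergenic", "splice_site"]
        for j in range(spec.n_sites_per_gene):
            kind = kinds[j % len(kinds)]
            pool = [p for p in candidates[kind] if p not in used_positions]
            if not pool:
                continue
            pos = int(pool[int(rng_bg.integers(len(pool)))])
            used_positions.add(pos)
            ref, alt = sample_substitution(rng_bg, spec.ti_tv_target)
            stats = _quality_stats(rng_bg)
            if lowqual_left > 0 and rng_bg.random() < 0.15:
                clause = next(lowqual_clauses)
                stats[clause] = {"qd": 2.0, "mq": 20.0, "fs": 300.0, "qual": 10.0}[clause]
                lowqual_left -= 1
            site = VariantSite(gene.chrom, pos, ref, alt, **stats)
            focal_sites.append(site)
            k = int(rng_bg.integers(1, 6))
            carriers = rng_bg.choice(all_focal, size=k, replace=False)
            focal_genotypes[site.key] = {s: 1 for s in carriers}
            annotations.append(
                AnnotatedVariant(
                    site=site,
                    effect_class=kind,
                    impact="HIGH" if kind == "splice_site" else "MODIFIER",
                    gene_id=gene.gene_id,
                )
            )

    # per-breed background sites (non-coding, never at focal positions) -
    for breed, samples in breed_samples.items():
        for _ in range(10):
            gene = genes[int(rng_breeds.integers(len(genes)))]
            lo, hi = gene.span
            pos = int(rng_breeds.integers(hi + 80, hi + 140))
            ref, alt = sample_substitution(rng_breeds, spec.ti_tv_target)
            site = VariantSite(
                gene.chrom, pos, ref, alt, **_quality_stats(rng_breeds)
            )
            if site.key in breed_genotypes[breed] or pos in used_positions:
                continue
            breed_sites[breed].append(site)
            carrier = samples[int(rng_breeds.integers(len(samples)))]
            breed_genotypes[breed][site.key] = {carrier: 1}

    # alignments ---------------------------------------------------------
    alignments: dict[str, GeneAlignment] = {}
    hits_by_gene: dict[str, list[tuple[int, str]]] = {}
    for gid, ppos, aa in species_hits:
        hits_by_gene.setdefault(gid, []).append((ppos, aa))
    planted_alts: dict[str, dict[int, str]] = {}
    for av in annotations:
        if av.effect_class == "non_synonymous" and av.gene_id is not None:
            planted_alts.setdefault(av.gene_id, {})[av.protein_position] = av.alt_aa
    for gene in genes:
        gid = gene.gene_id
        protein = str(Seq(cds[gid]).translate())
        rows = {"dog": protein}
        forbidden = {
            pos: planted_alts.get(gid, {}).get(pos)
            for pos in reserved_columns[gid]
        }
        hit_assignments = hits_by_gene.get(gid, [])
        for si, species in enumerate(spec.related_species):
            chars = list(protein)
            for col in range(len(chars)):
                ppos = col + 1
                if ppos in reserved_columns[gid]:
                    continue  # keep the reference residue at focal columns
                r = rng_aln.random()
                if r < 0.03:
                    chars[col] = "-"
                elif r < 0.10:
                    choices = [
                        a for a in "ACDEFGHIKLMNPQRSTVWY" if a != chars[col]
                    ]
                    chars[col] = choices[int(rng_aln.integers(len(choices)))]
            # decoy 'in_species': one species shows the focal alt residue
            for hi_idx, (ppos, aa) in enumerate(hit_assignments):
                target_species = spec.related_species[
                    hi_idx % len(spec.related_species)
                ]
                if species == target_species:
                    chars[ppos - 1] = aa
            rows[species] = "".join(chars)
        aln = GeneAlignment(gene_id=gid, rows=rows, focal="dog")
        # within-species alternative residues at unreserved columns
        for _ in range(int(rng_aln.integers(0, 4))):
            species = spec.related_species[
                int(rng_aln.integers(len(spec.related_species)))
            ]
            col = int(rng_aln.integers(1, len(protein) + 1))
            if col in reserved_columns[gid]:
                continue
            res_here = aln.residue(species, col)
            if res_here == "-":
                continue
            choices = [
                a
                for a in "ACDEFGHIKLMNPQRSTVWY"
                if a != res_here and a != forbidden.get(col)
            ]
            aln.alt_residues.setdefault((species, col), set()).add(
                choices[int(rng_aln.integers(len(choices)))]
            )
        alignments[gid] = aln

    return SimulatedCohort(
        spec=spec,
        genes=genes,
        cds=cds,
        focal_sites=focal_sites,
        focal_genotypes=focal_genotypes,
        focal_samples=focal_samples,
        breed_sites=breed_sites,
        breed_genotypes=breed_genotypes,
        breed_samples=breed_samples,
        alignments=alignments,
        annotations=annotations,
        truth=truth,
        child_seeds=child_seeds,
    )


# -- network simulation ------------------------------------------------


def simulate_network(
    n_proteins: int,
    mean_degree: float,
    score_distribution=None,
    rng_seed: int | np.random.Generator = 0,
) -> ScoredNetwork:
    """Erdos-Renyi network with sampled edge scores.

    Edge probability is mean_degree / (n - 1); at mean degree >= 4 the
    giant component covers essentially all nodes.  ``score_distribution``
    is a callable ``f(rng) -> float`` (default Beta(4, 2), a broad
    STRING-combined-score-like shape).
    """
    if n_proteins < 2:
        raise ValueError("n_proteins must be >= 2")
    if mean_degree >= n_proteins:
        raise ValueError("mean_degree must be < n_proteins")
    rng = np.random.default_rng(rng_seed)
    if score_distribution is None:
        score_distribution = lambda r: float(r.beta(4, 2))  # noqa: E731
    p = mean_degree / (n_proteins - 1)
    width = len(str(n_proteins - 1))
    names = [f"P{i:0{width}d}" for i in range(n_proteins)]
    net = ScoredNetwork()
    for name in names:
        net.add_node(name)
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            if rng.random() < p:
                net.add_edge(names[i], names[j], min(1.0, score_distribution(rng)))
    return net


# -- interaction history simulation ------------------------------------


@dataclass
class SimulatedHistory:
    """An interaction history evolved on a species tree, with truth."""

    tree: SpeciesTree
    pairs: list[PairKey]
    species_networks: dict[str, ScoredNetwork]
    ortholog_map: OrthologMap
    truth: PlantedTruth
    species: tuple[str, ...]
    outgroup: str

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.tree.write(out / "species_tree.nwk")
        for sp, net in self.species_networks.items():
            net.write_edge_list(out / f"network_{sp}.tsv")
        self.ortholog_map.write_tsv(out / "orthologs.tsv")
        lines = ["protein_a\tprotein_b"]
        lines += [f"{a}\t{b}" for a, b in self.pairs]
        (out / "pairs.tsv").write_text("\n".join(lines) + "\n")
        self.truth.write_json(out / "truth.json")


def simulate_interaction_history(
    tree: SpeciesTree | None = None,
    n_pairs: int = 2000,
    gain_rate: float = 0.04,
    loss_rate: float = 0.02,
    planted_gain_branch: str = "dog",
    excess_factor: float = 10.0,
    planted_fraction: float = 0.25,
    root_present_prob: float = 0.25,
    missing_group_rate: float = 0.0,
    outgroup: str = "mouse",
    rng_seed: int | np.random.Generator = 0,
) -> SimulatedHistory:
    """Evolve protein-pair interaction states root -> tips.

    Each pair's state follows a two-state Markov chain along every
    branch (gain with ``gain_rate`` from absent, loss with ``loss_rate``
    from present).  A ``planted_fraction`` subset of pairs uses
    ``gain_rate * excess_factor`` on the planted branch, planting a
    recoverable excess of gains there; with ``excess_factor = 1`` the
    subset is statistically exchangeable with the rest.  Tip states are
    materialized as per-species networks reachable through ortholog
    groups of 1-3 members, so the majority-rule transfer reproduces
    them exactly (a group missing with ``missing_group_rate`` yields an
    'unknown' state).  The outgroup species evolves from the root along
    one base-rate branch and is emitted as a related species.
    """
    if excess_factor < 1.0:
        raise ValueError("excess_factor must be >= 1")
    if not 0.0 <= gain_rate <= 1.0 or not 0.0 <= loss_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    tree = tree or default_species_tree()
    if planted_gain_branch not in tree.branches():
        raise ValueError(
            f"planted branch {planted_gain_branch!r} not a branch of the tree"
        )
    rng = np.random.default_rng(rng_seed)

    n_proteins = max(30, math.ceil((1 + math.sqrt(1 + 12 * n_pairs)) / 2))
    width = len(str(n_proteins - 1))
    proteins = [f"DP{i:0{width}d}" for i in range(n_proteins)]
    all_pairs = list(itertools.combinations(proteins, 2))
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    pairs: list[PairKey] = [all_pairs[i] for i in sorted(idx)]
    n_planted = round(planted_fraction * n_pairs)
    planted_idx = set(rng.choice(n_pairs, size=n_planted, replace=False).tolist())
    planted_pairs = [p for i, p in enumerate(pairs) if i in planted_idx]

    truth = PlantedTruth(
        planted_gain_branch=planted_gain_branch, planted_pairs=planted_pairs
    )

    species = tuple(t for t in tree.tip_names() if t != "dog") + (outgroup,)
    # evolve states
    for i, pair in enumerate(pairs):
        states: dict[str, int] = {}
        root_state = int(rng.random() < root_present_prob)
        states[tree.root.name] = root_state
        for node in tree.preorder():
            if node.parent is None:
                continue
            parent_state = states[node.parent.name]
            g = gain_rate
            if node.name == planted_gain_branch and i in planted_idx:
                g = min(1.0, gain_rate * excess_factor)
            if parent_state == 0:
                states[node.name] = int(rng.random() < g)
            else:
                states[node.name] = int(rng.random() >= loss_rate)
        # outgroup from the root along one base-rate branch
        if root_state == 0:
            states[outgroup] = int(rng.random() < gain_rate)
        else:
            states[outgroup] = int(rng.random() >= loss_rate)
        truth.true_node_states[pair] = states

    # ortholog groups: 1-3 members per species (occasionally missing)
    omap = OrthologMap()
    members: dict[tuple[str, str], list[str]] = {}
    for prot in proteins:
        group = f"OG_{prot}"
        omap.add("dog", prot, group)
        for sp in species:
            if missing_group_rate > 0 and rng.random() < missing_group_rate:
                members[(sp, prot)] = []
                continue
            size = int(rng.integers(1, 4))
            names = [f"{prot}_{sp}{j + 1}" for j in range(size)]
            members[(sp, prot)] = names
            for name in names:
                omap.add(sp, name, group)

    # materialize networks per species so majority-rule transfer
    # reproduces the evolved tip states
    networks: dict[str, ScoredNetwork] = {"dog": ScoredNetwork()}
    for sp in species:
        networks[sp] = ScoredNetwork()
    for pair in pairs:
        p, q = pair
        states = truth.true_node_states[pair]
        if states["dog"]:
            networks["dog"].add_edge(p, q, float(rng.uniform(0.75, 0.99)))
        for sp in species:
            mp, mq = members[(sp, p)], members[(sp, q)]
            if not mp or not mq:
                continue
            cross = [(a, b) for a in mp for b in mq]
            total = len(cross)
            half = total // 2
            if states[sp]:
                k = int(rng.integers(half + 1, total + 1))
            else:
                k = int(rng.integers(0, half + 1))
            chosen = rng.choice(total, size=k, replace=False) if k else []
            for ci in chosen:
                a, b = cross[int(ci)]
                if networks[sp].score(a, b) is None:
                    networks[sp].add_edge(a, b, float(rng.uniform(0.75, 0.99)))
    return SimulatedHistory(
        tree=tree,
        pairs=pairs,
        species_networks=networks,
        ortholog_map=omap,
        truth=truth,
        species=species,
        outgroup=outgroup,
    )
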