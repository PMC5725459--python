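"""Variant records and multi-sample VCF handling.

The pipeline consumes multi-sample VCFs of biallelic SNPs.  Genotypes
are reduced to carrier status: an individual is "alt-present" at a site
when it carries at least one copy of the alternative allele — the
weakest condition consistent with an allele being "present only" in a
population.  Non-SNP and multiallelic records are skipped with counted
reasons, never silently coerced.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

BASES = {"A", "C", "G", "T"}

SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP site with its call-quality statistics."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"{self.chrom}:{self.pos}: alleles must be single bases")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref})")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant site plus its coding-effect annotation.

    ``impact`` follows the HIGH/MODERATE/LOW/MODIFIER severity
    convention.  For non-synonymous variants the gene, protein position
    and the reference/alternative residues must all be set.
    """

    site: VariantSite
    effect_class: str
    impact: str
    gene_id: str | None = None
    protein_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        from .genes import EFFECT_PRECEDENCE

        if self.effect_class not in EFFECT_PRECEDENCE:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if self.impact not in ("HIGH", "MODERATE", "LOW", "MODIFIER"):
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.effect_class == "non_synonymous":
            if (
                self.gene_id is None
                or self.protein_position is None
                or self.ref_aa is None
                or self.alt_aa is None
                or self.ref_aa == self.alt_aa
            ):
                raise ValueError(
                    f"{self.site.chrom}:{self.site.pos}: non-synonymous variant "
                    "requires gene_id, protein_position and ref_aa != alt_aa"
                )

    @property
    def key(self) -> SiteKey:
        return self.site.key


@dataclass
class PopulationCallSet:
    """Per-sample alt-allele presence for one population's SNP sites."""

    name: str
    samples: list[str]
    population_of: dict[str, str]
    sites: list[VariantSite] = field(default_factory=list)
    carriers: dict[SiteKey, frozenset[str]] = field(default_factory=dict)
    n_skipped: Counter = field(default_factory=Counter)

    def add_site(self, site: VariantSite, carrier_samples: Iterable[str]) -> None:
        carriers = frozenset(carrier_samples)
        unknown = carriers - set(self.samples)
        if unknown:
            raise ValueError(f"carriers {sorted(unknown)} not among samples")
        self.sites.append(site)
        self.carriers[site.key] = carriers

    def has_alt(self, key: SiteKey) -> bool:
        """True when >= 1 individual of this population carries the alt."""
        return len(self.carriers.get(key, ())) > 0

    def carriers_of(self, key: SiteKey) -> frozenset[str]:
        return self.carriers.get(key, frozenset())

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.population_of[s] == population]

    @property
    def alt_keys(self) -> set[SiteKey]:
        return {k for k, c in self.carriers.items() if c}


# -- VCF I/O -----------------------------------------------------------


def read_vcf_cohort(
    path: str | Path,
    population_labels: Mapping[str, str],
    name: str | None = None,
) -> PopulationCallSet:
    """Read a multi-sample VCF of biallelic SNPs into a call set.

    Every sample in the file must appear in ``population_labels``
    (sample -> population); an unlabelled sample raises.  Multiallelic
    or non-SNP records are skipped and counted under
    ``n_skipped['multiallelic']`` / ``n_skipped['non_snp']``.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    unlabelled = [s for s in samples if s not in population_labels]
    if unlabelled:
        raise ValueError(f"unlabelled sample(s) in {path}: {unlabelled}")
    callset = PopulationCallSet(
        name=name or Path(path).stem,
        samples=samples,
        population_of={s: population_labels[s] for s in samples},
    )
    for rec in vcf:
        if len(rec.ALT) != 1:
            callset.n_skipped["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            callset.n_skipped["non_snp"] += 1
            continue
        site = VariantSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=ref,
            alt=alt,
            qual=rec.QUAL,
            qd=_info_float(rec, "QD"),
            mq=_info_float(rec, "MQ"),
            fs=_info_float(rec, "FS"),
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        carriers = [s for s, g in zip(samples, rec.gt_types) if g in (1, 3)]
        callset.add_site(site, carriers)
    if callset.n_skipped:
        logger.info("%s: skipped records %s", path, dict(callset.n_skipped))
    return callset


def _info_float(rec, key: str) -> float | None:
    val = rec.INFO.get(key)
    return None if val is None else float(val)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    path: str | Path,
    sites: list[VariantSite],
    genotypes: Mapping[SiteKey, Mapping[str, int]],
    samples: list[str],
    contigs: Iterable[str] = (),
) -> None:
    """Write biallelic SNP sites with per-sample alt-allele dosage.

    ``genotypes[key][sample]`` is the number of alt copies (0, 1 or 2);
    absent samples are written as homozygous reference.  Sites are
    sorted by position.
    """
    lines = [_VCF_HEADER.rstrip("\n")]
    seen_contigs = list(dict.fromkeys(contigs)) or sorted({s.chrom for s in sites})
    for c in seen_contigs:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    for site in sorted(sites, key=lambda s: (s.chrom, s.pos, s.ref, s.alt)):
        info_parts = []
        for tag, val in (("QD", site.qd), ("MQ", site.mq), ("FS", site.fs)):
            if val is not None:
                info_parts.append(f"{tag}={val:g}")
        info = ";".join(info_parts) or "."
        qual = "." if site.qual is None else f"{site.qual:g}"
        gts = genotypes.get(site.key, {})
        cols = [gt_str[int(gts.get(s, 0))] for s in samples]
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t{qual}\t.\t"
            f"{info}\tGT\t" + "\t".join(cols)
        )
    Path(path).write_text("\n".join(lines) + "\n")
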