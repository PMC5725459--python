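"""Simplified gene models and codon-level effect classification.

A :class:`GeneModel` is a minimal protein-coding annotation: ordered
exon intervals (1-based, closed), strand, a reading-frame offset and
optional UTR intervals.  :func:`classify_coding_effect` substitutes a
single base into the spliced coding sequence and reports whether the
encoded residue changes — a deliberately small, transparent stand-in
for a full effect-annotation tool, sufficient for missense/synonymous
calls and the splice/intron/UTR/intergenic region labels used by the
variant accounting.

Coordinates are genomic, 1-based and closed throughout; protein
positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, NamedTuple

from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover
    from .variants import VariantSite

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Effect classes, in the severity order used when a site overlaps
#: several annotations (exonic > splice > UTR > intron > intergenic).
EFFECT_PRECEDENCE = (
    "non_synonymous",
    "synonymous",
    "splice_site",
    "UTR",
    "intron",
    "intergenic",
)

#: Bases of intron flanking an exon boundary that count as splice site.
SPLICE_REGION_BP = 2


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding_frame_offset: int = 0
    protein_id: str = ""
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.coding_frame_offset not in (0, 1, 2):
            raise ValueError(f"{self.gene_id}: frame offset must be 0, 1 or 2")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"{self.gene_id}: exon {start}-{end} inverted")
            if prev_end is not None and start <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: coding length {self.cds_length} not divisible by 3"
            )

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.exonic_length - self.coding_frame_offset

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    # -- coordinate mapping -------------------------------------------

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def genomic_to_cds_index(self, pos: int) -> int | None:
        """0-based index into the spliced CDS, or None if pos is not a
        coding base (outside exons or eaten by the frame offset)."""
        if not self.in_exon(pos):
            return None
        if self.strand == "+":
            raw = 0
            for s, e in self.exons:
                if pos > e:
                    raw += e - s + 1
                elif s <= pos <= e:
                    raw += pos - s
                    break
        else:
            raw = 0
            for s, e in reversed(self.exons):
                if pos < s:
                    raw += e - s + 1
                elif s <= pos <= e:
                    raw += e - pos
                    break
        idx = raw - self.coding_frame_offset
        if idx < 0 or idx >= self.cds_length:
            return None
        return idx

    def cds_index_to_genomic(self, idx: int) -> int:
        if not 0 <= idx < self.cds_length:
            raise IndexError(f"CDS index {idx} out of range for {self.gene_id}")
        raw = idx + self.coding_frame_offset
        if self.strand == "+":
            for s, e in self.exons:
                length = e - s + 1
                if raw < length:
                    return s + raw
                raw -= length
        else:
            for s, e in reversed(self.exons):
                length = e - s + 1
                if raw < length:
                    return e - raw
                raw -= length
        raise AssertionError("unreachable")

    def region_of(self, pos: int) -> str:
        """'exon', 'splice_site', 'UTR', 'intron' or 'intergenic'."""
        if self.in_exon(pos):
            return "exon"
        lo, hi = self.span
        if lo <= pos <= hi:
            for s, e in self.exons:
                if 0 < s - pos <= SPLICE_REGION_BP or 0 < pos - e <= SPLICE_REGION_BP:
                    return "splice_site"
            return "intron"
        if any(s <= pos <= e for s, e in self.utrs):
            return "UTR"
        return "intergenic"


class CodingEffect(NamedTuple):
    effect_class: str
    ref_aa: str | None
    alt_aa: str | None
    protein_position: int | None


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_coding_effect(
    variant: "VariantSite", gene: GeneModel, coding_sequence: str
) -> CodingEffect:
    """Effect of a biallelic SNP on a gene's protein product.

    For exonic positions the reference base is cross-checked against the
    supplied spliced CDS (complemented for minus-strand genes); a
    mismatch raises ``ValueError``.  Non-exonic positions are labelled
    by region (splice site within 2 bp of an exon boundary, then
    UTR/intron/intergenic).
    """
    if len(coding_sequence) != gene.cds_length:
        raise ValueError(
            f"{gene.gene_id}: CDS length {len(coding_sequence)} != model "
            f"{gene.cds_length}"
        )
    region = gene.region_of(variant.pos)
    if region != "exon":
        return CodingEffect(region, None, None, None)
    idx = gene.genomic_to_cds_index(variant.pos)
    if idx is None:
        # exonic base ahead of the reading frame: treat as UTR
        return CodingEffect("UTR", None, None, None)
    if gene.strand == "+":
        ref_base, alt_base = variant.ref, variant.alt
    else:
        ref_base, alt_base = COMPLEMENT[variant.ref], COMPLEMENT[variant.alt]
    if coding_sequence[idx] != ref_base:
        raise ValueError(
            f"{gene.gene_id}: reference base {variant.ref} at {variant.chrom}:"
            f"{variant.pos} inconsistent with CDS ({coding_sequence[idx]} at "
            f"index {idx})"
        )
    codon_idx, codon_pos = divmod(idx, 3)
    codon = coding_sequence[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = codon[:codon_pos] + alt_base + codon[codon_pos + 1 :]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    effect = "synonymous" if ref_aa == alt_aa else "non_synonymous"
    return CodingEffect(effect, ref_aa, alt_aa, codon_idx + 1)


def default_impact(effect: CodingEffect) -> str:
    """SnpEff-convention severity for a classified effect.

    Stop gain/loss is HIGH, other missense MODERATE, synonymous LOW,
    splice site HIGH, everything non-coding MODIFIER.
    """
    if effect.effect_class == "non_synonymous":
        if "*" in (effect.ref_aa, effect.alt_aa):
            return "HIGH"
        return "MODERATE"
    if effect.effect_class == "synonymous":
        return "LOW"
    if effect.effect_class == "splice_site":
        return "HIGH"
    return "MODIFIER"


# -- gene model TSV ----------------------------------------------------


def _fmt_intervals(ivs: tuple[tuple[int, int], ...]) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivs) if ivs else "."


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    if text in (".", ""):
        return ()
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["gene_id\tchrom\tstrand\texons\tcoding_frame_offset\tprotein_id\tutrs"]
    for g in genes:
        lines.append(
            f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{_fmt_intervals(g.exons)}\t"
            f"{g.coding_frame_offset}\t{g.protein_id}\t{_fmt_intervals(g.utrs)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "chrom", "strand", "exons", "coding_frame_offset",
                    "protein_id", "utrs"]
        if header != expected:
            raise ValueError(f"{path}: unexpected gene-model header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            gid, chrom, strand, exons, off, pid, utrs = fields
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    exons=_parse_intervals(exons),
                    coding_frame_offset=int(off),
                    protein_id=pid,
                    utrs=_parse_intervals(utrs),
                )
            )
    return genes
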