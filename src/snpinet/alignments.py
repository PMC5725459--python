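"""Per-gene cross-species protein alignments.

Cross-species comparison of focal-population alleles happens at the
aligned-residue level: a focal missense allele only counts as
population-unique if no related species shows the same alternative
residue at the orthologous alignment column.  Each gene carries one
pre-computed multiple alignment (focal species row plus one row per
related species, gap character ``-``) and, separately, a table of
known alternative residues segregating within each species at given
columns (a residue-level stand-in for that species' own SNP set).

Columns are 1-based.  A gap in a species' row makes that species
non-informative at the column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneAlignment:
    gene_id: str
    rows: dict[str, str]
    focal: str = "dog"
    alt_residues: dict[tuple[str, int], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.focal not in self.rows:
            raise ValueError(f"{self.gene_id}: no row for focal species {self.focal!r}")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: rows have unequal lengths {lengths}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.focal])

    @property
    def species(self) -> list[str]:
        return [s for s in self.rows if s != self.focal]

    def column_of(self, protein_position: int) -> int:
        """Alignment column (1-based) of the focal sequence's i-th residue."""
        count = 0
        for col, ch in enumerate(self.rows[self.focal], start=1):
            if ch != "-":
                count += 1
                if count == protein_position:
                    return col
        raise IndexError(
            f"{self.gene_id}: focal row has only {count} residues, "
            f"position {protein_position} requested"
        )

    def residue(self, species: str, column: int) -> str:
        return self.rows[species][column - 1]

    def species_residues(self, species: str, column: int) -> set[str]:
        """All residues known in a species at a column: the aligned row
        residue plus any recorded within-species alternatives.  Empty if
        the row shows a gap (non-informative)."""
        res = self.residue(species, column)
        if res == "-":
            return set()
        return {res} | self.alt_residues.get((species, column), set())

    def shows_residue(self, species: str, column: int, residue: str) -> bool:
        return residue in self.species_residues(species, column)


# -- I/O ---------------------------------------------------------------


def write_alignment_fasta(aln: GeneAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=species, description="")
        for species, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(path: str | Path, gene_id: str, focal: str = "dog") -> GeneAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    return GeneAlignment(gene_id=gene_id, rows=rows, focal=focal)


def write_alt_residues(
    alignments: dict[str, GeneAlignment], path: str | Path
) -> None:
    """One TSV across genes: gene_id, species, column, residue."""
    lines = ["gene_id\tspecies\tcolumn\tresidue"]
    for gid in sorted(alignments):
        aln = alignments[gid]
        for (species, column), residues in sorted(aln.alt_residues.items()):
            for r in sorted(residues):
                lines.append(f"{gid}\t{species}\t{column}\t{r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_alt_residues(path: str | Path, alignments: dict[str, GeneAlignment]) -> None:
    """Load per-species alternative residues into existing alignments."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "species", "column", "residue"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            gid, species, column, residue = line.split("\t")
            if gid not in alignments:
                raise ValueError(f"{path}:{lineno}: unknown gene {gid}")
            aln = alignments[gid]
            aln.alt_residues.setdefault((species, int(column)), set()).add(residue)


def read_alignment_dir(
    directory: str | Path, focal: str = "dog"
) -> dict[str, GeneAlignment]:
    """Read ``<gene_id>.fasta`` alignments and, when present, the shared
    ``alt_residues.tsv`` in the same directory."""
    directory = Path(directory)
    alignments: dict[str, GeneAlignment] = {}
    for path in sorted(directory.glob("*.fasta")):
        gid = path.stem
        alignments[gid] = read_alignment_fasta(path, gene_id=gid, focal=focal)
    alt_path = directory / "alt_residues.tsv"
    if alt_path.exists():
        read_alt_residues(alt_path, alignments)
    return alignments
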