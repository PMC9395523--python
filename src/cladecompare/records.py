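"""Core sequence records shared across the package.

A :class:`GenomeRecord` carries contig sequences plus CDS annotations
(1-based inclusive coordinates, explicit strand); a :class:`ProteinRecord`
is one annotated protein product.  Translation uses the bacterial /
archaeal code (NCBI table 11) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: morphology phenotypes recognised on genomes
PHENOTYPES = ("rod", "muldi", "coccoid", "unknown")


class RecordError(ValueError):
    """Malformed sequence record or annotation."""


@dataclass(frozen=True)
class CdsFeature:
    """One CDS interval on a contig; coordinates 1-based inclusive."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    locus_tag: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise RecordError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise RecordError(
                f"invalid CDS interval {self.start}..{self.end} ({self.locus_tag})"
            )


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence identified by locus tag and source genome."""

    id: str
    genome_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise RecordError(f"protein {self.id}: empty sequence")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise RecordError(
                f"protein {self.id}: characters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )

    @property
    def qualified_id(self) -> str:
        """Genome-qualified identifier, unique across a multi-genome set."""
        return f"{self.genome_id}:{self.id}"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenomeRecord:
    """A genome assembly with CDS annotations and an optional phenotype."""

    id: str
    contigs: dict[str, str]
    cds: list[CdsFeature] = field(default_factory=list)
    phenotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise RecordError(
                f"genome {self.id}: unknown phenotype {self.phenotype!r}"
            )
        for feat in self.cds:
            if feat.contig_id not in self.contigs:
                raise RecordError(
                    f"genome {self.id}: CDS {feat.locus_tag} references "
                    f"unknown contig {feat.contig_id}"
                )
            if feat.end > len(self.contigs[feat.contig_id]):
                raise RecordError(
                    f"genome {self.id}: CDS {feat.locus_tag} extends past "
                    f"the end of contig {feat.contig_id}"
                )

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def cds_nucleotides(self, feat: CdsFeature) -> str:
        """Coding-strand nucleotide sequence of one CDS."""
        seq = self.contigs[feat.contig_id][feat.start - 1 : feat.end]
        if feat.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def translate_cds(self, feat: CdsFeature) -> str:
        """Translate one CDS (table 11), trimming a trailing stop."""
        nt = self.cds_nucleotides(feat)
        if len(nt) % 3 != 0:
            raise RecordError(
                f"genome {self.id}: CDS {feat.locus_tag} length {len(nt)} "
                "not divisible by 3"
            )
        aa = str(Seq(nt).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            raise RecordError(
                f"genome {self.id}: CDS {feat.locus_tag} contains an "
                "internal stop codon"
            )
        return aa

    def proteome(self) -> list[ProteinRecord]:
        """Translate every annotated CDS."""
        return [
            ProteinRecord(f.locus_tag, self.id, self.translate_cds(f))
            for f in self.cds
        ]
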