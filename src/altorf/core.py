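"""Core genomic value types shared across the altORF pipeline.

Coordinates are 0-based, half-open throughout the package; conversion to
the 1-based inclusive convention used in genome browsers happens only at
I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
STOP_CODONS = {"TAA", "TAG", "TGA"}

_DNA_RE = re.compile(r"^[ACGTN]+$")


def validate_dna(sequence: str) -> str:
    """Upper-case *sequence* and reject characters outside {A,C,G,T,N}."""
    seq = sequence.upper()
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise ValueError(f"sequence contains non-DNA characters: {bad}")
    return seq


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def translate_codons(nt: str) -> str:
    """Translate an in-frame nucleotide string (no terminal stop expected)."""
    if len(nt) % 3 != 0:
        raise ValueError("nucleotide length is not a multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class SpeciesLocus:
    """A genomic locus from one species/assembly.

    ``genome_offset`` is the genome coordinate of the first base of
    ``sequence`` so that ORF intervals can be reported in genome space.
    """

    species_id: str
    sequence: str
    assembly: str = ""
    chrom: str = "locus"
    genome_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence)
        if self.genome_offset < 0:
            raise ValueError("genome_offset must be >= 0")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfRecord:
    """One predicted ORF.

    The interval includes the terminal stop codon when
    ``has_terminal_stop`` is true, so ``len(interval) == 3 * (aa_length + 1)``
    in that case. ``frame`` is the reading-frame offset (0-2) on the ORF's
    own strand relative to the locus start (of the reverse complement for
    '-' ORFs). The Kozak context is the 10-mer covering positions -6..-1,
    the ATG and +4, read 5'->3' on the ORF strand, N-padded at locus edges.
    """

    orf_id: str
    species_id: str
    interval: GenomicInterval
    frame: int
    aa_length: int
    peptide: str
    kozak_context: str = ""
    kozak_score: float = float("nan")
    has_terminal_stop: bool = True
    nt_sequence: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not self.peptide.startswith("M"):
            raise ValueError(f"{self.orf_id}: peptide must start with M")
        if "*" in self.peptide:
            raise ValueError(f"{self.orf_id}: peptide contains a stop symbol")
        expected = 3 * (self.aa_length + (1 if self.has_terminal_stop else 0))
        if len(self.interval) != expected:
            raise ValueError(
                f"{self.orf_id}: interval length {len(self.interval)} does not "
                f"match aa_length {self.aa_length}"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def start_codon_position(self) -> int:
        """Genome coordinate of the first base of the ATG (strand-aware)."""
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1
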