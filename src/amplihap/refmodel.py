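"""Amplicon reference model and coordinate arithmetic.

An :class:`AmpliconReference` ties together the amplicon sequence, the PCR
primers at its termini, the coding sequence (CDS) embedded in it, and the
genomic anchor of the gene.  Three coordinate systems are used throughout
the pipeline:

* **amplicon offset** — 0-based index into the amplicon sequence (internal),
* **cDNA position** — 1-based ``c.`` numbering, ``c.1`` = first base of the
  start codon,
* **genomic position** — 1-based position on the reference assembly.

The gene modelled here (a connexin-26-like single-coding-exon gene) lies on
the minus strand, so for every coding position the cDNA and genomic
coordinates are related by a single affine constant::

    genomic = anchor_sum - cdna

``anchor_sum`` is calibrated from one known (cdna, genomic) pair and holds
across the whole coding exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_NUCS = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Three-letter amino-acid codes keyed by one-letter code; ``*`` is a stop.
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


class CoordinateRangeError(ValueError):
    """A coordinate fell outside the coding sequence."""


class AlphabetError(ValueError):
    """A sequence contained a non-nucleotide character."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement ``seq`` (alphabet A/C/G/T/N).

    Raises :class:`AlphabetError` on any other character.
    """
    if not _NUCS.issuperset(seq):
        bad = sorted(set(seq) - _NUCS)
        raise AlphabetError(f"non-nucleotide character(s): {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate a CDS with the standard genetic code.

    Returns ``(protein, premature_stop)``.  A stop codon in the final
    position is dropped from the protein (normal termination); a stop codon
    anywhere earlier sets the ``premature_stop`` flag and truncates the
    protein at that codon, mirroring how a nonsense allele would behave.

    Raises ``ValueError`` if the length is not a multiple of three, and
    :class:`AlphabetError` on non-ACGT characters.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if not set(cds) <= set("ACGT"):
        raise AlphabetError("CDS must contain only A/C/G/T")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    premature = "*" in aa
    if premature:
        aa = aa.split("*", 1)[0]
    return aa, premature


@dataclass(frozen=True)
class CoordinateTriple:
    """One position expressed in all three coordinate systems."""

    amplicon_offset: int
    cdna_pos: int | None  # None outside the CDS
    genomic_pos: int


@dataclass(frozen=True)
class AmpliconReference:
    """The amplicon sequence plus primer / CDS / genomic-anchor metadata."""

    name: str
    sequence: str
    primer_fwd: str
    primer_rev: str  # 5'->3' on the opposite strand
    cds_offset: int  # 0-based offset of c.1 within the amplicon
    cds_length_nt: int  # coding nt including the stop codon
    chrom: str
    anchor_sum: int  # genomic = anchor_sum - cdna for coding positions
    strand: str = "-"

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGT"):
            raise AlphabetError("amplicon sequence must be A/C/G/T")
        if not self.sequence.startswith(self.primer_fwd):
            raise ValueError("sequence does not begin with primer_fwd")
        if not self.sequence.endswith(reverse_complement(self.primer_rev)):
            raise ValueError(
                "sequence does not end with reverse_complement(primer_rev)"
            )
        if self.cds_offset + self.cds_length_nt > len(self.sequence):
            raise ValueError("CDS extends past the end of the amplicon")
        if self.cds_length_nt % 3 != 0:
            raise ValueError("cds_length_nt must be divisible by 3")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    # -- derived views -----------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_offset:self.cds_offset + self.cds_length_nt]

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)[0]

    # -- coordinate maps ---------------------------------------------------

    def map_cdna_to_genomic(self, cdna_pos: int) -> int:
        """Genomic coordinate of 1-based cDNA position ``cdna_pos``.

        The gene is on the minus strand, so the map is ``anchor_sum - cdna``.
        """
        if not 1 <= cdna_pos <= self.cds_length_nt:
            raise CoordinateRangeError(
                f"c.{cdna_pos} outside CDS (1..{self.cds_length_nt})"
            )
        return self.anchor_sum - cdna_pos

    def map_genomic_to_cdna(self, genomic_pos: int) -> int:
        """Inverse of :meth:`map_cdna_to_genomic`."""
        cdna = self.anchor_sum - genomic_pos
        if not 1 <= cdna <= self.cds_length_nt:
            raise CoordinateRangeError(
                f"genomic {genomic_pos} maps outside the CDS"
            )
        return cdna

    def cdna_to_offset(self, cdna_pos: int) -> int:
        """0-based amplicon offset of 1-based cDNA position."""
        if not 1 <= cdna_pos <= self.cds_length_nt:
            raise CoordinateRangeError(
                f"c.{cdna_pos} outside CDS (1..{self.cds_length_nt})"
            )
        return self.cds_offset + cdna_pos - 1

    def offset_to_cdna(self, offset: int) -> int | None:
        """1-based cDNA position of an amplicon offset, or None outside the CDS."""
        if not 0 <= offset < len(self.sequence):
            raise CoordinateRangeError(f"offset {offset} outside amplicon")
        cdna = offset - self.cds_offset + 1
        return cdna if 1 <= cdna <= self.cds_length_nt else None

    def offset_to_genomic(self, offset: int) -> int:
        """Genomic coordinate of any amplicon offset (minus-strand extension
        of the anchor relation beyond the CDS)."""
        if not 0 <= offset < len(self.sequence):
            raise CoordinateRangeError(f"offset {offset} outside amplicon")
        return self.anchor_sum - (offset - self.cds_offset + 1)

    def triple(self, offset: int) -> CoordinateTriple:
        return CoordinateTriple(
            amplicon_offset=offset,
            cdna_pos=self.offset_to_cdna(offset),
            genomic_pos=self.offset_to_genomic(offset),
        )


# -- reference bundle I/O --------------------------------------------------

def write_reference_bundle(ref: AmpliconReference, directory: str | Path) -> None:
    """Write the reference as ``<name>.fasta`` plus ``<name>.yaml`` metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rec = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    SeqIO.write([rec], directory / f"{ref.name}.fasta", "fasta")
    meta = {
        "name": ref.name,
        "primer_fwd": ref.primer_fwd,
        "primer_rev": ref.primer_rev,
        "cds_offset": ref.cds_offset,
        "cds_length_nt": ref.cds_length_nt,
        "chrom": ref.chrom,
        "anchor_sum": ref.anchor_sum,
        "strand": ref.strand,
    }
    with open(directory / f"{ref.name}.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_reference_bundle(directory: str | Path, name: str) -> AmpliconReference:
    """Load a reference written by :func:`write_reference_bundle`."""
    directory = Path(directory)
    rec = next(SeqIO.parse(directory / f"{name}.fasta", "fasta"))
    with open(directory / f"{name}.yaml") as fh:
        meta = yaml.safe_load(fh)
    return AmpliconReference(sequence=str(rec.seq).upper(), **meta)
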