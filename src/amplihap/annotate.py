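"""Protein-consequence annotation of coding single-nucleotide variants.

Maps a cDNA substitution to its codon, substitutes the alternate base,
translates both codons with the standard genetic code and reports the
change in protein-level notation (``p.Asp50Asn``), classified as
synonymous, missense, nonsense or stop-loss.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .refmodel import AA3, AmpliconReference, CoordinateRangeError
from .simdata import Variant


@dataclass(frozen=True)
class ProteinChange:
    codon_index: int  # 1-based
    ref_codon: str
    alt_codon: str
    ref_aa: str  # one-letter ("*" = stop)
    alt_aa: str
    hgvs_p: str  # e.g. "p.Asp50Asn"
    consequence: str  # synonymous | missense | nonsense | stop_loss


class ReferenceMismatchError(ValueError):
    """The variant's stated reference base disagrees with the reference
    sequence — a sign of stale coordinates."""


def codon_of(cdna_pos: int, cds_length_nt: int) -> tuple[int, int]:
    """(1-based codon index, 0-based offset within the codon) of a cDNA
    position; c.148 is the first base of codon 50."""
    if not 1 <= cdna_pos <= cds_length_nt:
        raise CoordinateRangeError(
            f"c.{cdna_pos} outside CDS (1..{cds_length_nt})")
    return (cdna_pos - 1) // 3 + 1, (cdna_pos - 1) % 3


def consequence(variant: Variant, ref: AmpliconReference) -> ProteinChange:
    """Protein consequence of a coding single-nucleotide substitution."""
    cds = ref.cds
    idx, offset = codon_of(variant.cdna_pos, ref.cds_length_nt)
    start = (idx - 1) * 3
    ref_codon = cds[start:start + 3]
    if ref_codon[offset] != variant.ref_base:
        raise ReferenceMismatchError(
            f"{variant.label}: reference CDS has {ref_codon[offset]} at "
            f"c.{variant.cdna_pos}, variant states {variant.ref_base}")
    alt_codon = ref_codon[:offset] + variant.alt_base + ref_codon[offset + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        csq = "synonymous"
    elif alt_aa == "*":
        csq = "nonsense"
    elif ref_aa == "*":
        csq = "stop_loss"
    else:
        csq = "missense"
    hgvs_p = f"p.{AA3[ref_aa]}{idx}{AA3[alt_aa]}"
    return ProteinChange(codon_index=idx, ref_codon=ref_codon,
                         alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
                         hgvs_p=hgvs_p, consequence=csq)


def annotation_table(variants: list[Variant], ref: AmpliconReference):
    """Protein / cDNA / genomic table for a list of coding variants."""
    import pandas as pd

    rows = []
    for v in variants:
        pc = consequence(v, ref)
        rows.append({
            "protein": pc.hgvs_p,
            "cdna": v.label,
            "genomic": f"{ref.chrom}:{ref.map_cdna_to_genomic(v.cdna_pos)}",
            "consequence": pc.consequence,
        })
    return pd.DataFrame(rows)
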