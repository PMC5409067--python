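"""Synthetic amplicon data generator.

Emulates ultra-deep single-molecule sequencing of a 1033 bp amplicon
spanning the single coding exon of a connexin-26-like gene (226 residues),
in a patient mosaic for revertant second-site mutations:

* a heterozygous germline missense variant (c.148G>A) on ~50% of molecules,
* two or three somatic second-site variants, each riding on the
  germline-mutant haplotype only, at low clonal frequency,
* multi-pass raw subreads with an insertion-dominant error profile that the
  circular-consensus stage is expected to suppress,
* a residue of unclassifiable molecules (decoys) making clonal-class
  percentages sum to slightly under 100%.

The reference sequence is synthetic: the true gene sequence is not bundled.
It is generated deterministically from a seed, with the codons touched by
the packaged variants pinned so that every variant produces the intended
amino-acid change (e.g. codon 50 = GAC so that c.148G>A gives Asp50Asn).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ccs import CcsRead
from .refmodel import AmpliconReference, reverse_complement, translate_cds

DEFAULT_SEED = 13

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Codons pinned in the packaged synthetic reference so the bundled variants
#: reproduce their published amino-acid changes.  Third-base choices are a
#: fixture convention, not a claim about the real gene.
PINNED_CODONS = {
    21: "GGA",   # Gly; c.61G>A  -> AGA Arg
    46: "GAC",   # Asp; c.136G>A -> AAC Asn, c.137A>C -> GCC Ala
    50: "GAC",   # Asp; c.148G>A -> AAC Asn (the germline KID variant)
    138: "AGC",  # Ser; c.413G>A -> AAC Asn
    148: "GCC",  # Ala; c.443C>A -> GAC Asp
}


class ConfigError(ValueError):
    """Reference or mixture configuration is infeasible."""


class MixtureError(ValueError):
    """Haplotype fractions are invalid."""


# -- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution in cDNA coordinates.

    Positions beyond the CDS length address the downstream non-coding
    amplicon region through the same linear extension the genomic anchor
    uses (needed for the always-alt marker polymorphism 3' of the stop).
    """

    cdna_pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")

    @property
    def label(self) -> str:
        return f"c.{self.cdna_pos}{self.ref_base}>{self.alt_base}"


@dataclass(frozen=True)
class Haplotype:
    name: str
    variants: tuple[Variant, ...] = ()

    def __post_init__(self) -> None:
        positions = [v.cdna_pos for v in self.variants]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one variant per position")


@dataclass(frozen=True)
class HaplotypeMixture:
    """Named haplotypes with clonal fractions; the remainder is decoy mass."""

    entries: tuple[tuple[Haplotype, Fraction], ...]
    decoy_fraction: Fraction

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.entries) + self.decoy_fraction
        if abs(total - 1) > Fraction(1, 10**9):
            raise MixtureError(f"fractions sum to {float(total)}, expected 1")
        names = [h.name for h, _ in self.entries]
        if len(names) != len(set(names)):
            raise MixtureError("duplicate haplotype names")

    @property
    def class_names(self) -> list[str]:
        return [h.name for h, _ in self.entries]


@dataclass(frozen=True)
class ErrorModel:
    """Per-base raw-read error probabilities (insertion-dominant default,
    the profile characteristic of raw single-molecule long reads)."""

    p_mismatch: float = 0.02
    p_insertion: float = 0.08
    p_deletion: float = 0.01

    def __post_init__(self) -> None:
        for name in ("p_mismatch", "p_insertion", "p_deletion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 0.2:
                raise ValueError(f"{name}={p} outside [0, 0.2]")


@dataclass
class SubreadRecord:
    read_id: str
    haplotype: str  # truth label, or "decoy"
    passes: list[str]
    orientations: list[str]  # "+" or "-" per pass


@dataclass
class SubreadSet:
    records: list[SubreadRecord]
    reference: AmpliconReference


# -- reference construction ------------------------------------------------

@dataclass(frozen=True)
class ReferenceConfig:
    name: str = "amplicon_synthetic"
    total_length: int = 1033
    primer_length: int = 21
    cds_offset: int = 150
    cds_length_nt: int = 681  # 226 codons + stop
    chrom: str = "chr13"
    anchor_sum: int = 20763721
    strand: str = "-"


def build_reference(config: ReferenceConfig | None = None,
                    seed: int = DEFAULT_SEED) -> AmpliconReference:
    """Build the deterministic synthetic amplicon reference.

    The layout is ``primer_fwd | 5' flank | CDS | 3' flank | revcomp(primer_rev)``.
    The CDS starts with ATG, ends with TAA, contains no internal stop, and
    carries the pinned codons of :data:`PINNED_CODONS`.
    """
    cfg = config or ReferenceConfig()
    if cfg.cds_offset < cfg.primer_length:
        raise ConfigError("CDS overlaps the forward primer")
    tail = cfg.total_length - cfg.cds_offset - cfg.cds_length_nt
    if tail < cfg.primer_length:
        raise ConfigError("primers + CDS exceed the amplicon length")
    if cfg.cds_length_nt % 3 != 0:
        raise ConfigError("cds_length_nt must be divisible by 3")

    rng = np.random.default_rng(seed)

    def rand_seq(n: int) -> str:
        return bytes(_BASES[rng.integers(0, 4, n)]).decode()

    non_stop = sorted(
        {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        - _STOP_CODONS
    )
    n_codons = cfg.cds_length_nt // 3
    codons = ["ATG"]
    codons += [non_stop[i] for i in rng.integers(0, len(non_stop), n_codons - 2)]
    codons.append("TAA")
    for idx, codon in PINNED_CODONS.items():
        codons[idx - 1] = codon
    cds = "".join(codons)

    sequence = (
        rand_seq(cfg.cds_offset)
        + cds
        + rand_seq(tail)
    )
    primer_fwd = sequence[:cfg.primer_length]
    primer_rev = reverse_complement(sequence[-cfg.primer_length:])

    ref = AmpliconReference(
        name=cfg.name,
        sequence=sequence,
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
        cds_offset=cfg.cds_offset,
        cds_length_nt=cfg.cds_length_nt,
        chrom=cfg.chrom,
        anchor_sum=cfg.anchor_sum,
        strand=cfg.strand,
    )
    protein, premature = translate_cds(ref.cds)
    assert not premature and len(protein) == n_codons - 1
    return ref


def apply_variants(ref: AmpliconReference, variants: tuple[Variant, ...] | list[Variant]) -> str:
    """Return the haplotype sequence carrying ``variants`` on ``ref``."""
    seq = list(ref.sequence)
    for v in variants:
        off = ref.cds_offset + v.cdna_pos - 1  # linear extension past the CDS
        if not 0 <= off < ref.length:
            raise ValueError(f"{v.label}: position outside the amplicon")
        if seq[off] != v.ref_base:
            raise ValueError(
                f"{v.label}: reference base at c.{v.cdna_pos} is {seq[off]}, "
                f"not {v.ref_base}"
            )
        seq[off] = v.alt_base
    return "".join(seq)


# -- packaged variants and mixture presets ---------------------------------

GERMLINE = Variant(148, "G", "A")           # p.Asp50Asn, the KID variant

SM_C61 = Variant(61, "G", "A")              # p.Gly21Arg
SM_C136 = Variant(136, "G", "A")            # p.Asp46Asn
SM_C137 = Variant(137, "A", "C")            # p.Asp46Ala
SM_C413 = Variant(413, "G", "A")            # p.Ser138Asn
SM_C443 = Variant(443, "C", "A")            # p.Ala148Asp

ALL_SOMATIC = (SM_C61, SM_C136, SM_C137, SM_C413, SM_C443)

#: extended-cDNA position of the homozygous non-coding polymorphism
#: (rs3751385-like, genomic 20762956): anchor_sum - 20762956 = 765,
#: downstream of the 681 nt CDS but inside the amplicon
MARKER_EXT_CDNA = 765


def marker_variant(ref: AmpliconReference) -> Variant:
    """The always-alt marker polymorphism on the packaged reference."""
    off = ref.cds_offset + MARKER_EXT_CDNA - 1
    ref_base = ref.sequence[off]
    alt = "C" if ref_base != "C" else "T"
    return Variant(MARKER_EXT_CDNA, ref_base, alt)


def with_marker(mixture: HaplotypeMixture,
                ref: AmpliconReference) -> HaplotypeMixture:
    """Add the homozygous marker polymorphism to every haplotype.

    The marker sits on all alleles (it is homozygous), so downstream it is
    called at ~100% frequency and excluded from clonal classification and
    somatic phasing by the near-fixed-site filter.
    """
    mv = marker_variant(ref)
    entries = tuple(
        (Haplotype(h.name, h.variants + (mv,)), f) for h, f in mixture.entries
    )
    return HaplotypeMixture(entries=entries,
                            decoy_fraction=mixture.decoy_fraction)


def _hap(name: str, *variants: Variant) -> Haplotype:
    return Haplotype(name, tuple(variants))


def _preset(rows: list[tuple[Haplotype, str]]) -> HaplotypeMixture:
    entries = tuple((h, Fraction(pct) / 100) for h, pct in rows)
    decoy = 1 - sum(f for _, f in entries)
    return HaplotypeMixture(entries=entries, decoy_fraction=decoy)


#: Clonal-composition presets: biopsy x template (genomic DNA or cDNA).
#: Percentages are the observed read-class frequencies of each sample;
#: the shortfall from 100% is decoy (unclassifiable) mass.
PRESETS: dict[str, HaplotypeMixture] = {
    "biopsy1_gDNA": _preset([
        (_hap("wt"), "46.5"),
        (_hap("germline-only", GERMLINE), "31.3"),
        (_hap("germline+c.136G>A", GERMLINE, SM_C136), "9.8"),
        (_hap("germline+c.443C>A", GERMLINE, SM_C443), "7.8"),
    ]),
    "biopsy1_cDNA": _preset([
        (_hap("wt"), "55.3"),
        (_hap("germline-only", GERMLINE), "26.5"),
        (_hap("germline+c.136G>A", GERMLINE, SM_C136), "12.5"),
        (_hap("germline+c.443C>A", GERMLINE, SM_C443), "4.2"),
    ]),
    "biopsy2_gDNA": _preset([
        (_hap("wt"), "48.7"),
        (_hap("germline-only", GERMLINE), "34.5"),
        (_hap("germline+c.137A>C", GERMLINE, SM_C137), "4.7"),
        (_hap("germline+c.61G>A", GERMLINE, SM_C61), "6.9"),
        (_hap("germline+c.413G>A", GERMLINE, SM_C413), "2.4"),
    ]),
    "biopsy2_cDNA": _preset([
        (_hap("wt"), "53.0"),
        (_hap("germline-only", GERMLINE), "21.0"),
        (_hap("germline+c.137A>C", GERMLINE, SM_C137), "11.8"),
        (_hap("germline+c.61G>A", GERMLINE, SM_C61), "7.6"),
        (_hap("germline+c.413G>A", GERMLINE, SM_C413), "5.4"),
    ]),
    # negative control: the somatic variant rides on the wild-type allele,
    # so phasing must NOT return a cis verdict
    "biopsy1_gDNA_trans": _preset([
        (_hap("wt"), "46.5"),
        (_hap("germline-only", GERMLINE), "41.1"),
        (_hap("c.136G>A", SM_C136), "9.8"),
    ]),
    "wt_only": _preset([(_hap("wt"), "100.0")]),
}


def make_mixture(haplotypes: list[Haplotype],
                 fractions: list[float | str | Fraction]) -> HaplotypeMixture:
    """Validate a mixture; the shortfall from 1 becomes decoy mass."""
    if len(haplotypes) != len(fractions):
        raise MixtureError("haplotypes and fractions differ in length")
    fracs = [Fraction(str(f)) if isinstance(f, float) else Fraction(f)
             for f in fractions]
    if any(f < 0 for f in fracs):
        raise MixtureError("fractions must be nonnegative")
    total = sum(fracs)
    if total > 1:
        raise MixtureError(f"fractions sum to {float(total)} > 1")
    return HaplotypeMixture(entries=tuple(zip(haplotypes, fracs)),
                            decoy_fraction=1 - total)


# -- read allocation -------------------------------------------------------

def allocate_counts(mixture: HaplotypeMixture, n_reads: int,
                    mode: str = "exact",
                    rng: np.random.Generator | None = None) -> list[int]:
    """Reads per class (mixture classes in order, decoy last).

    ``exact`` uses largest-remainder rounding so each count differs from
    ``fraction * n`` by less than 1; ``multinomial`` draws from the mixture.
    """
    fracs = [f for _, f in mixture.entries] + [mixture.decoy_fraction]
    if mode == "multinomial":
        if rng is None:
            raise ValueError("multinomial allocation needs an rng")
        return list(rng.multinomial(n_reads, [float(f) for f in fracs]))
    if mode != "exact":
        raise ValueError(f"unknown allocation mode {mode!r}")
    ideal = [f * n_reads for f in fracs]
    counts = [int(x) for x in ideal]  # floor (Fractions are nonnegative)
    remainder = n_reads - sum(counts)
    order = sorted(range(len(ideal)), key=lambda i: (ideal[i] - counts[i], -i),
                   reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


# -- sequence corruption ---------------------------------------------------

def corrupt_sequence(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """One noisy copy of ``seq`` under the per-base error model."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    u = rng.random((3, n))
    # substitutions: shift to one of the three other bases
    sub = u[0] < model.p_mismatch
    idx = np.searchsorted(_BASES, arr[sub])
    arr[sub] = _BASES[(idx + rng.integers(1, 4, sub.sum())) % 4]
    keep = u[1] >= model.p_deletion
    ins = u[2] < model.p_insertion
    if not ins.any() and keep.all():
        return bytes(arr).decode()
    out = bytearray()
    ins_bases = _BASES[rng.integers(0, 4, int(ins.sum()))]
    j = 0
    for i in range(n):
        if keep[i]:
            out.append(arr[i])
        if ins[i]:
            out.append(ins_bases[j])
            j += 1
    return bytes(out).decode()


def _decoy_sequence(ref: AmpliconReference, rng: np.random.Generator) -> str:
    """An unclassifiable molecule: intact primer termini (it was amplified
    with the same primers) around a shuffled interior."""
    k = len(ref.primer_fwd)
    interior = np.frombuffer(ref.sequence[k:-k].encode(), dtype=np.uint8).copy()
    rng.shuffle(interior)
    return ref.sequence[:k] + bytes(interior).decode() + ref.sequence[-k:]


# -- subread simulation ----------------------------------------------------

def simulate_subreads(ref: AmpliconReference,
                      mixture: HaplotypeMixture,
                      n_reads: int,
                      n_passes: int,
                      error_model: ErrorModel | None = None,
                      allocation_mode: str = "exact",
                      seed: int = DEFAULT_SEED) -> SubreadSet:
    """Simulate multi-pass subreads for ``n_reads`` circularized molecules.

    Each molecule is drawn from the mixture, and each of its ``n_passes``
    passes is an independently corrupted copy of the molecule's sequence;
    orientation alternates between passes (circular template). Decoy
    molecules have shuffled interiors and never match a real haplotype.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    model = error_model if error_model is not None else ErrorModel(0.0, 0.0, 0.0)
    rng = np.random.default_rng(seed)
    counts = allocate_counts(mixture, n_reads, allocation_mode, rng)
    templates = [(h.name, apply_variants(ref, h.variants))
                 for h, _ in mixture.entries]

    records: list[SubreadRecord] = []
    rid = 0
    noise_free = (model.p_mismatch == model.p_insertion == model.p_deletion == 0.0)
    for (name, template), count in zip(templates, counts):
        for _ in range(count):
            records.append(_make_record(rid, name, template, n_passes,
                                        model, rng, noise_free))
            rid += 1
    for _ in range(counts[-1]):  # decoys
        template = _decoy_sequence(ref, rng)
        records.append(_make_record(rid, "decoy", template, n_passes,
                                    model, rng, noise_free))
        rid += 1
    return SubreadSet(records=records, reference=ref)


def _make_record(rid: int, name: str, template: str, n_passes: int,
                 model: ErrorModel, rng: np.random.Generator,
                 noise_free: bool) -> SubreadRecord:
    passes, orients = [], []
    rc = reverse_complement(template) if n_passes > 1 else None
    for k in range(n_passes):
        fwd = (k % 2 == 0)
        base = template if fwd else rc
        passes.append(base if noise_free else corrupt_sequence(base, model, rng))
        orients.append("+" if fwd else "-")
    return SubreadRecord(f"read{rid:06d}", name, passes, orients)


def simulate_ccs_reads(ref: AmpliconReference,
                       mixture: HaplotypeMixture,
                       n_reads: int,
                       residual_error: float = 0.0,
                       allocation_mode: str = "exact",
                       seed: int = DEFAULT_SEED) -> tuple[list[CcsRead], list[str]]:
    """Simulate consensus-level reads directly (post-CCS model).

    Residual consensus error is modelled as substitutions only: the
    consensus stage suppresses the indel-dominant raw noise, leaving a
    small per-base mismatch rate. Returns (reads, truth labels).
    """
    rng = np.random.default_rng(seed)
    counts = allocate_counts(mixture, n_reads, allocation_mode, rng)
    reads: list[CcsRead] = []
    truth: list[str] = []
    rid = 0
    L = ref.length
    for (hap, _), count in zip(mixture.entries, counts):
        if count == 0:
            continue
        template = np.frombuffer(apply_variants(ref, hap.variants).encode(),
                                 dtype=np.uint8)
        block = np.tile(template, (count, 1))
        if residual_error > 0:
            hit = rng.random(block.shape) < residual_error
            n_hit = int(hit.sum())
            idx = np.searchsorted(_BASES, block[hit])
            block[hit] = _BASES[(idx + rng.integers(1, 4, n_hit)) % 4]
        for row in block:
            reads.append(CcsRead(f"read{rid:06d}", bytes(row).decode(),
                                 n_passes=1, fraction_agreeing=1.0))
            truth.append(hap.name)
            rid += 1
    for _ in range(counts[-1]):
        seq = _decoy_sequence(ref, rng)
        reads.append(CcsRead(f"read{rid:06d}", seq, n_passes=1,
                             fraction_agreeing=1.0))
        truth.append("decoy")
        rid += 1
    assert len(reads) == n_reads or n_reads != sum(counts)
    return reads, truth


# -- file output -----------------------------------------------------------

def write_subreads_fastq(subreads: SubreadSet, path: str | Path) -> None:
    """FASTQ with one record per pass, named ``<read_id>/pass_<k>``."""
    records = []
    for rec in subreads.records:
        for k, (seq, orient) in enumerate(zip(rec.passes, rec.orientations), 1):
            r = SeqRecord(Seq(seq), id=f"{rec.read_id}/pass_{k}",
                          description=f"strand={orient}")
            r.letter_annotations["phred_quality"] = [30] * len(seq)
            records.append(r)
    SeqIO.write(records, str(path), "fastq")


def read_subreads_fastq(path: str | Path) -> list[SubreadRecord]:
    """Reassemble subread records from a FASTQ written by
    :func:`write_subreads_fastq` (records grouped by read id)."""
    by_read: dict[str, SubreadRecord] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        read_id, _, _ = rec.id.partition("/")
        orient = "+"
        for token in rec.description.split():
            if token.startswith("strand="):
                orient = token.split("=", 1)[1]
        entry = by_read.setdefault(
            read_id, SubreadRecord(read_id, "unknown", [], []))
        entry.passes.append(str(rec.seq).upper())
        entry.orientations.append(orient)
    return list(by_read.values())


def write_truth_tsv(subreads: SubreadSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tn_passes\n")
        for rec in subreads.records:
            fh.write(f"{rec.read_id}\t{rec.haplotype}\t{len(rec.passes)}\n")


def write_mixture_json(mixture: HaplotypeMixture, path: str | Path) -> None:
    data = {
        "classes": [
            {"name": h.name,
             "variants": [v.label for v in h.variants],
             "fraction": float(f)}
            for h, f in mixture.entries
        ],
        "decoy_fraction": float(mixture.decoy_fraction),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
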