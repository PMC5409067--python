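"""Alignment, pileup and minor-variant calling against a binomial error null.

Every primer-filtered consensus read spans the full amplicon, so reads are
aligned globally (end-to-end) to the reference and contribute one allele —
a base or a gap — at every reference position. Minor variants are then
called from the per-position pileup against a binomial sequencing-error
null: under the null, the count of a specific non-reference base at a site
is Binomial(depth, e/3), where e is the residual per-base consensus error
rate (each of the three wrong bases assumed equally likely). The upper-tail
probability is Bonferroni-corrected across all 3L possible substitutions.

The null model and its defaults (e = 0.005, alpha = 0.01, minimum
frequency 2%) are this package's definition of a conservative desk-scale
minor-variant caller for ultra-deep amplicon data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .ccs import CcsRead
from .refmodel import AmpliconReference, CoordinateTriple

#: Alignment scoring: match +2, mismatch -3, gap of length k costs 5 + 2k.
MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

_ALLELES = "ACGT-"
_ALLELE_INDEX = {c: i for i, c in enumerate(_ALLELES)}

# fast-path threshold: an equal-length read whose mismatch fraction is below
# this is taken as substitution-only (column-to-column alignment); gaps are
# expensive enough under the scoring above that this is the DP optimum for
# the small mismatch loads seen after consensus
_FAST_PATH_MAX_MISMATCH_FRAC = 0.02


@dataclass(frozen=True)
class ReadAlleles:
    """One read's allele (base or ``-``) at every reference position."""

    read_id: str
    alleles: str  # length L over A/C/G/T/-

    def __post_init__(self) -> None:
        if not set(self.alleles) <= set(_ALLELES):
            raise ValueError("alleles must be over A/C/G/T/-")


@dataclass(frozen=True)
class PileupCounts:
    """Per-position counts of A/C/G/T/- over all aligned reads."""

    counts: np.ndarray  # shape (5, L), rows in _ALLELES order
    depth: int

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class VariantCall:
    coords: CoordinateTriple
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int
    p_value: float
    q_value: float
    label: str

    @property
    def frequency(self) -> float:
        return self.alt_count / self.depth


@lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=GAP_OPEN + GAP_EXTEND,
        extend_gap_score=GAP_EXTEND,
        mode="global",
    )
    return a


def align_read(ccs: CcsRead, ref: AmpliconReference) -> ReadAlleles:
    """Globally align a consensus read to the reference.

    Returns the read's allele at every reference position; bases inserted
    relative to the reference have no reference position and are dropped.
    Equal-length reads with a small mismatch load skip the dynamic program
    (substitution-only fast path).
    """
    seq = ccs.sequence
    if not seq:
        raise ValueError("empty read")
    L = ref.length
    if seq == ref.sequence:
        return ReadAlleles(ccs.read_id, seq)
    if len(seq) == L:
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        b = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        mism = int((a != b).sum())
        if mism <= max(2, int(_FAST_PATH_MAX_MISMATCH_FRAC * L)):
            return ReadAlleles(ccs.read_id, seq)
    aln = _aligner().align(ref.sequence, seq)[0]
    alleles = ["-"] * L
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        alleles[t0:t1] = seq[q0:q1]
    return ReadAlleles(ccs.read_id, "".join(alleles))


def pileup(reads: list[ReadAlleles]) -> PileupCounts:
    """Per-position allele counts; count sums equal the read count at
    every position (global alignment covers all positions)."""
    if not reads:
        raise ValueError("no reads to pile up")
    L = len(reads[0].alleles)
    if any(len(r.alleles) != L for r in reads):
        raise ValueError("reads aligned to different references")
    mat = np.frombuffer("".join(r.alleles for r in reads).encode(),
                        dtype=np.uint8).reshape(len(reads), L)
    counts = np.zeros((5, L), dtype=np.int64)
    for i, sym in enumerate(_ALLELES):
        counts[i] = (mat == ord(sym)).sum(axis=0)
    return PileupCounts(counts=counts, depth=len(reads))


def call_minor_variants(pile: PileupCounts,
                        ref: AmpliconReference,
                        error_rate: float = 0.005,
                        alpha: float = 0.01,
                        min_frequency: float = 0.02) -> list[VariantCall]:
    """Call non-reference bases that exceed the binomial error null.

    For each position and non-reference base with count >= 1, the p-value
    is the upper-tail Binomial(depth, error_rate/3) probability of at least
    the observed count; q = p * 3L (Bonferroni over every possible
    substitution). A call requires q < alpha and frequency >= min_frequency.
    Gap alleles count toward depth but are never called.
    """
    if pile.depth == 0:
        raise ValueError("pileup depth is 0")
    if not 0 < error_rate:
        raise ValueError("error_rate must be positive")
    if error_rate >= min_frequency:
        warnings.warn("error_rate >= min_frequency: calls at the frequency "
                      "floor sit inside the expected noise band")
    L = ref.length
    ref_idx = np.array([_ALLELE_INDEX[c] for c in ref.sequence])
    base_counts = pile.counts[:4]  # gaps excluded from calling
    nonref = base_counts.copy()
    cols = np.arange(L)
    coding_mask = ref_idx < 4
    nonref[ref_idx[coding_mask], cols[coding_mask]] = 0

    rows, positions = np.nonzero(nonref)
    k = nonref[rows, positions]
    pvals = stats.binom.sf(k - 1, pile.depth, error_rate / 3.0)
    qvals = np.minimum(pvals * 3 * L, 1.0)
    freq = k / pile.depth

    calls: list[VariantCall] = []
    for row, pos, kk, p, q, f in zip(rows, positions, k, pvals, qvals, freq):
        if q >= alpha or f < min_frequency:
            continue
        ref_base = ref.sequence[pos]
        alt_base = _ALLELES[row]
        coords = ref.triple(int(pos))
        if coords.cdna_pos is not None:
            label = f"c.{coords.cdna_pos}{ref_base}>{alt_base}"
        else:
            label = f"amp.{pos + 1}{ref_base}>{alt_base}"
        calls.append(VariantCall(coords=coords, ref_base=ref_base,
                                 alt_base=alt_base, alt_count=int(kk),
                                 depth=pile.depth, p_value=float(p),
                                 q_value=float(q), label=label))
    calls.sort(key=lambda c: (c.coords.amplicon_offset, c.alt_base))
    return calls


def round_percent(count: int, total: int) -> float:
    """Percentage to one decimal, rounding half away from zero (the
    convention used for all reported read-class frequencies)."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def frequency_table(calls: list[VariantCall]) -> pd.DataFrame:
    """Variant calls as a table with percent frequencies to one decimal."""
    if not calls:
        raise ValueError("no calls to tabulate")
    return pd.DataFrame([
        {
            "label": c.label,
            "cdna_pos": c.coords.cdna_pos,
            "genomic_pos": c.coords.genomic_pos,
            "ref": c.ref_base,
            "alt": c.alt_base,
            "alt_count": c.alt_count,
            "depth": c.depth,
            "percent": round_percent(c.alt_count, c.depth),
            "q_value": c.q_value,
        }
        for c in calls
    ])


# -- VCF output ------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def write_vcf(calls: list[VariantCall], ref: AmpliconReference,
              path: str | Path,
              phase_verdicts: dict[str, str] | None = None) -> None:
    """Write calls as VCF on the genomic (minus) strand.

    The gene is on the minus strand, so genomic REF/ALT are the complements
    of the amplicon-strand alleles and records are sorted by ascending POS.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={ref.chrom}>")
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt read count">')
    header.add_line('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency">')
    header.add_line('##INFO=<ID=PQ,Number=1,Type=Float,Description="Bonferroni-corrected binomial q-value">')
    header.add_line('##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA (c.) label on the coding strand">')
    header.add_line('##INFO=<ID=PHASE,Number=1,Type=String,Description="Phase relative to the germline variant">')
    header.add_line(f"##amplihap_strand=gene on {ref.strand} strand; REF/ALT are "
                    "genomic-strand alleles (complement of coding-strand)")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in sorted(calls, key=lambda c: c.coords.genomic_pos):
            rec = vcf.new_record(
                contig=ref.chrom,
                start=c.coords.genomic_pos - 1,
                alleles=(_COMP[c.ref_base], _COMP[c.alt_base]),
            )
            rec.info["DP"] = c.depth
            rec.info["AC"] = c.alt_count
            rec.info["AF"] = c.frequency
            rec.info["PQ"] = c.q_value
            rec.info["CDNA"] = c.label.replace(">", "-to-")
            if phase_verdicts and c.label in phase_verdicts:
                rec.info["PHASE"] = phase_verdicts[c.label]
            vcf.write(rec)
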