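"""Circular-consensus construction and primer filtering.

Raw single-molecule long reads carry insertion-dominant noise; because the
template is circular, the same molecule is read several times ("passes").
:func:`build_ccs` collapses the passes of one molecule into a consensus by
progressive pairwise alignment: each pass is globally aligned (edlib) to the
running consensus, building up a column matrix, and the final call takes the
plurality base per column. Columns in which fewer than half of the passes
have a base are treated as insertion noise and dropped.

:func:`primer_filter` then applies the strict amplicon gate: a consensus
read is kept only if, in one orientation, it starts exactly with the forward
primer and ends exactly with the reverse complement of the reverse primer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import edlib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refmodel import AmpliconReference, reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class CcsRead:
    """One consensus read built from ``n_passes`` passes of a molecule."""

    read_id: str
    sequence: str
    n_passes: int
    fraction_agreeing: float  # mean per-column plurality support

    def __post_init__(self) -> None:
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if not self.sequence:
            raise ValueError("empty consensus sequence")


def _orient_passes(passes: list[str],
                   orientations: list[str] | None) -> list[str]:
    if orientations is not None:
        if len(orientations) != len(passes):
            raise ValueError("orientations and passes differ in length")
        return [p if o == "+" else reverse_complement(p)
                for p, o in zip(passes, orientations)]
    # auto-detect: each pass keeps whichever orientation aligns better to
    # the first pass
    out = [passes[0]]
    for p in passes[1:]:
        d_f = edlib.align(p, out[0], mode="NW", task="distance")["editDistance"]
        rc = reverse_complement(p)
        d_r = edlib.align(rc, out[0], mode="NW", task="distance")["editDistance"]
        out.append(rc if d_r < d_f else p)
    return out


def _plurality(column: list[str]) -> tuple[str, int]:
    """Plurality symbol of a column; ties broken toward the earliest pass."""
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for i, c in enumerate(column):
        counts[c] = counts.get(c, 0) + 1
        first.setdefault(c, i)
    best = max(counts, key=lambda c: (counts[c], -first[c]))
    return best, counts[best]


def build_ccs(passes: list[str],
              orientations: list[str] | None = None,
              read_id: str = "") -> CcsRead:
    """Collapse the passes of one molecule into a consensus read.

    Orientations ("+"/"-" per pass) may be given; otherwise each pass is
    auto-oriented against the first by best edit distance.
    """
    if not passes:
        raise ValueError("empty pass list")
    fwd = _orient_passes(passes, orientations)
    n = len(fwd)
    if all(p == fwd[0] for p in fwd):  # noise-free fast path
        return CcsRead(read_id, fwd[0], n, 1.0)

    # column matrix: cols[j][i] = base of pass i at alignment column j
    cols: list[list[str]] = [[c] for c in fwd[0]]
    for t in range(1, n):
        cols = _add_pass(cols, fwd[t], t)

    seq_chars: list[str] = []
    support_sum = 0.0
    kept = 0
    for col in cols:
        n_base = sum(1 for c in col if c != "-")
        if 2 * n_base < n:  # insertion noise: <50% of passes have a base
            continue
        base, count = _plurality([c for c in col if c != "-"])
        seq_chars.append(base)
        support_sum += count / n
        kept += 1
    sequence = "".join(seq_chars)
    if not sequence:
        raise ValueError("consensus collapsed to an empty sequence")
    return CcsRead(read_id, sequence, n, support_sum / kept)


def _working_consensus(cols: list[list[str]]) -> tuple[str, list[int]]:
    """Interim consensus over the current columns.

    Majority-gap columns are left out of the alignment target (they stay in
    the bookkeeping and re-enter the final call). Returns the consensus
    string and the column index each of its characters maps to.
    """
    chars, mapping = [], []
    for j, col in enumerate(cols):
        sym, _ = _plurality(col)
        if sym != "-":
            chars.append(sym)
            mapping.append(j)
    return "".join(chars), mapping


def _add_pass(cols: list[list[str]], p: str, t: int) -> list[list[str]]:
    cons, mapping = _working_consensus(cols)
    aln = edlib.align(p, cons, mode="NW", task="path")
    out: list[list[str]] = []
    ci = 0  # pointer over the existing columns
    qi = 0  # pointer into the pass
    ti = 0  # pointer into the interim consensus
    for count, op in _CIGAR_RE.findall(aln["cigar"]):
        for _ in range(int(count)):
            if op in ("=", "X", "M"):
                j = mapping[ti]
                while ci <= j:
                    out.append(cols[ci])
                    ci += 1
                cols[j].append(p[qi])
                qi += 1
                ti += 1
            elif op == "D":  # consensus column skipped by this pass
                j = mapping[ti]
                while ci <= j:
                    out.append(cols[ci])
                    ci += 1
                cols[j].append("-")
                ti += 1
            else:  # "I": base in the pass absent from the consensus
                out.append(["-"] * t + [p[qi]])
                qi += 1
    while ci < len(cols):
        out.append(cols[ci])
        ci += 1
    for col in out:  # columns the pass never visited (majority-gap ones)
        if len(col) < t + 1:
            col.append("-")
    return out


# -- filters ---------------------------------------------------------------

def primer_filter(reads: list[CcsRead],
                  ref: AmpliconReference) -> tuple[list[CcsRead], int]:
    """Keep reads whose termini exactly match both primers.

    A read passes if, in forward or reverse-complement orientation, it
    starts with ``primer_fwd`` and ends with ``revcomp(primer_rev)``; kept
    reads are returned forward-oriented. Any mismatch in either primer
    removes the read.
    """
    if not ref.primer_fwd or not ref.primer_rev:
        raise ValueError("primers must be non-empty")
    head = ref.primer_fwd
    tail = reverse_complement(ref.primer_rev)
    kept: list[CcsRead] = []
    removed = 0
    for r in reads:
        seq = r.sequence
        if seq.startswith(head) and seq.endswith(tail):
            kept.append(r)
            continue
        rc = reverse_complement(seq)
        if rc.startswith(head) and rc.endswith(tail):
            kept.append(CcsRead(r.read_id, rc, r.n_passes, r.fraction_agreeing))
        else:
            removed += 1
    return kept, removed


def min_pass_filter(reads: list[CcsRead], min_passes: int = 3) -> list[CcsRead]:
    """Quality gate: keep reads built from at least ``min_passes`` passes."""
    if min_passes < 1:
        raise ValueError("min_passes must be >= 1")
    return [r for r in reads if r.n_passes >= min_passes]


# -- I/O -------------------------------------------------------------------

def write_ccs_fastq(reads: list[CcsRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id,
                        description=f"np={r.n_passes} fa={r.fraction_agreeing:.4f}")
        rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_ccs_fastq(path: str | Path) -> list[CcsRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        n_passes, fa = 1, 1.0
        for token in rec.description.split():
            if token.startswith("np="):
                n_passes = int(token[3:])
            elif token.startswith("fa="):
                fa = float(token[3:])
        reads.append(CcsRead(rec.id, str(rec.seq).upper(), n_passes, fa))
    return reads


def write_filter_stats(path: str | Path, n_input: int, n_kept: int,
                       n_removed_primer: int, n_removed_passes: int) -> None:
    with open(path, "w") as fh:
        json.dump({"n_input": n_input, "n_kept": n_kept,
                   "n_removed_primer": n_removed_primer,
                   "n_removed_passes": n_removed_passes}, fh, indent=2)
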