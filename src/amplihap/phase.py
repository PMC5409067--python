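"""Read-level clonal composition and cis/trans phasing.

Because each consensus read spans the whole amplicon, every read reports
the allele at every called variant site simultaneously. Reads are sorted
into haplotype classes (wild type; germline variant only; germline plus
each combination of somatic second-site variants), giving the sample's
clonal composition. Each somatic variant is then tested for exclusivity
with the germline variant: if essentially all reads carrying the somatic
allele also carry the germline allele (one-sided Fisher exact test plus a
co-occurrence floor), the somatic variant lies *in cis* with it — the
hallmark of a second-site event on the mutant allele rather than an
independent variant of the wild-type allele.

Class frequencies use ALL kept reads as denominator, so classes need not
sum to 100%; the remainder is the unclassified residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .refmodel import AmpliconReference
from .varcall import ReadAlleles, VariantCall, round_percent

UNCLASSIFIED = "unclassified"

#: classification marks a read unclassified when its overall identity to
#: the reference drops below this (chimeric / off-target molecules)
DEFAULT_MIN_IDENTITY = 0.9


@dataclass(frozen=True)
class ReadClass:
    read_id: str
    allele_vector: tuple[str, ...]  # per site: "ref", "alt" or "other"
    class_label: str


@dataclass(frozen=True)
class ClonalTable:
    rows: pd.DataFrame  # class_label, count, percent
    total_reads: int

    def percent_of(self, class_label: str) -> float:
        hit = self.rows[self.rows["class_label"] == class_label]
        if hit.empty:
            raise KeyError(class_label)
        return float(hit["percent"].iloc[0])


@dataclass(frozen=True)
class PhaseResult:
    variant: VariantCall
    n_with_germline: int
    n_without_germline: int
    fisher_p: float
    verdict: str  # "cis", "trans" or "unphased"


def pick_germline(calls: list[VariantCall],
                  low: float = 0.3, high: float = 0.7) -> VariantCall | None:
    """The germline heterozygous anchor: the highest-frequency call whose
    frequency is compatible with heterozygosity (within [low, high])."""
    het = [c for c in calls if low <= c.frequency <= high]
    if not het:
        return None
    return max(het, key=lambda c: c.frequency)


def classify_reads(reads: list[ReadAlleles],
                   sites: list[VariantCall],
                   ref: AmpliconReference,
                   germline: VariantCall | None = None,
                   min_identity: float = DEFAULT_MIN_IDENTITY) -> list[ReadClass]:
    """Assign every read to a haplotype class over the called sites.

    A read is ``unclassified`` if any site shows neither the reference nor
    the called alternate allele, or if the read's overall identity to the
    reference is below ``min_identity``. Otherwise the label is built from
    the alternate alleles the read carries, sorted by position, with the
    germline variant singled out ("wt", "germline-only",
    "germline+c.136G>A", ...).
    """
    L = ref.length
    offsets = [s.coords.amplicon_offset for s in sites]
    for off in offsets:
        if not 0 <= off < L:
            raise ValueError(f"site offset {off} outside the reference")
    if germline is None:
        germline = pick_germline(sites)

    if not reads:
        return []
    mat = np.frombuffer("".join(r.alleles for r in reads).encode(),
                        dtype=np.uint8).reshape(len(reads), L)
    ref_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    identity = (mat == ref_arr).sum(axis=1) / L
    # identity is computed against the reference, so alt alleles at the
    # called sites count as mismatches; with a handful of sites this is
    # far below the 1 - min_identity budget
    site_cols = mat[:, offsets] if offsets else np.empty((len(reads), 0), np.uint8)
    ref_bytes = np.array([ord(s.ref_base) for s in sites], dtype=np.uint8)
    alt_bytes = np.array([ord(s.alt_base) for s in sites], dtype=np.uint8)

    somatic = [s for s in sites if germline is None or s is not germline]
    classes: list[ReadClass] = []
    for i, read in enumerate(reads):
        vec = []
        for j in range(len(sites)):
            b = site_cols[i, j]
            vec.append("ref" if b == ref_bytes[j]
                       else "alt" if b == alt_bytes[j] else "other")
        vec = tuple(vec)
        if identity[i] < min_identity or "other" in vec:
            label = UNCLASSIFIED
        else:
            carried = [s for s, v in zip(sites, vec) if v == "alt"]
            has_germ = germline is not None and germline in carried
            sms = [s.label for s in carried
                   if germline is None or s is not germline]
            if not carried:
                label = "wt"
            elif has_germ and not sms:
                label = "germline-only"
            elif has_germ:
                label = "germline+" + "+".join(sms)
            else:
                label = "+".join(sms)
        classes.append(ReadClass(read.read_id, vec, label))
    return classes


def clonal_table(classes: list[ReadClass]) -> ClonalTable:
    """Clonal-composition table: one row per class, percent of ALL kept
    reads (including unclassified), sorted by descending frequency."""
    if not classes:
        raise ValueError("no classified reads")
    total = len(classes)
    counts: dict[str, int] = {}
    for c in classes:
        counts[c.class_label] = counts.get(c.class_label, 0) + 1
    rows = pd.DataFrame([
        {"class_label": label, "count": n,
         "percent": round_percent(n, total)}
        for label, n in counts.items()
    ]).sort_values(["count", "class_label"],
                   ascending=[False, True]).reset_index(drop=True)
    return ClonalTable(rows=rows, total_reads=total)


def phase_variant(sm: VariantCall,
                  germline: VariantCall,
                  classes: list[ReadClass],
                  sites: list[VariantCall],
                  alpha: float = 0.01,
                  min_cooccurrence: float = 0.95,
                  min_carrier: int = 5) -> PhaseResult:
    """Test a somatic variant for cis/trans phase with the germline variant.

    Builds the 2x2 table (somatic alt/ref) x (germline alt/ref) over
    classified reads and applies a one-sided Fisher exact test. Verdict
    ``cis`` requires enrichment of the somatic allele on germline-alt reads
    (p < alpha) and at least ``min_cooccurrence`` of somatic carriers to be
    germline-alt; ``trans`` is the mirrored condition; anything else —
    including fewer than ``min_carrier`` carriers — is ``unphased``.
    """
    if sm.label == germline.label:
        raise ValueError("somatic and germline variants must differ")
    i_sm = next(i for i, s in enumerate(sites) if s.label == sm.label)
    i_g = next(i for i, s in enumerate(sites) if s.label == germline.label)
    a = b = c = d = 0
    for rc in classes:
        if rc.class_label == UNCLASSIFIED:
            continue
        sm_alt = rc.allele_vector[i_sm] == "alt"
        g_alt = rc.allele_vector[i_g] == "alt"
        if sm_alt and g_alt:
            a += 1
        elif sm_alt:
            b += 1
        elif g_alt:
            c += 1
        else:
            d += 1

    carriers = a + b
    if carriers < min_carrier:
        return PhaseResult(sm, a, b, 1.0, "unphased")
    table = [[a, b], [c, d]]
    p_cis = stats.fisher_exact(table, alternative="greater").pvalue
    p_trans = stats.fisher_exact(table, alternative="less").pvalue
    if p_cis < alpha and a / carriers >= min_cooccurrence:
        verdict = "cis"
        p = p_cis
    elif p_trans < alpha and b / carriers >= min_cooccurrence:
        verdict = "trans"
        p = p_trans
    else:
        verdict = "unphased"
        p = min(p_cis, p_trans)
    return PhaseResult(sm, a, b, float(p), verdict)


def cross_sample_summary(per_sample: dict[str, list[PhaseResult]]) -> pd.DataFrame:
    """Union of somatic variants across samples with per-sample frequency
    and phase verdict; one row per distinct variant label."""
    if not per_sample:
        raise ValueError("no samples")
    rows: dict[str, dict] = {}
    for sample, results in per_sample.items():
        for res in results:
            row = rows.setdefault(res.variant.label, {"label": res.variant.label})
            row[f"{sample}_percent"] = round_percent(res.variant.alt_count,
                                                     res.variant.depth)
            row[f"{sample}_verdict"] = res.verdict
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["label"]))


def clonal_table_tsv(table: ClonalTable, classes: list[ReadClass],
                     sites: list[VariantCall], path) -> None:
    """Clonal table as TSV with one wt/mut column per variant site."""
    label_vec: dict[str, tuple[str, ...]] = {}
    for rc in classes:
        label_vec.setdefault(rc.class_label, rc.allele_vector)
    out = table.rows.copy()
    for j, s in enumerate(sites):
        out[s.label] = [
            {"ref": "wt", "alt": "mut"}.get(label_vec[lab][j], "-")
            if lab in label_vec and lab != UNCLASSIFIED else "-"
            for lab in out["class_label"]
        ]
    out.to_csv(path, sep="\t", index=False)
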