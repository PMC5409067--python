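"""Trinucleotide mutational-signature attribution.

Somatic single-nucleotide variants are binned into the standard 96
trinucleotide substitution classes (six pyrimidine-reference substitution
types x 16 flanking-base pairs; purine-reference changes are
reverse-complemented onto the pyrimidine strand). The resulting spectrum
is compared to each signature in a catalog by cosine similarity, the
stability of the score is assessed by leave-one-mutation-out jackknife
resampling, and scores are normalized to the best-scoring signature
(which therefore reports exactly 1.0).

A three-signature toy catalog ships with the package: a UV-like signature
(C>T concentrated at dipyrimidines, the pattern of ultraviolet damage), a
flat background, and a C>A-dominated signature (the oxidative-damage
pattern). Real catalogs in the COSMIC TSV dialect are read with
:func:`read_catalog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refmodel import AmpliconReference, reverse_complement
from .simdata import Variant

PYRIMIDINE_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: the 96 context classes in canonical order: substitution type major,
#: then 5' flank, then 3' flank
CONTEXT_CLASSES: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in PYRIMIDINE_TYPES
    for f5 in _FLANKS
    for f3 in _FLANKS
)
_CLASS_INDEX = {c: i for i, c in enumerate(CONTEXT_CLASSES)}


class EdgeError(ValueError):
    """A variant sits too close to the amplicon edge to have both flanks."""


@dataclass(frozen=True)
class SignatureCatalog:
    """Named signatures, each a probability vector over the 96 classes."""

    signatures: dict[str, np.ndarray]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, vec in self.signatures.items():
            if vec.shape != (96,):
                raise ValueError(f"{name}: expected 96 weights, got {vec.shape}")
            if (vec < 0).any():
                raise ValueError(f"{name}: negative weights")
            if abs(float(vec.sum()) - 1.0) > 1e-6:
                raise ValueError(f"{name}: weights sum to {vec.sum()}, not 1")

    @property
    def names(self) -> list[str]:
        return list(self.signatures)


@dataclass(frozen=True)
class MutationSpectrum:
    counts: np.ndarray  # 96 nonnegative integers

    def __post_init__(self) -> None:
        if self.counts.shape != (96,) or (self.counts < 0).any():
            raise ValueError("spectrum must be 96 nonnegative counts")

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SignatureScore:
    name: str
    raw_score: float
    normalized_score: float
    jackknife_mean: float | None = None
    jackknife_se: float | None = None


# -- spectrum construction -------------------------------------------------

def mutation_context(variant: Variant, ref: AmpliconReference) -> str:
    """96-class context of a substitution, pyrimidine-strand normalized.

    If the reference base is a purine, the substitution and both flanks are
    reverse-complemented so the reported class has a pyrimidine reference.
    """
    off = ref.cdna_to_offset(variant.cdna_pos)
    if off == 0 or off == ref.length - 1:
        raise EdgeError(f"{variant.label}: no flanking base within the amplicon")
    f5 = ref.sequence[off - 1]
    f3 = ref.sequence[off + 1]
    r, a = variant.ref_base, variant.alt_base
    if r in "AG":  # purine: flip to the pyrimidine strand
        r, a = reverse_complement(r), reverse_complement(a)
        f5, f3 = reverse_complement(f3), reverse_complement(f5)
    return f"{f5}[{r}>{a}]{f3}"


def build_spectrum(variants: list[Variant], ref: AmpliconReference) -> MutationSpectrum:
    """Histogram of the variants over the 96 context classes."""
    if not variants:
        raise ValueError("no variants")
    counts = np.zeros(96, dtype=np.int64)
    for v in variants:
        counts[_CLASS_INDEX[mutation_context(v, ref)]] += 1
    return MutationSpectrum(counts=counts)


# -- scoring ---------------------------------------------------------------

def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def score_signatures(spectrum: MutationSpectrum,
                     catalog: SignatureCatalog) -> dict[str, float]:
    """Cosine similarity of the spectrum to each catalog signature."""
    if spectrum.n_mutations == 0:
        raise ValueError("all-zero spectrum")
    x = spectrum.counts.astype(float)
    return {name: cosine(x, vec) for name, vec in catalog.signatures.items()}


def jackknife_scores(variants: list[Variant], ref: AmpliconReference,
                     catalog: SignatureCatalog) -> dict[str, tuple[float, float]]:
    """Leave-one-mutation-out jackknife (mean, SE) of each signature score."""
    n = len(variants)
    if n < 2:
        raise ValueError("jackknife needs at least 2 mutations")
    replicates: dict[str, list[float]] = {name: [] for name in catalog.names}
    for i in range(n):
        subset = variants[:i] + variants[i + 1:]
        scores = score_signatures(build_spectrum(subset, ref), catalog)
        for name, s in scores.items():
            replicates[name].append(s)
    out = {}
    for name, vals in replicates.items():
        arr = np.asarray(vals)
        mean = float(arr.mean())
        if np.ptp(arr) == 0.0:  # identical replicates: SE exactly 0
            mean, se = float(arr[0]), 0.0
        else:
            se = math.sqrt((n - 1) / n * float(((arr - mean) ** 2).sum()))
        out[name] = (mean, se)
    return out


def normalize_and_rank(raw: dict[str, float],
                       jack: dict[str, tuple[float, float]] | None = None
                       ) -> list[SignatureScore]:
    """Normalize raw scores by the maximum and rank descending; the top
    signature scores exactly 1.0. Ties keep catalog (input) order."""
    if not raw:
        raise ValueError("no scores")
    top = max(raw.values())
    if top == 0:
        raise ValueError("maximum score is 0; cannot normalize")
    scored = [
        SignatureScore(
            name=name,
            raw_score=s,
            normalized_score=s / top,
            jackknife_mean=jack[name][0] if jack else None,
            jackknife_se=jack[name][1] if jack else None,
        )
        for name, s in raw.items()
    ]
    order = {name: i for i, name in enumerate(raw)}
    scored.sort(key=lambda sc: (-sc.raw_score, order[sc.name]))
    return scored


def attribute(variants: list[Variant], ref: AmpliconReference,
              catalog: SignatureCatalog) -> list[SignatureScore]:
    """Full attribution: spectrum, cosine scores, jackknife (when >= 2
    mutations), max-normalization and ranking."""
    raw = score_signatures(build_spectrum(variants, ref), catalog)
    jack = jackknife_scores(variants, ref, catalog) if len(variants) >= 2 else None
    return normalize_and_rank(raw, jack)


# -- toy catalog -----------------------------------------------------------

def toy_catalog() -> SignatureCatalog:
    """Three-signature toy catalog for tests and demos.

    * ``signature_7_UV`` — C>T with most weight at dipyrimidine contexts
      (pyrimidine 5' flank), the ultraviolet-damage pattern;
    * ``signature_flat`` — uniform background over all 96 classes;
    * ``signature_18_CA`` — weight spread over the C>A classes, an
      oxidative-damage-like pattern.
    """
    uv = np.zeros(96)
    for f5 in _FLANKS:
        for f3 in _FLANKS:
            w = 3.0 if f5 in "CT" else 1.0  # dipyrimidine-heavy
            uv[_CLASS_INDEX[f"{f5}[C>T]{f3}"]] = w
    uv /= uv.sum()
    flat = np.full(96, 1.0 / 96)
    ca = np.zeros(96)
    for f5 in _FLANKS:
        for f3 in _FLANKS:
            ca[_CLASS_INDEX[f"{f5}[C>A]{f3}"]] = 1.0
    ca /= ca.sum()
    return SignatureCatalog(
        signatures={"signature_7_UV": uv, "signature_flat": flat,
                    "signature_18_CA": ca},
        metadata={"average_mutational_burden": "not computed (toy catalog)",
                  "tissue_prevalence": "not computed (toy catalog)"},
    )


# -- catalog I/O (COSMIC TSV dialect) --------------------------------------

def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    rows = []
    for cls in CONTEXT_CLASSES:
        sub = cls[2:5]
        tri = cls[0] + cls[2] + cls[6]
        row = {"Substitution Type": sub, "Trinucleotide": tri}
        for name, vec in catalog.signatures.items():
            row[name] = vec[_CLASS_INDEX[cls]]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> SignatureCatalog:
    df = pd.read_csv(path, sep="\t")
    required = {"Substitution Type", "Trinucleotide"}
    if not required <= set(df.columns):
        raise ValueError(f"catalog missing columns {required - set(df.columns)}")
    classes = [
        f"{tri[0]}[{sub}]{tri[2]}"
        for sub, tri in zip(df["Substitution Type"], df["Trinucleotide"])
    ]
    if sorted(classes) != sorted(CONTEXT_CLASSES):
        raise ValueError("catalog does not cover the 96 classes exactly once")
    order = [_CLASS_INDEX[c] for c in classes]
    sig_cols = [c for c in df.columns if c not in required]
    signatures = {}
    for col in sig_cols:
        vec = np.zeros(96)
        vec[order] = df[col].to_numpy(dtype=float)
        signatures[col] = vec / vec.sum()  # tolerate unnormalized input
    return SignatureCatalog(signatures=signatures)


def write_score_report(scores: list[SignatureScore], path: str | Path) -> None:
    import json

    data = [
        {"rank": i + 1, "signature": s.name, "raw": s.raw_score,
         "normalized": s.normalized_score,
         "jackknife_mean": s.jackknife_mean, "jackknife_se": s.jackknife_se}
        for i, s in enumerate(scores)
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def write_spectrum_tsv(spectrum: MutationSpectrum, path: str | Path) -> None:
    pd.DataFrame({"context": CONTEXT_CLASSES,
                  "count": spectrum.counts}).to_csv(path, sep="\t", index=False)
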