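"""End-to-end orchestration: consensus reads -> variants -> clonal table ->
phase verdicts -> annotation -> signature attribution.

Each sample is analyzed independently; a cross-sample summary then unions
the somatic variants and their phase verdicts, and the pooled somatic set
is attributed to mutational signatures.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from . import annotate, ccs as ccs_mod, phase as phase_mod, signature as sig_mod
from . import simdata, varcall
from .refmodel import AmpliconReference
from .varcall import ReadAlleles, VariantCall

_CLABEL_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


def parse_variant_label(label: str) -> simdata.Variant:
    """Parse a ``c.<pos><ref>><alt>`` label into a Variant."""
    m = _CLABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse variant label {label!r}")
    return simdata.Variant(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class SampleParams:
    """Tunable knobs of the per-sample analysis."""

    error_rate: float = 0.005      # residual per-base consensus error
    alpha: float = 0.01            # familywise level for variant calls
    min_frequency: float = 0.02    # call floor, below the smallest clone of interest
    min_passes: int = 3            # consensus quality gate (subread route)
    min_identity: float = 0.9      # read-level junk screen
    max_site_frequency: float = 0.95  # near-fixed sites (homozygous
    # polymorphisms, present on all alleles) are called but excluded from
    # clonal classification and phasing
    phase_alpha: float = 0.01
    min_cooccurrence: float = 0.95
    min_carrier: int = 5
    germline_label: str | None = None  # autodetect when None


@dataclass
class SampleResult:
    name: str
    n_input: int
    n_removed_primer: int
    n_kept: int
    pile: varcall.PileupCounts
    calls: list[VariantCall]
    germline: VariantCall | None
    classes: list
    table: phase_mod.ClonalTable
    phase_results: list[phase_mod.PhaseResult]
    annotations: object  # DataFrame

    @property
    def somatic_calls(self) -> list[VariantCall]:
        """Coding, non-germline, non-fixed calls (candidate somatic set)."""
        g = self.germline.label if self.germline else None
        return [c for c in self.calls
                if c.label != g and c.coords.cdna_pos is not None
                and c.frequency <= 0.95]


def _read_alleles(reads: list[ccs_mod.CcsRead], ref: AmpliconReference,
                  min_identity: float) -> list[ReadAlleles]:
    """Per-read allele strings, with two shortcuts over plain
    :func:`varcall.align_read`: identical sequences are aligned once, and
    reads whose edit distance to the reference already exceeds the
    identity floor are recorded as all-gap (they can only ever be
    unclassified, and their alleles would be alignment noise)."""
    L = ref.length
    junk = "-" * L
    max_dist = int((1.0 - min_identity) * L)
    cache: dict[str, str] = {}
    out = []
    for r in reads:
        alleles = cache.get(r.sequence)
        if alleles is None:
            d = edlib.align(r.sequence, ref.sequence, mode="NW",
                            task="distance", k=max_dist)["editDistance"]
            if d == -1:  # beyond the identity floor
                alleles = junk
            else:
                alleles = varcall.align_read(r, ref).alleles
            cache[r.sequence] = alleles
        out.append(ReadAlleles(r.read_id, alleles))
    return out


def analyze_sample(reads: list[ccs_mod.CcsRead], ref: AmpliconReference,
                   params: SampleParams = SampleParams(),
                   name: str = "sample") -> SampleResult:
    """Analyze one sample's consensus reads end to end."""
    kept, n_removed = ccs_mod.primer_filter(reads, ref)
    if not kept:
        raise ValueError(f"{name}: no reads survive the primer filter")
    aligned = _read_alleles(kept, ref, params.min_identity)
    pile = varcall.pileup(aligned)
    calls = varcall.call_minor_variants(
        pile, ref, error_rate=params.error_rate, alpha=params.alpha,
        min_frequency=params.min_frequency)
    sites = [c for c in calls if c.frequency <= params.max_site_frequency]
    if params.germline_label is not None:
        germline = next((c for c in sites if c.label == params.germline_label),
                        None)
    else:
        germline = phase_mod.pick_germline(sites)
    classes = phase_mod.classify_reads(aligned, sites, ref, germline=germline,
                                       min_identity=params.min_identity)
    table = phase_mod.clonal_table(classes)
    phase_results = []
    if germline is not None:
        for call in sites:
            if call.label == germline.label:
                continue
            phase_results.append(phase_mod.phase_variant(
                call, germline, classes, sites,
                alpha=params.phase_alpha,
                min_cooccurrence=params.min_cooccurrence,
                min_carrier=params.min_carrier))
    coding = [parse_variant_label(c.label) for c in calls
              if c.coords.cdna_pos is not None]
    annotations = annotate.annotation_table(coding, ref) if coding else None
    return SampleResult(name=name, n_input=len(reads),
                        n_removed_primer=n_removed, n_kept=len(kept),
                        pile=pile, calls=calls, germline=germline,
                        classes=classes, table=table,
                        phase_results=phase_results, annotations=annotations)


def consensus_from_subreads(subreads: simdata.SubreadSet | list,
                            min_passes: int = 3) -> list[ccs_mod.CcsRead]:
    """Build consensus reads for every molecule and apply the pass gate."""
    records = subreads.records if hasattr(subreads, "records") else subreads
    reads = [ccs_mod.build_ccs(rec.passes, rec.orientations, rec.read_id)
             for rec in records]
    return ccs_mod.min_pass_filter(reads, min_passes) if min_passes > 1 else reads


# -- multi-sample run ------------------------------------------------------

@dataclass
class RunConfig:
    samples: dict[str, str]  # sample name -> simulation preset or FASTQ path
    n_reads: int = 10000
    n_passes: int = 3
    noise_free: bool = True
    residual_error: float = 0.0   # post-consensus substitution rate (preset route)
    params: SampleParams = field(default_factory=SampleParams)
    catalog_path: str | None = None  # None -> packaged toy catalog
    seed: int = simdata.DEFAULT_SEED
    reference_seed: int = simdata.DEFAULT_SEED

    def config_hash(self) -> str:
        blob = json.dumps({
            "samples": self.samples, "n_reads": self.n_reads,
            "n_passes": self.n_passes, "noise_free": self.noise_free,
            "residual_error": self.residual_error,
            "params": vars(self.params) | {},
            "catalog": self.catalog_path, "seed": self.seed,
            "reference_seed": self.reference_seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sample_reads(source: str, ref: AmpliconReference,
                  config: RunConfig, sample_index: int) -> list[ccs_mod.CcsRead]:
    if source in simdata.PRESETS:
        mixture = simdata.PRESETS[source]
        seed = (config.seed + 1009 * sample_index) % (2 ** 31)
        if config.residual_error > 0.0:
            reads, _ = simdata.simulate_ccs_reads(
                ref, mixture, config.n_reads,
                residual_error=config.residual_error, seed=seed)
            return reads
        model = None if config.noise_free else simdata.ErrorModel()
        subreads = simdata.simulate_subreads(
            ref, mixture, config.n_reads, config.n_passes,
            error_model=model, seed=seed)
        return consensus_from_subreads(subreads, config.params.min_passes)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"sample source {source!r}: not a preset and "
                                "not an existing FASTQ path")
    if "pass" in next(iter(r.id for r in _peek_fastq(path)), ""):
        records = simdata.read_subreads_fastq(path)
        return consensus_from_subreads(records, config.params.min_passes)
    return ccs_mod.read_ccs_fastq(path)


def _peek_fastq(path: Path):
    from Bio import SeqIO
    it = SeqIO.parse(str(path), "fastq")
    try:
        yield next(it)
    except StopIteration:
        return


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every sample, write per-sample artifacts and the run report.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = simdata.build_reference(seed=config.reference_seed)

    results: dict[str, SampleResult] = {}
    for i, (name, source) in enumerate(sorted(config.samples.items())):
        reads = _sample_reads(source, ref, config, i)
        res = analyze_sample(reads, ref, config.params, name=name)
        results[name] = res
        varcall.write_vcf(
            res.calls, ref, out / f"{name}.vcf",
            phase_verdicts={p.variant.label: p.verdict
                            for p in res.phase_results})
        phase_mod.clonal_table_tsv(res.table, res.classes, res.calls,
                                   out / f"{name}.clonal.tsv")

    per_sample_phase = {n: r.phase_results for n, r in results.items()
                        if r.phase_results}
    summary = (phase_mod.cross_sample_summary(per_sample_phase)
               if per_sample_phase else None)

    # pooled somatic set -> signature attribution
    somatic_labels = sorted({c.label for r in results.values()
                             for c in r.somatic_calls})
    somatic_variants = [parse_variant_label(lab) for lab in somatic_labels]
    signature_section = None
    if somatic_variants:
        catalog = (sig_mod.read_catalog(config.catalog_path)
                   if config.catalog_path else sig_mod.toy_catalog())
        if len(somatic_variants) >= 2:
            scores = sig_mod.attribute(somatic_variants, ref, catalog)
        else:
            raw = sig_mod.score_signatures(
                sig_mod.build_spectrum(somatic_variants, ref), catalog)
            scores = sig_mod.normalize_and_rank(raw)
        sig_mod.write_score_report(scores, out / "signature_report.json")
        signature_section = [
            {"signature": s.name, "raw": s.raw_score,
             "normalized": s.normalized_score,
             "jackknife_mean": s.jackknife_mean,
             "jackknife_se": s.jackknife_se}
            for s in scores
        ]

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "samples": {
            name: {
                "n_input": r.n_input,
                "n_removed_primer": r.n_removed_primer,
                "n_kept": r.n_kept,
                "germline": r.germline.label if r.germline else None,
                "n_variant_calls": len(r.calls),
                "clonal_table": r.table.rows.to_dict(orient="records"),
                "phase": [
                    {"variant": p.variant.label, "verdict": p.verdict,
                     "fisher_p": p.fisher_p,
                     "n_with_germline": p.n_with_germline,
                     "n_without_germline": p.n_without_germline}
                    for p in r.phase_results
                ],
                "annotations": (r.annotations.to_dict(orient="records")
                                if r.annotations is not None else []),
            }
            for name, r in results.items()
        },
        "somatic_variants": somatic_labels,
        "n_somatic_variants": len(somatic_labels),
        "cross_sample": (summary.to_dict(orient="records")
                         if summary is not None else []),
        "signatures": signature_section,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
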