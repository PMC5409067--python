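# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic data do and do not emulate.

## The analysis problem

A patient heterozygous for a dominant pathogenic variant in a single-exon
gene develops somatic second-site mutations in revertant skin clones. A
1033 bp amplicon spanning the coding exon is sequenced to ultra-deep
coverage on a single-molecule long-read platform, so each molecule yields
several "passes" that are collapsed into one circular-consensus (CCS)
read. Because one read spans the whole amplicon, the analysis can (a) call
variants down to a few percent frequency, (b) count reads per haplotype
class (the clonal composition), and (c) decide, read by read, whether each
somatic variant lies on the same allele as the germline variant (in cis)
or on the other allele (in trans).

## Amplicon reference and coordinates

The packaged reference is **synthetic**: the real gene sequence is not
bundled. It is built deterministically from a seed as
`primer_fwd | flank | CDS (681 nt = 226 codons + stop) | flank |
revcomp(primer_rev)` with total length 1033 and 21 nt primers. Codons 21,
46, 50, 138 and 148 are pinned (GGA, GAC, GAC, AGC, GCC) so that the six
bundled variants produce their intended amino-acid changes; the remaining
codons are random non-stop codons. Third-base identities at the pinned
codons are a fixture convention — they are consistent with the variants'
reference bases and amino acids but are not asserted to be the real gene
sequence.

Three coordinate systems are linked by the reference: 0-based amplicon
offsets (internal), 1-based cDNA positions (c.1 = A of ATG), and 1-based
genomic positions. The gene sits on the minus strand, so one affine
constant relates the latter two: `genomic = anchor_sum - cdna`, with
`anchor_sum = 20763721` calibrated from one known (cdna, genomic) pair and
cross-checked against the rest. No general liftover is attempted
(single-exon amplicon; out of scope by design).

## Synthetic data generator

The generator emulates the study conditions: ~10,000 molecules per sample;
a heterozygous germline variant on roughly half of the molecules; two or
three somatic variants per sample, each riding on the germline-mutant
haplotype at 2.4–12.5% clonal frequency (the packaged presets encode the
published per-sample class fractions exactly); and a small residue of
unclassifiable molecules. Allocation of reads to classes is either exact
(largest-remainder rounding, used wherever published percentages are to be
reproduced exactly) or multinomial.

Two design points deserve emphasis:

- **Decoy molecules.** The published clonal tables report class
  frequencies as percent of *all* reads, and the columns sum to slightly
  under 100%. To reproduce those numbers exactly the remainder must stay
  in the denominator, so decoys are modelled as molecules with intact
  primer termini (they were amplified by the same primers) around a
  shuffled interior: they survive the strict primer filter and are
  reported as `unclassified` by the read classifier, exactly accounting
  for the missing mass. The primer filter itself is exercised by the
  error model, which corrupts primer bases like any others.
- **Raw-read noise.** Multi-pass subreads are corrupted with an
  insertion-dominant per-base error model (defaults: insertion 8%,
  mismatch 2%, deletion 1%), the profile of raw single-molecule long
  reads; pass orientation alternates, as on a circular template.
  Post-consensus residual error is modelled separately as
  substitutions-only at a small rate (default 0.5% where used), since the
  consensus stage suppresses indel noise preferentially. Quality values,
  chimera formation and allele-specific expression are not modelled, so
  passing tests say nothing about those failure modes in real data.

## Circular consensus

`build_ccs` normalizes pass orientation (given, or auto-detected by best
edit distance to the first pass), then aligns each pass globally (edlib)
to the running consensus, accumulating an alignment-column matrix. The
final call per column is the plurality base, with ties broken toward the
earliest pass; columns in which fewer than 50% of passes have a base are
treated as insertion noise and dropped. `fraction_agreeing` is the mean
plurality support over kept columns. This is a transparent desk-scale
consensus with the same contract as production CCS tools (high-quality
per-molecule consensus), not a reimplementation of any vendor algorithm;
there is no quality-weighting. The default quality gate keeps reads with
at least 3 passes.

The primer filter implements the strict published rule: a read is kept
only if, in forward or reverse-complement orientation, it starts exactly
with the forward primer and ends exactly with the reverse complement of
the reverse primer; kept reads are returned forward-oriented.

## Alignment and variant calling

Reads are aligned globally to the amplicon with affine gap scoring
(match +2, mismatch −3, a gap of length k costs 5 + 2k), via Biopython's
`PairwiseAligner`; ties are resolved deterministically (leftmost gap
placement in homopolymers). Two performance shortcuts are used and tested:
an equal-length read with at most max(2, 2% of L) mismatches takes the
substitution-only diagonal (provably optimal for ≤2 mismatches under this
scoring, since one insertion–deletion pair costs at least 14 while a
mismatch costs 5 relative to a match), and a read whose edit distance to
the reference already exceeds the identity floor (below) is recorded as
all-gap without a full alignment, since it can only ever be unclassified.

The minor-variant caller tests, at every position and for every
non-reference base, the null that the observed count arises from residual
consensus error: `p = P[Binomial(depth, e/3) >= count]` with uniform
per-base error `e` split evenly over the three wrong bases, Bonferroni
corrected over all 3L possible substitutions. Defaults: `e = 0.005`
(residual post-consensus), familywise `alpha = 0.01`, and a 2% minimum
frequency floor chosen below the smallest clone of interest (2.4%).
Deletions are never called (gap alleles still count toward depth); indel
calling is out of scope. The null model is this package's own definition —
transparent and conservative — not a reconstruction of any proprietary
caller.

Reported percentages throughout use one decimal, rounding half away from
zero (computed in exact decimal arithmetic to avoid float boundary
artifacts, e.g. 125/10000 → 1.3).

## Clonal composition and phasing

Each read is classified over the called sites as ref/alt/other; a read is
`unclassified` if any site shows a third allele or a gap, or if its
overall identity to the reference is below 90% (the junk screen that
catches shuffled/chimeric molecules). The germline anchor is the
highest-frequency call compatible with heterozygosity (frequency within
[0.3, 0.7]), overridable by configuration; a near-fixed marker variant
would exceed this band and is thereby excluded from class labels. Class
percentages use all kept reads as denominator, so classes need not sum to
100% — matching how the published tables are laid out.

Phasing builds the 2×2 table (somatic alt/ref × germline alt/ref) over
classified reads. Verdict `cis` requires a one-sided Fisher exact
p < 0.01 **and** at least 95% of somatic carriers on the germline-alt
background, with at least 5 carrier reads; `trans` is the mirrored
condition; everything else is `unphased`. The published analysis reports
exclusivity qualitatively; these thresholds are this package's
quantitative operationalization.

## Protein consequences

Codon arithmetic is `codon = (cdna − 1) div 3 + 1`; the alternate base is
substituted into the reference codon and both codons are translated with
the standard genetic code. Changes are classified synonymous / missense /
nonsense / stop-loss and named `p.<Ref3><codon><Alt3>`. Pathogenicity
prediction and population-frequency lookup are deliberately out of scope.

## Mutational signatures

Somatic variants are binned into the 96 trinucleotide classes
(pyrimidine-strand normalized: purine-reference changes are
reverse-complemented together with their flanks). The published analysis
derives a per-signature "score" without stating its formula; here the
score is defined as the cosine similarity between the count spectrum and
each catalog signature — the standard similarity in the signature
framework. Stability is assessed by leave-one-mutation-out jackknife
(mean, and SE with the (n−1)/n jackknife factor; identical replicates
yield an exact SE of 0), and scores are normalized by the maximum so the
top signature reports exactly 1.0, ties broken by catalog order. The
packaged toy catalog has three signatures (UV-like C>T with
dipyrimidine-heavy weights, flat background, C>A-dominated); real
catalogs in the COSMIC TSV dialect are accepted as input. Burden and
prevalence priors are carried as free-text catalog metadata only — they
require external cohort data. De novo signature extraction and
non-negative exposure fitting are non-goals.

## Problem sizes and determinism

The test suite runs the exact-reproduction checks at n = 10,000 reads per
sample (the published scale) and the stochastic-robustness check at 100
seeded replicates of 10,000 reads with 0.5% residual error; raw multi-pass
consensus tests use a few hundred molecules. In the robustness check the
clonal composition is compared as each class's share of classified reads
(both truth and observation renormalized over the named classes): with
errors also hitting primer bases, read survival is uniform across classes,
so composition shares are the unbiased comparison, whereas
percent-of-all-reads would carry a systematic ~1-point deflation of the
largest class purely from reads displaced into `unclassified`. All
randomness flows through explicit integer seeds (numpy `default_rng`);
rerunning any pipeline configuration with the same seed reproduces every
numeric output exactly.

## Known limitations

- The consensus builder is plurality-based and quality-blind; at low pass
  counts its residual error is higher than production CCS.
- The error null is uniform across positions and strands; systematic
  context-specific errors would inflate false calls at the floor.
- Only single-nucleotide substitutions are called and annotated.
- One germline anchor variant is assumed; clonal phylogenies and
  multi-anchor phasing are out of scope.
- The synthetic reference shares the real amplicon's geometry and variant
  codons but not its sequence; results on it validate the pipeline's
  logic, not locus-specific alignability.
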