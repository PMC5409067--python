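"""Alignment, pileup and the binomial minor-variant caller."""

import math
from fractions import Fraction

import numpy as np
import pytest

from amplihap import pipeline, simdata
from amplihap.ccs import CcsRead
from amplihap.varcall import (GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH,
                              PileupCounts, ReadAlleles, align_read,
                              call_minor_variants, frequency_table, pileup,
                              round_percent, write_vcf, _aligner)

# ---------------------------------------------------------------------------
# brute-force Gotoh oracle (same convention: a gap of length k costs
# |GAP_OPEN| + |GAP_EXTEND| * k)


def gotoh_score(ref: str, qry: str) -> int:
    n, m = len(ref), len(qry)
    NEG = -10 ** 9
    open_ = GAP_OPEN + GAP_EXTEND  # first gap base
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in qry (ref consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (qry consumed)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = open_ + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if ref[i - 1] == qry[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + GAP_EXTEND,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + GAP_EXTEND,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def exact_binom_sf(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p), exact rational arithmetic."""
    return sum(Fraction(math.comb(n, x)) * p ** x * (1 - p) ** (n - x)
               for x in range(k, n + 1))


# ---------------------------------------------------------------------------


class TestAlignRead:
    def test_identical_read_all_match(self, ref):
        ra = align_read(CcsRead("r", ref.sequence, 1, 1.0), ref)
        assert ra.alleles == ref.sequence

    def test_single_substitution(self, ref):
        k = 400
        alt = "A" if ref.sequence[k] != "A" else "C"
        seq = ref.sequence[:k] + alt + ref.sequence[k + 1:]
        ra = align_read(CcsRead("r", seq, 1, 1.0), ref)
        assert ra.alleles[k] == alt
        assert ra.alleles[:k] == ref.sequence[:k]
        assert ra.alleles[k + 1:] == ref.sequence[k + 1:]

    def test_single_deletion_single_gap_column(self, ref):
        seq = ref.sequence[:500] + ref.sequence[501:]
        ra = align_read(CcsRead("r", seq, 1, 1.0), ref)
        assert ra.alleles.count("-") == 1

    def test_empty_read_rejected_at_construction(self):
        with pytest.raises(ValueError):
            CcsRead("r", "", 1, 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_gotoh_oracle_on_toys(self, seed):
        rng = np.random.default_rng(seed)
        bases = "ACGT"
        n = int(rng.integers(10, 30))
        refseq = "".join(bases[i] for i in rng.integers(0, 4, n))
        qry = list(refseq)
        for _ in range(int(rng.integers(1, 4))):  # a few random edits
            op = rng.integers(0, 3)
            pos = int(rng.integers(0, len(qry)))
            if op == 0:
                qry[pos] = bases[int(rng.integers(0, 4))]
            elif op == 1 and len(qry) > 5:
                del qry[pos]
            else:
                qry.insert(pos, bases[int(rng.integers(0, 4))])
        qry = "".join(qry)
        assert _aligner().align(refseq, qry).score == gotoh_score(refseq, qry)

    def test_deletion_in_homopolymer_placed_leftmost(self):
        # unique-score but tie-broken placement: deletion inside AAAA run
        refseq = "CCGTAAAACGTCC"
        qry = "CCGTAAACGTCC"
        aligner = _aligner()
        aln = aligner.align(refseq, qry)[0]
        blocks = aln.aligned[0]
        # the gap column is the first A of the run (leftmost placement)
        assert blocks[0][1] == 4

    def test_fast_path_agrees_with_dp_on_substitutions(self, ref):
        rng = np.random.default_rng(3)
        seq = list(ref.sequence)
        for pos in rng.integers(50, 1000, 5):
            seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
        seq = "".join(seq)
        fast = align_read(CcsRead("r", seq, 1, 1.0), ref).alleles
        # force the DP by perturbing length then undoing is not possible;
        # instead verify the fast-path result is score-optimal
        diag_score = sum(MATCH if a == b else MISMATCH
                         for a, b in zip(seq, ref.sequence))
        assert fast == seq
        assert _aligner().align(ref.sequence, seq).score == diag_score


class TestPileup:
    def test_perfect_reads_count_reference(self, ref):
        reads = [ReadAlleles(f"r{i}", ref.sequence) for i in range(10)]
        pile = pileup(reads)
        assert pile.depth == 10
        assert pile.counts.sum(axis=0).min() == 10
        assert pile.counts.sum() == 10 * ref.length

    def test_mixed_site_counts(self, ref):
        k = 300
        alt = "A" if ref.sequence[k] != "A" else "C"
        alt_seq = ref.sequence[:k] + alt + ref.sequence[k + 1:]
        reads = [ReadAlleles(f"r{i}", ref.sequence) for i in range(7)]
        reads += [ReadAlleles(f"a{i}", alt_seq) for i in range(3)]
        pile = pileup(reads)
        ref_row = "ACGT-".index(ref.sequence[k])
        alt_row = "ACGT-".index(alt)
        assert pile.counts[ref_row, k] == 7
        assert pile.counts[alt_row, k] == 3

    def test_conservation_on_random_gappy_reads(self, ref):
        rng = np.random.default_rng(1)
        reads = []
        for i in range(20):
            alleles = list(ref.sequence)
            for pos in rng.integers(0, ref.length, 10):
                alleles[pos] = "ACGT-"[int(rng.integers(0, 5))]
            reads.append(ReadAlleles(f"r{i}", "".join(alleles)))
        pile = pileup(reads)
        assert (pile.counts.sum(axis=0) == 20).all()

    def test_mixed_lengths_rejected(self, ref):
        with pytest.raises(ValueError):
            pileup([ReadAlleles("a", "ACGT"), ReadAlleles("b", "ACG")])


class TestCallMinorVariants:
    def _pile_with_alt(self, ref, offset, alt, alt_count, depth):
        counts = np.zeros((5, ref.length), dtype=np.int64)
        for j, b in enumerate(ref.sequence):
            counts["ACGT-".index(b), j] = depth
        ref_row = "ACGT-".index(ref.sequence[offset])
        counts[ref_row, offset] -= alt_count
        counts["ACGT-".index(alt), offset] += alt_count
        return PileupCounts(counts=counts, depth=depth)

    def test_strong_signal_called(self, ref):
        off = ref.cdna_to_offset(148)
        pile = self._pile_with_alt(ref, off, "A", 240, 10000)
        calls = call_minor_variants(pile, ref)
        assert [c.label for c in calls] == ["c.148G>A"]
        assert calls[0].q_value < 0.01
        # cross-check the p-value against the exact rational tail at the
        # same parameters but a tractable depth
        p_small = exact_binom_sf(6, 50, Fraction(1, 600))
        from scipy.stats import binom
        assert binom.sf(5, 50, 1 / 600) == pytest.approx(float(p_small),
                                                         rel=1e-9)

    def test_weak_signal_not_called(self, ref):
        off = ref.cdna_to_offset(148)
        pile = self._pile_with_alt(ref, off, "A", 3, 10000)
        assert call_minor_variants(pile, ref) == []

    def test_frequency_floor_blocks_significant_noise(self, ref):
        # 150/10000 = 1.5% is hugely significant vs the null but sits
        # below the 2% frequency floor
        off = ref.cdna_to_offset(61)
        pile = self._pile_with_alt(ref, off, "A", 150, 10000)
        assert call_minor_variants(pile, ref) == []
        assert call_minor_variants(pile, ref, min_frequency=0.01) != []

    def test_noise_free_biopsy_two_calls_exactly_four(self, ref):
        reads, _ = simdata.simulate_ccs_reads(
            ref, simdata.PRESETS["biopsy2_gDNA"], 4000, 0.0, seed=6)
        res = pipeline.analyze_sample(reads, ref)
        assert sorted(c.label for c in res.calls) == [
            "c.137A>C", "c.148G>A", "c.413G>A", "c.61G>A"]

    def test_type_one_error_controlled(self, ref):
        """On 200 error-only pileups the fraction of runs with any call
        stays within twice the familywise level (Bonferroni is
        conservative)."""
        rng = np.random.default_rng(17)
        depth, e = 800, 0.005
        n_false = 0
        for _ in range(200):
            counts = np.zeros((5, ref.length), dtype=np.int64)
            errs = rng.binomial(depth, e, size=ref.length)
            split = rng.multinomial(1, [1 / 3] * 3, size=ref.length)
            for j, b in enumerate(ref.sequence):
                ref_row = "ACGT-".index(b)
                counts[ref_row, j] = depth - errs[j]
                others = [r for r in range(4) if r != ref_row]
                alloc = rng.multinomial(errs[j], [1 / 3] * 3)
                for r, c in zip(others, alloc):
                    counts[r, j] = c
            pile = PileupCounts(counts=counts, depth=depth)
            if call_minor_variants(pile, ref):
                n_false += 1
        assert n_false / 200 <= 2 * 0.01

    def test_power_at_lowest_reported_frequency(self, ref):
        """A 2.4% clone at depth 10,000 with 0.5% residual error is called
        in >=99% of 100 simulations."""
        rng = np.random.default_rng(23)
        off = ref.cdna_to_offset(413)
        depth = 10000
        detected = 0
        for _ in range(100):
            carriers = 240
            alt = rng.binomial(carriers, 1 - 0.005) + \
                rng.binomial(depth - carriers, 0.005 / 3)
            pile = self._pile_with_alt(ref, off, "A", int(alt), depth)
            calls = call_minor_variants(pile, ref)
            if any(c.label == "c.413G>A" for c in calls):
                detected += 1
        assert detected >= 99

    def test_calls_invariant_to_read_order(self, ref):
        reads, _ = simdata.simulate_ccs_reads(
            ref, simdata.PRESETS["biopsy1_gDNA"], 1000, 0.003, seed=9)
        aligned = pipeline._read_alleles(reads, ref, 0.9)
        fwd = call_minor_variants(pileup(aligned), ref)
        rev = call_minor_variants(pileup(aligned[::-1]), ref)
        assert [(c.label, c.alt_count) for c in fwd] == \
               [(c.label, c.alt_count) for c in rev]

    def test_zero_depth_raises(self, ref):
        pile = PileupCounts(counts=np.zeros((5, ref.length), dtype=np.int64),
                            depth=0)
        with pytest.raises(ValueError):
            call_minor_variants(pile, ref)


class TestFrequencyTable:
    @pytest.mark.parametrize("count,total,expected", [
        (313, 1000, 31.3),
        (125, 10000, 1.3),    # half-away-from-zero at the 0.5 boundary
        (10000, 10000, 100.0),
        (240, 10000, 2.4),
    ])
    def test_rounding_convention(self, count, total, expected):
        assert round_percent(count, total) == expected

    def test_table_and_vcf_output(self, ref, tmp_path):
        reads, _ = simdata.simulate_ccs_reads(
            ref, simdata.PRESETS["biopsy1_gDNA"], 1000, 0.0, seed=2)
        res = pipeline.analyze_sample(reads, ref)
        df = frequency_table(res.calls)
        assert set(df["label"]) == {"c.136G>A", "c.148G>A", "c.443C>A"}
        row = df[df["label"] == "c.136G>A"].iloc[0]
        assert row["percent"] == 9.8 and row["genomic_pos"] == 20763585
        write_vcf(res.calls, ref, tmp_path / "out.vcf")
        import pysam
        with pysam.VariantFile(tmp_path / "out.vcf") as vcf:
            recs = list(vcf)
        # minus-strand gene: ascending POS is descending cDNA, alleles
        # complemented (G>A on the coding strand is C>T genomically)
        assert [r.pos for r in recs] == sorted(r.pos for r in recs)
        by_pos = {r.pos: r for r in recs}
        assert by_pos[20763585].ref == "C" and by_pos[20763585].alts == ("T",)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            frequency_table([])
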