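import math
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pysam
import pytest
from scipy import stats

from ervtrace.io import Individual, Pedigree, alignment_header
from ervtrace.simulate import simulate_site_evidence
from ervtrace.zygosity import (
    HET,
    HOM_ALT,
    HOM_REF,
    UNDETERMINED,
    SiteTally,
    apply_site_filters,
    build_population_matrix,
    call_genotype_known,
    call_genotype_novel,
    compute_aaf,
    consensus_call,
    mendelian_consistent,
    miss_probability,
    site_qc,
    tally_site_reads,
)

HEADER = alignment_header({"c1": 100_000})


def _read(name, pos, cigar):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    length = sum(n for op, n in _parse_cigar(cigar))
    a.query_sequence = "A" * length
    a.reference_name = "c1"
    a.reference_start = pos
    a.cigarstring = cigar
    a.mapping_quality = 60
    return a


def _parse_cigar(cigar):
    out, n = [], ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out.append((ch, int(n)))
            n = ""
    return out


class TestTally:
    POS = 5000

    def test_unclipped_spanning_read_is_crossing(self):
        reads = [_read("r1", self.POS - 50, "100M")]  # spans [pos-50, pos+50)
        t = tally_site_reads(reads, "c1", self.POS)
        assert (t.n_softclip, t.n_crossing) == (0, 1)

    def test_clip_at_pos_plus_10_is_softclipped(self):
        # trailing clip terminus at pos+10: inclusive margin
        reads = [_read("r1", self.POS - 90, "100M50S")]
        t = tally_site_reads(reads, "c1", self.POS)
        assert t.n_softclip == 1

    def test_read_ending_at_pos_plus_11_without_clip_is_neither(self):
        # last aligned base pos+10 sits on the margin, not beyond it
        reads = [_read("r1", self.POS - 89, "100M")]
        t = tally_site_reads(reads, "c1", self.POS)
        assert (t.n_softclip, t.n_crossing) == (0, 0)

    def test_clip_outside_margin_ignored(self):
        reads = [_read("r1", self.POS + 50, "30S70M")]
        t = tally_site_reads(reads, "c1", self.POS)
        assert t.total == 0

    def test_site_outside_contig_errors(self):
        with pytest.raises(ValueError, match="outside"):
            tally_site_reads([], "c1", 200_000, contig_length=100_000)


class TestNovelCall:
    def test_balanced_is_het(self):
        assert call_genotype_novel(SiteTally(20, 20)) == HET

    def test_boundary_at_70_percent(self):
        assert call_genotype_novel(SiteTally(29, 11)) == HOM_ALT  # 0.725
        assert call_genotype_novel(SiteTally(28, 12)) == HET  # exactly 0.70

    def test_boundary_at_30_percent(self):
        assert call_genotype_novel(SiteTally(12, 28)) == HET  # exactly 0.30
        assert call_genotype_novel(SiteTally(11, 29)) == UNDETERMINED  # 0.275

    def test_empty_tally_undetermined(self):
        assert call_genotype_novel(SiteTally(0, 0)) == UNDETERMINED


class TestKnownCall:
    def test_all_crossing_is_hom_alt(self):
        assert call_genotype_known(SiteTally(0, 40), SiteTally(0, 38)) == HOM_ALT

    def test_balanced_is_het(self):
        assert call_genotype_known(SiteTally(20, 20), SiteTally(15, 15)) == HET

    def test_inclusive_70_edge_is_het(self):
        # crossing fractions exactly 0.70 at both breakpoints
        assert call_genotype_known(SiteTally(30, 70), SiteTally(30, 70)) == HET

    def test_one_empty_tally_uses_other(self):
        assert call_genotype_known(SiteTally(0, 0), SiteTally(0, 40)) == HOM_ALT
        assert call_genotype_known(None, SiteTally(20, 20)) == HET

    def test_both_empty_undetermined(self):
        assert call_genotype_known(SiteTally(0, 0), None) == UNDETERMINED


class TestMatrix:
    def test_absent_individual_gets_hom_ref(self):
        m = build_population_matrix({"A": {"s1": 1}}, ["s1"], ["A", "B"])
        assert m.at["B", "s1"] == HOM_REF

    def test_conflicting_replicates_become_undetermined(self):
        m = build_population_matrix({"A": {"s1": [1, 2]}}, ["s1"], ["A"])
        assert m.at["A", "s1"] == UNDETERMINED

    def test_unanimous_replicates_kept(self):
        m = build_population_matrix({"A": {"s1": [1, 1, 1]}}, ["s1"], ["A"])
        assert m.at["A", "s1"] == HET
        assert consensus_call([]) == UNDETERMINED

    def test_duplicate_individuals_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_population_matrix({}, ["s1"], ["A", "A"])


class TestQC:
    def test_aaf_formula(self):
        genos = [0] * 8 + [1] * 2
        assert compute_aaf(genos) == pytest.approx(0.1)

    def test_aaf_ignores_undetermined(self):
        assert compute_aaf([2, 2, -1, -1]) == 1.0
        assert compute_aaf([-1, -1]) == 0.0

    def test_parents_00_offspring_2_is_error(self):
        assert mendelian_consistent(2, 0, 0) is False
        assert mendelian_consistent(1, 0, 0) is False
        assert mendelian_consistent(0, 0, 0) is True

    def test_duo_check(self):
        assert mendelian_consistent(2, 0, None) is False
        assert mendelian_consistent(1, 0, None) is True
        assert mendelian_consistent(2, None, None) is None

    def test_site_qc_counts(self, trio_pedigree):
        matrix = pd.DataFrame(
            {"s1": [0, 0, 2], "s2": [1, 0, 1], "s3": [-1, 0, 0]},
            index=["sire1", "dam1", "joey1"],
            dtype=np.int8,
        )
        qc, per_animal = site_qc(matrix, trio_pedigree)
        assert qc.at["s1", "mendel_error_rate"] == 1.0
        assert qc.at["s2", "mendel_error_rate"] == 0.0
        assert qc.at["s1", "aaf"] == pytest.approx(2 / 6)
        assert qc.at["s3", "undetermined_fraction"] == pytest.approx(1 / 3)
        assert per_animal["joey1"] == pytest.approx(1 / 3)

    def test_filters(self, trio_pedigree):
        matrix = pd.DataFrame(
            {"keep": [1, 0, 1], "zero_aaf": [0, 0, 0], "bad_mendel": [0, 0, 2]},
            index=["sire1", "dam1", "joey1"],
            dtype=np.int8,
        )
        qc, _ = site_qc(matrix, trio_pedigree)
        out = apply_site_filters(matrix, qc)
        assert list(out.columns) == ["keep"]

    def test_undetermined_fraction_exactly_point1_retained(self):
        inds = [f"I{i}" for i in range(10)]
        ped = Pedigree([Individual(id=i) for i in inds])
        matrix = pd.DataFrame(
            {"s1": [-1] + [1] * 9}, index=inds, dtype=np.int8
        )
        qc, _ = site_qc(matrix, ped)
        assert qc.at["s1", "undetermined_fraction"] == pytest.approx(0.1)
        assert list(apply_site_filters(matrix, qc).columns) == ["s1"]

    def test_filter_idempotent(self, trio_pedigree):
        matrix = pd.DataFrame(
            {"a": [1, 0, 1], "b": [0, 0, 0]},
            index=["sire1", "dam1", "joey1"],
            dtype=np.int8,
        )
        qc, _ = site_qc(matrix, trio_pedigree)
        once = apply_site_filters(matrix, qc)
        twice = apply_site_filters(once, qc)
        pd.testing.assert_frame_equal(once, twice)


def exact_miss_probability(c: int) -> Fraction:
    """Independent oracle: exact tail mass of Binomial(c, 1/2) outside the
    inclusive [0.3c, 0.7c] count window, via integer combinatorics."""
    lo = math.ceil(Fraction(3 * c, 10))
    hi = math.floor(Fraction(7 * c, 10))
    inside = sum(math.comb(c, k) for k in range(lo, hi + 1))
    return 1 - Fraction(inside, 2**c)


class TestMissProbability:
    def test_coverage_40_prints_as_0_6_percent(self):
        p = miss_probability(40)
        assert p == pytest.approx(0.0064266, abs=5e-7)
        assert round(100 * p, 1) == 0.6

    def test_coverage_10(self):
        assert miss_probability(10) == pytest.approx(0.109375, abs=1e-12)

    def test_coverage_1_certain_miss(self):
        assert miss_probability(1) == 1.0
        assert miss_probability(0) == 1.0

    @pytest.mark.parametrize("c", list(range(1, 21)))
    def test_matches_exact_enumeration(self, c):
        assert miss_probability(c) == pytest.approx(
            float(exact_miss_probability(c)), abs=1e-12
        )

    @pytest.mark.parametrize("c", [6, 10])
    def test_matches_literal_2_to_c_enumeration(self, c):
        lo = math.ceil(0.3 * c - 1e-9)
        hi = math.floor(0.7 * c + 1e-9)
        miss = sum(
            1 for draws in product((0, 1), repeat=c)
            if not lo <= sum(draws) <= hi
        )
        assert miss_probability(c) == pytest.approx(miss / 2**c, abs=1e-12)


class TestConfusionRates:
    def test_het_miss_frequency_matches_binomial_model(self):
        # 1e5 simulated het tallies at coverage 40: miss rate within 3 SE
        rng = np.random.default_rng(7)
        n = 100_000
        soft = rng.binomial(40, 0.5, size=n)
        missed = np.sum((soft < 12) | (soft > 28)) / n
        p = miss_probability(40)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(missed - p) < 3 * se

    def test_simulated_calls_match_model(self):
        rng = np.random.default_rng(8)
        n = 20_000
        calls = np.array(
            [
                call_genotype_novel(simulate_site_evidence(1, 40, 0.0, rng))
                for _ in range(n)
            ]
        )
        p = miss_probability(40)
        observed = np.mean(calls != HET)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) < 3 * se

    def test_goodness_of_fit_binomial(self):
        # soft-clip counts for genotype 1 vs Binomial(c, 0.5), alpha=0.01
        rng = np.random.default_rng(9)
        c, n = 20, 10_000
        counts = np.array(
            [simulate_site_evidence(1, c, 0.0, rng).n_softclip for _ in range(n)]
        )
        observed = np.bincount(counts, minlength=c + 1)
        expected = stats.binom.pmf(np.arange(c + 1), c, 0.5) * n
        mask = expected > 5
        chi2 = np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask])
        crit = stats.chi2.ppf(0.99, df=mask.sum() - 1)
        assert chi2 < crit
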