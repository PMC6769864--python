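import itertools
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitolineage import (build_site_index, classify_variable_sites,
                         collapse_haplotypes, diversity_scan, diversity_stats,
                         haplotype_diversity, pairwise_differences, summarize)

from conftest import haplotypes_of, make_alignment

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_alignment(seed, n=None, L=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(2, 20))
    L = L or int(rng.integers(5, 200))
    # skewed base draw so columns are a mix of constant/singleton/informative
    mat = np.where(rng.random((n, L)) < 0.8, BASES[0], rng.choice(BASES, size=(n, L)))
    return make_alignment([row.tobytes().decode() for row in mat.astype(np.uint8)])


# --- independent brute-force oracles -------------------------------------

def oracle_site_classes(mat):
    S = singles = informative = 0
    for c in range(mat.shape[1]):
        counts = Counter(mat[:, c])
        if len(counts) >= 2:
            S += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                informative += 1
            else:
                singles += 1
    return S, singles, informative


def oracle_k(mat):
    n = mat.shape[0]
    tot = sum((mat[i] != mat[j]).sum() for i, j in itertools.combinations(range(n), 2))
    return tot / (n * (n - 1) / 2)


def oracle_hd(counts):
    n = sum(counts)
    p2 = sum((c / n) ** 2 for c in counts)
    return n * (1 - p2) / (n - 1)


def oracle_hd_var(counts):
    n = sum(counts)
    p = [c / n for c in counts]
    s2, s3 = sum(x**2 for x in p), sum(x**3 for x in p)
    return 2 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2**2) + s2 - s2**2)


# --- collapsing ------------------------------------------------------------

class TestCollapse:
    def test_identical_sequences_one_haplotype(self):
        h = haplotypes_of(["ACGT"], [4])
        assert h.n_haplotypes == 1 and list(h.counts) == [4]

    def test_three_haplotypes_with_counts(self):
        h = haplotypes_of(["AAA", "AAT", "ATT"], [2, 1, 1])
        assert h.n_haplotypes == 3
        assert sorted(h.counts, reverse=True) == [2, 1, 1]
        # labels ordered by descending count then first occurrence
        assert list(h.counts) == [2, 1, 1]
        assert h.members["H1"] == ["s1", "s2"]

    def test_counts_partition_samples(self, yunling):
        aln, _ = yunling
        h = collapse_haplotypes(aln, build_site_index(aln))
        assert h.counts.sum() == aln.n_samples
        assert sorted(s for m in h.members.values() for s in m) == sorted(aln.sample_ids)

    def test_generator_templates_recovered(self, yunling):
        aln, truth = yunling
        h = collapse_haplotypes(aln, build_site_index(aln))
        true_part = {frozenset(v) for v in truth.haplotype_partition().values()}
        assert {frozenset(v) for v in h.members.values()} == true_part
        assert h.n_haplotypes == 47


# --- site classification ---------------------------------------------------

class TestVariableSites:
    def test_singleton_column(self):
        aln = make_alignment(["A", "A", "A", "T"])
        assert classify_variable_sites(aln, build_site_index(aln)) == (1, 1, 0)

    def test_informative_column(self):
        aln = make_alignment(["A", "A", "T", "T"])
        assert classify_variable_sites(aln, build_site_index(aln)) == (1, 0, 1)

    def test_triallelic_with_one_singleton_is_informative(self):
        aln = make_alignment(["A", "A", "T", "T", "G"])
        assert classify_variable_sites(aln, build_site_index(aln)) == (1, 0, 1)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_column_tally_oracle(self, seed):
        aln = random_alignment(seed)
        idx = build_site_index(aln)
        assert classify_variable_sites(aln, idx) == oracle_site_classes(aln.seq_matrix)


# --- Nei diversity ----------------------------------------------------------

class TestHaplotypeDiversity:
    def test_monomorphic_is_zero(self):
        hd, sd = haplotype_diversity(haplotypes_of(["ACGT"], [4]))
        assert hd == 0 and sd == 0

    def test_all_distinct_is_one(self):
        hd, _ = haplotype_diversity(haplotypes_of(["AAAA", "AAAT", "AATT", "ATTT"], [1, 1, 1, 1]))
        assert hd == pytest.approx(1.0)

    def test_counts_2_1_1(self):
        h = haplotypes_of(["AAA", "AAT", "ATT"], [2, 1, 1])
        hd, sd = haplotype_diversity(h)
        assert hd == pytest.approx(oracle_hd([2, 1, 1]))
        assert hd == pytest.approx(4 / 3 * (1 - (4 + 1 + 1) / 16))
        assert sd == pytest.approx(math.sqrt(oracle_hd_var([2, 1, 1])))

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            haplotype_diversity(haplotypes_of(["ACGT"], [1]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(1, 9), min_size=2, max_size=8))
    def test_matches_formula_oracle(self, counts):
        # distinct sequences: one mutation position per haplotype
        L = len(counts) + 1
        seqs = []
        for i in range(len(counts)):
            s = ["A"] * L
            s[i] = "T"
            seqs.append("".join(s))
        h = haplotypes_of(seqs, counts)
        hd, sd = haplotype_diversity(h)
        assert hd == pytest.approx(oracle_hd(counts))
        assert sd == pytest.approx(math.sqrt(max(oracle_hd_var(counts), 0)))


class TestPairwiseDifferences:
    def test_single_difference(self):
        h = haplotypes_of(["AAAAAAAAAA", "AAAAAAAAAT"], [1, 1])
        k, pi, _ = pairwise_differences(h)
        assert k == 1 and pi == pytest.approx(0.1)

    def test_identical_sequences_zero(self):
        k, pi, sd = pairwise_differences(haplotypes_of(["ACGT"], [5]))
        assert k == 0 and pi == 0 and sd == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_matches_double_loop_oracle(self, seed):
        aln = random_alignment(seed)
        h = collapse_haplotypes(aln, build_site_index(aln))
        k, pi, _ = pairwise_differences(h)
        assert k == pytest.approx(oracle_k(aln.seq_matrix))
        assert pi == pytest.approx(k / aln.aligned_length)

    def test_permutation_invariant(self):
        seqs = ["AATT", "ACTT", "AAGT", "AATT"]
        a = pairwise_differences(haplotypes_of(seqs, [1] * 4))
        b = pairwise_differences(haplotypes_of(seqs[::-1], [1] * 4))
        assert a == pytest.approx(b)


# --- scan -------------------------------------------------------------------

class TestDiversityScan:
    def test_peak_overlaps_planted_variation(self):
        rng = np.random.default_rng(0)
        mat = np.full((8, 300), ord("A"), dtype=np.uint8)
        mat[:4, 100:150] = ord("T")  # all variation in columns 100-150
        aln = make_alignment([r.tobytes().decode() for r in mat])
        prof = diversity_scan(aln, build_site_index(aln), window_size=50, step=10)
        peak = prof.peak()
        assert peak.start_np <= 150 and peak.end_np >= 100

    def test_empty_window_flagged_nan(self):
        aln = make_alignment(["A-AA", "ATAA"])
        prof = diversity_scan(aln, build_site_index(aln), window_size=1, step=1)
        w2 = prof.windows[prof.windows.start_np == 2].iloc[0]
        assert np.isnan(w2.Pi)

    def test_uniform_alignment_windows_near_global(self):
        aln = random_alignment(7, n=12, L=2000)
        idx = build_site_index(aln)
        prof = diversity_scan(aln, idx, window_size=500, step=250)
        _, pi, _ = pairwise_differences(collapse_haplotypes(aln, idx))
        assert prof.windows.Pi.max() < 3 * pi
        assert prof.windows.Pi.min() > pi / 3

    def test_bad_window_params(self, small_cohort):
        aln, _ = small_cohort
        with pytest.raises(ValueError):
            diversity_scan(aln, build_site_index(aln), window_size=0)

    def test_hotspot_peak(self, yunling):
        aln, truth = yunling
        prof = diversity_scan(aln, build_site_index(aln))
        peak = prof.peak()
        lo, hi = truth.hotspot
        assert lo <= peak.start_np and peak.end_np <= hi + 200


# --- summary table ----------------------------------------------------------

class TestSummarize:
    def test_single_breed_total_matches(self):
        aln = make_alignment(["AAAA", "AATA", "AATA", "TTTA"],
                             breeds={f"s{i}": "X" for i in range(1, 5)})
        hg = {"s1": "T3", "s2": "T3", "s3": "I1", "s4": "I1"}
        rep = summarize(aln, lambda a: build_site_index(a), hg).table
        assert len(rep) == 2
        x, tot = rep.iloc[0], rep.iloc[1]
        assert tot.breed == "Total"
        for col in ["n", "S", "H", "k", "Hd", "Pi"]:
            assert x[col] == tot[col]

    def test_pooling_never_decreases_S_or_H(self, yunling, table):
        from mitolineage import brahman_composition, generate_cohort, merge_cohorts
        brah = generate_cohort(brahman_composition(seed=11), table)
        aln, truth = merge_cohorts(yunling, brah)
        hg = {s.sample_id: s.haplogroup for s in truth.samples}
        rep = summarize(aln, lambda a: build_site_index(a), hg).table
        tot = rep[rep.breed == "Total"].iloc[0]
        per = rep[rep.breed != "Total"]
        assert tot.S >= per.S.max() and tot.H >= per.H.max()
        # haplogroup count columns: Total = column sums
        for hg_label in ["T1", "T3", "I1", "I2"]:
            assert tot[hg_label] == per[hg_label].sum()

    def test_small_breed_flagged_unavailable(self):
        aln = make_alignment(["AAAA", "AATA", "TATA"],
                             breeds={"s1": "X", "s2": "X", "s3": "Y"})
        rep = summarize(aln, lambda a: build_site_index(a), {}).table
        y = rep[rep.breed == "Y"].iloc[0]
        assert np.isnan(y.Hd)


def test_stats_bundle_consistency(yunling):
    aln, _ = yunling
    idx = build_site_index(aln)
    st_ = diversity_stats(aln, idx)
    assert st_.S == st_.singletons + st_.parsimony_informative
    assert 0 <= st_.Hd <= 1
    assert st_.Pi == pytest.approx(st_.k / st_.L_used)
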