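"""Diversity, divergence, LD, reference-match, and bootstrap statistics.

The headline check is oracle equivalence: pi, d_xy, Tajima's D and r^2 must
match brute-force pairwise enumeration on random small matrices with missing
data.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from centrodrive.core_io import MISSING
from centrodrive.popgen import (
    bootstrap_mean_ci,
    dxy_between_classes,
    gene_diversity,
    gene_pair_ld,
    pairwise_r2,
    reference_match_fraction,
    tajima_constants,
    tajimas_d,
)
from conftest import make_matrix


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def brute_pi_total(calls):
    """Sum over sites of the fraction of differing pairs among called lines."""
    total = 0.0
    used = 0
    for j in range(calls.shape[1]):
        col = calls[:, j]
        vals = col[col != MISSING]
        if vals.size < 2:
            continue
        used += 1
        pairs = list(itertools.combinations(vals, 2))
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total, used


def brute_dxy(a, b):
    per_site = []
    for j in range(a.shape[1]):
        va = a[:, j][a[:, j] != MISSING]
        vb = b[:, j][b[:, j] != MISSING]
        if va.size == 0 or vb.size == 0:
            continue
        per_site.append(np.mean([x != y for x in va for y in vb]))
    return float(np.mean(per_site)) if per_site else None


def brute_r2(x, y):
    joint = (x != MISSING) & (y != MISSING)
    if joint.sum() < 4:
        return None
    xv, yv = x[joint], y[joint]
    p1, p2 = xv.mean(), yv.mean()
    if p1 in (0, 1) or p2 in (0, 1):
        return None
    d = (xv * yv).mean() - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def random_matrix(rng, n_max=8, m_max=12, p_missing=0.15):
    n = rng.integers(3, n_max + 1)
    m = rng.integers(2, m_max + 1)
    calls = rng.choice([0, 1], size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < p_missing] = MISSING
    return calls


class TestOracleEquivalence:
    def test_pi_matches_enumeration(self, rng):
        for _ in range(150):
            calls = random_matrix(rng)
            g = make_matrix(calls)
            rec = gene_diversity(g)
            pi_total, used = brute_pi_total(calls)
            expected = pi_total / used if used else 0.0
            assert rec.pi == pytest.approx(expected, abs=1e-12)

    def test_dxy_matches_enumeration_and_is_symmetric(self, rng):
        for _ in range(150):
            calls = random_matrix(rng)
            k = calls.shape[0] // 2
            a, b = make_matrix(calls[:k]), make_matrix(calls[k:])
            got = dxy_between_classes(a, b)
            assert got == pytest.approx(brute_dxy(calls[:k], calls[k:]), abs=1e-12)
            assert got == pytest.approx(dxy_between_classes(b, a), abs=1e-12)

    def test_r2_matches_covariance_formula(self, rng):
        checked = 0
        for _ in range(400):
            calls = random_matrix(rng, m_max=2)
            if calls.shape[1] < 2:
                continue
            got = pairwise_r2(calls[:, 0], calls[:, 1])
            want = brute_r2(calls[:, 0], calls[:, 1])
            if want is None:
                assert got is None
            else:
                checked += 1
                assert got == pytest.approx(want, abs=1e-10)
        assert checked > 50

    def test_tajimas_d_matches_constant_formulas(self, rng):
        for _ in range(100):
            calls = random_matrix(rng, p_missing=0.0)
            n, _ = calls.shape
            g = make_matrix(calls)
            rec = gene_diversity(g)
            pi_total, _ = brute_pi_total(calls)
            S = sum(
                0 < calls[:, j].sum() < n for j in range(calls.shape[1])
            )
            if S == 0:
                assert rec.tajima_d is None
                continue
            k = tajima_constants(n)
            var = k["e1"] * S + k["e2"] * S * (S - 1)
            if var <= 0:  # degenerate normalization (e.g. n=3, S=1)
                assert rec.tajima_d is None
                continue
            expected = (pi_total - S / k["a1"]) / math.sqrt(var)
            assert rec.tajima_d == pytest.approx(expected, abs=1e-12)


class TestGeneDiversityExamples:
    def test_monomorphic_gene(self):
        g = make_matrix(np.zeros((4, 10), dtype=np.int8))
        rec = gene_diversity(g)
        assert rec.pi == 0.0 and rec.S == 0 and rec.tajima_d is None

    def test_single_balanced_site(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[:2, 3] = 1
        rec = gene_diversity(make_matrix(calls))
        assert rec.pi == pytest.approx((4 / 6) / 10)

    def test_three_singletons_in_four_lines(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[0, 0] = calls[1, 1] = calls[2, 2] = 1
        rec = gene_diversity(make_matrix(calls))
        assert rec.tajima_d == pytest.approx(-0.754, abs=5e-4)

    def test_analytic_zero_when_pi_equals_watterson(self):
        # the numerator vanishes identically when pi_total = S / a1
        for n in (4, 10, 34):
            a1 = tajima_constants(n)["a1"]
            for S in (1, 5, 12):
                assert tajimas_d(n, S, S / a1) == pytest.approx(0.0, abs=1e-12)

    def test_dxy_fixed_difference_examples(self):
        a = make_matrix(np.zeros((2, 2), dtype=np.int8))
        b = make_matrix(np.array([[1, 1], [1, 0]], dtype=np.int8))
        assert dxy_between_classes(a, b) == pytest.approx(0.75)
        same = make_matrix(np.ones((2, 2), dtype=np.int8))
        assert dxy_between_classes(same, same) == 0.0

    def test_dxy_undefined_when_class_uncovered(self):
        a = make_matrix(np.zeros((2, 2), dtype=np.int8))
        b = make_matrix(np.full((2, 2), MISSING, dtype=np.int8))
        assert dxy_between_classes(a, b) is None


class TestGenePairLD:
    def test_duplicated_and_orthogonal_snps(self):
        s1 = [0, 0, 1, 1]
        s2 = [0, 1, 0, 1]
        g = make_matrix(np.array([s1, s1, s2]).T, gene_id=["a", "a", "b"])
        pairs = {(p.gene_a, p.gene_b): p for p in gene_pair_ld(g)}
        rec = pairs[("a", "b")]
        # a has two identical SNPs: r2(s1,s2)=0 twice
        assert rec.mean_r2 == pytest.approx(0.0)
        assert rec.n_pairs == 2
        assert pairwise_r2(np.array(s1), np.array(s1)) == pytest.approx(1.0)

    def test_hand_computed_r2(self):
        s1 = np.array([0, 0, 1, 1, 1, 1], dtype=np.int8)
        s2 = np.array([0, 1, 1, 1, 1, 0], dtype=np.int8)
        assert pairwise_r2(s1, s2) == pytest.approx(0.0625)

    def test_monomorphic_pairs_skipped(self):
        g = make_matrix(
            np.array([[0, 0], [0, 1], [0, 0], [0, 1]], dtype=np.int8),
            gene_id=["a", "b"],
        )
        assert gene_pair_ld(g) == []

    def test_invariant_to_line_order_and_allele_swap(self, rng):
        calls = rng.choice([0, 1], size=(8, 6)).astype(np.int8)
        g = make_matrix(calls, gene_id=["a"] * 3 + ["b"] * 3)
        base = gene_pair_ld(g)[0].mean_r2
        perm = rng.permutation(8)
        g2 = make_matrix(calls[perm], gene_id=["a"] * 3 + ["b"] * 3)
        assert gene_pair_ld(g2)[0].mean_r2 == pytest.approx(base)
        flipped = calls.copy()
        flipped[:, 2] = 1 - flipped[:, 2]
        g3 = make_matrix(flipped, gene_id=["a"] * 3 + ["b"] * 3)
        assert gene_pair_ld(g3)[0].mean_r2 == pytest.approx(base)


class TestReferenceMatch:
    def _matrix(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[1] = [1, 1, 1, 1, 1, 1, 1, 1, 0, 0]  # polymorphic at 8 sites
        calls[2] = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]  # matches ref at 8/10... see below
        return make_matrix(calls, line_ids=["ref", "other", "near"])

    def test_reference_line_scores_one(self):
        out = reference_match_fraction(self._matrix(), "ref", min_poly=7)
        assert out.loc["ref"].dropna().eq(1.0).all()

    def test_fraction_counts_polymorphic_sites_only(self):
        out = reference_match_fraction(self._matrix(), "ref", min_poly=7)
        # 8 polymorphic sites (cols 0-7); 'near' matches ref at 6 of them
        assert out.loc["near", "g1"] == pytest.approx(6 / 8)

    def test_sparse_gene_is_masked(self):
        calls = np.zeros((3, 6), dtype=np.int8)
        calls[1] = 1  # 6 polymorphic sites < 7
        g = make_matrix(calls)
        out = reference_match_fraction(g, "L0", min_poly=7)
        assert out.isna().all().all()

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            reference_match_fraction(self._matrix(), "nope")


class TestBootstrap:
    def test_constant_vector_degenerates(self):
        ci = bootstrap_mean_ci([3.0] * 8, seed=1)
        assert ci.lo == ci.hi == ci.mean == 3.0

    def test_deterministic_given_seed(self):
        v = [1.0, 2.0, 5.0, 9.0]
        a = bootstrap_mean_ci(v, seed=42)
        b = bootstrap_mean_ci(v, seed=42)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_nominal_coverage_on_normal_samples(self, rng):
        hits = 0
        reps = 200
        for r in range(reps):
            sample = rng.normal(loc=2.0, size=25)
            ci = bootstrap_mean_ci(sample, n_boot=400, seed=int(rng.integers(2**31)))
            hits += ci.lo <= 2.0 <= ci.hi
        assert 0.88 <= hits / reps <= 0.99

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_ci([np.nan])
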