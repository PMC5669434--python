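"""Rst/AMOVA variance components, permutation tests, YHRD filtering."""

import itertools

import numpy as np
import pytest

from conftest import make_population
from ystrpop.alleles import AlleleValue
from ystrpop.core import PopulationDataset
from ystrpop.rst import (
    RstConfig,
    bonferroni_threshold,
    pairwise_rst,
    permutation_test,
    rst_matrix_with_bonferroni,
    yhrd_filter,
)


def brute_force_rst(group_a, group_b):
    """Independent AMOVA oracle: explicit loops over every individual pair
    of single-locus allele lists."""
    pooled = list(group_a) + list(group_b)
    n_a, n_b = len(group_a), len(group_b)
    n = len(pooled)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += (pooled[i] - pooled[j]) ** 2
    ss_total /= n
    ss_within = 0.0
    for grp in (group_a, group_b):
        acc = 0.0
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                acc += (grp[i] - grp[j]) ** 2
        ss_within += acc / len(grp)
    ss_among = ss_total - ss_within
    s2_within = ss_within / (n - 2)
    n_prime = n - (n_a ** 2 + n_b ** 2) / n
    s2_among = (ss_among - s2_within) / n_prime
    if s2_among + s2_within == 0:
        raise ZeroDivisionError
    return s2_among / (s2_among + s2_within)


def test_rst_is_one_for_fixed_difference(single_locus_panel):
    pa = make_population("a", [(10,), (10,)])
    pb = make_population("b", [(12,), (12,)])
    assert pairwise_rst(pa, pb).rst == pytest.approx(1.0)


def test_rst_nonpositive_for_identical_populations():
    pa = make_population("a", [(10,), (12,), (11,), (13,)])
    pb = make_population("b", [(10,), (12,), (11,), (13,)])
    assert pairwise_rst(pa, pb).rst <= 1e-12


def test_rst_matches_brute_force_oracle_exhaustively():
    """Agreement with the explicit-pair AMOVA oracle on every dataset with
    N <= 6 over alleles {9, 10, 11} (plus seeded draws up to N = 8 from a
    wider allele range)."""
    alleles = (9, 10, 11)
    checked = 0
    for n_a in (2, 3):
        for n_b in (2, 3):
            for ga in itertools.combinations_with_replacement(alleles, n_a):
                for gb in itertools.combinations_with_replacement(alleles, n_b):
                    try:
                        expected = brute_force_rst(ga, gb)
                    except ZeroDivisionError:
                        continue
                    pa = make_population("a", [(v,) for v in ga])
                    pb = make_population("b", [(v,) for v in gb])
                    assert pairwise_rst(pa, pb).rst == pytest.approx(
                        expected, abs=1e-10
                    )
                    checked += 1
    assert checked > 100

    rng = np.random.default_rng(7)
    for _ in range(200):
        n_a = rng.integers(2, 5)
        n_b = rng.integers(2, min(9 - n_a, 5))
        ga = rng.integers(8, 15, size=n_a).tolist()
        gb = rng.integers(8, 15, size=n_b).tolist()
        try:
            expected = brute_force_rst(ga, gb)
        except ZeroDivisionError:
            continue
        pa = make_population("a", [(v,) for v in ga])
        pb = make_population("b", [(v,) for v in gb])
        assert pairwise_rst(pa, pb).rst == pytest.approx(expected, abs=1e-10)


def test_rst_symmetric_and_order_invariant():
    pa = make_population("a", [(10, 21), (12, 20), (11, 23)])
    pb = make_population("b", [(14, 20), (13, 22), (15, 21), (14, 23)])
    pa_shuffled = make_population("a", [(11, 23), (10, 21), (12, 20)])
    r1 = pairwise_rst(pa, pb).rst
    r2 = pairwise_rst(pb, pa).rst
    r3 = pairwise_rst(pa_shuffled, pb).rst
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert r1 == pytest.approx(r3, abs=1e-12)


def test_rst_invariant_under_repeat_shift():
    vecs_a = [(10, 21), (12, 20), (11, 23)]
    vecs_b = [(14, 20), (13, 22), (15, 21)]
    shift = lambda vs: [(a + 5, b + 5) for a, b in vs]
    r1 = pairwise_rst(make_population("a", vecs_a), make_population("b", vecs_b)).rst
    r2 = pairwise_rst(
        make_population("a", shift(vecs_a)), make_population("b", shift(vecs_b))
    ).rst
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_exhaustive_permutation_p_value():
    pa = make_population("a", [(10,), (10,)])
    pb = make_population("b", [(12,), (12,)])
    res = permutation_test(pa, pb, exhaustive=True)
    assert res.p_value == pytest.approx(2 / 6)


def test_permutation_deterministic_given_seed():
    rng = np.random.default_rng(5)
    pa = make_population("a", [tuple(rng.integers(10, 15, 3)) for _ in range(8)])
    pb = make_population("b", [tuple(rng.integers(10, 15, 3)) for _ in range(8)])
    cfg = RstConfig(n_permutations=500, rng_seed=42)
    p1 = permutation_test(pa, pb, cfg).p_value
    p2 = permutation_test(pa, pb, cfg).p_value
    assert p1 == p2


def test_singleton_population_rejected():
    pa = make_population("a", [(10,)])
    pb = make_population("b", [(12,), (13,)])
    with pytest.raises(ValueError, match="n < 2"):
        pairwise_rst(pa, pb)


# ---------------------------------------------------------------------------
# YHRD filter
# ---------------------------------------------------------------------------

def test_filter_keeps_microvariant_at_excluded_locus(modal_yfiler_haplotype):
    hap = modal_yfiler_haplotype("s1", DYS458=AlleleValue.microvariant(18, 2))
    ds = PopulationDataset("P", [hap])
    res = yhrd_filter(ds, RstConfig(excluded_loci=frozenset({"DYS458"})))
    assert res.dataset.n == 1
    assert "DYS458" not in res.dataset.haplotypes[0].calls


def test_filter_removes_duplicated_allele_outside_dys385(modal_yfiler_haplotype):
    hap = modal_yfiler_haplotype(
        "s1",
        DYS448=AlleleValue.multi(AlleleValue.integer(19), AlleleValue.integer(20)),
    )
    res = yhrd_filter(PopulationDataset("P", [hap]), RstConfig())
    assert res.dataset.n == 0
    assert res.removed == [("s1", "duplicated allele 19,20 at DYS448")]


def test_filter_removes_null_and_microvariant_elsewhere(modal_yfiler_haplotype):
    haps = [
        modal_yfiler_haplotype("s1", DYS392=AlleleValue.null()),
        modal_yfiler_haplotype("s2", DYS389II=AlleleValue.microvariant(30, 3)),
        modal_yfiler_haplotype("s3"),
    ]
    res = yhrd_filter(PopulationDataset("P", haps), RstConfig())
    assert [h.sample_id for h in res.dataset] == ["s3"]
    assert len(res.removed) == 2


def test_filter_keeps_regular_haplotypes_minus_excluded_loci(modal_yfiler_haplotype):
    ds = PopulationDataset("P", [modal_yfiler_haplotype("s1")])
    res = yhrd_filter(ds, RstConfig())
    hap = res.dataset.haplotypes[0]
    assert "DYS458" not in hap.calls
    assert len(hap.calls) == 16


# ---------------------------------------------------------------------------
# matrix + Bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_default_m_and_flags():
    rng = np.random.default_rng(3)
    pops = [
        make_population(f"p{k}", [tuple(rng.integers(10 + 3 * k, 14 + 3 * k, 2)) for _ in range(6)])
        for k in range(3)
    ]
    cfg = RstConfig(n_permutations=99, rng_seed=1)
    matrix, results = rst_matrix_with_bonferroni(pops, cfg)
    assert len(results) == 3
    for res in results.values():
        assert res.significant_raw == (res.p_value < 0.05)
        assert res.significant_bonferroni == (res.p_value < 0.05 / 3)
    assert np.allclose(matrix.values, matrix.values.T)


def test_bonferroni_threshold_276_comparisons():
    assert bonferroni_threshold(0.05, 276) == 0.0002


def test_matrix_needs_two_datasets():
    with pytest.raises(ValueError):
        rst_matrix_with_bonferroni([make_population("a", [(1,), (2,)])], RstConfig())
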