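"""Gene diversity, forensic summaries, and the variant census."""

import itertools
import math

import pytest

from ystrpop.alleles import AlleleValue
from ystrpop.core import PopulationDataset
from ystrpop.forensic import (
    allele_frequencies,
    average_gene_diversity,
    forensic_summary,
    gene_diversity,
    variant_census,
)
from ystrpop.panel import YFILER_17


def brute_force_mismatch_probability(counts):
    """Probability two draws without replacement differ (the oracle)."""
    labels = list(
        itertools.chain.from_iterable([i] * c for i, c in enumerate(counts))
    )
    pairs = list(itertools.permutations(labels, 2))
    return sum(1 for a, b in pairs if a != b) / len(pairs)


def _count_vectors(max_n):
    for n in range(2, max_n + 1):
        # all partitions of n
        def parts(n, max_part):
            if n == 0:
                yield ()
                return
            for p in range(min(n, max_part), 0, -1):
                for rest in parts(n - p, p):
                    yield (p,) + rest

        yield from parts(n, n)


def test_gene_diversity_equals_mismatch_probability_exhaustively():
    """GD must equal the without-replacement mismatch probability for
    every count vector with n <= 8."""
    for counts in _count_vectors(8):
        assert gene_diversity(counts) == pytest.approx(
            brute_force_mismatch_probability(counts), abs=1e-12
        )


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([2, 1, 1], 0.8333333333),
        ([5], 0.0),
        ([1] * 7, 1.0),
        ([1, 1], 1.0),
    ],
)
def test_gene_diversity_known_values(counts, expected):
    assert gene_diversity(counts) == pytest.approx(expected, abs=1e-9)


def test_gene_diversity_rejects_tiny_samples():
    with pytest.raises(ValueError):
        gene_diversity([1])


def test_frequencies_single_sample(modal_yfiler_haplotype):
    ds = PopulationDataset("P", [modal_yfiler_haplotype("s1")])
    freq = allele_frequencies(ds, YFILER_17)
    for locus in freq.loci:
        assert all(f == 1.0 for f in freq.frequencies(locus).values())


def test_frequencies_empty_dataset_rejected():
    with pytest.raises(ValueError):
        allele_frequencies(PopulationDataset("P", []), YFILER_17)


def test_irregular_calls_are_their_own_frequency_categories(modal_yfiler_haplotype):
    haps = [
        modal_yfiler_haplotype("s1", DYS458=AlleleValue.microvariant(18, 2)),
        modal_yfiler_haplotype("s2", DYS392=AlleleValue.null()),
        modal_yfiler_haplotype("s3"),
        modal_yfiler_haplotype("s4"),
    ]
    freq = allele_frequencies(PopulationDataset("P", haps), YFILER_17)
    assert freq.frequencies("DYS458")["18.2"] == pytest.approx(0.25)
    assert freq.frequencies("DYS392")["Null"] == pytest.approx(0.25)


def test_summary_of_identical_pair(modal_yfiler_haplotype):
    ds = PopulationDataset(
        "P", [modal_yfiler_haplotype("s1"), modal_yfiler_haplotype("s2")]
    )
    s = forensic_summary(ds, YFILER_17)
    assert s.hd == 0.0
    assert s.dc_percent == pytest.approx(50.0)
    assert s.uh_percent == 0.0


def test_summary_invariant_to_order_and_ids(modal_yfiler_haplotype):
    a = [
        modal_yfiler_haplotype("s1", DYS19=AlleleValue.integer(14)),
        modal_yfiler_haplotype("s2", DYS19=AlleleValue.integer(15)),
        modal_yfiler_haplotype("s3", DYS19=AlleleValue.integer(15)),
    ]
    b = [
        modal_yfiler_haplotype("x9", DYS19=AlleleValue.integer(15)),
        modal_yfiler_haplotype("x7", DYS19=AlleleValue.integer(14)),
        modal_yfiler_haplotype("x8", DYS19=AlleleValue.integer(15)),
    ]
    sa = forensic_summary(PopulationDataset("P", a), YFILER_17)
    sb = forensic_summary(PopulationDataset("P", b), YFILER_17)
    assert sa.hd == pytest.approx(sb.hd, abs=1e-15)
    assert (sa.n_unique, sa.n_different) == (sb.n_unique, sb.n_different)


def test_duplicating_a_haplotype_never_increases_unique_count(modal_yfiler_haplotype):
    base = [
        modal_yfiler_haplotype("s1", DYS19=AlleleValue.integer(14)),
        modal_yfiler_haplotype("s2", DYS19=AlleleValue.integer(15)),
    ]
    before = forensic_summary(PopulationDataset("P", base), YFILER_17)
    extended = base + [modal_yfiler_haplotype("s3", DYS19=AlleleValue.integer(14))]
    after = forensic_summary(PopulationDataset("P", extended), YFILER_17)
    assert after.n_unique <= before.n_unique


def test_dys385_gene_diversity_uses_the_unordered_pair(modal_yfiler_haplotype):
    haps = [
        modal_yfiler_haplotype(
            "s1",
            DYS385a=AlleleValue.integer(11),
            DYS385b=AlleleValue.integer(14),
        ),
        modal_yfiler_haplotype(
            "s2",
            DYS385a=AlleleValue.integer(11),
            DYS385b=AlleleValue.integer(14),
        ),
        modal_yfiler_haplotype(
            "s3",
            DYS385a=AlleleValue.integer(12),
            DYS385b=AlleleValue.integer(14),
        ),
    ]
    s = forensic_summary(PopulationDataset("P", haps), YFILER_17)
    assert "DYS385a/b" in s.gd
    assert "DYS385a" not in s.gd
    # pair categories {11,14}x2 and {12,14}: GD = (3/2)(1 - 5/9)
    assert s.gd["DYS385a/b"] == pytest.approx(gene_diversity([2, 1]))


def test_average_gd_counts_dys385_as_one_locus():
    gd = {"DYS19": 0.5, "DYS390": 0.7, "DYS385a/b": 0.9}
    avg_with, avg_without = average_gene_diversity(gd)
    assert avg_without == pytest.approx(0.6)
    assert avg_with == pytest.approx((0.5 + 0.7 + 0.9) / 3)


# ---------------------------------------------------------------------------
# variant census
# ---------------------------------------------------------------------------

def test_census_of_regular_data_is_empty(modal_yfiler_haplotype):
    ds = PopulationDataset(
        "P", [modal_yfiler_haplotype(f"s{i}") for i in range(4)]
    )
    census = variant_census(ds, YFILER_17)
    assert census.table.empty
    assert census.n_allelic_variants == 0


def test_census_finds_single_injected_null(modal_yfiler_haplotype):
    haps = [modal_yfiler_haplotype(f"s{i}") for i in range(9)]
    haps.append(modal_yfiler_haplotype("s9", DYS392=AlleleValue.null()))
    census = variant_census(PopulationDataset("P", haps), YFILER_17)
    assert len(census.table) == 1
    assert census.overall_frequency("DYS392", "Null") == pytest.approx(0.1)
    assert census.n_null_loci == 1


def test_census_classifies_off_ladder_integers_as_variants(modal_yfiler_haplotype):
    # DYS456 allele 12 lies below the Yfiler ladder range (13-18)
    haps = [modal_yfiler_haplotype(f"s{i}") for i in range(3)]
    haps.append(modal_yfiler_haplotype("s3", DYS456=AlleleValue.integer(12)))
    census = variant_census(PopulationDataset("P", haps), YFILER_17)
    assert census.n_allelic_variants == 1
    assert census.entries("allelic_variant")["locus"].tolist() == ["DYS456"]


def test_census_ignores_normal_dys385_pairs_but_flags_microvariants(
    modal_yfiler_haplotype,
):
    haps = [
        modal_yfiler_haplotype("s1"),  # ordinary 11,14 pair
        modal_yfiler_haplotype(
            "s2",
            DYS385a=AlleleValue.microvariant(15, 2),
            DYS385b=AlleleValue.integer(17),
        ),
    ]
    census = variant_census(PopulationDataset("P", haps), YFILER_17)
    assert census.n_biallelic_patterns == 0
    entries = census.entries("allelic_variant")
    assert entries["locus"].tolist() == ["DYS385a/b"]
    assert entries["variant"].tolist() == ["15.2, 17"]
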