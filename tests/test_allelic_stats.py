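"""Exact binomial test, folded odds ratio, BH correction, event calling."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnpscan import allelic_stats as als

from conftest import dual_site, make_counts


# independent oracles -------------------------------------------------------

def brute_force_two_sided_p(k: int, n: int) -> float:
    """Enumerate the Binomial(n, 1/2) pmf exactly with integer arithmetic."""
    total = Fraction(2) ** n
    lower = sum(math.comb(n, j) for j in range(0, k + 1))
    upper = sum(math.comb(n, j) for j in range(k, n + 1))
    p = 2 * min(Fraction(lower, 1), Fraction(upper, 1)) / total
    return float(min(Fraction(1), p))


def brute_force_bh(pvalues):
    """Textbook step-up: sort, scale by m/rank, running minimum from the top."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top, idx in enumerate(reversed(order)):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# binomial_two_sided_p ------------------------------------------------------

@pytest.mark.parametrize("k,n,expected", [
    (10, 20, 1.0),                      # central value, capped
    (15, 20, 0.04138946533203125),      # 2 * 21700 / 2**20
    (20, 20, 2 / 2**20),                # extreme tail
    (6, 10, 0.75390625),                # 2 * 386 / 1024
])
def test_binomial_p_frozen_values(k, n, expected):
    assert als.binomial_two_sided_p(k, n) == pytest.approx(expected, rel=1e-12)


def test_binomial_p_matches_enumeration_exhaustively():
    """Exact agreement with integer pmf enumeration for all n <= 50."""
    for n in range(1, 51):
        k = np.arange(n + 1)
        got = als.binomial_two_sided_p(k, np.full(n + 1, n))
        want = [brute_force_two_sided_p(int(j), n) for j in k]
        np.testing.assert_allclose(got, want, rtol=1e-10)


def test_binomial_p_rejects_invalid_input():
    with pytest.raises(ValueError):
        als.binomial_two_sided_p(0, 0)
    with pytest.raises(ValueError):
        als.binomial_two_sided_p(5, 4)


# folded_odds_ratio ---------------------------------------------------------

@pytest.mark.parametrize("ref,alt,expected,extreme", [
    (15, 5, 3.0, False),
    (5, 15, 3.0, False),    # folding symmetry
    (10, 0, 21.0, True),    # Haldane-Anscombe 10.5/0.5
    (0, 10, 21.0, True),
])
def test_folded_odds_ratio(ref, alt, expected, extreme):
    ratio, flag = als.folded_odds_ratio(ref, alt)
    assert ratio == pytest.approx(expected)
    assert flag is extreme


def test_folded_odds_ratio_requires_reads():
    with pytest.raises(ValueError):
        als.folded_odds_ratio(0, 0)


# bh_adjust -----------------------------------------------------------------

def test_bh_frozen_example_and_identity():
    np.testing.assert_allclose(
        als.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(als.bh_adjust([0.5]), [0.5])


def test_bh_matches_brute_force_on_random_vectors(rng):
    for _ in range(200):
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(als.bh_adjust(p), brute_force_bh(p), rtol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
def test_bh_is_order_equivariant(pvalues, pyrandom):
    perm = list(range(len(pvalues)))
    pyrandom.shuffle(perm)
    direct = als.bh_adjust([pvalues[i] for i in perm])
    permuted = np.asarray(als.bh_adjust(pvalues))[perm]
    np.testing.assert_allclose(direct, permuted, rtol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        als.bh_adjust([0.5, 1.5])


# call_allelic_events -------------------------------------------------------

def test_single_concordant_site_becomes_ase_event():
    counts = make_counts(dual_site("rs1", "S1", "RNA", (16, 4), (15, 5)))
    outcome = als.compute_test_results(counts, als.TestConfig())
    row = outcome.results.iloc[0]
    assert row["p_reference"] == pytest.approx(0.011817932128906, rel=1e-9)
    assert row["p_alternative"] == pytest.approx(0.041389465332031, rel=1e-9)
    assert row["or_reference"] == pytest.approx(4.0)
    assert row["or_alternative"] == pytest.approx(3.0)
    assert len(outcome.events) == 1
    event = outcome.events.iloc[0]
    assert event["event_class"] == "ASE" and event["direction"] == "ref"


def test_discordant_alternative_target_blocks_event():
    counts = make_counts(dual_site("rs1", "S1", "RNA", (15, 5), (10, 10)))
    assert als.call_allelic_events(counts).empty


def test_passing_or_with_nonsignificant_p_is_no_event():
    counts = make_counts(dual_site("rs1", "S1", "RNA", (6, 4), (6, 4)))
    outcome = als.compute_test_results(counts)
    assert outcome.results.iloc[0]["p_reference"] == pytest.approx(0.75390625)
    assert outcome.events.empty


def test_histone_mark_site_is_asb_with_mark():
    counts = make_counts(dual_site("rs1", "S1", "H3K27ac", (18, 2), (17, 3)))
    events = als.call_allelic_events(counts)
    assert list(events["event_class"]) == ["ASB"]
    assert list(events["mark"]) == ["H3K27ac"]


def test_single_target_sites_skipped_and_counted():
    counts = make_counts([("rs1", "S1", "RNA", "reference", 16, 4)])
    outcome = als.compute_test_results(counts)
    assert outcome.n_skipped_single_target == 1
    assert outcome.results.empty


def test_low_coverage_sites_excluded():
    counts = make_counts(dual_site("rs1", "S1", "RNA", (5, 0), (4, 1)))
    outcome = als.compute_test_results(counts, als.TestConfig(min_coverage=10))
    assert outcome.n_low_coverage == 1 and outcome.results.empty


def test_empty_input_returns_empty_tables():
    outcome = als.compute_test_results(make_counts([]))
    assert outcome.results.empty and outcome.events.empty


def test_bh_families_split_rna_from_chip():
    # Identical counts, different families: the lone RNA site keeps
    # padj == p, while the same site in the two-member ChIP family is
    # adjusted by m/rank = 2.
    rows = (
        dual_site("rs0", "S1", "RNA", (16, 4), (16, 4))
        + dual_site("rs1", "S1", "H3K4me3", (16, 4), (16, 4))
        + dual_site("rs2", "S1", "H3K27ac", (15, 5), (15, 5))
    )
    outcome = als.compute_test_results(make_counts(rows))
    res = outcome.results.set_index("snp_id")
    assert res.loc["rs0", "padj_reference"] == pytest.approx(
        res.loc["rs0", "p_reference"]
    )
    assert res.loc["rs1", "padj_reference"] == pytest.approx(
        2 * res.loc["rs1", "p_reference"]
    )


def test_tied_counts_have_no_direction_and_never_an_event():
    counts = make_counts(dual_site("rs1", "S1", "RNA", (10, 10), (10, 10)))
    outcome = als.compute_test_results(counts)
    assert outcome.results.iloc[0]["direction_reference"] == "none"
    assert outcome.events.empty


def test_swapping_allele_labels_flips_direction_preserves_stats():
    fwd = make_counts(
        dual_site("rs1", "S1", "RNA", (16, 4), (15, 5))
        + dual_site("rs2", "S1", "H3K9ac", (3, 17), (4, 16))
    )
    rev = fwd.rename(columns={"ref_reads": "alt_reads", "alt_reads": "ref_reads"})
    out_f = als.compute_test_results(fwd)
    out_r = als.compute_test_results(rev)
    for col in ("p_reference", "p_alternative", "or_reference", "or_alternative"):
        np.testing.assert_allclose(out_f.results[col], out_r.results[col])
    flip = {"ref": "alt", "alt": "ref", "none": "none"}
    assert [flip[d] for d in out_f.results["direction_reference"]] == \
        list(out_r.results["direction_reference"])
    assert set(out_f.events["snp_id"]) == set(out_r.events["snp_id"])
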