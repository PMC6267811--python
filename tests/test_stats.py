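"""The statistical battery against enumeration and closed-form oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st_h
from scipy import stats as sps

from varrep.annotation import CategoryCounts, ChromosomeBackground
from varrep.model import FrequencyEntry, FrequencyTable, VariantRecord
from varrep.stats import (
    benign_contamination,
    binomial_two_tailed,
    chromosome_bias_profile,
    coverage,
    expected_counts,
    ks_two_sample,
    pearson_chi_square,
)


# ---------------------------------------------------------------------------
# Expected counts


def test_expected_counts_exact_proportionality():
    assert expected_counts({"a": 1, "b": 1, "c": 2}, 8) == {"a": 2.0, "b": 2.0,
                                                            "c": 4.0}
    assert expected_counts({"only": 3.5}, 77) == {"only": 77.0}


def test_expected_counts_sum_to_total():
    rng = np.random.default_rng(5)
    w = {f"c{i}": float(x) for i, x in enumerate(rng.uniform(0, 10, 24))}
    exp = expected_counts(w, 445989)
    assert np.isclose(sum(exp.values()), 445989)


def test_expected_counts_zero_weights_rejected():
    with pytest.raises(ValueError):
        expected_counts({"a": 0.0, "b": 0.0}, 10)


# ---------------------------------------------------------------------------
# Two-tailed binomial


def _binomial_enumeration(k, n, p0):
    """Direct enumeration over all n+1 outcomes (minimum-likelihood rule)."""
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def test_binomial_modal_outcome_has_p_one():
    assert binomial_two_tailed(1, 2, 0.5) == 1.0


@pytest.mark.parametrize("p0", [0.1, 0.3, 0.5])
def test_binomial_equals_enumeration_oracle(p0):
    for n in range(1, 21):
        for k in range(n + 1):
            assert binomial_two_tailed(k, n, p0) == pytest.approx(
                _binomial_enumeration(k, n, p0), rel=1e-9
            )


def test_binomial_agrees_with_independent_implementation():
    # scipy's modern binomtest implements the same two-sided definition
    # through a different algorithm; spot check against it.
    rng = np.random.default_rng(9)
    for _ in range(50):
        n = int(rng.integers(1, 500))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.05, 0.95))
        assert binomial_two_tailed(k, n, p0) == pytest.approx(
            sps.binomtest(k, n, p0).pvalue, rel=1e-6
        )


def test_binomial_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        binomial_two_tailed(5, 4, 0.5)
    with pytest.raises(ValueError):
        binomial_two_tailed(1, 4, 0.0)


# ---------------------------------------------------------------------------
# Chi-square


def test_chi_square_zero_when_observed_equals_expected():
    stat, p = pearson_chi_square({"a": 5.0, "b": 7.0}, {"a": 5.0, "b": 7.0})
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi_square_three_cell_hand_computation():
    observed = {"a": 10.0, "b": 20.0, "c": 30.0}
    expected = {"a": 15.0, "b": 15.0, "c": 30.0}
    stat, p = pearson_chi_square(observed, expected)
    hand = (10 - 15) ** 2 / 15 + (20 - 15) ** 2 / 15 + 0.0
    assert stat == pytest.approx(hand)
    assert p == pytest.approx(float(sps.chi2.sf(hand, 2)))


def test_chi_square_relabeling_and_quadratic_scaling():
    rng = np.random.default_rng(2)
    o = rng.uniform(1, 50, 6)
    e = rng.uniform(1, 50, 6)
    e *= o.sum() / e.sum()
    keys = [f"k{i}" for i in range(6)]
    stat1, _ = pearson_chi_square(dict(zip(keys, o)), dict(zip(keys, e)))
    perm = np.random.default_rng(3).permutation(6)
    stat2, _ = pearson_chi_square(
        dict(zip(keys, o[perm])), dict(zip(keys, e[perm]))
    )
    assert stat1 == pytest.approx(stat2)
    stat3, _ = pearson_chi_square(
        dict(zip(keys, 4 * o)), dict(zip(keys, 4 * e))
    )
    assert stat3 == pytest.approx(4 * stat1)


def test_chi_square_key_mismatch_and_zero_cells_rejected():
    with pytest.raises(ValueError):
        pearson_chi_square({"a": 1.0}, {"b": 1.0})
    with pytest.raises(ValueError, match="zero cells"):
        pearson_chi_square({"a": 1.0, "b": 2.0}, {"a": 3.0, "b": 0.0})


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def _ks_brute_force_d(a, b):
    points = sorted(set(a) | set(b))
    return max(
        abs(sum(x <= t for x in a) / len(a) - sum(x <= t for x in b) / len(b))
        for t in points
    )


def test_ks_identical_samples():
    d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert d == 0.0 and p == pytest.approx(1.0)


@given(
    st_h.lists(st_h.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
    st_h.lists(st_h.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
)
def test_ks_statistic_equals_brute_force_ecdf_gap(a, b):
    d, _ = ks_two_sample(a, b)
    assert d == pytest.approx(_ks_brute_force_d(a, b))
    # Independent check of D against scipy's implementation.
    assert d == pytest.approx(float(sps.ks_2samp(a, b).statistic))


def test_ks_asymptotic_p_reproduces_reference_values():
    # Frequency vectors of three categories realising D = 1/3 and D = 2/3.
    d, p = ks_two_sample([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
    assert d == pytest.approx(1 / 3)
    assert p == pytest.approx(0.97621, abs=5e-4)
    d, p = ks_two_sample([1.0, 2.0, 3.0], [2.5, 3.5, 4.5])
    assert d == pytest.approx(2 / 3)
    assert p == pytest.approx(0.31972, abs=5e-4)


def test_ks_exact_mode_matches_scipy_exact():
    a, b = [0.1, 0.5, 0.9, 1.3], [0.2, 0.6, 1.4]
    d, p = ks_two_sample(a, b, mode="exact")
    ref = sps.ks_2samp(a, b, method="exact")
    assert d == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue))


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


# ---------------------------------------------------------------------------
# Coverage


def test_coverage_reference_ratios():
    assert round(100 * coverage(set(range(700)), set(range(907))).coverage, 2) \
        == 77.18
    assert round(
        100 * coverage(set(range(17343)), set(range(17637))).coverage, 2
    ) == 98.33


def test_coverage_bounds_and_excess():
    full = coverage({"a", "b"}, {"a", "b"})
    assert full.coverage == 1.0 and full.classes_in_dataset == 2
    none = coverage(set(), {"a", "b"})
    assert none.coverage == 0.0
    ex = coverage({"a", "z"}, {"a", "b"})
    assert ex.classes_in_dataset == 1 and ex.excess_labels == 1
    with pytest.raises(ValueError):
        coverage({"a"}, set())


@given(
    st_h.sets(st_h.integers(0, 30), max_size=15),
    st_h.sets(st_h.integers(0, 30), max_size=15),
    st_h.sets(st_h.integers(0, 30), min_size=1, max_size=31),
)
def test_coverage_monotone_under_union(d1, d2, bg):
    c1 = coverage(d1, bg).coverage
    c12 = coverage(d1 | d2, bg).coverage
    assert c12 >= c1
    assert 0 <= c12 <= 1


# ---------------------------------------------------------------------------
# Contamination screen


def _freq_table(rows):
    return FrequencyTable(
        populations=("p1", "p2"),
        entries=[FrequencyEntry(*r) for r in rows],
    )


def _mapped_record(acc, pos, ref_aa, alt_aa):
    return VariantRecord(
        dataset_label="t", ref_namespace="uniprot", ref_id=acc, position=pos,
        ref_aa=ref_aa, alt_aa=alt_aa, canonical_protein=acc,
        mapping_status="protein_mapped",
    )


def test_contamination_window_is_strict():
    table = _freq_table([("P1", 5, "A", "V", (0.25, 0.25)),
                         ("P2", 6, "G", "D", (0.01, 0.01))])
    records = [_mapped_record("P1", 5, "A", "V"), _mapped_record("P2", 6, "G", "D")]
    result = benign_contamination(records, table)
    assert result.matched == 0
    assert result.fraction == 0.0


def test_contamination_matches_nested_loop_join():
    rng = np.random.default_rng(4)
    accs = [f"P{i}" for i in range(8)]
    aas = list("ACDEFGHIK")
    rows = []
    for _ in range(60):
        ref_aa, alt_aa = rng.choice(aas, size=2, replace=False)
        rows.append(
            (str(rng.choice(accs)), int(rng.integers(1, 6)), str(ref_aa),
             str(alt_aa), (float(rng.uniform(0, 0.5)), float(rng.uniform(0, 0.5))))
        )
    table = _freq_table(rows)
    records = []
    for _ in range(80):
        ref_aa, alt_aa = rng.choice(aas, size=2, replace=False)
        records.append(
            _mapped_record(str(rng.choice(accs)), int(rng.integers(1, 6)),
                           str(ref_aa), str(alt_aa))
        )
    result = benign_contamination(records, table)
    brute = sum(
        1
        for r in records
        if any(
            e.accession == r.canonical_protein and e.position == r.position
            and e.ref_aa == r.ref_aa and e.alt_aa == r.alt_aa
            and any(0.01 < m < 0.25 for m in e.mafs)
            for e in table.entries
        )
    )
    assert result.matched == brute
    assert result.total == 80


# ---------------------------------------------------------------------------
# Chromosome profile


def test_profile_flags_equal_componentwise_binomial():
    rng = np.random.default_rng(7)
    chroms = [str(i) for i in range(1, 9)]
    genes = {c: int(rng.integers(50, 500)) for c in chroms}
    cds = {c: int(rng.integers(10_000, 90_000)) for c in chroms}
    observed = {c: int(rng.integers(0, 400)) for c in chroms}
    cc = CategoryCounts("chromosome", "chromosome",
                        __import__("collections").Counter(observed),
                        sum(observed.values()))
    results, unb_gene, unb_cds = chromosome_bias_profile(
        cc, ChromosomeBackground(genes, cds), alpha=0.05
    )
    n = sum(observed.values())
    for r in results:
        p_gene = binomial_two_tailed(observed[r.chromosome], n,
                                     genes[r.chromosome] / sum(genes.values()))
        assert r.p_gene == p_gene
        assert r.biased_gene == (p_gene <= 0.05)
    assert unb_gene == sum(1 for r in results if not r.biased_gene)
    exp_sum = sum(r.expected_gene for r in results)
    assert exp_sum == pytest.approx(n, rel=1e-9)


def test_profile_exactly_proportional_observed_is_unbiased_everywhere():
    genes = {"1": 10, "2": 20, "3": 30}
    cds = {"1": 1000, "2": 2000, "3": 3000}
    observed = {"1": 10, "2": 20, "3": 30}
    cc = CategoryCounts("chromosome", "chromosome",
                        __import__("collections").Counter(observed), 60)
    results, unb_gene, unb_cds = chromosome_bias_profile(
        cc, ChromosomeBackground(genes, cds), alpha=0.5
    )
    assert unb_gene == unb_cds == 3
    assert all(r.p_gene == 1.0 for r in results)


def test_profile_unknown_chromosome_rejected():
    cc = CategoryCounts("chromosome", "chromosome",
                        __import__("collections").Counter({"99": 5}), 5)
    with pytest.raises(ValueError, match="99"):
        chromosome_bias_profile(cc, ChromosomeBackground({"1": 10}, {"1": 100}))
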