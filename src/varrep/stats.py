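"""Statistical battery for representativeness assessment.

* Per-chromosome two-tailed binomial tests against gene-count- and
  CDS-length-weighted expectations, plus Pearson's chi-square over all
  chromosomes.
* Two-sample Kolmogorov-Smirnov on per-category frequency vectors, with the
  classical asymptotic p-value (Kolmogorov distribution evaluated at
  ``(e_n + 0.12 + 0.11/e_n) * D`` with ``e_n = sqrt(n*m/(n+m))``); an exact
  permutation-distribution alternative is available for honest small-sample
  use.
* Coverage A(DS)/A of classification schemes.
* The benign-contamination screen against a population allele-frequency
  table (minor allele frequency strictly between 1 % and 25 % in at least
  one population).

The two-tailed binomial p-value follows the minimum-likelihood definition:
the sum of Binomial(n, p0) probabilities of all outcomes whose probability
mass does not exceed the mass at k, with a 1 + 1e-7 relative slack on the
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import special, stats as sps

DEFAULT_ALPHA_CHROMOSOME = 0.05
DEFAULT_ALPHA_KS = 0.01
MAF_LOW = 0.01
MAF_HIGH = 0.25


@dataclass
class ChromosomeTestResult:
    chromosome: str
    observed: int
    expected_gene: float
    expected_cds: float
    p_gene: float
    p_cds: float
    biased_gene: bool
    biased_cds: bool


@dataclass
class DistributionTestResult:
    scheme: str
    level: str
    statistic: Optional[float]
    p_value: Optional[float]
    biased: Optional[bool]
    n_dataset: int
    n_background: int
    statistic_type: str = "KS"
    computable: bool = True
    note: str = ""


@dataclass
class CoverageResult:
    scheme: str
    level: str
    classes_in_dataset: int
    classes_total: int
    coverage: float
    excess_labels: int = 0


@dataclass
class ContaminationResult:
    matched: int
    total: int
    fraction: float  # percentage
    maf_low: float = MAF_LOW
    maf_high: float = MAF_HIGH


def expected_counts(
    weights: Mapping[str, float], total_observed: int
) -> dict[str, float]:
    """Expectations proportional to *weights*, summing to *total_observed*."""
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("weights must have positive sum")
    return {k: total_observed * wi / total_w for k, wi in zip(keys, w)}


def binomial_two_tailed(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-tailed binomial test p-value.

    Sums Binomial(n, p0) probabilities of all outcomes whose mass is at most
    the mass at *k* (with 1 + 1e-7 relative slack).  Returns a p in (0, 1].
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    d = sps.binom.pmf(k, n, p0)
    rerr = 1 + 1e-7
    if k == p0 * n:
        return 1.0
    if k < p0 * n:
        i = np.arange(np.ceil(p0 * n), n + 1)
        y = int(np.sum(sps.binom.pmf(i, n, p0) <= d * rerr))
        pval = sps.binom.cdf(k, n, p0) + sps.binom.sf(n - y, n, p0)
    else:
        i = np.arange(np.floor(p0 * n) + 1)
        y = int(np.sum(sps.binom.pmf(i, n, p0) <= d * rerr))
        pval = sps.binom.cdf(y - 1, n, p0) + sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, pval))


def pearson_chi_square(
    observed: Mapping[str, float], expected: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson's chi-square over matching category keys; dof = k - 1."""
    if set(observed) != set(expected):
        raise ValueError(
            "observed and expected must cover the same categories; "
            f"difference: {set(observed) ^ set(expected)}"
        )
    keys = sorted(observed)
    e = np.array([expected[k] for k in keys], dtype=float)
    if np.any(e <= 0):
        zero = [k for k in keys if expected[k] <= 0]
        raise ValueError(f"expected counts must be positive; zero cells: {zero}")
    o = np.array([observed[k] for k in keys], dtype=float)
    stat, p = sps.chisquare(o, e)
    return float(stat), float(p)


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    data_all = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), data_all, side="right") / len(a)
    cdf_b = np.searchsorted(np.sort(b), data_all, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_two_sample(
    sample_a: Sequence[float], sample_b: Sequence[float], mode: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``asymptotic`` evaluates the Kolmogorov distribution at
    ``(e_n + 0.12 + 0.11/e_n) * D`` (the small-sample-corrected classical
    approximation); ``exact`` uses the exact two-sample null distribution.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires two non-empty samples")
    d = _ks_statistic(a, b)
    if mode == "asymptotic":
        en = np.sqrt(a.size * b.size / (a.size + b.size))
        p = float(special.kolmogorov((en + 0.12 + 0.11 / en) * d))
        p = float(min(1.0, max(0.0, p)))
    elif mode == "exact":
        p = float(sps.ks_2samp(a, b, method="exact").pvalue)
    else:
        raise ValueError(f"mode must be 'asymptotic' or 'exact', got {mode!r}")
    return d, p


def coverage(
    dataset_labels: set, background_labels: set, scheme: str = "", level: str = ""
) -> CoverageResult:
    """Coverage A(DS)/A: the fraction of background classes with at least
    one representative in the dataset.  Labels outside the background are
    counted separately, never added to the numerator."""
    if not background_labels:
        raise ValueError("background label set is empty")
    inside = set(dataset_labels) & set(background_labels)
    return CoverageResult(
        scheme=scheme,
        level=level,
        classes_in_dataset=len(inside),
        classes_total=len(background_labels),
        coverage=len(inside) / len(background_labels),
        excess_labels=len(set(dataset_labels) - set(background_labels)),
    )


def benign_contamination(
    records,
    table,
    low: float = MAF_LOW,
    high: float = MAF_HIGH,
) -> ContaminationResult:
    """Fraction of records matching a frequency-table substitution whose
    minor allele frequency lies strictly in (low, high) in >= 1 population.

    A record matches on identical (canonical accession, position, reference
    residue, alternate residue).  The denominator is all records passed in.
    """
    frequent = {
        (e.accession, e.position, e.ref_aa, e.alt_aa)
        for e in table.entries
        if any(low < m < high for m in e.mafs)
    }
    matched = sum(
        1
        for r in records
        if r.canonical_protein is not None
        and (r.canonical_protein, r.position, r.ref_aa, r.alt_aa) in frequent
    )
    total = len(records)
    fraction = round(100.0 * matched / total, 2) if total else 0.0
    return ContaminationResult(
        matched=matched, total=total, fraction=fraction, maf_low=low, maf_high=high
    )


def chromosome_bias_profile(
    observed,
    background,
    alpha: float = DEFAULT_ALPHA_CHROMOSOME,
) -> tuple[list[ChromosomeTestResult], int, int]:
    """Per-chromosome binomial tests under both weight bases.

    *observed* is a chromosome :class:`~varrep.annotation.CategoryCounts`;
    *background* a :class:`~varrep.annotation.ChromosomeBackground`.  The
    test sample size is ``observed.total_assigned``.  Returns the per
    chromosome results plus the unbiased counts (p > alpha) under the gene
    and CDS bases.  A chromosome observed but absent from the background is
    an error.
    """
    missing = set(observed.counts) - set(background.gene_counts)
    if missing:
        raise ValueError(
            f"chromosomes absent from the background: {sorted(missing)}"
        )
    n = observed.total_assigned
    exp_gene = expected_counts(background.gene_counts, n)
    exp_cds = expected_counts(background.cds_lengths, n)
    gene_total = sum(background.gene_counts.values())
    cds_total = sum(background.cds_lengths.values())
    results = []
    for chrom in background.gene_counts:
        k = int(observed.counts.get(chrom, 0))
        p_gene = binomial_two_tailed(k, n, background.gene_counts[chrom] / gene_total)
        p_cds = binomial_two_tailed(k, n, background.cds_lengths[chrom] / cds_total)
        results.append(
            ChromosomeTestResult(
                chromosome=chrom,
                observed=k,
                expected_gene=exp_gene[chrom],
                expected_cds=exp_cds[chrom],
                p_gene=p_gene,
                p_cds=p_cds,
                biased_gene=p_gene <= alpha,
                biased_cds=p_cds <= alpha,
            )
        )
    unbiased_gene = sum(1 for r in results if not r.biased_gene)
    unbiased_cds = sum(1 for r in results if not r.biased_cds)
    return results, unbiased_gene, unbiased_cds
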