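"""Per-dataset assessment: mapping, tests, coverage, and the summary score.

The summary score awards one point per category test (CATH class /
architecture / topology / homology, EC levels 1-4, Pfam, GO terms, GO
aspect) whose distribution is unbiased (p above the KS significance level);
the per-chromosome unbiased count is reported separately and excluded from
the categorical score.  A category that cannot be computed (for example
CATH levels when no variant reached a structure) scores 0 and is annotated
explicitly, never silently omitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import annotation as ann
from . import stats as st
from .mapping import MappedDataset, MappingTally, map_dataset
from .model import STATUS_PROTEIN, STATUS_STRUCTURE, FrequencyTable, ProteomeReference

#: Categories entering the summary score, in reporting order.
SCORE_CATEGORIES: tuple[tuple[str, str], ...] = (
    ("cath", "class"),
    ("cath", "architecture"),
    ("cath", "topology"),
    ("cath", "homology"),
    ("ec", "1"),
    ("ec", "2"),
    ("ec", "3"),
    ("ec", "4"),
    ("pfam", "family"),
    ("go", "term"),
    ("go", "aspect"),
)


@dataclass
class AssessmentConfig:
    alpha_chromosome: float = st.DEFAULT_ALPHA_CHROMOSOME
    alpha_ks: float = st.DEFAULT_ALPHA_KS
    chromosome_basis: str = "gene"  # gene | cds : basis for the unbiased count
    multiplicity: str = "per_category"  # Pfam/GO multi-assignment policy
    ks_mode: str = "asymptotic"  # asymptotic | exact
    maf_low: float = st.MAF_LOW
    maf_high: float = st.MAF_HIGH

    def validate(self) -> None:
        if self.chromosome_basis not in ("gene", "cds"):
            raise ValueError(f"chromosome_basis must be gene|cds, got {self.chromosome_basis!r}")
        if self.ks_mode not in ("asymptotic", "exact"):
            raise ValueError(f"ks_mode must be asymptotic|exact, got {self.ks_mode!r}")
        for name in ("alpha_chromosome", "alpha_ks", "maf_low", "maf_high"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class SummaryScore:
    chromosome_unbiased_count: int
    category_flags: dict[str, int]  # "scheme:level" -> 0/1, reporting order
    score_without_chromosomes: int
    not_computable: list[str] = field(default_factory=list)


@dataclass
class DatasetReport:
    label: str
    n_records: int
    tally: MappingTally
    chromosome_tests: list[st.ChromosomeTestResult]
    chromosome_chi2_gene: tuple[float, float]
    chromosome_chi2_cds: tuple[float, float]
    unbiased_chromosomes_gene: int
    unbiased_chromosomes_cds: int
    distribution_tests: list[st.DistributionTestResult]
    coverages: list[st.CoverageResult]
    score: SummaryScore
    contamination: Optional[st.ContaminationResult] = None
    unique_cath_superfamilies: int = 0
    config: AssessmentConfig = field(default_factory=AssessmentConfig)

    def test(self, scheme: str, level: str) -> st.DistributionTestResult:
        for t in self.distribution_tests:
            if t.scheme == scheme and t.level == level:
                return t
        raise KeyError(f"no test for {scheme}:{level}")

    def coverage_of(self, scheme: str, level: str) -> st.CoverageResult:
        for c in self.coverages:
            if c.scheme == scheme and c.level == level:
                return c
        raise KeyError(f"no coverage for {scheme}:{level}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_records": self.n_records,
            "mapping": {
                "n_total": self.tally.n_total,
                "n_protein_mapped": self.tally.n_protein_mapped,
                "n_structure_mapped": self.tally.n_structure_mapped,
                "pct_protein_mapped": self.tally.pct_protein_mapped,
                "pct_structure_mapped": self.tally.pct_structure_mapped,
                "max_per_protein": self.tally.max_per_protein,
                "max_accession": self.tally.max_accession,
                "n_unique_proteins": len(self.tally.per_protein),
            },
            "chromosomes": {
                "chi2_gene": list(self.chromosome_chi2_gene),
                "chi2_cds": list(self.chromosome_chi2_cds),
                "unbiased_gene": self.unbiased_chromosomes_gene,
                "unbiased_cds": self.unbiased_chromosomes_cds,
                "tests": [
                    {
                        "chromosome": t.chromosome,
                        "observed": t.observed,
                        "expected_gene": t.expected_gene,
                        "expected_cds": t.expected_cds,
                        "p_gene": t.p_gene,
                        "p_cds": t.p_cds,
                        "biased_gene": t.biased_gene,
                        "biased_cds": t.biased_cds,
                    }
                    for t in self.chromosome_tests
                ],
            },
            "distribution_tests": [
                {
                    "scheme": t.scheme,
                    "level": t.level,
                    "statistic_type": t.statistic_type,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "biased": t.biased,
                    "n_dataset": t.n_dataset,
                    "n_background": t.n_background,
                    "computable": t.computable,
                    "note": t.note,
                }
                for t in self.distribution_tests
            ],
            "coverage": [
                {
                    "scheme": c.scheme,
                    "level": c.level,
                    "classes_in_dataset": c.classes_in_dataset,
                    "classes_total": c.classes_total,
                    "excess_labels": c.excess_labels,
                    "coverage_pct": round(100.0 * c.coverage, 2),
                }
                for c in self.coverages
            ],
            "contamination": (
                None
                if self.contamination is None
                else {
                    "matched": self.contamination.matched,
                    "total": self.contamination.total,
                    "fraction_pct": self.contamination.fraction,
                    "maf_low": self.contamination.maf_low,
                    "maf_high": self.contamination.maf_high,
                }
            ),
            "unique_cath_superfamilies": self.unique_cath_superfamilies,
            "score": {
                "chromosome_unbiased_count": self.score.chromosome_unbiased_count,
                "category_flags": dict(self.score.category_flags),
                "score_without_chromosomes": self.score.score_without_chromosomes,
                "not_computable": list(self.score.not_computable),
            },
        }


def score_dataset(
    tests: dict[tuple[str, str], st.DistributionTestResult],
    chromosome_unbiased_count: int,
    alpha_ks: float = st.DEFAULT_ALPHA_KS,
) -> SummaryScore:
    """Flag each category 1 (unbiased: p > alpha) or 0; sum the flags."""
    flags: dict[str, int] = {}
    not_computable: list[str] = []
    for scheme, level in SCORE_CATEGORIES:
        key = f"{scheme}:{level}"
        t = tests.get((scheme, level))
        if t is None or not t.computable or t.p_value is None:
            flags[key] = 0
            not_computable.append(key)
        else:
            flags[key] = int(t.p_value > alpha_ks)
    return SummaryScore(
        chromosome_unbiased_count=chromosome_unbiased_count,
        category_flags=flags,
        score_without_chromosomes=sum(flags.values()),
        not_computable=not_computable,
    )


def _ks_or_not_computable(
    dataset_counts: ann.CategoryCounts,
    background_counts: ann.CategoryCounts,
    config: AssessmentConfig,
) -> st.DistributionTestResult:
    scheme, level = dataset_counts.scheme, dataset_counts.level
    n_ds = len(dataset_counts.counts)
    n_bg = len(background_counts.counts)
    if dataset_counts.total_assigned == 0 or background_counts.total_assigned == 0:
        reason = (
            "no dataset assignments at this level"
            if dataset_counts.total_assigned == 0
            else "empty background at this level"
        )
        return st.DistributionTestResult(
            scheme, level, None, None, None, n_ds, n_bg,
            computable=False, note=reason,
        )
    d, p = st.ks_two_sample(
        list(dataset_counts.frequencies().values()),
        list(background_counts.frequencies().values()),
        mode=config.ks_mode,
    )
    return st.DistributionTestResult(
        scheme, level, d, p, p <= config.alpha_ks, n_ds, n_bg
    )


def assess_dataset(
    records,
    reference: ProteomeReference,
    freq_table: Optional[FrequencyTable] = None,
    config: Optional[AssessmentConfig] = None,
    label: Optional[str] = None,
) -> DatasetReport:
    """Run the full assessment pipeline over one dataset.

    Maps every record, projects into all category spaces, tests each level
    against its background, computes coverages, the contamination screen
    (when a frequency table is given) and the summary score.  Fully
    deterministic for fixed inputs.
    """
    config = config or AssessmentConfig()
    config.validate()
    label = label or (records[0].dataset_label if records else "dataset")

    mapped = map_dataset(list(records), reference)

    # Chromosome battery
    chrom_counts = ann.chromosome_counts(mapped.records, reference)
    chrom_bg = ann.build_background(reference, "chromosome")
    chrom_tests, unb_gene, unb_cds = st.chromosome_bias_profile(
        chrom_counts, chrom_bg, alpha=config.alpha_chromosome
    )
    observed_all = {
        c: int(chrom_counts.counts.get(c, 0)) for c in chrom_bg.gene_counts
    }
    chi2_gene = st.pearson_chi_square(
        observed_all,
        st.expected_counts(chrom_bg.gene_counts, chrom_counts.total_assigned),
    ) if chrom_counts.total_assigned else (0.0, 1.0)
    chi2_cds = st.pearson_chi_square(
        observed_all,
        st.expected_counts(chrom_bg.cds_lengths, chrom_counts.total_assigned),
    ) if chrom_counts.total_assigned else (0.0, 1.0)

    # Category assignments
    protein_mapped = [
        r
        for r in mapped.records
        if r.mapping_status in (STATUS_PROTEIN, STATUS_STRUCTURE)
    ]
    cath_codes = [
        ann.assign_cath(locus, reference)
        for rec, locus in zip(mapped.records, mapped.loci)
        if locus is not None
    ]
    pfam_assignments = [assign for r in protein_mapped
                        if (assign := ann.assign_pfam(r, reference))]
    ec_assignments = [assign for r in protein_mapped
                      if (assign := ann.assign_function(r, reference, "ec"))]
    go_assignments = [assign for r in protein_mapped
                      if (assign := ann.assign_function(r, reference, "go"))]

    assignments = {
        "cath": cath_codes,
        "pfam": pfam_assignments,
        "ec": ec_assignments,
        "go": go_assignments,
    }

    tests: dict[tuple[str, str], st.DistributionTestResult] = {}
    coverages: list[st.CoverageResult] = []
    for scheme in ("cath", "pfam", "ec", "go"):
        backgrounds = ann.build_background(reference, scheme)
        for level in ann.SCHEME_LEVELS[scheme]:
            ds_counts = ann.level_counts(
                assignments[scheme], scheme, level, multiplicity=config.multiplicity
            )
            bg_counts = backgrounds[level]
            tests[(scheme, level)] = _ks_or_not_computable(
                ds_counts, bg_counts, config
            )
            if bg_counts.counts:
                coverages.append(
                    st.coverage(
                        set(ds_counts.counts), set(bg_counts.counts), scheme, level
                    )
                )

    contamination = None
    if freq_table is not None:
        contamination = st.benign_contamination(
            mapped.records, freq_table, low=config.maf_low, high=config.maf_high
        )

    unbiased_count = unb_gene if config.chromosome_basis == "gene" else unb_cds
    score = score_dataset(tests, unbiased_count, alpha_ks=config.alpha_ks)

    return DatasetReport(
        label=label,
        n_records=len(mapped.records),
        tally=mapped.tally,
        chromosome_tests=chrom_tests,
        chromosome_chi2_gene=chi2_gene,
        chromosome_chi2_cds=chi2_cds,
        unbiased_chromosomes_gene=unb_gene,
        unbiased_chromosomes_cds=unb_cds,
        distribution_tests=[tests[k] for k in tests],
        coverages=coverages,
        score=score,
        contamination=contamination,
        unique_cath_superfamilies=len({c for c in cath_codes if c is not None}),
        config=config,
    )


def compare_datasets(reports: list[DatasetReport]) -> dict[str, pd.DataFrame]:
    """Cross-dataset summary, structure-coverage scatter and rank correlations.

    The scatter relates each dataset's number of unique CATH superfamilies
    to the log10 of its structure-mapped variant count; the rank
    correlation (Spearman) relates dataset size to deepest-level coverage
    per scheme.
    """
    if not reports:
        raise ValueError("compare_datasets requires at least one report")
    deepest = {"cath": "homology", "pfam": "family", "ec": "4", "go": "term"}
    rows = []
    for r in reports:
        row = {
            "dataset": r.label,
            "n_records": r.n_records,
            "pct_protein_mapped": r.tally.pct_protein_mapped,
            "pct_structure_mapped": r.tally.pct_structure_mapped,
            "unbiased_chromosomes": r.score.chromosome_unbiased_count,
            "score_without_chromosomes": r.score.score_without_chromosomes,
        }
        for scheme, level in deepest.items():
            try:
                row[f"coverage_{scheme}_pct"] = round(
                    100.0 * r.coverage_of(scheme, level).coverage, 2
                )
            except KeyError:
                row[f"coverage_{scheme}_pct"] = float("nan")
        rows.append(row)
    summary = pd.DataFrame(rows)

    scatter = pd.DataFrame(
        {
            "dataset": [r.label for r in reports],
            "unique_cath_superfamilies": [
                r.unique_cath_superfamilies for r in reports
            ],
            "log10_structure_mapped": [
                math.log10(r.tally.n_structure_mapped)
                if r.tally.n_structure_mapped > 0
                else float("nan")
                for r in reports
            ],
        }
    )

    corr_rows = []
    for scheme in deepest:
        col = summary[f"coverage_{scheme}_pct"]
        if (
            len(reports) >= 2
            and col.notna().all()
            and col.nunique() > 1
            and summary["n_records"].nunique() > 1
        ):
            from scipy.stats import spearmanr

            rho, p = spearmanr(summary["n_records"], col)
            corr_rows.append(
                {"scheme": scheme, "spearman_rho": float(rho), "p_value": float(p)}
            )
        else:
            corr_rows.append(
                {"scheme": scheme, "spearman_rho": float("nan"),
                 "p_value": float("nan")}
            )
    return {
        "summary": summary,
        "scatter": scatter,
        "rank_correlation": pd.DataFrame(corr_rows),
    }
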