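"""Tabular input/output for variant datasets, reference bundles and reports.

Every file-format decision lives here.  The internal dialect is
tab-separated text with one header line; per-source dialect descriptors map
foreign column names onto it.  Readers never coerce silently: malformed
variant rows are dropped, counted and logged, and reference bundles are
validated for cross-file referential integrity on load.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    CathDomain,
    ChainMapping,
    CrossRef,
    FrequencyEntry,
    FrequencyTable,
    Gene,
    GoAnnotation,
    PfamHit,
    Protein,
    ProteomeReference,
    ReferenceIntegrityError,
    StructureRecord,
    VariantRecord,
    validate_record,
)

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"

_BUNDLE_FILES = {
    "genes": "genes.tsv",
    "proteins": "proteins.tsv",
    "crossrefs_refseq": "crossrefs_refseq.tsv",
    "crossrefs_ensembl": "crossrefs_ensembl.tsv",
    "structure_map": "structure_map.tsv",
    "unobserved_residues": "unobserved_residues.tsv",
    "cath_classification": "cath_classification.tsv",
    "cath_boundaries": "cath_boundaries.tsv",
    "pfam": "pfam.tsv",
    "ec": "ec.tsv",
    "go": "go.tsv",
    "clusters": "clusters.tsv",
}


@dataclass
class TableDialect:
    """Column mapping for a variant table.

    ``fixed_namespace`` serves tables that lack a namespace column and carry
    identifiers from a single known namespace.
    """

    id_column: str = "accession"
    position_column: str = "position"
    ref_column: str = "ref_aa"
    alt_column: str = "alt_aa"
    namespace_column: Optional[str] = "namespace"
    fixed_namespace: Optional[str] = None
    chromosome_column: Optional[str] = "chromosome"
    gene_column: Optional[str] = "gene"
    dataset_column: Optional[str] = "dataset"
    delimiter: str = "\t"


def _write_rows(path: Path, header: list[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


# ---------------------------------------------------------------------------
# Variant tables


def read_variant_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    dataset_label: str = "dataset",
) -> tuple[list[VariantRecord], int]:
    """Read a variant table, returning (records, number of dropped rows).

    Rows with unknown residue letters, non-positive positions or identical
    reference/alternate residues are dropped and counted, never repaired.
    Raises ``ValueError`` naming any missing mandatory column.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    mandatory = [
        dialect.id_column,
        dialect.position_column,
        dialect.ref_column,
        dialect.alt_column,
    ]
    if dialect.fixed_namespace is None:
        mandatory.append(dialect.namespace_column)
    for col in mandatory:
        if col not in df.columns:
            raise ValueError(f"variant table {path} is missing mandatory column {col!r}")

    records: list[VariantRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            position = int(d[dialect.position_column])
        except (TypeError, ValueError):
            dropped += 1
            continue
        ns = (
            dialect.fixed_namespace
            if dialect.fixed_namespace is not None
            else d[dialect.namespace_column]
        )
        rec = VariantRecord(
            dataset_label=(
                d[dialect.dataset_column]
                if dialect.dataset_column and dialect.dataset_column in df.columns
                else dataset_label
            ),
            ref_namespace=ns,
            ref_id=d[dialect.id_column],
            position=position,
            ref_aa=d[dialect.ref_column],
            alt_aa=d[dialect.alt_column],
            chromosome=(
                d[dialect.chromosome_column] or None
                if dialect.chromosome_column and dialect.chromosome_column in df.columns
                else None
            ),
            gene=(
                d[dialect.gene_column] or None
                if dialect.gene_column and dialect.gene_column in df.columns
                else None
            ),
        )
        reason = validate_record(rec)
        if reason is not None:
            dropped += 1
            continue
        records.append(rec)
    if dropped:
        logger.info("dropped %d malformed rows while reading %s", dropped, path)
    return records, dropped


def write_variant_table(records: list[VariantRecord], path: str | Path) -> None:
    rows = [
        [
            r.dataset_label,
            r.ref_namespace,
            r.ref_id,
            r.position,
            r.ref_aa,
            r.alt_aa,
            r.chromosome or "",
            r.gene or "",
        ]
        for r in records
    ]
    _write_rows(
        Path(path),
        ["dataset", "namespace", "accession", "position", "ref_aa", "alt_aa",
         "chromosome", "gene"],
        rows,
    )


# ---------------------------------------------------------------------------
# Frequency tables


def write_frequency_table(table: FrequencyTable, path: str | Path) -> None:
    header = ["accession", "position", "ref_aa", "alt_aa"] + [
        f"maf_{p}" for p in table.populations
    ]
    rows = [
        [e.accession, e.position, e.ref_aa, e.alt_aa] + [repr(m) for m in e.mafs]
        for e in table.entries
    ]
    _write_rows(Path(path), header, rows)


def read_frequency_table(path: str | Path) -> FrequencyTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"accession": str}, float_precision="round_trip"
    )
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    populations = tuple(c[len("maf_"):] for c in maf_cols)
    entries = [
        FrequencyEntry(
            str(r.accession),
            int(r.position),
            str(r.ref_aa),
            str(r.alt_aa),
            tuple(float(getattr(r, c)) for c in maf_cols),
        )
        for r in df.itertuples(index=False)
    ]
    return FrequencyTable(populations=populations, entries=entries)


# ---------------------------------------------------------------------------
# Reference bundles


def write_reference_bundle(ref: ProteomeReference, directory: str | Path) -> None:
    """Write all registries of *ref* as one TSV per registry plus a manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_rows(
        d / _BUNDLE_FILES["genes"],
        ["gene", "chromosome", "cds_length"],
        [[g.gene_id, g.chromosome, g.cds_length] for g in ref.genes.values()],
    )
    _write_rows(
        d / _BUNDLE_FILES["proteins"],
        ["accession", "length", "gene"],
        [[p.accession, p.length, p.gene_id] for p in ref.proteins.values()],
    )
    for ns in ("refseq", "ensembl"):
        _write_rows(
            d / _BUNDLE_FILES[f"crossrefs_{ns}"],
            ["foreign_id", "canonical_id", "foreign_length", "canonical_length"],
            [
                [x.foreign_id, x.canonical_id, x.foreign_length, x.canonical_length]
                for x in ref.crossrefs[ns].values()
            ],
        )
    smap_rows = []
    unobserved_rows = []
    for sid, struct in ref.structures.items():
        res = "" if struct.resolution is None else repr(struct.resolution)
        for ch in struct.chains:
            smap_rows.append(
                [sid, ch.chain, ch.accession, ch.res_beg, ch.res_end,
                 ch.sp_beg, ch.sp_end, res]
            )
            for off in np.flatnonzero(~ch.observed):
                unobserved_rows.append([sid, ch.chain, ch.sp_beg + int(off)])
    _write_rows(
        d / _BUNDLE_FILES["structure_map"],
        ["structure", "chain", "accession", "res_beg", "res_end",
         "sp_beg", "sp_end", "resolution"],
        smap_rows,
    )
    _write_rows(
        d / _BUNDLE_FILES["unobserved_residues"],
        ["structure", "chain", "protein_position"],
        unobserved_rows,
    )
    _write_rows(
        d / _BUNDLE_FILES["cath_classification"],
        ["domain_id", "c", "a", "t", "h"],
        [[dom.domain_id, *dom.code.split(".")] for dom in ref.cath.values()],
    )
    _write_rows(
        d / _BUNDLE_FILES["cath_boundaries"],
        ["domain_id", "chain_id", "seg_start", "seg_end"],
        [
            [dom.domain_id, dom.chain_id, s, e]
            for dom in ref.cath.values()
            for s, e in dom.segments
        ],
    )
    _write_rows(
        d / _BUNDLE_FILES["pfam"],
        ["accession", "family", "start", "end"],
        [[h.accession, h.family, h.start, h.end]
         for hits in ref.pfam.values() for h in hits],
    )
    _write_rows(
        d / _BUNDLE_FILES["ec"],
        ["accession", "ec_code"],
        [[acc, code] for acc, codes in ref.ec.items() for code in codes],
    )
    _write_rows(
        d / _BUNDLE_FILES["go"],
        ["accession", "term", "aspect"],
        [[a.accession, a.term, a.aspect]
         for anns in ref.go.values() for a in anns],
    )
    _write_rows(
        d / _BUNDLE_FILES["clusters"],
        ["cluster", "member", "chain_id"],
        [
            [ci, mi, chain_id]
            for ci, cl in enumerate(ref.clusters)
            for mi, chain_id in enumerate(cl)
        ],
    )
    with open(d / MANIFEST_NAME, "w") as fh:
        json.dump({"format": "varrep-reference-bundle", "version": 1,
                   "files": _BUNDLE_FILES}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_reference_bundle(directory: str | Path) -> ProteomeReference:
    """Load a reference bundle directory, validating referential integrity.

    Raises ``ReferenceIntegrityError`` listing every dangling reference or
    out-of-bounds segment, with the file it came from.
    """
    d = Path(directory)
    manifest = d / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"{d} does not contain a bundle manifest")
    ref = ProteomeReference()
    for row in _read_tsv(d / _BUNDLE_FILES["genes"]).itertuples(index=False):
        ref.genes[row.gene] = Gene(row.gene, row.chromosome, int(row.cds_length))
    for row in _read_tsv(d / _BUNDLE_FILES["proteins"]).itertuples(index=False):
        ref.proteins[row.accession] = Protein(row.accession, int(row.length), row.gene)
    for ns in ("refseq", "ensembl"):
        for row in _read_tsv(d / _BUNDLE_FILES[f"crossrefs_{ns}"]).itertuples(
            index=False
        ):
            ref.crossrefs[ns][row.foreign_id] = CrossRef(
                row.foreign_id,
                row.canonical_id,
                int(row.foreign_length),
                int(row.canonical_length),
            )
    smap = _read_tsv(d / _BUNDLE_FILES["structure_map"])
    unobs = _read_tsv(d / _BUNDLE_FILES["unobserved_residues"])
    unobs_keys: dict[tuple[str, str], set[int]] = {}
    for row in unobs.itertuples(index=False):
        unobs_keys.setdefault((row.structure, row.chain), set()).add(
            int(row.protein_position)
        )
    for row in smap.itertuples(index=False):
        sid = row.structure
        resolution = None if row.resolution == "" else float(row.resolution)
        if sid not in ref.structures:
            ref.structures[sid] = StructureRecord(sid, resolution)
        sp_beg, sp_end = int(row.sp_beg), int(row.sp_end)
        observed = np.ones(sp_end - sp_beg + 1, dtype=bool)
        for pos in unobs_keys.get((sid, row.chain), ()):
            if sp_beg <= pos <= sp_end:
                observed[pos - sp_beg] = False
        ref.structures[sid].chains.append(
            ChainMapping(row.chain, row.accession, sp_beg, sp_end,
                         int(row.res_beg), observed)
        )
    cls = _read_tsv(d / _BUNDLE_FILES["cath_classification"])
    codes = {row.domain_id: f"{row.c}.{row.a}.{row.t}.{row.h}"
             for row in cls.itertuples(index=False)}
    segments: dict[str, list[tuple[str, int, int]]] = {}
    for row in _read_tsv(d / _BUNDLE_FILES["cath_boundaries"]).itertuples(index=False):
        segments.setdefault(row.domain_id, []).append(
            (row.chain_id, int(row.seg_start), int(row.seg_end))
        )
    for dom_id, segs in segments.items():
        if dom_id not in codes:
            raise ReferenceIntegrityError(
                f"{_BUNDLE_FILES['cath_boundaries']}: domain {dom_id} has no "
                "classification row"
            )
        chain_ids = {c for c, _, _ in segs}
        if len(chain_ids) != 1:
            raise ReferenceIntegrityError(
                f"{_BUNDLE_FILES['cath_boundaries']}: domain {dom_id} spans "
                "multiple chains"
            )
        ref.cath[dom_id] = CathDomain(
            dom_id, codes[dom_id], segs[0][0],
            tuple((s, e) for _, s, e in segs),
        )
    for row in _read_tsv(d / _BUNDLE_FILES["pfam"]).itertuples(index=False):
        ref.pfam.setdefault(row.accession, []).append(
            PfamHit(row.accession, row.family, int(row.start), int(row.end))
        )
    for row in _read_tsv(d / _BUNDLE_FILES["ec"]).itertuples(index=False):
        ref.ec.setdefault(row.accession, []).append(row.ec_code)
    for row in _read_tsv(d / _BUNDLE_FILES["go"]).itertuples(index=False):
        ref.go.setdefault(row.accession, []).append(
            GoAnnotation(row.accession, row.term, row.aspect)
        )
    clusters: dict[int, list[tuple[int, str]]] = {}
    for row in _read_tsv(d / _BUNDLE_FILES["clusters"]).itertuples(index=False):
        clusters.setdefault(int(row.cluster), []).append(
            (int(row.member), row.chain_id)
        )
    ref.clusters = [
        [cid for _, cid in sorted(members)]
        for _, members in sorted(clusters.items())
    ]
    ref.build_indexes()
    try:
        ref.validate()
    except ReferenceIntegrityError as err:
        raise ReferenceIntegrityError(f"bundle {d}: {err}") from None
    return ref


# ---------------------------------------------------------------------------
# Reports


def write_report(report, directory: str | Path) -> list[str]:
    """Write a :class:`~varrep.report.DatasetReport` as TSV sections plus a
    machine-readable JSON summary.  Returns the list of files written."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    summary = report.to_dict()
    files = []
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    files.append("summary.json")

    _write_rows(
        d / "chromosomes.tsv",
        ["chromosome", "observed", "expected_gene", "expected_cds",
         "p_gene", "p_cds", "biased_gene", "biased_cds"],
        [
            [t.chromosome, t.observed, repr(t.expected_gene), repr(t.expected_cds),
             repr(t.p_gene), repr(t.p_cds), int(t.biased_gene), int(t.biased_cds)]
            for t in report.chromosome_tests
        ],
    )
    files.append("chromosomes.tsv")

    _write_rows(
        d / "distribution_tests.tsv",
        ["scheme", "level", "statistic_type", "statistic", "p_value", "biased",
         "n_dataset", "n_background", "computable", "note"],
        [
            [t.scheme, t.level, t.statistic_type,
             "" if t.statistic is None else repr(t.statistic),
             "" if t.p_value is None else repr(t.p_value),
             "" if t.biased is None else int(t.biased),
             t.n_dataset, t.n_background, int(t.computable), t.note]
            for t in report.distribution_tests
        ],
    )
    files.append("distribution_tests.tsv")

    _write_rows(
        d / "coverage.tsv",
        ["scheme", "level", "classes_in_dataset", "classes_total",
         "excess_labels", "coverage_pct"],
        [
            [c.scheme, c.level, c.classes_in_dataset, c.classes_total,
             c.excess_labels, repr(round(100.0 * c.coverage, 2))]
            for c in report.coverages
        ],
    )
    files.append("coverage.tsv")

    _write_rows(
        d / "score.tsv",
        ["category", "flag"],
        [[cat, flag] for cat, flag in report.score.category_flags.items()],
    )
    files.append("score.tsv")
    return files


def read_report_summary(directory: str | Path) -> dict:
    with open(Path(directory) / "summary.json") as fh:
        return json.load(fh)
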