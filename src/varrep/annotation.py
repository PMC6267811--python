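"""Projection of variants and the reference universe into category spaces.

Schemes: chromosome (single level), CATH (class / architecture / topology /
homology, code prefixes of ``C.A.T.H``), Pfam (family intervals on the
protein sequence), EC (four dot-separated levels, possibly incomplete) and
GO (term level and aspect level).  Background distributions are rebuilt
from the raw registries: the CATH background counts each domain once per
cluster-representative chain; Pfam/EC/GO backgrounds count annotation rows
over all proteins; the chromosome background carries both weighting bases
(gene count and summed CDS length) side by side.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    ProteomeReference,
    ReferenceIntegrityError,
    ResidueLocus,
    VariantRecord,
)

CATH_LEVELS = ("class", "architecture", "topology", "homology")
EC_LEVELS = ("1", "2", "3", "4")
GO_LEVELS = ("term", "aspect")

SCHEME_LEVELS = {
    "chromosome": ("chromosome",),
    "cath": CATH_LEVELS,
    "pfam": ("family",),
    "ec": EC_LEVELS,
    "go": GO_LEVELS,
}


@dataclass
class CategoryCounts:
    """Counts of variants (or background members) per category at one level."""

    scheme: str
    level: str
    counts: Counter = field(default_factory=Counter)
    total_assigned: int = 0

    def frequencies(self) -> dict[str, float]:
        if self.total_assigned == 0:
            return {}
        return {k: v / self.total_assigned for k, v in self.counts.items()}

    def check(self) -> None:
        if sum(self.counts.values()) != self.total_assigned:
            raise ValueError("counts do not sum to total_assigned")


@dataclass
class ChromosomeBackground:
    """Both chromosome weighting bases, side by side."""

    gene_counts: dict[str, int]
    cds_lengths: dict[str, int]


def truncate_cath(code: str, level: str) -> str:
    depth = CATH_LEVELS.index(level) + 1
    return ".".join(code.split(".")[:depth])


def truncate_ec(code: str, level: str) -> Optional[str]:
    """Truncate an EC code, or None when the code is shallower than *level*."""
    depth = int(level)
    parts = code.split(".")
    if len(parts) < depth:
        return None
    return ".".join(parts[:depth])


def chromosome_counts(
    records: Sequence[VariantRecord],
    reference: Optional[ProteomeReference] = None,
) -> CategoryCounts:
    """Count variants per chromosome.

    The chromosome comes from the record itself or, failing that, from the
    canonical protein's gene.  Records without a resolvable chromosome are
    excluded from ``total_assigned``.
    """
    counts: Counter = Counter()
    for rec in records:
        chrom = rec.chromosome
        if chrom is None and reference is not None and rec.canonical_protein:
            chrom = reference.chromosome_of(rec.canonical_protein)
        if chrom is not None:
            counts[chrom] += 1
    return CategoryCounts(
        "chromosome", "chromosome", counts, total_assigned=sum(counts.values())
    )


def assign_cath(locus: ResidueLocus, reference: ProteomeReference) -> Optional[str]:
    """Full CATH code of the domain containing the structure residue, if any.

    Overlapping domain segments on one chain are a corrupt reference and
    raise ``ReferenceIntegrityError``.
    """
    chain_id = f"{locus.structure_id}_{locus.chain}"
    hits = [
        dom
        for dom in reference.domains_on_chain(chain_id)
        if dom.contains(locus.structure_residue)
    ]
    if len(hits) > 1:
        raise ReferenceIntegrityError(
            f"overlapping CATH domains on chain {chain_id} at residue "
            f"{locus.structure_residue}: "
            + ", ".join(d.domain_id for d in hits)
        )
    return hits[0].code if hits else None


def assign_pfam(record: VariantRecord, reference: ProteomeReference) -> list[str]:
    """All Pfam families whose interval contains the variant position."""
    if record.canonical_protein is None:
        return []
    return [
        h.family
        for h in reference.pfam.get(record.canonical_protein, [])
        if h.start <= record.position <= h.end
    ]


def assign_function(
    record: VariantRecord, reference: ProteomeReference, kind: str
):
    """Protein-level (position-independent) EC codes or (term, aspect) pairs."""
    if record.canonical_protein is None:
        return []
    if kind == "ec":
        return list(reference.ec.get(record.canonical_protein, []))
    if kind == "go":
        return [
            (a.term, a.aspect)
            for a in reference.go.get(record.canonical_protein, [])
        ]
    raise ValueError(f"kind must be 'ec' or 'go', got {kind!r}")


def _categories_at_level(assignment, scheme: str, level: str) -> set[str]:
    """Category labels one variant contributes at (scheme, level)."""
    if assignment is None:
        return set()
    if scheme == "cath":
        return {truncate_cath(assignment, level)}
    if scheme == "pfam":
        return set(assignment)
    if scheme == "ec":
        return {t for code in assignment if (t := truncate_ec(code, level))}
    if scheme == "go":
        if level == "term":
            return {term for term, _ in assignment}
        return {aspect for _, aspect in assignment}
    raise ValueError(f"unknown scheme {scheme!r}")


def level_counts(
    assignments: Iterable, scheme: str, level: str, multiplicity: str = "per_category"
) -> CategoryCounts:
    """Tally per-category counts over one dataset's assignments.

    *assignments* holds one entry per variant: a full CATH code (or None)
    for cath, a list of families for pfam, a list of codes for ec, a list
    of (term, aspect) pairs for go.  A variant contributing several
    categories at a level increments each once (``per_category``) or only
    its first (``first_only``); variants with nothing at the level are
    excluded from ``total_assigned``.
    """
    if scheme not in SCHEME_LEVELS or level not in SCHEME_LEVELS[scheme]:
        raise ValueError(f"unknown level {level!r} for scheme {scheme!r}")
    if multiplicity not in ("per_category", "first_only"):
        raise ValueError(f"unknown multiplicity policy {multiplicity!r}")
    counts: Counter = Counter()
    for assignment in assignments:
        cats = sorted(_categories_at_level(assignment, scheme, level))
        if not cats:
            continue
        if multiplicity == "first_only":
            cats = cats[:1]
        for c in cats:
            counts[c] += 1
    return CategoryCounts(scheme, level, counts, total_assigned=sum(counts.values()))


def build_background(reference: ProteomeReference, scheme: str):
    """Background category distribution(s) for *scheme*.

    Returns a dict level -> CategoryCounts, except for ``chromosome`` which
    returns a :class:`ChromosomeBackground` with both weighting bases.
    """
    if scheme == "chromosome":
        gene_counts: Counter = Counter()
        cds_lengths: Counter = Counter()
        for gene in reference.genes.values():
            gene_counts[gene.chromosome] += 1
            cds_lengths[gene.chromosome] += gene.cds_length
        return ChromosomeBackground(dict(gene_counts), dict(cds_lengths))
    if scheme == "cath":
        out = {lvl: CategoryCounts("cath", lvl) for lvl in CATH_LEVELS}
        for cluster in reference.clusters:
            representative = cluster[0]
            for dom in reference.domains_on_chain(representative):
                for lvl in CATH_LEVELS:
                    out[lvl].counts[truncate_cath(dom.code, lvl)] += 1
        for cc in out.values():
            cc.total_assigned = sum(cc.counts.values())
        return out
    if scheme == "pfam":
        cc = CategoryCounts("pfam", "family")
        for hits in reference.pfam.values():
            for h in hits:
                cc.counts[h.family] += 1
        cc.total_assigned = sum(cc.counts.values())
        return {"family": cc}
    if scheme == "ec":
        out = {lvl: CategoryCounts("ec", lvl) for lvl in EC_LEVELS}
        for codes in reference.ec.values():
            for code in codes:
                for lvl in EC_LEVELS:
                    t = truncate_ec(code, lvl)
                    if t is not None:
                        out[lvl].counts[t] += 1
        for cc in out.values():
            cc.total_assigned = sum(cc.counts.values())
        return out
    if scheme == "go":
        out = {lvl: CategoryCounts("go", lvl) for lvl in GO_LEVELS}
        for anns in reference.go.values():
            for a in anns:
                out["term"].counts[a.term] += 1
                out["aspect"].counts[a.aspect] += 1
        for cc in out.values():
            cc.total_assigned = sum(cc.counts.values())
        return out
    raise ValueError(f"unknown scheme {scheme!r}")
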