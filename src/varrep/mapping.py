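"""Identifier and structure-residue mapping.

Variants are first resolved to a canonical protein: UniProt identifiers
pass through if known; RefSeq/Ensembl identifiers map through the
cross-reference table only when the foreign and canonical sequence lengths
match exactly.  A mapped position must lie within the canonical protein.

Structure selection then walks candidate structures best resolution first.
A structure whose residue at the variant position is unobserved is
discarded entirely and the next structure tried; within the chosen
structure the first chain (input file order) containing the position wins.
Structures without a resolution value sort after all resolved structures;
ties break on structure id, so selection is a total order and deterministic.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    STATUS_PROTEIN,
    STATUS_STRUCTURE,
    STATUS_UNMAPPED,
    ProteomeReference,
    ResidueLocus,
    VariantRecord,
)


def to_canonical(record: VariantRecord, reference: ProteomeReference) -> VariantRecord:
    """Resolve a record's identifier to a canonical protein.

    Failures are statuses, never errors: the returned record is a copy with
    ``canonical_protein`` and ``mapping_status`` updated.
    """
    canonical: Optional[str] = None
    if record.ref_namespace == "uniprot":
        if record.ref_id in reference.proteins:
            canonical = record.ref_id
    else:
        xr = reference.crossrefs.get(record.ref_namespace, {}).get(record.ref_id)
        if (
            xr is not None
            and xr.foreign_length == xr.canonical_length
            and xr.canonical_id in reference.proteins
        ):
            canonical = xr.canonical_id
    if canonical is not None and record.position > reference.proteins[canonical].length:
        canonical = None
    return dataclasses.replace(
        record,
        canonical_protein=canonical,
        mapping_status=STATUS_PROTEIN if canonical else STATUS_UNMAPPED,
    )


def _structure_sort_key(reference: ProteomeReference, sid: str):
    resolution = reference.structures[sid].resolution
    return (resolution is None, resolution if resolution is not None else 0.0, sid)


def select_structure_residue(
    accession: str, position: int, reference: ProteomeReference
) -> Optional[ResidueLocus]:
    """Pick the observed structure residue for (accession, position).

    Candidates are structures with a chain interval containing the position,
    ordered best (lowest) resolution first.  An unobserved residue discards
    the whole structure.  Returns None when no candidate survives.
    """
    if accession not in reference.proteins:
        raise KeyError(f"unknown accession {accession!r}")
    covering: dict[str, list] = {}
    for sid, chain in reference.chains_for(accession):
        if chain.covers(position):
            covering.setdefault(sid, []).append(chain)
    for sid in sorted(covering, key=lambda s: _structure_sort_key(reference, s)):
        chain = covering[sid][0]  # first chain in file order
        if chain.is_observed(position):
            return ResidueLocus(
                structure_id=sid,
                chain=chain.chain,
                structure_residue=chain.structure_residue(position),
                resolution=reference.structures[sid].resolution,
            )
        # residue Not_Observed: discard this structure, try the next
    return None


@dataclass
class MappingTally:
    """Mapping bookkeeping for one dataset (percent of all records)."""

    n_total: int = 0
    n_protein_mapped: int = 0
    n_structure_mapped: int = 0
    pct_protein_mapped: float = 0.0
    pct_structure_mapped: float = 0.0
    per_protein: Counter = field(default_factory=Counter)
    max_per_protein: int = 0
    max_accession: Optional[str] = None


@dataclass
class MappedDataset:
    records: list[VariantRecord]
    loci: list[Optional[ResidueLocus]]  # parallel to records
    tally: MappingTally


def mapping_percentage(part: int, whole: int) -> float:
    """Percentage to 2 decimals, round-half-even; 0 for an empty dataset."""
    return round(100.0 * part / whole, 2) if whole else 0.0


def map_dataset(
    records: list[VariantRecord], reference: ProteomeReference
) -> MappedDataset:
    """Map every record to protein and structure; tally counts and rates."""
    out: list[VariantRecord] = []
    loci: list[Optional[ResidueLocus]] = []
    tally = MappingTally(n_total=len(records))
    for rec in records:
        rec = to_canonical(rec, reference)
        locus = None
        if rec.mapping_status == STATUS_PROTEIN:
            tally.per_protein[rec.canonical_protein] += 1
            locus = select_structure_residue(
                rec.canonical_protein, rec.position, reference
            )
            if locus is not None:
                rec = dataclasses.replace(rec, mapping_status=STATUS_STRUCTURE)
        out.append(rec)
        loci.append(locus)
    tally.n_protein_mapped = sum(
        1 for r in out if r.mapping_status in (STATUS_PROTEIN, STATUS_STRUCTURE)
    )
    tally.n_structure_mapped = sum(
        1 for r in out if r.mapping_status == STATUS_STRUCTURE
    )
    tally.pct_protein_mapped = mapping_percentage(
        tally.n_protein_mapped, tally.n_total
    )
    tally.pct_structure_mapped = mapping_percentage(
        tally.n_structure_mapped, tally.n_total
    )
    if tally.per_protein:
        tally.max_accession, tally.max_per_protein = max(
            tally.per_protein.items(), key=lambda kv: (kv[1], kv[0])
        )
    return MappedDataset(records=out, loci=loci, tally=tally)
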