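"""Core domain containers shared by every pipeline stage.

The annotation universe (:class:`ProteomeReference`) holds everything the
assessment consults: genes with chromosomes and coding-sequence lengths,
canonical proteins, identifier cross-references, structure residue mappings
with observed flags, CATH domains with boundaries, Pfam intervals, EC codes,
GO terms, and 95 %-identity structure chain clusters.  Variants are plain
records (:class:`VariantRecord`) that acquire a canonical protein and a
mapping status as they move through the pipeline.

All residue coordinates are 1-based inclusive.  Structure residue numbering
differs from protein (sequence) numbering only inside :class:`ChainMapping`,
which records the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Chromosome labels of the human nuclear genome universe (no MT).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

NAMESPACES = ("uniprot", "refseq", "ensembl")

STATUS_UNMAPPED = "unmapped"
STATUS_PROTEIN = "protein_mapped"
STATUS_STRUCTURE = "structure_mapped"


class ReferenceIntegrityError(ValueError):
    """Raised when a reference bundle violates cross-file referential integrity."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    cds_length: int  # nucleotides


@dataclass(frozen=True)
class Protein:
    accession: str
    length: int  # residues
    gene_id: str


@dataclass(frozen=True)
class CrossRef:
    """Identifier cross-reference carrying both sides' sequence lengths.

    Mapping through a cross-reference is only admitted when the two lengths
    agree; the lengths are therefore first-class data, not metadata.
    """

    foreign_id: str
    canonical_id: str
    foreign_length: int
    canonical_length: int


@dataclass
class ChainMapping:
    """One chain's residue-level mapping between a structure and a protein.

    ``observed[i]`` tells whether protein residue ``sp_beg + i`` is resolved
    in the structure; an unobserved residue disqualifies the whole structure
    for a variant at that position.
    """

    chain: str
    accession: str
    sp_beg: int  # protein numbering, inclusive
    sp_end: int
    res_beg: int  # structure numbering of the residue mapped to sp_beg
    observed: np.ndarray  # bool, length sp_end - sp_beg + 1

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.sp_beg > self.sp_end:
            raise ValueError(f"sp_beg {self.sp_beg} > sp_end {self.sp_end}")
        if len(self.observed) != self.sp_end - self.sp_beg + 1:
            raise ValueError(
                "observed flag array length "
                f"{len(self.observed)} != interval length "
                f"{self.sp_end - self.sp_beg + 1}"
            )

    def covers(self, position: int) -> bool:
        return self.sp_beg <= position <= self.sp_end

    def is_observed(self, position: int) -> bool:
        return bool(self.observed[position - self.sp_beg])

    def structure_residue(self, position: int) -> int:
        return self.res_beg + (position - self.sp_beg)

    @property
    def res_end(self) -> int:
        return self.res_beg + (self.sp_end - self.sp_beg)


@dataclass
class StructureRecord:
    structure_id: str
    resolution: Optional[float]  # angstrom; None for e.g. NMR models
    chains: list[ChainMapping] = field(default_factory=list)

    def chain_id(self, chain: ChainMapping) -> str:
        return f"{self.structure_id}_{chain.chain}"


@dataclass(frozen=True)
class CathDomain:
    """A CATH domain: four-level code plus residue segments on one chain.

    Segment coordinates are in structure residue numbering.
    """

    domain_id: str
    code: str  # "C.A.T.H"
    chain_id: str
    segments: tuple[tuple[int, int], ...]  # (start, end) inclusive

    def contains(self, structure_residue: int) -> bool:
        return any(s <= structure_residue <= e for s, e in self.segments)


@dataclass(frozen=True)
class PfamHit:
    accession: str
    family: str
    start: int  # protein numbering, inclusive
    end: int


@dataclass(frozen=True)
class GoAnnotation:
    accession: str
    term: str
    aspect: str


@dataclass
class VariantRecord:
    """One single amino acid substitution and its mapping state."""

    dataset_label: str
    ref_namespace: str  # uniprot | refseq | ensembl
    ref_id: str
    position: int  # 1-based residue index on the reference sequence
    ref_aa: str
    alt_aa: str
    chromosome: Optional[str] = None
    gene: Optional[str] = None
    canonical_protein: Optional[str] = None
    mapping_status: str = STATUS_UNMAPPED


def validate_record(rec: VariantRecord) -> Optional[str]:
    """Return a reason string if *rec* is malformed, else None."""
    if rec.ref_namespace not in NAMESPACES:
        return f"unknown namespace {rec.ref_namespace!r}"
    if not isinstance(rec.position, (int, np.integer)) or rec.position < 1:
        return f"non-positive position {rec.position!r}"
    if rec.ref_aa not in AMINO_ACIDS:
        return f"unknown reference residue {rec.ref_aa!r}"
    if rec.alt_aa not in AMINO_ACIDS:
        return f"unknown alternate residue {rec.alt_aa!r}"
    if rec.ref_aa == rec.alt_aa:
        return "reference and alternate residues identical"
    if rec.mapping_status == STATUS_STRUCTURE and rec.canonical_protein is None:
        return "structure_mapped record without canonical protein"
    return None


@dataclass(frozen=True)
class FrequencyEntry:
    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    mafs: tuple[float, ...]  # one minor allele frequency per population


@dataclass
class FrequencyTable:
    """Population allele-frequency table (ExAC-style, default 7 populations)."""

    populations: tuple[str, ...]
    entries: list[FrequencyEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if len(e.mafs) != len(self.populations):
                raise ValueError(
                    f"entry {e.accession}:{e.position} has {len(e.mafs)} MAFs, "
                    f"expected {len(self.populations)}"
                )
            for m in e.mafs:
                if not 0.0 <= m <= 0.5:
                    raise ValueError(f"MAF {m} outside [0, 0.5]")


@dataclass(frozen=True)
class ResidueLocus:
    """An observed structure residue a variant position was mapped to."""

    structure_id: str
    chain: str
    structure_residue: int
    resolution: Optional[float]


@dataclass
class ProteomeReference:
    """The annotation universe all pipeline stages consult."""

    genes: dict[str, Gene] = field(default_factory=dict)
    proteins: dict[str, Protein] = field(default_factory=dict)
    # namespace -> foreign id -> CrossRef
    crossrefs: dict[str, dict[str, CrossRef]] = field(
        default_factory=lambda: {"refseq": {}, "ensembl": {}}
    )
    structures: dict[str, StructureRecord] = field(default_factory=dict)
    cath: dict[str, CathDomain] = field(default_factory=dict)
    pfam: dict[str, list[PfamHit]] = field(default_factory=dict)
    ec: dict[str, list[str]] = field(default_factory=dict)
    go: dict[str, list[GoAnnotation]] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)  # chain ids

    # Derived indexes (built by build_indexes)
    _chain_index: dict[str, list[tuple[str, ChainMapping]]] = field(
        default_factory=dict, repr=False
    )
    _cath_by_chain: dict[str, list[CathDomain]] = field(
        default_factory=dict, repr=False
    )

    # -- indexes ---------------------------------------------------------
    def build_indexes(self) -> None:
        """(Re)build lookup indexes.  Chain order reflects input file order,
        which fixes the 'first chain' tie-break used during structure
        selection."""
        self._chain_index = {}
        for sid, struct in self.structures.items():
            for ch in struct.chains:
                self._chain_index.setdefault(ch.accession, []).append((sid, ch))
        self._cath_by_chain = {}
        for dom in self.cath.values():
            self._cath_by_chain.setdefault(dom.chain_id, []).append(dom)

    def chains_for(self, accession: str) -> list[tuple[str, ChainMapping]]:
        return self._chain_index.get(accession, [])

    def domains_on_chain(self, chain_id: str) -> list[CathDomain]:
        return self._cath_by_chain.get(chain_id, [])

    def chain_extent(self, chain_id: str) -> Optional[tuple[int, int]]:
        """Structure-numbering extent of a chain, or None if unknown."""
        sid, _, chain = chain_id.rpartition("_")
        struct = self.structures.get(sid)
        if struct is None:
            return None
        for ch in struct.chains:
            if ch.chain == chain:
                return ch.res_beg, ch.res_end
        return None

    # -- integrity -------------------------------------------------------
    def validate(self) -> None:
        """Check cross-registry referential integrity; raise with offenders."""
        problems: list[str] = []
        for gene in (p.gene_id for p in self.proteins.values()):
            if gene not in self.genes:
                problems.append(f"protein references unknown gene {gene}")
        for ns, table in self.crossrefs.items():
            for xr in table.values():
                if xr.canonical_id not in self.proteins:
                    problems.append(
                        f"{ns} crossref {xr.foreign_id} -> unknown protein "
                        f"{xr.canonical_id}"
                    )
        chain_ids = set()
        for sid, struct in self.structures.items():
            for ch in struct.chains:
                chain_ids.add(struct.chain_id(ch))
                prot = self.proteins.get(ch.accession)
                if prot is None:
                    problems.append(
                        f"structure {sid} chain {ch.chain} maps unknown "
                        f"protein {ch.accession}"
                    )
                elif not (1 <= ch.sp_beg <= ch.sp_end <= prot.length):
                    problems.append(
                        f"structure {sid} chain {ch.chain} interval "
                        f"[{ch.sp_beg}, {ch.sp_end}] outside protein "
                        f"{ch.accession} (length {prot.length})"
                    )
        for dom in self.cath.values():
            extent = self.chain_extent(dom.chain_id)
            if extent is None:
                problems.append(
                    f"CATH domain {dom.domain_id} on unknown chain {dom.chain_id}"
                )
                continue
            lo, hi = extent
            for s, e in dom.segments:
                if not (lo <= s <= e <= hi):
                    problems.append(
                        f"CATH domain {dom.domain_id} segment [{s}, {e}] outside "
                        f"chain {dom.chain_id} extent [{lo}, {hi}]"
                    )
        for acc, hits in self.pfam.items():
            prot = self.proteins.get(acc)
            if prot is None:
                problems.append(f"Pfam annotation on unknown protein {acc}")
                continue
            for h in hits:
                if not (1 <= h.start <= h.end <= prot.length):
                    problems.append(
                        f"Pfam {h.family} interval [{h.start}, {h.end}] outside "
                        f"protein {acc} (length {prot.length})"
                    )
        for acc in self.ec:
            if acc not in self.proteins:
                problems.append(f"EC annotation on unknown protein {acc}")
        for acc in self.go:
            if acc not in self.proteins:
                problems.append(f"GO annotation on unknown protein {acc}")
        clustered = [cid for cl in self.clusters for cid in cl]
        for cid in clustered:
            if cid not in chain_ids:
                problems.append(f"cluster member {cid} is not a known chain")
        if len(clustered) != len(set(clustered)):
            problems.append("clusters do not partition chains (duplicates)")
        if problems:
            raise ReferenceIntegrityError(
                "reference integrity violations:\n  " + "\n  ".join(problems)
            )

    def chromosome_of(self, accession: str) -> Optional[str]:
        prot = self.proteins.get(accession)
        if prot is None:
            return None
        gene = self.genes.get(prot.gene_id)
        return gene.chromosome if gene else None
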