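"""Synthetic miniature proteome universe and variant dataset generator.

The generator emits a self-contained annotation universe — genes on 24
chromosomes, one canonical protein per gene, identifier cross-references,
partial structure coverage with unobserved residues, a hierarchical CATH
universe, Pfam intervals, possibly-incomplete EC codes, GO terms in three
aspects, structure chain clusters — plus variant datasets drawn either
uniformly over residues (unbiased) or concentrated on hotspot proteins
(emulating disease-gene over-study), and an allele-frequency table.

Everything is deterministic for a fixed seed.  Each generator operation
draws from its own independently seeded stream, so adding one registry
never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import data as _data
from .model import (
    AMINO_ACIDS,
    CHROMOSOMES,
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
    StructureRecord,
    VariantRecord,
)

_AA = sorted(AMINO_ACIDS)

GO_ASPECTS = ("molecular_function", "biological_process", "cellular_component")


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class ProteomeConfig:
    """Parameters of the synthetic annotation universe.

    Defaults emulate the human proteome at roughly 1:100 scale: gene counts
    per chromosome proportional to the Ensembl protein-coding census,
    log-normal coding-sequence lengths with median ~1.3 kb, 21 % of proteins
    enzymes, three GO aspects, and a four-level CATH hierarchy.
    """

    n_chromosomes: int = 24
    genes_per_chromosome: Optional[list[int]] = None  # None -> census-proportional
    cds_lognormal_mean: float = 7.2  # log nucleotides; median ~1339 nt
    cds_lognormal_sigma: float = 0.6
    protein_count: int = 200
    structure_coverage_fraction: float = 0.4
    unobserved_residue_rate: float = 0.05
    n_cath_classes: int = 4
    n_cath_architectures: int = 12
    n_cath_topologies: int = 40
    n_cath_superfamilies: int = 90
    n_pfam_families: int = 60
    enzyme_fraction: float = 0.21
    ec_incomplete_rate: float = 0.15
    go_terms_total: int = 150
    go_aspect_labels: tuple[str, str, str] = GO_ASPECTS
    crossref_mismatch_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.n_chromosomes > len(CHROMOSOMES):
            raise ValueError(
                f"n_chromosomes must be in [1, {len(CHROMOSOMES)}], "
                f"got {self.n_chromosomes}"
            )
        if self.genes_per_chromosome is not None:
            if len(self.genes_per_chromosome) != self.n_chromosomes:
                raise ValueError(
                    "genes_per_chromosome length "
                    f"{len(self.genes_per_chromosome)} != n_chromosomes "
                    f"{self.n_chromosomes}"
                )
            if any(g < 0 for g in self.genes_per_chromosome):
                raise ValueError("genes_per_chromosome entries must be >= 0")
            if sum(self.genes_per_chromosome) != self.protein_count:
                raise ValueError(
                    "genes_per_chromosome must sum to protein_count "
                    f"({sum(self.genes_per_chromosome)} != {self.protein_count})"
                )
        for name in (
            "protein_count",
            "n_cath_classes",
            "n_cath_architectures",
            "n_cath_topologies",
            "n_cath_superfamilies",
            "n_pfam_families",
            "go_terms_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in (
            "structure_coverage_fraction",
            "unobserved_residue_rate",
            "enzyme_fraction",
            "ec_incomplete_rate",
            "crossref_mismatch_rate",
        ):
            _check_fraction(name, getattr(self, name))
        if len(set(self.go_aspect_labels)) != 3:
            raise ValueError(
                "go_aspect_labels must contain exactly 3 distinct labels, "
                f"got {self.go_aspect_labels!r}"
            )
        if self.cds_lognormal_sigma < 0:
            raise ValueError("cds_lognormal_sigma must be >= 0")


@dataclass
class SamplingSpec:
    """How to draw a synthetic variant dataset from a proteome.

    ``uniform`` draws residues uniformly over all residues of all proteins.
    ``hotspot`` draws proteins with probability proportional to
    rank^(-hotspot_concentration) (a Zipf rank law; 0 is uniform over
    proteins) and then a residue uniformly within the protein, emulating the
    extreme per-protein concentration seen in curated pathogenic sets.
    """

    mode: str = "uniform"  # uniform | hotspot
    n_variants: int = 1000
    hotspot_concentration: float = 0.0
    pathogenic_label: bool = False
    dataset_label: str = "synthetic"
    namespace_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)  # uniprot, refseq, ensembl
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("uniform", "hotspot"):
            raise ValueError(f"mode must be 'uniform' or 'hotspot', got {self.mode!r}")
        if self.n_variants < 1:
            raise ValueError(f"n_variants must be >= 1, got {self.n_variants}")
        if self.hotspot_concentration < 0:
            raise ValueError(
                f"hotspot_concentration must be >= 0, got {self.hotspot_concentration}"
            )
        if len(self.namespace_probs) != 3 or not np.isclose(
            sum(self.namespace_probs), 1.0
        ):
            raise ValueError("namespace_probs must be 3 probabilities summing to 1")


def _apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of *total* by *weights*."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts.tolist()


def _streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _cath_universe(config: ProteomeConfig, rng: np.random.Generator):
    """Generate a consistent 4-level CATH hierarchy and superfamily codes.

    Family sizes across superfamilies follow a power law (rank^-1); the true
    shape of the human distribution is heavy-tailed but not documented, so
    the power law is a stand-in (see methods note).
    """
    n_cls = max(1, config.n_cath_classes)
    n_arch = max(n_cls, config.n_cath_architectures)
    n_top = max(n_arch, config.n_cath_topologies)
    n_sf = max(n_top, config.n_cath_superfamilies)
    arch_class = np.concatenate(
        [np.arange(n_cls), rng.integers(0, n_cls, n_arch - n_cls)]
    )
    top_arch = np.concatenate(
        [np.arange(n_arch), rng.integers(0, n_arch, n_top - n_arch)]
    )
    sf_top = np.concatenate([np.arange(n_top), rng.integers(0, n_top, n_sf - n_top)])
    codes = []
    arch_no = {}
    top_no = {}
    sf_no = {}
    for s in range(n_sf):
        t = int(sf_top[s])
        a = int(top_arch[t])
        c = int(arch_class[a])
        a_idx = arch_no.setdefault(a, len([x for x in arch_no if arch_class[x] == c]) + 1)
        t_idx = top_no.setdefault(t, len([x for x in top_no if top_arch[x] == a]) + 1)
        s_idx = sf_no.setdefault(s, len([x for x in sf_no if sf_top[x] == t]) + 1)
        codes.append(f"{c + 1}.{a_idx * 10}.{t_idx * 10}.{s_idx * 10}")
    weights = 1.0 / np.arange(1, n_sf + 1)
    weights /= weights.sum()
    return codes, weights


def generate_proteome(config: ProteomeConfig) -> ProteomeReference:
    """Generate the full synthetic annotation universe.

    Deterministic for a fixed ``config.seed``.  Every protein has a gene
    with a chromosome and CDS length; a configurable subset carries
    structures with resolutions, covered intervals and per-residue observed
    flags; every structure-covered segment carries a CATH code; Pfam
    intervals never tile a whole sequence; EC codes attach only to the
    enzyme subset; every protein has at least one GO term; clusters
    partition the structure chains (one cluster per protein, emulating the
    95 %-identity grouping of near-identical chains).
    """
    config.validate()
    ref = ProteomeReference()
    if config.protein_count == 0:
        ref.build_indexes()
        return ref

    rngs = _streams(
        config.seed,
        ["genes", "crossrefs", "structures", "cath", "pfam", "ec", "go", "freq"],
    )

    chrom_labels = CHROMOSOMES[: config.n_chromosomes]
    if config.genes_per_chromosome is None:
        census = _data.gene_census_weights()
        weights = [census[c] for c in chrom_labels]
        per_chrom = _apportion(config.protein_count, weights)
    else:
        per_chrom = list(config.genes_per_chromosome)

    rng = rngs["genes"]
    gene_ids: list[str] = []
    gi = 0
    for chrom, n in zip(chrom_labels, per_chrom):
        for _ in range(n):
            gi += 1
            gid = f"G{gi:05d}"
            cds = int(
                max(
                    93,
                    round(
                        float(
                            rng.lognormal(
                                config.cds_lognormal_mean, config.cds_lognormal_sigma
                            )
                        )
                    ),
                )
            )
            ref.genes[gid] = Gene(gid, chrom, cds)
            gene_ids.append(gid)

    for i, gid in enumerate(gene_ids, start=1):
        acc = f"P{i:05d}"
        length = max(30, ref.genes[gid].cds_length // 3 - 1)
        ref.proteins[acc] = Protein(acc, length, gid)

    # Identifier cross-references; a small fraction carries a length
    # mismatch, which disqualifies mapping through that identifier.
    rng = rngs["crossrefs"]
    for i, acc in enumerate(ref.proteins, start=1):
        length = ref.proteins[acc].length
        for ns, prefix in (("refseq", "NM_"), ("ensembl", "ENSP")):
            foreign = f"{prefix}{i:06d}"
            flen = length
            if rng.random() < config.crossref_mismatch_rate:
                flen = length + int(rng.integers(1, 6))
            ref.crossrefs[ns][foreign] = CrossRef(foreign, acc, flen, length)

    # Structures with partial coverage and unobserved residues.
    rng = rngs["structures"]
    accs = list(ref.proteins)
    shuffled = list(accs)
    rng.shuffle(shuffled)
    n_covered = int(round(config.structure_coverage_fraction * len(accs)))
    covered = shuffled[:n_covered]
    si = 0
    for acc in covered:
        length = ref.proteins[acc].length
        for j in range(int(rng.integers(1, 4))):
            si += 1
            sid = f"S{si:04d}"
            resolution = (
                None if rng.random() < 0.10 else round(float(rng.uniform(1.0, 3.5)), 2)
            )
            if j == 0:
                # First structure spans the whole protein; later ones are
                # fragments, emulating partial deposition coverage.
                cov = length
            else:
                cov = min(length, int(max(30, round(length * rng.uniform(0.3, 1.0)))))
            sp_beg = int(rng.integers(1, length - cov + 2))
            sp_end = sp_beg + cov - 1
            res_beg = int(rng.integers(1, 21))
            struct = StructureRecord(sid, resolution)
            n_chains = 2 if rng.random() < 0.25 else 1
            for label in "AB"[:n_chains]:
                observed = rng.random(cov) >= config.unobserved_residue_rate
                struct.chains.append(
                    ChainMapping(label, acc, sp_beg, sp_end, res_beg, observed)
                )
            ref.structures[sid] = struct

    # CATH: partition every chain's structure-numbering extent into 1-2
    # disjoint domain segments, each drawing a superfamily code.
    rng = rngs["cath"]
    codes, sf_weights = _cath_universe(config, rng)
    for sid, struct in ref.structures.items():
        for ch in struct.chains:
            chain_id = struct.chain_id(ch)
            lo, hi = ch.res_beg, ch.res_end
            if hi - lo + 1 >= 80 and rng.random() < 0.5:
                split = int(rng.integers(lo + 30, hi - 29))
                segs = [(lo, split), (split + 1, hi)]
            else:
                segs = [(lo, hi)]
            for k, (s, e) in enumerate(segs, start=1):
                code = codes[int(rng.choice(len(codes), p=sf_weights))]
                dom_id = f"{sid}{ch.chain}{k:02d}"
                ref.cath[dom_id] = CathDomain(dom_id, code, chain_id, ((s, e),))

    # Clusters: one per protein, members in generation order.
    by_acc: dict[str, list[str]] = {}
    for sid, struct in ref.structures.items():
        for ch in struct.chains:
            by_acc.setdefault(ch.accession, []).append(struct.chain_id(ch))
    ref.clusters = [by_acc[a] for a in accs if a in by_acc]

    # Pfam intervals: never tiling the whole protein (residue 1 stays free).
    rng = rngs["pfam"]
    if config.n_pfam_families > 0:
        fam_weights = 1.0 / np.arange(1, config.n_pfam_families + 1)
        fam_weights /= fam_weights.sum()
        for acc in accs:
            length = ref.proteins[acc].length
            hits = []
            for _ in range(int(rng.integers(0, 4))):
                fam = f"PF{int(rng.choice(config.n_pfam_families, p=fam_weights)) + 1:05d}"
                width = int(rng.integers(10, max(11, int(length * 0.6))))
                width = min(width, length - 1)
                start = int(rng.integers(2, length - width + 2))
                hits.append(PfamHit(acc, fam, start, start + width - 1))
            if hits:
                ref.pfam[acc] = hits

    # EC codes: enzyme subset only; a fraction lacks the 4th level.
    rng = rngs["ec"]
    for acc in accs:
        if rng.random() >= config.enzyme_fraction:
            continue
        n_codes = 2 if rng.random() < 0.1 else 1
        codes_ec = []
        for _ in range(n_codes):
            parts = [
                str(int(rng.integers(1, 7))),
                str(int(rng.integers(1, 9))),
                str(int(rng.integers(1, 11))),
                str(int(rng.integers(1, 51))),
            ]
            if rng.random() < config.ec_incomplete_rate:
                parts = parts[:3]
            codes_ec.append(".".join(parts))
        ref.ec[acc] = codes_ec

    # GO: every protein gets >= 1 term; each term has exactly one aspect.
    rng = rngs["go"]
    n_go = max(1, config.go_terms_total)
    term_aspect = rng.choice(3, size=n_go, p=[0.25, 0.55, 0.20])
    term_weights = 1.0 / np.arange(1, n_go + 1)
    term_weights /= term_weights.sum()
    for acc in accs:
        k = min(n_go, 1 + int(rng.poisson(3)))
        terms = rng.choice(n_go, size=k, replace=False, p=term_weights)
        ref.go[acc] = [
            GoAnnotation(
                acc,
                f"GO:{int(t) + 1:07d}",
                config.go_aspect_labels[int(term_aspect[int(t)])],
            )
            for t in sorted(terms)
        ]

    ref.build_indexes()
    ref.validate()
    return ref


def generate_variant_dataset(
    proteome: ProteomeReference, spec: SamplingSpec
) -> list[VariantRecord]:
    """Draw a synthetic variant dataset from *proteome* per *spec*."""
    spec.validate()
    if not proteome.proteins:
        raise ValueError("cannot sample variants from an empty proteome")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    accs = list(proteome.proteins)
    lengths = np.array([proteome.proteins[a].length for a in accs], dtype=float)
    if spec.mode == "uniform":
        probs = lengths / lengths.sum()
    else:
        ranks = np.arange(1, len(accs) + 1, dtype=float)
        probs = ranks ** (-spec.hotspot_concentration)
        probs /= probs.sum()

    # Reverse crossref lookup for emitting refseq/ensembl identifiers.
    reverse = {
        ns: {xr.canonical_id: fid for fid, xr in proteome.crossrefs[ns].items()}
        for ns in ("refseq", "ensembl")
    }
    namespaces = ("uniprot", "refseq", "ensembl")

    records: list[VariantRecord] = []
    idx = rng.choice(len(accs), size=spec.n_variants, p=probs)
    ns_draw = rng.choice(3, size=spec.n_variants, p=list(spec.namespace_probs))
    for i, ns_i in zip(idx, ns_draw):
        acc = accs[int(i)]
        prot = proteome.proteins[acc]
        position = int(rng.integers(1, prot.length + 1))
        ref_aa, alt_aa = (
            _AA[int(j)] for j in rng.choice(len(_AA), size=2, replace=False)
        )
        ns = namespaces[int(ns_i)]
        if ns == "uniprot":
            rid = acc
        else:
            rid = reverse[ns].get(acc, acc)
        gene = proteome.genes[prot.gene_id]
        records.append(
            VariantRecord(
                dataset_label=spec.dataset_label,
                ref_namespace=ns,
                ref_id=rid,
                position=position,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                chromosome=gene.chromosome,
                gene=gene.gene_id,
            )
        )
    return records


def generate_frequency_table(
    proteome: ProteomeReference,
    n_entries: int,
    n_populations: int = 7,
    fraction_in_window: float = 0.5,
    maf_low: float = 0.01,
    maf_high: float = 0.25,
    seed: int = 0,
) -> FrequencyTable:
    """Generate an allele-frequency table over substitutions in *proteome*.

    A ``fraction_in_window`` share of entries gets at least one population
    minor allele frequency strictly inside ``(maf_low, maf_high)`` — the
    window the benign-contamination screen uses; the remaining entries have
    every population frequency outside it.
    """
    if n_populations < 1:
        raise ValueError(f"n_populations must be >= 1, got {n_populations}")
    _check_fraction("fraction_in_window", fraction_in_window)
    populations = tuple(f"pop{i + 1}" for i in range(n_populations))
    table = FrequencyTable(populations=populations)
    if n_entries == 0:
        return table
    if not proteome.proteins:
        raise ValueError("cannot build a frequency table over an empty proteome")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    accs = list(proteome.proteins)
    for _ in range(n_entries):
        acc = accs[int(rng.integers(len(accs)))]
        position = int(rng.integers(1, proteome.proteins[acc].length + 1))
        ref_aa, alt_aa = (
            _AA[int(j)] for j in rng.choice(len(_AA), size=2, replace=False)
        )
        in_window = rng.random() < fraction_in_window
        mafs = []
        for _p in range(n_populations):
            if rng.random() < 0.5:
                mafs.append(float(rng.uniform(0.0, maf_low)))
            else:
                mafs.append(float(rng.uniform(maf_high, 0.5)))
        if in_window:
            pop = int(rng.integers(n_populations))
            span = maf_high - maf_low
            mafs[pop] = float(
                rng.uniform(maf_low + 0.01 * span, maf_high - 0.01 * span)
            )
        table.entries.append(
            FrequencyEntry(acc, position, ref_aa, alt_aa, tuple(mafs))
        )
    return table
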