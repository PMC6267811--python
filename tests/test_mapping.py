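"""Identifier resolution and structure selection against brute-force oracles."""

import dataclasses

import numpy as np
import pytest

from varrep.mapping import map_dataset, select_structure_residue, to_canonical
from varrep.model import (
    STATUS_PROTEIN,
    STATUS_STRUCTURE,
    STATUS_UNMAPPED,
    ChainMapping,
    CrossRef,
    Gene,
    Protein,
    ProteomeReference,
    StructureRecord,
    VariantRecord,
)
from varrep.synth import ProteomeConfig, SamplingSpec, generate_proteome, \
    generate_variant_dataset


def _record(ns, rid, pos, label="t"):
    return VariantRecord(
        dataset_label=label, ref_namespace=ns, ref_id=rid, position=pos,
        ref_aa="A", alt_aa="V",
    )


@pytest.fixture(scope="module")
def fixture_universe():
    return generate_proteome(ProteomeConfig(protein_count=50, seed=17))


def test_uniprot_passthrough(fixture_universe):
    acc = next(iter(fixture_universe.proteins))
    rec = to_canonical(_record("uniprot", acc, 1), fixture_universe)
    assert rec.mapping_status == STATUS_PROTEIN
    assert rec.canonical_protein == acc


def test_unknown_accession_stays_unmapped(fixture_universe):
    rec = to_canonical(_record("uniprot", "NOPE", 1), fixture_universe)
    assert rec.mapping_status == STATUS_UNMAPPED
    assert rec.canonical_protein is None


def test_crossref_length_mismatch_blocks_mapping():
    ref = ProteomeReference()
    ref.genes["G1"] = Gene("G1", "1", 300)
    ref.proteins["P1"] = Protein("P1", 99, "G1")
    ref.crossrefs["refseq"]["NM_1"] = CrossRef("NM_1", "P1", 100, 99)  # off by 1
    ref.crossrefs["ensembl"]["E1"] = CrossRef("E1", "P1", 99, 99)
    ref.build_indexes()
    assert to_canonical(_record("refseq", "NM_1", 5), ref).mapping_status \
        == STATUS_UNMAPPED
    assert to_canonical(_record("ensembl", "E1", 5), ref).mapping_status \
        == STATUS_PROTEIN


def test_position_beyond_protein_length_unmapped(fixture_universe):
    acc, prot = next(iter(fixture_universe.proteins.items()))
    rec = to_canonical(_record("uniprot", acc, prot.length + 1), fixture_universe)
    assert rec.mapping_status == STATUS_UNMAPPED


def test_to_canonical_equals_brute_force_filter(fixture_universe):
    """Both rules (length match, position within canonical length) applied
    independently must select the same records."""
    records = generate_variant_dataset(
        fixture_universe, SamplingSpec(mode="uniform", n_variants=500, seed=5)
    )
    # Corrupt some positions to exercise the bounds rule.
    rng = np.random.default_rng(0)
    records = [
        dataclasses.replace(r, position=r.position + 10000)
        if rng.random() < 0.1 else r
        for r in records
    ]
    mapped = [to_canonical(r, fixture_universe) for r in records]

    def brute(rec):
        if rec.ref_namespace == "uniprot":
            acc = rec.ref_id if rec.ref_id in fixture_universe.proteins else None
        else:
            acc = None
            for xr in fixture_universe.crossrefs[rec.ref_namespace].values():
                if xr.foreign_id == rec.ref_id and \
                        xr.foreign_length == xr.canonical_length:
                    acc = xr.canonical_id
        if acc is not None and rec.position > fixture_universe.proteins[acc].length:
            acc = None
        return acc

    for rec, out in zip(records, mapped):
        assert out.canonical_protein == brute(rec)


def _toy_structure_reference(structures):
    """Reference with one 100-residue protein and the given structures.

    *structures* is a list of (sid, resolution, chains) where chains is a
    list of (label, sp_beg, sp_end, observed_positions_or_None)."""
    ref = ProteomeReference()
    ref.genes["G1"] = Gene("G1", "1", 303)
    ref.proteins["P1"] = Protein("P1", 100, "G1")
    for sid, resolution, chains in structures:
        struct = StructureRecord(sid, resolution)
        for label, beg, end, unobserved in chains:
            observed = np.ones(end - beg + 1, dtype=bool)
            for pos in unobserved or ():
                observed[pos - beg] = False
            struct.chains.append(ChainMapping(label, "P1", beg, end, beg, observed))
        ref.structures[sid] = struct
    ref.build_indexes()
    return ref


def test_single_covering_structure_returns_locus():
    ref = _toy_structure_reference([("S1", 2.0, [("A", 10, 60, None)])])
    locus = select_structure_residue("P1", 30, ref)
    assert (locus.structure_id, locus.chain, locus.structure_residue) \
        == ("S1", "A", 30)


def test_unobserved_best_resolution_falls_through_to_next():
    ref = _toy_structure_reference(
        [
            ("S1", 1.5, [("A", 10, 60, [30])]),  # best but unobserved at 30
            ("S2", 2.5, [("A", 10, 60, None)]),
        ]
    )
    locus = select_structure_residue("P1", 30, ref)
    assert locus.structure_id == "S2"
    assert locus.resolution == 2.5


def test_unresolved_structures_sort_last():
    ref = _toy_structure_reference(
        [
            ("S1", None, [("A", 10, 60, None)]),
            ("S2", 3.4, [("A", 10, 60, None)]),
        ]
    )
    assert select_structure_residue("P1", 30, ref).structure_id == "S2"


def test_first_chain_in_file_order_wins():
    ref = _toy_structure_reference(
        [("S1", 2.0, [("B", 10, 60, None), ("A", 10, 60, None)])]
    )
    assert select_structure_residue("P1", 30, ref).chain == "B"


def test_whole_structure_discarded_even_if_other_chain_observed():
    # The first covering chain is unobserved at the position: the structure
    # is discarded outright, not retried on its other chain.
    ref = _toy_structure_reference(
        [
            ("S1", 1.0, [("A", 10, 60, [30]), ("B", 10, 60, None)]),
            ("S2", 2.0, [("A", 10, 60, None)]),
        ]
    )
    assert select_structure_residue("P1", 30, ref).structure_id == "S2"


def test_no_surviving_candidate_returns_none():
    ref = _toy_structure_reference([("S1", 1.0, [("A", 10, 60, [30])])])
    assert select_structure_residue("P1", 30, ref) is None
    assert select_structure_residue("P1", 99, ref) is None  # outside interval


def test_unknown_accession_is_an_error(fixture_universe):
    with pytest.raises(KeyError):
        select_structure_residue("NOPE", 1, fixture_universe)


def test_structure_selection_equals_brute_force(fixture_universe):
    """Exhaustive enumeration over (structure, chain) pairs under the stated
    ordering must agree with the implementation at every residue."""

    def brute(acc, pos):
        ref = fixture_universe
        candidates = []
        for sid, struct in ref.structures.items():
            chains = [ch for ch in struct.chains
                      if ch.accession == acc and ch.sp_beg <= pos <= ch.sp_end]
            if chains:
                candidates.append((sid, struct, chains))
        candidates.sort(
            key=lambda t: (t[1].resolution is None,
                           t[1].resolution if t[1].resolution is not None else 0.0,
                           t[0])
        )
        for sid, struct, chains in candidates:
            ch = chains[0]
            if ch.observed[pos - ch.sp_beg]:
                from varrep.model import ResidueLocus
                return ResidueLocus(sid, ch.chain, ch.res_beg + pos - ch.sp_beg,
                                    struct.resolution)
            # discard whole structure
        return None

    rng = np.random.default_rng(1)
    accs = list(fixture_universe.proteins)
    for _ in range(400):
        acc = accs[int(rng.integers(len(accs)))]
        pos = int(rng.integers(1, fixture_universe.proteins[acc].length + 1))
        assert select_structure_residue(acc, pos, fixture_universe) \
            == brute(acc, pos)


def test_map_dataset_tallies_and_monotonicity(fixture_universe):
    records = generate_variant_dataset(
        fixture_universe, SamplingSpec(mode="uniform", n_variants=800, seed=6)
    )
    mapped = map_dataset(records, fixture_universe)
    t = mapped.tally
    assert t.n_structure_mapped <= t.n_protein_mapped <= t.n_total == 800
    # Max per protein equals a brute-force groupby count.
    import collections

    byprot = collections.Counter(
        r.canonical_protein for r in mapped.records if r.canonical_protein
    )
    assert t.max_per_protein == max(byprot.values())
    assert byprot[t.max_accession] == t.max_per_protein
    assert sum(byprot.values()) == t.n_protein_mapped
    # Every structure-mapped record has a locus and a canonical protein.
    for rec, locus in zip(mapped.records, mapped.loci):
        if rec.mapping_status == STATUS_STRUCTURE:
            assert locus is not None and rec.canonical_protein is not None
        else:
            assert locus is None


def test_empty_dataset_gives_zero_tallies(fixture_universe):
    t = map_dataset([], fixture_universe).tally
    assert (t.n_total, t.n_protein_mapped, t.n_structure_mapped) == (0, 0, 0)
    assert t.pct_protein_mapped == 0 and t.pct_structure_mapped == 0


def test_more_unobserved_residues_never_increase_structure_mapping():
    counts = []
    for rate in (0.0, 0.2, 0.6):
        ref = generate_proteome(
            ProteomeConfig(protein_count=80, unobserved_residue_rate=rate, seed=23)
        )
        recs = generate_variant_dataset(
            ref, SamplingSpec(mode="uniform", n_variants=600, seed=31)
        )
        counts.append(map_dataset(recs, ref).tally.n_structure_mapped)
    assert counts[0] >= counts[1] >= counts[2]
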