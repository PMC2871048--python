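import itertools

import pytest

from refrec.reconstruction import (DanglingLinkError, EmptySequenceError,
                                   InvalidRecordError, PpiRecord,
                                   ReactionRecord, SourceRecord,
                                   assemble_network,
                                   build_assembly_interactions, ec_matches,
                                   instantiate_central_dogma,
                                   link_enzymes_by_ec,
                                   merge_species_by_sequence,
                                   split_reversible_reactions)


def gene(db, acc, seq):
    return SourceRecord(db, acc, "gene", seq)


def protein(db, acc, seq):
    return SourceRecord(db, acc, "protein", seq)


class TestSequenceMerging:
    def test_identical_coding_sequences_merge(self):
        species, mm = merge_species_by_sequence(
            [gene("ensembl", "G1", "ATGAAA"), gene("ensembl", "G2", "ATGAAA")])
        assert len(species) == 1
        assert species[0].xrefs == {("ensembl", "G1"), ("ensembl", "G2")}
        assert mm[("ensembl", "G1")] == mm[("ensembl", "G2")]

    def test_cross_database_protein_merge(self):
        species, _ = merge_species_by_sequence(
            [protein("ensembl", "P1", "MKL"), protein("refseq", "NP_1", "MKL"),
             protein("uniprot", "Q1", "MKL")])
        assert len(species) == 1
        assert len(species[0].xrefs) == 3

    def test_distinct_sequences_give_bijection(self):
        records = [gene("ensembl", f"G{i}", "ATG" + "A" * i) for i in range(8)]
        species, mm = merge_species_by_sequence(records)
        assert len(species) == 8
        assert len(set(mm.values())) == 8

    def test_normalization_uppercase_whitespace(self):
        species, _ = merge_species_by_sequence(
            [gene("a", "G1", "atg aaa"), gene("b", "G2", "ATGAAA")])
        assert len(species) == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(EmptySequenceError, match="G1"):
            merge_species_by_sequence([gene("ensembl", "G1", "  ")])

    def test_merging_is_idempotent(self):
        records = [gene("a", "G1", "ATG"), gene("b", "G2", "ATG"),
                   gene("a", "G3", "TTT")]
        species, _ = merge_species_by_sequence(records)
        again, _ = merge_species_by_sequence(
            [SourceRecord("merged", s.id, "gene", s.primary_sequence)
             for s in species])
        assert ([s.primary_sequence for s in again]
                == [s.primary_sequence for s in species])


class TestCentralDogma:
    def test_one_per_link_and_transcript(self):
        gt = [(f"g:{i}", f"tr:{i}") for i in range(10)]
        tp = [(f"tr:{i}", f"p:{i}") for i in range(10)]
        ix = instantiate_central_dogma(gt, tp)
        assert sum(i.interaction_type == "transcription" for i in ix) == 10
        assert sum(i.interaction_type == "translation" for i in ix) == 10

    def test_merged_transcript_gets_two_transcriptions(self):
        ix = instantiate_central_dogma(
            [("g:1", "tr:1"), ("g:2", "tr:1")], [("tr:1", "p:1")])
        txn = [i for i in ix if i.interaction_type == "transcription"]
        tln = [i for i in ix if i.interaction_type == "translation"]
        assert len(txn) == 2 and len(tln) == 1
        assert {i.controllers[0] for i in txn} == {"g:1", "g:2"}
        assert txn[0].products == [("tr:1", 1.0)]

    def test_transcript_with_conflicting_proteins_rejected(self):
        with pytest.raises(DanglingLinkError):
            instantiate_central_dogma(
                [("g:1", "tr:1")], [("tr:1", "p:1"), ("tr:1", "p:2")])


class TestEnzymeLinking:
    def test_one_reaction_per_capable_protein(self):
        rec = ReactionRecord("R1", [("C1", 1)], [("C2", 1)],
                             ec_numbers=["5.3.1.9"])
        ix = link_enzymes_by_ec([rec], {"p:1": {"5.3.1.9"},
                                        "p:2": {"5.3.1.9"}})
        assert len(ix) == 2
        assert sorted(i.controllers for i in ix) == [["p:1"], ["p:2"]]

    def test_unmatched_reaction_kept_uncatalyzed(self):
        rec = ReactionRecord("R1", [("C1", 1)], [("C2", 1)],
                             ec_numbers=["1.1.1.1"])
        ix = link_enzymes_by_ec([rec], {"p:1": {"2.2.2.2"}})
        assert len(ix) == 1 and ix[0].controllers == []
        assert link_enzymes_by_ec([rec], {"p:1": {"2.2.2.2"}},
                                  include_uncatalyzed=False) == []

    def test_matches_equal_bruteforce_bipartite_enumeration(self):
        # enumerate the EC match relation independently and compare pair sets
        recs = [ReactionRecord(f"R{k}", [("C1", 1)], [("C2", 1)],
                               ec_numbers=[ec])
                for k, ec in enumerate(
                    ["1.1.1.1", "1.1.1.2", "2.7.1.-", "5.3.1.9", "1.1.1.1"])]
        annotations = {"p:1": {"1.1.1.1"}, "p:2": {"2.7.1.11", "5.3.1.9"},
                       "p:3": {"1.1.1.1", "9.9.9.9"}}
        ix = link_enzymes_by_ec(recs, annotations, include_uncatalyzed=False)
        got = {(i.controllers[0], tuple(i.substrates)) for i in ix}
        expected_pairs = set()
        for rec, (pid, ecs) in itertools.product(recs, annotations.items()):
            if any(ec_matches(a, b) for a in rec.ec_numbers for b in ecs):
                expected_pairs.add(pid)
        assert {p for p, _ in got} == expected_pairs
        # 1.1.1.1: p1,p3 on two records = 4; 2.7.1.-: p2; 5.3.1.9: p2
        assert len(ix) == 6

    @pytest.mark.parametrize("a,b,match", [
        ("1.2.3.4", "1.2.3.4", True),
        ("1.2.3.-", "1.2.3.4", True),
        ("1.2.3.4", "1.2.-.-", True),
        ("1.2.3.4", "1.2.3.5", False),
    ])
    def test_wildcard_matching(self, a, b, match):
        assert ec_matches(a, b) is match

    def test_malformed_ec_rejected(self):
        rec = ReactionRecord("R1", [("C1", 1)], [("C2", 1)],
                             ec_numbers=["1.2.3"])
        with pytest.raises(ValueError, match="malformed EC"):
            link_enzymes_by_ec([rec], {})


class TestAssemblies:
    def test_binary_record(self):
        complexes, assemblies = build_assembly_interactions(
            [PpiRecord("EBI-1", ("p:1", "p:2"))])
        assert len(complexes) == 1
        assert len(assemblies[0].substrates) == 2
        assert assemblies[0].products[0][0] == complexes[0].id
        assert assemblies[0].reversible is False

    def test_99_member_record(self):
        members = tuple(f"p:{i:04d}" for i in range(99))
        _, assemblies = build_assembly_interactions(
            [PpiRecord("EBI-1", members)])
        assert len(assemblies[0].substrates) == 99

    def test_duplicate_member_sets_deduplicated(self):
        complexes, assemblies = build_assembly_interactions(
            [PpiRecord("EBI-1", ("p:1", "p:2")),
             PpiRecord("EBI-2", ("p:2", "p:1"))])
        assert len(complexes) == 1 and len(assemblies) == 1

    def test_single_member_rejected(self):
        with pytest.raises(InvalidRecordError):
            build_assembly_interactions([PpiRecord("EBI-1", ("p:1", "p:1"))])


class TestReversibleSplitting:
    def test_reversible_becomes_mirrored_pair(self):
        from refrec.network_model import Interaction
        rxn = Interaction("ix:rxn:0001", "metabolic_reaction",
                          substrates=[("m:1", 1.0)], products=[("m:2", 2.0)],
                          controllers=["p:1"], reversible=True)
        fwd, rev = split_reversible_reactions([rxn])
        assert fwd.substrates == rev.products
        assert fwd.products == rev.substrates
        assert fwd.controllers == rev.controllers == ["p:1"]
        assert not fwd.reversible and not rev.reversible

    def test_counting(self):
        from refrec.network_model import Interaction
        mk = lambda k, rev: Interaction(
            f"ix:rxn:{k}", "metabolic_reaction",
            substrates=[("m:1", 1.0)], products=[("m:2", 1.0)],
            reversible=rev)
        out = split_reversible_reactions(
            [mk(k, True) for k in range(3)] + [mk(k + 10, False)
                                               for k in range(4)])
        assert len(out) == 2 * 3 + 4
        assert all(not i.reversible for i in out)
        # irreversible inputs pass through unchanged
        assert out[-1].id == "ix:rxn:13"


class TestAssembleNetwork:
    def test_minimal_chain_counts_five_objects(self):
        net = assemble_network(
            gene_records=[gene("ensembl", "G1", "ATG")],
            transcript_records=[SourceRecord("ensembl", "T1", "transcript",
                                             "ATG")],
            protein_records=[protein("ensembl", "P1", "M")],
            gene_transcript_links=[("G1", "T1")],
            transcript_protein_links=[("T1", "P1")])
        assert net.n_objects == 5

    def test_duplicated_cds_pair_drops_transcript_count(self):
        net = assemble_network(
            gene_records=[gene("ensembl", "G1", "ATGC"),
                          gene("ensembl", "G2", "ATGG"),
                          gene("ensembl", "G3", "ATGT")],
            transcript_records=[
                SourceRecord("ensembl", "T1", "transcript", "AAA"),
                SourceRecord("ensembl", "T2", "transcript", "AAA"),
                SourceRecord("ensembl", "T3", "transcript", "CCC")],
            protein_records=[protein("ensembl", f"P{i}", seq)
                             for i, seq in ((1, "MK"), (2, "MK"), (3, "ML"))],
            gene_transcript_links=[("G1", "T1"), ("G2", "T2"), ("G3", "T3")],
            transcript_protein_links=[("T1", "P1"), ("T2", "P2"),
                                      ("T3", "P3")])
        assert len(net.species_of_type("transcript")) == 2  # genes - 1
        assert len(net.interactions_of_type("transcription")) == 3
        assert len(net.interactions_of_type("translation")) == 2

    def test_dangling_link_raises(self):
        with pytest.raises(DanglingLinkError):
            assemble_network(
                gene_records=[gene("ensembl", "G1", "ATG")],
                transcript_records=[SourceRecord("ensembl", "T1",
                                                 "transcript", "ATG")],
                protein_records=[protein("ensembl", "P1", "M")],
                gene_transcript_links=[("G9", "T1")],
                transcript_protein_links=[("T1", "P1")])
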