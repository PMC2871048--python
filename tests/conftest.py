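import pytest

from refrec.network_model import Interaction, MolecularSpecies, Network


def make_chain_network() -> Network:
    """Minimal central-dogma chain: gene -> transcription -> transcript ->
    translation -> protein (5 objects)."""
    net = Network()
    net.add_species(MolecularSpecies("g:0001", "gene", "ATGAAA"))
    net.add_species(MolecularSpecies("tr:0001", "transcript", "ATGAAA"))
    net.add_species(MolecularSpecies("p:0001", "protein", "MK"))
    net.add_interaction(Interaction(
        "ix:txn:0001", "transcription",
        products=[("tr:0001", 1.0)], controllers=["g:0001"]))
    net.add_interaction(Interaction(
        "ix:tln:0001", "translation",
        products=[("p:0001", 1.0)], controllers=["tr:0001"]))
    return net


def make_redundant_route_network() -> Network:
    """Two genes with distinct transcripts whose translations produce the
    same protein: knocking either gene leaves the protein feasible."""
    net = Network()
    for k in (1, 2):
        net.add_species(MolecularSpecies(f"g:{k:04d}", "gene", "AT" * (k + 2)))
        net.add_species(MolecularSpecies(
            f"tr:{k:04d}", "transcript", "GC" * (k + 2)))
        net.add_interaction(Interaction(
            f"ix:txn:{k:04d}", "transcription",
            products=[(f"tr:{k:04d}", 1.0)], controllers=[f"g:{k:04d}"]))
    net.add_species(MolecularSpecies("p:0001", "protein", "MKL"))
    for k in (1, 2):
        net.add_interaction(Interaction(
            f"ix:tln:{k:04d}", "translation",
            products=[("p:0001", 1.0)], controllers=[f"tr:{k:04d}"]))
    return net


@pytest.fixture
def chain_network():
    return make_chain_network()


@pytest.fixture
def redundant_route_network():
    return make_redundant_route_network()
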