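"""Build a multi-omic network from database-export-like source records.

The reconstruction follows the reference-object approach: genes,
transcripts and proteins are identified by their exact primary sequence,
so records from different source databases that carry the same sequence
collapse into a single reference object whose xrefs remember every
contributing accession.  On top of the merged species the module
instantiates the interactions that databases do not document explicitly —
one transcription per (gene, transcript) link and one translation per
transcript — links enzymes to reactions through EC numbers, builds protein
complexes from protein-protein interaction records, and finally splits
every reversible reaction into two irreversible directions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .network_model import Interaction, MolecularSpecies, Network, validate_network

RECORD_TYPES = frozenset({"gene", "transcript", "protein"})

_ID_PREFIX = {"gene": "g", "transcript": "tr", "protein": "p"}


class EmptySequenceError(ValueError):
    """A source record carried an empty primary sequence."""


class DanglingLinkError(KeyError):
    """A link table referenced an accession with no corresponding record."""


class InvalidRecordError(ValueError):
    """A source record violated its own invariants (e.g. <2 PPI members)."""


@dataclass
class SourceRecord:
    """A gene/transcript/protein record as exported by a source database."""

    source_db: str
    accession: str
    record_type: str
    primary_sequence: str
    links: tuple = ()

    def __post_init__(self):
        self.links = tuple(self.links)
        if self.record_type not in RECORD_TYPES:
            raise InvalidRecordError(
                f"{self.accession}: unknown record type {self.record_type!r}")


@dataclass
class ReactionRecord:
    """A metabolic reaction with substrates, products and EC numbers."""

    accession: str
    substrates: list
    products: list
    ec_numbers: list = field(default_factory=list)
    reversible: bool = False

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise InvalidRecordError(
                f"{self.accession}: reaction needs >=1 substrate and product")


@dataclass
class PpiRecord:
    """A protein-protein interaction record listing >=2 member proteins."""

    accession: str
    member_proteins: tuple

    def __post_init__(self):
        self.member_proteins = tuple(self.member_proteins)
        if len(self.member_proteins) < 2:
            raise InvalidRecordError(
                f"{self.accession}: needs >=2 member proteins")


def _normalize_sequence(seq: str) -> str:
    # identity comparison is exact: uppercase, whitespace stripped, no tolerance
    return re.sub(r"\s+", "", seq).upper()


def merge_species_by_sequence(records, record_type=None, start_index=1):
    """Merge records sharing an identical normalized primary sequence.

    Returns ``(species, merge_map)`` where ``merge_map`` maps every input
    ``(source_db, accession)`` pair to the id of its merged reference
    object.  One species is produced per distinct sequence; its xrefs are
    the union of the contributing accessions.

    Raises
    ------
    EmptySequenceError
        If any record has an empty sequence after normalization.
    """
    records = list(records)
    if record_type is None:
        if not records:
            raise ValueError("record_type required for empty input")
        record_type = records[0].record_type
    if any(r.record_type != record_type for r in records):
        raise InvalidRecordError("records must all share one record_type")

    prefix = _ID_PREFIX[record_type]
    by_sequence: dict[str, str] = {}
    species: dict[str, MolecularSpecies] = {}
    xrefs: dict[str, set] = {}
    merge_map: dict[tuple, str] = {}
    counter = start_index
    for r in records:
        seq = _normalize_sequence(r.primary_sequence)
        if not seq:
            raise EmptySequenceError(
                f"{r.source_db}:{r.accession}: empty primary sequence")
        if seq not in by_sequence:
            oid = f"{prefix}:{counter:04d}"
            counter += 1
            by_sequence[seq] = oid
            species[oid] = MolecularSpecies(
                id=oid, species_type=record_type, primary_sequence=seq)
            xrefs[oid] = set()
        oid = by_sequence[seq]
        xrefs[oid].add((r.source_db, r.accession))
        merge_map[(r.source_db, r.accession)] = oid
    for oid, s in species.items():
        s.xrefs = frozenset(xrefs[oid])
    return list(species.values()), merge_map


def _accession_index(merge_map):
    """Accession -> merged id, irrespective of source database.

    Fixture link tables reference accessions without naming the database;
    an accession used by several databases must resolve to a single merged
    object to be usable.
    """
    idx: dict[str, str] = {}
    for (_db, acc), oid in merge_map.items():
        if acc in idx and idx[acc] != oid:
            raise DanglingLinkError(
                f"accession {acc!r} is ambiguous across databases")
        idx[acc] = oid
    return idx


def instantiate_central_dogma(gene_transcript_links, transcript_protein_links):
    """Instantiate transcription and translation interactions.

    Parameters are lists of already-resolved id pairs: ``(gene_id,
    transcript_id)`` and ``(transcript_id, protein_id)``.  Exactly one
    transcription is created per distinct (gene, transcript) link — a
    transcript merged from k genes therefore receives k transcriptions —
    and exactly one translation per transcript.
    """
    interactions = []
    seen = set()
    n = 0
    for gene_id, tr_id in gene_transcript_links:
        key = (gene_id, tr_id)
        if key in seen:
            continue
        seen.add(key)
        n += 1
        interactions.append(Interaction(
            id=f"ix:txn:{n:04d}", interaction_type="transcription",
            products=[(tr_id, 1.0)], controllers=[gene_id]))

    protein_of: dict[str, str] = {}
    for tr_id, p_id in transcript_protein_links:
        if tr_id in protein_of and protein_of[tr_id] != p_id:
            raise DanglingLinkError(
                f"transcript {tr_id!r} linked to multiple distinct proteins")
        protein_of[tr_id] = p_id
    n = 0
    for tr_id in protein_of:
        n += 1
        interactions.append(Interaction(
            id=f"ix:tln:{n:04d}", interaction_type="translation",
            products=[(protein_of[tr_id], 1.0)], controllers=[tr_id]))
    return interactions


_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


def ec_matches(a: str, b: str) -> bool:
    """Exact EC equality with dash wildcards (partial annotations)."""
    fa, fb = a.split("."), b.split(".")
    return all(x == y or x == "-" or y == "-" for x, y in zip(fa, fb))


def link_enzymes_by_ec(reaction_records, protein_ec_annotations,
                       metabolite_id=lambda acc: f"m:{acc}",
                       include_uncatalyzed=True):
    """Connect metabolic reactions to catalyzing proteins via EC numbers.

    ``protein_ec_annotations`` maps protein id -> iterable of EC strings.
    A *separate* reaction interaction is created for each (reaction,
    matching protein) pair, each with that single protein as controller.
    Reactions matching no annotated protein yield one interaction with no
    controllers when ``include_uncatalyzed`` is true, else none.
    """
    for pid, ecs in protein_ec_annotations.items():
        for ec in ecs:
            if not _EC_RE.match(ec):
                raise ValueError(f"malformed EC number {ec!r} on {pid}")
    for rec in reaction_records:
        for ec in rec.ec_numbers:
            if not _EC_RE.match(ec):
                raise ValueError(
                    f"malformed EC number {ec!r} on {rec.accession}")

    interactions = []
    n = 0
    for rec in reaction_records:
        matching = sorted(
            pid for pid, ecs in protein_ec_annotations.items()
            if any(ec_matches(rec_ec, ec)
                   for rec_ec in rec.ec_numbers for ec in ecs))
        subs = [(metabolite_id(acc), c) for acc, c in rec.substrates]
        prods = [(metabolite_id(acc), c) for acc, c in rec.products]
        if matching:
            for pid in matching:
                n += 1
                interactions.append(Interaction(
                    id=f"ix:rxn:{n:04d}", interaction_type="metabolic_reaction",
                    substrates=subs, products=prods, controllers=[pid],
                    reversible=rec.reversible))
        elif include_uncatalyzed:
            n += 1
            interactions.append(Interaction(
                id=f"ix:rxn:{n:04d}", interaction_type="metabolic_reaction",
                substrates=subs, products=prods, controllers=[],
                reversible=rec.reversible))
    return interactions


def build_assembly_interactions(ppi_records):
    """Instantiate protein complexes and their assembly interactions.

    One complex species and one irreversible assembly interaction per
    deduplicated record (key: sorted tuple of member ids); member proteins
    are substrates with coefficient 1, the complex the sole product.  No
    disassembly interaction is created.
    """
    complexes, assemblies = [], []
    seen: dict[tuple, str] = {}
    n = 0
    for rec in ppi_records:
        members = tuple(sorted(set(rec.member_proteins)))
        if len(members) < 2:
            raise InvalidRecordError(
                f"{rec.accession}: needs >=2 distinct member proteins")
        if members in seen:
            continue
        n += 1
        cx_id = f"cx:{n:04d}"
        seen[members] = cx_id
        complexes.append(MolecularSpecies(
            id=cx_id, species_type="protein_complex",
            xrefs=frozenset({("intact", rec.accession)})))
        assemblies.append(Interaction(
            id=f"ix:asm:{n:04d}", interaction_type="complex_assembly",
            substrates=[(m, 1.0) for m in members],
            products=[(cx_id, 1.0)], reversible=False))
    return complexes, assemblies


def split_reversible_reactions(interactions):
    """Replace each reversible interaction by two irreversible directions.

    The forward copy keeps substrates/products as given, the reverse copy
    swaps them; controllers are shared.  All outputs have
    ``reversible=False``.
    """
    out = []
    for i in interactions:
        if not i.reversible:
            out.append(i)
            continue
        out.append(Interaction(
            id=f"{i.id}:fwd", interaction_type=i.interaction_type,
            substrates=list(i.substrates), products=list(i.products),
            controllers=list(i.controllers), reversible=False))
        out.append(Interaction(
            id=f"{i.id}:rev", interaction_type=i.interaction_type,
            substrates=list(i.products), products=list(i.substrates),
            controllers=list(i.controllers), reversible=False))
    return out


def assemble_network(gene_records, transcript_records, protein_records,
                     gene_transcript_links=(), transcript_protein_links=(),
                     reaction_records=(), protein_ec_links=(),
                     ppi_records=(), exchange_metabolites=(),
                     include_uncatalyzed=True) -> Network:
    """Compose the full reconstruction from source inputs.

    Link tables (``gene_transcript_links``, ``transcript_protein_links``,
    ``protein_ec_links``, PPI member lists, exchange metabolites) reference
    source accessions; they are resolved through the merge maps so that
    records merged by sequence identity share their downstream structure.

    Returns a validated :class:`~refrec.network_model.Network`.
    """
    genes, gene_map = merge_species_by_sequence(list(gene_records), "gene")
    transcripts, tr_map = merge_species_by_sequence(
        list(transcript_records), "transcript")
    proteins, p_map = merge_species_by_sequence(
        list(protein_records), "protein")
    gene_idx = _accession_index(gene_map)
    tr_idx = _accession_index(tr_map)
    p_idx = _accession_index(p_map)

    def _resolve(idx, acc, what):
        try:
            return idx[acc]
        except KeyError:
            raise DanglingLinkError(
                f"{what} link references unknown accession {acc!r}") from None

    gt = [(_resolve(gene_idx, g, "gene-transcript"),
           _resolve(tr_idx, t, "gene-transcript"))
          for g, t in gene_transcript_links]
    tp = [(_resolve(tr_idx, t, "transcript-protein"),
           _resolve(p_idx, p, "transcript-protein"))
          for t, p in transcript_protein_links]
    dogma = instantiate_central_dogma(gt, tp)

    ec_by_protein: dict[str, set] = {}
    for acc, ec in protein_ec_links:
        ec_by_protein.setdefault(
            _resolve(p_idx, acc, "protein-EC"), set()).add(ec)

    reactions = link_enzymes_by_ec(
        list(reaction_records), ec_by_protein,
        include_uncatalyzed=include_uncatalyzed)

    resolved_ppi = [
        PpiRecord(rec.accession,
                  tuple(_resolve(p_idx, m, "PPI member")
                        for m in rec.member_proteins))
        for rec in ppi_records]
    complexes, assemblies = build_assembly_interactions(resolved_ppi)

    metabolite_ids: dict[str, str] = {}
    for rec in reaction_records:
        for acc, _c in list(rec.substrates) + list(rec.products):
            metabolite_ids.setdefault(acc, f"m:{acc}")
    exchanges = []
    for k, acc in enumerate(sorted(set(exchange_metabolites)), start=1):
        metabolite_ids.setdefault(acc, f"m:{acc}")
        exchanges.append(Interaction(
            id=f"ix:ex:{k:04d}", interaction_type="exchange",
            products=[(metabolite_ids[acc], 1.0)], reversible=False))

    net = Network()
    for s in genes + transcripts + proteins + complexes:
        net.add_species(s)
    for acc, mid in sorted(metabolite_ids.items()):
        net.add_species(MolecularSpecies(
            id=mid, species_type="metabolite",
            xrefs=frozenset({("kegg.compound", acc)})))
    for i in split_reversible_reactions(dogma + reactions + assemblies
                                        + exchanges):
        net.add_interaction(i)

    violations = validate_network(net)
    if violations:  # pragma: no cover - assembly guarantees validity
        raise InvalidRecordError(
            f"assembled network invalid: {violations[:3]}")
    return net


# ---------------------------------------------------------------------------
# fixture file I/O (FASTA sequences + TSV tables)
# ---------------------------------------------------------------------------

def read_fasta_records(path, record_type) -> list:
    """Read source records from FASTA with ``>db|accession`` headers."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        db, _, acc = rec.id.partition("|")
        if not acc:
            db, acc = "unknown", rec.id
        records.append(SourceRecord(
            source_db=db, accession=acc, record_type=record_type,
            primary_sequence=str(rec.seq)))
    return records


def write_fasta_records(records, path):
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.source_db}|{r.accession}\n{r.primary_sequence}\n")


def _parse_participants(cell: str):
    # "C0001:1,C0002:2" -> [("C0001", 1.0), ("C0002", 2.0)]
    out = []
    for part in str(cell).split(","):
        acc, _, coeff = part.strip().partition(":")
        out.append((acc, float(coeff) if coeff else 1.0))
    return out


def read_reaction_table(path) -> list:
    """TSV columns: accession, substrates, products, ec_numbers, reversible."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(ReactionRecord(
            accession=row.accession,
            substrates=_parse_participants(row.substrates),
            products=_parse_participants(row.products),
            ec_numbers=[e for e in str(row.ec_numbers).split(";") if e],
            reversible=str(row.reversible) in ("1", "True", "true")))
    return out


def read_ppi_table(path) -> list:
    """TSV columns: accession, members (semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [PpiRecord(row.accession, tuple(str(row.members).split(";")))
            for row in df.itertuples(index=False)]


def read_link_table(path):
    """TSV columns: link_type, from_accession, to_accession."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gt = [(r.from_accession, r.to_accession)
          for r in df.itertuples(index=False) if r.link_type == "gene_transcript"]
    tp = [(r.from_accession, r.to_accession)
          for r in df.itertuples(index=False)
          if r.link_type == "transcript_protein"]
    return gt, tp


def read_ec_table(path):
    """TSV columns: protein_accession, ec_number."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [(r.protein_accession, r.ec_number)
            for r in df.itertuples(index=False)]
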