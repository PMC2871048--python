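"""Synthetic networks, database-export fixtures and knockout studies.

The generator emulates the structure of a yeast-scale multi-omic
reconstruction without any download: layered central-dogma chains (one
transcription per gene, one translation per transcript), occasional
identical coding sequences (two genes sharing a merged transcript),
redundant cross-database protein records, proteins with alternative
production routes, hub-skewed protein-interaction membership, an
enzyme-catalyzed reaction network with exchange (medium) metabolites,
and 1-3-gene knockout experiments whose viable/inviable labels derive
from a planted set of essential objects.

The phenotype mechanism — a strain is inviable exactly when its Boolean
damage intersects the planted essential set, optionally flipped by label
noise — is the inverse of the problem the scoring and classification
stages solve, which makes ground-truth recovery a fair end-to-end check.
Sequences are random strings over the appropriate alphabet; no
biological realism is claimed for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boolean_damage import compile_boolean_model, simulate_knockout
from .essentiality import INVIABLE, VIABLE, KnockoutExperiment
from .network_model import Interaction, MolecularSpecies, Network
from .reconstruction import (PpiRecord, ReactionRecord, SourceRecord,
                             split_reversible_reactions, write_fasta_records)

_DNA = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class NetworkConfig:
    """Structural parameters of a generated network.

    Counts that default to ``None`` are scaled from ``n_genes`` using the
    approximate proportions of the yeast network (metabolites ~0.12 and
    reaction records ~0.35 per gene, two PPI records per protein).
    """

    n_genes: int = 250
    p_duplicate_cds: float = 0.01
    p_orphan_protein: float = 0.025
    p_redundant_protein_route: float = 0.01
    n_complex_records: int = None
    p_complex_pair: float = 0.6      # P(assembly has exactly 2 members)
    complex_tail_p: float = 0.3      # geometric tail above 2, capped at 99
    n_metabolites: int = None
    n_reactions: int = None
    fraction_reversible: float = 0.3
    fraction_catalyzed: float = 0.88
    enzyme_fraction: float = 0.1
    p_shared_ec: float = 0.1         # enzyme reuses an existing EC (isozymes)
    n_exchange: int = None
    hub_skew: float = 1.3            # pareto shape for PPI member weights
    seed: int = 0

    def __post_init__(self):
        for name in ("p_duplicate_cds", "p_orphan_protein",
                     "p_redundant_protein_route", "fraction_reversible",
                     "fraction_catalyzed", "enzyme_fraction", "p_shared_ec",
                     "p_complex_pair"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_complex_records is None:
            self.n_complex_records = 2 * self.n_genes
        if self.n_metabolites is None:
            self.n_metabolites = max(12, round(0.12 * self.n_genes))
        if self.n_reactions is None:
            self.n_reactions = round(0.35 * self.n_genes)
        if self.n_exchange is None:
            self.n_exchange = max(2, self.n_metabolites // 8)
        if self.n_exchange > self.n_metabolites:
            raise ValueError("n_exchange exceeds n_metabolites")
        if self.n_complex_records > 0 and self.n_genes < 2:
            raise ValueError("complexes requested but fewer than 2 proteins")


@dataclass
class NetworkTruth:
    """Bookkeeping the generator guarantees about its network."""

    counts: dict
    transcript_of_gene: dict
    protein_of_transcript: dict
    duplicate_cds_groups: list
    redundant_route_proteins: list
    orphan_proteins: list
    enzymes: dict                     # protein id -> EC
    exchange_metabolites: list
    reaction_records: list = field(default_factory=list, repr=False)
    complex_members: dict = field(default_factory=dict, repr=False)
    metabolite_accession: dict = field(default_factory=dict, repr=False)


@dataclass
class StudyConfig:
    """Design of a knockout study with planted essential objects."""

    n_essential_objects: int = 25
    n_single: int = None             # None = one knockout per gene
    n_double: int = 4500
    n_triple: int = 250
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be in [0, 1]")


@dataclass
class StudyTruth:
    """Planted ground truth of a generated study."""

    planted: frozenset
    flipped_strains: frozenset


def _random_distinct_sequences(rng, n, length, alphabet):
    seen, out = set(), []
    while len(out) < n:
        seq = "".join(rng.choice(alphabet, size=length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def generate_network(config: NetworkConfig):
    """Generate a layered network plus its ground-truth bookkeeping.

    Reproducible from ``config.seed``; the returned network passes
    validation by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # --- genes and coding-sequence classes ------------------------------
    gene_ids = [f"g:{i + 1:04d}" for i in range(n)]
    gene_seqs = _random_distinct_sequences(rng, n, 60, _DNA)
    cds_class = []            # per gene, index of its transcript class
    class_reps = []           # per class, first gene index
    for i in range(n):
        if class_reps and rng.random() < config.p_duplicate_cds:
            cds_class.append(int(rng.integers(0, len(class_reps))))
        else:
            cds_class.append(len(class_reps))
            class_reps.append(i)
    n_tr = len(class_reps)
    tr_ids = [f"tr:{k + 1:04d}" for k in range(n_tr)]
    tr_seqs = _random_distinct_sequences(rng, n_tr, 48, _DNA)

    # --- proteins: one class per transcript, occasionally shared --------
    protein_class = []        # per transcript class, protein index
    protein_reps = []
    for k in range(n_tr):
        if protein_reps and rng.random() < config.p_redundant_protein_route:
            protein_class.append(int(rng.integers(0, len(protein_reps))))
        else:
            protein_class.append(len(protein_reps))
            protein_reps.append(k)
    n_core_p = len(protein_reps)
    n_orphan = round(config.p_orphan_protein * n_core_p)
    n_p = n_core_p + n_orphan
    p_ids = [f"p:{j + 1:04d}" for j in range(n_p)]
    p_seqs = _random_distinct_sequences(rng, n_p, 40, _AA)
    orphans = p_ids[n_core_p:]

    net = Network()
    for i in range(n):
        net.add_species(MolecularSpecies(
            gene_ids[i], "gene", primary_sequence=gene_seqs[i],
            xrefs=frozenset({("ensembl", f"ENSG{i + 1:04d}")})))
    for k in range(n_tr):
        net.add_species(MolecularSpecies(
            tr_ids[k], "transcript", primary_sequence=tr_seqs[k]))
    for j in range(n_p):
        net.add_species(MolecularSpecies(
            p_ids[j], "protein", primary_sequence=p_seqs[j]))

    transcript_of_gene, n_txn = {}, 0
    for i in range(n):
        n_txn += 1
        transcript_of_gene[gene_ids[i]] = tr_ids[cds_class[i]]
        net.add_interaction(Interaction(
            f"ix:txn:{n_txn:04d}", "transcription",
            products=[(tr_ids[cds_class[i]], 1.0)],
            controllers=[gene_ids[i]]))
    protein_of_transcript = {}
    for k in range(n_tr):
        protein_of_transcript[tr_ids[k]] = p_ids[protein_class[k]]
        net.add_interaction(Interaction(
            f"ix:tln:{k + 1:04d}", "translation",
            products=[(p_ids[protein_class[k]], 1.0)],
            controllers=[tr_ids[k]]))

    duplicate_groups = {}
    for i in range(n):
        duplicate_groups.setdefault(cds_class[i], []).append(gene_ids[i])
    duplicate_cds_groups = [tuple(v) for v in duplicate_groups.values()
                            if len(v) > 1]
    route_counts = {}
    for k in range(n_tr):
        pid = p_ids[protein_class[k]]
        route_counts[pid] = route_counts.get(pid, 0) + 1
    redundant_route_proteins = sorted(
        p for p, c in route_counts.items() if c > 1)

    # --- protein complexes (hub-skewed membership) -----------------------
    weights = rng.pareto(config.hub_skew, n_p) + 1.0
    weights /= weights.sum()
    seen_members, n_cx = {}, 0
    complex_members = {}
    max_size = min(99, n_p)
    for _ in range(config.n_complex_records):
        if rng.random() < config.p_complex_pair:
            size = 2
        else:
            size = min(2 + int(rng.geometric(config.complex_tail_p)),
                       max_size)
        members = tuple(sorted(
            str(p) for p in
            rng.choice(p_ids, size=size, replace=False, p=weights)))
        if members in seen_members:
            continue
        n_cx += 1
        cx_id = f"cx:{n_cx:04d}"
        seen_members[members] = cx_id
        complex_members[cx_id] = members
        net.add_species(MolecularSpecies(cx_id, "protein_complex"))
        net.add_interaction(Interaction(
            f"ix:asm:{n_cx:04d}", "complex_assembly",
            substrates=[(m, 1.0) for m in members],
            products=[(cx_id, 1.0)]))

    # --- metabolism ------------------------------------------------------
    met_acc = {f"m:{k + 1:04d}": f"C{k + 1:04d}"
               for k in range(config.n_metabolites)}
    met_ids = list(met_acc)
    for mid, acc in met_acc.items():
        net.add_species(MolecularSpecies(
            mid, "metabolite", xrefs=frozenset({("kegg.compound", acc)})))

    produced = p_ids[:n_core_p]
    n_enzymes = min(round(config.enzyme_fraction * n_p), len(produced))
    enzyme_ids = sorted(
        str(p) for p in rng.choice(produced, size=n_enzymes, replace=False))
    ec_list, enzymes = [], {}
    for pid in enzyme_ids:
        if ec_list and rng.random() < config.p_shared_ec:
            ec = ec_list[int(rng.integers(0, len(ec_list)))]
        else:
            ec = (f"{rng.integers(1, 7)}.{rng.integers(1, 20)}"
                  f".{rng.integers(1, 20)}.{rng.integers(1, 200)}")
            ec_list.append(ec)
        enzymes[pid] = ec
    ec_to_enzymes = {}
    for pid, ec in enzymes.items():
        ec_to_enzymes.setdefault(ec, []).append(pid)

    reaction_records, reaction_interactions = [], []
    n_rx = 0
    for r in range(config.n_reactions):
        n_sub = int(rng.integers(1, 4))
        n_prod = int(rng.integers(1, 4))
        mets = rng.choice(met_ids, size=n_sub + n_prod, replace=False)
        subs = [(met_acc[m], 1.0) for m in mets[:n_sub]]
        prods = [(met_acc[m], 1.0) for m in mets[n_sub:]]
        reversible = bool(rng.random() < config.fraction_reversible)
        if enzymes and rng.random() < config.fraction_catalyzed:
            ec = ec_list[int(rng.integers(0, len(ec_list)))]
            ecs = [ec]
            controllers = ec_to_enzymes[ec]
        else:
            ecs, controllers = [], [None]
        reaction_records.append(ReactionRecord(
            accession=f"R{r + 1:04d}", substrates=subs, products=prods,
            ec_numbers=ecs, reversible=reversible))
        acc_to_id = {v: k for k, v in met_acc.items()}
        for ctrl in controllers:
            n_rx += 1
            reaction_interactions.append(Interaction(
                f"ix:rxn:{n_rx:04d}", "metabolic_reaction",
                substrates=[(acc_to_id[a], c) for a, c in subs],
                products=[(acc_to_id[a], c) for a, c in prods],
                controllers=[] if ctrl is None else [ctrl],
                reversible=reversible))
    for i in split_reversible_reactions(reaction_interactions):
        net.add_interaction(i)

    exchange_mets = sorted(
        str(m) for m in
        rng.choice(met_ids, size=config.n_exchange, replace=False))
    for k, mid in enumerate(exchange_mets, start=1):
        net.add_interaction(Interaction(
            f"ix:ex:{k:04d}", "exchange", products=[(mid, 1.0)]))

    counts = {}
    for s in net.species.values():
        counts[s.species_type] = counts.get(s.species_type, 0) + 1
    for i in net.interactions.values():
        counts[i.interaction_type] = counts.get(i.interaction_type, 0) + 1
    truth = NetworkTruth(
        counts=counts,
        transcript_of_gene=transcript_of_gene,
        protein_of_transcript=protein_of_transcript,
        duplicate_cds_groups=duplicate_cds_groups,
        redundant_route_proteins=redundant_route_proteins,
        orphan_proteins=orphans,
        enzymes=enzymes,
        exchange_metabolites=[met_acc[m] for m in exchange_mets],
        reaction_records=reaction_records,
        complex_members=complex_members,
        metabolite_accession=met_acc)
    return net, truth


# ---------------------------------------------------------------------------
# source-record fixtures
# ---------------------------------------------------------------------------

@dataclass
class SourceFixtures:
    """In-memory database-export fixtures for the reconstruction stage."""

    gene_records: list
    transcript_records: list
    protein_records: list
    gene_transcript_links: list
    transcript_protein_links: list
    protein_ec_links: list
    reaction_records: list
    ppi_records: list
    exchange_metabolites: list

    def write(self, outdir):
        """Write FASTA + TSV fixture files consumable by the CLI."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta_records(self.gene_records, outdir / "genes.fasta")
        write_fasta_records(self.transcript_records,
                            outdir / "transcripts.fasta")
        write_fasta_records(self.protein_records, outdir / "proteins.fasta")
        with open(outdir / "links.tsv", "w") as fh:
            fh.write("link_type\tfrom_accession\tto_accession\n")
            for g, t in self.gene_transcript_links:
                fh.write(f"gene_transcript\t{g}\t{t}\n")
            for t, p in self.transcript_protein_links:
                fh.write(f"transcript_protein\t{t}\t{p}\n")
        with open(outdir / "ec.tsv", "w") as fh:
            fh.write("protein_accession\tec_number\n")
            for acc, ec in self.protein_ec_links:
                fh.write(f"{acc}\t{ec}\n")
        with open(outdir / "reactions.tsv", "w") as fh:
            fh.write("accession\tsubstrates\tproducts\tec_numbers\treversible\n")
            for r in self.reaction_records:
                subs = ",".join(f"{a}:{c:g}" for a, c in r.substrates)
                prods = ",".join(f"{a}:{c:g}" for a, c in r.products)
                fh.write(f"{r.accession}\t{subs}\t{prods}\t"
                         f"{';'.join(r.ec_numbers)}\t{int(r.reversible)}\n")
        with open(outdir / "ppi.tsv", "w") as fh:
            fh.write("accession\tmembers\n")
            for r in self.ppi_records:
                fh.write(f"{r.accession}\t{';'.join(r.member_proteins)}\n")
        with open(outdir / "exchanges.tsv", "w") as fh:
            fh.write("metabolite_accession\n")
            for acc in self.exchange_metabolites:
                fh.write(f"{acc}\n")

    def assemble_kwargs(self):
        from dataclasses import asdict  # noqa: F401 - keep signature simple
        return dict(
            gene_records=self.gene_records,
            transcript_records=self.transcript_records,
            protein_records=self.protein_records,
            gene_transcript_links=self.gene_transcript_links,
            transcript_protein_links=self.transcript_protein_links,
            reaction_records=self.reaction_records,
            protein_ec_links=self.protein_ec_links,
            ppi_records=self.ppi_records,
            exchange_metabolites=self.exchange_metabolites)


def generate_source_records(config: NetworkConfig):
    """Derive database-export-like records reproducing the generated net.

    Returns ``(fixtures, network, truth)`` where assembling ``fixtures``
    through the reconstruction stage yields a network isomorphic (up to id
    renaming) to the directly generated ``network``.  Roughly half the
    proteins additionally appear in pseudo-RefSeq/UniProt records with
    identical sequences, exercising cross-database merging.
    """
    net, truth = generate_network(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    genes = sorted(net.species_of_type("gene"), key=lambda s: s.id)
    gene_records, tr_records, gt_links, tp_links = [], [], [], []
    protein_records = []
    p_accessions: dict[str, list] = {}

    for i, g in enumerate(genes):
        acc = f"ENSG{i + 1:04d}"
        gene_records.append(SourceRecord(
            "ensembl", acc, "gene", g.primary_sequence))
        tr = net.species[truth.transcript_of_gene[g.id]]
        tr_acc = f"ENST{i + 1:04d}"
        tr_records.append(SourceRecord(
            "ensembl", tr_acc, "transcript", tr.primary_sequence))
        gt_links.append((acc, tr_acc))
        prot = net.species[truth.protein_of_transcript[tr.id]]
        p_acc = f"ENSP{i + 1:04d}"
        protein_records.append(SourceRecord(
            "ensembl", p_acc, "protein", prot.primary_sequence))
        p_accessions.setdefault(prot.id, []).append(p_acc)
        tp_links.append((tr_acc, p_acc))

    # redundant cross-database protein records with identical sequences
    for j, pid in enumerate(sorted(p_accessions)):
        seq = net.species[pid].primary_sequence
        if rng.random() < 0.5:
            acc = f"NP_{j + 1:06d}"
            protein_records.append(SourceRecord("refseq", acc, "protein", seq))
            p_accessions[pid].append(acc)
        if rng.random() < 0.5:
            acc = f"Q{j + 1:05d}"
            protein_records.append(SourceRecord("uniprot", acc, "protein", seq))
            p_accessions[pid].append(acc)
    for j, pid in enumerate(truth.orphan_proteins):
        acc = f"NP_O{j + 1:05d}"
        protein_records.append(SourceRecord(
            "refseq", acc, "protein", net.species[pid].primary_sequence))
        p_accessions.setdefault(pid, []).append(acc)

    ec_links = [(p_accessions[pid][0], ec)
                for pid, ec in sorted(truth.enzymes.items())]

    ppi_records = []
    for k, (cx_id, members) in enumerate(sorted(truth.complex_members.items())):
        accs = [p_accessions[m][int(rng.integers(0, len(p_accessions[m])))]
                for m in members]
        ppi_records.append(PpiRecord(f"EBI-{k + 1:06d}", tuple(accs)))

    fixtures = SourceFixtures(
        gene_records=gene_records, transcript_records=tr_records,
        protein_records=protein_records,
        gene_transcript_links=gt_links, transcript_protein_links=tp_links,
        protein_ec_links=ec_links, reaction_records=truth.reaction_records,
        ppi_records=ppi_records,
        exchange_metabolites=list(truth.exchange_metabolites))
    return fixtures, net, truth


# ---------------------------------------------------------------------------
# isomorphism signatures
# ---------------------------------------------------------------------------

def network_signature(network: Network):
    """Canonical content signature, invariant under id renaming.

    Sequence-bearing species are identified by (type, sequence),
    metabolites by their sorted xref accessions, complexes by the sorted
    signatures of the proteins their assembly consumes.  Interactions are
    identified by type plus the signatures of their participants.  Two
    networks are isomorphic up to id renaming iff their signatures match.
    """
    sig: dict[str, tuple] = {}
    for s in network.species.values():
        if s.species_type in ("gene", "transcript", "protein"):
            sig[s.id] = (s.species_type, s.primary_sequence)
        elif s.species_type == "metabolite":
            sig[s.id] = ("metabolite",
                         tuple(sorted(acc for _db, acc in s.xrefs)))
    for i in network.interactions.values():
        if i.interaction_type == "complex_assembly":
            cx = i.products[0][0]
            sig[cx] = ("protein_complex",
                       tuple(sorted(sig[m] for m, _ in i.substrates)))
    isig = []
    for i in network.interactions.values():
        isig.append((
            i.interaction_type,
            tuple(sorted((sig[m], c) for m, c in i.substrates)),
            tuple(sorted((sig[m], c) for m, c in i.products)),
            tuple(sorted(sig[m] for m in i.controllers))))
    return (tuple(sorted(sig.values())), tuple(sorted(isig)))


# ---------------------------------------------------------------------------
# knockout studies with planted ground truth
# ---------------------------------------------------------------------------

def _planted_candidates(network: Network, model):
    """Objects a knockout can ever block: everything except non-gene roots."""
    out = [s for s in network.species
           if s not in model.roots or s in model.gene_ids]
    out += list(network.interactions)
    return sorted(out)


def generate_phenotypes(network: Network, config: StudyConfig, model=None):
    """Generate knockout experiments with planted-truth phenotypes.

    Plants ``config.n_essential_objects`` essential objects (uniformly
    over all blockable objects, hence across object types), draws single,
    double and triple knockouts, labels each strain inviable exactly when
    its Boolean damage intersects the planted set, then flips each label
    independently with probability ``config.label_noise``.

    Returns ``(experiments, truth)``; reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = compile_boolean_model(network)
    genes = sorted(model.gene_ids)

    candidates = _planted_candidates(network, model)
    planted = frozenset(str(o) for o in rng.choice(
        candidates, size=min(config.n_essential_objects, len(candidates)),
        replace=False))

    knockouts = []
    if config.n_single is None:
        knockouts.extend((g,) for g in genes)
    else:
        knockouts.extend(
            (str(g),) for g in rng.choice(genes, size=config.n_single,
                                          replace=False))
    for size, count in ((2, config.n_double), (3, config.n_triple)):
        for _ in range(count):
            knockouts.append(tuple(
                str(g) for g in rng.choice(genes, size=size, replace=False)))

    experiments, flipped = [], []
    for k, ko in enumerate(knockouts, start=1):
        damage = simulate_knockout(model, ko)
        inviable = bool(damage.infeasible & planted)
        sid = f"strain:{k:05d}"
        if config.label_noise > 0 and rng.random() < config.label_noise:
            inviable = not inviable
            flipped.append(sid)
        experiments.append(KnockoutExperiment(
            sid, ko, INVIABLE if inviable else VIABLE))
    return experiments, StudyTruth(planted=planted,
                                   flipped_strains=frozenset(flipped))


def generate_study(network_config: NetworkConfig, study_config: StudyConfig):
    """End-to-end convenience: network, experiments and feasibility matrix.

    Returns ``(network, network_truth, experiments, study_truth, matrix)``.
    """
    from .boolean_damage import batch_damage

    net, net_truth = generate_network(network_config)
    model = compile_boolean_model(net)
    experiments, study_truth = generate_phenotypes(
        net, study_config, model=model)
    matrix = batch_damage(model, experiments)
    return net, net_truth, experiments, study_truth, matrix
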