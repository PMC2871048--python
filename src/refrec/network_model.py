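"""Domain types for the multi-omic molecular interaction network.

The network covers five layers of molecular species — genes, transcripts,
proteins, protein complexes and metabolites — connected by typed
interactions (transcriptions, translations, metabolic reactions, complex
assemblies, transports and exchanges).  Species may *control* an
interaction without being consumed by it (a gene controls its
transcription, a transcript its translation, an enzyme the reaction it
catalyzes); control edges are kept separate from the physical
substrate/product stoichiometry.

The module also provides structural validation and SBML import/export.
Cross-references to source databases are emitted as MIRIAM-style
annotation URIs so that every species remains traceable to its origin.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import libsbml

SPECIES_TYPES = frozenset(
    {"gene", "transcript", "protein", "protein_complex", "metabolite"}
)
INTERACTION_TYPES = frozenset(
    {
        "transcription",
        "translation",
        "metabolic_reaction",
        "complex_assembly",
        "transport",
        "exchange",
    }
)

#: species types that may carry a primary sequence
_SEQUENCE_TYPES = frozenset({"gene", "transcript", "protein"})

_ANNOT_NS = "http://refrec-toolkit.org/ns/1"
_ANNOT_PREFIX = "refrec"

SBML_LEVEL = 3
SBML_VERSION = 1


class SbmlImportWarning(UserWarning):
    """Raised once per SBML species whose layer type could not be inferred."""


class InvalidNetworkError(ValueError):
    """Writing was refused because the network violates its invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(f"{v.object_id}: {v.rule}" for v in self.violations[:5])
        if len(self.violations) > 5:
            msg += f" (+{len(self.violations) - 5} more)"
        super().__init__(f"invalid network: {msg}")


class SbmlParseError(ValueError):
    """The SBML source could not be parsed."""


@dataclass
class MolecularSpecies:
    """A molecular species on one of the five network layers.

    Parameters
    ----------
    id
        Stable identifier, unique within a network.  Internal identifiers
        are namespaced ("g:", "tr:", "p:", "cx:", "m:") to keep the species
        and interaction id spaces disjoint.
    species_type
        One of ``gene``, ``transcript``, ``protein``, ``protein_complex``,
        ``metabolite``.
    primary_sequence
        Nucleotide or amino-acid sequence; only meaningful for genes,
        transcripts and proteins.
    compartment
        Optional compartment label (used for metabolites of
        compartmentalized models).
    xrefs
        Set of ``(database_name, accession)`` pairs pointing back to the
        source records this species was built from.
    """

    id: str
    species_type: str
    primary_sequence: Optional[str] = None
    compartment: Optional[str] = None
    xrefs: frozenset = field(default_factory=frozenset)
    display_name: Optional[str] = None

    def __post_init__(self):
        self.xrefs = frozenset(tuple(x) for x in self.xrefs)


@dataclass
class Interaction:
    """A typed interaction between molecular species.

    ``substrates`` and ``products`` are lists of ``(species_id,
    stoichiometric_coefficient)`` with positive coefficients;
    ``controllers`` lists species that are required for the interaction to
    occur without being consumed.  ``reversible`` is only meaningful before
    reconstruction finalization: a finished network contains irreversible
    interactions only (reversible reactions having been split into two
    opposite directions).
    """

    id: str
    interaction_type: str
    substrates: list = field(default_factory=list)
    products: list = field(default_factory=list)
    controllers: list = field(default_factory=list)
    reversible: bool = False

    def __post_init__(self):
        self.substrates = [(s, float(c)) for s, c in self.substrates]
        self.products = [(s, float(c)) for s, c in self.products]
        self.controllers = list(self.controllers)

    def participant_ids(self):
        ids = [s for s, _ in self.substrates]
        ids += [s for s, _ in self.products]
        ids += list(self.controllers)
        return ids


@dataclass
class Violation:
    object_id: str
    rule: str
    message: str = ""

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.object_id}: {self.rule} {self.message}".rstrip()


class Network:
    """Container for species and interactions with referential lookups."""

    def __init__(self, species: Iterable[MolecularSpecies] = (),
                 interactions: Iterable[Interaction] = ()):
        self.species: dict[str, MolecularSpecies] = {}
        self.interactions: dict[str, Interaction] = {}
        for s in species:
            self.add_species(s)
        for i in interactions:
            self.add_interaction(i)

    # -- construction -----------------------------------------------------
    def add_species(self, s: MolecularSpecies):
        if s.id in self.species or s.id in self.interactions:
            raise ValueError(f"duplicate object id {s.id!r}")
        self.species[s.id] = s
        return s

    def add_interaction(self, i: Interaction):
        if i.id in self.interactions or i.id in self.species:
            raise ValueError(f"duplicate object id {i.id!r}")
        self.interactions[i.id] = i
        return i

    # -- queries ----------------------------------------------------------
    @property
    def n_objects(self) -> int:
        """Total object count: |species| + |interactions|."""
        return len(self.species) + len(self.interactions)

    def species_of_type(self, species_type: str):
        return [s for s in self.species.values() if s.species_type == species_type]

    def interactions_of_type(self, interaction_type: str):
        return [i for i in self.interactions.values()
                if i.interaction_type == interaction_type]

    def object_type(self, object_id: str) -> str:
        if object_id in self.species:
            return self.species[object_id].species_type
        if object_id in self.interactions:
            return self.interactions[object_id].interaction_type
        raise KeyError(object_id)

    def __eq__(self, other):
        if not isinstance(other, Network):
            return NotImplemented
        return (self.species == other.species
                and self.interactions == other.interactions)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"<Network {len(self.species)} species, "
                f"{len(self.interactions)} interactions>")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(network: Network) -> list:
    """Check all structural invariants; return a list of :class:`Violation`.

    An empty report means the network is well formed.  Violations are data,
    not exceptions: callers decide whether to refuse downstream work.
    """
    out: list[Violation] = []
    sp = network.species
    ix = network.interactions

    overlap = set(sp) & set(ix)
    for oid in sorted(overlap):
        out.append(Violation(oid, "id-spaces-disjoint",
                             "id used for both a species and an interaction"))

    for s in sp.values():
        if s.species_type not in SPECIES_TYPES:
            out.append(Violation(s.id, "species-type",
                                 f"unknown type {s.species_type!r}"))
        if s.primary_sequence is not None and s.species_type not in _SEQUENCE_TYPES:
            out.append(Violation(s.id, "sequence-forbidden",
                                 f"{s.species_type} must not carry a sequence"))

    for i in ix.values():
        if i.interaction_type not in INTERACTION_TYPES:
            out.append(Violation(i.id, "interaction-type",
                                 f"unknown type {i.interaction_type!r}"))
            continue
        for sid in i.participant_ids():
            if sid not in sp:
                out.append(Violation(i.id, "referential-integrity",
                                     f"references unknown species {sid!r}"))
        for sid, coeff in i.substrates + i.products:
            if coeff <= 0:
                out.append(Violation(i.id, "positive-stoichiometry",
                                     f"coefficient {coeff} for {sid!r}"))

        def _types(ids):
            return [sp[s].species_type for s in ids if s in sp]

        if i.interaction_type == "transcription":
            if _types(i.controllers) != ["gene"]:
                out.append(Violation(i.id, "transcription-controller",
                                     "requires exactly one gene controller"))
            if _types([s for s, _ in i.products]) != ["transcript"]:
                out.append(Violation(i.id, "transcription-product",
                                     "requires exactly one transcript product"))
        elif i.interaction_type == "translation":
            if _types(i.controllers) != ["transcript"]:
                out.append(Violation(i.id, "translation-controller",
                                     "requires exactly one transcript controller"))
            if _types([s for s, _ in i.products]) != ["protein"]:
                out.append(Violation(i.id, "translation-product",
                                     "requires exactly one protein product"))
        elif i.interaction_type == "complex_assembly":
            sub_types = _types([s for s, _ in i.substrates])
            if len(sub_types) < 2 or any(t != "protein" for t in sub_types):
                out.append(Violation(i.id, "assembly-substrates",
                                     "requires >=2 protein substrates"))
            if _types([s for s, _ in i.products]) != ["protein_complex"]:
                out.append(Violation(i.id, "assembly-product",
                                     "requires exactly one complex product"))
    return out


# ---------------------------------------------------------------------------
# SBML export / import
# ---------------------------------------------------------------------------

_SID_RE = re.compile(r"[^A-Za-z0-9_]")


def _sid(object_id: str) -> str:
    """Sanitize an internal id into a valid SBML SId.

    The verbatim id is preserved in the annotation, so this mapping does
    not need to be invertible — only collision-free enough in practice
    (distinct internal ids differing only in punctuation do not occur with
    the namespaced id policy).
    """
    sid = _SID_RE.sub("_", object_id)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    return sid


def _annotation_node(attrs: dict) -> libsbml.XMLNode:
    triple = libsbml.XMLTriple("info", _ANNOT_NS, _ANNOT_PREFIX)
    xattrs = libsbml.XMLAttributes()
    for k, v in attrs.items():
        if v is not None:
            xattrs.add(k, str(v))
    ns = libsbml.XMLNamespaces()
    ns.add(_ANNOT_NS, _ANNOT_PREFIX)
    return libsbml.XMLNode(triple, xattrs, ns)


def _read_annotation(sbase) -> dict:
    annot = sbase.getAnnotation()
    if annot is None:
        return {}
    for k in range(annot.getNumChildren()):
        child = annot.getChild(k)
        if child.getURI() == _ANNOT_NS and child.getName() == "info":
            attrs = child.getAttributes()
            return {attrs.getName(j): attrs.getValue(j)
                    for j in range(attrs.getLength())}
    return {}


def _set_xrefs(sbase, xrefs):
    if not xrefs:
        return
    sbase.setMetaId("meta_" + sbase.getId())
    term = libsbml.CVTerm()
    term.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
    term.setBiologicalQualifierType(libsbml.BQB_IS)
    for db, acc in sorted(xrefs):
        if db == "uri":  # opaque foreign resource retained verbatim
            term.addResource(acc)
        else:
            term.addResource(f"http://identifiers.org/{db}/{acc}")
    sbase.addCVTerm(term)


_IDENTIFIERS_RE = re.compile(
    r"^https?://identifiers\.org/([^/]+)/(.+)$")


def _get_xrefs(sbase) -> frozenset:
    xrefs = set()
    for k in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(k)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            m = _IDENTIFIERS_RE.match(uri)
            if m:
                xrefs.add((m.group(1), m.group(2)))
            else:
                xrefs.add(("uri", uri))
    return frozenset(xrefs)


def write_sbml(network: Network, destination=None) -> str:
    """Serialize a network to SBML Level 3 Version 1.

    One SBML species is written per molecular species and one SBML
    reaction per interaction; controllers are encoded as modifier species
    references so that the substrate/product stoichiometry stays physical.
    Layer types, sequences and verbatim internal ids go into a controlled
    annotation namespace; database cross-references are written as MIRIAM
    URIs.  Round-trip through :func:`read_sbml` is lossless.

    Parameters
    ----------
    destination
        Path to write to; if ``None`` the document is only returned as a
        string.

    Raises
    ------
    InvalidNetworkError
        If :func:`validate_network` reports violations.
    """
    violations = validate_network(network)
    if violations:
        raise InvalidNetworkError(violations)

    doc = libsbml.SBMLDocument(SBML_LEVEL, SBML_VERSION)
    model = doc.createModel()
    model.setId("refrec_network")

    compartments = {s.compartment or "default" for s in network.species.values()}
    for comp in sorted(compartments):
        c = model.createCompartment()
        c.setId(_sid(comp))
        c.setName(comp)
        c.setConstant(True)

    for s in network.species.values():
        sp = model.createSpecies()
        sp.setId(_sid(s.id))
        if s.display_name:
            sp.setName(s.display_name)
        sp.setCompartment(_sid(s.compartment or "default"))
        sp.setHasOnlySubstanceUnits(True)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.appendAnnotation(_annotation_node({
            "id": s.id,
            "speciesType": s.species_type,
            "sequence": s.primary_sequence,
            "compartmentLabel": s.compartment,
        }))
        _set_xrefs(sp, s.xrefs)

    for i in network.interactions.values():
        rx = model.createReaction()
        rx.setId(_sid(i.id))
        rx.setReversible(bool(i.reversible))
        rx.setFast(False)
        for sid, coeff in i.substrates:
            ref = rx.createReactant()
            ref.setSpecies(_sid(sid))
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for sid, coeff in i.products:
            ref = rx.createProduct()
            ref.setSpecies(_sid(sid))
            ref.setStoichiometry(coeff)
            ref.setConstant(True)
        for sid in i.controllers:
            ref = rx.createModifier()
            ref.setSpecies(_sid(sid))
        rx.appendAnnotation(_annotation_node({
            "id": i.id,
            "interactionType": i.interaction_type,
        }))
        _set_xrefs(rx, frozenset())

    text = libsbml.writeSBMLToString(doc)
    if destination is not None:
        with open(destination, "w") as fh:
            fh.write(text)
    return text


def read_sbml(source) -> Network:
    """Parse an SBML document into a :class:`Network`.

    Inverse of :func:`write_sbml` on documents this package wrote.  For
    foreign documents, SBML species/reactions/modifiers map onto the
    corresponding types; MIRIAM resources become xrefs (non-identifiers.org
    URIs are retained as opaque ``("uri", ...)`` pairs).  Species without a
    recognized layer annotation are imported as metabolites, each emitting
    one :class:`SbmlImportWarning`.

    Parameters
    ----------
    source
        Path to an SBML file, or an SBML document as a string.
    """
    text = source
    if "<" not in str(source):
        with open(source) as fh:
            text = fh.read()
    doc = libsbml.readSBMLFromString(text)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise SbmlParseError(
            f"line {err.getLine()}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise SbmlParseError("document contains no model")

    compartment_labels = {}
    for k in range(model.getNumCompartments()):
        c = model.getCompartment(k)
        compartment_labels[c.getId()] = c.getName() or c.getId()

    net = Network()
    for k in range(model.getNumSpecies()):
        sp = model.getSpecies(k)
        attrs = _read_annotation(sp)
        stype = attrs.get("speciesType")
        if stype not in SPECIES_TYPES:
            warnings.warn(
                f"species {sp.getId()!r} has no layer annotation; "
                "importing as metabolite", SbmlImportWarning, stacklevel=2)
            stype = "metabolite"
        comp = attrs.get("compartmentLabel")
        if comp is None and "id" not in attrs:
            comp = compartment_labels.get(sp.getCompartment())
            if comp == "default":
                comp = None
        net.add_species(MolecularSpecies(
            id=attrs.get("id", sp.getId()),
            species_type=stype,
            primary_sequence=attrs.get("sequence"),
            compartment=comp,
            xrefs=_get_xrefs(sp),
            display_name=sp.getName() or None,
        ))

    sid_to_id = {}
    for k in range(model.getNumSpecies()):
        sp = model.getSpecies(k)
        attrs = _read_annotation(sp)
        sid_to_id[sp.getId()] = attrs.get("id", sp.getId())

    for k in range(model.getNumReactions()):
        rx = model.getReaction(k)
        attrs = _read_annotation(rx)
        itype = attrs.get("interactionType")
        if itype not in INTERACTION_TYPES:
            itype = "metabolic_reaction"
        net.add_interaction(Interaction(
            id=attrs.get("id", rx.getId()),
            interaction_type=itype,
            substrates=[(sid_to_id[rx.getReactant(j).getSpecies()],
                         rx.getReactant(j).getStoichiometry())
                        for j in range(rx.getNumReactants())],
            products=[(sid_to_id[rx.getProduct(j).getSpecies()],
                       rx.getProduct(j).getStoichiometry())
                      for j in range(rx.getNumProducts())],
            controllers=[sid_to_id[rx.getModifier(j).getSpecies()]
                         for j in range(rx.getNumModifiers())],
            reversible=rx.getReversible(),
        ))
    return net
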