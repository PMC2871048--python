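"""Boolean knockout-damage propagation.

Every network object carries a Boolean *feasibility*: a species exists in
its functional form, an interaction may occur.  An interaction is feasible
only if every molecular species it needs (substrates and controllers) is
feasible — a conjunction; a species is feasible if at least one of the
interactions producing it is feasible — a disjunction.  Species with no
producers (genes, medium-like metabolites, orphan proteins) are roots and
stay feasible unless explicitly knocked out.

A knockout clamps the given genes infeasible with every other object
feasible, then propagates blockage to the unique greatest fixed point:
only damage spreads, nothing recovers, and no self-sustaining loop is
spuriously blocked.  The result is independent of evaluation order; the
implementation uses a worklist rather than full sweeps, but the contract
fixes only the fixed point, not the schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .essentiality import FeasibilityMatrix
from .network_model import Network


class UnknownGeneError(KeyError):
    """A knockout referenced a gene id absent from the model."""


@dataclass
class BooleanModel:
    """Compiled feasibility rules for a network.

    ``requirements[i]`` is the set of species an interaction needs
    (substrates plus controllers); ``producers[s]`` the interactions
    producing species ``s``; ``roots`` the species with no producers.
    """

    requirements: dict
    producers: dict
    roots: frozenset
    gene_ids: frozenset
    object_ids: tuple
    consumers: dict = field(repr=False, default=None)
    products: dict = field(repr=False, default=None)
    uncatalyzed: tuple = ()

    def __post_init__(self):
        if self.consumers is None:
            consumers: dict[str, list] = {}
            for iid, req in self.requirements.items():
                for sid in req:
                    consumers.setdefault(sid, []).append(iid)
            self.consumers = consumers


@dataclass(frozen=True)
class DamageResult:
    """The set of objects rendered infeasible by a knockout."""

    knockout: frozenset
    infeasible: frozenset

    @property
    def size(self) -> int:
        return len(self.infeasible)


def compile_boolean_model(network: Network,
                          exclude_requirements=frozenset()) -> BooleanModel:
    """Translate a network into Boolean feasibility rules.

    Parameters
    ----------
    exclude_requirements
        Species ids (typically ubiquitous currency metabolites such as
        water or ATP) to drop from every interaction's requirement set.
        Empty by default: no metabolite is treated specially unless the
        caller opts in, and any use is visible in the compiled model.
    """
    exclude = frozenset(exclude_requirements)
    requirements, producers, products = {}, {}, {}
    uncatalyzed = []
    for i in network.interactions.values():
        req = {s for s, _ in i.substrates} | set(i.controllers)
        requirements[i.id] = frozenset(req - exclude)
        products[i.id] = tuple(s for s, _ in i.products)
        for s, _ in i.products:
            producers.setdefault(s, []).append(i.id)
        if i.interaction_type == "metabolic_reaction" and not i.controllers:
            # empty controller conjunct is vacuously true; flagged, not silent
            uncatalyzed.append(i.id)
    producers = {s: tuple(v) for s, v in producers.items()}
    roots = frozenset(s for s in network.species if s not in producers)
    genes = frozenset(s.id for s in network.species_of_type("gene"))
    return BooleanModel(
        requirements=requirements, producers=producers, roots=roots,
        gene_ids=genes,
        object_ids=tuple(network.species) + tuple(network.interactions),
        products=products, uncatalyzed=tuple(uncatalyzed))


def simulate_knockout(model: BooleanModel, knocked_genes) -> DamageResult:
    """Propagate a knockout to its Boolean fixed point.

    The knocked genes are clamped infeasible and every other object starts
    feasible; blockage then propagates until fixed: an interaction becomes
    infeasible as soon as any required species is infeasible, a non-root
    species once all its producers are infeasible.  Roots other than the
    knocked genes stay feasible.
    """
    knocked = frozenset(knocked_genes)
    unknown = knocked - model.gene_ids
    if unknown:
        raise UnknownGeneError(
            f"unknown gene id(s): {sorted(unknown)[:3]}")

    infeasible = set(knocked)
    # count of still-feasible producers per species, touched lazily
    live_producers: dict[str, int] = {}
    stack = list(knocked)
    while stack:
        obj = stack.pop()
        if obj in model.requirements:  # an interaction went down
            for s in model.products[obj]:
                if s in infeasible or s in model.roots:
                    continue
                n = live_producers.get(s)
                if n is None:
                    n = len(model.producers[s])
                n -= 1
                live_producers[s] = n
                if n == 0:
                    infeasible.add(s)
                    stack.append(s)
        else:  # a species went down: every interaction needing it follows
            for iid in model.consumers.get(obj, ()):
                if iid not in infeasible:
                    infeasible.add(iid)
                    stack.append(iid)
    return DamageResult(knockout=knocked, infeasible=frozenset(infeasible))


def batch_damage(model: BooleanModel, experiments) -> FeasibilityMatrix:
    """Simulate a list of knockout experiments into a feasibility matrix.

    One row per experiment, one column per network object; an entry is
    ``True`` when the object stayed feasible.  Identical experiments yield
    identical rows (the simulation is deterministic).
    """
    col_index = {oid: j for j, oid in enumerate(model.object_ids)}
    values = np.ones((len(experiments), len(model.object_ids)), dtype=bool)
    row_ids = []
    for i, exp in enumerate(experiments):
        row_ids.append(exp.strain_id)
        damage = simulate_knockout(model, exp.genes)
        for oid in damage.infeasible:
            values[i, col_index[oid]] = False
    return FeasibilityMatrix(
        row_ids=row_ids, column_ids=list(model.object_ids), values=values)


def damage_statistics(matrix: FeasibilityMatrix, network: Network,
                      rows=None) -> pd.DataFrame:
    """Per-object-type damage statistics over a set of knockouts.

    For each object type: ``damage_probability`` is the fraction of
    knockouts blocking at least one object of that type;
    ``mean_blocked``/``sd_blocked`` are computed over the knockouts that
    do block the type (conditional on the damage reaching it), NaN when
    no knockout does.  ``rows`` optionally restricts to a subset of rows
    (e.g. the single-gene knockouts).
    """
    if matrix.n_experiments == 0:
        raise ValueError("empty feasibility matrix")
    values = matrix.values if rows is None else matrix.values[rows]
    if values.shape[0] == 0:
        raise ValueError("no rows selected")
    blocked = ~values

    type_of = {}
    for var, members in matrix.groups.items():
        # statistics are defined over original objects, not merged variables
        if len(members) != 1 or members[0] not in (
                network.species.keys() | network.interactions.keys()):
            raise ValueError(
                "damage_statistics requires an unmerged object-level matrix")
        type_of[var] = network.object_type(var)

    types = sorted(set(type_of.values()))
    records = []
    for t in types:
        cols = [j for j, var in enumerate(matrix.column_ids)
                if type_of[var] == t]
        counts = blocked[:, cols].sum(axis=1)
        hit = counts > 0
        prob = hit.mean()
        if hit.any():
            mean = counts[hit].mean()
            sd = counts[hit].std(ddof=0)
        else:
            mean = sd = np.nan
        records.append((t, prob, mean, sd))
    return pd.DataFrame(
        records,
        columns=["object_type", "damage_probability", "mean_blocked",
                 "sd_blocked"]).set_index("object_type")


def fixpoint_by_sweeps(model: BooleanModel, knocked_genes, rng=None):
    """Reference fixed-point computation by repeated full rule sweeps.

    Applies both rule families in (optionally shuffled) order until no
    value changes.  Exists as an independent oracle for the worklist
    implementation; quadratic, use on small networks only.
    """
    knocked = frozenset(knocked_genes)
    infeasible = set(knocked)
    order = list(model.object_ids)
    while True:
        if rng is not None:
            rng.shuffle(order)
        changed = False
        for obj in order:
            if obj in infeasible:
                continue
            if obj in model.requirements:
                if model.requirements[obj] & infeasible:
                    infeasible.add(obj)
                    changed = True
            elif obj not in model.roots:
                if all(p in infeasible for p in model.producers[obj]):
                    infeasible.add(obj)
                    changed = True
        if not changed:
            return frozenset(infeasible)
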