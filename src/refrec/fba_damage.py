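"""Constraint-based metabolic damage estimation.

For a compartmentalized stoichiometric model (iND750-style), the damage
of a gene knockout is estimated in three steps: gene-protein-reaction
(GPR) rules are evaluated to find reactions whose catalyst is lost;
a flux-balance computation finds every reaction that can no longer carry
steady-state flux; and a metabolite is declared blocked when all reactions
producing it are blocked and it cannot be taken up from the medium.

Damage computed under a maximally permissive medium — every exchange
reaction open in both directions, oxygen included — is *unconditional*:
any reaction blocked with all exchanges open is also blocked under every
restricted medium, so the blocked set is a lower bound valid across all
cultivation conditions.  Reactions already blocked with no knockout at
all (pathway dead-ends) form a constitutive baseline that is reported
separately and subtracted from knockout damage.

Sign convention: exchange reactions are written with the metabolite as
the sole substrate, so positive flux is secretion and negative flux is
uptake; "open for uptake" means the lower bound is negative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.optimize
import scipy.sparse

#: magnitude used for open flux bounds
BOUND = 1000.0
#: a reaction is blocked when |max flux| and |min flux| are both below this
FLUX_TOL = 1e-9


class GprParseError(ValueError):
    """The GPR expression could not be parsed."""


class GprRule:
    """Boolean gene-protein-reaction rule with AND/OR connectives.

    Isozymes appear as OR (any gene suffices), complex subunits as AND
    (every gene required).  Evaluation sets knocked genes to False and all
    others to True.

    >>> GprRule.parse("(g1 and g2) or g3").evaluate({"g1"})
    True
    """

    def __init__(self, ast, text=None):
        self._ast = ast
        self.text = text

    # -- parsing ----------------------------------------------------------
    _TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

    @classmethod
    def parse(cls, text: str) -> "GprRule":
        tokens = cls._TOKEN_RE.findall(text)
        if not tokens:
            raise GprParseError("empty GPR expression")
        pos = 0

        def peek():
            return tokens[pos] if pos < len(tokens) else None

        def take():
            nonlocal pos
            tok = peek()
            pos += 1
            return tok

        def parse_or():
            terms = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                take()
                terms.append(parse_and())
            return terms[0] if len(terms) == 1 else ("or", terms)

        def parse_and():
            terms = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                take()
                terms.append(parse_atom())
            return terms[0] if len(terms) == 1 else ("and", terms)

        def parse_atom():
            tok = take()
            if tok is None:
                raise GprParseError(f"unexpected end of expression: {text!r}")
            if tok == "(":
                inner = parse_or()
                if take() != ")":
                    raise GprParseError(f"unbalanced parentheses: {text!r}")
                return inner
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GprParseError(f"unexpected token {tok!r} in {text!r}")
            return tok

        ast = parse_or()
        if pos != len(tokens):
            raise GprParseError(
                f"trailing tokens {tokens[pos:]} in {text!r}")
        return cls(ast, text=text)

    # -- queries ----------------------------------------------------------
    @property
    def genes(self) -> frozenset:
        out = set()

        def walk(node):
            if isinstance(node, tuple):
                for child in node[1]:
                    walk(child)
            else:
                out.add(node)

        walk(self._ast)
        return frozenset(out)

    def evaluate(self, knocked_genes) -> bool:
        knocked = set(knocked_genes)

        def walk(node):
            if isinstance(node, tuple):
                op, children = node
                vals = (walk(c) for c in children)
                return all(vals) if op == "and" else any(vals)
            return node not in knocked

        return walk(self._ast)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"GprRule({self.text!r})"


def evaluate_gpr(rule, knocked_genes) -> bool:
    """Availability of a reaction's catalyst under a knockout."""
    if isinstance(rule, str):
        rule = GprRule.parse(rule)
    return rule.evaluate(knocked_genes)


@dataclass
class MetabolicReaction:
    """One column of the stoichiometric matrix.

    ``stoichiometry`` maps metabolite id -> coefficient (substrates
    negative, products positive).  Reversible source reactions are
    expected to be pre-split, so irreversible reactions have lower bound
    zero; exchanges keep a negative lower bound when open for uptake.
    """

    id: str
    stoichiometry: dict
    lower: float = 0.0
    upper: float = BOUND
    exchange: bool = False
    gpr: Optional[GprRule] = None

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = GprRule.parse(self.gpr)


@dataclass
class StoichiometricModel:
    """Metabolites, reactions with bounds and GPRs, and the medium."""

    metabolites: list
    reactions: list
    medium: frozenset = frozenset()
    compartments: dict = field(default_factory=dict)

    def __post_init__(self):
        self.medium = frozenset(self.medium)
        met_set = set(self.metabolites)
        for r in self.reactions:
            if not r.stoichiometry:
                raise ValueError(f"{r.id}: reaction touches no metabolite")
            unknown = set(r.stoichiometry) - met_set
            if unknown:
                raise ValueError(f"{r.id}: unknown metabolites {unknown}")
            if r.exchange and len(r.stoichiometry) != 1:
                raise ValueError(
                    f"{r.id}: exchange must touch exactly one metabolite")

    @property
    def reaction_ids(self):
        return [r.id for r in self.reactions]

    def reaction(self, rid) -> MetabolicReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self):
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[met_index[m], j] = c
        return S

    def exchanges_for(self, metabolite):
        return [r for r in self.reactions
                if r.exchange and metabolite in r.stoichiometry]


@dataclass
class MetabolicDamage:
    """Result of the GPR + flux-balance damage estimation.

    ``blocked_reactions`` includes the constitutive ``baseline_blocked``
    set; ``damage_reactions``/``damage_metabolites`` are net of baseline,
    i.e. the *additional* blockage attributable to the knockout.
    """

    knockout: frozenset
    disabled_reactions: frozenset
    blocked_reactions: frozenset
    blocked_metabolites: frozenset
    baseline_blocked: frozenset = frozenset()
    baseline_blocked_metabolites: frozenset = frozenset()

    @property
    def damage_reactions(self) -> frozenset:
        return self.blocked_reactions - self.baseline_blocked

    @property
    def damage_metabolites(self) -> frozenset:
        return self.blocked_metabolites - self.baseline_blocked_metabolites


def _bounds(model, disabled, open_all_exchanges):
    lo, hi = [], []
    for r in model.reactions:
        if r.id in disabled:
            lo.append(0.0)
            hi.append(0.0)
        elif open_all_exchanges and r.exchange:
            lo.append(-BOUND)
            hi.append(BOUND)
        else:
            lo.append(r.lower)
            hi.append(r.upper)
    return np.array(lo), np.array(hi)


def find_blocked_reactions(model: StoichiometricModel,
                           disabled=frozenset(),
                           open_all_exchanges=False,
                           tol=FLUX_TOL) -> frozenset:
    """Reactions unable to carry any steady-state flux.

    For each reaction the attainable flux is probed by a pair of linear
    programs (maximize then minimize the reaction's flux subject to
    ``S v = 0`` and the bounds, with ``disabled`` reactions clamped to
    zero); the reaction is blocked when both optima are within ``tol`` of
    zero.  The zero flux vector always satisfies the constraints, so the
    base problem is feasible by construction.  The returned set contains
    the disabled reactions.
    """
    S = model.stoichiometric_matrix()
    lo, hi = _bounds(model, disabled, open_all_exchanges)
    n = len(model.reactions)
    blocked = set(disabled)
    for j, r in enumerate(model.reactions):
        if r.id in blocked:
            continue
        c = np.zeros(n)
        c[j] = -1.0  # maximize v_j
        res = scipy.optimize.linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lo, hi)), method="highs")
        if not res.success:  # pragma: no cover - zero flux is admissible
            raise RuntimeError(f"LP failed for {r.id}: {res.message}")
        if -res.fun > tol:
            continue
        if lo[j] >= -tol:  # cannot go negative anyway
            blocked.add(r.id)
            continue
        c[j] = 1.0  # minimize v_j
        res = scipy.optimize.linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lo, hi)), method="highs")
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"LP failed for {r.id}: {res.message}")
        if abs(res.fun) <= tol:
            blocked.add(r.id)
    return frozenset(blocked)


def blocked_metabolites(model: StoichiometricModel, blocked_reactions,
                        medium=None) -> frozenset:
    """Metabolites with every producing reaction blocked and no uptake.

    A reaction produces a metabolite when its stoichiometric coefficient
    is positive.  A metabolite with an exchange reaction open for uptake
    in the ``medium`` (default: the model's medium) is never blocked.
    """
    blocked_reactions = frozenset(blocked_reactions)
    unknown = blocked_reactions - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown reactions {sorted(unknown)[:3]}")
    medium = model.medium if medium is None else frozenset(medium)
    out = set()
    for i, m in enumerate(model.metabolites):
        if any(r.id in medium for r in model.exchanges_for(m)):
            continue
        producers = [r for r in model.reactions
                     if r.stoichiometry.get(m, 0) > 0]
        if producers and all(r.id in blocked_reactions for r in producers):
            out.add(m)
    return frozenset(out)


def unconditional_damage(model: StoichiometricModel, knocked_genes,
                         baseline=None) -> MetabolicDamage:
    """Knockout damage under the maximally permissive medium.

    Opens every exchange reaction in both directions (the cell may take up
    and secrete every metabolite with an exchange, subsuming aerobic
    conditions), disables reactions whose GPR evaluates false under the
    knockout, finds the blocked reactions and derives blocked metabolites
    with every exchange counted as open for uptake.

    ``baseline`` may carry a precomputed no-knockout
    ``(blocked_reactions, blocked_metabolites)`` pair to avoid
    recomputation across a batch of knockouts.
    """
    if not any(r.exchange for r in model.reactions):
        raise ValueError("model has no exchange reactions")
    knocked = frozenset(knocked_genes)
    all_exchange_ids = frozenset(
        r.id for r in model.reactions if r.exchange)

    if baseline is None:
        base_blocked = find_blocked_reactions(
            model, frozenset(), open_all_exchanges=True)
        base_mets = blocked_metabolites(model, base_blocked,
                                        medium=all_exchange_ids)
    else:
        base_blocked, base_mets = baseline

    disabled = frozenset(
        r.id for r in model.reactions
        if r.gpr is not None and not r.gpr.evaluate(knocked))
    if disabled:
        blocked = find_blocked_reactions(
            model, disabled, open_all_exchanges=True)
        mets = blocked_metabolites(model, blocked, medium=all_exchange_ids)
    else:
        blocked, mets = base_blocked, base_mets
    return MetabolicDamage(
        knockout=knocked, disabled_reactions=disabled,
        blocked_reactions=frozenset(blocked),
        blocked_metabolites=frozenset(mets),
        baseline_blocked=frozenset(base_blocked),
        baseline_blocked_metabolites=frozenset(base_mets))


# ---------------------------------------------------------------------------
# interoperability
# ---------------------------------------------------------------------------

def from_cobra(cobra_model) -> StoichiometricModel:
    """Convert a cobra model (e.g. read from SBML-fbc) to the local form.

    Reversible cobra reactions are split into forward/reverse irreversible
    copies to satisfy the pre-split invariant.
    """
    metabolites = [m.id for m in cobra_model.metabolites]
    compartments = dict(cobra_model.compartments)
    reactions = []
    for rx in cobra_model.reactions:
        stoich = {m.id: c for m, c in rx.metabolites.items()}
        gpr = str(rx.gene_reaction_rule) or None
        exchange = rx in cobra_model.exchanges or (
            rx.boundary and len(stoich) == 1)
        lo, hi = rx.lower_bound, rx.upper_bound
        if lo < 0 and not exchange:
            reactions.append(MetabolicReaction(
                id=rx.id + ":fwd", stoichiometry=stoich,
                lower=0.0, upper=max(hi, 0.0), exchange=False, gpr=gpr))
            reactions.append(MetabolicReaction(
                id=rx.id + ":rev",
                stoichiometry={m: -c for m, c in stoich.items()},
                lower=0.0, upper=-lo, exchange=False, gpr=gpr))
        else:
            reactions.append(MetabolicReaction(
                id=rx.id, stoichiometry=stoich, lower=lo, upper=hi,
                exchange=exchange, gpr=gpr))
    medium = frozenset(r.id for r in reactions
                       if r.exchange and r.lower < 0)
    return StoichiometricModel(metabolites=metabolites, reactions=reactions,
                               medium=medium, compartments=compartments)


def read_stoichiometric_sbml(path) -> StoichiometricModel:
    """Read a stoichiometric model from SBML (flux bounds and GPRs via
    the fbc package), delegating parsing to cobrapy."""
    import cobra.io

    return from_cobra(cobra.io.read_sbml_model(str(path)))


def read_stoichiometric_tsv(reactions_path) -> StoichiometricModel:
    """Read a model from a single TSV: columns ``id``, ``stoichiometry``
    (``met:coeff`` comma-separated, negatives = substrates), ``lower``,
    ``upper``, ``exchange`` (0/1), ``gpr`` (may be empty)."""
    import pandas as pd

    df = pd.read_csv(reactions_path, sep="\t", dtype=str).fillna("")
    reactions, mets = [], []
    for row in df.itertuples(index=False):
        stoich = {}
        for part in row.stoichiometry.split(","):
            m, _, c = part.strip().partition(":")
            stoich[m] = float(c)
            if m not in mets:
                mets.append(m)
        reactions.append(MetabolicReaction(
            id=row.id, stoichiometry=stoich,
            lower=float(row.lower or 0.0), upper=float(row.upper or BOUND),
            exchange=row.exchange in ("1", "True", "true"),
            gpr=row.gpr or None))
    medium = frozenset(r.id for r in reactions if r.exchange and r.lower < 0)
    return StoichiometricModel(metabolites=mets, reactions=reactions,
                               medium=medium)
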