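import numpy as np
import pytest

from refrec.fba_damage import (GprParseError, GprRule, MetabolicReaction,
                               StoichiometricModel, blocked_metabolites,
                               evaluate_gpr, find_blocked_reactions,
                               unconditional_damage)


def random_gpr(rng, genes, depth=0):
    """Random well-formed GPR string plus an eval-able Python mirror."""
    if depth >= 3 or rng.random() < 0.4:
        g = genes[rng.integers(0, len(genes))]
        return g, g
    op = "and" if rng.random() < 0.5 else "or"
    left, pl = random_gpr(rng, genes, depth + 1)
    right, pr = random_gpr(rng, genes, depth + 1)
    return f"({left} {op} {right})", f"({pl} {op} {pr})"


def random_toy_model(rng, n_mets=8, n_rxns=12):
    mets = [f"M{k}" for k in range(n_mets)]
    reactions = []
    n_ex = 3
    for k in range(n_ex):
        reactions.append(MetabolicReaction(
            f"EX_{mets[k]}", {mets[k]: -1.0}, lower=-1000, upper=1000,
            exchange=True))
    for k in range(n_rxns - n_ex):
        ns, np_ = rng.integers(1, 3), rng.integers(1, 3)
        chosen = rng.choice(mets, size=ns + np_, replace=False)
        stoich = {m: -float(rng.integers(1, 3)) for m in chosen[:ns]}
        stoich.update({m: float(rng.integers(1, 3)) for m in chosen[ns:]})
        reactions.append(MetabolicReaction(f"r{k}", stoich))
    return StoichiometricModel(
        metabolites=mets, reactions=reactions,
        medium={r.id for r in reactions if r.exchange})


def cobra_blocked(model, disabled=frozenset(), open_all=False):
    """Independent oracle: cobrapy's FVA-based blocked-reaction finder."""
    import cobra

    m = cobra.Model("toy")
    mets = {mid: cobra.Metabolite(mid) for mid in model.metabolites}
    rxns = []
    for r in model.reactions:
        rx = cobra.Reaction(r.id)
        if r.id in disabled:
            rx.lower_bound, rx.upper_bound = 0.0, 0.0
        elif open_all and r.exchange:
            rx.lower_bound, rx.upper_bound = -1000.0, 1000.0
        else:
            rx.lower_bound, rx.upper_bound = r.lower, r.upper
        rxns.append(rx)
    m.add_reactions(rxns)
    for r, rx in zip(model.reactions, rxns):
        rx.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
    blocked = set(cobra.flux_analysis.find_blocked_reactions(
        m, open_exchanges=False))
    return blocked | set(disabled)


class TestGprEvaluation:
    @pytest.mark.parametrize("rule,knocked,expected", [
        ("g1 or g2", {"g1"}, True),
        ("g1 and g2", {"g1"}, False),
        ("(g1 and g2) or g3", {"g1", "g3"}, False),
        ("g1", set(), True),
    ])
    def test_examples(self, rule, knocked, expected):
        assert evaluate_gpr(rule, knocked) is expected

    def test_random_rules_agree_with_python_eval_oracle(self):
        rng = np.random.default_rng(42)
        genes = [f"g{k}" for k in range(5)]
        for _ in range(100):
            rule_text, py_text = random_gpr(rng, genes)
            rule = GprRule.parse(rule_text)
            knocked = {g for g in genes if rng.random() < 0.4}
            env = {g: g not in knocked for g in genes}
            assert rule.evaluate(knocked) == eval(py_text, {}, env)
            assert rule.genes <= set(genes)

    @pytest.mark.parametrize("bad", ["", "g1 and", "and g1", "(g1 or g2",
                                     "g1 g2", "g1 ) or g2"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(GprParseError):
            GprRule.parse(bad)


@pytest.fixture
def chain_model():
    # EX_A <-> A -> B <-> EX_B
    return StoichiometricModel(
        metabolites=["A", "B"],
        reactions=[
            MetabolicReaction("EX_A", {"A": -1}, lower=-1000, upper=1000,
                              exchange=True),
            MetabolicReaction("r1", {"A": -1, "B": 1}, gpr="g1"),
            MetabolicReaction("EX_B", {"B": -1}, lower=-1000, upper=1000,
                              exchange=True)],
        medium={"EX_A", "EX_B"})


class TestBlockedReactions:
    def test_open_chain_carries_flux(self, chain_model):
        assert find_blocked_reactions(chain_model) == frozenset()

    def test_cut_chain_blocks_everything(self, chain_model):
        blocked = find_blocked_reactions(chain_model, disabled={"r1"})
        assert blocked == {"EX_A", "r1", "EX_B"}

    @pytest.mark.parametrize("seed", range(8))
    def test_random_toys_agree_with_cobra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_toy_model(rng)
        internal = [r.id for r in model.reactions if not r.exchange]
        disabled = frozenset(
            str(r) for r in rng.choice(internal, size=2, replace=False))
        mine = find_blocked_reactions(model, disabled)
        oracle = cobra_blocked(model, disabled)
        assert mine == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_all_open_blocked_subset_of_restricted(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = random_toy_model(rng)
        open_blocked = find_blocked_reactions(model, open_all_exchanges=True)
        # restrict: close uptake on a random subset of exchanges
        for r in model.reactions:
            if r.exchange and rng.random() < 0.5:
                r.lower = 0.0
        restricted = find_blocked_reactions(model)
        assert open_blocked <= restricted


class TestBlockedMetabolites:
    def model(self, medium):
        return StoichiometricModel(
            metabolites=["A", "B"],
            reactions=[
                MetabolicReaction("EX_B", {"B": -1}, lower=-1000, upper=1000,
                                  exchange=True),
                MetabolicReaction("r1", {"A": -1, "B": 1})],
            medium=medium)

    def test_metabolite_with_only_blocked_producer(self):
        m = self.model(medium=set())
        assert blocked_metabolites(m, {"r1", "EX_B"}) == {"B"}

    def test_uptake_from_medium_rescues(self):
        m = self.model(medium={"EX_B"})
        assert blocked_metabolites(m, {"r1", "EX_B"}) == frozenset()

    def test_one_live_producer_suffices(self):
        m = StoichiometricModel(
            metabolites=["A", "B"],
            reactions=[MetabolicReaction(f"r{k}", {"A": -1, "B": 1})
                       for k in range(3)] +
                      [MetabolicReaction("src", {"A": 1})],
            medium=set())
        assert "B" not in blocked_metabolites(m, {"r0", "r1"})

    def test_unknown_blocked_reaction_rejected(self, chain_model):
        with pytest.raises(KeyError):
            blocked_metabolites(chain_model, {"nope"})


class TestUnconditionalDamage:
    def test_knockout_of_sole_producer_gene(self, chain_model):
        d = unconditional_damage(chain_model, {"g1"})
        assert d.disabled_reactions == {"r1"}
        assert d.damage_reactions == {"EX_A", "r1", "EX_B"}
        assert d.disabled_reactions <= d.blocked_reactions

    def test_constitutive_dead_end_reported_as_baseline(self):
        # r_dead consumes C which nothing produces and no exchange reaches
        model = StoichiometricModel(
            metabolites=["A", "B", "C", "D"],
            reactions=[
                MetabolicReaction("EX_A", {"A": -1}, lower=-1000, upper=1000,
                                  exchange=True),
                MetabolicReaction("EX_B", {"B": -1}, lower=-1000, upper=1000,
                                  exchange=True),
                MetabolicReaction("r1", {"A": -1, "B": 1}, gpr="g1"),
                MetabolicReaction("r_dead", {"C": -1, "D": 1}, gpr="g2")],
            medium={"EX_A"})
        d = unconditional_damage(model, set())
        assert d.baseline_blocked == {"r_dead"}
        assert d.damage_reactions == frozenset()
        d2 = unconditional_damage(model, {"g1"})
        assert d2.baseline_blocked <= d2.blocked_reactions
        assert "r1" in d2.damage_reactions

    def test_model_without_exchanges_rejected(self):
        model = StoichiometricModel(
            metabolites=["A", "B"],
            reactions=[MetabolicReaction("r1", {"A": -1, "B": 1})])
        with pytest.raises(ValueError, match="exchange"):
            unconditional_damage(model, set())
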