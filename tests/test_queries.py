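"""Query parsing, CTL satisfaction, and pool filtering."""

import random

import numpy as np
import pytest

from logicpool.network import BooleanFunction, Model, parse_pkn
from logicpool.pools import build_pool
from logicpool.queries import (
    AG,
    And,
    Atom,
    EF,
    Fix,
    Query,
    QueryError,
    check_model,
    filter_pool,
    format_query,
    intersect_pools,
    parse_queries,
    satisfying_states,
    steady_as_fixed_point,
)
from logicpool.fixtures import random_pkn

from oracles import oracle_check


class TestParsing:
    def test_steady_state_query(self):
        (q,) = parse_queries("WB.DMSO: EF(AG(mTORC1=1)) IS:Sora=0")
        assert q.name == "WB.DMSO"
        assert q.formula == EF(AG(Atom("mTORC1", 1)))
        assert q.init == {"Sora": 0}

    def test_nested_chain_and_aliases(self):
        text = (
            "Bp: EF(mTor=1&Akt=0&EF(mTor=0&Akt=1&EF(mTor=1&Akt=1)))IS:Sora=1"
        )
        (q,) = parse_queries(text, aliases={"mTor": "mTORC1"})
        # three nesting levels, atoms aliased
        levels = 0
        node = q.formula
        atoms = set()
        while isinstance(node, EF):
            levels += 1
            inner = node.child
            node = None
            stack = [inner]
            while stack:
                x = stack.pop()
                if isinstance(x, And):
                    stack.extend(x.children)
                elif isinstance(x, EF):
                    node = x
                elif isinstance(x, Atom):
                    atoms.add(x.component)
        assert levels == 3
        assert atoms == {"mTORC1", "Akt"}

    def test_delta_atom_is_fix(self):
        (q,) = parse_queries("S: EF(Delta=0&A=1) IS:B=0")
        assert isinstance(q.formula.child.children[0], Fix)

    @pytest.mark.parametrize(
        "text",
        [
            "X: EF(v=2)",
            "X: EF(v=1",
            "X: AF(v=1)",
            "X: EF(Delta=1)",
            "X: EF(v=1) IS:v=2",
        ],
    )
    def test_malformed_queries_rejected(self, text):
        with pytest.raises(QueryError):
            parse_queries(text)

    def test_continuation_lines_and_whitespace(self):
        text = "Long: EF( A=1 &\n  EF( B=0 ) )\n  IS: A=0 , B=0\n"
        (q,) = parse_queries(text)
        assert q.init == {"A": 0, "B": 0}

    def test_format_roundtrip(self):
        text = "Q: EF(A=1&EF(Delta=0&B=0)) IS:A=0"
        (q,) = parse_queries(text)
        (again,) = parse_queries(format_query(q))
        assert again == q


class TestSatisfyingStates:
    def test_ef_true_is_everything(self):
        pkn = parse_pkn("v -> v +\n")
        model = Model({"v": BooleanFunction.identity("v")})
        sat = satisfying_states(pkn, model, EF(Atom("v", 1)))
        assert sorted(sat) == [1]

    def test_ag_on_constant_activator(self):
        # f = 1: state 1 is fixed (self-loop) so AG(v=1) = {1}
        pkn = parse_pkn("u -> u +\nu -> v +?\n")
        model = Model(
            {"u": BooleanFunction.identity("u"), "v": BooleanFunction.constant(1)}
        )
        sat = satisfying_states(pkn, model, AG(Atom("v", 1)))
        assert all((s >> 1) & 1 for s in sat)
        assert len(sat) == 2  # v=1 states only: v can never fall back to 0

    def test_oscillator_never_settles(self):
        pkn = parse_pkn("v -> v -\n")
        model = Model({"v": BooleanFunction.from_expr("!v", ["v"])})
        assert len(satisfying_states(pkn, model, EF(AG(Atom("v", 1))))) == 0


class TestCheckModel:
    def test_unsatisfiable_formula_fails_everywhere(self, toy):
        pool = build_pool(toy.pkn)
        bad = Query("bad", And((Atom("A", 0), Atom("A", 1))))
        assert not any(check_model(toy.pkn, m, bad) for m in pool)

    def test_two_node_chain_reachability(self):
        pkn = parse_pkn("A -> A +\nA -> B +\n")
        model = build_pool(pkn).model(0)
        q = Query("r", EF(Atom("B", 1)), {"A": 1})
        assert check_model(pkn, model, q)
        q0 = Query("r0", EF(Atom("B", 1)), {"A": 0, "B": 0})
        assert not check_model(pkn, model, q0)

    def test_universal_is_stricter(self):
        pkn = parse_pkn("A -> A +\nA -> B +\n")
        model = build_pool(pkn).model(0)
        q = Query("r", EF(Atom("B", 1)), {})  # no IS clause: all states initial
        assert check_model(pkn, model, q)
        assert not check_model(pkn, model, q, universal=True)

    def test_agreement_with_path_enumeration_oracle(self):
        """Bit-parallel fixpoint checker == explicit-graph oracle, both
        quantifier modes, random models and random queries (n <= 3)."""
        rng = random.Random(42)
        checked = 0
        seed = 0
        while checked < 120:
            seed += 1
            pkn = random_pkn(seed, n_components=3, p_optional=0.6)
            pool = build_pool(pkn)
            for i in range(min(len(pool), 4)):
                model = pool.model(rng.randrange(len(pool)))
                formula = _random_formula(rng, pkn.components)
                init = {
                    c: rng.randint(0, 1)
                    for c in pkn.components
                    if rng.random() < 0.4
                }
                q = Query("rnd", formula, init)
                for universal in (False, True):
                    assert check_model(pkn, model, q, universal) == oracle_check(
                        pkn, model, q, universal
                    )
                checked += 1


def _random_formula(rng, components, depth=0):
    choice = rng.random()
    if depth >= 3 or choice < 0.35:
        if rng.random() < 0.1:
            return Fix()
        return Atom(rng.choice(components), rng.randint(0, 1))
    if choice < 0.6:
        return EF(_random_formula(rng, components, depth + 1))
    if choice < 0.8:
        return AG(_random_formula(rng, components, depth + 1))
    return And(
        (
            _random_formula(rng, components, depth + 1),
            _random_formula(rng, components, depth + 1),
        )
    )


class TestFilterPool:
    def test_empty_query_list_keeps_everything(self, toy):
        pool = build_pool(toy.pkn)
        ap = filter_pool(pool, [])
        assert len(ap.subpool([])) == len(pool)

    def test_toy_query_rejects_exactly_one_model(self, toy):
        pool = build_pool(toy.pkn)
        ap = filter_pool(pool, toy.queries)
        sub = ap.subpool()
        assert len(sub) == 2
        # the rejected model is the one whose C-rule is constant 0
        rejected = set(range(3)) - set(int(i) for i in sub.ids)
        (rid,) = rejected
        assert pool.model(rid)["C"] == BooleanFunction.constant(0)

    def test_filtering_is_antitone_and_intersective(self, toy):
        pool = build_pool(toy.pkn)
        extra = Query("extra", EF(Atom("D", 1)), {"A": 1})
        ap = filter_pool(pool, list(toy.queries) + [extra])
        both = ap.subpool()
        single = ap.subpool([toy.queries[0].name])
        other = ap.subpool(["extra"])
        assert set(both.ids) == set(single.ids) & set(other.ids)
        assert len(both) <= len(single)

    def test_intersection_requires_same_network(self, toy):
        pool = build_pool(toy.pkn)
        other_pkn = parse_pkn("A -> A +\nA -> B +\n")
        other = build_pool(other_pkn)
        a = filter_pool(pool, []).subpool([])
        b = filter_pool(other, []).subpool([])
        with pytest.raises(ValueError):
            intersect_pools(a, b)
        assert np.array_equal((a & a).ids, a.ids)

    def test_determinism(self, toy):
        pool = build_pool(toy.pkn)
        t1 = filter_pool(pool, toy.queries).table
        t2 = filter_pool(pool, toy.queries).table
        assert t1.equals(t2)


class TestSteadyRewrite:
    def test_ef_ag_becomes_fixed_point_form(self):
        (q,) = parse_queries("W: EF(AG(m=1)) IS:S=0")
        r = steady_as_fixed_point(q)
        assert r.formula == EF(And((Fix(), Atom("m", 1))))
        assert r.init == q.init

    def test_nested_temporal_ag_left_alone(self):
        (q,) = parse_queries("W: AG(EF(m=1))")
        assert steady_as_fixed_point(q) == q

    def test_fixed_point_form_is_stricter(self):
        # on the toy pool the fixed-point reading accepts a subset of models
        from logicpool.fixtures import toy_network

        toy = toy_network()
        pool = build_pool(toy.pkn)
        (q,) = parse_queries("W: EF(AG(C=1)) IS:A=1,C=0")
        strict = steady_as_fixed_point(q)
        for m in pool:
            if check_model(toy.pkn, m, strict):
                assert check_model(toy.pkn, m, q)
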