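"""SCC quotient, attractor detection and hierarchical transition graphs."""

import networkx as nx
import pytest

from mvlogic import (
    Interaction,
    Literal,
    LogicalModel,
    NodeSpec,
    Not,
    Perturbation,
    RuleEntry,
    State,
    UpdatingScheme,
    attractors,
    build_htg,
    build_stg,
    random_model,
    reduce_model,
    scc_quotient,
    states_to_patterns,
)

from conftest import codes


@pytest.fixture(scope="module")
def async_stg(p53):
    return build_stg(p53)


class TestSccQuotient:
    def test_fixture_has_two_nontrivial_components(self, async_stg):
        quotient = scc_quotient(async_stg)
        sizes = sorted(len(c) for c in quotient.nodes if len(c) > 1)
        assert sizes == [6, 9]

    def test_quotient_is_acyclic(self, async_stg):
        quotient = scc_quotient(async_stg)
        relabeled = nx.convert_node_labels_to_integers(quotient)
        assert nx.is_directed_acyclic_graph(relabeled)

    def test_quotient_preserves_reachability(self, async_stg):
        quotient = scc_quotient(async_stg)
        comp_of = {s: c for c in quotient.nodes for s in c}
        # spot-check: reachability between sampled states matches
        states = async_stg.states()[::7]
        for a in states:
            reach_states = nx.descendants(async_stg.graph, a) | {a}
            reach_comps = nx.descendants(quotient, comp_of[a]) | {comp_of[a]}
            assert {comp_of[s] for s in reach_states} == reach_comps

    def test_three_state_cycle_collapses(self):
        # Boolean repressilator-like ring has a cyclic attractor under
        # synchronous updating; its states form one component
        m = _ring_model()
        stg = build_stg(m, UpdatingScheme.synchronous())
        quotient = scc_quotient(stg)
        assert any(len(c) > 1 for c in quotient.nodes)

    def test_sync_nontrivial_sccs_are_attractors(self, p53):
        # deterministic dynamics: any nontrivial SCC is terminal
        stg = build_stg(p53, UpdatingScheme.synchronous())
        quotient = scc_quotient(stg)
        for c in quotient.nodes:
            if len(c) > 1:
                assert quotient.out_degree(c) == 0


class TestAttractors:
    def test_async_fixture_attractor_is_the_stable_state(self, async_stg):
        found = attractors(async_stg)
        assert [(k, codes(ms)) for k, ms in found] == [("stable", ["0110"])]

    def test_sync_fixture_has_three_attractors(self, p53):
        stg = build_stg(p53, UpdatingScheme.synchronous())
        found = attractors(stg)
        kinds = sorted((k, len(ms)) for k, ms in found)
        assert kinds == [("cyclic", 2), ("cyclic", 2), ("stable", 1)]

    def test_sync_attractor_basins_partition_the_state_space(self, p53):
        stg = build_stg(p53, UpdatingScheme.synchronous())
        sizes = {}
        for kind, members in attractors(stg):
            basin = stg.predecessors_of(members)
            sizes[codes(members)[0]] = len(basin)
        # the rest state is reachable from 26 other states, the cyclic
        # attractors from 3 and 2; basins 27 + 5 + 4 cover all 36 states
        assert sorted(sizes.values()) == [4, 5, 27]
        assert sum(sizes.values()) == 36

    def test_clamped_damage_yields_single_cyclic_attractor(self, p53):
        stg = build_stg(p53, perturbation=Perturbation.ectopic("DNAdam", 1))
        found = attractors(stg)
        assert len(found) == 1
        kind, members = found[0]
        assert kind == "cyclic" and len(members) > 1


class TestHtg:
    def test_fixture_htg_has_six_nodes(self, async_stg):
        htg = build_htg(async_stg)
        assert len(htg) == 6

    def test_cyclic_transient_components_match_printed_sizes(self, async_stg, p53):
        htg = build_htg(async_stg)
        transients = {n.label: n for n in htg.by_kind("cyclic_transient")}
        assert set(transients) == {"ct#9", "ct#6"}
        damage = p53.index("DNAdam")
        assert all(s[damage] == 1 for s in transients["ct#9"].members)
        assert all(s[damage] == 0 for s in transients["ct#6"].members)

    def test_stable_node_is_terminal(self, async_stg):
        htg = build_htg(async_stg)
        (rest,) = htg.by_kind("stable")
        assert rest.label == "0110"
        assert rest in htg.terminal_nodes()

    def test_members_partition_the_state_set(self, async_stg):
        htg = build_htg(async_stg)
        seen = [s for n in htg.nodes for s in n.members]
        assert len(seen) == len(async_stg)
        assert set(seen) == set(async_stg.states())

    def test_htg_is_acyclic(self, async_stg):
        htg = build_htg(async_stg)
        g = nx.DiGraph((a.label, b.label) for a, b in htg.edges)
        assert nx.is_directed_acyclic_graph(g)

    def test_terminal_htg_nodes_are_the_attractors(self, p53):
        for scheme in (UpdatingScheme.asynchronous(), UpdatingScheme.synchronous()):
            stg = build_stg(p53, scheme)
            htg = build_htg(stg)
            terminal = {frozenset(n.members) for n in htg.terminal_nodes()}
            assert terminal == {frozenset(ms) for _, ms in attractors(stg)}

    def test_linear_path_collapses_to_chain_plus_stable(self):
        # A chain 1 -> 0 on a single multi-valued node decaying to zero
        m = LogicalModel([NodeSpec("A", 4)])  # no rule: target always 0
        stg = build_stg(m)
        htg = build_htg(stg)
        assert sorted(n.kind for n in htg.nodes) == ["stable", "transient_chain"]
        chain = htg.by_kind("transient_chain")[0]
        assert len(chain.members) == 4

    def test_reduced_model_keeps_both_oscillatory_components(self, p53):
        reduced = reduce_model(p53, ["Mdm2cyt"])
        htg = build_htg(build_stg(reduced))
        assert len(htg.by_kind("cyclic_transient")) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_htg_invariants_on_random_models(self, seed):
        m = random_model(4, max_level_cap=2, density=0.5, seed=40 + seed)
        stg = build_stg(m)
        htg = build_htg(stg)
        seen = [s for n in htg.nodes for s in n.members]
        assert len(seen) == len(stg) and set(seen) == set(stg.states())
        g = nx.DiGraph((id(a), id(b)) for a, b in htg.edges)
        assert nx.is_directed_acyclic_graph(g)
        terminal = {frozenset(n.members) for n in htg.terminal_nodes()}
        assert terminal == {frozenset(ms) for _, ms in attractors(stg)}


class TestPatternRendering:
    def test_ct9_first_pattern_covers_two_states(self, async_stg, p53):
        htg = build_htg(async_stg)
        ct9 = {n.label: n for n in htg.nodes}["ct#9"]
        patterns = ct9.patterns(p53)
        # the pattern 01*1 stands for the two states 0101 and 0111
        assert "01*1" in patterns

    def test_patterns_cover_member_set_exactly(self, async_stg, p53):
        htg = build_htg(async_stg)
        for node in htg.nodes:
            covered = set()
            for pattern in node.patterns(p53):
                from mvlogic import InitialPattern

                covered |= set(InitialPattern.from_string(pattern).expand(p53))
            assert covered == set(node.members)

    def test_full_product_set_renders_as_all_stars(self, p53):
        patterns = states_to_patterns(p53, frozenset(p53.states()))
        assert patterns == ["****"]


def _ring_model() -> LogicalModel:
    nodes = [NodeSpec("A"), NodeSpec("B"), NodeSpec("C")]
    inter = [
        Interaction("A", "B", 1, "-"),
        Interaction("B", "C", 1, "-"),
        Interaction("C", "A", 1, "-"),
    ]
    rules = {
        "B": [RuleEntry(1, [Not(Literal("A"))])],
        "C": [RuleEntry(1, [Not(Literal("B"))])],
        "A": [RuleEntry(1, [Not(Literal("C"))])],
    }
    return LogicalModel(nodes, inter, rules)
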