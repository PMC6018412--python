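"""Updating schemes, perturbations and STG construction."""

import pytest

from mvlogic import (
    CapExceededError,
    InitialPattern,
    Interaction,
    Literal,
    LogicalModel,
    ModelError,
    NodeSpec,
    Perturbation,
    PriorityClass,
    RuleEntry,
    State,
    UpdatingScheme,
    apply_perturbation,
    attractors,
    build_stg,
    random_model,
    successors,
)

from conftest import code, codes

ASYNC = UpdatingScheme.asynchronous()
SYNC = UpdatingScheme.synchronous()
COMPLETE = UpdatingScheme.complete()
SEQUENTIAL = UpdatingScheme.sequential()


class TestSuccessors:
    def test_async_successors_of_0200(self, p53):
        assert codes(successors(p53, code("0200"), ASYNC)) == [
            "0100",
            "0210",
            "1200",
        ]

    def test_sync_successor_of_0010(self, p53):
        # Mdm2cyt and Mdm2nuc change simultaneously
        assert codes(successors(p53, code("0010"), SYNC)) == ["0100"]

    @pytest.mark.parametrize(
        "scheme", [ASYNC, SYNC, COMPLETE, SEQUENTIAL], ids=lambda s: s.mode
    )
    def test_stable_state_has_no_successor_under_any_scheme(self, p53, scheme):
        assert successors(p53, code("0110"), scheme) == []

    def test_complete_mode_yields_all_call_subsets(self, p53):
        # three calls at 0200 -> 2^3 - 1 successors
        succ = successors(p53, code("0200"), COMPLETE)
        assert len(succ) == 7
        assert set(successors(p53, code("0200"), ASYNC)) <= set(succ)
        assert set(successors(p53, code("0200"), SYNC)) <= set(succ)

    def test_async_steps_are_unitary(self, p53):
        for state in p53.states():
            for succ in successors(p53, state, ASYNC):
                diffs = [
                    abs(a - b) for a, b in zip(state.levels, succ.levels)
                ]
                assert sum(diffs) == 1 and max(diffs) == 1

    def test_sync_steps_every_called_node_by_one(self, p53):
        for state in p53.states():
            succ = successors(p53, state, SYNC)
            calls = p53.called_nodes(state)
            if not calls:
                assert succ == []
                continue
            (only,) = succ
            for g, d in calls:
                i = p53.index(g)
                assert only[i] - state[i] == d

    def test_sequential_sweep_uses_partially_updated_state(self):
        # A activates B; B activates C at its threshold.  Sweeping in
        # declared order from 100, A=1 raises B, and the refreshed B
        # immediately raises C within the same sweep.
        m = LogicalModel(
            [NodeSpec("A"), NodeSpec("B"), NodeSpec("C")],
            [
                Interaction("A", "A", 1, "+"),
                Interaction("A", "B", 1, "+"),
                Interaction("B", "C", 1, "+"),
            ],
            {
                "A": [RuleEntry(1, [Literal("A")])],
                "B": [RuleEntry(1, [Literal("A")])],
                "C": [RuleEntry(1, [Literal("B")])],
            },
        )
        assert codes(successors(m, code("100"), SEQUENTIAL)) == ["111"]
        # asynchronous dynamics needs two separate transitions
        assert codes(successors(m, code("100"), ASYNC)) == ["110"]


class TestPriorityScheme:
    def test_single_async_class_reproduces_async_stg(self, p53):
        scheme = UpdatingScheme.priority([PriorityClass(p53.node_ids)])
        assert (
            build_stg(p53, scheme).transitions()
            == build_stg(p53, ASYNC).transitions()
        )

    def test_single_sync_class_reproduces_sync_stg(self, p53):
        scheme = UpdatingScheme.priority(
            [PriorityClass(p53.node_ids, mode="synchronous")]
        )
        assert (
            build_stg(p53, scheme).transitions()
            == build_stg(p53, SYNC).transitions()
        )

    def test_higher_priority_class_masks_lower(self, p53):
        # p53 alone at rank 0: wherever p53 is called, only p53 moves
        scheme = UpdatingScheme.priority(
            [
                PriorityClass(["p53"], rank=0),
                PriorityClass(["Mdm2cyt", "Mdm2nuc", "DNAdam"], rank=1),
            ]
        )
        state = code("0200")  # calls: p53, Mdm2cyt, Mdm2nuc
        assert codes(successors(p53, state, scheme)) == ["1200"]

    def test_equal_ranks_combine_asynchronously(self, p53):
        scheme = UpdatingScheme.priority(
            [
                PriorityClass(["p53"], rank=0),
                PriorityClass(["Mdm2cyt"], rank=0),
                PriorityClass(["Mdm2nuc", "DNAdam"], rank=0),
            ]
        )
        assert codes(successors(p53, code("0200"), scheme)) == [
            "0100",
            "0210",
            "1200",
        ]

    def test_classes_must_partition_nodes(self, p53):
        scheme = UpdatingScheme.priority([PriorityClass(["p53"])])
        with pytest.raises(ModelError, match="do not cover"):
            successors(p53, code("0200"), scheme)


class TestPerturbations:
    def test_damage_clamp_destabilizes_rest_state(self, p53):
        clamped = apply_perturbation(p53, Perturbation.ectopic("DNAdam", 1))
        assert ("DNAdam", +1) in clamped.called_nodes(code("0110"))
        assert not clamped.is_stable(code("0110"))

    def test_damage_clamp_leaves_no_stable_state(self, p53):
        clamped = apply_perturbation(p53, Perturbation.ectopic("DNAdam", 1))
        assert all(not clamped.is_stable(s) for s in clamped.states())

    def test_identity_clamp_changes_nothing(self, p53):
        clamped = apply_perturbation(p53, Perturbation([("Mdm2cyt", 0, 2)]))
        for s in p53.states():
            assert clamped.targets_vector(s) == p53.targets_vector(s)

    def test_knockdown_clamps_to_zero(self, p53):
        kd = apply_perturbation(p53, Perturbation.knockdown("p53"))
        assert all(kd.target_level(s, "p53") == 0 for s in kd.states())

    def test_attractor_levels_respect_clamp(self, p53):
        clamped = Perturbation.ectopic("DNAdam", 1)
        stg = build_stg(p53, ASYNC, perturbation=clamped)
        i = p53.index("DNAdam")
        for _, members in attractors(stg):
            assert all(s[i] == 1 for s in members)

    def test_unknown_node_rejected(self, p53):
        with pytest.raises(ModelError):
            apply_perturbation(p53, Perturbation([("nope", 0, 0)]))

    def test_clamp_above_max_rejected(self, p53):
        with pytest.raises(ModelError, match="max level"):
            apply_perturbation(p53, Perturbation([("DNAdam", 0, 3)]))


class TestBuildStg:
    def test_full_async_stg(self, p53):
        stg = build_stg(p53)
        assert len(stg) == 36
        assert codes(stg.stable_states()) == ["0110"]

    def test_sync_stg_is_deterministic(self, p53):
        stg = build_stg(p53, SYNC)
        assert all(stg.out_degree(s) <= 1 for s in stg.states())

    def test_initial_pattern_restricts_to_reachable_subgraph(self, p53):
        full = build_stg(p53)
        sub = build_stg(p53, ASYNC, initial=[InitialPattern.from_string("0111")])
        assert code("0111") in sub
        assert set(sub.states()) <= set(full.states())
        assert set(sub.transitions()) <= set(full.transitions())
        # every kept state is reachable from the initial state
        import networkx as nx

        reachable = {code("0111")} | nx.descendants(sub.graph, code("0111"))
        assert set(sub.states()) == reachable

    def test_wildcard_pattern_expansion(self, p53):
        pattern = InitialPattern.from_string("0**0")
        assert len(list(pattern.expand(p53))) == 6

    def test_state_cap_enforced(self, p53):
        with pytest.raises(CapExceededError):
            build_stg(p53, ASYNC, max_states=10)

    def test_input_node_level_is_frozen_in_dynamics(self):
        m = LogicalModel(
            [NodeSpec("S", is_input=True), NodeSpec("A")],
            [Interaction("S", "A", 1, "+")],
            {"A": [RuleEntry(1, [Literal("S")])]},
        )
        stg = build_stg(m)
        for a, b in stg.transitions():
            assert a[0] == b[0]  # transitions never move the input
        assert codes(stg.stable_states()) == ["00", "11"]


class TestSchemeIndependence:
    @pytest.mark.parametrize("seed", range(6))
    def test_stable_states_identical_across_schemes(self, seed):
        m = random_model(4, max_level_cap=2, density=0.5, seed=seed)
        reference = codes(build_stg(m, ASYNC).stable_states())
        for scheme in (SYNC, COMPLETE, SEQUENTIAL):
            assert codes(build_stg(m, scheme).stable_states()) == reference

    @pytest.mark.parametrize("seed", range(6))
    def test_async_and_sync_are_subrelations_of_complete(self, seed):
        m = random_model(4, max_level_cap=2, density=0.5, seed=10 + seed)
        complete = set(build_stg(m, COMPLETE).transitions())
        assert set(build_stg(m, ASYNC).transitions()) <= complete
        assert set(build_stg(m, SYNC).transitions()) <= complete
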