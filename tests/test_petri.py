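"""Colored Petri-net engine: axioms, enabling, firing, replay, reachability."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldchain import (Arc, ColoredPetriNet, Marking, Place, Token,
                       Transition, enabled_transitions, fire,
                       incidence_matrices, make_token, run, validate_net)
from coldchain import fixtures as fx
from coldchain.petri import reachable_signatures

from conftest import brute_force_reachability


def codes(violations):
    return sorted(v.code for v in violations)


class TestValidation:
    def test_valid_net_has_empty_report(self, toy_chain_net):
        assert validate_net(toy_chain_net) == []

    def test_shared_place_transition_id_breaks_disjointness(self):
        net = ColoredPetriNet(
            places=(Place("X"), Place("P2")),
            transitions=(Transition("X"),),
            arcs=(Arc("X", "P2"),),  # would-be arc; id clash is the point
        )
        assert "P∩T ≠ Φ" in codes(validate_net(net))

    def test_empty_net_breaks_nonemptiness(self):
        net = ColoredPetriNet(places=(), transitions=(), arcs=())
        assert codes(validate_net(net)) == ["P∪T = Φ"]

    def test_place_to_place_arc_is_non_bipartite(self, toy_chain_net):
        net = ColoredPetriNet(
            toy_chain_net.places, toy_chain_net.transitions,
            toy_chain_net.arcs + (Arc("P1", "P2"),),
            toy_chain_net.initial_marking)
        assert "non-bipartite arc" in codes(validate_net(net))

    def test_overfull_and_inadmissible_initial_marking(self):
        net = ColoredPetriNet(
            places=(Place("P1", capacity=1, color_domain=frozenset({"red"})),),
            transitions=(Transition("T1"),),
            arcs=(Arc("P1", "T1"),),
            initial_marking=Marking.from_dict(
                {"P1": [make_token("red"), make_token("blue")]}),
        )
        assert codes(validate_net(net)) == ["capacity-exceeded", "color-inadmissible"]

    def test_isolated_transition_flagged(self, toy_chain_net):
        net = ColoredPetriNet(
            toy_chain_net.places,
            toy_chain_net.transitions + (Transition("T9"),),
            toy_chain_net.arcs, toy_chain_net.initial_marking)
        assert "isolated-transition" in codes(validate_net(net))

    @given(st.lists(st.sampled_from(["shared-id", "pp-arc", "tt-arc", "zero-weight"]),
                    min_size=0, max_size=3, unique=True))
    @settings(max_examples=40, deadline=None)
    def test_flags_exactly_the_injected_violations(self, injections):
        """Starting from a valid random-ish chain net, each injected defect is
        reported and nothing else is."""
        places = [Place(f"P{i}") for i in range(4)]
        transitions = [Transition(f"T{i}") for i in range(3)]
        arcs = [Arc(f"P{i}", f"T{i}") for i in range(3)] + \
               [Arc(f"T{i}", f"P{i+1}") for i in range(3)]
        expected = set()
        for kind in injections:
            if kind == "shared-id":
                # reuse the terminal place's id for a transition; the arc
                # touching it keeps the new transition non-isolated
                transitions.append(Transition("P3"))
                arcs.append(Arc("P1", "P3"))
                expected.add("P∩T ≠ Φ")
            elif kind == "pp-arc":
                arcs.append(Arc("P0", "P2"))
                expected.add("non-bipartite arc")
            elif kind == "tt-arc":
                arcs.append(Arc("T0", "T1"))
                expected.add("non-bipartite arc")
            elif kind == "zero-weight":
                arcs.append(Arc("P0", "T1", weight=0))
                expected.add("bad-weight")
        net = ColoredPetriNet(tuple(places), tuple(transitions), tuple(arcs))
        assert set(codes(validate_net(net))) == expected


class TestEnabling:
    def test_empty_input_place_disables(self, toy_chain_net):
        m = Marking.from_dict({})
        assert enabled_transitions(toy_chain_net, m) == set()

    def test_ship_processing_start(self):
        """With one token at 'Captured tilapia', only delivery can fire, and
        its lineage record is C(P1:P2)."""
        net = fx.ship_processing_layer().subnet
        assert enabled_transitions(net, net.initial_marking) == {"T1"}
        m2, event = fire(net, net.initial_marking, "T1")
        assert event.lineage == "C(P1:P2)"
        assert m2.count("P2") == 1 and m2.count("P1") == 0

    def test_full_output_place_disables(self):
        net = ColoredPetriNet(
            places=(Place("A"), Place("B", capacity=3)),
            transitions=(Transition("T"),),
            arcs=(Arc("A", "T"), Arc("T", "B")),
        )
        m = Marking.from_dict({"A": [make_token()],
                               "B": [make_token()] * 3})
        assert enabled_transitions(net, m) == set()
        # brute-force check of the capacity rule: any fewer tokens at B enables
        for n in range(3):
            m_ok = Marking.from_dict({"A": [make_token()], "B": [make_token()] * n})
            assert enabled_transitions(net, m_ok) == {"T"}

    def test_guard_blocks(self):
        net = ColoredPetriNet(
            places=(Place("A"), Place("B")),
            transitions=(Transition("T", guard=lambda toks: toks[0].color == "red"),),
            arcs=(Arc("A", "T"), Arc("T", "B")),
        )
        assert enabled_transitions(net, Marking.from_dict({"A": [make_token("blue")]})) == set()
        assert enabled_transitions(net, Marking.from_dict({"A": [make_token("red")]})) == {"T"}

    def test_unknown_place_in_marking_raises(self, toy_chain_net):
        with pytest.raises(ValueError, match="unknown places"):
            enabled_transitions(toy_chain_net, Marking.from_dict({"Zz": [make_token()]}))


class TestFiring:
    def test_weight_one_conservation(self, toy_chain_net):
        m = toy_chain_net.initial_marking
        assert m.total() == 1
        m2, _ = fire(toy_chain_net, m, "T1")
        assert m2.total() == 1

    def test_storage_temperature_examination(self):
        """Temperature examination consumes the logger data and the standard
        parameters, producing the standardized and exceeding portions."""
        net = fx.storage_layer().subnet
        m, _ = fire(net, net.initial_marking, "T1")
        m2, event = fire(net, m, "T3")
        assert event.lineage == "C(P5,P8:P9,P10)"
        assert m2.count("P9") == 1 and m2.count("P10") == 1
        assert m2.count("P5") == 0 and m2.count("P8") == 0

    def test_firing_disabled_transition_raises(self, toy_chain_net):
        with pytest.raises(ValueError, match="not enabled"):
            fire(toy_chain_net, toy_chain_net.initial_marking, "T2")

    def test_lineage_accumulates_along_the_chain(self, toy_chain_net):
        m, _ = fire(toy_chain_net, toy_chain_net.initial_marking, "T1")
        m2, _ = fire(toy_chain_net, m, "T2")
        (tok,) = m2.at("P3")
        assert tok.lineage == ("C(P1:P2)", "C(P2:P3)")


class TestRun:
    def test_quiescent_start_gives_empty_log(self, toy_chain_net):
        net = ColoredPetriNet(toy_chain_net.places, toy_chain_net.transitions,
                              toy_chain_net.arcs)  # no tokens
        assert run(net).events == []

    def test_ship_processing_fires_in_document_order(self):
        net = fx.ship_processing_layer().subnet
        log = run(net)
        assert log.transitions_fired() == ["T1", "T2", "T3", "T4", "T5", "T6"]
        assert log.final_marking.count("P13") == 1  # processing stage reached

    @pytest.mark.parametrize("policy", ["priority", "random"])
    def test_replay_determinism(self, choice_net, policy):
        log1 = run(choice_net, policy=policy, rng_seed=42, max_steps=30)
        log2 = run(choice_net, policy=policy, rng_seed=42, max_steps=30)
        assert log1.transitions_fired() == log2.transitions_fired()
        assert log1.final_marking == log2.final_marking
        assert [e.lineage for e in log1.events] == [e.lineage for e in log2.events]

    def test_different_seeds_can_diverge(self, choice_net):
        logs = {tuple(run(choice_net, policy="random", rng_seed=s, max_steps=5)
                      .transitions_fired()) for s in range(20)}
        assert len(logs) > 1


class TestReachability:
    def test_run_sampling_matches_brute_force(self, choice_net):
        """On a small capacity-bounded net, the markings visited by seeded
        random runs equal the brute-force breadth-first reachability set."""
        exact = brute_force_reachability(choice_net)
        sampled = reachable_signatures(choice_net, n_seeds=80, max_steps=60)
        assert sampled == exact

    def test_larger_net_still_matches(self):
        net = ColoredPetriNet(
            places=tuple(Place(f"P{i}", capacity=2) for i in range(6)),
            transitions=(Transition("T0"), Transition("T1"), Transition("T2")),
            arcs=(Arc("P0", "T0"), Arc("T0", "P1"), Arc("T0", "P2"),
                  Arc("P1", "T1"), Arc("P2", "T1"), Arc("T1", "P3"),
                  Arc("P3", "T2"), Arc("T2", "P4"), Arc("T2", "P5")),
            initial_marking=Marking.from_dict(
                {"P0": [make_token(), make_token()]}),
        )
        assert reachable_signatures(net, n_seeds=60, max_steps=60) == \
            brute_force_reachability(net)


class TestIncidence:
    def test_matrix_view_matches_arcs(self, toy_chain_net):
        i_minus, i_plus = incidence_matrices(toy_chain_net)
        assert i_minus.loc["P1", "T1"] == 1 and i_plus.loc["P2", "T1"] == 1
        assert i_minus.loc["P2", "T2"] == 1 and i_plus.loc["P3", "T2"] == 1
        assert int(i_minus.to_numpy().sum()) == 2
        # every transition has effect on at least one place
        assert ((i_minus.sum(axis=0) + i_plus.sum(axis=0)) > 0).all()
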