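import pytest

from coldchain import (Arc, BaranyiParams, ColoredPetriNet, Marking, Place,
                       Transition, make_token)
from coldchain import fixtures as fx


@pytest.fixture
def toy_chain_net():
    """P1 -> T1 -> P2 -> T2 -> P3, one token at P1."""
    return ColoredPetriNet(
        places=(Place("P1"), Place("P2"), Place("P3")),
        transitions=(Transition("T1"), Transition("T2")),
        arcs=(Arc("P1", "T1"), Arc("T1", "P2"), Arc("P2", "T2"), Arc("T2", "P3")),
        initial_marking=Marking.from_dict({"P1": [make_token()]}),
        name="toy-chain",
    )


@pytest.fixture
def choice_net():
    """A net with a real conflict: P1 feeds both T1 (-> P2) and T2 (-> P3),
    and T3 recycles P3 -> P1.  Capacity 2 everywhere."""
    return ColoredPetriNet(
        places=(Place("P1", capacity=2), Place("P2", capacity=2), Place("P3", capacity=2)),
        transitions=(Transition("T1"), Transition("T2"), Transition("T3")),
        arcs=(Arc("P1", "T1"), Arc("T1", "P2"),
              Arc("P1", "T2"), Arc("T2", "P3"),
              Arc("P3", "T3"), Arc("T3", "P1")),
        initial_marking=Marking.from_dict({"P1": [make_token(), make_token()]}),
        name="choice",
    )


@pytest.fixture
def quality_model():
    return fx.tilapia_quality_model()


@pytest.fixture
def baranyi_params():
    return BaranyiParams(y0=3.0, nmax=9.0, mu_max=0.8, v=0.8, h0=1.0)


def brute_force_reachability(net, max_states=20000):
    """Independent breadth-first enumeration of reachable marking signatures."""
    from coldchain import enabled_transitions, fire

    seen = {net.initial_marking.signature(): net.initial_marking}
    frontier = [net.initial_marking]
    while frontier:
        m = frontier.pop()
        for tid in enabled_transitions(net, m):
            m2, _ = fire(net, m, tid)
            sig = m2.signature()
            if sig not in seen:
                if len(seen) >= max_states:
                    raise RuntimeError("state space too large for brute force")
                seen[sig] = m2
                frontier.append(m2)
    return set(seen)
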