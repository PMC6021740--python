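"""Colored Petri-net core: structure, axioms, firing semantics.

The net is the classical bipartite triple (P, T; F) extended with color sets,
token payloads and an initial marking, Sigma = (P, T; F, C, I-, I+, M0).
Incidence I-/I+ is represented by weighted arcs; a read-only matrix view is
derivable with :func:`incidence_matrices`.

Three structural axioms are enforced by :func:`validate_net` (violations are
returned as data, never raised):

* disjointness  — places and transitions are different kinds of element;
* non-emptiness — the net contains at least one element;
* bipartite flow — every arc joins a place to a transition or vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Registry of named guard predicates so that nets restored from disk can
#: re-attach behaviour (e.g. a HACCP gate) without serialising code.
GUARD_REGISTRY: dict[str, Callable[[list["Token"]], bool]] = {}


def register_guard(name: str, fn: Callable[[list["Token"]], bool]) -> None:
    GUARD_REGISTRY[name] = fn


@dataclass(frozen=True)
class Place:
    """A location node.  ``capacity=None`` means unbounded."""

    id: str
    label: str = ""
    capacity: int | None = None
    color_domain: frozenset[str] | None = None  # None = any color admitted

    def admits(self, color: str) -> bool:
        return self.color_domain is None or color in self.color_domain


@dataclass(frozen=True)
class Transition:
    """A variation node.  ``guard`` (or ``guard_name`` into the registry) is a
    pure predicate over the list of tokens the firing would consume."""

    id: str
    label: str = ""
    guard: Callable[[list["Token"]], bool] | None = None
    guard_name: str | None = None

    def guard_fn(self) -> Callable[[list["Token"]], bool] | None:
        if self.guard is not None:
            return self.guard
        if self.guard_name is not None:
            return GUARD_REGISTRY.get(self.guard_name)
        return None


@dataclass(frozen=True)
class Arc:
    source: str
    target: str
    weight: int = 1
    annotation: Callable[[dict], dict] | None = None  # content-transfer rule


@dataclass(frozen=True)
class Token:
    """A colored token carrying a multidimensional information payload.

    ``lineage`` accumulates content-transfer records written C(m_x:m_y): the
    input and output node ids of every firing the token's information passed
    through.
    """

    color: str = "default"
    content: tuple = ()  # frozen dict items, see make_token
    lineage: tuple[str, ...] = ()

    @property
    def content_dict(self) -> dict:
        return dict(self.content)


def make_token(color: str = "default", content: Mapping | None = None,
               lineage: Iterable[str] = ()) -> Token:
    items = tuple(sorted((content or {}).items()))
    return Token(color, items, tuple(lineage))


@dataclass(frozen=True)
class Marking:
    """Per-place token multiset (tokens kept in FIFO order)."""

    tokens: tuple[tuple[str, tuple[Token, ...]], ...]

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[Token]]) -> "Marking":
        return cls(tuple(sorted((p, tuple(toks)) for p, toks in d.items() if toks)))

    def as_dict(self) -> dict[str, list[Token]]:
        return {p: list(toks) for p, toks in self.tokens}

    def at(self, place_id: str) -> list[Token]:
        return dict(self.tokens).get(place_id, [])  # type: ignore[return-value]

    def count(self, place_id: str) -> int:
        return len(self.at(place_id))

    def total(self) -> int:
        return sum(len(toks) for _, toks in self.tokens)

    def signature(self) -> tuple:
        """Hashable color-multiset view (content/lineage excluded), used for
        reachability comparisons."""
        return tuple(
            (p, tuple(sorted(t.color for t in toks))) for p, toks in self.tokens
        )


EMPTY_MARKING = Marking(())


@dataclass(frozen=True)
class ColoredPetriNet:
    places: tuple[Place, ...]
    transitions: tuple[Transition, ...]
    arcs: tuple[Arc, ...]
    initial_marking: Marking = EMPTY_MARKING
    name: str = "net"

    @property
    def place_ids(self) -> list[str]:
        return [p.id for p in self.places]

    @property
    def transition_ids(self) -> list[str]:
        return [t.id for t in self.transitions]

    def place(self, pid: str) -> Place:
        for p in self.places:
            if p.id == pid:
                return p
        raise KeyError(f"unknown place {pid!r}")

    def transition(self, tid: str) -> Transition:
        for t in self.transitions:
            if t.id == tid:
                return t
        raise KeyError(f"unknown transition {tid!r}")

    def inputs(self, tid: str) -> list[Arc]:
        """Arcs place -> transition feeding ``tid``."""
        return [a for a in self.arcs if a.target == tid]

    def outputs(self, tid: str) -> list[Arc]:
        """Arcs transition -> place leaving ``tid``."""
        return [a for a in self.arcs if a.source == tid]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.code}] {self.message}"


def validate_net(net: ColoredPetriNet) -> list[Violation]:
    """Check the structural axioms plus capacity/color admissibility.

    Returns one :class:`Violation` per defect; an empty list means the net is
    valid.  Violations are data, not exceptions.
    """
    out: list[Violation] = []
    pids, tids = net.place_ids, net.transition_ids
    pset, tset = set(pids), set(tids)

    for dup in _duplicates(pids):
        out.append(Violation("duplicate-place", f"place id {dup!r} declared twice"))
    for dup in _duplicates(tids):
        out.append(Violation("duplicate-transition", f"transition id {dup!r} declared twice"))
    for shared in sorted(pset & tset):
        out.append(Violation("P∩T ≠ Φ", f"id {shared!r} used for both a place and a transition"))
    if not pset and not tset:
        out.append(Violation("P∪T = Φ", "net has no places and no transitions"))

    for p in net.places:
        if p.capacity is not None and p.capacity < 1:
            out.append(Violation("bad-capacity", f"place {p.id!r} capacity must be >= 1"))

    def _kind(eid: str) -> str | None:
        # 'both' is already reported as a disjointness violation
        if eid in pset and eid in tset:
            return "both"
        if eid in pset:
            return "p"
        if eid in tset:
            return "t"
        return None

    for a in net.arcs:
        s_kind, t_kind = _kind(a.source), _kind(a.target)
        if s_kind is None:
            out.append(Violation("unknown-endpoint", f"arc source {a.source!r} is not in the net"))
        if t_kind is None:
            out.append(Violation("unknown-endpoint", f"arc target {a.target!r} is not in the net"))
        if s_kind in ("p", "t") and s_kind == t_kind:
            out.append(
                Violation("non-bipartite arc",
                          f"arc {a.source!r}->{a.target!r} joins two elements of the same kind")
            )
        if a.weight < 1:
            out.append(Violation("bad-weight", f"arc {a.source!r}->{a.target!r} weight must be >= 1"))

    # every transition must take effect on at least one place
    touched = {a.source for a in net.arcs} | {a.target for a in net.arcs}
    for t in net.transitions:
        if t.id not in touched:
            out.append(Violation("isolated-transition", f"transition {t.id!r} has no input or output arc"))

    # initial marking against capacities and color domains
    for pid, toks in net.initial_marking.tokens:
        if pid not in pset:
            out.append(Violation("unknown-place-marked", f"initial marking places tokens at unknown {pid!r}"))
            continue
        place = net.place(pid)
        if place.capacity is not None and len(toks) > place.capacity:
            out.append(
                Violation("capacity-exceeded",
                          f"initial marking puts {len(toks)} tokens at {pid!r} (capacity {place.capacity})")
            )
        for tok in toks:
            if not place.admits(tok.color):
                out.append(
                    Violation("color-inadmissible",
                              f"token color {tok.color!r} not admitted at place {pid!r}")
                )
    return out


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen, dups = set(), []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


# ---------------------------------------------------------------------------
# Firing semantics
# ---------------------------------------------------------------------------

def _check_marking(net: ColoredPetriNet, m: Marking) -> None:
    unknown = [p for p, _ in m.tokens if p not in set(net.place_ids)]
    if unknown:
        raise ValueError(f"marking references unknown places: {unknown}")


def _candidate_tokens(net: ColoredPetriNet, m: Marking, tid: str) -> dict[str, list[Token]] | None:
    """FIFO token selection per input arc; None if some input is short."""
    chosen: dict[str, list[Token]] = {}
    for arc in net.inputs(tid):
        pool = m.at(arc.source)
        if len(pool) < arc.weight:
            return None
        chosen[arc.source] = pool[: arc.weight]
    return chosen


def is_enabled(net: ColoredPetriNet, m: Marking, tid: str) -> bool:
    return tid in enabled_transitions(net, m)


def enabled_transitions(net: ColoredPetriNet, m: Marking) -> set[str]:
    """Transitions enabled in marking ``m``.

    Enabled iff every input place holds >= arc-weight tokens, the guard (if
    any) accepts the tokens that would be consumed, and firing would not
    overflow any output-place capacity or color domain.
    """
    _check_marking(net, m)
    enabled: set[str] = set()
    for t in net.transitions:
        if not net.inputs(t.id):
            # a source transition never fires spontaneously here
            continue
        chosen = _candidate_tokens(net, m, t.id)
        if chosen is None:
            continue
        consumed = [tok for toks in chosen.values() for tok in toks]
        guard = t.guard_fn()
        if guard is not None and not guard(consumed):
            continue
        if _outputs_fit(net, m, t.id, chosen, consumed):
            enabled.add(t.id)
    return enabled


def _produced_color(consumed: list[Token]) -> str:
    return consumed[0].color if consumed else "default"


def _outputs_fit(net, m, tid, chosen, consumed) -> bool:
    color = _produced_color(consumed)
    for arc in net.outputs(tid):
        place = net.place(arc.target)
        room_used = m.count(arc.target) - len(chosen.get(arc.target, []))
        if place.capacity is not None and room_used + arc.weight > place.capacity:
            return False
        if not place.admits(color):
            return False
    return True


@dataclass(frozen=True)
class FiredEvent:
    step: int
    transition: str
    consumed: tuple[tuple[str, tuple[Token, ...]], ...]
    produced: tuple[tuple[str, tuple[Token, ...]], ...]
    lineage: str
    policy: str = "manual"


def lineage_record(input_places: Sequence[str], output_places: Sequence[str]) -> str:
    """Content-transfer record C(m_x:m_y) naming input and output nodes."""
    return f"C({','.join(input_places)}:{','.join(output_places)})"


def fire(net: ColoredPetriNet, m: Marking, tid: str,
         rng_seed: int | None = None, step: int = 0,
         policy: str = "manual") -> tuple[Marking, FiredEvent]:
    """Fire ``tid`` in marking ``m``; returns the new marking and the event.

    Token choice among interchangeable tokens is FIFO by default; with
    ``rng_seed`` the choice is a seeded permutation, so replay is
    deterministic either way.  Firing a disabled transition raises.
    """
    if tid not in enabled_transitions(net, m):
        raise ValueError(f"transition {tid!r} is not enabled in this marking")
    state = m.as_dict()
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None

    consumed: dict[str, tuple[Token, ...]] = {}
    for arc in net.inputs(tid):
        pool = list(state.get(arc.source, []))
        if rng is not None and len(pool) > arc.weight:
            idx = sorted(rng.choice(len(pool), size=arc.weight, replace=False).tolist())
        else:
            idx = list(range(arc.weight))
        take = tuple(pool[i] for i in idx)
        for i in reversed(idx):
            pool.pop(i)
        state[arc.source] = pool
        consumed[arc.source] = take

    in_places = sorted(consumed)
    out_places = [a.target for a in net.outputs(tid)]
    rec = lineage_record(in_places, out_places)

    all_consumed = [tok for toks in consumed.values() for tok in toks]
    color = _produced_color(all_consumed)
    merged_content: dict = {}
    merged_lineage: tuple[str, ...] = ()
    for tok in all_consumed:
        merged_content.update(tok.content_dict)
        if len(tok.lineage) > len(merged_lineage):
            merged_lineage = tok.lineage

    produced: dict[str, tuple[Token, ...]] = {}
    for arc in net.outputs(tid):
        content = dict(merged_content)
        if arc.annotation is not None:
            content = arc.annotation(content)
        tok = make_token(color, content, merged_lineage + (rec,))
        produced[arc.target] = tuple([tok] * arc.weight)
        state.setdefault(arc.target, [])
        state[arc.target] = list(state[arc.target]) + list(produced[arc.target])

    new_m = Marking.from_dict(state)
    event = FiredEvent(
        step=step,
        transition=tid,
        consumed=tuple(sorted(consumed.items())),
        produced=tuple(sorted(produced.items())),
        lineage=rec,
        policy=policy,
    )
    return new_m, event


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

@dataclass
class EventLog:
    events: list[FiredEvent] = field(default_factory=list)
    policy: str = "priority"
    seed: int | None = None
    final_marking: Marking = EMPTY_MARKING

    def transitions_fired(self) -> list[str]:
        return [e.transition for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "step": e.step,
                    "transition": e.transition,
                    "consumed": ";".join(
                        f"{p}:{t.color}" for p, toks in e.consumed for t in toks),
                    "produced": ";".join(
                        f"{p}:{t.color}" for p, toks in e.produced for t in toks),
                    "lineage": e.lineage,
                    "policy": e.policy,
                }
            )
        return pd.DataFrame(rows, columns=["step", "transition", "consumed",
                                           "produced", "lineage", "policy"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run(net: ColoredPetriNet, policy: str = "priority", max_steps: int = 1000,
        rng_seed: int = 0, marking: Marking | None = None) -> EventLog:
    """Run the net to quiescence or ``max_steps``.

    ``policy`` resolves conflicts when several transitions are enabled:

    * ``"priority"`` — deterministic document order (the order transitions
      were declared in);
    * ``"random"`` — seeded uniform choice.

    Same seed => identical log (replay determinism).
    """
    if policy not in ("priority", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    violations = validate_net(net)
    if violations:
        raise ValueError(f"invalid net: {[str(v) for v in violations]}")
    rng = np.random.default_rng(rng_seed)
    m = marking if marking is not None else net.initial_marking
    log = EventLog(policy=policy, seed=rng_seed)
    order = {tid: i for i, tid in enumerate(net.transition_ids)}
    for step in range(max_steps):
        enabled = enabled_transitions(net, m)
        if not enabled:
            break
        if policy == "priority":
            tid = min(enabled, key=lambda t: order[t])
            m, ev = fire(net, m, tid, rng_seed=None, step=step, policy=policy)
        else:
            choices = sorted(enabled, key=lambda t: order[t])
            tid = choices[int(rng.integers(len(choices)))]
            m, ev = fire(net, m, tid, rng_seed=int(rng.integers(2**31)),
                         step=step, policy=policy)
        log.events.append(ev)
    log.final_marking = m
    return log


def reachable_signatures(net: ColoredPetriNet, n_seeds: int = 64,
                         max_steps: int = 200) -> set[tuple]:
    """Marking signatures visited by random-policy runs over many seeds.

    A sampling view of the reachability set; on small nets with bounded
    capacity it converges to the exact set (compared against brute-force
    enumeration in the test suite).
    """
    seen: set[tuple] = {net.initial_marking.signature()}
    for seed in range(n_seeds):
        m = net.initial_marking
        rng = np.random.default_rng(seed)
        order = {tid: i for i, tid in enumerate(net.transition_ids)}
        for step in range(max_steps):
            enabled = enabled_transitions(net, m)
            if not enabled:
                break
            choices = sorted(enabled, key=lambda t: order[t])
            tid = choices[int(rng.integers(len(choices)))]
            m, _ = fire(net, m, tid, rng_seed=int(rng.integers(2**31)), step=step)
            seen.add(m.signature())
    return seen


def incidence_matrices(net: ColoredPetriNet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read-only incidence view (I-, I+) derived from the arcs.

    Rows are places, columns transitions; I-[p, t] is the weight consumed
    from p when t fires, I+[p, t] the weight produced at p.
    """
    pids, tids = net.place_ids, net.transition_ids
    i_minus = pd.DataFrame(0, index=pids, columns=tids, dtype=int)
    i_plus = pd.DataFrame(0, index=pids, columns=tids, dtype=int)
    pset = set(pids)
    for a in net.arcs:
        if a.source in pset:
            i_minus.loc[a.source, a.target] += a.weight
        else:
            i_plus.loc[a.target, a.source] += a.weight
    i_minus.flags.allows_duplicate_labels = False
    i_plus.flags.allows_duplicate_labels = False
    return i_minus, i_plus
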