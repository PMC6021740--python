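"""Stage hierarchy: multidimensional meta-nodes, per-stage sub-nets, and the
bridge links that join the ending node of one stage to the beginning node of
the next.

Every basic information node (meta-node) carries three attribute categories:
circulation (stage, location, supplier), processing (method, facility,
operator, timestamp) and environment (medium, temperature, moisture,
timestamp, logger readings).  Stages are colored Petri sub-nets whose places
map onto meta-nodes; a chain of stages is welded into one flat net by one
bridge transition per adjacent stage pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

from .petri import (Arc, ColoredPetriNet, Marking, Place, Transition,
                    validate_net)
from .profiles import TemperatureProfile

VALID_MEDIA = ("air", "liquid", "solid")
VALID_ROLES = ("begin", "internal", "end")


@dataclass(frozen=True)
class MetaAttributes:
    """The three information categories recorded per node.

    ``environment`` may carry ``readings``: a tuple of (timestamp_min,
    temperature_C) logger samples attached to that node.
    """

    circulation: tuple = ()
    processing: tuple = ()
    environment: tuple = ()

    @classmethod
    def build(cls, circulation: dict | None = None, processing: dict | None = None,
              environment: dict | None = None) -> "MetaAttributes":
        env = dict(environment or {})
        if "medium" in env and env["medium"] not in VALID_MEDIA:
            raise ValueError(f"medium must be one of {VALID_MEDIA}")
        if "moisture" in env and not 0 <= env["moisture"] <= 100:
            raise ValueError("moisture must lie in [0, 100] %")
        for cat in (circulation, processing, env):
            ts = (cat or {}).get("timestamp_min")
            if ts is not None and ts < 0:
                raise ValueError("timestamps must be non-negative")
        if "readings" in env:
            env["readings"] = tuple((float(t), float(T)) for t, T in env["readings"])
        return cls(
            circulation=tuple(sorted((circulation or {}).items())),
            processing=tuple(sorted((processing or {}).items())),
            environment=tuple(sorted(env.items())),
        )

    def category(self, kind: str) -> dict:
        return dict(getattr(self, kind))


@dataclass(frozen=True)
class MetaNode:
    """Smallest unit of information description; maps onto one place."""

    id: str
    attributes: MetaAttributes = field(default_factory=MetaAttributes)
    layer: str = ""
    role: str = "internal"

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}")

    @property
    def timestamp_min(self) -> float | None:
        """theta(m): the node's time attribute (processing first, then
        environment)."""
        for cat in ("processing", "environment", "circulation"):
            ts = self.attributes.category(cat).get("timestamp_min")
            if ts is not None:
                return float(ts)
        return None


@dataclass(frozen=True)
class OperationRecord:
    """One behavior-cluster entry: an operation performed on the product."""

    id: str
    description: str
    layer: str
    timestamp_min: float


@dataclass(frozen=True)
class HierarchyLayer:
    """One stage of the chain: a validated sub-net plus its meta-nodes."""

    id: str
    subnet: ColoredPetriNet
    begin_node: str
    end_node: str
    nodes: tuple[MetaNode, ...] = ()
    operations: tuple[OperationRecord, ...] = ()

    def __post_init__(self) -> None:
        pids = set(self.subnet.place_ids)
        for role, nid in (("begin", self.begin_node), ("end", self.end_node)):
            if nid not in pids:
                raise ValueError(f"layer {self.id!r}: {role} node {nid!r} not in subnet")
        bad = validate_net(self.subnet)
        if bad:
            raise ValueError(f"layer {self.id!r}: invalid subnet: {[str(v) for v in bad]}")

    def node(self, nid: str) -> MetaNode | None:
        for n in self.nodes:
            if n.id == nid:
                return n
        return None


@dataclass(frozen=True)
class BridgeLink:
    """End-of-upper-layer to begin-of-lower-layer connector.

    ``readings`` optionally carries the (timestamp_min, temp_C) logger series
    recorded while the product crossed between the two stages.
    """

    upper_end: tuple[str, str]    # (layer id, node id)
    lower_begin: tuple[str, str]
    label: str
    readings: tuple[tuple[float, float], ...] = ()


@dataclass(frozen=True)
class HierarchyChain:
    layers: tuple[HierarchyLayer, ...]
    bridges: tuple[BridgeLink, ...]

    def __post_init__(self) -> None:
        if len(self.bridges) != len(self.layers) - 1:
            raise ValueError(
                f"{len(self.layers)} layers need {len(self.layers) - 1} bridges, "
                f"got {len(self.bridges)}"
            )
        for k, b in enumerate(self.bridges):
            if b.upper_end != (self.layers[k].id, self.layers[k].end_node):
                raise ValueError(f"bridge {b.label!r} does not leave layer {k}'s end node")
            if b.lower_begin != (self.layers[k + 1].id, self.layers[k + 1].begin_node):
                raise ValueError(f"bridge {b.label!r} does not enter layer {k + 1}'s begin node")

    def bridge_labels(self) -> list[str]:
        return [b.label for b in self.bridges]


def _default_labels(n_layers: int) -> list[str]:
    # consecutive alphabet pairs: AB, CD, EF, ...
    letters = ascii_uppercase
    return [letters[2 * k] + letters[2 * k + 1] for k in range(n_layers - 1)]


def build_chain(layers, bridge_labels=None, bridge_readings=None) -> HierarchyChain:
    """Assemble layers into a chain, auto-creating end(k) -> begin(k+1)
    bridges in order.

    ``bridge_labels`` overrides the default two-letter names; the tilapia
    case uses the printed letters EF, GH, IJ.  ``bridge_readings`` attaches a
    logger series per bridge.
    """
    layers = tuple(layers)
    if not layers:
        raise ValueError("need at least one layer")
    labels = list(bridge_labels) if bridge_labels is not None else _default_labels(len(layers))
    if len(labels) != len(layers) - 1:
        raise ValueError(f"{len(layers)} layers need {len(layers) - 1} bridge labels")
    readings = list(bridge_readings) if bridge_readings is not None else [()] * len(labels)
    bridges = tuple(
        BridgeLink(
            upper_end=(layers[k].id, layers[k].end_node),
            lower_begin=(layers[k + 1].id, layers[k + 1].begin_node),
            label=labels[k],
            readings=tuple(readings[k]),
        )
        for k in range(len(layers) - 1)
    )
    return HierarchyChain(layers=layers, bridges=bridges)


def qualified(layer_id: str, node_id: str) -> str:
    return f"{layer_id}:{node_id}"


def merge_to_net(chain: HierarchyChain) -> ColoredPetriNet:
    """Weld the chain into one flat net.

    Places and transitions are the disjoint union of the layers under
    qualified ``layer:node`` ids, plus one bridge transition per bridge link
    (input: the upper end place; output: the lower begin place).  Tokens can
    therefore cross between stages only through the bridge transitions.
    """
    places, transitions, arcs = [], [], []
    marking: dict = {}
    seen: set[str] = set()
    for layer in chain.layers:
        for p in layer.subnet.places:
            qid = qualified(layer.id, p.id)
            if qid in seen:
                raise ValueError(f"id collision across layers: {qid!r}")
            seen.add(qid)
            places.append(Place(qid, p.label, p.capacity, p.color_domain))
        for t in layer.subnet.transitions:
            qid = qualified(layer.id, t.id)
            if qid in seen:
                raise ValueError(f"id collision across layers: {qid!r}")
            seen.add(qid)
            transitions.append(Transition(qid, t.label, t.guard, t.guard_name))
        for a in layer.subnet.arcs:
            arcs.append(Arc(qualified(layer.id, a.source), qualified(layer.id, a.target),
                            a.weight, a.annotation))
        for pid, toks in layer.subnet.initial_marking.tokens:
            marking[qualified(layer.id, pid)] = list(toks)
    for b in chain.bridges:
        tid = f"bridge:{b.label}"
        transitions.append(Transition(tid, f"bridge {b.label}"))
        arcs.append(Arc(qualified(*b.upper_end), tid))
        arcs.append(Arc(tid, qualified(*b.lower_begin)))
    return ColoredPetriNet(
        places=tuple(places),
        transitions=tuple(transitions),
        arcs=tuple(arcs),
        initial_marking=Marking.from_dict(marking),
        name="+".join(layer.id for layer in chain.layers),
    )


def extract_cluster(chain: HierarchyChain, kind: str):
    """Extract one information cluster from the whole chain, time-ordered.

    * ``"environment"`` — all logger readings on nodes and bridges, merged
      and sorted by timestamp, returned as a :class:`TemperatureProfile`
      (or ``None`` when the chain carries no environment readings);
    * ``"behavior"`` — the operation records of every layer in chain order;
    * ``"quality"`` — per-node quality attribute dicts, time-ordered.
    """
    if kind == "environment":
        readings: list[tuple[float, float]] = []
        missing: list[str] = []
        for layer in chain.layers:
            for node in layer.nodes:
                env = node.attributes.category("environment")
                if "readings" in env:
                    if node.timestamp_min is None and not env["readings"]:
                        missing.append(node.id)
                    readings.extend(env["readings"])
        for b in chain.bridges:
            readings.extend(b.readings)
        if missing:
            raise ValueError(f"nodes missing timestamps: {missing}")
        if not readings:
            return None
        readings.sort(key=lambda r: r[0])
        times = [t for t, _ in readings]
        temps = [T for _, T in readings]
        step_min = times[1] - times[0] if len(times) > 1 else 0.5
        bp = [t / 1440.0 for t in times] + [(times[-1] + step_min) / 1440.0]
        return TemperatureProfile(tuple(bp), tuple(temps),
                                  sampling_interval_s=step_min * 60.0)
    if kind == "behavior":
        ops: list[OperationRecord] = []
        for layer in chain.layers:
            ops.extend(sorted(layer.operations, key=lambda o: o.timestamp_min))
        return ops
    if kind == "quality":
        out = []
        missing = []
        for layer in chain.layers:
            for node in layer.nodes:
                q = {k: v for k, v in node.attributes.category("circulation").items()
                     if k.startswith("quality")}
                q.update({k: v for k, v in node.attributes.category("processing").items()
                          if k.startswith("quality")})
                if q:
                    if node.timestamp_min is None:
                        missing.append(node.id)
                    else:
                        out.append((node.timestamp_min, node.id, q))
        if missing:
            raise ValueError(f"nodes missing timestamps: {missing}")
        return [dict(node=nid, timestamp_min=ts, **q) for ts, nid, q in sorted(out)]
    raise ValueError(f"unknown cluster kind {kind!r}; expected behavior, environment or quality")
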