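"""PNML-subset reader/writer.

Supports the features the engine uses: places (with label, capacity, color
domain), transitions (with label and registered guard name), weighted arcs,
and an initial marking whose tokens carry colors and JSON-encoded content.
Capacities, colors and token payloads travel in ``<toolspecific>`` elements,
as PNML prescribes for tool extensions.  Round-trip is lossless for these
features; guard callables are restored by name from the guard registry.
"""

from __future__ import annotations

import json

from lxml import etree

from .petri import (Arc, ColoredPetriNet, Marking, Place, Token, Transition,
                    make_token)

_NS = "http://www.pnml.org/version-2009/grammar/pnml"
_TOOL = "coldchain"


def _text_child(parent, tag: str, text: str) -> None:
    el = etree.SubElement(parent, tag)
    sub = etree.SubElement(el, "text")
    sub.text = text


def net_to_pnml(net: ColoredPetriNet) -> bytes:
    root = etree.Element("pnml")
    net_el = etree.SubElement(root, "net", id=net.name, type=_NS)
    page = etree.SubElement(net_el, "page", id="page0")

    marking = net.initial_marking.as_dict()
    for p in net.places:
        p_el = etree.SubElement(page, "place", id=p.id)
        _text_child(p_el, "name", p.label)
        toks = marking.get(p.id, [])
        if toks:
            _text_child(p_el, "initialMarking", str(len(toks)))
        tool = etree.SubElement(p_el, "toolspecific", tool=_TOOL, version="1")
        spec = {
            "capacity": p.capacity,
            "color_domain": sorted(p.color_domain) if p.color_domain is not None else None,
            "tokens": [
                {"color": t.color, "content": t.content_dict, "lineage": list(t.lineage)}
                for t in toks
            ],
        }
        tool.text = json.dumps(spec)
    for t in net.transitions:
        t_el = etree.SubElement(page, "transition", id=t.id)
        _text_child(t_el, "name", t.label)
        if t.guard_name:
            tool = etree.SubElement(t_el, "toolspecific", tool=_TOOL, version="1")
            tool.text = json.dumps({"guard_name": t.guard_name})
    for i, a in enumerate(net.arcs):
        a_el = etree.SubElement(page, "arc", id=f"a{i}", source=a.source, target=a.target)
        _text_child(a_el, "inscription", str(a.weight))
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


def write_pnml(net: ColoredPetriNet, path) -> None:
    with open(path, "wb") as fh:
        fh.write(net_to_pnml(net))


def _get_text(el, tag: str, default: str = "") -> str:
    sub = el.find(f"{tag}/text")
    return sub.text if sub is not None and sub.text is not None else default


def _tool_spec(el) -> dict:
    for tool in el.findall("toolspecific"):
        if tool.get("tool") == _TOOL and tool.text:
            return json.loads(tool.text)
    return {}


def pnml_to_net(data: bytes) -> ColoredPetriNet:
    root = etree.fromstring(data)
    net_el = root.find("net")
    if net_el is None:
        raise ValueError("not a PNML document: missing <net>")
    name = net_el.get("id", "net")
    places, transitions, arcs = [], [], []
    marking: dict[str, list[Token]] = {}
    pages = net_el.findall("page") or [net_el]
    for page in pages:
        for p_el in page.findall("place"):
            spec = _tool_spec(p_el)
            dom = spec.get("color_domain")
            places.append(
                Place(
                    id=p_el.get("id"),
                    label=_get_text(p_el, "name"),
                    capacity=spec.get("capacity"),
                    color_domain=frozenset(dom) if dom is not None else None,
                )
            )
            toks = [
                make_token(t["color"], t.get("content", {}), t.get("lineage", []))
                for t in spec.get("tokens", [])
            ]
            if not toks:
                n = _get_text(p_el, "initialMarking", "0")
                toks = [make_token() for _ in range(int(n or 0))]
            if toks:
                marking[p_el.get("id")] = toks
        for t_el in page.findall("transition"):
            spec = _tool_spec(t_el)
            transitions.append(
                Transition(
                    id=t_el.get("id"),
                    label=_get_text(t_el, "name"),
                    guard_name=spec.get("guard_name"),
                )
            )
        for a_el in page.findall("arc"):
            weight = int(_get_text(a_el, "inscription", "1") or "1")
            arcs.append(Arc(a_el.get("source"), a_el.get("target"), weight))
    return ColoredPetriNet(
        places=tuple(places),
        transitions=tuple(transitions),
        arcs=tuple(arcs),
        initial_marking=Marking.from_dict(marking),
        name=name,
    )


def read_pnml(path) -> ColoredPetriNet:
    with open(path, "rb") as fh:
        return pnml_to_net(fh.read())
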