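"""Embedded tilapia cold-chain case fixtures.

Three logger grids record the temperature while the product crossed the
bridges between stages (EF: ship processing -> transportation, 10x10; GH:
transportation -> shore processing, 15x10; IJ: shore processing -> storage,
30x10).  Each grid prints ten logger columns (Tem.1 ... Tem.10); the reading
stream is taken column-major (all of Tem.1, then Tem.2, ...) because the
within-column sequences are smooth while rows jump between loggers.  Extrema
and counts are order-independent.

The stage tables (places, transitions, token relations) are exposed as
ready-made :class:`~coldchain.hierarchy.HierarchyLayer` objects and as the
assembled four-stage tilapia chain.  Token relations are printed only for the
storage and transportation stages; the two processing stages use a linear
backbone with time-temperature side outputs so that every listed place and
transition exists and the nets validate and run.
"""

from __future__ import annotations

from .hierarchy import (HierarchyChain, HierarchyLayer, MetaAttributes,
                        MetaNode, OperationRecord, build_chain)
from .petri import Arc, ColoredPetriNet, Marking, Place, Transition, make_token
from .profiles import TemperatureProfile

# --------------------------------------------------------------------------
# Bridge logger grids (degC; rows as printed, ten logger columns each)
# --------------------------------------------------------------------------

_EF_GRID = """
5.44 3 -0.94 -3.44 -3.19 -0.06 2.25 4 4.94 4.63
4.38 2 -1 -3.81 -3 0.25 2.38 4.13 5.06 4.63
3.81 0.13 -1.19 -3.87 -2.31 0.56 2.56 4.25 5.13 4.63
3.56 -0.12 -1.37 -4 -1.37 0.94 2.69 4.44 4.94 4.56
3.5 -0.5 -1.44 -4 -0.94 1.25 2.88 4.56 4.88 4.56
3.81 -0.5 -1.37 -4.06 -0.69 1.44 3.06 4.56 4.81 4.56
3.19 -0.5 -2.56 -3.56 -0.56 1.63 3.31 4.56 4.75 4.56
3.31 -0.56 -2.12 -3.12 -0.44 1.81 3.5 4.69 4.69 4.56
3.94 -0.69 -2.06 -4.37 -0.37 2 3.69 4.81 4.69 4.63
4.13 -0.81 -2.94 -3.62 -0.25 2.13 3.88 4.88 4.63 4.63
"""

_GH_GRID = """
5.63 5.44 5.06 4.81 8.75 4.94 4.06 17.94 17.63 20.75
5.63 5.38 5.06 4.88 8.94 4.88 4.06 18 17.81 21.25
5.63 5.38 5.06 4.88 8.94 4.81 4.13 18 20.44 19.63
5.63 5.38 5 4.88 9.94 4.69 4.13 17.88 18.63 19.13
5.63 5.31 5 4.88 10.31 4.63 4.19 17.63 18.31 18.88
5.63 5.31 5 4.94 9 4.56 4.25 17.44 18.31 24.13
5.63 5.25 5 4.94 9 4.5 23 17.38 18.38 -13
5.56 5.25 4.94 5 7.5 4.44 20.38 17.13 18.44 -16.69
5.56 5.25 4.94 5 6.63 4.38 17.5 17.13 18.69 -17.63
5.56 5.19 4.94 5 6.13 4.38 17.5 17 18.75 20.75
5.5 5.19 4.88 5.94 5.88 4.31 17.63 17.13 18.88 21.25
5.5 5.13 4.88 7.44 5.63 4.13 17.75 17.13 18.88 19.63
5.5 5.13 4.88 7.38 5.38 4.13 17.69 17.25 19.13 19.13
5.44 5.13 4.88 7.81 5.25 4.06 17.81 17.25 19.19 18.88
5.44 5.13 4.88 8.5 5.06 4.06 17.88 17.56 19.25 24.13
"""

_IJ_GRID = """
-17.25 -13.69 -11.31 -9.38 -7.75 -6.31 -5.13 -4.13 -3.25 -2.5
-17.13 -13.56 -11.25 -9.31 -7.69 -6.25 -5.13 -4.06 -3.19 -2.5
-16.94 -13.5 -11.19 -9.25 -7.63 -6.25 -5.06 -4.06 -3.19 -2.5
-16.81 -13.38 -11.13 -9.19 -7.63 -6.19 -5 -4 -3.13 -2.44
-16.69 -13.31 -11.06 -9.19 -7.56 -6.13 -5 -3.94 -3.13 -2.44
-16.56 -13.19 -11 -9.13 -7.5 -6.13 -4.94 -3.94 -3.13 -2.38
-16.44 -13.13 -10.94 -9.06 -7.44 -6.06 -4.94 -3.88 -3.06 -2.38
-16.31 -13.06 -10.81 -9 -7.44 -6 -4.88 -3.88 -3.06 -2.38
-16.19 -13 -10.75 -8.94 -7.31 -6 -4.81 -3.81 -3 -2.31
-16.06 -12.88 -10.69 -8.88 -7.31 -5.94 -4.81 -3.81 -3 -2.31
-15.94 -12.81 -10.63 -8.81 -7.25 -5.88 -4.75 -3.81 -3 -2.31
-15.81 -12.75 -10.56 -8.75 -7.19 -5.88 -4.75 -3.75 -2.94 -2.31
-15.69 -12.69 -10.5 -8.69 -7.19 -5.81 -4.69 -3.69 -2.94 -2.25
-15.63 -12.56 -10.44 -8.63 -7.13 -5.75 -4.69 -3.69 -2.88 -2.25
-15.5 -12.5 -10.38 -8.56 -7.06 -5.75 -4.63 -3.69 -2.88 -2.25
-15.38 -12.44 -10.31 -8.5 -7 -5.69 -4.63 -3.63 -2.81 -2.19
-15.25 -12.31 -10.25 -8.44 -7 -5.69 -4.56 -3.63 -2.81 -2.19
-15.13 -12.25 -10.19 -8.44 -6.94 -5.63 -4.5 -3.56 -2.81 -2.19
-15 -12.19 -10.13 -8.38 -6.88 -5.56 -4.5 -3.56 -2.75 -2.19
-14.88 -12.13 -10.06 -8.31 -6.81 -5.56 -4.44 -3.5 -2.75 -2.13
-14.75 -12 -10 -8.25 -6.75 -5.5 -4.44 -3.5 -2.75 -2.13
-14.63 -11.94 -9.94 -8.19 -6.75 -5.44 -4.38 -3.5 -2.69 -2.13
-14.5 -11.88 -9.88 -8.19 -6.69 -5.44 -4.38 -3.44 -2.69 -2.06
-14.44 -11.81 -9.81 -8.13 -6.63 -5.38 -4.31 -3.44 -2.69 -2.06
-14.31 -11.75 -9.75 -8.06 -6.63 -5.31 -4.31 -3.38 -2.63 -2.06
-14.19 -11.69 -9.69 -8 -6.56 -5.31 -4.25 -3.38 -2.63 -2
-14.13 -11.63 -9.63 -7.94 -6.5 -5.25 -4.25 -3.31 -2.63 -2
-14 -11.5 -9.56 -7.88 -6.44 -5.25 -4.19 -3.31 -2.56 -2
-13.88 -11.44 -9.5 -7.88 -6.44 -5.19 -4.19 -3.25 -2.56 -1.94
-13.75 -11.38 -9.44 -7.81 -6.38 -5.19 -4.13 -3.25 -2.5 -1.94
"""


def _parse_grid(text: str) -> tuple[tuple[float, ...], ...]:
    rows = []
    for line in text.strip().splitlines():
        rows.append(tuple(float(x) for x in line.split()))
    width = {len(r) for r in rows}
    assert len(width) == 1, "ragged grid"
    return tuple(rows)


def _column_major(grid) -> tuple[float, ...]:
    n_cols = len(grid[0])
    return tuple(grid[r][c] for c in range(n_cols) for r in range(len(grid)))


TEMPERATURE_GRIDS = {
    "EF": _parse_grid(_EF_GRID),
    "GH": _parse_grid(_GH_GRID),
    "IJ": _parse_grid(_IJ_GRID),
}

#: Column-major reading streams per bridge, degC, one reading per 30 s.
TEMPERATURE_READINGS = {k: _column_major(g) for k, g in TEMPERATURE_GRIDS.items()}

PROVENANCE = {
    "EF": "bridge EF logger grid (10 rows x 10 loggers): ship processing -> transportation handover, critical conditions",
    "GH": "bridge GH logger grid (15 rows x 10 loggers): transportation -> shore processing handover, critical conditions",
    "IJ": "bridge IJ logger grid (30 rows x 10 loggers): shore processing -> cold-store handover, critical conditions",
}

SAMPLING_INTERVAL_S = 30.0  # logger metadata; the source stream is stated only loosely


def bridge_profile(name: str, t0_d: float = 0.0) -> TemperatureProfile:
    """The named bridge's reading stream as a uniform temperature profile."""
    readings = TEMPERATURE_READINGS[name]
    return TemperatureProfile.from_readings(
        readings, interval_s=SAMPLING_INTERVAL_S, t0_d=t0_d,
        stage=f"bridge {name}", sensor_id=name)


# --------------------------------------------------------------------------
# Stage nets
# --------------------------------------------------------------------------

_CAP = 3  # per-place token bound used throughout the tilapia case


def _net(name, place_labels, transition_labels, flows, initial):
    """Build a capacity-bounded net from (id -> label) maps and arc flows."""
    places = tuple(Place(pid, lbl, capacity=_CAP) for pid, lbl in place_labels)
    transitions = tuple(Transition(tid, lbl) for tid, lbl in transition_labels)
    arcs = tuple(Arc(s, t) for s, t in flows)
    marking = Marking.from_dict(
        {pid: [make_token("product", {"node": pid}) for _ in range(n)]
         for pid, n in initial.items()})
    return ColoredPetriNet(places, transitions, arcs, marking, name=name)


_SHIP_PLACES = [
    ("P1", "Captured tilapia"), ("P2", "Delivered tilapia"),
    ("P3", "Unqualified tilapia after being inspected"),
    ("P4", "Qualified tilapia after being inspected"),
    ("P5", "A class tilapia"), ("P6", "B class tilapia"), ("P7", "C class tilapia"),
    ("P8", "Time-temperature data"), ("P9", "Tilapia being processed with CO"),
    ("P10", "Time-temperature data"), ("P11", "Bloodletting and disinfection of tilapia"),
    ("P12", "Time-temperature data"), ("P13", "Tilapia in the processing stage"),
]
_SHIP_TRANSITIONS = [
    ("T1", "Deliver tilapia to the factory"),
    ("T2", "Receiving inspection of raw materials"),
    ("T3", "Assorting tilapia according to different specifications"),
    ("T4", "CO processing"),
    ("T5", "Bloodletting and disinfection"),
    ("T6", "Delivering to the processing workshop"),
]
_SHIP_FLOWS = [
    ("P1", "T1"), ("T1", "P2"),
    ("P2", "T2"), ("T2", "P4"),
    ("P4", "T3"), ("T3", "P5"),
    ("P5", "T4"), ("T4", "P9"), ("T4", "P8"),
    ("P9", "T5"), ("T5", "P11"), ("T5", "P10"),
    ("P11", "T6"), ("T6", "P13"), ("T6", "P12"),
]

_TRANSPORT_PLACES = [
    ("P1", "Temperature sensors"), ("P2", "Await temperature sensors"),
    ("P3", "Await delivered tilapia"), ("P4", "Await delivered tilapia"),
    ("P5", "Time-temperature records"), ("P6", "Delivered tilapia"),
    ("P7", "Standard parameters of the temperature fluctuations"),
    ("P8", "Exceeding parameters of temperature fluctuations"),
    ("P9", "Regulated temperature"),
    ("P10", "Standard parameters of the temperature fluctuations"),
    ("P11", "Exceeding parameters of temperature fluctuations"),
    ("P13", "Qualified parameters of the standard temperature fluctuation"),
    ("P14", "Information communion center of the cold chain"),
    ("P15", "Quality parameters of inspection"), ("P16", "Qualified quality"),
    ("P17", "Tilapia delivered to the next stage"), ("P18", "Unqualified quality"),
    ("P19", "Urgent processed tilapia"), ("P20", "GPS system"),
    ("P21", "GPS system in holding stage"), ("P22", "Locating conditions of GPS"),
    ("P23", "Uploading GPS data"),
]
_TRANSPORT_TRANSITIONS = [
    ("T1", "Sensors are cleared and verified"), ("T2", "Truck loading"),
    ("T3", "Transportation"), ("T4", "Reading time-temperature data"),
    ("T5", "Examining temperature fluctuations"),
    ("T6", "Risk warning of temperature and launching regulation mechanism"),
    ("T7", "Examining temperature fluctuations"),
    ("T8", "Uploading time-temperature data"),
    ("T9", "Inspection after unloading"), ("T10", "Moving to the next stage"),
    ("T11", "Urgent processing"), ("T12", "Launched GPS"),
    ("T13", "Extracting information from the GPS"),
    ("T14", "Uploading GPS data to the information communion center"),
]
# printed token relations: T1 C(m1:m2), T2 C(m3:m4), T3 C(m21:m4,m5,m6,m22),
# T4 C(m5:m7), T5 C(m7,m8:m9,m13), T6 C(m9:m10), T7 C(m10:m11,m12->m13),
# T8 C(m13:m14), T9 C(m6,m15,m16:m18), T10 C(m16:m17), T11 C(m18:m19),
# T12 C(m20:m21), T13 C(m22:m23), T14 C(m23:m14); the table has no P12, the
# T7 output "m12" is read as the qualified-parameters place P13.
_TRANSPORT_FLOWS = [
    ("P1", "T1"), ("T1", "P2"),
    ("P3", "T2"), ("T2", "P4"),
    ("P21", "T3"), ("T3", "P4"), ("T3", "P5"), ("T3", "P6"), ("T3", "P22"),
    ("P5", "T4"), ("T4", "P7"),
    ("P7", "T5"), ("P8", "T5"), ("T5", "P9"), ("T5", "P13"),
    ("P9", "T6"), ("T6", "P10"),
    ("P10", "T7"), ("T7", "P11"), ("T7", "P13"),
    ("P13", "T8"), ("T8", "P14"),
    ("P6", "T9"), ("P15", "T9"), ("P16", "T9"), ("T9", "P18"),
    ("P16", "T10"), ("T10", "P17"),
    ("P18", "T11"), ("T11", "P19"),
    ("P20", "T12"), ("T12", "P21"),
    ("P22", "T13"), ("T13", "P23"),
    ("P23", "T14"), ("T14", "P14"),
]
# P20 holds three GPS tokens so that, under the document-order policy, the
# transportation cycle exhausts its capacity-bounded loop and a token survives
# at the end node P21 for the GH bridge to carry into the next stage.
_TRANSPORT_INITIAL = {"P1": 1, "P3": 1, "P8": 1, "P15": 1, "P16": 2, "P20": 3}

_SHORE_PLACES = [
    ("P1", "Unloading tilapia"), ("P2", "Time-temperature data"),
    ("P3", "Disinfected tilapia"), ("P4", "Time-temperature data"),
    ("P5", "Refrigerated tilapia"), ("P6", "Time-temperature data"),
    ("P7", "Disinfected tilapia"), ("P8", "Time-temperature data"),
    ("P9", "Tilapia being processed through 3 necessary steps"),
    ("P10", "Time-temperature data"), ("P11", "Skin of tilapia being removed"),
    ("P12", "Time-temperature data"), ("P13", "Classified tilapia"),
    ("P14", "Time-temperature data"), ("P15", "Washing tilapia"),
    ("P16", "Tilapia in individual packages"), ("P17", "Tilapias in bulk"),
    ("P18", "Time-temperature data"), ("P19", "Refrigerated tilapia"),
    ("P20", "Ice-glazed tilapia"), ("P21", "Weighting tilapia"),
    ("P22", "Tilapia in bulk"), ("P23", "Time-temperature data"),
    ("P24", "Vacuum packing tilapia"), ("P25", "Refrigerated tilapia"),
    ("P26", "Weighting tilapia"), ("P27", "Qualified tilapia after metal detection"),
    ("P28", "Packed tilapia"), ("P29", "Time-temperature data"),
    ("P30", "Tilapia in the storage stage"),
]
_SHORE_TRANSITIONS = [
    ("T1", "Disinfection of raw material inlets"),
    ("T2", "Refrigeration with crushed ice"), ("T3", "Disinfection"),
    ("T4", "3 steps of processing tilapias (skin removing, scaling and guts removing)"),
    ("T5", "Skin removing (shallow skin removing and deep skin removing)"),
    ("T6", "Classification"), ("T7", "Washing and disinfecting process"),
    ("T8", "Individual package"), ("T9", "In bulk"),
    ("T10", "Tilapias refrigerated in the individual quick freezing machine"),
    ("T11", "Ice glazing"), ("T12", "Weighting"),
    ("T13", "Packing in big plastic bag"), ("T14", "Vacuum packing"),
    ("T15", "Tilapias refrigerated in the individual quick freezing machine"),
    ("T16", "Weighting"), ("T17", "Metal detection"), ("T18", "Packing in cartons"),
    ("T19", "Being refrigerated in warehouse"),
]
# linear backbone with time-temperature side outputs (relations not printed)
_SHORE_FLOWS = [
    ("P1", "T1"), ("T1", "P3"), ("T1", "P2"),
    ("P3", "T2"), ("T2", "P5"), ("T2", "P4"),
    ("P5", "T3"), ("T3", "P7"), ("T3", "P6"),
    ("P7", "T4"), ("T4", "P9"), ("T4", "P8"),
    ("P9", "T5"), ("T5", "P11"), ("T5", "P10"),
    ("P11", "T6"), ("T6", "P13"), ("T6", "P12"),
    ("P13", "T7"), ("T7", "P15"), ("T7", "P14"),
    ("P15", "T8"), ("T8", "P16"),
    ("P15", "T9"), ("T9", "P17"),
    ("P16", "T10"), ("T10", "P19"), ("T10", "P18"),
    ("P19", "T11"), ("T11", "P20"),
    ("P20", "T12"), ("T12", "P21"),
    ("P21", "T13"), ("T13", "P22"),
    ("P22", "T14"), ("T14", "P24"), ("T14", "P23"),
    ("P24", "T15"), ("T15", "P25"),
    ("P25", "T16"), ("T16", "P26"),
    ("P26", "T17"), ("T17", "P27"),
    ("P27", "T18"), ("T18", "P28"), ("T18", "P29"),
    ("P28", "T19"), ("T19", "P30"),
]

_STORAGE_PLACES = [
    ("P1", "The first batch of tilapia"), ("P2", "The second batch of tilapia"),
    ("P3", "The third batch of tilapia"), ("P4", "Temperature sensors"),
    ("P5", "Time-temperature data"), ("P6", "Tilapia at the refrigeration stage"),
    ("P7", "Tilapia delivered from warehouse"),
    ("P8", "Standard parameters of temperature fluctuations"),
    ("P9", "Standardized temperature fluctuations"),
    ("P10", "Exceeding portion beyond the standard temperature fluctuations"),
    ("P11", "Regulated temperature"),
    ("P12", "Standard parameters of temperature fluctuations"),
    ("P13", "Information database of the cold chain"),
]
_STORAGE_TRANSITIONS = [
    ("T1", "Refrigeration in warehouse"),
    ("T2", "Delivering from warehouse on order"),
    ("T3", "Temperature examination"), ("T4", "Temperature regulation"),
    ("T5", "Uploading time-temperature data"), ("T6", "Temperature examination"),
]
# printed relations: T1 C(m1,m2,m3,m4:m5,m6), T2 C(m6:m7), T3 C(m5,m8:m9,m10),
# T4 C(m10:m11), T5 C(m9:m13), T6 C(m11:m9,m10,m12)
_STORAGE_FLOWS = [
    ("P1", "T1"), ("P2", "T1"), ("P3", "T1"), ("P4", "T1"),
    ("T1", "P5"), ("T1", "P6"),
    ("P6", "T2"), ("T2", "P7"),
    ("P5", "T3"), ("P8", "T3"), ("T3", "P9"), ("T3", "P10"),
    ("P10", "T4"), ("T4", "P11"),
    ("P9", "T5"), ("T5", "P13"),
    ("P11", "T6"), ("T6", "P9"), ("T6", "P10"), ("T6", "P12"),
]


def _meta_nodes(layer_id, place_labels, t0_min, step_min=2.0):
    nodes = []
    for i, (pid, lbl) in enumerate(place_labels):
        ts = t0_min + i * step_min
        env = None
        if "emperature data" in lbl or "emperature records" in lbl:
            env = {"medium": "air", "timestamp_min": ts}
        nodes.append(
            MetaNode(
                id=pid,
                attributes=MetaAttributes.build(
                    circulation={"stage": layer_id, "location": "cold chain",
                                 "supplier": "tilapia case"},
                    processing={"method": lbl, "timestamp_min": ts},
                    environment=env,
                ),
                layer=layer_id,
                role="internal",
            )
        )
    return nodes


def _with_roles(nodes, begin, end):
    out = []
    for n in nodes:
        role = "begin" if n.id == begin else ("end" if n.id == end else "internal")
        out.append(MetaNode(n.id, n.attributes, n.layer, role))
    return tuple(out)


def _operations(layer_id, transition_labels, t0_min, step_min=2.0):
    return tuple(
        OperationRecord(tid, lbl, layer_id, t0_min + i * step_min)
        for i, (tid, lbl) in enumerate(transition_labels)
    )


def _layer(layer_id, place_labels, transition_labels, flows, initial,
           begin, end, t0_min):
    net = _net(layer_id, place_labels, transition_labels, flows, initial)
    nodes = _with_roles(_meta_nodes(layer_id, place_labels, t0_min), begin, end)
    ops = _operations(layer_id, transition_labels, t0_min + 1.0)
    return HierarchyLayer(id=layer_id, subnet=net, begin_node=begin,
                          end_node=end, nodes=nodes, operations=ops)


def ship_processing_layer() -> HierarchyLayer:
    return _layer("ship_processing", _SHIP_PLACES, _SHIP_TRANSITIONS,
                  _SHIP_FLOWS, {"P1": 1}, "P1", "P13", t0_min=0.0)


def transportation_layer() -> HierarchyLayer:
    return _layer("transportation", _TRANSPORT_PLACES, _TRANSPORT_TRANSITIONS,
                  _TRANSPORT_FLOWS, _TRANSPORT_INITIAL, "P1", "P21", t0_min=600.0)


def shore_processing_layer() -> HierarchyLayer:
    return _layer("shore_processing", _SHORE_PLACES, _SHORE_TRANSITIONS,
                  _SHORE_FLOWS, {"P1": 1}, "P1", "P12", t0_min=1500.0)


def storage_layer() -> HierarchyLayer:
    return _layer("storage", _STORAGE_PLACES, _STORAGE_TRANSITIONS,
                  _STORAGE_FLOWS, {"P1": 1, "P2": 1, "P3": 1, "P4": 1, "P8": 1},
                  "P1", "P13", t0_min=3000.0)


#: Bridge logger streams start after the upper layer's node timestamps and
#: keep the printed order EF, GH, IJ (30 s = 0.5 min per reading).
_BRIDGE_T0_MIN = {"EF": 100.0, "GH": 900.0, "IJ": 2000.0}


def _bridge_readings(name: str) -> tuple[tuple[float, float], ...]:
    t0 = _BRIDGE_T0_MIN[name]
    return tuple((t0 + 0.5 * i, T) for i, T in enumerate(TEMPERATURE_READINGS[name]))


def tilapia_chain() -> HierarchyChain:
    """The four-stage tilapia chain with the printed bridge letters: the end
    node of each stage is wired to the begin node of the next via bridges
    EF (P13 -> P1), GH (P21 -> P1) and IJ (P12 -> P1)."""
    layers = [ship_processing_layer(), transportation_layer(),
              shore_processing_layer(), storage_layer()]
    return build_chain(
        layers,
        bridge_labels=["EF", "GH", "IJ"],
        bridge_readings=[_bridge_readings(n) for n in ("EF", "GH", "IJ")],
    )


_FIXTURES = {
    "EF": lambda: {
        "readings": TEMPERATURE_READINGS["EF"],
        "grid": TEMPERATURE_GRIDS["EF"],
        "provenance": PROVENANCE["EF"],
        "sampling_interval_s": SAMPLING_INTERVAL_S,
    },
    "GH": lambda: {
        "readings": TEMPERATURE_READINGS["GH"],
        "grid": TEMPERATURE_GRIDS["GH"],
        "provenance": PROVENANCE["GH"],
        "sampling_interval_s": SAMPLING_INTERVAL_S,
    },
    "IJ": lambda: {
        "readings": TEMPERATURE_READINGS["IJ"],
        "grid": TEMPERATURE_GRIDS["IJ"],
        "provenance": PROVENANCE["IJ"],
        "sampling_interval_s": SAMPLING_INTERVAL_S,
    },
    "ship_processing": ship_processing_layer,
    "transportation": transportation_layer,
    "shore_processing": shore_processing_layer,
    "storage": storage_layer,
    "tilapia_chain": tilapia_chain,
}


def load_fixture(name: str):
    """Load an embedded fixture by name; unknown names raise with the list of
    available fixtures."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return factory()


# --------------------------------------------------------------------------
# Quality / shelf-life calibration for the tilapia case
# --------------------------------------------------------------------------

#: Reference shelf lives, d, by holding temperature.  Only the 1.5 degC point
#: is an observed calibration value; the remaining rows are an illustrative
#: synthetic table for exercising interpolation, clearly not measurements.
TILAPIA_SL_TABLE = ((-2.0, 7.5), (0.0, 6.0), (1.5, 4.8), (5.0, 3.0), (10.0, 1.5))

#: Quality-decay anchors: quality 0.8 at 6 d, 0.2 at 24 d (a straight line
#: q(t) = 1 - t/30 through the five-band calibration).
TILAPIA_QUALITY_ANCHORS = ((6.0, 0.8), (24.0, 0.2))


def tilapia_quality_model():
    from .shelf_life import QualityModel

    return QualityModel(anchors=TILAPIA_QUALITY_ANCHORS,
                        sl_reference=TILAPIA_SL_TABLE)
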