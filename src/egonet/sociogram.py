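"""Sociogram export with the study's visual encoding, as GraphML or DOT.

Nodes carry the drawing attributes as plain strings/numbers — shape, colour,
a degree-proportional size, and a ``boxed`` flag — and rendering (layout,
actual pixels) is left to any GraphML or DOT consumer:

* shape: circle for injectable-contraceptive users, square for non-users;
* colour: red for the ego; alters by relationship to ego — pink for
  relatives and close friends, blue for close friends (when coded
  separately), black for co-workers, green for neighbours/acquaintances;
* size: strictly increasing in degree centrality;
* boxed: marks the actors with the top three betweenness values; no node is
  boxed when all betweenness values are equal (e.g. a complete network).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Set

from . import metrics as m
from .model import EgoNetwork

logger = logging.getLogger(__name__)

FORMATS = ("graphml", "dot")

DEFAULT_COLOR_MAP: Dict[str, str] = {
    "relative_or_close_friend": "pink",
    "close_friend": "blue",
    "co_worker": "black",
    "neighbour_or_acquaintance": "green",
}
EGO_COLOR = "red"
FALLBACK_COLOR = "grey"

#: node size = BASE + SCALE * degree, so size is monotone in degree.
SIZE_BASE = 10.0
SIZE_SCALE = 4.0


def boxed_actors(betweenness: Mapping[str, float], top: int = 3) -> Set[str]:
    """Ids of actors with the ``top`` highest betweenness values.

    Empty when every actor has the same value.  Actors sitting at the global
    minimum are never boxed (a box singles out *high* mediators; in a star,
    only the centre qualifies).  Ranking is by value then actor id; if a tie
    at the cut would exclude some equal-valued actors, all tied actors are
    included (and the widening is logged).
    """
    values = list(betweenness.values())
    if not values or max(values) == min(values):
        return set()
    floor = min(values)
    ranked = sorted(
        ((aid, val) for aid, val in betweenness.items() if val > floor),
        key=lambda kv: (-kv[1], kv[0]),
    )
    cutoff = ranked[min(top, len(ranked)) - 1][1]
    chosen = {aid for aid, val in ranked if val >= cutoff}
    if len(chosen) > top:
        logger.info(
            "betweenness tie at rank %d: boxing %d actors", top, len(chosen)
        )
    return chosen


def node_attributes(
    network: EgoNetwork,
    betweenness: Optional[Mapping[str, float]] = None,
    color_map: Optional[Mapping[str, str]] = None,
) -> Dict[str, Dict[str, object]]:
    """The per-node drawing attributes (shape, color, size, boxed, degree)."""
    color_map = dict(DEFAULT_COLOR_MAP if color_map is None else color_map)
    if betweenness is None:
        betweenness = (
            m.betweenness_normalized(network)
            if network.n_actors >= 3
            else {i: 0.0 for i in network.actor_ids}
        )
    boxed = boxed_actors(betweenness)
    degs = m.degrees(network)
    out: Dict[str, Dict[str, object]] = {}
    for actor in network.actors:
        if actor.role == "ego":
            color = EGO_COLOR
        else:
            color = color_map.get(actor.get("relationship") or "", FALLBACK_COLOR)
        out[actor.actor_id] = {
            "role": actor.role,
            "shape": "circle" if actor.get("cbdic_use") == "yes" else "square",
            "color": color,
            "size": SIZE_BASE + SIZE_SCALE * degs[actor.actor_id],
            "degree": degs[actor.actor_id],
            "betweenness_pct": float(betweenness[actor.actor_id]),
            "boxed": actor.actor_id in boxed,
        }
    return out


_GRAPHML_KEYS = [
    ("role", "string"),
    ("shape", "string"),
    ("color", "string"),
    ("size", "double"),
    ("degree", "int"),
    ("betweenness_pct", "double"),
    ("boxed", "boolean"),
]


def _write_graphml(network: EgoNetwork, attrs, path: Path) -> None:
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    for name, typ in _GRAPHML_KEYS:
        key = ET.SubElement(root, f"{{{ns}}}key")
        key.set("id", name)
        key.set("for", "node")
        key.set("attr.name", name)
        key.set("attr.type", typ)
    graph = ET.SubElement(root, f"{{{ns}}}graph")
    graph.set("id", network.label)
    graph.set("edgedefault", "undirected")
    for aid in network.actor_ids:
        node = ET.SubElement(graph, f"{{{ns}}}node")
        node.set("id", aid)
        for name, _ in _GRAPHML_KEYS:
            data = ET.SubElement(node, f"{{{ns}}}data")
            data.set("key", name)
            value = attrs[aid][name]
            data.text = str(value).lower() if isinstance(value, bool) else str(value)
    for idx, (a, b) in enumerate(sorted(network.ties)):
        edge = ET.SubElement(graph, f"{{{ns}}}edge")
        edge.set("id", f"e{idx}")
        edge.set("source", a)
        edge.set("target", b)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _write_dot(network: EgoNetwork, attrs, path: Path) -> None:
    lines = [f"graph {_dot_quote(network.label)} {{"]
    for aid in network.actor_ids:
        a = attrs[aid]
        # peripheries=2 draws the box around top-betweenness nodes
        shape = "circle" if a["shape"] == "circle" else "box"
        parts = [
            "shape=" + shape,
            "style=filled",
            "fillcolor=" + str(a["color"]),
            "width={:.2f}".format(a["size"] / 25.0),
            "peripheries={}".format(2 if a["boxed"] else 1),
            "tooltip=" + _dot_quote("degree={}".format(a["degree"])),
        ]
        lines.append(f"  {_dot_quote(aid)} [{', '.join(parts)}];")
    for a, b in sorted(network.ties):
        lines.append(f"  {_dot_quote(a)} -- {_dot_quote(b)};")
    lines.append("}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_sociogram(
    network: EgoNetwork,
    path: str | Path,
    fmt: str = "graphml",
    betweenness: Optional[Mapping[str, float]] = None,
    color_map: Optional[Mapping[str, str]] = None,
) -> Path:
    """Write one sociogram file; ``fmt`` is ``graphml`` or ``dot``."""
    fmt = fmt.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unsupported sociogram format {fmt!r}; use {FORMATS}")
    path = Path(path)
    attrs = node_attributes(network, betweenness=betweenness, color_map=color_map)
    if fmt == "graphml":
        _write_graphml(network, attrs, path)
    else:
        _write_dot(network, attrs, path)
    return path
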