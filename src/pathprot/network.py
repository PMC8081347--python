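"""Signed directed signaling-network model and SIF-like text I/O.

The central object is :class:`PathwayNetwork`: a directed graph of proteins
with activating (+1) or inhibiting (-1) edges, one receptor source node and
absorbing terminal states that encode the two possible Bcl-2 outcomes
(activation vs inhibition).  The packaged reference network is a curated
PI3K/AKT reconstruction downstream of the alpha7 nicotinic acetylcholine
receptor with 28 nodes, 43 interactions and 2 terminal states, including a
p53 module (MYC, BIM, TP53, BAX, NOXA, PUMA) that counteracts the Bcl-2
pro-survival branch.

File dialect: tab-separated ``source<TAB>relation<TAB>target`` lines with
relation in ``{activates, inhibits}``.  Optional header comments declare
roles and terminal polarities::

    #role CHRNA7 source
    #role BCL2_ACT terminal
    #polarity BCL2_INH -1

Without role headers, roles are inferred from the topology (in-degree 0 ->
source, out-degree 0 -> terminal).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "PathwayNode",
    "PathwayEdge",
    "PathwayNetwork",
    "ValidationReport",
    "NetworkParseError",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "validate_network",
    "depth_partition",
    "depth_strata",
    "reference_network",
]

SOURCE = "source"
INTERMEDIATE = "intermediate"
TERMINAL = "terminal"

_RELATIONS = {"activates": 1, "inhibits": -1}
_SIGN_TO_RELATION = {1: "activates", -1: "inhibits"}


class NetworkParseError(ValueError):
    """Malformed network file (carries the offending line number)."""


class NetworkValidationError(ValueError):
    """Structurally invalid network."""


@dataclass(frozen=True)
class PathwayNode:
    id: str
    label: str = ""
    role: str = INTERMEDIATE
    #: Terminal outcome polarity: +1 = activation state, -1 = inhibition
    #: state.  Ignored for non-terminal nodes.
    polarity: int = 1

    def __post_init__(self):
        if self.role not in (SOURCE, INTERMEDIATE, TERMINAL):
            raise NetworkValidationError(f"unknown role {self.role!r} for node {self.id!r}")
        if not self.label:
            object.__setattr__(self, "label", self.id)


@dataclass(frozen=True)
class PathwayEdge:
    source: str
    target: str
    sign: int


@dataclass
class PathwayNetwork:
    nodes: list[PathwayNode] = field(default_factory=list)
    edges: list[PathwayEdge] = field(default_factory=list)

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise NetworkValidationError(f"duplicate node ids: {sorted(dup)}")
        self._by_id = {n.id: n for n in self.nodes}

    # -- convenience accessors -------------------------------------------------
    def node(self, node_id: str) -> PathwayNode:
        return self._by_id[node_id]

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def sources(self) -> list[PathwayNode]:
        return [n for n in self.nodes if n.role == SOURCE]

    @property
    def terminals(self) -> list[PathwayNode]:
        return [n for n in self.nodes if n.role == TERMINAL]

    @property
    def source(self) -> PathwayNode:
        src = self.sources
        if len(src) != 1:
            raise NetworkValidationError(f"expected exactly one source node, found {len(src)}")
        return src[0]

    def out_edges(self, node_id: str) -> list[PathwayEdge]:
        return [e for e in self.edges if e.source == node_id]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, role=n.role, polarity=n.polarity)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def to_json(self) -> dict:
        return {"valid": self.valid, "violations": list(self.violations)}


def _infer_roles(node_ids: Iterable[str], edges: list[PathwayEdge],
                 declared: dict[str, str]) -> dict[str, str]:
    out_deg = Counter(e.source for e in edges)
    in_deg = Counter(e.target for e in edges)
    roles = {}
    for nid in node_ids:
        if nid in declared:
            roles[nid] = declared[nid]
        elif out_deg[nid] == 0:
            roles[nid] = TERMINAL
        elif in_deg[nid] == 0:
            roles[nid] = SOURCE
        else:
            roles[nid] = INTERMEDIATE
    return roles


def load_network(path: str | Path) -> PathwayNetwork:
    """Parse a SIF-like network file.

    Raises :class:`NetworkParseError` (with line number) on malformed lines
    or unknown relation tokens, and :class:`NetworkValidationError` on
    duplicate edges.
    """
    path = Path(path)
    declared_roles: dict[str, str] = {}
    polarity: dict[str, int] = {}
    edges: list[PathwayEdge] = []
    seen: set[tuple[str, str]] = set()
    order: list[str] = []

    def remember(nid: str) -> None:
        if nid not in order:
            order.append(nid)

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#role"):
            parts = line.split()
            if len(parts) != 3 or parts[2] not in (SOURCE, TERMINAL, INTERMEDIATE):
                raise NetworkParseError(f"{path.name}:{lineno}: malformed #role header: {line!r}")
            declared_roles[parts[1]] = parts[2]
            continue
        if line.startswith("#polarity"):
            parts = line.split()
            try:
                pol = int(parts[2])
            except (IndexError, ValueError):
                raise NetworkParseError(
                    f"{path.name}:{lineno}: malformed #polarity header: {line!r}") from None
            if len(parts) != 3 or pol not in (1, -1):
                raise NetworkParseError(f"{path.name}:{lineno}: polarity must be +1 or -1")
            polarity[parts[1]] = pol
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise NetworkParseError(
                f"{path.name}:{lineno}: expected 'source<TAB>relation<TAB>target', got {line!r}")
        src, rel, tgt = (f.strip() for f in fields)
        if rel not in _RELATIONS:
            raise NetworkParseError(
                f"{path.name}:{lineno}: unknown relation {rel!r} "
                f"(expected one of {sorted(_RELATIONS)})")
        if (src, tgt) in seen:
            raise NetworkValidationError(
                f"{path.name}:{lineno}: duplicate edge {src} -> {tgt}")
        seen.add((src, tgt))
        remember(src)
        remember(tgt)
        edges.append(PathwayEdge(src, tgt, _RELATIONS[rel]))

    roles = _infer_roles(order, edges, declared_roles)
    nodes = [PathwayNode(nid, role=roles[nid], polarity=polarity.get(nid, 1))
             for nid in order]
    return PathwayNetwork(nodes, edges)


def write_network(net: PathwayNetwork, path: str | Path) -> Path:
    """Serialize a network; ``load_network`` round-trips it up to ordering."""
    if not net.nodes or not net.edges:
        raise NetworkValidationError(
            "refusing to write an empty network: a pathway network needs at "
            "least one source and its terminal states")
    if not net.sources or not net.terminals:
        raise NetworkValidationError(
            "network must declare at least one source and one terminal state")
    path = Path(path)
    lines = []
    for n in net.nodes:
        if n.role in (SOURCE, TERMINAL):
            lines.append(f"#role {n.id} {n.role}")
    for n in net.terminals:
        lines.append(f"#polarity {n.id} {n.polarity:+d}")
    for e in net.edges:
        lines.append(f"{e.source}\t{_SIGN_TO_RELATION[e.sign]}\t{e.target}")
    path.write_text("\n".join(lines) + "\n")
    return path


def validate_network(net: PathwayNetwork) -> ValidationReport:
    """Coherence checks; an empty report means the network is valid."""
    v: list[str] = []
    pairs = Counter((e.source, e.target) for e in net.edges)
    for (s, t), c in sorted(pairs.items()):
        if c > 1:
            v.append(f"duplicate edge {s} -> {t} ({c} copies)")
    for e in net.edges:
        if e.sign not in (1, -1):
            v.append(f"edge {e.source} -> {e.target} has invalid sign {e.sign}")
        if e.source == e.target and net.node(e.source).role != TERMINAL:
            v.append(f"self-loop on non-terminal node {e.source}")

    out_deg = Counter(e.source for e in net.edges)
    deg = Counter()
    for e in net.edges:
        deg[e.source] += 1
        deg[e.target] += 1
    for n in net.nodes:
        if deg[n.id] == 0:
            v.append(f"orphan node {n.id} (no incident edges)")
        if n.role == TERMINAL and out_deg[n.id] > 0:
            v.append(f"terminal node {n.id} has outgoing edges")
        if n.role != TERMINAL and out_deg[n.id] == 0:
            v.append(f"non-terminal node {n.id} has out-degree 0")

    srcs = net.sources
    if not srcs:
        v.append("no source node declared or inferable")
    else:
        g = net.to_networkx()
        reachable = set()
        for s in srcs:
            reachable |= {s.id} | nx.descendants(g, s.id)
        for t in net.terminals:
            if t.id not in reachable:
                v.append(f"terminal node {t.id} unreachable from source")
    return ValidationReport(v)


def depth_partition(net: PathwayNetwork, source: str | None = None) -> dict[str, int]:
    """Shortest-path depth of every node from the source.

    Raises :class:`NetworkValidationError` naming any unreachable node.
    Shortest (not longest) paths keep the partition well defined on cyclic
    networks.
    """
    src = source if source is not None else net.source.id
    if src not in net._by_id:
        raise NetworkValidationError(f"source node {src!r} not in network")
    g = net.to_networkx()
    depths = nx.single_source_shortest_path_length(g, src)
    missing = sorted(set(net.node_ids) - set(depths))
    if missing:
        raise NetworkValidationError(f"nodes unreachable from {src}: {missing}")
    return {nid: depths[nid] for nid in net.node_ids}


def depth_strata(depths: dict[str, int]) -> list[list[str]]:
    """Group node ids into consecutive depth strata (index = depth)."""
    max_d = max(depths.values())
    strata: list[list[str]] = [[] for _ in range(max_d + 1)]
    for nid, d in depths.items():
        strata[d].append(nid)
    return strata


def reference_network() -> PathwayNetwork:
    """The packaged PI3K/AKT reference reconstruction (28 nodes, 43 edges)."""
    ref = resources.files("pathprot.data") / "pi3k_akt_reference.sif"
    with resources.as_file(ref) as p:
        return load_network(p)
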