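"""Signed, weighted, provenance-tagged directed regulatory networks.

The data model is deliberately small: molecular nodes carrying a metabolic
role and an optional UniProt accession, and directed edges that either
activate or inhibit their target.  Two plain-text dialects are supported:

* ``sif3`` — three whitespace-separated columns ``source sign target`` with
  sign tokens ``+`` / ``-``.  Lossy: weights, provenance, roles are dropped.
* ``tsv_extended`` — a tab-separated edge table with header
  ``source sign target weight provenance mutable`` followed by an optional
  ``#nodes`` section (``id role accession``).  Lossless round-trip format.
"""

from __future__ import annotations

import dataclasses
import enum
import re
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "Sign",
    "Role",
    "Provenance",
    "Node",
    "Edge",
    "RegulatoryNetwork",
    "ValidationReport",
    "MergeReport",
    "NetworkError",
    "NetworkParseError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "merge_networks",
    "validate_network",
    "canonical_id",
    "NAME_ALIASES",
]

#: UniProt accession pattern (release-stable form, 6 or 10 characters).
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)

DIALECTS = ("sif3", "tsv_extended")


class NetworkError(Exception):
    """Base class for network-model errors."""


class NetworkParseError(NetworkError):
    """Raised when a network file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NetworkValidationError(NetworkError):
    """Raised when a structural invariant is violated."""


class Sign(str, enum.Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"

    @property
    def token(self) -> str:
        return "+" if self is Sign.ACTIVATION else "-"

    @classmethod
    def from_token(cls, token: str) -> "Sign":
        if token == "+":
            return cls.ACTIVATION
        if token == "-":
            return cls.INHIBITION
        raise ValueError(f"unknown sign token {token!r} (expected '+' or '-')")


class Role(str, enum.Enum):
    PRO_INFLAMMATORY = "pro_inflammatory"
    ANTI_INFLAMMATORY = "anti_inflammatory"
    GROWTH_FACTOR = "growth_factor"
    DEGRADING_ENZYME = "degrading_enzyme"
    STRUCTURAL_PROTEIN = "structural_protein"
    PAIN_RELATED = "pain_related"
    APOPTOSIS_RELATED = "apoptosis_related"
    OTHER = "other"


class Provenance(str, enum.Enum):
    LITERATURE = "literature"
    ENRICHMENT = "enrichment"
    OPTIMIZED = "optimized"
    SYNTHETIC = "synthetic"


#: Common display names mapped to canonical, file-safe node tokens.
NAME_ALIASES = {
    "IL-1β": "IL1B", "IL-1b": "IL1B", "IL1b": "IL1B", "IL-1B": "IL1B",
    "TNF-α": "TNFA", "TNF-a": "TNFA", "TNFa": "TNFA", "TNF": "TNFA",
    "IL-6": "IL6", "IL-8": "IL8", "IL-17": "IL17", "IL-18": "IL18",
    "IL-4": "IL4", "IL-10": "IL10", "IL-13": "IL13",
    "IFN-γ": "IFNG", "IFN-g": "IFNG", "IFNg": "IFNG",
    "TGF-β": "TGFB", "TGF-b": "TGFB", "TGFb": "TGFB", "TGFB1": "TGFB",
    "FGF-2": "FGF2", "BMP-2": "BMP2", "IGF-1": "IGF1", "IGF_1": "IGF1",
    "MMP-1": "MMP1", "MMP-3": "MMP3", "MMP-13": "MMP13",
    "ADAMTS4": "ADAMTS", "ADAMTs": "ADAMTS",
    "TIMP1": "TIMP", "COL2A1": "COL2A", "VEGFA": "VEGF",
    "PGE-2": "PGE2", "PEG2": "PGE2",
}


def canonical_id(name: str) -> str:
    """Map a display name (possibly with dashes/Greek letters) to its token."""
    name = name.strip()
    if name in NAME_ALIASES:
        return NAME_ALIASES[name]
    cleaned = name.replace("β", "B").replace("α", "A").replace("γ", "G")
    cleaned = cleaned.replace("-", "").replace("_", "").upper()
    return NAME_ALIASES.get(cleaned, cleaned)


@dataclasses.dataclass
class Node:
    """A molecular species (cytokine, enzyme, structural protein, ...)."""

    id: str
    role: Role = Role.OTHER
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("node id must be non-empty")
        if isinstance(self.role, str) and not isinstance(self.role, Role):
            self.role = Role(self.role)
        if self.accession is not None and not _UNIPROT_RE.match(self.accession):
            raise NetworkValidationError(
                f"node {self.id!r}: accession {self.accession!r} is not a "
                "valid UniProt identifier"
            )


@dataclasses.dataclass
class Edge:
    """A signed regulatory interaction ``source -> target``.

    ``weight`` is the activator weight (alpha) for activating edges and the
    inhibitor weight (beta) for inhibiting edges; both default to 1.
    ``mutable`` marks the edge as eligible for removal during calibration.
    """

    source: str
    target: str
    sign: Sign
    weight: float = 1.0
    provenance: Provenance = Provenance.LITERATURE
    mutable: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.sign, str) and not isinstance(self.sign, Sign):
            self.sign = Sign(self.sign)
        if isinstance(self.provenance, str) and not isinstance(self.provenance, Provenance):
            self.provenance = Provenance(self.provenance)
        self.weight = float(self.weight)
        if self.weight <= 0:
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: weight must be > 0, "
                f"got {self.weight}"
            )

    @property
    def key(self) -> tuple:
        return (self.source, self.target, self.sign)


@dataclasses.dataclass
class ValidationReport:
    errors: list = dataclasses.field(default_factory=list)
    warnings: list = dataclasses.field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def empty(self) -> bool:
        return not self.errors and not self.warnings


@dataclasses.dataclass
class MergeReport:
    added: list = dataclasses.field(default_factory=list)
    conflicts: list = dataclasses.field(default_factory=list)


class RegulatoryNetwork:
    """Directed signed graph over :class:`Node` and :class:`Edge`.

    Node insertion order is preserved and defines the state-vector ordering
    used by the dynamics layer, so it is deterministic for a given
    construction sequence (e.g. file order).
    """

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[Edge] = ()):
        self._nodes: dict[str, Node] = {}
        self._edges: list[Edge] = []
        self._edge_keys: set = set()
        for node in nodes:
            self.add_node(node)
        for edge in edges:
            self.add_edge(edge)

    # -- construction -------------------------------------------------
    def add_node(self, node: Node) -> Node:
        if node.id in self._nodes:
            existing = self._nodes[node.id]
            if existing != node:
                raise NetworkValidationError(f"duplicate node id {node.id!r}")
            return existing
        self._nodes[node.id] = node
        return node

    def add_edge(self, edge: Edge, declare_nodes: bool = True) -> Edge:
        if edge.key in self._edge_keys:
            raise NetworkValidationError(
                f"duplicate edge {edge.source} {edge.sign.token} {edge.target}"
            )
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._nodes:
                if not declare_nodes:
                    raise NetworkValidationError(
                        f"edge references undeclared node {endpoint!r}"
                    )
                self.add_node(Node(endpoint))
        self._edges.append(edge)
        self._edge_keys.add(edge.key)
        return edge

    def remove_edge(self, edge: Edge) -> None:
        self._edges.remove(edge)
        self._edge_keys.discard(edge.key)

    # -- access --------------------------------------------------------
    @property
    def nodes(self) -> tuple:
        return tuple(self._nodes.values())

    @property
    def node_ids(self) -> tuple:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple:
        return tuple(self._edges)

    def node(self, node_id: str) -> Node:
        return self._nodes[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge_key(self, source: str, target: str, sign: Sign) -> bool:
        return (source, target, sign) in self._edge_keys

    def regulators(self, target: str):
        """Return ``(activators, inhibitors)`` as lists of ``(source, weight)``."""
        activators, inhibitors = [], []
        for edge in self._edges:
            if edge.target != target:
                continue
            if edge.sign is Sign.ACTIVATION:
                activators.append((edge.source, edge.weight))
            else:
                inhibitors.append((edge.source, edge.weight))
        return activators, inhibitors

    def in_degree(self, node_id: str) -> int:
        return sum(1 for e in self._edges if e.target == node_id)

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            (dataclasses.replace(n) for n in self._nodes.values()),
            (dataclasses.replace(e) for e in self._edges),
        )

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        mine = sorted(dataclasses.astuple(e) for e in self._edges)
        theirs = sorted(dataclasses.astuple(e) for e in other._edges)
        return self._nodes == other._nodes and mine == theirs

    def __repr__(self) -> str:
        return (
            f"<RegulatoryNetwork {len(self._nodes)} nodes, "
            f"{len(self._edges)} edges>"
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_network(net: RegulatoryNetwork) -> ValidationReport:
    """Structural audit: errors break the model, warnings are biology flags.

    Opposite-sign parallel edges and self-loops are *reported*, never
    forbidden — ambivalent regulators and autocrine signaling are both real.
    """
    report = ValidationReport()
    node_ids = set(net.node_ids)
    targets = {e.target for e in net.edges}
    for edge in net.edges:
        for endpoint in (edge.source, edge.target):
            if endpoint not in node_ids:
                report.errors.append(f"dangling reference: {endpoint}")
    seen_pairs: dict[tuple, set] = {}
    for edge in net.edges:
        seen_pairs.setdefault((edge.source, edge.target), set()).add(edge.sign)
        if edge.source == edge.target:
            report.warnings.append(f"self-loop: {edge.source}")
    for (source, target), signs in seen_pairs.items():
        if len(signs) == 2:
            report.warnings.append(
                f"opposite-sign duplicate pair: {source} -> {target}"
            )
    for node_id in net.node_ids:
        if node_id not in targets:
            report.warnings.append(f"no incoming edges: {node_id}")
    return report


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_network(path, dialect: str = "sif3") -> RegulatoryNetwork:
    """Parse an edge-list file into a validated network.

    The node set is the union of all edge endpoints plus any explicit node
    declarations; missing roles default to ``other``, missing weights to 1.
    """
    _check_dialect(dialect)
    text = Path(path).read_text()
    if dialect == "sif3":
        return _read_sif3(text)
    return _read_tsv_extended(text)


def _read_sif3(text: str) -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 3:
            raise NetworkParseError(
                f"expected 'source sign target', got {line!r}", line=lineno
            )
        source, token, target = fields
        try:
            sign = Sign.from_token(token)
        except ValueError as exc:
            raise NetworkParseError(str(exc), line=lineno) from None
        try:
            net.add_edge(Edge(source, target, sign))
        except NetworkValidationError as exc:
            raise NetworkParseError(str(exc), line=lineno) from None
    return net


_TSV_HEADER = "source\tsign\ttarget\tweight\tprovenance\tmutable"
_NODE_HEADER = "id\trole\taccession"


def _read_tsv_extended(text: str) -> RegulatoryNetwork:
    lines = text.splitlines()
    net = RegulatoryNetwork()
    section = "edges"
    header_seen = False
    node_header_seen = False
    node_table_mode = False
    pending_edges: list[tuple[int, Edge]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.strip() == "#nodes":
            section = "nodes"
            node_table_mode = True
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if section == "edges":
            if not header_seen:
                if [f.strip() for f in fields] != _TSV_HEADER.split("\t"):
                    raise NetworkParseError(
                        f"expected header {_TSV_HEADER!r}", line=lineno
                    )
                header_seen = True
                continue
            if len(fields) != 6:
                raise NetworkParseError(
                    f"expected 6 tab-separated fields, got {len(fields)}",
                    line=lineno,
                )
            source, token, target, weight, provenance, mutable = (
                f.strip() for f in fields
            )
            try:
                edge = Edge(
                    source,
                    target,
                    Sign.from_token(token),
                    weight=float(weight) if weight else 1.0,
                    provenance=Provenance(provenance) if provenance else Provenance.LITERATURE,
                    mutable=mutable in ("1", "true", "True", ""),
                )
            except (ValueError, NetworkValidationError) as exc:
                raise NetworkParseError(str(exc), line=lineno) from None
            pending_edges.append((lineno, edge))
        else:
            if not node_header_seen:
                if [f.strip() for f in fields] != _NODE_HEADER.split("\t"):
                    raise NetworkParseError(
                        f"expected node header {_NODE_HEADER!r}", line=lineno
                    )
                node_header_seen = True
                continue
            if len(fields) != 3:
                raise NetworkParseError(
                    f"expected 3 tab-separated node fields, got {len(fields)}",
                    line=lineno,
                )
            node_id, role, accession = (f.strip() for f in fields)
            try:
                net.add_node(
                    Node(
                        node_id,
                        role=Role(role) if role else Role.OTHER,
                        accession=accession or None,
                    )
                )
            except (ValueError, NetworkValidationError) as exc:
                raise NetworkParseError(str(exc), line=lineno) from None
    for lineno, edge in pending_edges:
        try:
            net.add_edge(edge, declare_nodes=not node_table_mode)
        except NetworkValidationError as exc:
            raise NetworkValidationError(f"line {lineno}: {exc}") from None
    return net


def _format_weight(weight: float) -> str:
    return format(weight, ".17g")


def write_network(net: RegulatoryNetwork, path, dialect: str = "tsv_extended") -> None:
    """Serialize a network; ``tsv_extended`` round-trips exactly, ``sif3``
    keeps topology and signs only."""
    _check_dialect(dialect)
    lines: list[str] = []
    if dialect == "sif3":
        for edge in net.edges:
            lines.append(f"{edge.source} {edge.sign.token} {edge.target}")
    else:
        lines.append(_TSV_HEADER)
        for edge in net.edges:
            lines.append(
                "\t".join(
                    (
                        edge.source,
                        edge.sign.token,
                        edge.target,
                        _format_weight(edge.weight),
                        edge.provenance.value,
                        "1" if edge.mutable else "0",
                    )
                )
            )
        lines.append("#nodes")
        lines.append(_NODE_HEADER)
        for node in net.nodes:
            lines.append(
                "\t".join((node.id, node.role.value, node.accession or ""))
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Merge / enrichment
# ---------------------------------------------------------------------------

CONFLICT_POLICIES = ("keep_both", "prefer_base", "prefer_addition")


def merge_networks(
    base: RegulatoryNetwork,
    addition: RegulatoryNetwork,
    conflict_policy: str = "keep_both",
):
    """Union of two networks; returns ``(network, MergeReport)``.

    Edges only present in ``addition`` are tagged with provenance
    ``enrichment``.  When the same (source, target) pair carries opposite
    signs in the two inputs, ``conflict_policy`` decides and the conflict is
    reported either way.
    """
    if conflict_policy not in CONFLICT_POLICIES:
        raise ValueError(
            f"conflict_policy must be one of {CONFLICT_POLICIES}, "
            f"got {conflict_policy!r}"
        )
    result = base.copy()
    report = MergeReport()
    for node in addition.nodes:
        if not result.has_node(node.id):
            result.add_node(dataclasses.replace(node))
    for edge in addition.edges:
        if result.has_edge_key(edge.source, edge.target, edge.sign):
            continue  # duplicate triple collapses onto the base edge
        opposite = (
            Sign.INHIBITION if edge.sign is Sign.ACTIVATION else Sign.ACTIVATION
        )
        conflicting = base.has_edge_key(edge.source, edge.target, opposite)
        incoming = dataclasses.replace(edge, provenance=Provenance.ENRICHMENT)
        if conflicting:
            report.conflicts.append((edge.source, edge.target))
            if conflict_policy == "prefer_base":
                continue
            if conflict_policy == "prefer_addition":
                for existing in list(result.edges):
                    if (
                        existing.source == edge.source
                        and existing.target == edge.target
                        and existing.sign is opposite
                    ):
                        result.remove_edge(existing)
        result.add_edge(incoming)
        report.added.append(incoming)
    return result, report
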