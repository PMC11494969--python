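"""Typed two-time-slice network representation, structural constraints, and I/O.

A two-time-slice Bayesian network (2TBN) places every measured entity at two
adjacent time points (slice 0 = current, slice 1 = next).  Edges are either
*intra* (lag 0, within a slice) or *inter* (lag 1, across slices).  Which
edges a structure learner may even consider is governed by a typed permission
table (the "skeleton"): within a time point taxa may drive gene expression and
genes may drive metabolite concentrations, while metabolites feed back on
taxon abundances only in the next time point; every entity may carry a
self-loop to its own next-slice copy.  An "augmented" variant additionally
permits same-slice taxon -> metabolite edges, to cover metabolite production
that gene profiling fails to capture.

Networks learned from reduced omic subsets (e.g., taxa only) cannot contain
the intermediate layers, so their skeletons *bridge* the missing layers: a
taxon -> taxon inter edge stands in for the collapsed
taxon -> gene -> metabolite -> taxon chain.  :func:`derive_subset_skeleton`
performs that collapse mechanically on the type graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import yaml

from .errors import InvalidLagError, NetworkFormatError

OMIC_TYPES: tuple[str, ...] = ("taxon", "gene", "metabolite", "clinical")

#: Omic-layer letter codes used in subset labels.
LAYER_CODES: Mapping[str, str] = {"T": "taxon", "G": "gene", "M": "metabolite"}

SUBSET_LABELS: tuple[str, ...] = ("T", "G", "M", "TG", "TM", "GM", "TGM")

SKELETON_VARIANTS: tuple[str, ...] = ("skeleton", "augmented")


def subset_types(label: str) -> frozenset[str]:
    """Omic layers covered by a subset label (clinical variables excluded).

    >>> sorted(subset_types("TM"))
    ['metabolite', 'taxon']
    """
    if label not in SUBSET_LABELS:
        raise ValueError(f"unknown subset label {label!r}; expected one of {SUBSET_LABELS}")
    return frozenset(LAYER_CODES[c] for c in label)


def allowed_entity_types(label: str) -> frozenset[str]:
    """Entity types that may appear in a network with this subset label.

    Clinical variables ride along with every subset.
    """
    return subset_types(label) | {"clinical"}


@dataclass(frozen=True, order=True)
class EntityRef:
    """A named biological variable with an omic type.

    The (name, omic_type) pair is the unit of identity across networks;
    comparison is case-sensitive exact match.
    """

    name: str
    omic_type: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("entity name must be non-empty")
        if self.omic_type not in OMIC_TYPES:
            raise ValueError(f"unknown omic type {self.omic_type!r}")


@dataclass(frozen=True, order=True)
class NodeRef:
    """An entity placed at one of the two slices (0 = current, 1 = next)."""

    entity: EntityRef
    slice: int

    def __post_init__(self):
        if self.slice not in (0, 1):
            raise ValueError(f"slice must be 0 or 1, got {self.slice}")


@dataclass(frozen=True)
class Edge:
    """A directed, weighted edge with a bootstrap confidence score.

    ``weight`` is the signed regression coefficient of the source in the
    destination's conditional model; ``bootstrap_score`` is the fraction of
    bootstrap repetitions in which the edge was learned.
    """

    src: NodeRef
    dst: NodeRef
    weight: float
    bootstrap_score: float = 1.0

    def __post_init__(self):
        if self.lag not in (0, 1):
            raise InvalidLagError(
                f"edge lag must be 0 or 1, got {self.lag} "
                f"({self.src.entity.name}@{self.src.slice} -> {self.dst.entity.name}@{self.dst.slice})"
            )
        if not 0.0 <= self.bootstrap_score <= 1.0:
            raise ValueError(f"bootstrap_score must lie in [0, 1], got {self.bootstrap_score}")

    @property
    def lag(self) -> int:
        return self.dst.slice - self.src.slice

    @property
    def is_self_loop(self) -> bool:
        return self.src.entity == self.dst.entity and self.lag == 1


class TwoSliceNetwork:
    """Directed weighted graph over entities at slices t and t+1.

    ``subset_label`` records which omic subset the network was learned from
    ({T, G, M, TG, TM, GM, TGM}); at most one edge per (src, dst) node pair.
    """

    def __init__(self, subset_label: str, edges: Iterable[Edge] = (), metadata: dict | None = None):
        if subset_label not in SUBSET_LABELS:
            raise ValueError(f"unknown subset label {subset_label!r}")
        self.subset_label = subset_label
        self.metadata: dict = dict(metadata or {})
        self._edges: dict[tuple[NodeRef, NodeRef], Edge] = {}
        self._nodes: set[NodeRef] = set()
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: NodeRef) -> None:
        self._nodes.add(node)

    def add_edge(self, edge: Edge) -> None:
        key = (edge.src, edge.dst)
        if key in self._edges:
            raise ValueError(
                f"duplicate edge {edge.src.entity.name}@{edge.src.slice} -> "
                f"{edge.dst.entity.name}@{edge.dst.slice}"
            )
        allowed = allowed_entity_types(self.subset_label)
        for node in key:
            if node.entity.omic_type not in allowed:
                raise ValueError(
                    f"entity {node.entity.name!r} of type {node.entity.omic_type!r} is not "
                    f"consistent with subset label {self.subset_label!r}"
                )
        self._edges[key] = edge
        self._nodes.update(key)

    @property
    def nodes(self) -> frozenset[NodeRef]:
        return frozenset(self._nodes)

    @property
    def edges(self) -> list[Edge]:
        """Edges in a deterministic (sorted) order."""
        return [self._edges[k] for k in sorted(self._edges, key=_edge_sort_key)]

    def get_edge(self, src: NodeRef, dst: NodeRef) -> Edge | None:
        return self._edges.get((src, dst))

    def entities(self) -> list[EntityRef]:
        return sorted({n.entity for n in self._nodes})

    def __len__(self) -> int:
        return len(self._edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TwoSliceNetwork):
            return NotImplemented
        return (
            self.subset_label == other.subset_label
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return f"TwoSliceNetwork({self.subset_label!r}, {len(self._edges)} edges, {len(self._nodes)} nodes)"


def _edge_sort_key(key: tuple[NodeRef, NodeRef]):
    src, dst = key
    return (src.entity.name, src.entity.omic_type, src.slice, dst.entity.name, dst.entity.omic_type, dst.slice)


# ---------------------------------------------------------------------------
# Skeleton constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SkeletonConstraint:
    """Permission table (source type, destination type, lag) -> allowed.

    The table is total over all type pairs and both lags.  Same-entity
    self-loops at lag 1 are always allowed regardless of the table.
    """

    variant: str
    subset_label: str
    allowed: Mapping[tuple[str, str, int], bool] = field(hash=False)

    def __post_init__(self):
        if self.variant not in SKELETON_VARIANTS:
            raise ValueError(f"unknown skeleton variant {self.variant!r}")
        for t1, t2 in itertools.product(OMIC_TYPES, repeat=2):
            for lag in (0, 1):
                if (t1, t2, lag) not in self.allowed:
                    raise ValueError(f"permission table is missing entry ({t1}, {t2}, {lag})")


def is_allowed_edge(
    constraint: SkeletonConstraint,
    src_type: str,
    dst_type: str,
    lag: int,
    is_self: bool = False,
) -> bool:
    """Whether the skeleton permits an edge of this type signature.

    Self-loops (same entity, lag 1) are always allowed, for every omic type.
    """
    if lag not in (0, 1):
        raise InvalidLagError(f"lag must be 0 or 1, got {lag}")
    if is_self and lag == 1 and src_type == dst_type:
        return True
    return constraint.allowed[(src_type, dst_type, lag)]


def _type_graph(variant: str) -> set[tuple[str, str, int]]:
    """The lag-labeled omic-type interaction graph of the full TGM skeleton."""
    edges = {
        ("taxon", "gene", 0),        # taxa express genes they carry
        ("gene", "metabolite", 0),   # genes synthesize/consume metabolites
        ("metabolite", "taxon", 1),  # metabolites shape growth at the next step
    }
    if variant == "augmented":
        edges.add(("taxon", "metabolite", 0))
    # Clinical covariates may act on anything at the next time point, but
    # nothing feeds into them (they are externally set).
    for t in OMIC_TYPES:
        edges.add(("clinical", t, 1))
    return edges


def derive_subset_skeleton(variant: str, subset_label: str) -> SkeletonConstraint:
    """Adapt the typed skeleton to a reduced omic subset by bridging absent layers.

    An edge ``src -> dst`` at lag L is permitted in the reduced table iff the
    full TGM type graph contains a path from src to dst whose intermediate
    types are all *absent* from the subset and whose lags sum to L.  For the
    full TGM subset no layer is absent, so the table equals the stated
    skeleton (or augmented) exactly; for the taxa-only subset the collapsed
    taxon -> gene -> metabolite -> taxon chain yields a taxon -> taxon inter
    edge, and so on.
    """
    if variant not in SKELETON_VARIANTS:
        raise ValueError(f"unknown skeleton variant {variant!r}")
    present = allowed_entity_types(subset_label)
    absent = set(OMIC_TYPES) - present
    graph = _type_graph(variant)

    def bridged(src: str, dst: str, lag: int) -> bool:
        # DFS over type paths whose intermediates are absent layers.
        stack = [(src, 0, frozenset())]
        while stack:
            here, acc, seen = stack.pop()
            for a, b, l in graph:
                if a != here or acc + l > lag:
                    continue
                if b == dst and acc + l == lag:
                    return True
                if b in absent and b not in seen:
                    stack.append((b, acc + l, seen | {b}))
        return False

    allowed: dict[tuple[str, str, int], bool] = {}
    for t1, t2 in itertools.product(OMIC_TYPES, repeat=2):
        for lag in (0, 1):
            ok = t1 in present and t2 in present and bridged(t1, t2, lag)
            allowed[(t1, t2, lag)] = ok
    return SkeletonConstraint(variant=variant, subset_label=subset_label, allowed=allowed)


@dataclass(frozen=True)
class Violation:
    """An edge whose type signature the skeleton disallows."""

    edge: Edge
    reason: str


def validate_network(net: TwoSliceNetwork, constraint: SkeletonConstraint) -> list[Violation]:
    """Return every edge whose (src type, dst type, lag) is disallowed."""
    out: list[Violation] = []
    for e in net.edges:
        src_t, dst_t = e.src.entity.omic_type, e.dst.entity.omic_type
        if not is_allowed_edge(constraint, src_t, dst_t, e.lag, is_self=e.src.entity == e.dst.entity):
            out.append(
                Violation(
                    edge=e,
                    reason=f"{src_t} -> {dst_t} at lag {e.lag} disallowed by "
                    f"{constraint.variant}/{constraint.subset_label}",
                )
            )
    return out


def entity_adjacency(net: TwoSliceNetwork) -> dict[tuple[EntityRef, EntityRef], Edge]:
    """Collapse slices to an entity-level adjacency map.

    An entity-level edge (A, B) exists iff some edge has source entity A and
    destination entity B at any lag; when both lags carry such an edge the one
    with the higher bootstrap score is kept (lower lag on ties).
    """
    out: dict[tuple[EntityRef, EntityRef], Edge] = {}
    for e in net.edges:
        key = (e.src.entity, e.dst.entity)
        prev = out.get(key)
        if prev is None or (e.bootstrap_score, -e.lag) > (prev.bootstrap_score, -prev.lag):
            out[key] = e
    return out


# ---------------------------------------------------------------------------
# I/O: edge-list TSV, GraphML, constraint YAML
# ---------------------------------------------------------------------------

TSV_COLUMNS = (
    "src_name",
    "src_type",
    "src_slice",
    "dst_name",
    "dst_type",
    "dst_slice",
    "weight",
    "bootstrap_score",
)


def write_network_tsv(net: TwoSliceNetwork, path) -> None:
    """Write an edge-list TSV (one row per edge, UTF-8, tab-separated).

    The subset label and metadata are preserved in ``#``-prefixed comment
    lines ahead of the mandatory header row.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# subset_label={net.subset_label}\n")
        for k in sorted(net.metadata):
            fh.write(f"# meta:{k}={net.metadata[k]}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for e in net.edges:
            fh.write(
                "\t".join(
                    [
                        e.src.entity.name,
                        e.src.entity.omic_type,
                        str(e.src.slice),
                        e.dst.entity.name,
                        e.dst.entity.omic_type,
                        str(e.dst.slice),
                        repr(e.weight),
                        repr(e.bootstrap_score),
                    ]
                )
                + "\n"
            )


def read_network_tsv(path, subset_label: str | None = None) -> TwoSliceNetwork:
    """Read an edge-list TSV written by :func:`write_network_tsv`.

    ``subset_label`` overrides the label stored in the file's comment header
    (required when reading files produced by other tools that omit it).
    Malformed rows raise :class:`NetworkFormatError` naming the line number.
    """
    label = subset_label
    metadata: dict[str, str] = {}
    edges: list[Edge] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("subset_label=") and label is None:
                    label = body.split("=", 1)[1]
                elif body.startswith("meta:"):
                    k, _, v = body[5:].partition("=")
                    metadata[k] = v
                continue
            if not header_seen:
                cols = tuple(line.split("\t"))
                if cols != TSV_COLUMNS:
                    raise NetworkFormatError(
                        f"expected header {list(TSV_COLUMNS)}, got {list(cols)}", line=lineno
                    )
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != len(TSV_COLUMNS):
                raise NetworkFormatError(
                    f"expected {len(TSV_COLUMNS)} columns, got {len(fields)}", line=lineno
                )
            try:
                src = NodeRef(EntityRef(fields[0], fields[1]), int(fields[2]))
                dst = NodeRef(EntityRef(fields[3], fields[4]), int(fields[5]))
                edge = Edge(src, dst, float(fields[6]), float(fields[7]))
            except (ValueError, InvalidLagError) as exc:
                raise NetworkFormatError(str(exc), line=lineno) from exc
            edges.append(edge)
    if not header_seen:
        raise NetworkFormatError("file has no header row")
    if label is None:
        raise NetworkFormatError("no subset label in file and none supplied")
    return TwoSliceNetwork(label, edges, metadata=metadata)


def to_networkx(net: TwoSliceNetwork) -> nx.DiGraph:
    """Convert to a networkx DiGraph with string node ids ``name@type@slice``."""
    g = nx.DiGraph(subset_label=net.subset_label, **{f"meta_{k}": str(v) for k, v in net.metadata.items()})
    for n in sorted(net.nodes):
        g.add_node(
            f"{n.entity.name}@{n.entity.omic_type}@{n.slice}",
            name=n.entity.name,
            omic_type=n.entity.omic_type,
            slice=n.slice,
        )
    for e in net.edges:
        g.add_edge(
            f"{e.src.entity.name}@{e.src.entity.omic_type}@{e.src.slice}",
            f"{e.dst.entity.name}@{e.dst.entity.omic_type}@{e.dst.slice}",
            weight=e.weight,
            bootstrap_score=e.bootstrap_score,
            lag=e.lag,
        )
    return g


def write_graphml(net: TwoSliceNetwork, path) -> None:
    """Export the network as GraphML for visualization tools."""
    nx.write_graphml(to_networkx(net), path)


def save_constraint_yaml(constraint: SkeletonConstraint, path) -> None:
    """Serialize a permission table as YAML (``srcType->dstType@lag: bool``)."""
    doc = {
        "variant": constraint.variant,
        "subset_label": constraint.subset_label,
        "allowed": {
            f"{s}->{d}@{lag}": bool(v) for (s, d, lag), v in sorted(constraint.allowed.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_constraint_yaml(path) -> SkeletonConstraint:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    allowed: dict[tuple[str, str, int], bool] = {}
    for key, val in doc["allowed"].items():
        pair, _, lag = key.partition("@")
        s, _, d = pair.partition("->")
        allowed[(s, d, int(lag))] = bool(val)
    return SkeletonConstraint(variant=doc["variant"], subset_label=doc["subset_label"], allowed=allowed)
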