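"""Explicit simple-graph realization of a degree/edge partition.

The TCNB(m,n) family is published only as class counts (how many vertices of
each degree, how many edges per endpoint-degree pair), i.e. a joint degree
matrix.  This module constructs a concrete labelled simple graph with exactly
those counts, so that every index computed from the partition has a
brute-force oracle on an actual edge set.

The realized graph is *not* claimed isomorphic to the chemical TCNB net: it
need not be planar or connected.  That is deliberate — every degree-based
index in this package is a function of the endpoint-degree edge partition
alone, and any partition-faithful simple graph yields the same values.

Construction is deterministic: class-by-class greedy stub pairing, always
taking the vertex with the most unused stubs (smallest id on ties) and
skipping partners that would create a loop or a parallel edge.  Two calls
with the same (m, n) produce byte-identical edge lists.  An optional
``shuffle_seed`` permutes vertex ids first (robustness testing only).
"""

from __future__ import annotations

import heapq
import random
from dataclasses import dataclass, field
from typing import TextIO, Union

import networkx as nx

from .partition import GridSize, PartitionSpec, as_grid, consistency_report, tcnb_partition

PathOrFile = Union[str, TextIO]

#: order in which edge classes are wired; constrained classes first
CLASS_ORDER = [(1, 3), (3, 4), (2, 3), (2, 2), (3, 3)]


class RealizationError(RuntimeError):
    """Raised when greedy stub placement cannot complete."""


@dataclass
class SimpleGraph:
    """A labelled simple graph whose vertices carry intended degrees.

    ``edges`` holds unordered pairs stored as (u, v) with u < v.
    """

    intended_degrees: dict[int, int]
    edges: set[tuple[int, int]]

    def __post_init__(self) -> None:
        self.edges = {tuple(sorted(e)) for e in self.edges}

    @property
    def number_of_vertices(self) -> int:
        return len(self.intended_degrees)

    @property
    def number_of_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {v: set() for v in self.intended_degrees}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def realized_degrees(self) -> dict[int, int]:
        deg = dict.fromkeys(self.intended_degrees, 0)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def degree_histogram(self) -> dict[int, int]:
        """Count of vertices per realized degree."""
        hist: dict[int, int] = {}
        for d in self.realized_degrees().values():
            hist[d] = hist.get(d, 0) + 1
        return hist

    def edge_class_histogram(self) -> dict[tuple[int, int], int]:
        """Count of edges per unordered realized endpoint-degree pair."""
        deg = self.realized_degrees()
        hist: dict[tuple[int, int], int] = {}
        for u, v in self.edges:
            key = tuple(sorted((deg[u], deg[v])))
            hist[key] = hist.get(key, 0) + 1
        return hist

    def is_simple(self) -> bool:
        return all(u != v for u, v in self.edges) and all(
            u in self.intended_degrees and v in self.intended_degrees
            for u, v in self.edges
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for v, d in self.intended_degrees.items():
            g.add_node(v, intended_degree=d)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "SimpleGraph":
        """Wrap an existing simple graph; intended degrees = realized degrees."""
        return cls(
            intended_degrees={v: g.degree(v) for v in g.nodes},
            edges={tuple(sorted(e)) for e in g.edges},
        )


@dataclass(frozen=True)
class ValidationReport:
    degree_histogram_match: bool
    edge_class_histogram_match: bool
    simplicity: bool
    details: tuple[str, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return (
            self.degree_histogram_match
            and self.edge_class_histogram_match
            and self.simplicity
        )


class _StubHeap:
    """Vertices of one degree class ordered by remaining stubs (max first)."""

    def __init__(self, remaining: dict[int, int], members: list[int]):
        self.remaining = remaining
        self.heap = [(-remaining[v], v) for v in sorted(members)]
        heapq.heapify(self.heap)

    def pop_best(self, adjacency: dict[int, set[int]], avoid: int | None) -> int:
        """Take the vertex with most remaining stubs that is not ``avoid``
        and not adjacent to it; smallest id breaks ties."""
        skipped: list[tuple[int, int]] = []
        try:
            while True:
                neg, v = heapq.heappop(self.heap)
                if -neg != self.remaining[v] or self.remaining[v] <= 0:
                    continue  # stale entry
                if v == avoid or (avoid is not None and v in adjacency[avoid]):
                    skipped.append((neg, v))
                    continue
                for item in skipped:
                    heapq.heappush(self.heap, item)
                return v
        except IndexError:
            for item in skipped:
                heapq.heappush(self.heap, item)
            raise RealizationError(
                "no available partner vertex (class exhausted or all candidates adjacent)"
            ) from None

    def pop_any(self) -> int:
        """Take the vertex with most remaining stubs, ignoring adjacency."""
        while True:
            try:
                neg, v = heapq.heappop(self.heap)
            except IndexError:
                raise RealizationError("degree class has no remaining stubs") from None
            if -neg == self.remaining[v] and self.remaining[v] > 0:
                return v

    def consume(self, v: int) -> None:
        self.remaining[v] -= 1
        if self.remaining[v] > 0:
            heapq.heappush(self.heap, (-self.remaining[v], v))


def realize(
    size: "GridSize | tuple[int, int]",
    spec: PartitionSpec | None = None,
    shuffle_seed: int | None = None,
) -> SimpleGraph:
    """Construct a simple graph realizing the partition at (m, n).

    Vertex ids are contiguous per degree class in partition order (for TCNB:
    degree-1 vertices first, then 2, 3, 4).  Raises :class:`RealizationError`
    with a diagnostic if greedy placement cannot complete.
    """
    size = as_grid(size)
    spec = spec or tcnb_partition()
    failed = [c for c in consistency_report(size, spec) if not c.passed]
    if failed:
        raise ValueError(
            f"partition inconsistent at {size}: " + "; ".join(c.name for c in failed)
        )

    dcounts = spec.degree_counts(size)
    ecounts = spec.edge_counts(size)

    members: dict[int, list[int]] = {}
    intended: dict[int, int] = {}
    next_id = 0
    for cls in spec.degree_classes:
        count = dcounts[cls.degree]
        ids = list(range(next_id, next_id + count))
        members.setdefault(cls.degree, []).extend(ids)
        for v in ids:
            intended[v] = cls.degree
        next_id += count

    if shuffle_seed is not None:
        ids = sorted(intended)
        shuffled = ids[:]
        random.Random(shuffle_seed).shuffle(shuffled)
        relabel = dict(zip(ids, shuffled))
        intended = {relabel[v]: d for v, d in intended.items()}
        members = {d: sorted(relabel[v] for v in vs) for d, vs in members.items()}

    remaining = dict(intended)
    heaps = {d: _StubHeap(remaining, vs) for d, vs in members.items()}
    adjacency: dict[int, set[int]] = {v: set() for v in intended}
    edges: set[tuple[int, int]] = set()

    def add_edge(u: int, v: int) -> None:
        adjacency[u].add(v)
        adjacency[v].add(u)
        edges.add((u, v) if u < v else (v, u))

    def drop_edge(u: int, v: int) -> None:
        adjacency[u].discard(v)
        adjacency[v].discard(u)
        edges.discard((u, v) if u < v else (v, u))

    order = [p for p in CLASS_ORDER if p in ecounts]
    order += [p for p in sorted(ecounts) if p not in order]
    for a, b in order:
        need = ecounts[(a, b)]
        placed: list[tuple[int, int]] = []  # oriented: (class-a endpoint, class-b endpoint)
        for k in range(need):
            try:
                u = heaps[a].pop_best(adjacency, avoid=None)
            except (RealizationError, KeyError) as exc:
                raise RealizationError(
                    f"class ({a},{b}) at {size}: placed {k} of {need} edges, then {exc}"
                ) from None
            try:
                v = heaps[b].pop_best(adjacency, avoid=u)
                placed.append((u, v))
                add_edge(u, v)
            except RealizationError:
                # Direct placement blocked: every class-b stub holder is u
                # itself or already adjacent to it.  Repair by a degree- and
                # class-preserving swap: drop an earlier (a,b) edge (x, y)
                # and wire (u, y) and (x, v) instead.
                v = heaps[b].pop_any()
                swap = next(
                    (
                        (x, y)
                        for x, y in sorted(placed)
                        if x != u and y != v and x != v and y != u
                        and y not in adjacency[u] and x not in adjacency[v]
                    ),
                    None,
                )
                if swap is None:
                    raise RealizationError(
                        f"class ({a},{b}) at {size}: placed {k} of {need} edges "
                        "and no repair swap exists"
                    ) from None
                x, y = swap
                drop_edge(x, y)
                placed.remove((x, y))
                add_edge(u, y)
                add_edge(x, v)
                placed += [(u, y), (x, v)]
            heaps[a].consume(u)
            heaps[b].consume(v)

    leftover = {v: r for v, r in remaining.items() if r}
    if leftover:
        raise RealizationError(f"unused stubs remain at {size}: {leftover}")
    return SimpleGraph(intended_degrees=intended, edges=edges)


def validate(
    graph: SimpleGraph,
    spec: PartitionSpec | None = None,
    size: "GridSize | tuple[int, int]" = (1, 1),
) -> ValidationReport:
    """Compare a graph's realized histograms against a partition at (m, n)."""
    spec = spec or tcnb_partition()
    size = as_grid(size)
    details: list[str] = []

    simple = graph.is_simple()
    if not simple:
        loops = [e for e in graph.edges if e[0] == e[1]]
        if loops:
            details.append(f"self-loops present: {sorted(loops)[:5]}")
        undeclared = [
            e
            for e in graph.edges
            if e[0] not in graph.intended_degrees or e[1] not in graph.intended_degrees
        ]
        if undeclared:
            details.append(f"edges reference undeclared vertices: {sorted(undeclared)[:5]}")

    want_deg = {d: c for d, c in spec.degree_counts(size).items() if c}
    got_deg = graph.degree_histogram()
    deg_ok = want_deg == got_deg
    if not deg_ok:
        for d in sorted(set(want_deg) | set(got_deg)):
            w, g = want_deg.get(d, 0), got_deg.get(d, 0)
            if w != g:
                details.append(f"degree {d}: expected {w} vertices, found {g}")

    want_edge = {p: c for p, c in spec.edge_counts(size).items() if c}
    got_edge = graph.edge_class_histogram()
    edge_ok = want_edge == got_edge
    if not edge_ok:
        for p in sorted(set(want_edge) | set(got_edge)):
            w, g = want_edge.get(p, 0), got_edge.get(p, 0)
            if w != g:
                details.append(f"edge class {p}: expected {w}, found {g}")

    return ValidationReport(deg_ok, edge_ok, simple, tuple(details))


# -- plain-text edge-list I/O -------------------------------------------

_SEPARATOR = "%"


def write_edge_list(graph: SimpleGraph, destination: PathOrFile) -> None:
    """Write the graph as text: vertex header, a '%' separator, then edges.

    Header lines are ``id TAB intended_degree``; edge lines ``u TAB v`` with
    u < v, sorted.  Deterministic byte-for-byte.
    """
    lines = [f"{v}\t{d}" for v, d in sorted(graph.intended_degrees.items())]
    lines.append(_SEPARATOR)
    lines += [f"{u}\t{v}" for u, v in sorted(graph.edges)]
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)


def read_edge_list(source: PathOrFile) -> SimpleGraph:
    """Parse the edge-list format written by :func:`write_edge_list`.

    Rejects self-loops, duplicate edges, duplicate vertex declarations and
    edges referencing undeclared ids.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()

    intended: dict[int, int] = {}
    edges: set[tuple[int, int]] = set()
    in_edges = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == _SEPARATOR:
            if in_edges:
                raise ValueError(f"line {lineno}: repeated separator")
            in_edges = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected two TAB-separated fields")
        try:
            x, y = int(parts[0]), int(parts[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-integer field") from None
        if not in_edges:
            if x in intended:
                raise ValueError(f"line {lineno}: vertex {x} declared twice")
            if y < 1:
                raise ValueError(f"line {lineno}: intended degree must be positive")
            intended[x] = y
        else:
            if x == y:
                raise ValueError(f"line {lineno}: self-loop on vertex {x}")
            if x not in intended or y not in intended:
                raise ValueError(f"line {lineno}: edge references undeclared vertex")
            edge = (x, y) if x < y else (y, x)
            if edge in edges:
                raise ValueError(f"line {lineno}: duplicate edge {edge}")
            edges.add(edge)
    if not in_edges:
        raise ValueError("missing '%' separator between vertices and edges")
    return SimpleGraph(intended_degrees=intended, edges=edges)
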