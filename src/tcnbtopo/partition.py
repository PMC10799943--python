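"""Degree and edge partitions of the TCNB(m,n) framework graph.

The TCNB(m,n) metal–organic framework is modelled purely combinatorially: a
family of simple graphs indexed by a horizontal expansion m >= 1 and a
vertical expansion n >= 1.  Vertices (atoms) fall into four degree classes
(terminal cyano nitrogens of degree 1 up to metal nodes of degree 4) and
edges (bonds) into five classes by the unordered pair of endpoint degrees.
Each class size is an exact polynomial in (m, n); every degree-based
topological index of the family is a function of these class sizes alone.

The module also supports arbitrary user-supplied partitions (loaded from a
plain-text YAML config) so the same index engine can be applied to other
lattice families.

A note on the vertex total: the family's published description states the
atom count with a 32mn term, while the degree classes sum to
33mn + 25m + 25n + 17.  The class sum is adopted here (it is what the
degree-1..4 frequencies imply, and what the coindex values require); the
32mn variant is surfaced as an erratum by :mod:`tcnbtopo.closed_forms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Sequence, TextIO, Union

import yaml

from .polynomial import BivariatePolynomial, poly

PathOrFile = Union[str, "TextIO"]


@dataclass(frozen=True)
class GridSize:
    """Lattice dimensions: horizontal expansion m and vertical expansion n."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if not (isinstance(self.m, int) and isinstance(self.n, int)):
            raise TypeError("grid dimensions must be integers")
        if self.m < 1 or self.n < 1:
            raise ValueError(f"grid dimensions must satisfy m >= 1 and n >= 1, got {self}")

    def __iter__(self):
        return iter((self.m, self.n))

    def __str__(self) -> str:
        return f"({self.m},{self.n})"


def as_grid(size: "GridSize | tuple[int, int]") -> GridSize:
    if isinstance(size, GridSize):
        return size
    return GridSize(*size)


@dataclass(frozen=True)
class DegreeClassSpec:
    """One vertex class: common degree and its frequency polynomial."""

    degree: int
    frequency: BivariatePolynomial
    label: str = ""


@dataclass(frozen=True)
class EdgeClassSpec:
    """One edge class: canonical endpoint-degree pair (a <= b) and frequency."""

    degree_pair: tuple[int, int]
    frequency: BivariatePolynomial
    label: str = ""

    def __post_init__(self) -> None:
        a, b = self.degree_pair
        if a > b:
            raise ValueError(f"degree pair must be canonical (a <= b), got ({a},{b})")


@dataclass(frozen=True)
class PartitionSpec:
    """A family of graphs described by degree classes and edge classes."""

    degree_classes: tuple[DegreeClassSpec, ...]
    edge_classes: tuple[EdgeClassSpec, ...]

    # -- totals ---------------------------------------------------------

    def vertex_count_polynomial(self) -> BivariatePolynomial:
        total = BivariatePolynomial()
        for cls in self.degree_classes:
            total = total + cls.frequency
        return total

    def edge_count_polynomial(self) -> BivariatePolynomial:
        total = BivariatePolynomial()
        for cls in self.edge_classes:
            total = total + cls.frequency
        return total

    # -- evaluation -----------------------------------------------------

    def degree_counts(self, size: GridSize) -> dict[int, int]:
        """Vertex count per degree at a fixed (m, n)."""
        size = as_grid(size)
        return {c.degree: _as_count(c.frequency(size.m, size.n)) for c in self.degree_classes}

    def edge_counts(self, size: GridSize) -> dict[tuple[int, int], int]:
        """Edge count per degree pair at a fixed (m, n)."""
        size = as_grid(size)
        return {
            c.degree_pair: _as_count(c.frequency(size.m, size.n)) for c in self.edge_classes
        }

    # -- structural identities (as polynomials) -------------------------

    def handshake_defect(self) -> BivariatePolynomial:
        """Sum of degree*frequency minus twice the edge total; zero iff consistent."""
        lhs = BivariatePolynomial()
        for c in self.degree_classes:
            lhs = lhs + c.degree * c.frequency
        return lhs - 2 * self.edge_count_polynomial()

    def stub_defect(self, degree: int) -> BivariatePolynomial:
        """Stub balance for one degree class, as a polynomial.

        degree * |V_degree| minus the number of edge endpoints of that degree
        (an intra-class (d,d) edge contributes two).  Zero iff the edge classes
        exactly absorb the class's stubs.
        """
        lhs = BivariatePolynomial()
        for c in self.degree_classes:
            if c.degree == degree:
                lhs = lhs + degree * c.frequency
        for e in self.edge_classes:
            mult = (e.degree_pair[0] == degree) + (e.degree_pair[1] == degree)
            if mult:
                lhs = lhs - mult * e.frequency
        return lhs


def _as_count(value: Fraction) -> int:
    if value.denominator != 1 or value < 0:
        raise ValueError(f"class frequency evaluated to {value}, not a non-negative integer")
    return int(value)


@lru_cache(maxsize=1)
def tcnb_partition() -> PartitionSpec:
    """The TCNB(m,n) vertex and edge partition.

    Four degree classes (degrees 1-4) and five edge classes
    ((1,3),(2,3),(2,2),(3,3),(3,4)), each with its exact frequency
    polynomial in (m, n).
    """
    degree_classes = (
        DegreeClassSpec(1, poly(m=2, n=2, mn=4), "V1"),
        DegreeClassSpec(2, poly(m=8, n=8, mn=4, const=12), "V2"),
        DegreeClassSpec(3, poly(m=14, n=14, mn=24, const=4), "V3"),
        DegreeClassSpec(4, poly(m=1, n=1, mn=1, const=1), "V4"),
    )
    edge_classes = (
        EdgeClassSpec((1, 3), poly(m=2, n=2, mn=4), "E1"),
        EdgeClassSpec((2, 3), poly(m=8, n=8, mn=8, const=8), "E2"),
        EdgeClassSpec((2, 2), poly(m=4, n=4, const=8), "E3"),
        EdgeClassSpec((3, 3), poly(m=14, n=14, mn=28), "E4"),
        EdgeClassSpec((3, 4), poly(m=4, n=4, mn=4, const=4), "E5"),
    )
    return PartitionSpec(degree_classes, edge_classes)


def totals(size: "GridSize | tuple[int, int]") -> tuple[int, int]:
    """Atom and bond counts of TCNB(m,n).

    Returns (vertex_count, edge_count) = (33mn+25m+25n+17, 44mn+32m+32n+20).
    """
    size = as_grid(size)
    spec = tcnb_partition()
    return (
        _as_count(spec.vertex_count_polynomial()(size.m, size.n)),
        _as_count(spec.edge_count_polynomial()(size.m, size.n)),
    )


@dataclass(frozen=True)
class Check:
    """One named internal-consistency check."""

    name: str
    passed: bool
    detail: str = ""


def consistency_report(
    size: "GridSize | tuple[int, int]", spec: PartitionSpec | None = None
) -> list[Check]:
    """Validate a partition against itself at a fixed (m, n).

    Checks the handshake lemma and per-degree stub balance both as polynomial
    identities and on the evaluated counts, plus non-negativity of every
    class size.  For the TCNB partition every check passes for all m, n >= 1.
    """
    size = as_grid(size)
    spec = spec or tcnb_partition()
    checks: list[Check] = []

    defect = spec.handshake_defect()
    checks.append(
        Check(
            "handshake lemma (polynomial identity)",
            defect.is_zero,
            "" if defect.is_zero else f"defect {defect}",
        )
    )

    dcounts = spec.degree_counts(size)
    ecounts = spec.edge_counts(size)
    stub_sum = sum(d * c for d, c in dcounts.items())
    edge_total = sum(ecounts.values())
    checks.append(
        Check(
            f"handshake lemma at {size}",
            stub_sum == 2 * edge_total,
            f"sum d*|V_d| = {stub_sum}, 2|E| = {2 * edge_total}",
        )
    )

    for degree in sorted(dcounts):
        pdefect = spec.stub_defect(degree)
        incident = sum(
            ((a == degree) + (b == degree)) * k for (a, b), k in ecounts.items()
        )
        ok = pdefect.is_zero and degree * dcounts[degree] == incident
        checks.append(
            Check(
                f"degree-{degree} stub balance",
                ok,
                f"{degree}*|V_{degree}| = {degree * dcounts[degree]}, "
                f"incident endpoints = {incident}"
                + ("" if pdefect.is_zero else f"; polynomial defect {pdefect}"),
            )
        )

    negative = [
        f"degree {d}: {c}" for d, c in dcounts.items() if c < 0
    ] + [f"pair {p}: {c}" for p, c in ecounts.items() if c < 0]
    checks.append(
        Check("all class sizes non-negative", not negative, "; ".join(negative))
    )
    return checks


# -- plain-text config I/O ----------------------------------------------


def save_partition(spec: PartitionSpec, destination: PathOrFile) -> None:
    """Write a partition as a YAML config (polynomials as coefficient maps)."""
    data = {
        "degree_classes": [
            {
                "degree": c.degree,
                "label": c.label,
                "frequency": c.frequency.to_coeff_map(),
            }
            for c in spec.degree_classes
        ],
        "edge_classes": [
            {
                "degree_pair": list(c.degree_pair),
                "label": c.label,
                "frequency": c.frequency.to_coeff_map(),
            }
            for c in spec.edge_classes
        ],
    }
    text = yaml.safe_dump(data, sort_keys=False)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


def load_partition(source: PathOrFile) -> PartitionSpec:
    """Read a partition config written by :func:`save_partition`."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source.read())
    else:
        with open(source, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    degree_classes = tuple(
        DegreeClassSpec(
            int(c["degree"]),
            BivariatePolynomial.from_coeff_map(c["frequency"]),
            str(c.get("label", "")),
        )
        for c in data["degree_classes"]
    )
    edge_classes = tuple(
        EdgeClassSpec(
            tuple(int(x) for x in c["degree_pair"]),
            BivariatePolynomial.from_coeff_map(c["frequency"]),
            str(c.get("label", "")),
        )
        for c in data["edge_classes"]
    )
    return PartitionSpec(degree_classes, edge_classes)
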