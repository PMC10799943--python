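"""Deterministic realization of the partition and edge-list round trips."""

import io

import pytest

from tcnbtopo import (
    SimpleGraph,
    read_edge_list,
    realize,
    validate,
    write_edge_list,
)


def test_unit_cell_realization_size(spec):
    g = realize((1, 1))
    assert g.number_of_vertices == 100
    assert g.number_of_edges == 128
    assert validate(g, spec, (1, 1)).passed


def test_realizations_validate_across_grid(spec):
    for m in range(1, 7):
        for n in range(1, 7):
            report = validate(realize((m, n)), spec, (m, n))
            assert report.passed, (m, n, report.details)


def test_edge_class_histogram_at_2_3(spec):
    g = realize((2, 3))
    assert g.edge_class_histogram() == {
        (1, 3): 34,
        (2, 3): 96,
        (2, 2): 28,
        (3, 3): 238,
        (3, 4): 48,
    }


def test_determinism_byte_identical():
    a, b = io.StringIO(), io.StringIO()
    write_edge_list(realize((2, 3)), a)
    write_edge_list(realize((2, 3)), b)
    assert a.getvalue() == b.getvalue()


def test_pendant_vertices_attach_to_degree_three(spec):
    g = realize((2, 2))
    adj = g.adjacency()
    deg = g.realized_degrees()
    for v, d in g.intended_degrees.items():
        if d == 1:
            (neighbor,) = adj[v]
            assert deg[neighbor] == 3


def test_shuffled_realization_still_validates(spec):
    g = realize((3, 4), shuffle_seed=7)
    assert validate(g, spec, (3, 4)).passed


def test_validation_flags_self_loop(spec):
    g = realize((1, 1))
    broken = SimpleGraph(dict(g.intended_degrees), set(g.edges))
    broken.edges.add((5, 5))
    report = validate(broken, spec, (1, 1))
    assert not report.simplicity
    assert not report.passed


def test_validation_flags_missing_edge_class(spec):
    g = realize((1, 1))
    deg = g.realized_degrees()
    victim = next(
        e for e in sorted(g.edges) if deg[e[0]] == 2 and deg[e[1]] == 2
    )
    broken = SimpleGraph(dict(g.intended_degrees), set(g.edges) - {victim})
    report = validate(broken, spec, (1, 1))
    assert not report.edge_class_histogram_match
    assert any("(2, 2)" in d for d in report.details)


def test_edge_list_round_trip():
    g = realize((1, 1))
    buffer = io.StringIO()
    write_edge_list(g, buffer)
    back = read_edge_list(io.StringIO(buffer.getvalue()))
    assert back.intended_degrees == g.intended_degrees
    assert back.edges == g.edges


@pytest.mark.parametrize(
    "body, message",
    [
        ("0\t1\n1\t3\n%\n0\t0\n", "self-loop"),
        ("0\t1\n1\t1\n%\n0\t1\n0\t1\n", "duplicate edge"),
        ("0\t1\n%\n0\t7\n", "undeclared"),
        ("0\t1\n0\t2\n%\n", "declared twice"),
        ("0\t1\n1\t1\n", "separator"),
    ],
)
def test_edge_list_rejects_malformed_input(body, message):
    with pytest.raises(ValueError, match=message):
        read_edge_list(io.StringIO(body))
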