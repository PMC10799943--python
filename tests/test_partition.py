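"""TCNB(m,n) vertex/edge partition: counts, totals, structural identities."""

import io

import pytest

from tcnbtopo.partition import (
    EdgeClassSpec,
    GridSize,
    PartitionSpec,
    consistency_report,
    load_partition,
    save_partition,
    tcnb_partition,
    totals,
)


def test_counts_at_unit_cell(spec):
    size = GridSize(1, 1)
    assert spec.degree_counts(size) == {1: 8, 2: 32, 3: 56, 4: 4}
    assert spec.edge_counts(size) == {
        (1, 3): 8,
        (2, 3): 32,
        (2, 2): 16,
        (3, 3): 56,
        (3, 4): 16,
    }
    # handshake on the evaluated counts: 1*8 + 2*32 + 3*56 + 4*4 = 256 = 2*128
    assert sum(d * c for d, c in spec.degree_counts(size).items()) == 256


@pytest.mark.parametrize(
    "size, expected",
    [((1, 1), (100, 128)), ((5, 6), (1282, 1692)), ((2, 3), (340, 444))],
)
def test_totals(size, expected):
    assert totals(size) == expected


@pytest.mark.parametrize("bad", [(0, 1), (1, 0), (-2, 3)])
def test_domain_restriction(bad):
    with pytest.raises(ValueError):
        totals(bad)


def test_structural_identities_hold_as_polynomials(spec):
    assert spec.handshake_defect().is_zero
    for degree in (1, 2, 3, 4):
        assert spec.stub_defect(degree).is_zero


def test_consistency_report_passes_on_grid(spec):
    for m in range(1, 7):
        for n in range(1, 7):
            assert all(c.passed for c in consistency_report((m, n), spec))


def test_corrupted_partition_fails_stub_balance(spec):
    # decrement the (3,4) class by one edge: degree-4 stubs no longer balance
    corrupted = PartitionSpec(
        spec.degree_classes,
        tuple(
            EdgeClassSpec(c.degree_pair, c.frequency - 1, c.label)
            if c.degree_pair == (3, 4)
            else c
            for c in spec.edge_classes
        ),
    )
    report = consistency_report((1, 1), corrupted)
    failed = {c.name for c in report if not c.passed}
    assert "degree-4 stub balance" in failed


def test_symmetry_in_m_and_n(spec):
    for m, n in [(2, 3), (1, 5), (4, 2)]:
        assert spec.degree_counts((m, n)) == spec.degree_counts((n, m))
        assert spec.edge_counts((m, n)) == spec.edge_counts((n, m))


def test_totals_strictly_increasing():
    for m in range(1, 6):
        for n in range(1, 6):
            v, e = totals((m, n))
            v_m, e_m = totals((m + 1, n))
            v_n, e_n = totals((m, n + 1))
            assert v_m > v and e_m > e
            assert v_n > v and e_n > e


def test_config_round_trip(spec):
    buffer = io.StringIO()
    save_partition(spec, buffer)
    loaded = load_partition(io.StringIO(buffer.getvalue()))
    assert loaded == spec
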