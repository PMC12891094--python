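import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from progmat import (
    ArityError,
    FeasibilityError,
    RegistryError,
    RuleRangeError,
    UnsupportedRuleError,
    apply_rule,
    cof,
    logical_partition,
    make_logical_row,
    make_primitive,
    rule,
    visible_indices,
)


class TestRegistry:
    def test_rotation_5_theta(self):
        assert rule("rotation.5").theta == pytest.approx(math.pi / 5)

    def test_rotation_default_theta(self):
        assert rule("rotation").theta == pytest.approx(math.pi / 4)

    @pytest.mark.parametrize("x", range(1, 10))
    def test_rotation_x_theta(self, x):
        assert rule(f"rotation.{x}").theta == pytest.approx(math.pi / x)

    def test_size_constants(self):
        assert rule("size").k == 0.9
        assert rule("size.inv").k == 0.6

    @pytest.mark.parametrize("name", ["shade.inv", "multi.shade.inv",
                                      "AND.inv", "OR.inv", "XOR.inv"])
    def test_unsupported_reverse_forms(self, name):
        with pytest.raises(UnsupportedRuleError):
            rule(name)

    def test_unknown_rule(self):
        with pytest.raises(RegistryError):
            rule("teleport")

    def test_lty_maps(self):
        # 1 solid, 2 dashed, 3 dotted: forward = dashed, dotted, solid
        assert rule("lty").lty_map == (2, 3, 1)
        assert rule("lty.inv").lty_map == (2, 1, 3)

    def test_logical_have_no_parameters(self):
        for name in ("AND", "OR", "XOR"):
            r = rule(name)
            assert r.is_logical and r.theta is None and r.k is None


class TestIncremental:
    def test_identity(self, square):
        assert apply_rule("identity", square, 3) == square

    def test_size_formula(self):
        # frozen oracle: 10 / (2 * 0.9) = 5.5555...
        sq = make_primitive("square", size_x=10, size_y=10)
        out = apply_rule("size", sq, 2)
        assert out.elements[0].size_x == pytest.approx(10 / 1.8)
        assert out.elements[0].size_y == pytest.approx(10 / 1.8)

    def test_size_step_one_is_identity(self, square):
        assert apply_rule("size", square, 1) == square

    def test_size_monotone_decreasing(self, square):
        sizes = [apply_rule("size", square, n).elements[0].size_x for n in range(1, 4)]
        assert sizes == sorted(sizes, reverse=True)

    def test_size_inv_monotone_increasing(self, square):
        sizes = [apply_rule("size.inv", square, n).elements[0].size_x for n in range(1, 4)]
        assert sizes == sorted(sizes)

    def test_rotation_clockwise_step(self, square):
        out = apply_rule("rotation.4", square, 3)
        assert out.elements[0].rotation == pytest.approx(
            square.elements[0].rotation + 2 * math.pi / 4)

    def test_rotation_requires_tag(self):
        with pytest.raises(FeasibilityError, match="rotate"):
            apply_rule("rotation", make_primitive("miley"), 2)

    def test_rotation_inverse_undoes(self, square):
        fwd = apply_rule("rotation.3", square, 3)
        back = apply_rule("rotation.3.inv", fwd, 3)
        assert back.elements[0].rotation == pytest.approx(square.elements[0].rotation)

    @given(st.integers(1, 6), st.integers(1, 6))
    def test_rotation_additivity(self, n, m):
        sq = make_primitive("square")
        theta = rule("rotation.4").theta
        once = apply_rule("rotation.4", apply_rule("rotation.4", sq, n), m)
        angle = once.elements[0].rotation - sq.elements[0].rotation
        expected = ((n - 1) + (m - 1)) * theta
        assert math.isclose((angle - expected) % (2 * math.pi), 0, abs_tol=1e-9) or \
            math.isclose((angle - expected) % (2 * math.pi), 2 * math.pi, abs_tol=1e-9)


class TestPermutational:
    def test_shade_ignores_previous_color(self):
        black = make_primitive("square", shade="black")
        assert apply_rule("shade", black, 1).elements[0].shade == "white"

    def test_shade_map(self, square):
        shades = [apply_rule("shade", square, n).elements[0].shade for n in (1, 2, 3)]
        assert shades == ["white", "gray", "black"]

    def test_shade_requires_fill(self):
        with pytest.raises(FeasibilityError, match="fill"):
            apply_rule("shade", make_primitive("vline"), 1)

    def test_shade_range(self, square):
        with pytest.raises(RuleRangeError):
            apply_rule("shade", square, 4)

    @pytest.mark.parametrize("name", ["shade", "lty", "lwd", "multi.shade"])
    def test_idempotence_at_fixed_n(self, square, name):
        once = apply_rule(name, square, 2)
        assert apply_rule(name, once, 2) == once

    def test_lwd_forward_and_reverse(self, square):
        assert [apply_rule("lwd", square, n).elements[0].lwd for n in (1, 2, 3)] == [1, 2, 3]
        assert [apply_rule("lwd.inv", square, n).elements[0].lwd for n in (1, 2, 3)] == [3, 2, 1]

    def test_lty_forward_order(self, square):
        # dashed, dotted, solid
        assert [apply_rule("lty", square, n).elements[0].lty for n in (1, 2, 3)] == [2, 3, 1]

    def test_shape_forward(self, shape_triple):
        for n, expected in zip((1, 2, 3), ("hexagon", "pentagon", "square")):
            out = apply_rule("shape", shape_triple, n)
            vis = visible_indices(out)
            assert vis == set(out.groups[out.names.index(expected)])

    def test_shape_reverse_order(self, shape_triple):
        out = apply_rule("shape.inv", shape_triple, 1)
        assert visible_indices(out) == set(out.groups[out.names.index("square")])

    def test_shape_coverage(self, shape_triple):
        for name in ("shape", "shape.inv"):
            seen = set()
            for n in (1, 2, 3):
                vis = visible_indices(apply_rule(name, shape_triple, n))
                assert len(vis) == 1
                seen |= vis
            assert seen == {0, 1, 2}

    def test_shape_arity(self, square):
        with pytest.raises(ArityError):
            apply_rule("shape", square, 1)

    def test_multi_shade_deterministic(self):
        fig = cof(make_primitive("square"), make_primitive("circle"),
                  make_primitive("hexagon"))
        a = apply_rule("multi.shade", fig, 2)
        b = apply_rule("multi.shade", fig, 2)
        assert a == b
        assert all(e.shade in ("white", "gray", "black") for e in a.elements)


class TestLogical:
    def test_rejected_by_apply_rule(self, square):
        with pytest.raises(FeasibilityError):
            apply_rule("AND", cof(square, square, square), 1)

    def test_arity(self, square):
        with pytest.raises(ArityError):
            make_logical_row("AND", square, 1, seed=0)

    def test_partition_properties(self):
        a, b, c = logical_partition(7, index=2, seed=11)
        assert a and b and c
        assert not (a & b or a & c or b & c)
        assert a | b | c == set(range(7))

    def test_partition_determinism(self):
        fig = make_primitive("square4")
        assert make_logical_row("AND", fig, 2, seed=5) == make_logical_row("AND", fig, 2, seed=5)

    def test_rows_differ_across_indices(self):
        fig = cof(*(make_primitive(n) for n in
                    ("square", "circle", "triangle", "pentagon", "hexagon")))
        rows = [make_logical_row("OR", fig, i, seed=3) for i in (1, 2, 3)]
        assert len({tuple(visible_indices(r[0]) for r in rows)}) >= 1  # well-formed
        assert rows[0] != rows[1] or rows[1] != rows[2]

    @given(st.integers(0, 10_000), st.integers(1, 3),
           st.sampled_from(["AND", "OR", "XOR"]))
    def test_set_semantics(self, seed, index, name):
        fig = cof(*(make_primitive(n) for n in
                    ("square", "circle", "triangle", "pentagon")))
        c1, c2, c3 = make_logical_row(name, fig, index, seed=seed)
        v1, v2, v3 = (visible_indices(c) for c in (c1, c2, c3))
        oracle = {"AND": v1 & v2, "OR": v1 | v2, "XOR": v1 ^ v2}[name]
        assert v3 == oracle

    def test_hidden_elements_retained(self):
        fig = make_primitive("square4")
        for cell in make_logical_row("XOR", fig, 1, seed=0):
            assert len(cell.elements) == len(fig.elements)


def test_rules_never_mutate_input(shape_triple):
    snapshot = shape_triple
    for name in ("size", "rotation", "lwd", "lty", "shade", "shape", "multi.shade"):
        apply_rule(name, shape_triple, 2)
    make_logical_row("OR", shape_triple, 1, seed=0)
    assert shape_triple == snapshot
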