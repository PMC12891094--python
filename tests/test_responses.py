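import pytest

from progmat import (
    OPTION_NAMES,
    build_matrix,
    cof,
    com,
    correct_response,
    figures_equal,
    is_crossed,
    make_primitive,
    mat_apply,
    response_list,
    response_list_to_dict,
    select_source_cell,
)
from progmat.responses import IC_INC_SINGLE_WARNING, crossed_out, gen_difference
from progmat.fixtures import FixtureConfig, sample_item_specs


class TestStructure:
    def test_names_in_canonical_order(self, shape_matrix):
        rl = response_list(shape_matrix)
        assert tuple(rl.names()) == OPTION_NAMES
        assert len(rl.names()) == 11

    def test_family_counts(self):
        names = list(OPTION_NAMES)
        assert sum(n.startswith("r_") for n in names) == 3
        assert sum(n.startswith("wp_") for n in names) == 2
        assert sum(n == "difference" for n in names) == 1
        assert sum(n.startswith("ic_") for n in names) == 4
        assert names[0] == "correct"

    def test_determinism(self, tutorial_matrix):
        a = response_list(tutorial_matrix, seed=3)
        b = response_list(tutorial_matrix, seed=3)
        assert a == b

    def test_serialization(self, shape_matrix):
        d = response_list_to_dict(response_list(shape_matrix))
        assert list(d["options"]) == list(OPTION_NAMES)
        assert d["correct"] == "correct"


class TestRepetition:
    def test_sources_3x3(self, shape_matrix):
        rl = response_list(shape_matrix)
        # H-rule matrix: r_diag (Sq5) and r_left (Sq8) differ from Sq9
        assert rl["r_diag"] == shape_matrix.cells["Sq5"]
        assert rl["r_left"] == shape_matrix.cells["Sq8"]

    def test_vertical_single_rule_r_left_crossed(self):
        m = mat_apply(make_primitive("square"), vrules=["shade"])
        rl = response_list(m)
        assert figures_equal(m.cells["Sq8"], correct_response(m))
        assert "r_left" in rl.crossed
        assert any(w[0] == "r_left" for w in rl.warnings)

    def test_sources_2x2(self):
        m = mat_apply(make_primitive("square"), hrules=["shade"], mat_type=4)
        rl = response_list(m)
        assert rl["r_top"] == m.cells["Sq2"] or is_crossed(rl["r_top"])
        # 2x2: r_left = Sq3, r_top = Sq2, r_diag = Sq1
        assert rl["r_diag"] == m.cells["Sq1"] or is_crossed(rl["r_diag"])


class TestSourceCell:
    def test_single_h_rule(self, shape_matrix):
        assert select_source_cell(shape_matrix) == "Sq1"

    def test_two_rules(self):
        m = mat_apply(make_primitive("square"), hrules=["shade"], vrules=["rotation.4"])
        assert select_source_cell(m) == "Sq3"

    def test_ll_tr_single_rule(self):
        m = mat_apply(make_primitive("square"), hrules=["size"], vrules=["size"])
        assert select_source_cell(m) == "Sq3"

    def test_tl_lr_single_rule(self):
        m = mat_apply(make_primitive("square"), hrules=["size"], vrules=["size.inv"])
        assert select_source_cell(m) == "Sq1"

    def test_2x2_both_directions(self):
        m = mat_apply(make_primitive("square"), hrules=["size"], vrules=["size"],
                      mat_type=4)
        assert select_source_cell(m, "wp") == "Sq3"
        m2 = mat_apply(make_primitive("square"), hrules=["shade"], mat_type=4)
        assert select_source_cell(m2, "wp") == "Sq2"
        assert select_source_cell(m2, "difference") == "Sq1"


class TestWrongPrinciple:
    def test_wp_copy_is_source_cell(self, shape_matrix):
        rl = response_list(shape_matrix)
        assert rl["wp_copy"] == shape_matrix.cells["Sq1"]

    def test_wp_matrix_element_arithmetic(self, shape_matrix):
        rl = response_list(shape_matrix)
        assert len(rl["wp_matrix"].elements) == (
            len(shape_matrix.cells["Sq1"].elements)
            + len(shape_matrix.cells["Sq2"].elements))

    def test_degenerate_wp_copy_crossed(self, square):
        rl = response_list(mat_apply(square))  # identity everywhere
        assert "wp_copy" in rl.crossed


class TestDifference:
    def test_foreign_figure_not_in_matrix(self, shape_matrix):
        rl = response_list(shape_matrix)
        in_matrix = set()
        for fig in shape_matrix.cells.values():
            in_matrix |= set(fig.names) | {e.shape for e in fig.elements}
        merged_len = sum(len(shape_matrix.cells[c].elements) for c in ("Sq1", "Sq4", "Sq7"))
        foreign = rl["difference"].elements[merged_len:]
        assert foreign
        assert all(e.shape not in in_matrix for e in foreign)

    def test_seed_isolation(self, shape_matrix):
        lists = {s: response_list(shape_matrix, seed=s) for s in range(6)}
        diffs = {tuple(e.shape for e in rl["difference"].elements) for rl in lists.values()}
        assert len(diffs) > 1  # seed reaches the difference option
        base = lists[0]
        for rl in lists.values():
            for name in OPTION_NAMES:
                if name != "difference":
                    assert rl[name] == base[name]

    def test_registry_exhaustion_falls_back(self):
        # a matrix using every registered primitive, so nothing foreign remains
        from progmat import list_primitives

        big = cof(*(make_primitive(n) for n in list_primitives()))
        m = mat_apply(big)
        fig, warning = gen_difference(m, seed=0)
        assert fig is None and "Difference" in warning
        rl = response_list(m)
        assert "difference" in rl.crossed


class TestIncompleteCorrelates:
    def test_single_layer_ic_inc_warning(self, shape_matrix):
        rl = response_list(shape_matrix)
        assert ("ic_inc", IC_INC_SINGLE_WARNING) in rl.warnings
        assert "ic_inc" in rl.crossed

    def test_tutorial_ic_neg_fallback(self, tutorial_matrix):
        rl = response_list(tutorial_matrix)
        assert "ic_neg" in rl.crossed
        assert any(w[0] == "ic_neg" for w in rl.warnings)

    def test_multilayer_ic_inc_removes_foreground(self):
        a = mat_apply(make_primitive("square"), hrules=["shade"])
        b = mat_apply(make_primitive("dot"), vrules=["size"])
        m = com(a, b)
        rl = response_list(m)
        correct = correct_response(m)
        foreground = m.layer_sizes[-1]
        assert len(rl["ic_inc"].elements) == len(correct.elements) - foreground

    def test_logic_matrix_ic_inc_random_removal(self, tutorial_matrix):
        rl = response_list(tutorial_matrix)
        correct = correct_response(tutorial_matrix)
        assert not is_crossed(rl["ic_inc"])
        assert len(rl["ic_inc"].elements) == len(correct.elements) - 1

    def test_ic_neg_inverts_fill(self):
        m = mat_apply(make_primitive("square", shade="black"), hrules=["rotation.4"])
        rl = response_list(m)
        assert rl["ic_neg"].elements[0].shade == "white"

    def test_ic_size_shrinks_foreground(self):
        a = mat_apply(make_primitive("square"), hrules=["shade"])
        b = mat_apply(make_primitive("circle"), vrules=["lwd"])
        m = com(a, b)
        rl = response_list(m)
        correct = correct_response(m)
        assert rl["ic_size"].elements[-1].size_x == pytest.approx(
            correct.elements[-1].size_x * 0.5)
        assert rl["ic_size"].elements[0] == correct.elements[0]  # background untouched

    def test_ic_flip_rotates_rotatable_layer(self):
        m = mat_apply(make_primitive("ellipse"), hrules=["shade"])
        rl = response_list(m)
        correct = correct_response(m)
        assert rl["ic_flip"].elements[0].rotation != correct.elements[0].rotation


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixture_corpus(self, seed):
        cfg = FixtureConfig(seed=seed, n_items=15, include_degenerate=(seed == 0))
        for spec in sample_item_specs(cfg):
            m = build_matrix(spec)
            rl = response_list(m, seed=spec["seed"])
            assert tuple(rl.names()) == OPTION_NAMES
            correct = correct_response(m)
            for name in OPTION_NAMES[1:]:
                opt = rl[name]
                # no accidental key: every live distractor differs from correct
                if not is_crossed(opt):
                    assert not figures_equal(opt, correct), (spec["id"], name)
            for name in rl.crossed:
                assert any(w[0] == name for w in rl.warnings) or name == "correct"

    def test_crossed_overlay_shape(self, square):
        fig = crossed_out(square)
        assert is_crossed(fig)
        bars = [e for e in fig.elements if e.shape == "cross.out"]
        assert len(bars) == 2
        assert all(e.lwd == 3 for e in bars)
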