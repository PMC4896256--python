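"""Model representation, GPR grammar, I/O round-trips and augmentation."""

import numpy as np
import pytest

import fluxfuse as ff
from fluxfuse.model import (
    GprParseError,
    GprUpdate,
    ModelValidationError,
    ReactionAddition,
    format_gpr,
    parse_gpr,
    read_model,
    write_model,
)


class TestGprGrammar:
    @pytest.mark.parametrize(
        "text, op, n_leaves",
        [
            ("argD OR astC OR gabT OR puuE", "or", 4),
            ("aspC or tyrB", "or", 2),
            ("g1", "gene", 1),
            ("g1 AND g2 AND g3", "and", 3),
        ],
    )
    def test_flat_expressions(self, text, op, n_leaves):
        tree = parse_gpr(text)
        assert tree.op == op
        assert len(tree.genes()) == n_leaves

    def test_precedence_and_parentheses(self):
        # AND binds tighter than OR
        t = parse_gpr("g1 AND g2 OR g3")
        assert t.op == "or" and t.children[0].op == "and"
        t2 = parse_gpr("(g1 AND g2) OR g3")
        assert t2 == t
        t3 = parse_gpr("g1 AND (g2 OR g3)")
        assert t3.op == "and" and t3.children[1].op == "or"

    def test_case_insensitive_operators(self):
        assert parse_gpr("a and b") == parse_gpr("a AND b")

    @pytest.mark.parametrize("bad", ["", "g1 AND", "(g1 OR g2", "g1 g2", "AND g1"])
    def test_malformed_text_raises_with_position(self, bad):
        with pytest.raises(GprParseError):
            parse_gpr(bad)

    def test_parse_format_roundtrip_random_trees(self):
        from conftest import random_gpr_tuple, tuple_to_text

        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(6)]
        for _ in range(30):
            text = tuple_to_text(random_gpr_tuple(rng, 3, genes))
            tree = parse_gpr(text)
            assert parse_gpr(format_gpr(tree)) == tree


class TestModelValidation:
    def test_dimension_mismatch(self):
        with pytest.raises(ModelValidationError):
            ff.MetabolicModel(["m1"], ["r1", "r2"], np.zeros((1, 1)),
                              np.zeros(2), np.ones(2), [None, None])

    def test_duplicate_ids(self):
        with pytest.raises(ModelValidationError, match="duplicate"):
            ff.MetabolicModel(["m1"], ["r1", "r1"], np.zeros((1, 2)),
                              np.zeros(2), np.ones(2), [None, None])

    def test_inverted_bounds(self):
        with pytest.raises(ModelValidationError, match="v_min"):
            ff.MetabolicModel(["m1"], ["r1"], np.zeros((1, 1)),
                              np.array([1.0]), np.array([0.0]), [None])

    def test_unknown_gene_in_gpr(self):
        with pytest.raises(ModelValidationError, match="unknown genes"):
            ff.MetabolicModel(["m1"], ["r1"], np.zeros((1, 1)),
                              np.zeros(1), np.ones(1), [parse_gpr("gX")],
                              gene_ids=[])


class TestModelIO:
    def test_json_roundtrip_identity(self, tmp_path, chain_model):
        path = tmp_path / "model.json"
        write_model(chain_model, path)
        back = read_model(path)
        assert back.metabolite_ids == chain_model.metabolite_ids
        assert back.reaction_ids == chain_model.reaction_ids
        assert back.gene_ids == chain_model.gene_ids
        np.testing.assert_array_equal(back.A, chain_model.A)
        np.testing.assert_array_equal(back.v_min, chain_model.v_min)
        np.testing.assert_array_equal(back.v_max, chain_model.v_max)
        assert back.gpr == chain_model.gpr

    def test_toy_json_fixture_shape(self, tmp_path, chain_model):
        path = tmp_path / "model.json"
        write_model(chain_model, path)
        model = read_model(path, format="json")
        assert (model.m, model.n) == (1, 3)

    def test_default_bounds_when_absent(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(
            '{"metabolites": ["M"], "reactions": ['
            '{"id": "r_irrev", "stoichiometry": {"M": 1}},'
            '{"id": "r_rev", "stoichiometry": {"M": -1}, "reversible": true}]}'
        )
        model = read_model(path)
        assert model.v_min[0] == 0 and model.v_max[0] == 1000
        assert model.v_min[1] == -1000 and model.v_max[1] == 1000

    def test_sbml_roundtrip_with_isozyme_gpr(self, tmp_path, branch_model):
        pytest.importorskip("cobra")
        path = tmp_path / "model.xml"
        write_model(branch_model, path, format="sbml")
        back = read_model(path, format="sbml")
        assert set(back.reaction_ids) == set(branch_model.reaction_ids)
        j = back.reaction_index("R_product")
        tree = back.gpr[j]
        assert tree is not None and tree.op == "or"
        assert tree.genes() == {"gP1", "gP2"}

    def test_parse_error_names_offending_content(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"metabolites": ["M"], "reactions": [{"stoichiometry": {}}]}')
        with pytest.raises(ModelValidationError, match="no id"):
            read_model(path)


class TestAugmentation:
    def test_gpr_update_citrate_synthase_style(self, chain_model):
        out = ff.augment_model(
            chain_model,
            gpr_updates=[GprUpdate("R_biomass", "gB1", "gB1 OR prpC")],
        )
        j = out.reaction_index("R_biomass")
        assert format_gpr(out.gpr[j]) == "gB1 OR prpC"
        assert "prpC" in out.gene_ids
        # untouched reactions unchanged
        assert out.gpr[out.reaction_index("R_uptake")] == chain_model.gpr[0]

    def test_empty_tables_identity(self, chain_model):
        out = ff.augment_model(chain_model)
        assert out.reaction_ids == chain_model.reaction_ids
        np.testing.assert_array_equal(out.A, chain_model.A)

    def test_add_reaction_dimension_bookkeeping(self, chain_model):
        add = ReactionAddition("R_ug", {"M": -1.0}, 0.0, 5.0, "gUG")
        out = ff.augment_model(chain_model, additions=[add])
        assert out.n == chain_model.n + 1
        assert out.m == chain_model.m  # consumes an existing metabolite
        # direct matrix construction: new column is -1 in M's row
        np.testing.assert_array_equal(out.A[:, -1], [-1.0])
        # zero flux stays feasible
        assert np.allclose(out.A @ np.zeros(out.n), 0)

    def test_new_metabolite_adds_row(self, chain_model):
        add = ReactionAddition("R_new", {"M": -1.0, "X": 1.0}, 0.0, 5.0)
        out = ff.augment_model(chain_model, additions=[add])
        assert out.m == chain_model.m + 1 and out.n == chain_model.n + 1

    def test_idempotent_reapplication(self, chain_model):
        add = ReactionAddition("R_ug", {"M": -1.0}, 0.0, 5.0)
        upd = GprUpdate("R_biomass", "gB1", "gB1 OR prpC")
        once = ff.augment_model(chain_model, [add], [upd])
        twice = ff.augment_model(once, [add], [upd])
        assert twice.reaction_ids == once.reaction_ids
        np.testing.assert_array_equal(twice.A, once.A)
        assert twice.gpr == once.gpr

    def test_conflicting_duplicate_addition_raises(self, chain_model):
        add = ReactionAddition("R_uptake", {"M": -2.0}, 0.0, 5.0)
        with pytest.raises(ModelValidationError, match="already present"):
            ff.augment_model(chain_model, additions=[add])

    def test_unknown_reaction_in_update_raises(self, chain_model):
        with pytest.raises(KeyError):
            ff.augment_model(chain_model, gpr_updates=[GprUpdate("nope", "", "g1")])
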