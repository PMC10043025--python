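import json

import numpy as np
import pytest

from sensnet.io import (
    ModelFormatError,
    curate_model,
    fva,
    load_model,
    maximize_biomass,
    save_model,
)
from sensnet.model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    common_reactions,
    reaction_key,
)


def rxn(id, stoich, **kw):
    return Reaction(id=id, stoichiometry=stoich, **kw)


class TestReactionKey:
    def test_metabolite_order_invariance(self):
        a = rxn("x", {"A[c]": -1, "B[c]": -1, "C[c]": 1})
        b = rxn("y", {"C[c]": 1, "B[c]": -1, "A[c]": -1})
        assert reaction_key(a) == reaction_key(b)
        assert reaction_key(a).orientation_sign == reaction_key(b).orientation_sign

    def test_reversal_gives_same_key_opposite_sign(self):
        fwd = rxn("x", {"A[c]": -1, "B[c]": -1, "C[c]": 1})
        rev = rxn("y", {"A[c]": 1, "B[c]": 1, "C[c]": -1})
        kf, kr = reaction_key(fwd), reaction_key(rev)
        assert kf == kr
        assert kf.canonical_form == kr.canonical_form
        assert kf.orientation_sign == -kr.orientation_sign

    def test_distinct_formulas_distinct_keys(self):
        assert reaction_key(rxn("x", {"A[c]": -1, "C[c]": 1})) != reaction_key(
            rxn("y", {"A[c]": -1, "D[c]": 1})
        )

    def test_key_idempotent_under_canonicalization(self):
        r = rxn("x", {"B[c]": 2, "A[c]": -1})
        key = reaction_key(r)
        canonical = rxn("x2", dict(key.canonical_form))
        key2 = reaction_key(canonical)
        assert key2 == key
        assert key2.orientation_sign == 1

    def test_coefficients_matter(self):
        assert reaction_key(rxn("x", {"A[c]": -1, "B[c]": 1})) != reaction_key(
            rxn("y", {"A[c]": -2, "B[c]": 1})
        )


class TestCommonReactions:
    def _model(self, mid, formulas):
        mets = sorted({met for f in formulas for met, _ in f})
        return MetabolicModel(
            id=mid,
            metabolites=[
                Metabolite(id=m.replace("[c]", "_c"), compartment="c") for m in mets
            ],
            reactions=[
                rxn(f"r{i}", dict(f)) for i, f in enumerate(formulas)
            ],
        )

    def test_intersection(self):
        l = self._model("l", [
            (("A[c]", -1.0), ("B[c]", 1.0)),
            (("B[c]", -1.0), ("C[c]", 1.0)),
            (("C[c]", -1.0), ("D[c]", 1.0)),
        ])
        m = self._model("m", [
            (("B[c]", -1.0), ("C[c]", 1.0)),
            (("C[c]", -1.0), ("D[c]", 1.0)),
            (("D[c]", -1.0), ("A[c]", 1.0)),
        ])
        assert len(common_reactions(l, m)) == 2

    def test_self_intersection_is_everything(self):
        l = self._model("l", [
            (("A[c]", -1.0), ("B[c]", 1.0)),
            (("B[c]", -1.0), ("C[c]", 1.0)),
        ])
        assert common_reactions(l, l) == set(l.reaction_keys)

    def test_opposite_directions_still_common(self):
        l = self._model("l", [(("A[c]", -1.0), ("B[c]", 1.0))])
        m = self._model("m", [(("A[c]", 1.0), ("B[c]", -1.0))])
        assert len(common_reactions(l, m)) == 1

    def test_disjoint_namespace_warns_empty(self):
        l = self._model("l", [(("A[c]", -1.0), ("B[c]", 1.0))])
        m = self._model("m", [(("X[c]", -1.0), ("Y[c]", 1.0))])
        with pytest.warns(UserWarning, match="namespace"):
            assert common_reactions(l, m) == set()


class TestModelValidation:
    def test_undeclared_metabolite_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            MetabolicModel(
                id="bad",
                metabolites=[Metabolite(id="A_c", compartment="c")],
                reactions=[rxn("r1", {"A[c]": -1, "Z[c]": 1})],
            )

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ValueError, match="empty stoichiometry"):
            Reaction(id="r", stoichiometry={"A[c]": 0.0})

    def test_stoichiometric_matrix_matches_reactions(self):
        model = MetabolicModel(
            id="toy",
            metabolites=[Metabolite(id="A_c", compartment="c")],
            reactions=[rxn("r1", {"A[c]": 1.0}), rxn("r2", {"A[c]": -1.0})],
        )
        assert np.array_equal(model.N, [[1.0, -1.0]])


class TestJsonIO:
    def test_toy_two_reaction_fixture(self, tmp_path):
        doc = {
            "id": "toy",
            "metabolites": [{"id": "A_c", "compartment": "c"}],
            "reactions": [
                {"id": "r1", "metabolites": {"A_c": 1}, "lower_bound": 0,
                 "upper_bound": 1000},
                {"id": "r2", "metabolites": {"A_c": -1}, "lower_bound": 0,
                 "upper_bound": 1000},
            ],
        }
        p = tmp_path / "toy.json"
        p.write_text(json.dumps(doc))
        model = load_model(p, format="json")
        assert np.array_equal(model.N, [[1.0, -1.0]])
        assert [r.id for r in model.reactions] == ["r1", "r2"]

    def test_undeclared_metabolite_is_format_error(self, tmp_path):
        doc = {
            "id": "bad",
            "metabolites": [{"id": "A_c", "compartment": "c"}],
            "reactions": [{"id": "r1", "metabolites": {"Z_c": 1}}],
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="undeclared"):
            load_model(p, format="json")

    def test_round_trip_reproduces_matrix_exactly(self, tmp_path, medium_network):
        p = tmp_path / "net.json"
        save_model(medium_network, p)
        again = load_model(p, format="json")
        assert np.array_equal(again.N, medium_network.N)
        assert [r.id for r in again.reactions] == [
            r.id for r in medium_network.reactions
        ]
        assert [r.reversible for r in again.reactions] == [
            r.reversible for r in medium_network.reactions
        ]

    def test_ec_and_genes_round_trip(self, tmp_path):
        model = MetabolicModel(
            id="annot",
            metabolites=[Metabolite(id="A_c", compartment="c")],
            reactions=[
                rxn("r1", {"A[c]": 1.0}, ec_numbers=["1.2.3.4"], genes=["g1", "g2"]),
                rxn("r2", {"A[c]": -1.0}, subsystem="Glycolysis"),
            ],
        )
        p = tmp_path / "annot.json"
        save_model(model, p)
        again = load_model(p, format="json")
        assert again.reactions[0].ec_numbers == ["1.2.3.4"]
        assert again.reactions[0].genes == ["g1", "g2"]
        assert again.reactions[1].subsystem == "Glycolysis"
        assert again.gene_to_reactions == {"g1": {"r1"}, "g2": {"r1"}}


class TestSbmlIO:
    def test_reversibility_flag_preserved(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        cm = cobra.Model("sb")
        a = cobra.Metabolite("A_c", compartment="c")
        b = cobra.Metabolite("B_c", compartment="c")
        r1 = cobra.Reaction("r1")
        r1.add_metabolites({a: -1, b: 1})
        r1.lower_bound, r1.upper_bound = -1000, 1000
        ex = cobra.Reaction("EX_A")
        ex.add_metabolites({a: -1})
        ex.lower_bound, ex.upper_bound = 0, 1000
        cm.add_reactions([r1, ex])
        p = tmp_path / "sb.xml"
        cobra.io.write_sbml_model(cm, str(p))
        model = load_model(p, format="sbml")
        assert model.reactions[0].reversible
        assert not model.reactions[1].reversible
        assert np.array_equal(
            model.N, [[-1.0, -1.0], [1.0, 0.0]]
        )


def _curation_base(extra=()):
    """EX_A -> A -> B -> biomass, optionally with extra reactions."""
    names = {"A", "B"}
    for r in extra:
        names |= {m[:-3] for m in r.stoichiometry}
    mets = [Metabolite(id=f"{n}_c", compartment="c") for n in sorted(names)]
    reactions = [
        rxn("EX_A", {"A[c]": -1.0}, reversible=True),
        rxn("r1", {"A[c]": -1.0, "B[c]": 1.0}),
        rxn("BIOMASS", {"B[c]": -1.0}),
    ] + list(extra)
    return MetabolicModel(
        id="cur", metabolites=mets, reactions=reactions,
        biomass_reaction="BIOMASS",
    )


class TestCuration:
    def test_dead_end_reaction_removed(self):
        # r_dead produces C which nothing consumes or exchanges: any flux
        # through it would accumulate C, so its flux polytope is {0}
        model = _curation_base(extra=[rxn("r_dead", {"B[c]": -1.0, "C[c]": 1.0})])
        ranges = fva(model)
        dead = model.reaction_index("r_dead")
        assert np.allclose(ranges[dead], 0.0)
        curated, report = curate_model(model)
        assert report.feasible and report.accepted
        assert report.removed == ["r_dead"]
        assert "r_dead" not in [r.id for r in curated.reactions]

    def test_connected_chain_untouched(self):
        model = _curation_base()
        curated, report = curate_model(model)
        assert report.accepted
        assert report.removed == []
        assert curated is model
        assert report.biomass_after == report.biomass_before

    def test_biomass_change_rejects_reduction(self):
        # a coarse LP tolerance misclassifies the low-flux cofactor branch
        # as blocked; removing it kills biomass, so the original is returned
        extra = [
            rxn("r_cof", {"A[c]": -1.0, "D[c]": 1.0}),
            rxn("BIOMASS2", {"B[c]": -1.0, "D[c]": -0.001}),
        ]
        names = {"A", "B", "D"}
        mets = [Metabolite(id=f"{n}_c", compartment="c") for n in sorted(names)]
        model = MetabolicModel(
            id="cur2",
            metabolites=mets,
            reactions=[
                rxn("EX_A", {"A[c]": -1.0}, reversible=True),
                rxn("r1", {"A[c]": -1.0, "B[c]": 1.0}),
            ] + extra,
            biomass_reaction="BIOMASS2",
        )
        curated, report = curate_model(model, lp_tolerance=5.0)
        assert not report.accepted
        assert curated is model
        assert report.removed == []

    def test_infeasible_biomass_flagged(self):
        model = MetabolicModel(
            id="dead",
            metabolites=[Metabolite(id="A_c", compartment="c"),
                         Metabolite(id="B_c", compartment="c")],
            reactions=[
                rxn("EX_A", {"A[c]": -1.0}, reversible=True),
                rxn("BIOMASS", {"B[c]": -1.0}),  # B is never produced
            ],
            biomass_reaction="BIOMASS",
        )
        curated, report = curate_model(model)
        assert not report.feasible
        assert curated is model

    def test_curation_is_monotone(self):
        from sensnet.synthetic import make_network

        model = make_network(seed=11, n_metabolites=25, n_reactions=40,
                             with_biomass=True)
        before = maximize_biomass(model)
        curated, report = curate_model(model)
        assert set(r.id for r in curated.reactions) <= set(
            r.id for r in model.reactions
        )
        if report.accepted:
            assert abs(report.biomass_after - before) <= 1e-6 * max(1.0, before)
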