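"""Network data model: construction, propensities, conservation analysis,
and the SBML-shorthand dialect."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import inoise
from inoise import models
from inoise.netmodel import (NetworkError, Reaction, SbmlShSyntaxError,
                             UnsupportedOrderError, build_network,
                             conservation_analysis, parse_sbmlsh, propensity,
                             propensities, write_sbmlsh)


class TestConstruction:
    def test_birth_death_structure(self, birth_death):
        assert birth_death.n_species == 1
        assert birth_death.n_reactions == 2
        assert birth_death.stoichiometric_matrix().tolist() == [[1, -1]]

    def test_autoreg_structure(self, autoreg):
        assert autoreg.n_species == 14
        assert autoreg.n_reactions == 20
        orders = autoreg.reaction_orders()
        assert set(orders) <= {1, 2}

    def test_duplicate_species_rejected(self):
        with pytest.raises(NetworkError, match="duplicate"):
            build_network([("A", 1.0), ("A", 2.0)], [])

    def test_negative_stoichiometry_rejected(self):
        with pytest.raises(NetworkError, match="nonnegative integer"):
            Reaction({"A": -1}, {}, 1.0)

    def test_trimolecular_rejected(self):
        with pytest.raises(UnsupportedOrderError, match="order 3"):
            build_network([("A", 1.0)], [({"A": 3}, {}, 1.0)])

    def test_unknown_species_in_reaction(self):
        with pytest.raises(NetworkError, match="unknown species"):
            build_network([("A", 1.0)], [({"B": 1}, {}, 1.0)])

    def test_negative_omega_rejected(self):
        with pytest.raises(NetworkError, match="Omega"):
            build_network([("A", 1.0)], [], omega=-1.0)

    def test_catalytic_noop_allowed_and_flagged(self):
        net = build_network([("A", 1.0)], [({"A": 1}, {"A": 1}, 1.0, "noop")])
        assert net.reactions[0].is_noop()


class TestPropensity:
    def test_first_order(self, birth_death):
        # death reaction X -> 0 with k=0.1: a = k*n
        assert propensity(birth_death, 1, [7]) == pytest.approx(0.7)

    def test_zeroth_order_scales_with_omega(self, birth_death):
        # birth: a = k*Omega
        assert propensity(birth_death, 0, [0]) == pytest.approx(100.0)

    def test_heterodimer_example(self):
        net = build_network([("A", 0.0), ("B", 0.0)],
                            [({"A": 1, "B": 1}, {}, 2.0)], omega=1.0)
        assert propensity(net, 0, [10, 5]) == pytest.approx(2.0 * 50)

    def test_homodimer_combinatorial_factor(self):
        net = build_network([("A", 0.0)], [({"A": 2}, {}, 2.0)], omega=1.0)
        # a = k * n(n-1) = 2 * 3 * 2
        assert propensity(net, 0, [3]) == pytest.approx(12.0)

    def test_insufficient_copies_gives_zero(self):
        net = build_network([("A", 0.0)], [({"A": 2}, {}, 1.0)], omega=1.0)
        assert propensity(net, 0, [1]) == 0.0

    def test_negative_copy_number_rejected(self, birth_death):
        with pytest.raises(NetworkError, match="negative"):
            propensity(birth_death, 0, [-1])

    def test_macroscopic_limit_of_bimolecular(self):
        # a/Omega -> k * X_A * X_B as Omega grows at fixed concentration
        net = build_network([("A", 2.0), ("B", 3.0)],
                            [({"A": 1, "B": 1}, {}, 0.5)], omega=1.0)
        for om in [10.0, 100.0, 1000.0]:
            n = np.array([2.0 * om, 3.0 * om])
            assert propensity(net, 0, n, omega=om) / om == pytest.approx(
                0.5 * 2.0 * 3.0, rel=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(n=st.lists(st.integers(0, 30), min_size=2, max_size=2),
           om=st.floats(0.5, 50.0))
    def test_nonnegative_and_vanishing(self, n, om):
        """Mass-action propensities are nonnegative and vanish whenever
        reactant copies are insufficient, for every reaction order."""
        net = build_network(
            [("A", 1.0), ("B", 1.0)],
            [({}, {"A": 1}, 1.3), ({"A": 1}, {}, 0.7),
             ({"A": 1, "B": 1}, {}, 0.2), ({"A": 2}, {"B": 1}, 0.4)],
            omega=om)
        a = propensities(net, n, omega=om)
        assert np.all(a >= 0)
        if n[0] < 2:
            assert a[3] == 0.0
        if n[0] < 1:
            assert a[1] == a[2] == 0.0


class TestConservation:
    def test_open_system_has_no_laws(self, birth_death):
        red = conservation_analysis(birth_death)
        assert red.n_laws == 0
        assert red.n_independent == 1

    def test_isomerization_single_law(self, isomerization):
        red = conservation_analysis(isomerization)
        assert red.n_laws == 1
        assert red.gamma.tolist() == [[1, 1]]
        assert red.totals[0] == pytest.approx(1.0)
        # deterministic elimination: the last-indexed species is dependent
        assert red.dependent_ids == ["B"]
        assert red.independent_ids == ["A"]

    def test_autoreg_five_pools(self, autoreg_reduction):
        red = autoreg_reduction
        assert red.n_laws == 5
        assert red.n_independent == 9
        S = red.network.stoichiometric_matrix()
        assert np.all(red.gamma @ S == 0)  # exact integer arithmetic

    def test_autoreg_law_contents(self, autoreg, autoreg_reduction):
        """Each law is one molecular pool: gene, kinase, phosphatase and the
        two protease totals."""
        ids = autoreg.species_ids()
        pools = [{"G", "GPs", "GPs2"}, {"K", "KP"}, {"R", "RPs"},
                 {"E", "EP"}, {"D", "DPs"}]
        found = []
        for row in autoreg_reduction.gamma:
            support = {ids[i] for i in np.nonzero(row)[0]}
            assert np.all(row[np.nonzero(row)] == 1)
            found.append(support)
        assert sorted(map(sorted, found)) == sorted(map(sorted, pools))

    def test_recovery_reproduces_any_reachable_state(self, autoreg,
                                                     autoreg_reduction):
        red = autoreg_reduction
        tr = inoise.ssa_run(autoreg, t_end=0.05, seed=1, max_events=2000)
        for state in tr.states[:: max(1, len(tr.states) // 20)]:
            x = state / autoreg.omega
            y = x[red.independent_idx]
            np.testing.assert_allclose(red.recover(y), x, atol=1e-12)

    def test_with_totals_shifts_affine_part(self, isomerization):
        red = conservation_analysis(isomerization)
        red2 = red.with_totals([2.5])
        np.testing.assert_allclose(red2.recover([1.0]), [1.0, 1.5])

    def test_laws_csv_roundtrip_values(self, autoreg_reduction):
        text = autoreg_reduction.laws_csv()
        assert text.count("\n") == 6  # header + 5 laws


SBMLSH_MINIMAL = """\
@model = bd
  omega = 50
@species
  X = 0.5
@reactions
@r = birth
  -> X
  2.0
@r = death
  X ->
  0.4
"""


class TestSbmlSh:
    def test_minimal_document(self):
        net = parse_sbmlsh(SBMLSH_MINIMAL)
        assert net.n_species == 1 and net.n_reactions == 2
        assert net.omega == 50.0
        assert net.reactions[0].product_stoich == {"X": 1}
        assert net.reactions[1].rate_constant == pytest.approx(0.4)

    def test_reversible_expands_to_two_reactions(self):
        text = SBMLSH_MINIMAL.replace("@r = death\n  X ->\n  0.4\n",
                                      "@r = iso\n  X <-> X + X\n  0.4, 0.1\n")
        net = parse_sbmlsh(text)
        assert net.n_reactions == 3
        assert net.reactions[2].label == "iso_rev"

    def test_undeclared_species_error_names_reaction(self):
        bad = SBMLSH_MINIMAL.replace("-> X", "-> Y", 1)
        with pytest.raises(SbmlShSyntaxError, match="undeclared species 'Y'"):
            parse_sbmlsh(bad)

    def test_missing_reactions_section(self):
        with pytest.raises(SbmlShSyntaxError, match="no @reactions"):
            parse_sbmlsh("@model = empty\n@species\n  X = 1\n")

    def test_syntax_error_carries_line_number(self):
        bad = SBMLSH_MINIMAL.replace("X = 0.5", "X == 0.5")
        with pytest.raises(SbmlShSyntaxError) as err:
            parse_sbmlsh(bad)
        assert err.value.line == 4

    @pytest.mark.parametrize("builder", [
        lambda: models.birth_death(1.0, 0.1, omega=100.0),
        models.linear_gene,
        models.dimerization,
        models.enzyme_cycle,
        lambda: models.srna_model("i"),
        lambda: models.srna_model("ii"),
        models.autoreg_model,
        lambda: models.autoreg_model(variant="oscillatory", n_genes=10),
    ])
    def test_write_parse_roundtrip_identity(self, builder):
        """parse(write(net)) reproduces every field of every fixture."""
        net = builder()
        net2 = parse_sbmlsh(write_sbmlsh(net))
        assert net2.name == net.name
        assert net2.omega == net.omega
        assert [s.id for s in net2.species] == [s.id for s in net.species]
        assert [s.initial_value for s in net2.species] == [
            s.initial_value for s in net.species]
        for r1, r2 in zip(net.reactions, net2.reactions):
            assert r1.reactant_stoich == r2.reactant_stoich
            assert r1.product_stoich == r2.product_stoich
            assert r1.rate_constant == r2.rate_constant
            assert r1.label == r2.label
        # and the serialisation is a fixed point
        assert write_sbmlsh(net2) == write_sbmlsh(net)

    def test_shipped_fixture_files_match_builders(self):
        from importlib import resources
        pairs = {
            "autoreg_reference.sbmlsh": models.autoreg_model,
            "srna_set_i.sbmlsh": lambda: models.srna_model("i"),
        }
        for fname, builder in pairs.items():
            text = (resources.files("inoise") / "fixtures" / fname).read_text()
            net = parse_sbmlsh(text)
            ref = builder()
            assert net.n_species == ref.n_species
            assert net.n_reactions == ref.n_reactions
            assert write_sbmlsh(net) == write_sbmlsh(ref)

    def test_stoichiometry_csv(self, birth_death):
        text = birth_death.stoichiometry_csv()
        assert text.splitlines()[1] == "X,1,-1"
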