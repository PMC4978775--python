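"""Species/reaction enumeration, stoichiometry, and the mass-action RHS."""

import itertools

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lckphos.network import (
    build_network,
    build_rhs,
    build_validation_network,
    count_pair_dimers,
    enumerate_species,
)
from lckphos.params import (
    FORMS,
    LCK_PAIRS,
    PAIR_INDEX,
    SUBSTRATE_SITES,
    RateParameterSet,
    phosphorylate,
)


from conftest import uniform_params


class TestEnumeration:
    def test_active_network_counts(self, active_network):
        net = active_network
        assert len(net.species) == 23
        assert net.n_lck_dimers() == 16
        assert net.n_csk_dimers() == 2
        assert len(net.reactions) == 54
        kinds = {k: sum(1 for r in net.reactions if r.kind == k)
                 for k in ("association", "dissociation", "catalysis")}
        assert kinds == {"association": 18, "dissociation": 18, "catalysis": 18}

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(include_dead=True, csk_binding=False), 73),
            (dict(include_dead=True), 77),
            (dict(include_dead=True, dead_policy="substrate_only"), 45),
        ],
    )
    def test_dead_variant_species_counts(self, kwargs, expected):
        assert len(enumerate_species(**kwargs)) == expected

    def test_pair_dimer_counts_match_brute_force(self):
        """Heterodimer count for every 2-form pair against direct enumeration."""
        for a, b in itertools.combinations(FORMS, 2):
            brute = 0
            for enz, sub in ((a, b), (b, a)):
                for site, host in SUBSTRATE_SITES:
                    if host == sub:
                        brute += 1
            assert count_pair_dimers(a, b) == brute
        # the canonical illustrative pair
        assert count_pair_dimers("UU", "PU") == 3

    def test_enumeration_is_deterministic(self, active_network):
        again = build_network()
        assert [s.label for s in again.species] == [
            s.label for s in active_network.species
        ]
        assert [(r.kind, r.reactants, r.products, r.param) for r in again.reactions] == [
            (r.kind, r.reactants, r.products, r.param)
            for r in active_network.reactions
        ]

    def test_pair_index_covers_every_enzyme_and_site(self):
        for enz in FORMS:
            sites = {(s, h) for e, s, h in LCK_PAIRS if e == enz}
            assert sites == set(SUBSTRATE_SITES)
        assert len(PAIR_INDEX) == 16

    def test_no_reaction_consumes_fully_phosphorylated_substrate(self, active_network):
        for s in active_network.species:
            if s.kind in ("lck_dimer", "csk_dimer"):
                assert s.substrate.form != "PP"
        # and catalysis of (UU enzyme, Y394 on UU) yields free UU + free PU
        net = active_network
        dimer = net.index["UU:UU@Y394"]
        cat = [r for r in net.reactions
               if r.kind == "catalysis" and r.reactants == (dimer,)]
        assert len(cat) == 1
        assert set(cat[0].products) == {net.index["UU"], net.index["PU"]}

    def test_dead_enzymes_bind_like_active_but_never_catalyze(
        self, validation_network
    ):
        net = validation_network
        for s in net.species:
            if s.kind != "lck_dimer" or not s.enzyme.dead:
                continue
            i = net.index[s.label]
            by_kind = {r.kind: r for r in net.reactions if i in r.reactants}
            assoc = [r for r in net.reactions
                     if r.kind == "association" and r.products == (i,)]
            assert assoc[0].param == "k_on"
            pair = PAIR_INDEX[(s.enzyme.form, s.site, s.substrate.form)]
            assert by_kind["dissociation"].param == f"k_off_{pair}"
            assert by_kind["catalysis"].param is None  # rate exactly 0


class TestConservation:
    def test_stoichiometry_conserves_totals(self, active_network, validation_network):
        for net in (active_network, validation_network):
            for name, w in net.conservation_groups.items():
                residual = np.abs(w @ net.stoichiometry).max()
                assert residual == 0.0, name


class TestRHS:
    def test_no_catalysis_means_no_phosphorylation(self, active_network, rng):
        p = uniform_params().replace(
            **{f"k_cat_{i}": 0.0 for i in range(1, 17)},
            k_cat_csk_uu=0.0, k_cat_csk_pu=0.0,
        )
        rhs = build_rhs(active_network, p)
        y = rng.uniform(0, 100, len(active_network.species))
        d_p394 = active_network.phospho_y394_counts() @ rhs(0.0, y)
        d_p505 = active_network.phospho_y505_counts() @ rhs(0.0, y)
        assert abs(d_p394) < 1e-9 * np.abs(y).sum()
        assert abs(d_p505) < 1e-9 * np.abs(y).sum()

    def test_derivatives_finite_for_negative_inputs(self, active_network, rng):
        rhs = build_rhs(active_network, uniform_params(2.0))
        y = rng.uniform(-1, 1, len(active_network.species))
        assert np.all(np.isfinite(rhs(0.0, y)))

    def test_jacobian_matches_finite_differences(self, active_network, rng):
        rhs = build_rhs(active_network, uniform_params(0.37))
        y = rng.uniform(0, 10, len(active_network.species))
        J = rhs.jac(0.0, y)
        eps = 1e-6
        for i in rng.choice(len(y), 5, replace=False):
            dy = np.zeros_like(y)
            dy[i] = eps
            col = (rhs(0.0, y + dy) - rhs(0.0, y - dy)) / (2 * eps)
            np.testing.assert_allclose(J[:, i], col, rtol=1e-5, atol=1e-7)

    def test_single_dimer_matches_hand_written_michaelis_menten(self, active_network):
        """Isolated enzyme-substrate pair against a hand-coded 3-ODE system.

        Pair 6 (UU enzyme phosphorylating Y394 of UP) is isolated by making
        every other pair's binding vanishingly weak (huge k_off, zero k_cat):
        the full 23-species network must then track E + S <-> C -> E + P.
        """
        kon, koff, kcat = 1e-3, 1.0, 0.1
        p = uniform_params(0.0).replace(
            k_on=kon,
            **{f"k_off_{i}": 1e9 for i in range(1, 17)},
            k_off_csk_uu=1e9, k_off_csk_pu=1e9,
        ).replace(k_off_6=koff, k_cat_6=kcat)
        E0, S0 = 30.0, 200.0

        def mm(t, y):
            e, s, c = y
            return [
                -kon * e * s + (koff + kcat) * c,
                -kon * e * s + koff * c,
                kon * e * s - (koff + kcat) * c,
            ]

        T = 200.0
        t_eval = np.linspace(0, T, 21)
        ref = solve_ivp(mm, (0, T), [E0, S0, 0.0], t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        rhs = build_rhs(active_network, p)
        y0 = np.zeros(23)
        y0[active_network.index["UU"]] = E0
        y0[active_network.index["UP"]] = S0
        sol = solve_ivp(rhs, (0, T), y0, t_eval=t_eval, jac=rhs.jac,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        product = sol.y[active_network.index["PP"]]
        complex_ = sol.y[active_network.index["UU:UP@Y394"]]
        p_ref = S0 - ref.y[1] - ref.y[2]
        np.testing.assert_allclose(product, p_ref, atol=1e-4 * S0)
        np.testing.assert_allclose(complex_, ref.y[2], atol=1e-4 * S0)

    def test_phosphorylate_transitions(self):
        assert phosphorylate("UU", "Y394") == "PU"
        assert phosphorylate("UU", "Y505") == "UP"
        assert phosphorylate("PU", "Y505") == "PP"
        assert phosphorylate("UP", "Y394") == "PP"
        with pytest.raises(ValueError):
            phosphorylate("PP", "Y394")
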