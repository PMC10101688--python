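"""State space, generator construction, equilibria and detailed balance."""

import math
import warnings

import numpy as np
import pytest

from otopkin import (
    ChannelModel,
    Conditions,
    ConfigurationError,
    InvalidParameterError,
    boltzmann_distribution,
    build_rate_matrix,
    detailed_balance_violation,
    effective_rate,
    enumerate_states,
    stationary_distribution,
    verify_cycles,
)

RT = 0.593


class TestStateSpace:
    def test_four_elements_give_sixteen_states(self, model):
        space = enumerate_states(model)
        assert space.n_states == 16
        # index <-> bits is a bijection with bit i = element i
        seen = {space.index(space.bits(s)) for s in range(16)}
        assert seen == set(range(16))

    def test_single_element_gives_two_states(self, pore_only):
        assert enumerate_states(pore_only).n_states == 2

    def test_enumeration_is_deterministic(self, model):
        a = enumerate_states(model)
        b = enumerate_states(model)
        assert a.labels() == b.labels()

    def test_labels_encode_configuration(self, model):
        space = enumerate_states(model)
        assert space.label(0) == "pore-.H-.ZnA-.ZnB-"
        assert space.label(0b0011) == "pore+.H+.ZnA-.ZnB-"


class TestEffectiveRate:
    def test_no_modifiers_returns_base(self):
        assert effective_rate(0.02, [], RT) == 0.02

    def test_proton_coupling_factor_is_about_850(self):
        assert effective_rate(1.0, [-4.0], RT) == pytest.approx(850, abs=5)

    def test_barrier_increase_slows_rate(self):
        assert effective_rate(25.0, [3.0], RT) == pytest.approx(
            25 * math.exp(-3 / RT), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            effective_rate(0.0, [], RT)
        with pytest.raises(InvalidParameterError):
            effective_rate(1.0, [], 0.0)


class TestGeneratorMatrix:
    def q(self, model, ph=5.5, zn=1e-3):
        return build_rate_matrix(model, Conditions.from_ph_zn(ph, zn))

    def test_rows_sum_to_zero_and_offdiagonals_nonnegative(self, model):
        Q = self.q(model).Q
        scale = np.abs(Q).max()
        assert np.abs(Q.sum(axis=1)).max() <= 1e-12 * scale
        off = Q - np.diag(np.diag(Q))
        assert off.min() >= 0

    def test_sparsity_is_hypercube_adjacency(self, model):
        Q = self.q(model).Q
        for s in range(16):
            for t in range(16):
                if s != t and Q[s, t] != 0:
                    assert bin(s ^ t).count("1") == 1

    def test_unliganded_opening_rate(self, model):
        rm = self.q(model, ph=7.4, zn=0.0)
        closed = rm.space.index([0, 0, 0, 0])
        open_ = rm.space.index([1, 0, 0, 0])
        assert rm.Q[closed, open_] == pytest.approx(0.02, rel=1e-12)

    def test_proton_bound_opening_is_sped_by_minus4(self, model):
        rm = self.q(model)
        hc = rm.space.index([0, 1, 0, 0])
        ho = rm.space.index([1, 1, 0, 0])
        c = rm.space.index([0, 0, 0, 0])
        o = rm.space.index([1, 0, 0, 0])
        assert rm.Q[hc, ho] == pytest.approx(0.02 * math.exp(4 / RT), rel=1e-12)
        # the speed-up ratio itself
        assert rm.Q[hc, ho] / rm.Q[c, o] == pytest.approx(
            math.exp(4 / RT), rel=1e-10
        )

    def test_pseudo_first_order_proton_binding(self, model):
        rm = self.q(model, ph=5.5, zn=0.0)
        c = rm.space.index([0, 0, 0, 0])
        hc = rm.space.index([0, 1, 0, 0])
        assert rm.Q[c, hc] == pytest.approx(5e4 * 10 ** -5.5, rel=1e-12)

    def test_open_pore_modulates_activating_zn_binding(self, model):
        rm = self.q(model)
        o = rm.space.index([1, 0, 0, 0])
        ozn = rm.space.index([1, 0, 1, 0])
        c = rm.space.index([0, 0, 0, 0])
        czn = rm.space.index([0, 0, 1, 0])
        assert rm.Q[o, ozn] / rm.Q[c, czn] == pytest.approx(
            math.exp(5 / RT), rel=1e-10
        )
        assert rm.Q[ozn, o] / rm.Q[czn, c] == pytest.approx(
            math.exp(-1 / RT), rel=1e-10
        )

    def test_blocking_site_rates_are_state_independent(self, model):
        rm = self.q(model)
        ratios = []
        for s in range(16):
            if not (s >> 3) & 1:
                t = s | 0b1000
                ratios.append((rm.Q[s, t], rm.Q[t, s]))
        expected_on = 5e4 * 1e-3
        for on, off in ratios:
            assert on == pytest.approx(expected_on, rel=1e-12)
            assert off == pytest.approx(20.0, rel=1e-12)

    def test_competition_destabilization_speeds_only_exits(self, model):
        """Leaving a doubly-occupied (H+ and ZnA) state is accelerated by
        exp(+6/RT); entering it is untouched (exit-only partition)."""
        rm = self.q(model)
        idx = rm.space.index
        hzn_c = idx([0, 1, 1, 0])
        h_c = idx([0, 1, 0, 0])
        zn_c = idx([0, 0, 1, 0])
        # exits: ZnA unbinding and H unbinding from the doubly-bound state
        assert rm.Q[hzn_c, h_c] == pytest.approx(
            1.0 * math.exp(6 / RT), rel=1e-12
        )
        assert rm.Q[hzn_c, zn_c] == pytest.approx(
            1.0 * math.exp(6 / RT), rel=1e-12
        )
        # entries keep their unmodified closed-pore rates
        assert rm.Q[h_c, hzn_c] == pytest.approx(35 * 1e-3, rel=1e-12)
        assert rm.Q[zn_c, hzn_c] == pytest.approx(5e4 * 10 ** -5.5, rel=1e-12)
        # pore flips between two doubly-occupied states are unmodified
        hzn_o = idx([1, 1, 1, 0])
        assert rm.Q[hzn_c, hzn_o] == pytest.approx(
            0.02 * math.exp((4 + 3) / RT), rel=1e-12
        )

    def test_missing_ligand_concentration_raises(self, model):
        with pytest.raises(ConfigurationError, match="Zn"):
            build_rate_matrix(model, Conditions({"H": 1e-7}))


class TestEquilibrium:
    def test_isolated_pore_open_probability(self, pore_only):
        p = boltzmann_distribution(pore_only, Conditions({}))
        assert p[1] == pytest.approx(0.02 / 25.02, rel=1e-12)

    def test_isolated_blocking_site_occupancy(self, blocker_only):
        p = boltzmann_distribution(blocker_only, Conditions({"Zn": 1e-3}))
        blocked = p[2] + p[3]
        assert blocked == pytest.approx(50 / 70, rel=1e-10)

    @pytest.mark.parametrize("ph", [7.4, 6.0, 5.5])
    @pytest.mark.parametrize("zn", [0.0, 0.3e-3, 1e-3, 3e-3])
    def test_energy_and_kernel_routes_agree(self, model, ph, zn):
        cond = Conditions.from_ph_zn(ph, zn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_energy = boltzmann_distribution(model, cond)
        p_kernel = stationary_distribution(build_rate_matrix(model, cond).Q)
        assert p_energy.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.abs(p_energy - p_kernel).max() <= 1e-9

    def test_zero_concentration_warns_and_restricts_support(self, model):
        cond = Conditions.from_ph_zn(7.4, 0.0)
        with pytest.warns(UserWarning, match="unreachable"):
            p = boltzmann_distribution(model, cond)
        space = enumerate_states(model)
        zn_on = space.mask(ZnA=True) | space.mask(ZnB=True)
        assert p[zn_on].sum() == 0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestDetailedBalance:
    @pytest.mark.parametrize("ph,zn", [(5.5, 1e-3), (7.4, 3e-3), (6.0, 0.3e-3)])
    def test_built_generator_satisfies_detailed_balance(self, model, ph, zn):
        assert verify_cycles(model, Conditions.from_ph_zn(ph, zn)) <= 1e-9

    def test_perturbed_edge_breaks_detailed_balance(self, model):
        """Doubling a single directed transition rate violates Kolmogorov's
        cycle criterion (the energetic construction is destroyed)."""
        rm = build_rate_matrix(model, Conditions.from_ph_zn(5.5, 1e-3))
        Q = rm.Q.copy()
        hc = rm.space.index([0, 1, 0, 0])
        c = rm.space.index([0, 0, 0, 0])
        Q[hc, c] *= 2.0
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        assert detailed_balance_violation(Q) > 0.1

    def test_single_element_has_no_cycles(self, pore_only):
        assert verify_cycles(pore_only, Conditions({})) <= 1e-12


class TestPartitionConvention:
    def test_any_partition_preserves_detailed_balance(self, model):
        for alpha in (0.0, 0.37, 1.0):
            m = model.with_partition(alpha)
            assert verify_cycles(m, Conditions.from_ph_zn(5.5, 1e-3)) <= 1e-9

    def test_partition_leaves_equilibrium_unchanged(self, model):
        cond = Conditions.from_ph_zn(5.5, 1e-3)
        p1 = boltzmann_distribution(model, cond)
        p2 = boltzmann_distribution(model.with_partition(0.5), cond)
        assert np.abs(p1 - p2).max() <= 1e-15
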