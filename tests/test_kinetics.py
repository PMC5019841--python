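"""Mechanistic degradation model: elementary rates, trajectories,
steady states, conservation and competition."""

import numpy as np
import pytest
from scipy.integrate import odeint, solve_ivp
from scipy.linalg import expm

from mapk_rewire import (
    KineticParams,
    Scenario,
    binding_occupancy,
    competition_fold_change,
    effective_phospho_rate,
    simulate,
    steady_state,
)


class TestEffectivePhosphoRate:
    def test_no_degron_no_phosphorylation(self, default_params):
        assert effective_phospho_rate(0, default_params) == 0.0

    def test_linear_below_saturation(self, default_params):
        r1 = effective_phospho_rate(1, default_params)
        r2 = effective_phospho_rate(2, default_params)
        assert r2 == pytest.approx(2 * r1)

    def test_flat_at_and_beyond_saturation(self, default_params):
        r3 = effective_phospho_rate(3, default_params)
        assert effective_phospho_rate(4, default_params) == r3
        assert effective_phospho_rate(5, default_params) == r3

    def test_smooth_variant_plateaus_and_rises(self):
        p = KineticParams(smooth_saturation=True)
        rates = [effective_phospho_rate(m, p) for m in range(6)]
        assert rates[0] == 0.0
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_out_of_range_count_rejected(self, default_params):
        with pytest.raises(ValueError):
            effective_phospho_rate(6, default_params)


class TestBindingOccupancy:
    def test_unmatched_domains_never_bind(self, default_params):
        s = Scenario(domains_matched=False)
        assert binding_occupancy(10.0, 100.0, s, default_params) == 0.0

    def test_aba_inducible_requires_aba(self, default_params):
        s = Scenario(binding_mode="aba_inducible")
        assert binding_occupancy(10.0, 0.0, s, default_params) == 0.0

    def test_aba_saturation_matches_closed_form(self):
        p = KineticParams(K_aba=1.0, n_aba=2.0)
        s = Scenario(binding_mode="aba_inducible")
        asymptote = binding_occupancy(0.0, 1e9, s, p)
        at_100 = binding_occupancy(0.0, 100.0, s, p)
        hill_100 = 100.0**2 / (1.0 + 100.0**2)
        assert at_100 == pytest.approx(asymptote * hill_100, rel=1e-12)
        assert at_100 >= 0.99 * asymptote

    def test_swapped_orientation_halves_binding(self, default_params):
        full = binding_occupancy(0, 0, Scenario(), default_params)
        swapped = binding_occupancy(
            0, 0, Scenario(binding_mode="constitutive_swapped"), default_params
        )
        assert swapped == pytest.approx(0.5 * full)


class TestSimulate:
    times = np.linspace(0.0, 300.0, 11)

    def test_broken_degron_equals_zero_phospho_rate(self, default_params):
        inputs = {"alpha": 10.0}
        broken = simulate(
            default_params, Scenario(degron_functional=False), inputs, self.times
        )
        no_phos = simulate(
            KineticParams(k_phos=0.0), Scenario(), inputs, self.times
        )
        np.testing.assert_allclose(
            broken.total_reporter, no_phos.total_reporter, rtol=1e-9
        )

    def test_no_degradation_steady_state_is_synthesis_over_dilution(self):
        p = KineticParams(k_phos=0.0, k_basal_deg=0.0)
        traj = simulate(p, Scenario(), {"alpha": 10.0}, [0.0, 5000.0])
        assert traj.total_reporter[-1] == pytest.approx(
            p.k_syn / p.k_dil, rel=1e-6
        )

    def test_linear_regime_matches_matrix_exponential(self, default_params):
        """With the kinase pinned active and occupancy fixed, the substrate
        system is linear: x' = Mx + b with closed form via expm."""
        p = default_params
        s = Scenario(constitutive_kinase=True)
        fb = binding_occupancy(0.0, 0.0, s, p)
        r_p = effective_phospho_rate(p.m, p) * fb * p.kinase_total
        M = np.array(
            [
                [-(p.k_dil + r_p), p.k_deph],
                [r_p, -(p.k_deg + p.k_dil + p.k_deph)],
            ]
        )
        b = np.array([p.k_syn, 0.0])
        x0 = np.array([80.0, 0.0])
        xss = -np.linalg.solve(M, b)
        times = np.linspace(0.0, 240.0, 9)
        traj = simulate(
            p, s, {"alpha": 0.0}, times, y0=[p.kinase_total, x0[0], x0[1]]
        )
        for t, total in zip(times, traj.total_reporter):
            x = xss + expm(M * t) @ (x0 - xss)
            assert total == pytest.approx(x.sum(), rel=1e-3)

    def test_nonnegative_species_everywhere(self, default_params):
        traj = simulate(
            default_params, Scenario(), {"alpha": 10.0}, np.linspace(0, 600, 25)
        )
        for name, arr in traj.species.items():
            assert np.all(arr >= 0), name

    def test_mass_conserved_without_sources_or_sinks(self):
        p = KineticParams(
            k_syn=0.0, k_dil=0.0, k_deg=0.0, k_basal_deg=0.0,
            k_phos=0.1, k_deph=0.02,
        )
        s = Scenario(explicit_binding=True, constitutive_kinase=True)
        y0 = [p.kinase_total, 5.0, 1.0, 0.5]
        traj = simulate(p, s, {"alpha": 0.0}, np.linspace(0, 500, 11), y0=y0)
        total = traj.total_reporter
        np.testing.assert_allclose(total, total[0], rtol=1e-6)

    def test_invalid_times_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, Scenario(), {"alpha": 1.0}, [10.0, 5.0])


class TestSteadyState:
    def test_exact_without_degradation(self):
        p = KineticParams(k_phos=0.0)
        ss = steady_state(p, Scenario(), {"alpha": 10.0})
        assert ss["total_reporter"] == pytest.approx(p.k_syn / p.k_dil, rel=1e-9)

    def test_constitutive_kinase_degrades_functional_reporter(
        self, default_params
    ):
        functional = steady_state(
            default_params, Scenario(constitutive_kinase=True), {}
        )
        broken = steady_state(
            default_params,
            Scenario(constitutive_kinase=True, degron_functional=False),
            {},
        )
        assert broken["total_reporter"] / functional["total_reporter"] > 1.0

    def test_agrees_with_long_time_integration(self, rng):
        for _ in range(5):
            p = KineticParams(
                k_syn=rng.uniform(0.5, 2),
                k_dil=rng.uniform(0.005, 0.02),
                k_phos=rng.uniform(0.01, 0.1),
                k_deg=rng.uniform(0.05, 0.5),
                k_deph=rng.uniform(0.0, 0.05),
                m=int(rng.integers(1, 4)),
            )
            ss = steady_state(p, Scenario(), {"alpha": 10.0})
            traj = simulate(p, Scenario(), {"alpha": 10.0}, [0.0, 1e4])
            assert ss["total_reporter"] == pytest.approx(
                traj.total_reporter[-1], rel=1e-3
            )

    @pytest.mark.parametrize(
        "other",
        [
            Scenario(kinase_active=False),
            Scenario(degron_functional=False),
            Scenario(domains_matched=False),
        ],
        ids=["dead_kinase", "broken_degron", "unmatched_domains"],
    )
    def test_control_scenarios_equivalent(self, default_params, other):
        """All three controls disable the same (phospho-degradation) arm,
        so their reporter trajectories coincide."""
        times = np.linspace(0, 300, 7)
        ref = simulate(
            default_params, Scenario(kinase_active=False), {"alpha": 10.0}, times
        )
        alt = simulate(default_params, other, {"alpha": 10.0}, times)
        np.testing.assert_allclose(
            ref.total_reporter, alt.total_reporter, rtol=1e-9
        )

    def test_monotone_in_phospho_rate_degron_count_and_aba(self):
        base = dict(k_syn=1.0, k_dil=0.0077, k_deg=0.2)
        levels_kphos = [
            steady_state(
                KineticParams(**base, k_phos=k), Scenario(), {"alpha": 10.0}
            )["total_reporter"]
            for k in (0.0, 0.02, 0.05, 0.1)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(levels_kphos, levels_kphos[1:]))
        levels_m = [
            steady_state(
                KineticParams(**base, m=m), Scenario(), {"alpha": 10.0}
            )["total_reporter"]
            for m in (0, 1, 2, 3)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(levels_m, levels_m[1:]))
        s_aba = Scenario(binding_mode="aba_inducible")
        levels_aba = [
            steady_state(
                KineticParams(**base), s_aba, {"alpha": 10.0, "aba": dose}
            )["total_reporter"]
            for dose in (0.0, 0.3, 1.0, 3.0, 30.0)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(levels_aba, levels_aba[1:]))

    def test_basal_degradation_lowers_steady_state_with_degron_count(self):
        """Multi-degron reporters express lower even without induction when
        the phospho-independent arm is enabled."""
        levels = [
            steady_state(
                KineticParams(k_basal_deg=0.002, m=m), Scenario(), {"alpha": 0.0}
            )["total_reporter"]
            for m in (1, 3, 5)
        ]
        assert levels[0] > levels[1] > levels[2]


class TestCompetition:
    def test_infinite_capacity_means_no_competition(self, default_params):
        for comp in ("kinase", "substrate"):
            alone, with_c = competition_fold_change(
                default_params, Scenario(), comp
            )
            # the two runs use ODE systems of different size, so agreement
            # is to integrator accuracy, not bitwise
            assert with_c == pytest.approx(alone, rel=1e-6)

    def test_finite_pools_reduce_fold_change(self):
        alone_k, with_k = competition_fold_change(
            KineticParams(ste7_capacity=2.0), Scenario(), "kinase"
        )
        assert with_k < alone_k
        alone_s, with_s = competition_fold_change(
            KineticParams(scf_capacity=30.0), Scenario(), "substrate"
        )
        assert with_s < alone_s

    def test_substrate_competition_matches_independent_oracle(self):
        """Direct coupled two-substrate ODE, independently coded and
        integrated with LSODA, reproduces the reported fold change."""
        p = KineticParams(scf_capacity=30.0)
        s = Scenario()
        alone, with_c = competition_fold_change(p, s, "substrate")

        occ = 10.0 / (p.K_alpha + 10.0)
        fb = 1.0 / (1.0 + p.K_bind / p.kinase_total)
        r_coeff = p.k_phos * min(p.m, p.m_sat) * fb

        def rhs(y, t):
            kstar, su1, sp1, su2, sp2 = y
            dk = p.k_act * occ * (p.kinase_total - kstar) - p.k_inact * kstar
            r_p = r_coeff * kstar
            kdeg = p.k_deg * p.scf_capacity / (p.scf_capacity + sp1 + sp2)
            return [
                dk,
                p.k_syn - (p.k_dil + r_p) * su1 + p.k_deph * sp1,
                r_p * su1 - (kdeg + p.k_dil + p.k_deph) * sp1,
                p.k_syn - (p.k_dil + r_p) * su2 + p.k_deph * sp2,
                r_p * su2 - (kdeg + p.k_dil + p.k_deph) * sp2,
            ]

        su0 = p.k_syn / p.k_dil
        y = odeint(
            rhs, [0.0, su0, 0.0, su0, 0.0], [0.0, 180.0], rtol=1e-10, atol=1e-12
        )
        oracle = (y[0, 1] + y[0, 2]) / (y[-1, 1] + y[-1, 2])
        assert with_c == pytest.approx(oracle, rel=1e-2)

    def test_unknown_competitor_rejected(self, default_params):
        with pytest.raises(ValueError):
            competition_fold_change(default_params, Scenario(), "nonsense")
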