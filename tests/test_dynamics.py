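"""Dynamics core: feeding kernel, single-step physics, mass bookkeeping."""

import numpy as np
import pytest

import reefspectra as rs
from reefspectra import CommunityState, ModelParams, ReefDynamics, feeding_kernel
from reefspectra.habitat import RefugeProfile


@pytest.fixture()
def params():
    return ModelParams()


class TestFeedingKernel:
    def test_maximum_at_preferred_ratio(self, params):
        prey = 1.0
        pred = prey * np.exp(params.ppmr_mean)
        assert feeding_kernel(pred, prey, params) == pytest.approx(1.0)
        assert feeding_kernel(pred * 1.5, prey, params) < 1.0

    def test_symmetric_in_log_ratio(self, params):
        prey = 2.0
        up = prey * np.exp(params.ppmr_mean + params.ppmr_sigma)
        dn = prey * np.exp(params.ppmr_mean - params.ppmr_sigma)
        assert feeding_kernel(up, prey, params) == pytest.approx(
            feeding_kernel(dn, prey, params), rel=1e-12
        )

    def test_three_sigma_tail_below_two_percent(self, params):
        prey = 1.0
        pred = prey * np.exp(params.ppmr_mean + 3 * params.ppmr_sigma)
        assert feeding_kernel(pred, prey, params) < 0.02
        assert feeding_kernel(pred, prey, params) == pytest.approx(np.exp(-4.5), rel=1e-9)

    def test_rejects_nonpositive_mass(self, params):
        with pytest.raises(ValueError):
            feeding_kernel(0.0, 1.0, params)
        with pytest.raises(ValueError):
            feeding_kernel(1.0, -2.0, params)


class TestCommunityState:
    def test_rejects_negative_spectrum(self, coarse_grid):
        n = np.zeros(coarse_grid.n_bins)
        bad = n.copy()
        bad[3] = -1e-9
        with pytest.raises(ValueError):
            CommunityState(bad, n, n, 0.0, 0.0)

    def test_biomass_accounting(self, coarse_grid):
        st = CommunityState.seed(coarse_grid, biomass_per_bin=1.0, algae=10.0, detritus=5.0)
        assert st.biomass(coarse_grid, "predators") == pytest.approx(coarse_grid.n_bins)
        assert st.system_mass(coarse_grid) == pytest.approx(3 * coarse_grid.n_bins + 15.0)


def zero_input_params(**kw):
    base = dict(
        larval_input={"predators": 0.0, "herbivores": 0.0, "invertebrates": 0.0},
        algal_production=1e-12,
        interference=0.0,
        dt=0.01,
    )
    base.update(kw)
    return ModelParams(**base)


class TestStep:
    def test_empty_state_is_fixed_point(self, coarse_grid):
        p = zero_input_params()
        dyn = ReefDynamics(coarse_grid, p)
        st = CommunityState.empty(coarse_grid)
        nxt, diag = dyn.step(st)
        for grp in rs.GROUPS:
            assert np.all(nxt.spectrum(grp) == 0.0)
        assert diag.residual == pytest.approx(0.0, abs=1e-15)

    def test_pure_background_mortality_decays_exponentially(self, coarse_grid):
        # no food, no recruitment, no predators: herbivores decay bin-wise
        # at their intrinsic mortality rate
        p = zero_input_params(dt=0.002)
        dyn = ReefDynamics(coarse_grid, p)
        n0 = np.zeros(coarse_grid.n_bins)
        occupied = slice(20, 40)
        n0[occupied] = 1.0
        st = CommunityState(np.zeros_like(n0), n0.copy(), np.zeros_like(n0), 0.0, 0.0)
        t_end = 1.0
        for _ in range(int(t_end / p.dt)):
            st, _ = dyn.step(st)
        mort = dyn._mort["herbivores"][occupied]
        expected = np.exp(-mort * t_end)
        np.testing.assert_allclose(st.herbivores[occupied], expected, rtol=0.01)

    def test_mass_balance_closes_each_step(self, coarse_grid, census, supplement):
        p = ModelParams(fishing_F=0.4, dt=0.05)
        profile = rs.crevices_to_refuge_profile(census, coarse_grid)
        subs = {
            g: rs.subsidy_vector(supplement, coarse_grid, g) for g in rs.FISH_GROUPS
        }
        dyn = ReefDynamics(coarse_grid, p, profile, subs)
        st = CommunityState.seed(coarse_grid)
        for _ in range(200):
            st, diag = dyn.step(st)
            assert abs(diag.residual) < 1e-8 * max(st.system_mass(coarse_grid), 1.0)

    def test_no_prey_no_ingestion(self, coarse_grid):
        p = zero_input_params()
        dyn = ReefDynamics(coarse_grid, p)
        n = np.zeros(coarse_grid.n_bins)
        npred = n.copy()
        npred[40] = 1.0
        st = CommunityState(npred, n.copy(), n.copy(), 0.0, 0.0)
        # the predator's own bin is its only biomass; shield it with refuges
        prof = RefugeProfile(coarse_grid, np.full(coarse_grid.n_bins, 1e9))
        dyn = ReefDynamics(coarse_grid, p, prof)
        assert dyn.ingestion(st)["predators"][40] == 0.0

    def test_fully_refuged_prey_not_eaten(self, coarse_grid):
        p = zero_input_params()
        prof = RefugeProfile(coarse_grid, np.full(coarse_grid.n_bins, 1e9))
        dyn = ReefDynamics(coarse_grid, p, prof)
        n = np.zeros(coarse_grid.n_bins)
        pred = n.copy()
        pred[45] = 0.5
        herb = n.copy()
        herb[25] = 5.0
        st = CommunityState(pred, herb, n.copy(), 0.0, 0.0)
        assert np.all(dyn.ingestion(st)["predators"] == 0.0)
        nxt, _ = dyn.step(st)
        # herbivores only lose background mortality, no predation
        expected = herb[25] * np.exp(-dyn._mort["herbivores"][25] * p.dt)
        assert nxt.herbivores[25] == pytest.approx(expected, rel=1e-12)

    def test_single_pair_ingestion_matches_hand_quadrature(self, coarse_grid):
        p = zero_input_params()
        i_pred = 50
        j_prey = i_pred - int(round(p.ppmr_mean / coarse_grid.log_width))
        refs = np.zeros(coarse_grid.n_bins)
        refs[i_pred] = 1e9  # shield the predator bin so it is not prey
        dyn = ReefDynamics(coarse_grid, p, RefugeProfile(coarse_grid, refs))
        n = np.zeros(coarse_grid.n_bins)
        pred = n.copy()
        pred[i_pred] = 0.01
        herb = n.copy()
        herb[j_prey] = 0.02
        st = CommunityState(pred, herb, n.copy(), 0.0, 0.0)
        m_pred = coarse_grid.mass[i_pred]
        m_prey = coarse_grid.mass[j_prey]
        prey_biomass = 0.02 * m_prey
        expected = (
            p.search_coeff
            * m_pred**p.search_exp
            * feeding_kernel(m_pred, m_prey, p)
            * prey_biomass
        )
        expected = min(expected, p.intake_max_coeff * m_pred**p.search_exp)
        assert dyn.ingestion(st)["predators"][i_pred] == pytest.approx(expected, rel=1e-12)

    def test_interference_divides_encounter(self, coarse_grid):
        # doubling predator standing stock scales encounter by the
        # Beddington-DeAngelis factor (1 + eta B)
        eta = 0.05
        p = zero_input_params(interference=eta)
        refs = np.zeros(coarse_grid.n_bins)
        i_pred, j_prey = 50, 36
        refs[i_pred] = 1e9
        dyn = ReefDynamics(coarse_grid, p, RefugeProfile(coarse_grid, refs))
        n = np.zeros(coarse_grid.n_bins)
        pred = n.copy()
        pred[i_pred] = 0.01
        herb = n.copy()
        herb[j_prey] = 0.02
        st = CommunityState(pred, herb, n.copy(), 0.0, 0.0)
        base = ReefDynamics(
            coarse_grid, zero_input_params(), RefugeProfile(coarse_grid, refs)
        ).ingestion(st)["predators"][i_pred]
        b_pred = 0.01 * coarse_grid.mass[i_pred]
        got = dyn.ingestion(st)["predators"][i_pred]
        assert got == pytest.approx(base / (1.0 + eta * b_pred), rel=1e-12)

    def test_consumed_prey_equals_predator_intake(self, coarse_grid, census):
        # predator-prey mass exchange is exact by construction
        p = ModelParams()
        prof = rs.crevices_to_refuge_profile(census, coarse_grid)
        dyn = ReefDynamics(coarse_grid, p, prof)
        st = CommunityState.seed(coarse_grid)
        percap, consumed, intake = dyn._realised_feeding(st)
        total_consumed = sum(c.sum() for c in consumed.values())
        assert intake["predators"] == pytest.approx(total_consumed, rel=1e-12)

    def test_integration_error_on_nonfinite(self, coarse_grid):
        p = zero_input_params()
        dyn = ReefDynamics(coarse_grid, p)
        st = CommunityState.seed(coarse_grid)
        st.algae = np.inf
        with pytest.raises(FloatingPointError):
            dyn.step(st)

    def test_mismatched_refuge_grid_rejected(self, coarse_grid, grid):
        prof = RefugeProfile(grid, np.zeros(grid.n_bins))
        with pytest.raises(ValueError, match="grid"):
            ReefDynamics(coarse_grid, ModelParams(), prof)
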