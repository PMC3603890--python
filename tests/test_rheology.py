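"""Maxwell element, critical aspiration pressure and contact reaction stress."""

import math

import numpy as np
import pytest

from celltransit import (
    AxisymChannel,
    CellModel,
    ContactBand,
    MaxwellState,
    critical_pressure,
    maxwell_update,
    reaction_stress,
    relaxation_time,
    squeeze_length,
)


class TestRelaxationTime:
    def test_reference_cell(self, cell):
        assert relaxation_time(cell) == pytest.approx(31.0 / 186.0)
        assert relaxation_time(cell) == pytest.approx(0.1667, abs=5e-5)

    def test_stiff_limit_is_viscous(self):
        assert relaxation_time(CellModel(G_cell=1e12)) == pytest.approx(0.0, abs=1e-9)

    def test_unit_parameters(self):
        assert relaxation_time(CellModel(mu_cell=1.0, G_cell=1.0)) == 1.0


class TestMaxwellUpdate:
    def test_stress_relaxation_matches_closed_form(self, cell):
        """Step strain then hold: sigma(t) = sigma0 exp(-t/lambda)."""
        lam = cell.relaxation_time
        dt = 1e-4
        state = MaxwellState(sigma=10.0, epsilon=0.05)
        n = int(round(lam / dt))  # one relaxation time
        for _ in range(n):
            state = maxwell_update(state, 0.0, dt, cell)
        expected = 10.0 * math.exp(-n * dt / lam)
        assert abs(state.sigma - expected) / expected < 1e-6
        assert state.epsilon == pytest.approx(0.05)

    def test_relaxation_at_dt_lambda_over_1000(self, cell):
        lam = cell.relaxation_time
        dt = lam / 1000.0
        state = MaxwellState(sigma=3.0)
        for _ in range(500):
            state = maxwell_update(state, 0.0, dt, cell)
        assert abs(state.sigma - 3.0 * math.exp(-0.5)) / (3.0 * math.exp(-0.5)) < 1e-6

    def test_creep_limit(self, cell):
        """At constant strain rate the stress saturates at mu*rate, i.e. the
        long-time strain rate under constant stress is sigma/mu."""
        rate = 0.2
        dt = 1e-3
        state = MaxwellState()
        for _ in range(5000):  # 5 s >> lambda
            state = maxwell_update(state, rate, dt, cell)
        assert state.sigma == pytest.approx(cell.mu_cell * rate, rel=1e-6)

    def test_oscillatory_moduli(self, cell):
        """Storage/loss moduli of the integrated response match the analytic
        Maxwell moduli G(wl)^2/(1+(wl)^2) and G wl/(1+(wl)^2)."""
        lam = cell.relaxation_time
        omega = 10.0
        dt = 2e-5
        eps0 = 0.01
        t = np.arange(0, 6.0, dt)
        state = MaxwellState()
        sig = np.empty_like(t)
        eps_prev = 0.0
        for i, ti in enumerate(t):
            eps_now = eps0 * math.sin(omega * (ti + dt))
            state = maxwell_update(state, (eps_now - eps_prev) / dt, dt, cell)
            eps_prev = eps_now
            sig[i] = state.sigma
        keep = t > 5 * lam  # discard the start-up transient
        ph = omega * (t[keep] + dt)
        A = np.column_stack([np.sin(ph), np.cos(ph)])
        coef, *_ = np.linalg.lstsq(A, sig[keep], rcond=None)
        wl = omega * lam
        g_store = cell.G_cell * wl**2 / (1 + wl**2)
        g_loss = cell.G_cell * wl / (1 + wl**2)
        assert coef[0] / eps0 == pytest.approx(g_store, rel=1e-2)
        assert coef[1] / eps0 == pytest.approx(g_loss, rel=1e-2)

    def test_rejects_nonpositive_dt(self, cell):
        with pytest.raises(ValueError):
            maxwell_update(MaxwellState(), 0.0, -1e-3, cell)


class TestCriticalPressure:
    def test_zero_at_cell_radius(self, cell):
        assert critical_pressure(cell, 4.0) == 0.0

    @pytest.mark.parametrize("r,expected", [(2.75, 7.045), (2.0, 15.5)])
    def test_closed_form_values(self, cell, r, expected):
        assert critical_pressure(cell, r) == pytest.approx(expected, abs=5e-4)

    def test_strictly_decreasing_in_throat_radius(self, cell):
        rs = np.linspace(0.5, 4.0, 40)
        ps = [critical_pressure(cell, r) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] == pytest.approx(0.0, abs=1e-12)

    def test_wide_opening_warns_and_returns_zero(self, cell):
        with pytest.warns(UserWarning):
            assert critical_pressure(cell, 5.0) == 0.0


class TestReactionStress:
    def band(self, theta=1.2, l=1.0, r_contact=3.0):
        return ContactBand(l=l, theta=theta, r_contact=r_contact)

    def test_zero_at_critical_pressure(self):
        assert reaction_stress(7.0, 7.0, self.band(), 2.85) == 0.0

    def test_linear_in_excess_pressure(self):
        t1 = reaction_stress(20.0, 10.0, self.band(), 2.85)
        t2 = reaction_stress(30.0, 10.0, self.band(), 2.85)
        assert t2 == pytest.approx(2.0 * t1)
        assert t1 > 0

    def test_monotone_in_driving_pressure(self):
        taus = [reaction_stress(dp, 7.0, self.band(), 2.85)
                for dp in np.linspace(7, 40, 12)]
        assert all(b >= a for a, b in zip(taus, taus[1:]))

    def test_undefined_contact(self):
        with pytest.raises(ValueError):
            reaction_stress(20.0, 7.0, self.band(l=0.0), 2.85)

    def test_squeeze_component_grows_with_throat_radius(self, cell):
        """Wider throats squeeze harder: theta grows and dP_crit falls with
        r_min, so tau*sin(theta) at first contact increases."""
        out = {}
        for r_min in (2.0, 2.85):
            ch = AxisymChannel(r_min=r_min)
            fc = squeeze_length(ch, cell.R_cell)
            band = ContactBand(
                l=1.0, theta=fc.theta,
                r_contact=cell.R_cell * math.sin(fc.theta),
            )
            dp_crit = critical_pressure(cell, ch.r_min - ch.delta)
            tau = reaction_stress(40.0, dp_crit, band, ch.r_min)
            out[r_min] = tau * math.sin(fc.theta)
        assert out[2.85] > out[2.0]
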