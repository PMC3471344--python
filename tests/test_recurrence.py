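import numpy as np
import pytest

from fractorun.recurrence import (
    EventRates,
    RecurrenceConfig,
    RecurrenceState,
    StepSizeError,
    TruncationError,
    _rates_from_rho,
    advance,
    compute_rates,
    delta_pi,
    delta_tau,
    geometric_rho,
    run_recurrence,
)

import naive_oracles as no


class TestGeometricRho:
    def test_degenerate_unit_mean(self):
        rho, e = geometric_rho(1.0)
        assert np.array_equal(rho, [1.0]) and e == 1.0

    def test_head_values(self):
        # before renormalization rho(1)=0.25, rho(2)=0.1875 at v_bar=4
        rho, e = geometric_rho(4.0)
        assert rho[0] == pytest.approx(0.25, rel=1e-9)
        assert rho[1] == pytest.approx(0.1875, rel=1e-9)
        assert e == pytest.approx(4.0, rel=1e-7)
        assert rho.sum() == pytest.approx(1.0)

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            geometric_rho(0.8)

    def test_truncation_cap(self):
        with pytest.raises(TruncationError):
            geometric_rho(1e6, 1e-10, l_max_cap=1000)


def _random_rho(seed: int, L: int = 12) -> np.ndarray:
    rng = np.random.default_rng(seed)
    rho = rng.random(L) + 0.05
    return rho / rho.sum()


class TestCollectedForms:
    """The correlation-based sums must equal the naive nested summations."""

    @pytest.mark.parametrize("seed,mu", [(1, 3.3), (2, 1.7), (3, 6.0)])
    def test_pA_pCii_pDiii_match_naive(self, seed, mu):
        rho = _random_rho(seed)
        e = no.e_rho(rho)
        phi, tau = 0.7, 0.2
        rates = _rates_from_rho(rho, e, mu, phi, tau)
        v = rates.by_variant
        assert v["pA1"] == pytest.approx(phi * no.naive_pA(rho, mu), abs=1e-12)
        assert v["pC11"] == pytest.approx(
            phi**2 * (1 - tau) * no.naive_pCii(rho, mu), abs=1e-12
        )
        assert v["pD111"] == pytest.approx(
            phi**3 * (1 - tau) ** 2 * no.naive_pDiii(rho, mu), abs=1e-12
        )

    def test_mean_length_contributions_match_naive(self):
        rho = _random_rho(7)
        e = no.e_rho(rho)
        mu, phi, tau = 4.2, 0.5, 0.0
        rates = _rates_from_rho(rho, e, mu, phi, tau)
        s2 = phi**2 + (1 - phi) ** 2
        s3 = phi**3 + (1 - phi) ** 3
        assert rates.mu_by_family["A"] == pytest.approx(
            no.naive_muA(rho, mu), abs=1e-12
        )
        assert rates.mu_by_family["Cii"] == pytest.approx(
            s2 * no.naive_muCii(rho, mu), abs=1e-12
        )
        assert rates.mu_by_family["Diii"] == pytest.approx(
            s3 * no.naive_muDiii(rho, mu), abs=1e-12
        )


class TestRateStructure:
    def _state(self, u=6.0, v=6.0, tau_total=0.0, r_max=50):
        pi = np.zeros(r_max)
        pi[0] = 1.0
        tau = np.zeros(r_max)
        if tau_total:
            pi[0], pi[1] = 0.5, 0.5
            tau[1] = 2 * tau_total
        theta = v / (u + v)
        return RecurrenceState(pi=pi, tau=tau, u_bar=u, v_bar=v, theta=theta)

    def test_single_chromosome_degeneracy(self):
        """phi=1 kills every rate carrying a factor phi2."""
        cfg = RecurrenceConfig(mu=6.0, phi=1.0)
        rates = compute_rates(self._state(), cfg)
        v = rates.by_variant
        for key in ("pA2", "pB12", "pB21", "pB22", "pC22", "pC12", "pC21",
                    "pD222", "pD112", "pD221", "pE222", "pE121", "pE212",
                    "pE122", "pE211"):
            assert v[key] == pytest.approx(0.0, abs=1e-15), key
        assert rates.pA == pytest.approx(v["pA1"])

    def test_chromosome_exchange_symmetry(self):
        """tau=0, phi=0.5: all rates symmetric under relabeling 1 <-> 2."""
        cfg = RecurrenceConfig(mu=4.0, phi=0.5)
        v = compute_rates(self._state(), cfg).by_variant
        for a, b in (
            ("pA1", "pA2"), ("pB11", "pB22"), ("pB12", "pB21"),
            ("pC11", "pC22"), ("pC12", "pC21"), ("pD111", "pD222"),
            ("pE111", "pE222"), ("pE112", "pE221"),
        ):
            assert v[a] == pytest.approx(v[b], rel=1e-12)

    def test_probability_closure(self):
        cfg = RecurrenceConfig(mu=6.0, phi=0.75)
        for vbar in (2.0, 6.0, 40.0):
            state = self._state(u=6.0, v=vbar)
            rates = compute_rates(state, cfg)
            assert rates.total_modeled <= 1.0 + 10 * cfg.tail_epsilon
            total = rates.total_modeled + rates.p_other
            assert total == pytest.approx(1.0, abs=10 * cfg.tail_epsilon)


def _manual_rates(pA=0.0, pB=0.0, pC=0.0, pD=0.0, pE=0.0, phi=0.5, cross=0.0):
    v = {k: 0.0 for k in (
        "pA1", "pA2", "pB11", "pB12", "pB21", "pB22",
        "pC11", "pC12", "pC21", "pC22",
        "pD111", "pD222", "pD112", "pD221",
        "pE111", "pE222", "pE112", "pE221", "pE121", "pE212", "pE122", "pE211",
    )}
    v["pB12"] = v["pB21"] = cross / 2.0 if cross else 0.0
    return EventRates(
        pA=pA, pB=pB, pC=pC, pD=pD, pE=pE,
        p_other=max(0.0, 1 - (pA + pB + pC + pD + pE)),
        mu_total=0.0, by_variant=v, mu_by_family={}, phi1=phi, phi2=1 - phi,
    )


class TestDeltaPi:
    def test_extension_only_substitution(self):
        pi = np.zeros(6); pi[0] = 1.0
        rates = _manual_rates(pA=0.5, pB=0.2, pC=0.1)
        d = delta_pi(rates, pi)
        assert d[0] == pytest.approx(0.5 - 0.3)
        assert d[1] == pytest.approx(0.3)
        assert np.all(d[2:] == 0.0)

    def test_zero_rates_fixed_point(self):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        assert np.all(delta_pi(_manual_rates(), pi) == 0.0)

    @pytest.mark.parametrize("mode,expected", [
        ("corrected", lambda r: r.pA - (r.pD + r.pE)),
        ("as_printed", lambda r: r.pA),
    ])
    def test_total_change_identity(self, mode, expected):
        """Net run creation: pA - (pD+pE) corrected, pA as printed.

        pi has compact support well inside the truncation so no merger mass
        escapes past r_max.
        """
        rng = np.random.default_rng(3)
        pi = np.zeros(200)
        pi[:20] = rng.random(20)
        pi /= pi.sum()
        rates = _manual_rates(pA=0.3, pB=0.15, pC=0.2, pD=0.1, pE=0.12)
        d = delta_pi(rates, pi, mode)
        assert d.sum() == pytest.approx(expected(rates), abs=1e-12)


class TestDeltaTau:
    def test_r1_never_both_chromosomes(self):
        pi = np.array([0.5, 0.3, 0.2])
        tau = np.array([0.0, 0.1, 0.4])
        rates = _manual_rates(pA=0.4, pB=0.2, pC=0.2, cross=0.1)
        assert delta_tau(rates, pi, tau)[0] == 0.0

    def test_single_chromosome_never_mixes(self):
        """phi=1: no cross extensions and same-homeolog mergers stay pure."""
        pi = np.array([0.5, 0.3, 0.15, 0.05])
        tau = np.zeros(4)
        rates = _manual_rates(pA=0.3, pB=0.2, pC=0.2, pD=0.1, pE=0.1, phi=1.0)
        d = delta_tau(rates, pi, tau)
        assert np.all(np.abs(d) < 1e-15)

    def test_cross_extension_substitution(self):
        """All mass at r=1: only the cross-extension gain feeds tau(2)."""
        pi = np.zeros(5); pi[0] = 1.0
        tau = np.zeros(5)
        rates = _manual_rates(pB=0.2, cross=0.08)
        d = delta_tau(rates, pi, tau)
        assert d[1] == pytest.approx(0.08)


class TestAdvance:
    def _state(self):
        pi = np.array([0.6, 0.25, 0.1, 0.05])
        tau = np.array([0.0, 0.2, 0.3, 0.4])
        return RecurrenceState(
            pi=pi, tau=tau, u_bar=6.0, v_bar=9.0, theta=0.6, R=2.0
        )

    def test_zero_delta_fixed_point(self):
        st = self._state()
        cfg = RecurrenceConfig(mu=6.0, phi=0.5)
        rates = _manual_rates()
        new = advance(st, rates, np.zeros(4), np.zeros(4), 1.0, cfg)
        assert np.allclose(new.pi, st.pi) and np.allclose(new.tau, st.tau)
        assert new.u_bar == st.u_bar and new.R == st.R

    def test_gene_conservation(self):
        st = self._state()
        cfg = RecurrenceConfig(mu=6.0, phi=0.5)
        rates = compute_rates(st, cfg)
        dpi = delta_pi(rates, st.pi)
        dtau = delta_tau(rates, st.pi, st.tau)
        new = advance(st, rates, dpi, dtau, 0.01, cfg)
        assert new.R * (new.u_bar + new.v_bar) == pytest.approx(
            st.R * (st.u_bar + st.v_bar), rel=1e-10
        )
        assert new.v_bar == pytest.approx(
            new.theta / (1 - new.theta) * new.u_bar, rel=1e-10
        )

    def test_oversized_step_raises(self):
        st = self._state()
        cfg = RecurrenceConfig(mu=6.0, phi=0.5)
        dpi = np.array([-1.0, -0.5, -0.3, -0.2])
        with pytest.raises(StepSizeError):
            advance(st, _manual_rates(), dpi, np.zeros(4), 10.0, cfg)


@pytest.fixture(scope="module")
def traj_mu2():
    cfg = RecurrenceConfig(mu=2.0, phi=0.5, theta_stop=0.3)
    return run_recurrence(cfg)


class TestTrajectory:
    def test_pA_decreases_as_deletion_accumulates(self, traj_mu2):
        pa = traj_mu2.records["pA"].to_numpy()
        assert np.all(np.diff(pa) < 1e-9)
        assert pa[0] > 0.95

    def test_theta_strictly_decreasing(self, traj_mu2):
        th = traj_mu2.records["theta"].to_numpy()
        assert np.all(np.diff(th) < 0)

    def test_conservation_and_closure_along_trajectory(self, traj_mu2):
        df = traj_mu2.records
        total_genes = df["R"] * (df["u_bar"] + df["v_bar"])
        assert np.allclose(total_genes, total_genes.iloc[0], rtol=1e-9)
        psum = df[["pA", "pB", "pC", "pD", "pE", "p_other"]].sum(axis=1)
        assert np.allclose(psum, 1.0, atol=1e-8)
        assert np.allclose(
            df["v_bar"], df["theta"] / (1 - df["theta"]) * df["u_bar"], rtol=1e-9
        )

    def test_pi_tail_light_near_start(self):
        # early regime: nearly all runs from single events
        cfg = RecurrenceConfig(mu=2.0, phi=0.5, theta_stop=0.95)
        t = run_recurrence(cfg)
        pi = t.final_state.pi
        assert pi[0] > 0.9
        assert np.all(np.diff(pi[:10]) <= 1e-12)

    def test_biased_large_deletions_delay_mergers(self):
        """pD+pE grows more slowly for (mu=11, phi=1) than (mu=2, phi=0.5)."""
        t_big = run_recurrence(RecurrenceConfig(mu=11.0, phi=1.0, theta_stop=0.45))
        t_small = run_recurrence(RecurrenceConfig(mu=2.0, phi=0.5, theta_stop=0.45))
        for frac in (0.35, 0.45, 0.5):
            de_big = t_big.interp(frac, "pD") + t_big.interp(frac, "pE")
            de_small = t_small.interp(frac, "pD") + t_small.interp(frac, "pE")
            assert de_big < de_small

    def test_single_chromosome_tau_stays_zero(self):
        t = run_recurrence(RecurrenceConfig(mu=6.0, phi=1.0, theta_stop=0.5))
        assert np.all(t.records["tau_total"].to_numpy() < 1e-12)

    def test_literal_update_mode_runs(self):
        t = run_recurrence(
            RecurrenceConfig(mu=2.0, phi=0.5, theta_stop=0.7, literal_tau=True)
        )
        assert t.final_state.theta <= 0.7

    def test_fixed_lambda_requires_small_steps(self):
        with pytest.raises(StepSizeError):
            run_recurrence(
                RecurrenceConfig(mu=2.0, phi=0.5, theta_stop=0.5, Lambda=1e6)
            )
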