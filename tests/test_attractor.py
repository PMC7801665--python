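"""EIF attractor network: synapse kinetics, connectivity, integration."""
import numpy as np
import pytest

from gridnet import attractor as att


class TestBetaSynapse:
    def test_peak_normalisation_closed_form(self):
        syn = att.SynapseParams(tau_rise=1.0, tau_decay=5.0)
        tp = syn.t_peak
        g = syn.k_norm * (np.exp(-tp / 5.0) - np.exp(-tp / 1.0))
        assert g == pytest.approx(1.0, abs=1e-12)
        # analytic t_peak
        assert tp == pytest.approx(5.0 / 4.0 * np.log(5.0), abs=1e-12)

    def test_discrete_scheme_matches_closed_form(self):
        # the simulator's decay-pair update vs the analytic beta function
        syn = att.SynapseParams(tau_rise=1.0, tau_decay=5.0)
        w, dt = 2.3, 0.01
        n = int(30.0 / dt)
        gd = gr = w * syn.k_norm
        trace = np.empty(n)
        for i in range(n):
            trace[i] = gd - gr
            gd *= np.exp(-dt / syn.tau_decay)
            gr *= np.exp(-dt / syn.tau_rise)
        t = np.arange(n) * dt
        analytic = w * syn.k_norm * (np.exp(-t / 5.0) - np.exp(-t / 1.0))
        assert np.allclose(trace, analytic, atol=1e-6)
        i_peak = int(np.argmax(trace))
        assert trace[i_peak] == pytest.approx(w, abs=1e-4)
        assert t[i_peak] == pytest.approx(syn.t_peak, abs=dt)

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            att.SynapseParams(tau_rise=5.0, tau_decay=1.0)


class TestConnectivity:
    def test_uniform_out_degree_by_torus_symmetry(self):
        cfg = att.AttractorConfig(n_side=20)
        w_ei, w_ie = att.build_connectivity(cfg)
        deg_e = np.diff(w_ei.indptr)
        deg_i = np.diff(w_ie.indptr)
        assert len(set(deg_e)) == 1 and len(set(deg_i)) == 1

    def test_out_degree_matches_bruteforce_annulus_count(self):
        cfg = att.AttractorConfig(n_side=20)
        w_ei, _ = att.build_connectivity(cfg)
        c = cfg.conn
        step = 2 * np.pi / 20
        count = 0
        for i in range(20):
            for j in range(20):
                dx = min(abs(i * step), 2 * np.pi - abs(i * step))
                dy = min(abs(j * step), 2 * np.pi - abs(j * step))
                if c.r_ei_inner ** 2 < dx * dx + dy * dy < c.r_ei_outer ** 2:
                    count += 1
        assert np.diff(w_ei.indptr)[0] == count

    def test_vanishing_disc_keeps_only_colocated_partner(self):
        # as r_IE -> 0+ the disc retains just the E unit sharing the
        # lattice site (distance exactly 0); all true neighbours drop out
        cfg = att.AttractorConfig(n_side=10)
        cfg.conn.r_ie_outer = 1e-6
        _, w_ie = att.build_connectivity(cfg)
        assert w_ie.nnz == cfg.n_per_pop
        assert (w_ie.diagonal() > 0).all()

    def test_empty_annulus_rejected(self):
        cfg = att.AttractorConfig(n_side=10)
        cfg.conn.r_ei_inner = 0.30
        cfg.conn.r_ei_outer = 0.31  # no lattice point in this thin ring
        with pytest.raises(ValueError):
            att.build_connectivity(cfg)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ValueError):
            att.ConnectivitySpec(r_ei_inner=0.9, r_ei_outer=0.5)
        with pytest.raises(ValueError):
            att.ConnectivitySpec(r_ie_outer=0.0)


def _quiet_config(n_side=8, duration=0.2, **kw):
    cfg = att.AttractorConfig(n_side=n_side, duration=duration, settle=0.0,
                              seed=3, **kw)
    return cfg


class TestSimulation:
    def test_silent_network_stays_at_rest(self):
        cfg = _quiet_config(p_rate=0.0)
        cfg.conn.g_ei = 0.0
        cfg.conn.g_ie = 0.0
        res = att.simulate_network(cfg)
        assert sum(len(s) for s in res.spike_times) == 0
        s = att.population_rate_summary(res, window=(0.0, 0.2))
        assert s["E"]["median_all"] == 0.0 and s["I"]["median_all"] == 0.0

    def test_reproducible_under_seed(self):
        cfg = _quiet_config(n_side=10, duration=0.5)
        a = att.simulate_network(cfg)
        b = att.simulate_network(cfg)
        for sa, sb in zip(a.spike_times, b.spike_times):
            assert np.array_equal(sa, sb)

    def test_uncoupled_poisson_sheet_matches_single_neuron_oracle(self):
        # independent Euler reference at 10x finer dt, same drive statistics
        cfg = _quiet_config(n_side=12, duration=2.0)
        cfg.conn.g_ei = 0.0
        cfg.conn.g_ie = 0.0
        res = att.simulate_network(cfg)
        net_rate = att.population_rate_summary(res, window=(0.0, 2.0))["E"]["mean_all"]

        rng = np.random.default_rng(99)
        p, syn = cfg.eif_e, cfg.syn_ext
        dt = 0.01  # ms
        n_steps = int(20_000.0 / dt)  # 20 s of a single neuron
        wk = cfg.w_ext * syn.k_norm
        dec_d, dec_r = np.exp(-dt / syn.tau_decay), np.exp(-dt / syn.tau_rise)
        v, gd, gr, ref, spikes = p.e_l, 0.0, 0.0, 0.0, 0
        cap = (p.v_peak - p.v_t) / p.delta_t
        for i in range(n_steps):
            inc = rng.poisson(cfg.p_rate * dt / 1000.0) * wk
            gd += inc
            gr += inc
            g = gd - gr
            exp_term = p.g_l * p.delta_t * np.exp(min((v - p.v_t) / p.delta_t, cap))
            v += dt / p.c_m * (-p.g_l * (v - p.e_l) + exp_term - g * (v - syn.e_rev))
            if ref > 0:
                v = p.v_reset
                ref -= dt
            if v >= p.v_peak:
                v = p.v_reset
                ref = p.t_ref
                spikes += 1
            gd *= dec_d
            gr *= dec_r
        oracle = spikes / 20.0
        assert net_rate == pytest.approx(oracle, rel=0.05)

    def test_divergence_detected(self):
        cfg = _quiet_config(duration=0.05, p_rate=1e5)
        cfg.w_ext = 1e308  # overflow-scale drive -> membrane blows up
        with pytest.raises(FloatingPointError):
            att.simulate_network(cfg)

    def test_dt_convergence_of_population_rate(self):
        rates = []
        for dt in (0.1, 0.05):
            cfg = _quiet_config(n_side=12, duration=1.0, dt=dt)
            cfg.conn.g_ei = 0.0
            cfg.conn.g_ie = 0.0
            res = att.simulate_network(cfg)
            rates.append(att.population_rate_summary(
                res, window=(0.0, 1.0))["E"]["mean_all"])
        assert rates[0] == pytest.approx(rates[1], rel=0.1)


class TestManipulations:
    def test_identity_factor_changes_nothing(self):
        cfg = att.AttractorConfig()
        out = att.apply_pnn_manipulation(cfg, "reduced_EI", 1.0)
        assert out.to_dict() == cfg.to_dict()

    def test_wrong_direction_warns_but_applies(self):
        cfg = att.AttractorConfig()
        with pytest.warns(UserWarning):
            out = att.apply_pnn_manipulation(cfg, "reduced_EI", 1.3)
        assert out.conn.g_ei == pytest.approx(cfg.conn.g_ei * 1.3)
        with pytest.warns(UserWarning):
            att.apply_pnn_manipulation(cfg, "increased_Cm", 0.5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            att.apply_pnn_manipulation(att.AttractorConfig(), "nope", 0.5)
        with pytest.raises(ValueError):
            att.apply_pnn_manipulation(att.AttractorConfig(), "reduced_EI", -1.0)

    def test_original_config_untouched(self):
        cfg = att.AttractorConfig()
        g0 = cfg.conn.g_ei
        att.apply_pnn_manipulation(cfg, "reduced_EI", 0.7)
        assert cfg.conn.g_ei == g0


class TestReadouts:
    def test_shuffled_positions_destroy_gridness(self):
        from conftest import hex_bump_lattice
        img = hex_bump_lattice(n=40, spacing=8.0, sigma=1.5)
        ac = att._wrap_autocorrelogram(img)
        from gridnet.gridness import gridness_score
        good = gridness_score(ac).score
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(img.ravel()).reshape(img.shape)
        bad = gridness_score(att._wrap_autocorrelogram(shuffled)).score
        assert good > 0.5
        assert not np.isfinite(bad) or bad < 0.2

    def test_empty_window_rejected(self):
        cfg = _quiet_config(duration=0.1)
        res = att.simulate_network(cfg)
        with pytest.raises(ValueError):
            att.sheet_pattern_gridness(res, window=(0.1, 0.1))
        with pytest.raises(ValueError):
            res.rates("E", window=(0.2, 0.1))

    def test_config_roundtrip_through_dict(self):
        cfg = att.desk_config(seed=5)
        d = cfg.to_dict()
        back = att.AttractorConfig.from_dict(d)
        assert back.to_dict() == d
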