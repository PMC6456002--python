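import numpy as np
import pytest
from scipy.optimize import fsolve

from atpfret.bioenergetics import (ARCHETYPES, CellArchetype, hk_flux,
                                   initial_state, sample_population,
                                   simulate_cell, is_glycolytic)
from atpfret.protocols import PerfusionProtocol, Segment, make_protocol


def null_archetype():
    return CellArchetype(label="null", v_glut=0, k_hk_f=0, k_hk_r=0, k_gly=0,
                         y_atp=0, v_ox=0, k_hyd=0, k_ant=0, k_cons_c=0,
                         k_cons_m=0, k_er_in=0, k_er_cons=0,
                         a_tot_c=6.0, a_tot_m=5.0)


class TestHkFlux:
    def test_no_substrate_no_flux(self, hela):
        assert hk_flux(0.0, 0.0, 2.0, 3.0, hela) == 0.0

    def test_pure_reverse_is_negative(self, hela):
        arch = hela.replace(k_hk_f=0.0)
        assert hk_flux(5.0, 1.0, 2.0, 3.0, arch) < 0

    def test_detailed_balance_point(self, hela):
        # balance h6p solved independently from the mass-action equality
        glc, atp_m, adp_m = 7.0, 2.0, 3.0
        h6p_star = hela.k_hk_f * glc * atp_m / (hela.k_hk_r * adp_m)
        assert hk_flux(glc, h6p_star, atp_m, adp_m, hela) == pytest.approx(0.0, abs=1e-15)

    def test_negative_inputs_rejected(self, hela):
        with pytest.raises(ValueError):
            hk_flux(-1.0, 0.0, 1.0, 1.0, hela)


class TestSimulateCell:
    def test_null_dynamics_state_constant(self):
        arch = null_archetype()
        p = make_protocol("glucose_removal", baseline_s=60, removal_s=120)
        y0 = np.array([1.0, 0.0, 0.5, 0.0, 3.0, 2.0, 1.0])
        tr = simulate_cell(arch, p, y0=y0)
        assert np.allclose(tr.states, y0, atol=1e-12)

    def test_terminal_state_is_ode_fixed_point(self, hela):
        """Constant-glucose terminal state solves the steady-state equations,
        written out independently here."""
        p = PerfusionProtocol((Segment(0, 2000.0, "glucose", 10.0),))
        tr = simulate_cell(hela, p)
        a = hela

        def rhs(y):
            hex_g, hex_n, h6p_g, h6p_n, atp_c, atp_m, atp_er = y
            adp_m = max(a.a_tot_m - atp_m, 0.0)
            v_g = a.k_hk_f * hex_g * atp_m - a.k_hk_r * h6p_g * adp_m
            v_n = a.k_hk_f * hex_n * atp_m - a.k_hk_r * h6p_n * adp_m
            v_gly = a.k_gly * h6p_g
            free_c = 1 - atp_c / a.a_tot_c
            free_m = 1 - atp_m / a.a_tot_m
            ant = a.k_ant * a.a_tot_m * (atp_c / a.a_tot_c - atp_m / a.a_tot_m)
            return [
                a.v_glut * (10.0 - hex_g) - v_g,
                a.v_glut * (0.0 - hex_n) - v_n,
                v_g - v_gly,
                v_n,
                (a.y_atp * v_gly + a.v_base_c) * free_c - ant
                - (a.k_cons_c + a.k_er_in) * atp_c,
                ant + a.v_ox * free_m - a.k_hyd * atp_m
                - a.k_cons_m * atp_m - v_g - v_n,
                a.k_er_in * atp_c - a.k_er_cons * atp_er,
            ]

        terminal = tr.states[-1]
        root = fsolve(rhs, terminal, full_output=False)
        assert np.allclose(terminal, root, rtol=1e-5, atol=1e-7)
        assert np.max(np.abs(rhs(terminal))) < 1e-7

    def test_removal_produces_transient_peak_then_decline(self, hela_removal_sim):
        tr = hela_removal_sim
        basal = tr.atp_m[(tr.time >= 240) & (tr.time <= 300)].mean()
        post = tr.time >= 300
        assert tr.atp_m[post].max() > basal * 1.05
        assert tr.atp_m[-1] < basal * 0.95

    def test_er_lags_cytosol_on_removal(self, hela_removal_sim):
        """ER ATP is a slow follower of cytosolic ATP, so its fractional
        change within the recording stays smaller."""
        tr = hela_removal_sim
        def frac_change(x):
            b = x[(tr.time >= 240) & (tr.time <= 300)].mean()
            d = x[tr.time >= 300] / b - 1
            return np.abs(d).max()
        assert frac_change(tr.atp_er) < frac_change(tr.atp_c)

    def test_invalid_dt_rejected(self, hela, removal_protocol):
        with pytest.raises(ValueError):
            simulate_cell(hela, removal_protocol, dt_out=0.0)


class TestInvariants:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_adenine_conservation_under_sampled_rates(self, hela, beta, seed):
        p = make_protocol("glc_removal_then_oligo", removal_s=900, drug_s=300)
        for base in (hela, beta):
            for arch in sample_population(base, 2, 0.4, seed):
                tr = simulate_cell(arch, p)
                assert tr.atp_c.min() >= 0 and tr.atp_m.min() >= 0
                assert tr.atp_er.min() >= 0
                assert tr.atp_c.max() <= arch.a_tot_c + 1e-9
                assert tr.atp_m.max() <= arch.a_tot_m + 1e-9

    def test_peak_monotone_in_hk_scaling(self, hela, removal_protocol):
        """Scaling both hexokinase rates down never increases the transient
        mitochondrial peak (knockdown analog)."""
        peaks = []
        for alpha in (1.0, 0.6, 0.3, 0.0):
            tr = simulate_cell(hela.scaled_hk(alpha), removal_protocol)
            basal = tr.atp_m[(tr.time >= 240) & (tr.time <= 300)].mean()
            peaks.append(max(tr.atp_m[tr.time >= 300].max() - basal, 0.0))
        assert all(a >= b - 1e-9 for a, b in zip(peaks, peaks[1:]))
        assert peaks[-1] == pytest.approx(0.0, abs=1e-6)

    def test_dg2_mannose_glucose_terminal_ordering(self, hela):
        """Matched 900-s exposure: 2-DG depletes mitochondrial ATP deepest,
        mannose intermediate, plain removal least."""
        terminal = {}
        for name in ("dg2_substitution", "mannose_switch", "glucose_removal"):
            tr = simulate_cell(hela, make_protocol(name, removal_s=900))
            sel = (tr.time >= 300) & (tr.time <= 1200)
            terminal[name] = tr.atp_m[sel].min()
        assert (terminal["dg2_substitution"] < terminal["mannose_switch"]
                < terminal["glucose_removal"])

    def test_oligomycin_dichotomy(self, hela, beta):
        """Blocking the synthase raises matrix ATP in the glycolytic
        archetype (reverse mode) and lowers it in the oxidative one."""
        p = make_protocol("oligo_then_glc_removal", drug_s=600, removal_s=300)
        for arch, expect_rise in ((hela, True), (beta, False)):
            tr = simulate_cell(arch, p)
            basal = tr.atp_m[(tr.time >= 240) & (tr.time <= 300)].mean()
            during = tr.atp_m[(tr.time >= 300) & (tr.time <= 900)]
            dev = during - basal
            biggest = dev[np.argmax(np.abs(dev))]
            assert (biggest > 0) == expect_rise

    def test_repeated_depletion_peaks_non_increasing(self, hela):
        tr = simulate_cell(hela, make_protocol("repeated_depletion"))
        peaks, t0 = [], 300.0
        for _ in range(3):
            sel = (tr.time >= t0) & (tr.time <= t0 + 450)
            base = tr.atp_m[(tr.time >= t0 - 50) & (tr.time <= t0)].mean()
            peaks.append(max(tr.atp_m[sel].max() - base, 0.0))
            t0 += 550
        assert peaks[0] >= peaks[1] >= peaks[2]
        assert peaks[0] > peaks[2]


class TestSamplePopulation:
    def test_cv_zero_gives_identical_copies(self, hela):
        pop = sample_population(hela, 5, 0.0, seed=1)
        assert all(p.k_hk_f == hela.k_hk_f for p in pop)
        assert len(pop) == 5

    def test_seeded_determinism(self, hela):
        a = sample_population(hela, 10, 0.3, seed=7)
        b = sample_population(hela, 10, 0.3, seed=7)
        assert all(x.k_ant == y.k_ant for x, y in zip(a, b))

    def test_lognormal_moments(self, hela):
        """Median-1 log-normal with CV c has mean sqrt(1 + c^2)."""
        cv, n = 0.3, 1000
        pop = sample_population(hela, n, cv, seed=3)
        factors = np.array([p.k_ant / hela.k_ant for p in pop])
        expected_mean = np.sqrt(1 + cv ** 2)
        sem = factors.std(ddof=1) / np.sqrt(n)
        assert abs(factors.mean() - expected_mean) < 3 * sem

    def test_invalid_args(self, hela):
        with pytest.raises(ValueError):
            sample_population(hela, 0, 0.3, seed=1)
        with pytest.raises(ValueError):
            sample_population(hela, 3, -0.1, seed=1)


def test_archetype_classes():
    assert is_glycolytic(ARCHETYPES["hela_like"])
    assert is_glycolytic(ARCHETYPES["mef_young_like"])
    assert not is_glycolytic(ARCHETYPES["beta_like"])
    assert not is_glycolytic(ARCHETYPES["mef_old_like"])
    assert not is_glycolytic(ARCHETYPES["mfn2_ko_like"])


def test_archetype_validation():
    with pytest.raises(ValueError):
        null_archetype().replace(a_tot_m=0.0)
    with pytest.raises(ValueError):
        null_archetype().replace(k_ant=-1.0)
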