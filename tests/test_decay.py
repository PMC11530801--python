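"""Decay physics: closed-form curves, gate survival, photon sampling."""

import numpy as np
import pytest
from scipy import stats

from ldflim.decay import (
    DecayModel,
    FLF_GATE,
    Gate,
    UNFILTERED_GATE,
    WINDOW_NS,
    calibrate_ld_fraction,
    default_bin_edges,
    effective_lifetime_for_loss,
    ld_model,
    loss_percent,
    lro_model,
    model_curve,
    sample_histogram,
    survival_fraction,
    truncated_mean_arrival,
)


def brute_force_curve(model, bin_edges, n_grid=200_000):
    """Numerical convolution of the decay mixture with the Gaussian IRF
    (discrete FFT convolution on a fine uniform grid), integrated per bin —
    independent of the closed form under test."""
    from scipy.signal import fftconvolve

    t0, t1 = model.window
    sigma = model.irf_sigma
    if sigma == 0:
        # delta IRF: adaptive quadrature of the sampled density, with the
        # onset discontinuity declared as a breakpoint
        from scipy.integrate import quad

        def dens(t):
            u = t - model.irf_center
            return sum(f * (np.exp(-u / tau) / tau if u >= 0 else 0.0)
                       for f, tau in model.components)

        edges = np.asarray(bin_edges, dtype=float)
        masses = [quad(dens, a, b, points=[model.irf_center]
                       if a < model.irf_center < b else None,
                       limit=200)[0]
                  for a, b in zip(edges[:-1], edges[1:])]
        return np.concatenate([[0.0], np.cumsum(masses)])

    pad = 8 * sigma + 1.0
    h = (t1 - t0 + 2 * pad) / n_grid
    t = np.arange(t0 - pad, t1 + pad, h)
    density = np.zeros(len(t))
    for frac, tau in model.components:
        # decay sampled on its support (grid starts at the onset) and a
        # truncated Gaussian kernel, discretely convolved; trapezoid
        # end-weights on the decay side
        s = np.arange(0.0, t1 - t0 + 2 * pad, h)
        decay = np.exp(-s / tau) / tau
        decay[0] *= 0.5
        k = np.arange(-8 * sigma, 8 * sigma + h, h)
        kern = np.exp(-0.5 * (k / sigma) ** 2) / (
            np.sqrt(2 * np.pi) * sigma)
        conv = fftconvolve(decay, kern) * h
        conv_t = model.irf_center + s[0] + k[0] + h * np.arange(len(conv))
        density += frac * np.interp(t, conv_t, conv, left=0.0, right=0.0)
    cdf = np.concatenate([[0], np.cumsum(
        0.5 * (density[1:] + density[:-1]) * h)])
    return np.interp(bin_edges, t, cdf)


class TestModelCurve:
    def test_pure_exponential_bin_ratio(self):
        """With a delta IRF, consecutive bins of a monoexponential decay
        fall off by exactly exp(-width/tau)."""
        m = DecayModel(components=((1.0, 1.0),), irf_sigma=0.0)
        edges = np.arange(0.5, 8.0, 0.25)
        c = model_curve(m, edges)
        ratios = c[1:] / c[:-1]
        assert np.allclose(ratios, np.exp(-0.25), rtol=1e-10)

    def test_conservation_with_background(self):
        m = DecayModel(components=((0.3, 0.9), (0.7, 4.0)), background=0.5)
        edges = default_bin_edges()
        c = model_curve(m, edges)
        in_window = survival_fraction(m, UNFILTERED_GATE)
        # unit total untruncated signal: window sum = in-window mass + T*bg
        total_mass = brute_force_curve(m, np.array(WINDOW_NS))
        expected = (total_mass[1] - total_mass[0]) + 0.5 * (len(edges) - 1)
        assert c.sum() == pytest.approx(expected, rel=1e-4)
        assert in_window == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("sigma", [0.0, 0.05, 0.15, 0.3])
    def test_matches_numerical_convolution(self, sigma):
        """Closed form agrees with a fine-grid trapezoid convolution."""
        m = DecayModel(components=((1.0, 2.5),), irf_sigma=sigma)
        edges = default_bin_edges()
        c = model_curve(m, edges)
        oracle = np.diff(brute_force_curve(m, edges))
        scale = oracle.max()
        assert np.max(np.abs(c - oracle)) / scale < 1e-6

    def test_two_component_against_oracle(self):
        m = DecayModel(components=((0.4, 0.8), (0.6, 3.5)), irf_sigma=0.15)
        edges = default_bin_edges()
        c = model_curve(m, edges)
        oracle = np.diff(brute_force_curve(m, edges))
        assert np.max(np.abs(c - oracle)) / oracle.max() < 1e-6

    def test_rejects_bins_outside_window(self):
        m = DecayModel(components=((1.0, 2.0),))
        with pytest.raises(ValueError, match="window"):
            model_curve(m, np.array([-2.0, 0.0, 1.0]))

    def test_nonnegative(self):
        m = DecayModel(components=((0.5, 0.3), (0.5, 6.0)), irf_sigma=0.3)
        assert np.all(model_curve(m, default_bin_edges()) >= 0)

    def test_periodic_summation_adds_incomplete_decay(self):
        """The optional wrap-around correction folds in previous-pulse
        tails, so it adds mass everywhere and more for longer lifetimes."""
        edges = default_bin_edges()
        long_m = DecayModel(components=((1.0, 8.0),), irf_sigma=0.0)
        short_m = DecayModel(components=((1.0, 1.0),), irf_sigma=0.0)
        extra_long = (model_curve(long_m, edges, periodic=True)
                      - model_curve(long_m, edges)).sum()
        extra_short = (model_curve(short_m, edges, periodic=True)
                       - model_curve(short_m, edges)).sum()
        assert extra_long > extra_short > 0


class TestSurvivalFraction:
    def test_identity_gate(self):
        m = lro_model()
        assert survival_fraction(m, UNFILTERED_GATE) == pytest.approx(1.0)
        assert loss_percent(m, UNFILTERED_GATE) == pytest.approx(0.0)

    def test_lro_closed_form_under_flf(self):
        """Monoexponential 1.5 ns with a delta IRF: the gated survival has
        the textbook closed form and a loss of ~93.1%."""
        m = lro_model(irf_sigma=0.0)
        s = survival_fraction(m, FLF_GATE)
        tau = 1.5
        expected = (np.exp(-4 / tau) - np.exp(-11.5 / tau)) / (
            1 - np.exp(-11.5 / tau))
        assert s == pytest.approx(expected, rel=1e-10)
        assert loss_percent(m, FLF_GATE) == pytest.approx(93.10, abs=0.05)

    def test_effective_lifetime_for_ld_loss(self):
        """The single lifetime matching the LD-class 58.3% loss is ~5.7 ns."""
        tau_eff = effective_lifetime_for_loss(58.3)
        assert tau_eff == pytest.approx(5.66, abs=0.05)
        m = DecayModel(components=((1.0, tau_eff),), irf_sigma=0.0)
        assert loss_percent(m, FLF_GATE) == pytest.approx(58.3, abs=1e-6)

    def test_empty_gate_rejected(self):
        with pytest.raises(ValueError, match="empty gate"):
            Gate(4.0, 4.0)

    def test_gate_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            survival_fraction(lro_model(), Gate(4.0, 12.0))

    def test_monotone_in_gate_bounds(self):
        """Survival is nonincreasing in t_min and nondecreasing in t_max."""
        m = ld_model()
        tmins = np.linspace(-1, 6, 15)
        s_tmin = [survival_fraction(m, Gate(t, 11.5)) for t in tmins]
        assert np.all(np.diff(s_tmin) <= 1e-12)
        tmaxs = np.linspace(0, 11.5, 15)
        s_tmax = [survival_fraction(m, Gate(-1.0, t)) for t in tmaxs]
        assert np.all(np.diff(s_tmax) >= -1e-12)

    def test_survival_ratio_grows_with_threshold(self):
        """For tau_A > tau_B, survival_A / survival_B is nondecreasing in
        t_min — the mechanism that makes long-pass gates raise the LD:LRO
        contrast."""
        a = DecayModel(components=((1.0, 5.7),), irf_sigma=0.0)
        b = DecayModel(components=((1.0, 1.5),), irf_sigma=0.0)
        ratios = []
        for t in np.linspace(-1, 8, 19):
            g = Gate(t, 11.5)
            ratios.append(survival_fraction(a, g) / survival_fraction(b, g))
        assert np.all(np.diff(ratios) >= -1e-9)


class TestLdCalibration:
    def test_calibrated_model_hits_target_loss(self):
        m = ld_model()
        assert loss_percent(m, FLF_GATE) == pytest.approx(58.3, abs=1e-6)

    def test_fraction_in_open_interval(self):
        f = calibrate_ld_fraction()
        assert 0.0 < f < 1.0


class TestSampleHistogram:
    def test_empty_draw(self):
        h = sample_histogram(lro_model(), 0, seed=1)
        assert h.total == 0

    def test_count_conservation_and_determinism(self):
        m = ld_model()
        h1 = sample_histogram(m, 5000, seed=42)
        h2 = sample_histogram(m, 5000, seed=42)
        assert h1.total == 5000
        assert np.array_equal(h1.counts, h2.counts)

    def test_mean_arrival_matches_analytic_moment(self):
        m = DecayModel(components=((1.0, 2.0),), irf_sigma=0.0)
        n = 1_000_000
        h = sample_histogram(m, n, seed=3)
        emp = float((h.bin_centers * h.counts).sum() / h.total)
        centers = h.bin_centers
        var = float(((centers - emp) ** 2 * h.counts).sum() / h.total)
        se = np.sqrt(var / n)
        assert abs(emp - truncated_mean_arrival(m)) < 3 * se + 0.05 / 2

    def test_counts_consistent_with_expected_curve(self):
        """Chi-square goodness of fit of sampled counts against the
        closed-form expectations."""
        m = DecayModel(components=((0.4, 0.8), (0.6, 3.5)), irf_sigma=0.15)
        n = 1_000_000
        h = sample_histogram(m, n, seed=7)
        curve = model_curve(m, h.bin_edges)
        expected = n * curve / curve.sum()
        keep = expected >= 5
        obs = np.append(h.counts[keep], h.counts[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        if exp[-1] == 0:
            obs, exp = obs[:-1], exp[:-1]
        stat, p = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert p > 0.001
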