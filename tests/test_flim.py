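"""Reconvolution model, Poisson fitting, amplitude-weighted lifetime, rendering."""

import numpy as np
import pytest

from fpolimg import (
    DecayHistogram,
    DecaySpec,
    amplitude_weighted_tau,
    fit_biexponential,
    fit_cell_map,
    generate_decay,
    model_decay,
)
from fpolimg.flim import flim_lut, poisson_deviance, render_flim
from fpolimg.synthetic import generate_cell_decays


def _delta_irf(n):
    irf = np.zeros(n)
    irf[0] = 1.0
    return irf


class TestModelDecay:
    def test_delta_irf_consecutive_bin_ratio(self):
        n, dt, tau = 256, 0.05, 0.6
        mu = model_decay(tau, 2 * tau, a1=100.0, a2=0.0,
                         irf=_delta_irf(n), bin_width_ns=dt)
        ratios = mu[2:50] / mu[1:49]
        assert np.allclose(ratios, np.exp(-dt / tau), rtol=1e-9)

    def test_linearity_in_amplitudes(self):
        n, dt = 128, 0.1
        irf = _delta_irf(n)
        m1 = model_decay(0.3, 0.9, 10.0, 5.0, irf, dt, background=2.0)
        m2 = model_decay(0.3, 0.9, 20.0, 10.0, irf, dt, background=2.0)
        np.testing.assert_allclose(m2 - 2.0, 2.0 * (m1 - 2.0), rtol=1e-9)

    def test_total_counts_match_integral_oracle(self):
        """Total expected counts = integral of a1 e^{-t/tau1} + a2 e^{-t/tau2}."""
        n, dt = 4096, 0.01
        a1, a2, tau1, tau2 = 50.0, 20.0, 0.3, 0.9
        mu = model_decay(tau1, tau2, a1, a2, _delta_irf(n), dt)
        t = np.linspace(0, n * dt, 400001)
        oracle = np.trapezoid(a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2), t)
        assert mu.sum() == pytest.approx(oracle, rel=1e-4)
        assert mu.sum() == pytest.approx(a1 * tau1 + a2 * tau2, rel=1e-3)

    def test_nonpositive_tau_raises(self):
        with pytest.raises(ValueError):
            model_decay(-0.1, 0.9, 1.0, 1.0, _delta_irf(64), 0.05)


class TestAmplitudeWeightedTau:
    @pytest.mark.parametrize(
        "a1, tau1, a2, tau2, expected",
        [
            (1.0, 0.3, 1.0, 0.9, 0.6),    # equal weights -> midpoint
            (5.0, 0.42, 0.0, 1.3, 0.42),  # single-component limit
            (3.0, 0.2, 1.0, 1.0, 0.4),    # hand arithmetic
        ],
    )
    def test_examples(self, a1, tau1, a2, tau2, expected):
        assert amplitude_weighted_tau(a1, tau1, a2, tau2) == pytest.approx(expected)

    def test_zero_total_amplitude_raises(self):
        with pytest.raises(ZeroDivisionError):
            amplitude_weighted_tau(0.0, 0.3, 0.0, 0.9)

    def test_bounded_by_component_lifetimes(self, rng):
        for _ in range(50):
            a1, a2 = rng.uniform(0, 5, 2)
            if a1 + a2 == 0:
                continue
            tau1 = rng.uniform(0.05, 0.5)
            tau2 = tau1 + rng.uniform(0.01, 1.0)
            tau = amplitude_weighted_tau(a1, tau1, a2, tau2)
            assert tau1 - 1e-12 <= tau <= tau2 + 1e-12


def _fast_spec(**kw):
    base = dict(tau1_ns=0.27, tau2_ns=0.75, a1=1.5, a2=1.0, window_ns=15.0,
                n_bins=2048, irf_fwhm_ns=0.12, irf_center_ns=1.5,
                n_photons=10**6, seed=0)
    base.update(kw)
    return DecaySpec(**base)


class TestFitBiexponential:
    def test_recovers_both_lifetimes(self):
        hist = generate_decay(_fast_spec(seed=5))
        fit = fit_biexponential(hist)
        assert fit.converged and not fit.effectively_mono
        assert fit.tau1_ns == pytest.approx(0.27, rel=0.05)
        assert fit.tau2_ns == pytest.approx(0.75, rel=0.05)
        assert fit.tau1_ns < fit.tau_amp_ns < fit.tau2_ns
        assert 0.8 <= fit.chi2_reduced <= 1.5

    def test_mono_truth_flagged_and_recovered(self):
        hist = generate_decay(_fast_spec(tau1_ns=0.5, tau2_ns=1.2, a1=1.0,
                                         a2=0.0, seed=21))
        fit = fit_biexponential(hist)
        assert fit.effectively_mono
        assert fit.a2 == 0.0
        assert fit.a2 / fit.a1 < 0.05
        assert fit.tau1_ns == pytest.approx(0.5, rel=0.03)
        assert fit.tau_amp_ns == pytest.approx(fit.tau1_ns)

    def test_binning_invariance_on_expected_counts(self):
        """Halving the bin width leaves the lifetimes unchanged within 1%.

        Uses deterministic (rounded expected-value) histograms so the two
        binnings see the same underlying curve rather than independent noise.
        """
        taus = {}
        for n_bins in (1024, 2048):
            spec = _fast_spec(n_bins=n_bins)
            template = generate_decay(spec)
            counts = np.round(_expected_counts(spec)).astype(np.int64)
            hist = DecayHistogram(counts=counts,
                                  bin_width_ns=template.bin_width_ns,
                                  irf=template.irf)
            fit = fit_biexponential(hist)
            taus[n_bins] = (fit.tau1_ns, fit.tau2_ns)
        for i in range(2):
            assert taus[1024][i] == pytest.approx(taus[2048][i], rel=0.01)

    def test_fitted_deviance_not_worse_than_truth(self):
        spec = _fast_spec(seed=9)
        hist = generate_decay(spec)
        fit = fit_biexponential(hist)
        # truth amplitudes on the fitter's counts/ns scale
        denom = spec.a1 * spec.tau1_ns + spec.a2 * spec.tau2_ns
        a1c = spec.n_photons * spec.a1 / denom
        a2c = spec.n_photons * spec.a2 / denom
        mu_truth = model_decay(spec.tau1_ns, spec.tau2_ns, a1c, a2c,
                               hist.irf, hist.bin_width_ns)
        dev_truth = poisson_deviance(hist.counts.astype(float), mu_truth)
        assert fit.deviance <= dev_truth + 1e-6
        assert fit.n_free_params == 4

    def test_low_count_histogram_rejected(self):
        hist = generate_decay(_fast_spec(n_photons=200))
        with pytest.raises(ValueError, match="total counts"):
            fit_biexponential(hist)

    def test_recovery_grid_and_chi2_calibration(self):
        """Median lifetime errors < 5% (tau_amp < 3%) and chi2 near 1 over a grid."""
        errs1, errs2, errs_amp, chi2s = [], [], [], []
        cases = [(0.2, 0.7, 1.0), (0.2, 1.0, 2.0), (0.3, 0.9, 0.5),
                 (0.3, 0.7, 1.0), (0.2, 0.9, 0.5), (0.3, 1.0, 2.0)]
        for i, (t1, t2, ratio) in enumerate(cases):
            spec = _fast_spec(tau1_ns=t1, tau2_ns=t2, a1=ratio, a2=1.0,
                              seed=100 + i)
            fit = fit_biexponential(generate_decay(spec))
            truth_amp = amplitude_weighted_tau(ratio, t1, 1.0, t2)
            errs1.append(abs(fit.tau1_ns - t1) / t1)
            errs2.append(abs(fit.tau2_ns - t2) / t2)
            errs_amp.append(abs(fit.tau_amp_ns - truth_amp) / truth_amp)
            chi2s.append(fit.chi2_reduced)
        assert np.median(errs1) < 0.05
        assert np.median(errs2) < 0.05
        assert np.median(errs_amp) < 0.03
        assert 0.9 <= np.mean(chi2s) <= 1.1


class TestCellMapAndRendering:
    def test_identical_decays_identical_fits(self):
        decays = generate_cell_decays({
            1: _fast_spec(seed=3, n_photons=10**5),
            2: _fast_spec(seed=3, n_photons=10**5),
        })
        table, image = fit_cell_map(decays)
        assert image is None
        assert table.tau_amp_ns[0] == table.tau_amp_ns[1]
        assert table.tau1_ns[0] == table.tau1_ns[1]

    def test_two_population_field_separates(self):
        specs = {}
        for i in range(3):  # short-lifetime (cancer-like) cells
            specs[i + 1] = _fast_spec(tau1_ns=0.27, tau2_ns=0.75, seed=30 + i,
                                      n_photons=3 * 10**5)
        for i in range(3):  # long-lifetime (normal-like) cells
            specs[i + 4] = _fast_spec(tau1_ns=0.30, tau2_ns=0.95, seed=60 + i,
                                      n_photons=3 * 10**5)
        table, _ = fit_cell_map(specs_to_decays(specs))
        short = table[table.cell_id <= 3].tau_amp_ns.mean()
        long_ = table[table.cell_id >= 4].tau_amp_ns.mean()
        truth_short = amplitude_weighted_tau(1.5, 0.27, 1.0, 0.75)
        truth_long = amplitude_weighted_tau(1.5, 0.30, 1.0, 0.95)
        assert short == pytest.approx(truth_short, rel=0.05)
        assert long_ == pytest.approx(truth_long, rel=0.05)
        assert short < long_

    def test_render_endpoints_clamp_to_lut(self):
        labels = np.array([[1, 2]])
        lut = flim_lut()
        rgb = render_flim(labels, {1: 0.1, 2: 1.4}, 0.2, 1.0, lut=lut)
        assert (rgb[0, 0] == lut[0]).all()    # tau <= 0.2 ns -> first entry
        assert (rgb[0, 1] == lut[-1]).all()   # tau >= 1.0 ns -> last entry
        # blue-to-red orientation
        assert lut[0][2] > lut[0][0] and lut[-1][0] > lut[-1][2]


def specs_to_decays(specs):
    return generate_cell_decays(specs)


def _expected_counts(spec):
    """Noise-free expected histogram from the generator's continuous model."""
    from fpolimg.synthetic import _emg_density

    dt = spec.window_ns / spec.n_bins
    t = (np.arange(spec.n_bins) + 0.5) * dt
    sigma = spec.irf_fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w1 = spec.a1 * spec.tau1_ns
    w2 = spec.a2 * spec.tau2_ns
    dens = (w1 * _emg_density(t, spec.tau1_ns, sigma, spec.irf_center_ns)
            + w2 * _emg_density(t, spec.tau2_ns, sigma, spec.irf_center_ns)) / (w1 + w2)
    return spec.n_photons * dens * dt
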