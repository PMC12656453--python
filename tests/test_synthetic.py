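import dataclasses

import numpy as np
import pandas as pd
import pytest

import soilrisk as sr
from soilrisk.synthetic import _latent_correlation, _lognormal_sigma


class TestSpec:
    def test_default_spec_calibration(self):
        spec = sr.default_spec()
        assert spec.n_samples == 48
        assert spec.marginals["Hg"] == (0.05, 69.97)
        assert spec.correlation.loc["Cd", "Zn"] == 0.710
        assert {h.element for h in spec.hotspots} == {"Cd", "Hg"}

    def test_invalid_spec_rejected(self):
        with pytest.raises(sr.ValidationError):
            sr.GeneratorSpec(n_samples=0)
        with pytest.raises(sr.ValidationError):
            sr.GeneratorSpec(domain=(0, 0, -1, 1))

    def test_config_round_trip(self):
        spec = sr.default_spec(seed=9)
        back = sr.spec_from_dict(sr.spec_to_dict(spec))
        assert back.n_samples == spec.n_samples
        assert back.marginals == spec.marginals
        assert back.hotspots == spec.hotspots
        pd.testing.assert_frame_equal(
            back.correlation.loc[spec.elements, spec.elements], spec.correlation
        )


class TestGenerate:
    def test_deterministic_for_fixed_seed(self):
        spec = sr.default_spec(seed=4)
        a = sr.generate(spec)
        b = sr.generate(spec)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a = sr.generate(sr.default_spec(seed=1))
        b = sr.generate(sr.default_spec(seed=2))
        assert not a.data.equals(b.data)

    def test_zero_cv_no_hotspots_gives_constant_means(self):
        spec = sr.default_spec()
        spec = dataclasses.replace(
            spec,
            marginals={el: (m, 0.0) for el, (m, _) in spec.marginals.items()},
            hotspots=(),
        )
        samples = sr.generate(spec)
        for el, (mean, _) in spec.marginals.items():
            np.testing.assert_allclose(samples.concentrations[el], mean, rtol=1e-12)

    def test_moment_recovery_across_replicates(self):
        """Replicate-averaged sample means within 2% of the calibration
        targets and CVs within 10% relative, hotspots included."""
        spec = sr.default_spec()
        means, cvs = [], []
        for seed in range(300):
            stats = sr.summary_statistics(sr.generate(spec, seed=seed))
            means.append(stats["mean"])
            cvs.append(stats["cv_percent"])
        mean_of_means = pd.concat(means, axis=1).mean(axis=1)
        mean_of_cvs = pd.concat(cvs, axis=1).mean(axis=1)
        for el, (target_mean, target_cv) in spec.marginals.items():
            assert mean_of_means[el] == pytest.approx(target_mean, rel=0.02), el
            assert mean_of_cvs[el] == pytest.approx(target_cv, rel=0.10), el

    def test_lognormal_sigma_relation(self):
        """For CV c the log-scale sd is sqrt(ln(1+c^2)); sample moments
        converge to it at large n (hotspot-free)."""
        spec = sr.default_spec()
        spec = dataclasses.replace(spec, n_samples=20000, hotspots=())
        samples = sr.generate(spec, seed=0)
        cd = samples.concentrations["Cd"]
        sigma = _lognormal_sigma(0.9079)
        assert np.log(cd).std(ddof=1) == pytest.approx(sigma, rel=0.02)
        assert cd.mean() == pytest.approx(0.29, rel=0.02)

    def test_hotspot_elevates_max_to_mean_ratio(self):
        """Paired draws (same seed, same locations): a hotspot placed on the
        plain run's maximal-Cd sample multiplies that sample by ~4 while the
        column mean moves only slightly, so max/mean must rise."""
        plain_spec = dataclasses.replace(sr.default_spec(), hotspots=())
        plain = sr.generate(plain_spec, seed=6)
        top = plain.data.loc[plain.concentrations["Cd"].idxmax()]
        hot_spec = dataclasses.replace(
            plain_spec,
            hotspots=(sr.Hotspot("Cd", (top["x"], top["y"]), 120.0, 4.0),),
        )
        hot = sr.generate(hot_spec, seed=6)
        ratio = lambda s: s.concentrations["Cd"].max() / s.concentrations["Cd"].mean()
        assert ratio(hot) > 1.5 * ratio(plain)


class TestCorrelationMachinery:
    def test_nearest_psd_repairs_and_normalizes(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = sr.nearest_psd(bad)
        eigvals = np.linalg.eigvalsh(fixed)
        assert eigvals.min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)

    def test_psd_matrix_unchanged(self):
        good = np.array([[1.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(sr.nearest_psd(good), good)

    def test_latent_correlation_inverts_lognormal_attenuation(self):
        """Simulated lognormal pairs recover the target Pearson r when the
        latent Gaussian correlation is pre-adjusted."""
        sigmas = np.array([_lognormal_sigma(0.9), _lognormal_sigma(0.15)])
        target = np.array([[1.0, 0.7], [0.7, 1.0]])
        latent = _latent_correlation(target, sigmas)
        assert latent[0, 1] > 0.7  # adjustment inflates the latent value
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], latent, size=200000)
        x = np.exp(sigmas * z)
        r = np.corrcoef(x, rowvar=False)[0, 1]
        assert r == pytest.approx(0.7, abs=0.02)

    def test_degenerate_margin_gets_zero_latent(self):
        latent = _latent_correlation(
            np.array([[1.0, 0.5], [0.5, 1.0]]), np.array([0.0, 0.5])
        )
        assert latent[0, 1] == 0.0

    def test_infeasible_target_warns(self, caplog):
        spec = sr.default_spec()
        corr = spec.correlation.copy()
        corr.loc["Pb", "Cd"] = corr.loc["Cd", "Pb"] = -0.99
        corr.loc["Pb", "Zn"] = corr.loc["Zn", "Pb"] = 0.99
        corr.loc["Cd", "Zn"] = corr.loc["Zn", "Cd"] = 0.99
        spec = dataclasses.replace(spec, correlation=corr)
        with caplog.at_level("WARNING"):
            sr.generate(spec, seed=0)
        assert "PSD repair" in caplog.text
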