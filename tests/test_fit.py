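"""Reconvolution fitting: oracle recovery, calibration, diagnostics."""

import numpy as np
import pytest

from flimfret import (
    FitSpec,
    LowSignalError,
    TwoSpeciesParams,
    amplitude_mean_lifetime,
    fit_one_exp,
    fit_two_species,
    intensity_mean_lifetime,
    model_decay,
    simulate_decay,
)

TAU_D = 2.65
TAU_F = 0.83


class TestOneExp:
    def test_noiseless_self_consistency(self, config, delta0):
        m = model_decay(TwoSpeciesParams(f_D=0.0, total_intensity=1e4), config, delta0)
        r = fit_one_exp(m, config, delta0)
        assert r.converged
        assert r.estimates["tau_D"] == pytest.approx(TAU_D, rel=1e-6)

    def test_simulated_high_count_accuracy(self, config, gauss_irf):
        """tau recovered within 1% of 2.65 ns at 1e5 photons, Gaussian IRF."""
        dec = simulate_decay(
            TwoSpeciesParams(f_D=0.0, total_intensity=1e5), config, gauss_irf, seed=11
        )
        r = fit_one_exp(dec, config, gauss_irf)
        assert r.converged
        assert r.estimates["tau_D"] == pytest.approx(TAU_D, rel=0.01)
        assert r.standard_errors is not None
        assert r.standard_errors["tau_D"] > 0

    def test_low_signal_raises(self, config, gauss_irf):
        dec = simulate_decay(
            TwoSpeciesParams(f_D=0.0, total_intensity=50.0), config, gauss_irf, seed=3
        )
        with pytest.raises(LowSignalError):
            fit_one_exp(dec, config, gauss_irf)

    def test_wls_objective_also_recovers_noiseless(self, config, gauss_irf):
        m = model_decay(TwoSpeciesParams(f_D=0.0, total_intensity=1e4), config, gauss_irf)
        r = fit_one_exp(m, config, gauss_irf, FitSpec(model="one-exp", objective="wls"))
        assert r.estimates["tau_D"] == pytest.approx(TAU_D, rel=1e-4)


class TestTwoSpecies:
    def test_noiseless_grid_recovery(self, config, gauss_irf):
        """Both free parameters recovered to numerical precision on exact
        model expectations over the f_D x tau_F grid."""
        spec_base = {"tau_D": TAU_D}
        for f in np.round(np.arange(0.0, 1.01, 0.1), 2):
            for tf in (0.5, 0.83, 1.2):
                m = model_decay(
                    TwoSpeciesParams(f_D=float(f), tau_F=tf, total_intensity=1e4),
                    config,
                    gauss_irf,
                )
                r = fit_two_species(
                    m, config, gauss_irf,
                    FitSpec(model="two-species", fixed=dict(spec_base), objective="wls"),
                )
                assert r.estimates["f_D"] == pytest.approx(f, abs=1e-4)
                if 0.0 < f < 1.0:  # tau_F unidentifiable at f=0, meaningless at clip
                    assert r.estimates["tau_F"] == pytest.approx(tf, abs=1e-3)

    def test_requires_fixed_donor_lifetime(self, config, gauss_irf, rng):
        dec = rng.poisson(5.0, size=config.n_channels)
        with pytest.raises(ValueError, match="tau_D"):
            fit_two_species(dec, config, gauss_irf, FitSpec(model="two-species"))

    def test_donor_only_estimates_stay_small(self, config, gauss_irf):
        """Fitting donor-only decays with the two-species model yields a
        median f_D at the zero boundary and small typical values."""
        spec = FitSpec(model="two-species", fixed={"tau_D": TAU_D, "tau_F": TAU_F})
        ests = []
        for s in range(60):
            dec = simulate_decay(
                TwoSpeciesParams(f_D=0.0, total_intensity=600.0),
                config, gauss_irf, seed=8000 + s,
            )
            ests.append(fit_two_species(dec, config, gauss_irf, spec).estimates["f_D"])
        assert np.median(ests) <= 0.05
        assert np.all((np.array(ests) >= 0.0) & (np.array(ests) <= 1.0))

    def test_population_mean_recovery(self, config, gauss_irf):
        """200 decays at f_D=0.17, ~600 photons, tau_F fixed at the FRET
        lifetime: population mean recovered within ±0.03."""
        spec = FitSpec(model="two-species", fixed={"tau_D": TAU_D, "tau_F": TAU_F})
        ests = []
        for s in range(200):
            dec = simulate_decay(
                TwoSpeciesParams(f_D=0.17, total_intensity=600.0),
                config, gauss_irf, seed=17000 + s,
            )
            ests.append(fit_two_species(dec, config, gauss_irf, spec).estimates["f_D"])
        assert np.mean(ests) == pytest.approx(0.17, abs=0.03)

    def test_identifiability_warning_when_tau_f_collapses(self, config, gauss_irf):
        """A donor-only decay fitted with tau_F free drives tau_F toward
        tau_D; the result carries an explicit warning."""
        m = model_decay(TwoSpeciesParams(f_D=0.0, total_intensity=5e4), config, gauss_irf)
        r = fit_two_species(
            m, config, gauss_irf,
            FitSpec(model="two-species", fixed={"tau_D": TAU_D},
                    initial_values={"tau_F": 2.5, "f_D": 0.5}),
        )
        if r.estimates["tau_F"] > 0.9 * TAU_D:
            assert any("identifiab" in w for w in r.warnings)

    def test_standard_errors_match_replicate_scatter(self, config, gauss_irf):
        """Reported standard errors agree with the replicate sd of f_D
        within a factor of 2 (statistical calibration at 600 photons)."""
        spec = FitSpec(model="two-species", fixed={"tau_D": TAU_D, "tau_F": TAU_F})
        ests, ses = [], []
        for s in range(200):
            dec = simulate_decay(
                TwoSpeciesParams(f_D=0.28, total_intensity=600.0),
                config, gauss_irf, seed=28000 + s,
            )
            r = fit_two_species(dec, config, gauss_irf, spec)
            ests.append(r.estimates["f_D"])
            if r.standard_errors is not None:
                ses.append(r.standard_errors["f_D"])
        assert abs(np.mean(ests) - 0.28) < 0.02
        sd = np.std(ests, ddof=1)
        typical_se = np.median(ses)
        assert typical_se / 2 < sd < typical_se * 2


class TestObjectiveAndReconvolution:
    def test_objective_never_worse_than_start(self, config, gauss_irf):
        for s in range(5):
            dec = simulate_decay(
                TwoSpeciesParams(f_D=0.2, total_intensity=800.0),
                config, gauss_irf, seed=90 + s,
            )
            r = fit_two_species(
                dec, config, gauss_irf,
                FitSpec(model="two-species", fixed={"tau_D": TAU_D, "tau_F": TAU_F}),
            )
            assert r.objective <= r.objective_initial + 1e-9

    def test_irf_is_actually_used(self, config, gauss_irf, delta0):
        """Fitting delta-IRF data while assuming a wide IRF biases the
        recovered lifetime; assuming the correct IRF does not."""
        m = model_decay(TwoSpeciesParams(f_D=0.0, total_intensity=1e5), config, delta0)
        good = fit_one_exp(m, config, delta0).estimates["tau_D"]
        wide = IRF_WIDE = type(gauss_irf)(kind="gaussian", center=0.5, fwhm=1.0)
        biased = fit_one_exp(m, config, wide).estimates["tau_D"]
        assert abs(good - TAU_D) < 1e-4
        assert abs(biased - TAU_D) > 10 * abs(good - TAU_D)


class TestMeanLifetimeHelpers:
    @pytest.mark.parametrize(
        "f,expected",
        [(0.0, TAU_D), (1.0, TAU_F), (0.0714, 0.0714 * TAU_F + (1 - 0.0714) * TAU_D)],
    )
    def test_amplitude_mean(self, f, expected):
        assert amplitude_mean_lifetime(TwoSpeciesParams(f_D=f)) == pytest.approx(
            expected, abs=1e-9
        )
        if f == 0.0714:
            assert expected == pytest.approx(2.520, abs=5e-4)

    @pytest.mark.parametrize(
        "f,expected,tol",
        [(0.0, TAU_D, 1e-12), (1.0, TAU_F, 1e-12), (0.28, 2.452, 5e-4)],
    )
    def test_intensity_mean(self, f, expected, tol):
        assert intensity_mean_lifetime(TwoSpeciesParams(f_D=f)) == pytest.approx(
            expected, abs=tol
        )

    def test_intensity_mean_dominates_amplitude_mean(self):
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            p = TwoSpeciesParams(f_D=f)
            assert intensity_mean_lifetime(p) > amplitude_mean_lifetime(p)
            assert TAU_F < intensity_mean_lifetime(p) < TAU_D
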