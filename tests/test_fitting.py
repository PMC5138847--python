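"""Steady-state, progress-curve, deconvolution and LRT estimation."""

import numpy as np
import pytest
from scipy.optimize import least_squares, minimize_scalar

from uricolysis import (
    AbsorbanceTrace,
    AssayConditions,
    EnzymeSpec,
    FitConvergenceError,
    KineticParameters,
    ModelFit,
    RankDeficiencyError,
    RateDataset,
    SpectraMatrix,
    deconvolve_sequential_spectra,
    fit_competitive_global,
    fit_michaelis_menten,
    fit_progress_curve,
    initial_velocity,
    integrated_mm_substrate,
    likelihood_ratio_test,
    simulate_uricolysis,
)
from uricolysis.synthetic import (
    GeneratorConfig,
    gen_progress_curves,
    gen_rate_dataset,
    gen_time_resolved_spectra,
)

WT_GRID = 11.0 * np.array([0.25, 0.5, 1, 2, 4, 8, 16, 32])


def noiseless_rates(K_M, k_cat, E, S, K_i=None, levels=(0.0,)):
    SS = np.tile(S, len(levels))
    II = np.repeat(np.asarray(levels, dtype=float), len(S))
    bracket = 1.0 + (II / K_i if K_i is not None else 0.0)
    v = k_cat * E * SS / (K_M * bracket + SS)
    return RateDataset(substrate=SS, velocity=v, inhibitor=II, enzyme_conc=E)


class TestMichaelisMenten:
    def test_noiseless_recovery_at_wild_type_constants(self):
        ds = noiseless_rates(11.0, 3.95, 0.9, WT_GRID)
        fr = fit_michaelis_menten(ds)
        assert fr.estimates["K_M"] == pytest.approx(11.0, rel=1e-6)
        assert fr.estimates["k_cat"] == pytest.approx(3.95, rel=1e-6)
        assert fr.converged

    def test_saturating_only_data_flags_km(self):
        S = np.array([500.0, 1000.0, 2000.0, 4000.0, 8000.0])
        ds = noiseless_rates(11.0, 3.95, 0.9, S)
        rng = np.random.default_rng(3)
        ds = RateDataset(S, ds.velocity * (1 + 0.03 * rng.standard_normal(5)),
                         enzyme_conc=0.9)
        fr = fit_michaelis_menten(ds)
        assert "K_M" in fr.poorly_determined

    def test_scale_equivariance(self):
        ds = noiseless_rates(11.0, 3.95, 0.9, WT_GRID)
        ds2 = RateDataset(ds.substrate, 2.0 * ds.velocity, enzyme_conc=1.8)
        fr, fr2 = fit_michaelis_menten(ds), fit_michaelis_menten(ds2)
        assert fr2.estimates["K_M"] == pytest.approx(fr.estimates["K_M"], rel=1e-8)
        assert fr2.estimates["k_cat"] == pytest.approx(fr.estimates["k_cat"], rel=1e-8)

    def test_requires_inhibitor_free(self):
        ds = noiseless_rates(11.0, 3.95, 0.9, WT_GRID, K_i=4.3, levels=(0.0, 4.3))
        with pytest.raises(ValueError, match="inhibitor-free"):
            fit_michaelis_menten(ds)

    def test_recovery_and_coverage_on_noisy_replicates(self):
        """Median over 100 noisy replicates within 5%; 1.96*SE coverage 90-99%."""
        km, kcat, cover = [], [], 0
        for i in range(100):
            cfg = GeneratorConfig(seed=1000 + i, scenario="wt-KP-292")
            ds = gen_rate_dataset(cfg, inhibitor_levels=(0.0,))
            fr = fit_michaelis_menten(ds, seed=i)
            km.append(fr.estimates["K_M"])
            kcat.append(fr.estimates["k_cat"])
            half = 1.96 * fr.standard_errors["K_M"]
            cover += fr.estimates["K_M"] - half <= 11.0 <= fr.estimates["K_M"] + half
        assert np.median(km) == pytest.approx(11.0, rel=0.05)
        assert np.median(kcat) == pytest.approx(3.95, rel=0.05)
        assert 90 <= cover <= 99


class TestCompetitiveGlobal:
    @pytest.mark.parametrize(
        "K_M,k_cat,K_i",
        [(11.0, 3.95, 4.3), (284.0, 3.99, 59.2)],
        ids=["wild-type", "F216S"],
    )
    def test_noiseless_recovery(self, K_M, k_cat, K_i):
        levels = K_i * np.array([0.0, 1.0, 3.0, 10.0])
        ds = noiseless_rates(K_M, k_cat, 0.9, K_M * np.array([0.25, 0.5, 1, 2, 4, 8]),
                             K_i=K_i, levels=levels)
        fr = fit_competitive_global(ds)
        assert fr.estimates["K_M"] == pytest.approx(K_M, rel=1e-6)
        assert fr.estimates["k_cat"] == pytest.approx(k_cat, rel=1e-6)
        assert fr.estimates["K_i"] == pytest.approx(K_i, rel=1e-6)

    def test_apparent_km_linear_in_inhibitor(self):
        """Per-level MM fits give K_M,app = K_M (1 + I/K_i): slope K_M/K_i."""
        K_M, K_i, levels = 11.0, 4.3, np.array([0.0, 4.3, 12.9, 43.0])
        ds = noiseless_rates(K_M, 3.95, 0.9, WT_GRID, K_i=K_i, levels=levels)
        km_app = []
        for lev in levels:
            m = ds.inhibitor == lev
            sub = RateDataset(ds.substrate[m], ds.velocity[m], enzyme_conc=0.9)
            km_app.append(fit_michaelis_menten(sub).estimates["K_M"])
        slope, intercept = np.polyfit(levels, km_app, 1)
        assert intercept == pytest.approx(K_M, rel=1e-5)
        assert slope == pytest.approx(K_M / K_i, rel=1e-5)

    def test_shared_vmax_not_rejected_on_competitive_data(self):
        """Relaxing Vmax across xanthine series brings no significant gain."""
        cfg = GeneratorConfig(seed=21, scenario="wt-KP-292")
        ds = gen_rate_dataset(cfg)
        shared = fit_competitive_global(ds)
        unshared = fit_competitive_global(ds, share_vmax=False)
        res = likelihood_ratio_test(
            shared.as_model_fit("competitive"), unshared.as_model_fit("free-Vmax")
        )
        assert res.p_value > 0.05
        kcats = [v for k, v in unshared.estimates.items() if k.startswith("k_cat")]
        assert np.ptp(kcats) / np.mean(kcats) < 0.1

    def test_requires_zero_level(self):
        ds = noiseless_rates(11.0, 3.95, 0.9, WT_GRID, K_i=4.3, levels=(4.3, 43.0))
        with pytest.raises(ValueError, match="zero"):
            fit_competitive_global(ds)


class TestProgressCurve:
    def test_closed_form_self_consistency(self):
        t = np.linspace(0.0, 600.0, 601)
        S = integrated_mm_substrate(t, 100.0, 3.55, 11.0)
        trace = AbsorbanceTrace(292.0, 1.0, t, 0.05 + 12.2 * S / 1000.0)
        fr = fit_progress_curve(trace, 12.2, 0.9)
        assert fr.estimates["S0"] == pytest.approx(100.0, rel=1e-6)
        assert fr.estimates["K_M"] == pytest.approx(11.0, rel=1e-6)
        assert fr.estimates["Vmax"] == pytest.approx(3.55, rel=1e-6)
        assert fr.estimates["offset"] == pytest.approx(0.05, abs=1e-8)

    def test_low_conversion_warns(self):
        t = np.linspace(0.0, 5.0, 101)  # ~17% conversion only
        S = integrated_mm_substrate(t, 100.0, 3.55, 11.0)
        trace = AbsorbanceTrace(292.0, 1.0, t, 12.2 * S / 1000.0)
        with pytest.warns(UserWarning, match="50%"):
            fit_progress_curve(trace, 12.2, 0.9)

    def test_product_inhibited_trace_inflates_apparent_km(self):
        """Competitive product inhibition is again MM-shaped in disguise:
        K_M,app = K_M (1 + S0/K_p) / a and Vmax,app = Vmax / a with
        a = 1 - K_M/K_p, so a closed-form fit of the ODE trace must land on
        those apparent constants: higher K_M, near-unchanged Vmax."""
        K_M, Vmax, K_p, S0 = 11.0, 3.555, 500.0, 100.0
        p = KineticParameters(K_M=K_M, k_cat=Vmax / 0.9, K_p=K_p)
        cond = AssayConditions(
            substrate_0=S0, enzymes=(EnzymeSpec("Uox", 0.9, parameters=p),),
            k_HIU=0.0, k_OHCU=0.0,
        )
        t = np.linspace(0.0, 300.0, 601)
        s = simulate_uricolysis(cond, p, t)
        trace = AbsorbanceTrace(292.0, 1.0, t, 12.2 * s.urate / 1000.0)
        fr = fit_progress_curve(trace, 12.2, 0.9, model="closed_form")
        a = 1.0 - K_M / K_p
        assert fr.estimates["K_M"] == pytest.approx(K_M * (1 + S0 / K_p) / a, rel=1e-4)
        assert fr.estimates["Vmax"] == pytest.approx(Vmax / a, rel=1e-4)
        assert fr.estimates["K_M"] > K_M
        assert fr.estimates["Vmax"] == pytest.approx(Vmax, rel=0.05)

    def test_ode_model_recovers_kp(self):
        p = KineticParameters(K_M=11.0, k_cat=3.95, K_p=10.0)
        cond = AssayConditions(
            substrate_0=100.0, enzymes=(EnzymeSpec("Uox", 0.9, parameters=p),)
        )
        t = np.linspace(0.0, 400.0, 401)
        s = simulate_uricolysis(cond, p, t)
        trace = AbsorbanceTrace(292.0, 1.0, t, 12.2 * s.urate / 1000.0)
        fr = fit_progress_curve(
            trace, 12.2, 0.9, model="ode_product_inhibition", conditions=cond
        )
        assert fr.estimates["K_M"] == pytest.approx(11.0, rel=1e-4)
        assert fr.estimates["Vmax"] == pytest.approx(3.555, rel=1e-4)
        assert fr.estimates["K_p"] == pytest.approx(10.0, rel=1e-3)

    def test_hiu_formation_trace_recovers_decay_rate(self):
        """320 nm observable (urate transparent, HIU absorbing): k_HIU back."""
        p = KineticParameters(K_M=11.0, k_cat=3.95)
        cond = AssayConditions(
            substrate_0=100.0, enzymes=(EnzymeSpec("Uox", 0.9, parameters=p),),
            k_HIU=0.006,
        )
        t = np.linspace(0.0, 400.0, 401)
        s = simulate_uricolysis(cond, p, t)
        eps320 = 3.0
        trace = AbsorbanceTrace(320.0, 1.0, t, eps320 * s.hiu / 1000.0)
        fr = fit_progress_curve(
            trace, eps320, 0.9, model="ode_product_inhibition", conditions=cond,
            observed={"hiu": eps320},
            free=("S0", "K_M", "Vmax", "k_HIU", "offset"),
        )
        assert fr.estimates["k_HIU"] == pytest.approx(0.006, rel=0.05)

    def test_progress_and_initial_velocity_routes_agree(self):
        """Closed-form progress K_M vs K_M from extracted v0 data: within 10%."""
        S0_grid = [11.0, 22.0, 44.0, 88.0, 176.0, 352.0]
        for seed in (11, 22, 33):
            cfg = GeneratorConfig(seed=seed, scenario="wt-KP-292")
            trace = gen_progress_curves(cfg, n_curves=1)[0]
            fr = fit_progress_curve(trace, 12.2, 0.9)
            v0 = []
            for s0 in S0_grid:
                cfg_i = GeneratorConfig(
                    seed=seed, scenario="wt-KP-292", overrides={"substrate_0": s0}
                )
                reps = gen_progress_curves(cfg_i, n_curves=3)
                v0.append(np.mean([initial_velocity(r, 12.2) for r in reps]))
            ds = RateDataset(np.array(S0_grid), np.array(v0), enzyme_conc=0.9)
            fr2 = fit_michaelis_menten(ds)
            assert fr.estimates["K_M"] == pytest.approx(fr2.estimates["K_M"], rel=0.10)


class TestDeconvolution:
    def test_self_consistency_noiseless(self):
        truth = gen_time_resolved_spectra(
            GeneratorConfig(seed=3, noise_sd_abs=0.0), "Uox+Urad"
        )
        res, spectra = deconvolve_sequential_spectra(
            truth.matrix, "Uox+Urad",
            init={"Vmax": 3.0, "K_M": 10.0, "k_HIU": 0.008, "S0": 100.0},
        )
        assert res.estimates["Vmax"] == pytest.approx(3.555, rel=1e-4)
        assert res.estimates["K_M"] == pytest.approx(11.0, rel=1e-4)
        assert res.estimates["k_HIU"] == pytest.approx(0.006, rel=1e-4)
        for got, want in zip(spectra, truth.spectra):
            assert np.max(np.abs(got.epsilon - want.epsilon)) < 1e-6

    def test_urah_scheme_resolves_ohcu(self):
        truth = gen_time_resolved_spectra(
            GeneratorConfig(seed=5, noise_sd_abs=0.0), "Uox+Urah"
        )
        res, spectra = deconvolve_sequential_spectra(
            truth.matrix, "Uox+Urah",
            init={"Vmax": 3.0, "K_M": 10.0, "k_OHCU": 0.005, "S0": 100.0},
        )
        assert res.estimates["k_OHCU"] == pytest.approx(0.004, rel=1e-3)
        assert spectra[1].species == "ohcu"
        want = truth.spectra[2].epsilon  # species order: urate, hiu, ohcu, allantoin
        assert np.max(np.abs(spectra[1].epsilon - want)) < 1e-5

    def test_hiu_ratio_recovered_under_noise(self):
        """eps_HIU(292)/eps_urate(292) = 0.50 +/- 0.02 at sigma = 0.002 AU."""
        truth = gen_time_resolved_spectra(
            GeneratorConfig(seed=7, noise_sd_abs=0.002), "Uox+Urad"
        )
        _res, spectra = deconvolve_sequential_spectra(
            truth.matrix, "Uox+Urad",
            init={"Vmax": 3.0, "K_M": 10.0, "k_HIU": 0.008, "S0": 100.0},
        )
        ratio = spectra[1].at(292.0) / spectra[0].at(292.0)
        assert ratio == pytest.approx(0.50, abs=0.02)

    def test_rank_check_on_quenched_species(self):
        truth = gen_time_resolved_spectra(
            GeneratorConfig(seed=3, noise_sd_abs=0.0), "Uox+Urad"
        )
        with pytest.raises(RankDeficiencyError):
            deconvolve_sequential_spectra(
                truth.matrix, "Uox+Urad+OHCU",
                init={"Vmax": 3.0, "K_M": 10.0, "k_HIU": 0.008, "S0": 100.0},
            )

    def test_single_scheme_matches_direct_least_squares(self):
        """One species degenerates to a per-wavelength exponential-amplitude
        fit; cross-checked against a 1-D scan with analytic amplitudes."""
        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 20.0, 20)
        eps_true = np.array([5.0, 3.0, 1.0, 0.5, 8.0])
        A = np.exp(-0.15 * t)[:, None] * eps_true[None, :] / 1000.0
        A = A + 0.0005 * rng.standard_normal(A.shape)
        m = SpectraMatrix(
            times=t, wavelengths=np.array([240.0, 260.0, 280.0, 300.0, 320.0]),
            absorbance=A,
        )
        res, _sp = deconvolve_sequential_spectra(
            m, "single-exponential", {"k": 0.1}, nonneg=False
        )

        def rss_of_k(k):
            c = np.exp(-k * t) / 1000.0
            amps = (c @ A) / (c @ c)
            return (((c[:, None] * amps[None, :]) - A) ** 2).sum()

        oracle = minimize_scalar(
            rss_of_k, bounds=(0.01, 1.0), method="bounded", options={"xatol": 1e-12}
        )
        assert res.estimates["k"] == pytest.approx(oracle.x, rel=1e-5)
        assert res.rss == pytest.approx(oracle.fun, rel=1e-9)

    def test_varpro_equals_joint_least_squares(self):
        """Variable-projection optimum = brute-force joint optimum (5 wl x 20 t)."""
        rng = np.random.default_rng(1)
        t = np.linspace(0.0, 20.0, 20)
        eps_true = np.array([5.0, 3.0, 1.0, 0.5, 8.0])
        A = np.exp(-0.15 * t)[:, None] * eps_true[None, :] / 1000.0
        A = A + 0.0005 * rng.standard_normal(A.shape)
        m = SpectraMatrix(
            times=t, wavelengths=np.array([240.0, 260.0, 280.0, 300.0, 320.0]),
            absorbance=A,
        )
        res, _ = deconvolve_sequential_spectra(
            m, "single-exponential", {"k": 0.1}, nonneg=False
        )

        def joint(x):
            return (np.exp(-x[0] * t)[:, None] * x[1:][None, :] / 1000.0 - A).ravel()

        sol = least_squares(joint, [0.1, 4, 4, 4, 4, 4], method="lm",
                            xtol=1e-15, ftol=1e-15)
        assert res.rss == pytest.approx(2.0 * sol.cost, rel=1e-8)
        assert res.estimates["k"] == pytest.approx(sol.x[0], rel=1e-6)


class TestLikelihoodRatio:
    @pytest.mark.parametrize(
        "lnl0,lnl1,df,printed,tol",
        [
            (-2881.94, -2856.90, 1, 1.5e-12, None),  # formatted check below
            (-2856.90, -2854.75, 1, 0.04, 0.005),
            (-2854.75, -2854.69, 1, 0.72, 0.015),
            (-2854.69, -2854.25, 3, 0.83, 0.01),
        ],
    )
    def test_printed_p_values(self, lnl0, lnl1, df, printed, tol):
        """dN/dS model-comparison arithmetic on the published log-likelihoods.

        Inputs are rounded to 2 decimals, which moves p by up to ~0.02 for
        the near-1 statistics; tolerances reflect that input rounding."""
        res = likelihood_ratio_test(
            ModelFit("null", lnl0, 1), ModelFit("alt", lnl1, 1 + df)
        )
        if tol is None:
            assert f"{res.p_value:.1E}" == "1.5E-12"
        else:
            assert res.p_value == pytest.approx(printed, abs=tol)

    def test_zero_statistic_gives_p_one(self):
        res = likelihood_ratio_test(ModelFit("a", -10.0, 1), ModelFit("b", -10.0, 2))
        assert res.p_value == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError, match="more parameters"):
            likelihood_ratio_test(ModelFit("a", -10.0, 2), ModelFit("b", -9.0, 2))
        with pytest.raises(ValueError, match="below the null"):
            likelihood_ratio_test(ModelFit("a", -9.0, 1), ModelFit("b", -10.0, 2))


class TestFitInfrastructure:
    def test_chi_square_tail_independent_check(self):
        """2*dlnL = 50.08, df 1: p equals the normal-tail closed form."""
        from math import erfc, sqrt
        res = likelihood_ratio_test(
            ModelFit("null", -2881.94, 1), ModelFit("alt", -2856.90, 2)
        )
        assert res.p_value == pytest.approx(erfc(sqrt(50.08 / 2.0)), rel=1e-10)

    def test_convergence_error_is_loud(self):
        # a residual that always explodes can never converge
        from uricolysis.fitting import _multistart_fit

        def bad(_x):
            raise RuntimeError("model blew up")

        with pytest.raises(FitConvergenceError):
            _multistart_fit(bad, ("a",), [1.0], n_obs=10)
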