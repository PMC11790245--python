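"""Concentration-viscosity model evaluation, fitting, knees and regimes."""

import numpy as np
import pytest
from scipy import optimize

from mabvisc import (
    ModelSpec,
    SyntheticSpec,
    ViscosityProfile,
    compare_regimes,
    evaluate_model,
    fit_model,
    gen_viscosity_profile,
    rank_molecules,
    segment_regimes,
)
from mabvisc.models import MODEL_REGISTRY


class TestEvaluateModel:
    @pytest.mark.parametrize("spec,c,expected", [
        (ModelSpec("growth_exponential", {"Y0": 2.0, "k": 0.0}), 100.0, 2.0),
        (ModelSpec("ross_minton",
                   {"intrinsic_viscosity": 0.0063, "crowding_ratio": 0.3}),
         0.0, 1.13),
        # 1.13 * exp(-0.58 + 0.0208*180), frozen from direct scalar arithmetic
        (ModelSpec("tomar", {"lnA": -0.58, "B": 0.0208}), 180.0,
         26.741525856022136),
    ])
    def test_pointwise_values(self, spec, c, expected):
        assert evaluate_model(spec, c) == pytest.approx(expected, rel=1e-12)

    def test_zero_concentration_limits(self, model_truths):
        """eta(0): growth -> Y0, 3-param -> e^(a1+a3/T), RM -> eta0,
        tomar -> eta0*A."""
        expected = {
            "growth_exponential": 2.0,
            "three_param_exponential": np.exp(0.5),
            "ross_minton": 1.13,
            "tomar": 1.13 * np.exp(-0.58),
        }
        for name, params in model_truths.items():
            spec = ModelSpec(name, params)
            assert evaluate_model(spec, 0.0) == pytest.approx(
                expected[name], rel=1e-12)

    def test_ross_minton_singularity_raises(self):
        spec = ModelSpec("ross_minton",
                         {"intrinsic_viscosity": 0.01, "crowding_ratio": 1.0})
        with pytest.raises(ValueError, match="singularity"):
            evaluate_model(spec, 150.0)

    def test_negative_concentration_raises(self):
        spec = ModelSpec("growth_exponential", {"Y0": 2.0, "k": 0.02})
        with pytest.raises(ValueError, match="non-negative"):
            evaluate_model(spec, -1.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec("power_law", {"a": 1.0})

    def test_ross_minton_increasing_and_convex(self):
        spec = ModelSpec("ross_minton",
                         {"intrinsic_viscosity": 0.0063, "crowding_ratio": 0.3})
        c = np.linspace(0, 500, 200)  # singularity at ~529 mg/mL
        eta = evaluate_model(spec, c)
        assert np.all(np.diff(eta) > 0)
        assert np.all(np.diff(eta, 2) > 0)


class TestFitModel:
    @pytest.mark.parametrize("model_name", list(MODEL_REGISTRY))
    def test_noiseless_recovery(self, model_name, model_truths,
                                noiseless_profile):
        res = fit_model(noiseless_profile(model_name), model_name)
        assert res.converged
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        truth = model_truths[model_name]
        for name, val in truth.items():
            if val == 0.0:
                assert abs(res.param_dict[name]) < 1e-8
            else:
                assert res.param_dict[name] == pytest.approx(val, rel=1e-5)

    def test_ross_minton_matches_grid_search_oracle(self, noiseless_profile):
        """NLS optimum agrees with a dense 2-D grid search over
        ([eta], k/v) refined by Nelder-Mead on the same SSE."""
        prof = noiseless_profile("ross_minton")
        c, eta = prof.concentrations, prof.viscosities

        def sse(p):
            iv, kv = p
            denom = 1.0 - kv * iv * c
            if iv <= 0 or np.any(denom <= 0):
                return 1e30
            with np.errstate(over="ignore"):
                s = float(np.sum((1.13 * np.exp(iv * c / denom) - eta) ** 2))
            return s if np.isfinite(s) else 1e30

        grid_iv = np.linspace(0.002, 0.02, 60)
        grid_kv = np.linspace(0.0, 0.9, 60)
        best = min(((sse([iv, kv]), iv, kv)
                    for iv in grid_iv for kv in grid_kv))
        polished = optimize.minimize(
            sse, [best[1], best[2]], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-24},
        )
        res = fit_model(prof, "ross_minton")
        assert res.param_dict["intrinsic_viscosity"] == pytest.approx(
            polished.x[0], rel=1e-5)
        assert res.param_dict["crowding_ratio"] == pytest.approx(
            polished.x[1], rel=1e-4)

    def test_insufficient_data_raises(self):
        prof = ViscosityProfile.from_arrays("x", [10, 50], [2.0, 5.0])
        with pytest.raises(ValueError, match="insufficient data"):
            fit_model(prof, "growth_exponential")

    def test_covariance_positive_semidefinite(self, noiseless_profile):
        spec = ModelSpec("growth_exponential", {"Y0": 2.0, "k": 0.02})
        prof = gen_viscosity_profile(
            spec, SyntheticSpec(seed=5, sd_value=0.05))
        res = fit_model(prof, "growth_exponential")
        assert res.cov is not None
        assert np.all(np.linalg.eigvalsh(res.cov) >= -1e-12)


class TestPredictWithCI:
    def test_zero_residual_interval_is_degenerate(self, noiseless_profile):
        res = fit_model(noiseless_profile("growth_exponential"),
                        "growth_exponential")
        eta, ci = res.predict_with_ci(180.0)
        assert ci[1] - ci[0] == pytest.approx(0.0, abs=1e-6)

    def test_interval_widens_away_from_data(self):
        spec = ModelSpec("growth_exponential", {"Y0": 2.0, "k": 0.02})
        prof = gen_viscosity_profile(spec, SyntheticSpec(seed=2, sd_value=0.05))
        res = fit_model(prof, "growth_exponential")
        cbar = prof.concentrations.mean()
        widths = []
        for c in (cbar, cbar + 100, cbar + 200):
            _, ci = res.predict_with_ci(c)
            widths.append(ci[1] - ci[0])
        assert widths[0] < widths[1] < widths[2]

    def test_interval_contains_point_estimate(self):
        spec = ModelSpec("tomar", {"lnA": -0.58, "B": 0.0208})
        prof = gen_viscosity_profile(spec, SyntheticSpec(seed=3, sd_value=0.05))
        res = fit_model(prof, "tomar")
        eta, ci = res.predict_with_ci(200.0)
        assert ci[0] < eta < ci[1]


class TestKnee:
    def test_growth_knee_at_zero(self, noiseless_profile):
        prof = noiseless_profile("growth_exponential")
        res = fit_model(prof, "growth_exponential")
        kn = res.model.knee(np.array([1.0, 1.0]))
        assert kn.c_knee == pytest.approx(0.0, abs=1e-12)
        assert kn.ok

    def test_growth_knee_value(self, noiseless_profile):
        # numeric root of Y0*k*e^(kc) - 1 for Y0=1.2, k=0.03 (brentq oracle)
        oracle = optimize.brentq(
            lambda c: 1.2 * 0.03 * np.exp(0.03 * c) - 1.0, 0, 1000)
        prof = noiseless_profile("growth_exponential")
        kn = fit_model(prof, "growth_exponential").model.knee(
            np.array([1.2, 0.03]))
        assert kn.c_knee == pytest.approx(oracle, abs=1e-6)
        assert kn.c_knee == pytest.approx(110.81, abs=0.01)

    def test_ross_minton_knee_vs_central_difference_oracle(
            self, noiseless_profile):
        """Bisection knee agrees with a root found on an independent
        central-difference derivative of the curve itself."""
        spec = ModelSpec("ross_minton",
                         {"intrinsic_viscosity": 0.0063, "crowding_ratio": 0.3})

        def slope(c, h=1e-5):
            return (evaluate_model(spec, c + h)
                    - evaluate_model(spec, c - h)) / (2 * h)

        oracle = optimize.brentq(lambda c: slope(c) - 1.0, 1.0, 500.0,
                                 xtol=1e-10)
        res = fit_model(noiseless_profile("ross_minton"), "ross_minton")
        kn = res.knee()
        assert kn.method == "numeric"
        assert kn.residual < 1e-8
        assert kn.c_knee == pytest.approx(oracle, abs=1e-4)
        assert kn.c_knee == pytest.approx(271.0, abs=0.5)

    def test_analytic_equals_numeric_for_closed_form_models(
            self, noiseless_profile):
        """Seeded sweep: analytic knee formulas match the numeric
        d(eta)/dc = 1 root."""
        rng = np.random.default_rng(11)
        prof = noiseless_profile("growth_exponential")
        tomar_prof = noiseless_profile("tomar")
        g = fit_model(prof, "growth_exponential").model
        t = fit_model(tomar_prof, "tomar").model
        for _ in range(20):
            y0 = rng.uniform(0.5, 5.0)
            k = rng.uniform(0.005, 0.05)
            kn = g.knee(np.array([y0, k]))
            if not kn.ok:
                continue
            root = optimize.brentq(
                lambda c: y0 * k * np.exp(k * c) - 1, -1, 2000)
            assert kn.c_knee == pytest.approx(root, abs=1e-6)
            lna, b = np.log(y0 / 1.13), k
            kt = t.knee(np.array([lna, b]))
            root_t = optimize.brentq(
                lambda c: 1.13 * b * np.exp(lna + b * c) - 1, -1, 2000)
            if kt.ok:
                assert kt.c_knee == pytest.approx(root_t, abs=1e-6)

    def test_slope_exceeding_one_at_zero_flagged(self, noiseless_profile):
        prof = noiseless_profile("growth_exponential")
        model = fit_model(prof, "growth_exponential").model
        kn = model.knee(np.array([200.0, 0.02]))  # d eta/dc (0) = 4
        assert kn.status == "slope_exceeds_one_at_zero"

    def test_no_root_when_curve_flat(self, noiseless_profile):
        prof = noiseless_profile("ross_minton")
        model = fit_model(prof, "ross_minton").model
        # tiny [eta]: slope never reaches 1 before the singularity
        kn = model.knee(np.array([1e-4, 5.0]))
        assert kn.status == "no_root_in_range"
        assert np.isnan(kn.c_knee)


class TestRegimes:
    def make_profile(self, cs):
        eta = 2.0 * np.exp(0.02 * np.asarray(cs, dtype=float))
        return ViscosityProfile.from_arrays("m", cs, eta)

    def test_segment_counts_inclusive(self):
        prof = self.make_profile([20, 60, 120, 180, 240])
        high, ultra = segment_regimes(prof)
        assert high.n_points == 3       # 120 itself goes to "high" (<=)
        assert ultra.n_points == 5

    def test_segment_counts_exclusive(self):
        prof = self.make_profile([20, 60, 120, 180, 240])
        _, ultra = segment_regimes(prof, ultra_inclusive=False)
        assert ultra.n_points == 2

    def test_boundary_point_assigned_to_high(self):
        prof = self.make_profile([40, 80, 120])
        high, _ = segment_regimes(prof, ultra_inclusive=True)
        assert 120.0 in high.concentrations

    def test_empty_segment_raises(self):
        prof = self.make_profile([150, 200, 250])
        with pytest.raises(ValueError, match="high"):
            segment_regimes(prof)


class TestCompareRegimes:
    @pytest.mark.parametrize("high,ultra,expected", [
        (47.69, 81.24, 52),    # printed WT growth row
        (18.26, 77.52, 124),   # printed D70N growth row
    ])
    def test_printed_percent_differences(self, high, ultra, expected):
        assert round(compare_regimes(high, ultra)) == expected

    def test_identical_inputs_give_zero(self):
        assert compare_regimes(33.3, 33.3) == 0.0

    def test_antisymmetry_and_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b = rng.uniform(0.1, 1000, size=2)
            d = compare_regimes(a, b)
            assert d == pytest.approx(-compare_regimes(b, a))
            assert -200 < d < 200

    def test_nonpositive_input_raises(self):
        with pytest.raises(ValueError):
            compare_regimes(-1.0, 10.0)


class TestRankMolecules:
    def fits(self, params_by_mol, grid=tuple(range(10, 241, 10))):
        out = {}
        for mol, (y0, k) in params_by_mol.items():
            spec = ModelSpec("growth_exponential", {"Y0": y0, "k": k})
            prof = gen_viscosity_profile(
                spec, SyntheticSpec(seed=0, sd_value=0.0), grid=grid,
                molecule_id=mol)
            out[mol] = fit_model(prof, "growth_exponential")
        return out

    def test_identical_regimes_correlate_perfectly(self):
        fits = self.fits({"a": (1, 0.01), "b": (2, 0.02), "c": (3, 0.03)})
        table = rank_molecules({"high": fits, "ultra_high": fits}, 180.0)
        assert table.attrs["spearman_rho"] == pytest.approx(1.0)

    def test_reversed_order_correlates_negatively(self):
        low = self.fits({"a": (1, 0.01), "b": (2, 0.02), "c": (3, 0.03)})
        rev = self.fits({"a": (3, 0.03), "b": (2, 0.02), "c": (1, 0.01)})
        table = rank_molecules({"high": low, "ultra_high": rev}, 180.0)
        assert table.attrs["spearman_rho"] == pytest.approx(-1.0)

    def test_single_swap_matches_bruteforce_spearman(self):
        """4 molecules with one adjacent swap: rho = 0.8, verified against
        the closed form 1 - 6*sum(d^2)/(n(n^2-1))."""
        base = {"a": (1, 0.01), "b": (1.5, 0.015), "c": (2, 0.02),
                "d": (2.5, 0.025)}
        swapped = {"a": (1.5, 0.015), "b": (1, 0.01), "c": (2, 0.02),
                   "d": (2.5, 0.025)}
        table = rank_molecules(
            {"high": self.fits(base), "ultra_high": self.fits(swapped)}, 180.0)
        d2 = np.sum((table["rank_high"] - table["rank_ultra_high"]) ** 2)
        brute = 1 - 6 * d2 / (4 * (16 - 1))
        assert table.attrs["spearman_rho"] == pytest.approx(brute)
        assert table.attrs["spearman_rho"] == pytest.approx(0.8)

    def test_missing_molecule_excluded_with_warning(self):
        full = self.fits({"a": (1, 0.01), "b": (2, 0.02), "c": (3, 0.03)})
        partial = {k: v for k, v in full.items() if k != "c"}
        with pytest.warns(UserWarning, match="excluded"):
            table = rank_molecules({"high": full, "ultra_high": partial}, 180.0)
        assert "c" not in table.index
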