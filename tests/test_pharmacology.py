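"""Hill dose-response, inhibition, onset and density-decay fitting."""

import numpy as np
import pytest

from srbindex import (
    InsufficientDataError,
    detect_growth_onset,
    fit_density_decay,
    fit_dose_response,
    fit_inhibition,
    hill_response,
    max_growth_percent,
)
from srbindex.synthsim import simulate_dose_response_data, simulate_inhibition_data

PARAMS_24H = (0.266, 0.174, 0.50, 0.185)
PARAMS_48H = (0.289, 0.223, 0.67, 0.844)


class TestHillResponse:
    def test_zero_dose_is_baseline(self):
        assert hill_response(0.0, PARAMS_24H) == PARAMS_24H[0]

    def test_half_maximal_at_ec50(self):
        # R0 + Rhyp/2 = 0.266 + 0.087 = 0.353 at the 24 h EC50
        assert hill_response(0.185, PARAMS_24H) == pytest.approx(0.353)

    def test_saturates_at_r0_plus_rhyp(self):
        assert hill_response(1e9, PARAMS_24H) == pytest.approx(
            PARAMS_24H[0] + PARAMS_24H[1], rel=1e-3
        )

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-1.0, PARAMS_24H)

    def test_monotone_nondecreasing_in_dose(self):
        doses = np.geomspace(1e-4, 1e3, 200)
        resp = hill_response(doses, PARAMS_24H)
        assert np.all(np.diff(resp) >= 0)


class TestFitDoseResponse:
    def test_noiseless_selfconsistency_to_six_digits(self):
        doses = np.concatenate([[0.0], np.geomspace(0.01, 30.0, 8)])
        fit = fit_dose_response(doses, hill_response(doses, PARAMS_24H))
        assert np.allclose(fit.params, PARAMS_24H, rtol=1e-6)

    @pytest.mark.parametrize("params", [PARAMS_24H, PARAMS_48H], ids=["24h", "48h"])
    def test_ec50_recovery_under_noise(self, params):
        """Median recovery error over replicate simulations within +-25%."""
        errors = []
        for seed in range(9):
            d, r = simulate_dose_response_data(params, rng=seed)
            fit = fit_dose_response(d, r)
            errors.append(abs(fit.EC50 - params[3]) / params[3])
        assert np.median(errors) < 0.25

    def test_too_few_doses_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_dose_response([0.0, 1.0, 10.0], [0.1, 0.2, 0.3])

    def test_roundtrip_random_parameter_sets(self, rng):
        """Noiseless fit/evaluate round-trip over identifiable parameter draws."""
        doses = np.concatenate([[0.0], np.geomspace(0.01, 30.0, 10)])
        for _ in range(10):
            truth = (
                rng.uniform(0.1, 1.0),
                rng.uniform(0.05, 1.0),
                rng.uniform(0.4, 3.0),
                np.exp(rng.uniform(np.log(0.05), np.log(5.0))),
            )
            fit = fit_dose_response(doses, hill_response(doses, truth))
            assert np.allclose(fit.params, truth, rtol=1e-5)


class TestMaxGrowthPercent:
    def test_48h_parameters_give_177_percent(self):
        assert round(max_growth_percent(PARAMS_48H)) == 177

    def test_24h_parameters_approach_166_percent(self):
        value = max_growth_percent(PARAMS_24H)
        assert value <= 166.0
        assert value == pytest.approx(165.4, abs=0.1)

    def test_no_hypertrophic_component_is_100_percent(self):
        assert max_growth_percent((0.3, 0.0)) == pytest.approx(100.0)

    def test_invariant_under_common_rescaling(self):
        assert max_growth_percent((0.266, 0.174)) == pytest.approx(
            max_growth_percent((2.66, 1.74))
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            max_growth_percent((0.0, 0.2))


class TestFitInhibition:
    def test_zero_dose_returns_g0(self):
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        growth = 77.0 / (1.0 + doses / 9.0)
        fit = fit_inhibition(doses, growth)
        assert fit.G0 == pytest.approx(77.0, rel=1e-6)

    def test_noiseless_ki_recovery(self):
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        fit = fit_inhibition(doses, 50.0 / (1.0 + doses / 9.0))
        assert fit.Ki == pytest.approx(9.0, rel=1e-6)

    def test_ki_recovery_under_noise(self):
        """Median recovery error over replicate screens within +-30%."""
        errors = []
        for seed in range(9):
            d, g = simulate_inhibition_data(ki=9.0, rng=seed)
            errors.append(abs(fit_inhibition(d, g).Ki - 9.0) / 9.0)
        assert np.median(errors) < 0.30

    def test_halved_at_ki(self):
        doses = np.array([0.0, 2.0, 9.0, 20.0, 40.0])
        fit = fit_inhibition(doses, 60.0 / (1.0 + doses / 9.0))
        predicted = fit.G0 / (1.0 + 9.0 / fit.Ki)
        assert predicted == pytest.approx(30.0, rel=1e-4)

    def test_floor_variant(self):
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])
        truth = 20.0 + 60.0 / (1.0 + doses / 9.0)
        fit = fit_inhibition(doses, truth, fit_floor=True)
        assert fit.Ki == pytest.approx(9.0, rel=1e-4)
        assert fit.floor == pytest.approx(20.0, rel=1e-3)

    def test_too_few_doses_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_inhibition([0.0, 1.0, 10.0], [50.0, 40.0, 20.0])


class TestDetectGrowthOnset:
    TIMES = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 24.0])

    def hinge_series(self, rng, onset=4.0, slope=1.0, sd=1.0, n=8):
        treated, control = [], []
        for t in self.TIMES:
            mean = slope * max(t - onset, 0.0) * 3.0 * sd / (24.0 - onset)
            base = 10.0
            treated.append(rng.normal(base + (3.0 * sd if t >= onset else 0.0), sd, n))
            control.append(rng.normal(base, sd, n))
        return treated, control

    def test_hinge_onset_detected(self, rng):
        treated, control = self.hinge_series(rng)
        res = detect_growth_onset(self.TIMES, treated, control)
        assert res.onset_time == 4.0
        assert res.slope is not None

    def test_flat_series_has_no_onset(self, rng):
        flat_t = [rng.normal(10.0, 1.0, 8) for _ in self.TIMES]
        flat_c = [rng.normal(10.0, 1.0, 8) for _ in self.TIMES]
        res = detect_growth_onset(self.TIMES, flat_t, flat_c)
        assert res.onset_time is None
        assert res.slope is None

    def test_rise_from_first_timepoint(self, rng):
        treated = [rng.normal(20.0, 1.0, 8) for _ in self.TIMES]
        control = [rng.normal(10.0, 1.0, 8) for _ in self.TIMES]
        res = detect_growth_onset(self.TIMES, treated, control)
        assert res.onset_time == self.TIMES[0]

    def test_type_i_error_controlled_on_null(self):
        """Bonferroni keeps spurious onsets <= 7% on flat simulations."""
        rng = np.random.default_rng(2024)
        times = np.array([2.0, 4.0, 8.0, 16.0, 24.0])
        hits = 0
        reps = 1000
        for _ in range(reps):
            treated = [rng.normal(0.0, 1.0, 8) for _ in times]
            control = [rng.normal(0.0, 1.0, 8) for _ in times]
            if detect_growth_onset(times, treated, control).onset_time is not None:
                hits += 1
        assert hits / reps <= 0.07


class TestFitDensityDecay:
    def test_noiseless_recovery(self):
        dens = np.array([500.0, 1000.0, 2000.0, 3000.0, 4500.0])
        a, k = fit_density_decay(dens, 0.6 * np.exp(-2e-4 * dens))
        assert a == pytest.approx(0.6, rel=1e-6)
        assert k == pytest.approx(2e-4, rel=1e-6)

    def test_constant_indices_give_zero_decay(self):
        with pytest.warns(UserWarning):
            a, k = fit_density_decay([1000, 2000, 3000, 4000], [0.4] * 4)
        assert k == 0.0
        assert a == pytest.approx(0.4)

    def test_increasing_trend_clamped(self):
        with pytest.warns(UserWarning):
            _, k = fit_density_decay(
                [1000, 2000, 3000, 4000], [0.2, 0.3, 0.4, 0.5]
            )
        assert k == 0.0

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_density_decay([1000, 2000, 3000], [0.5, 0.4, 0.3])
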