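import math

import numpy as np
import pytest

from eif2btools.binding_models import (
    MODELS,
    FitError,
    FitResult,
    KineticTrace,
    evaluate,
    fit,
    half_life,
    half_life_from_rate,
    percent_fast_dose_response,
)
from eif2btools.synthetic import TraceLedger, default_trace_ledgers, simulate_trace


@pytest.mark.parametrize(
    "model_id, params, x, expected",
    [
        ("one_phase_decay", {"Y0": 200.0, "Plateau": 50.0, "K": 0.5}, 0.0, 200.0),
        ("one_site_specific", {"Bmax": 100.0, "Kd": 10.0}, 10.0, 50.0),
        ("fourpl_inhibition",
         {"Bottom": 40.0, "Top": 240.0, "LogIC50": math.log10(0.25),
          "HillSlope": 2.4}, math.log10(0.25), 140.0),
        ("agonist_response", {"Bottom": 50.0, "Top": 75.0, "EC50": 1.8}, 1.8, 62.5),
    ],
)
def test_evaluate_known_points(model_id, params, x, expected):
    assert evaluate(model_id, params, x) == pytest.approx(expected, abs=1e-12)


def test_evaluate_validates_inputs():
    with pytest.raises(FitError, match="missing parameter"):
        evaluate("one_phase_decay", {"Y0": 1.0, "K": 1.0}, 0.0)
    with pytest.raises(ValueError, match=">= 0"):
        evaluate("one_site_specific", {"Bmax": 1.0, "Kd": 1.0}, -1.0)
    with pytest.raises(FitError, match="unknown model"):
        evaluate("sigmoid", {}, 0.0)


@pytest.mark.parametrize("model_id", sorted(MODELS))
def test_noiseless_generate_fit_round_trip(model_id):
    """Fitting data generated by a model recovers its parameters exactly."""
    ledger, x = default_trace_ledgers(0)[model_id]
    trace = simulate_trace(TraceLedger(model_id, ledger.true_params, 0.0, 0), x)
    result = fit(model_id, trace)
    for name, truth in ledger.params.items():
        assert result.params[name] == pytest.approx(truth, rel=1e-6, abs=1e-9)
    assert result.r_squared == pytest.approx(1.0, abs=1e-9)
    for name, (lo, hi) in result.ci95.items():
        assert lo <= result.params[name] <= hi


def test_biphasic_with_full_fast_fraction_is_single_exponential():
    params = {"Y0": 0.2, "Plateau": 1.4, "PercentFast": 100.0, "KFast": 0.8,
              "KSlow": 0.05}
    x = np.linspace(0.0, 20.0, 200)
    biphasic = evaluate("two_phase_association", params, x)
    mono = params["Y0"] + (params["Plateau"] - params["Y0"]) * (
        1.0 - np.exp(-params["KFast"] * x))
    assert np.allclose(biphasic, mono, atol=1e-9)


def test_total_binding_reduces_to_specific_binding():
    x = np.linspace(0.0, 100.0, 50)
    total = evaluate("one_site_total",
                     {"Bmax": 2.0, "Kd": 15.0, "NS": 0.0, "Background": 0.0}, x)
    specific = evaluate("one_site_specific", {"Bmax": 2.0, "Kd": 15.0}, x)
    assert np.allclose(total, specific, atol=1e-12)


@pytest.mark.parametrize("hill, increasing", [(2.4, True), (-2.4, False)])
def test_fourpl_monotonicity_follows_slope_sign(hill, increasing):
    x = np.linspace(-4.0, 2.0, 200)
    y = evaluate("fourpl_inhibition",
                 {"Bottom": 40.0, "Top": 240.0, "LogIC50": -0.6, "HillSlope": hill}, x)
    diffs = np.diff(y)
    assert np.all(diffs > 0) if increasing else np.all(diffs < 0)


def test_fit_independent_of_replicate_order():
    ledger, x = default_trace_ledgers(3)["one_phase_decay"]
    trace = simulate_trace(ledger, x)
    forward = fit("one_phase_decay", trace)
    # interleave two copies in scrambled replicate order
    xx = np.concatenate([trace.x, trace.x])
    yy = np.concatenate([trace.y, trace.y])
    rep = np.concatenate([np.zeros(len(x), int), np.ones(len(x), int)])
    order = np.concatenate([np.arange(len(x), 2 * len(x)), np.arange(len(x))])
    scrambled = KineticTrace(xx[order], yy[order], rep[order])
    backward = fit("one_phase_decay", scrambled)
    assert backward.params["K"] == pytest.approx(forward.params["K"], rel=1e-9)


def test_fit_window_restricts_the_data():
    ledger, x = default_trace_ledgers(4)["one_phase_decay"]
    trace = simulate_trace(ledger, x)
    windowed = fit("one_phase_decay", trace, x_window=(0.0, 3.0))
    mask = trace.x <= 3.0
    manual = fit("one_phase_decay", KineticTrace(trace.x[mask], trace.y[mask]))
    assert windowed.params == pytest.approx(manual.params)
    assert windowed.n_points == int(mask.sum())


def test_fit_needs_enough_points():
    with pytest.raises(FitError, match="need >="):
        fit("one_phase_decay", KineticTrace([0.0, 1.0, 2.0], [3.0, 2.0, 1.0]))


def test_trace_csv_round_trip(tmp_path):
    trace = KineticTrace([0.0, 1.0, 2.0], [5.0, 3.0, 2.0], x_units="min",
                         y_units="mP")
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    again = KineticTrace.from_csv(path)
    assert np.array_equal(again.x, trace.x)
    assert np.array_equal(again.y, trace.y)
    assert again.x_units == "min" and again.y_units == "mP"


def test_trace_requires_monotone_x_within_replicate():
    with pytest.raises(ValueError, match="strictly increasing"):
        KineticTrace([0.0, 2.0, 1.0], [1.0, 2.0, 3.0])


class TestHalfLife:
    def test_ln2_rate_gives_unit_half_life(self):
        assert half_life_from_rate(math.log(2.0))["half_life"] == pytest.approx(1.0)

    def test_published_off_rate_half_life(self):
        # ln 2 / 0.74 computed independently: 0.93668537913...
        out = half_life_from_rate(0.74, (0.68, 0.9))
        assert out["half_life"] == pytest.approx(0.9366853791350612, abs=1e-12)
        lo, hi = out["half_life_ci95"]
        assert lo == pytest.approx(math.log(2.0) / 0.9, abs=1e-12)
        assert hi == pytest.approx(math.log(2.0) / 0.68, abs=1e-12)

    def test_nonpositive_rate_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            half_life_from_rate(0.0)

    def test_half_life_from_fit_result(self):
        ledger, x = default_trace_ledgers(5)["one_phase_decay"]
        trace = simulate_trace(TraceLedger("one_phase_decay", ledger.true_params,
                                           0.0, 0), x)
        res = fit("one_phase_decay", trace)
        assert half_life(res)["half_life"] == pytest.approx(math.log(2.0) / 0.74,
                                                            rel=1e-6)
        with pytest.raises(ValueError, match="rate"):
            half_life(FitResult("agonist_response", {}, {}, {}, 1.0,
                                np.zeros(1), 1, True))


class TestPercentFastDoseResponse:
    CONCS = [0.0, 0.25, 0.5, 1.0, 1.5, 2.5, 4.0, 8.0, 16.0, 32.0]

    def test_noiseless_ec50_recovery(self):
        truth = {"Bottom": 50.0, "Top": 75.0, "EC50": 1.8}
        pf = evaluate("agonist_response", truth, np.array(self.CONCS))
        res = percent_fast_dose_response(self.CONCS, list(pf))
        for name, val in truth.items():
            assert res.params[name] == pytest.approx(val, rel=1e-6)

    def test_noisy_ec50_recovery(self):
        """With 2-percentage-point noise (averaged over the assay's
        triplicates) the EC50 estimate is typically within 30% and unbiased:
        at this noise level the EC50's own sampling spread is ~30%, so the
        median error and the mean estimate are the meaningful checks."""
        truth = {"Bottom": 50.0, "Top": 75.0, "EC50": 1.8}
        base = evaluate("agonist_response", truth, np.array(self.CONCS))
        rng = np.random.default_rng(11)
        errors, estimates = [], []
        for _ in range(100):
            noise = rng.normal(0.0, 2.0, size=(3, len(base))).mean(axis=0)
            pf = np.clip(base + noise, 0.0, 100.0)
            res = percent_fast_dose_response(self.CONCS, list(pf))
            estimates.append(res.params["EC50"])
            errors.append(abs(res.params["EC50"] - 1.8) / 1.8)
        assert np.median(errors) < 0.30
        assert abs(np.mean(estimates) - 1.8) / 1.8 < 0.10

    def test_degenerate_constant_input_flagged(self):
        res = percent_fast_dose_response(self.CONCS, [60.0] * len(self.CONCS))
        assert not res.success
        assert "degenerate_constant_y" in res.flags

    def test_validates_inputs(self):
        with pytest.raises(FitError, match=">= 4"):
            percent_fast_dose_response([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="outside"):
            percent_fast_dose_response(self.CONCS, [150.0] * len(self.CONCS))
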