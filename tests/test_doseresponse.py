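"""Hill model, fitting, and group comparison statistics."""

import numpy as np
import pandas as pd
import pytest

from asictox.doseresponse import (
    HillCurveModel,
    HillParams,
    compare_params,
    dunnett_pvalues,
    fit_hill,
    hill_predict,
    normalize_currents,
    significance_tier,
)
from asictox.synthetic import DoseResponseSpec, generate_dose_response

GRID = np.logspace(1, 4, 10)  # 10 nM .. 10 uM


# ---------------------------------------------------------------------------
# prediction and normalization
# ---------------------------------------------------------------------------


def test_hill_midpoint_and_asymptote_identities():
    p = HillParams(ic50_nm=200.0, bottom=0.2, nh=1.7)
    assert hill_predict(p, 200.0) == pytest.approx(0.2 + 0.8 / 2)
    assert hill_predict(p, 0.0) == 1.0
    assert hill_predict(p, 1e-6) == pytest.approx(1.0, abs=1e-6)
    assert hill_predict(p, 1e12) == pytest.approx(p.bottom, abs=1e-6)


def test_hill_tenfold_above_ic50_with_unit_slope():
    p = HillParams(ic50_nm=100.0, bottom=0.0, nh=1.0)
    assert hill_predict(p, 1000.0) == pytest.approx(1.0 / 11.0)


def test_hill_curve_is_monotone_decreasing():
    p = HillParams(ic50_nm=300.0, bottom=0.1, nh=2.3)
    y = hill_predict(p, np.logspace(-1, 6, 200))
    assert np.all(np.diff(y) < 0)


def test_normalization_is_signed_amplitude_ratio():
    assert normalize_currents([-2.0], -4.0)[0] == pytest.approx(0.5)
    assert normalize_currents([-4.0], -4.0)[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        normalize_currents([-2.0], 0.0)


def test_params_validation():
    with pytest.raises(ValueError):
        HillParams(-1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        HillParams(100.0, 1.5, 1.0)
    with pytest.raises(ValueError):
        HillParams(100.0, 0.0, -1.0)
    assert HillParams(100.0, 0.0, 1.0).logic50 == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ic50", [50.0, 220.0, 1000.0])
@pytest.mark.parametrize("bottom", [0.0, 0.2, 0.4])
@pytest.mark.parametrize("nh", [1.0, 2.0, 3.0])
def test_noiseless_round_trip_recovers_parameters(ic50, bottom, nh):
    theta = HillParams(ic50, bottom, nh)
    res = HillCurveModel(GRID, hill_predict(theta, GRID)).fit()
    assert res.converged
    assert res.params.ic50_nm == pytest.approx(ic50, rel=1e-4)
    assert res.params.bottom == pytest.approx(bottom, abs=1e-4)
    assert res.params.nh == pytest.approx(nh, rel=1e-3)


def test_flat_curve_is_flagged_degenerate():
    res = HillCurveModel(GRID, np.ones_like(GRID)).fit()
    assert res.degenerate and not res.converged


def test_too_few_nonzero_concentrations_rejected():
    with pytest.raises(ValueError, match="four distinct"):
        HillCurveModel([0.0, 10.0, 100.0, 1000.0], [1.0, 0.9, 0.5, 0.1])


def test_zero_concentration_points_are_excluded_from_fit():
    theta = HillParams(150.0, 0.1, 1.5)
    conc = np.concatenate([[0.0], GRID])
    y = hill_predict(theta, conc)
    y[0] = 0.7  # corrupt the control point; the fit must not care
    res = HillCurveModel(conc, y).fit()
    assert res.params.ic50_nm == pytest.approx(150.0, rel=1e-4)


def test_fit_replicates_summary_reports_mean_and_sem():
    theta = HillParams(200.0, 0.1, 2.0)
    data = generate_dose_response(
        DoseResponseSpec(theta, n_replicates=5, noise_sd=0.03, seed=2))
    fits = fit_hill(data)
    assert len(fits.results) == 5
    summary = fits.summary()
    assert set(summary.index) == {"ic50_nm", "logic50", "bottom", "nh"}
    assert summary.loc["ic50_nm", "mean"] == pytest.approx(200.0, rel=0.25)
    assert summary.loc["ic50_nm", "n"] == 5
    assert summary.loc["bottom", "sem"] >= 0


def test_standard_errors_positive_on_noisy_fits():
    theta = HillParams(150.0, 0.2, 1.5)
    rng = np.random.default_rng(4)
    y = hill_predict(theta, GRID) + rng.normal(0, 0.03, len(GRID))
    res = HillCurveModel(GRID, np.clip(y, 0, 1.2)).fit()
    assert res.converged
    assert res.bse["logic50"] > 0
    assert "IC50" in res.summary()


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------


def _param_frame(rng, n, logic50=2.1, bottom=0.1, nh=1.6, shift=0.0):
    return pd.DataFrame({
        "logic50": rng.normal(logic50 + shift, 0.05, n),
        "bottom": rng.normal(bottom, 0.03, n).clip(0, 1),
        "nh": rng.normal(nh, 0.2, n),
    })


def test_identical_groups_are_not_significant():
    rng = np.random.default_rng(0)
    base = _param_frame(rng, 6)
    groups = {"WT": base, "M1": base.copy(), "M2": base.copy()}
    result = compare_params(groups, reference="WT", seed=1)
    assert (result.comparisons["tier"] == "n.s.").all()
    assert (result.comparisons["adj_p"] > 0.9).all()


def test_planted_logic50_shift_is_detected():
    rng = np.random.default_rng(1)
    groups = {
        "WT": _param_frame(rng, 5),
        "MUT": _param_frame(rng, 5, shift=0.3),  # ~0.3 log-unit shift, sd 0.05
    }
    result = compare_params(groups, reference="WT", seed=2)
    row = result.comparisons.query("parameter == 'logic50'").iloc[0]
    assert row["adj_p"] < 0.05
    assert row["tier"] != "n.s."


def test_dunnett_adjusted_p_between_raw_and_bonferroni():
    rng = np.random.default_rng(3)
    for _ in range(50):
        k = int(rng.integers(2, 5))
        groups = {"WT": rng.normal(0, 1, int(rng.integers(4, 8)))}
        for i in range(k):
            groups[f"G{i}"] = rng.normal(0, 1, int(rng.integers(4, 8)))
        out = dunnett_pvalues(groups, "WT", seed=9)
        assert (out["adj_p"] >= out["raw_p"] - 1e-12).all()
        assert (out["adj_p"] <= np.minimum(k * out["raw_p"], 1.0) + 1e-12).all()


def test_dunnett_matches_scipy_reference():
    from scipy.stats import dunnett as scipy_dunnett

    rng = np.random.default_rng(7)
    groups = {"WT": rng.normal(0, 1, 6), "A": rng.normal(0.8, 1, 5),
              "B": rng.normal(0, 1, 6), "C": rng.normal(2.0, 1, 5)}
    mine = dunnett_pvalues(groups, "WT", seed=3, n_draws=200_000)
    ref = scipy_dunnett(groups["A"], groups["B"], groups["C"],
                        control=groups["WT"], random_state=1)
    assert mine["adj_p"].to_numpy() == pytest.approx(ref.pvalue, abs=0.01)


def test_comparison_requires_reference_and_minimum_replicates():
    rng = np.random.default_rng(0)
    with pytest.raises(KeyError):
        dunnett_pvalues({"A": rng.normal(0, 1, 5),
                         "B": rng.normal(0, 1, 5)}, "WT")
    with pytest.raises(ValueError, match="three replicates"):
        dunnett_pvalues({"WT": np.array([0.0, 1.0]),
                         "A": rng.normal(0, 1, 5)}, "WT")


def test_significance_tiers_follow_conventional_cutpoints():
    assert significance_tier(0.2) == "n.s."
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.003) == "**"
    assert significance_tier(0.0003) == "***"
    assert significance_tier(0.00003) == "****"
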