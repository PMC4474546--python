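import copy
import math

import numpy as np
import pytest

from rdmlkit import generate_document, read_rdml, semantic_equal, write_rdml_bytes
from rdmlkit.efficiency import (
    StandardPoint,
    annotate_target,
    efficiency_from_per_curve,
    fit_standard_curve,
    standard_points_from_document,
)
from rdmlkit.model import (
    ElementWrongVersionError,
    InsufficientDataError,
    Quantity,
    UnitMismatchError,
)
from rdmlkit.synth import SyntheticRunSpec, SyntheticTarget


def _ols_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS slope for each row of y (independent oracle)."""
    xc = x - x.mean()
    return (y - y.mean(axis=-1, keepdims=True)) @ xc / (xc @ xc)


def test_exact_doubling_worked_example():
    """A dilution series losing exactly one cycle per 2-fold (3.32193 per
    10-fold) has slope -1/log10(2) and efficiency 2."""
    points = [StandardPoint(0, 30.0), StandardPoint(-1, 33.32193),
              StandardPoint(-2, 36.64386)]
    fit = fit_standard_curve(points)
    assert fit.slope == pytest.approx(-3.32193, abs=1e-5)
    assert fit.efficiency == pytest.approx(2.000, abs=1e-4)
    assert fit.rSquared == pytest.approx(1.0, abs=1e-9)
    assert fit.nPoints == 3 and fit.method == "standard-curve"


@pytest.mark.parametrize("n_points", [2, 1, 0])
def test_too_few_points(n_points):
    with pytest.raises(InsufficientDataError):
        fit_standard_curve([StandardPoint(-i, 30.0 + i)
                            for i in range(n_points)])


def test_degenerate_x_spread():
    with pytest.raises(InsufficientDataError):
        fit_standard_curve([StandardPoint(0, 30), StandardPoint(0, 31),
                            StandardPoint(0, 30.5)])


def test_non_negative_slope_warns_but_returns():
    points = [StandardPoint(0, 30), StandardPoint(-1, 29),
              StandardPoint(-2, 28)]
    with pytest.warns(UserWarning, match="non-negative"):
        fit = fit_standard_curve(points)
    assert fit.efficiency < 1.0


@pytest.mark.parametrize("true_e", [1.80, 1.90, 2.00])
def test_exact_recovery_on_noise_free_series(true_e):
    """Noise-free synthetic dilution series recover the true efficiency to
    1e-9 relative, document route included."""
    doc = generate_document(SyntheticRunSpec(
        noiseSd=0.0, cqNoiseSd=0.0, includeMelt=False,
        targets=[SyntheticTarget(trueEfficiency=true_e)]))
    points = standard_points_from_document(doc, "tgt1")
    fit = fit_standard_curve(points)
    assert abs(fit.efficiency - true_e) / true_e < 1e-9


def test_scale_invariance_of_efficiency():
    rng = np.random.default_rng(0)
    x = np.repeat([5.0, 4.0, 3.0, 2.0, 1.0], 2)
    y = 38 - 3.3 * x + rng.normal(0, 0.1, x.size)
    base = fit_standard_curve([StandardPoint(a, b) for a, b in zip(x, y)])
    shifted = fit_standard_curve(
        [StandardPoint(a + 3.0, b) for a, b in zip(x, y)])
    assert shifted.efficiency == pytest.approx(base.efficiency, rel=1e-12)
    assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
    assert shifted.intercept != pytest.approx(base.intercept, rel=1e-6)


def test_estimator_consistency_with_more_standards():
    """Mean |E_hat - E*| shrinks as the dilution series grows 5 -> 10 -> 20
    points (200 replicates each, Cq noise SD 0.1)."""
    true_e = 1.9
    slope = -1.0 / math.log10(true_e)
    rng = np.random.default_rng(1234)
    mean_abs_err = []
    for replicates in (1, 2, 4):  # 5 levels x r replicates
        x = np.tile(np.array([5.0, 4.0, 3.0, 2.0, 1.0]), replicates)
        noise = rng.normal(0, 0.1, size=(200, x.size))
        y = 38.0 + slope * x + noise
        slopes = _ols_slopes(x, y)
        e_hat = 10.0 ** (-1.0 / slopes)
        mean_abs_err.append(np.abs(e_hat - true_e).mean())
    assert mean_abs_err[0] > mean_abs_err[1] > mean_abs_err[2]


def test_delta_method_se_matches_bootstrap_oracle():
    """First-order propagation of the slope SE agrees with a 10,000-replicate
    parametric bootstrap within 20% at Cq noise SD 0.1."""
    true_e, sd = 1.90, 0.1
    slope = -1.0 / math.log10(true_e)
    x = np.repeat([5.0, 4.0, 3.0, 2.0, 1.0], 4)  # 20 points
    rng = np.random.default_rng(99)
    y = 38.0 + slope * x + rng.normal(0, sd, x.size)
    fit = fit_standard_curve(
        [StandardPoint(a, b) for a, b in zip(x, y)])
    boot = rng.normal(0, sd, size=(10_000, x.size))
    slopes = _ols_slopes(x, 38.0 + slope * x + boot)
    boot_se = float(np.std(10.0 ** (-1.0 / slopes), ddof=1))
    assert abs(fit.efficiencySE - boot_se) / boot_se < 0.20


# ---------------------------------------------------------------------------
# per-curve SEM route

def test_per_curve_mean_and_sem():
    fit = efficiency_from_per_curve([1.9, 2.0, 2.1])
    assert fit.efficiency == pytest.approx(2.0)
    assert fit.efficiencySE == pytest.approx(0.1 / math.sqrt(3), abs=1e-9)
    assert fit.method == "per-curve-sem" and fit.slope is None


def test_per_curve_identical_values():
    fit = efficiency_from_per_curve([2.0, 2.0])
    assert fit.efficiency == 2.0 and fit.efficiencySE == 0.0


def test_per_curve_single_value_rejected():
    with pytest.raises(InsufficientDataError):
        efficiency_from_per_curve([2.0])


# ---------------------------------------------------------------------------
# document bridge

def test_standard_points_counts(doc12):
    # 5 dilution steps x 2 replicates
    assert len(standard_points_from_document(doc12, "tgt1")) == 10


def test_mixed_units_rejected(clean12):
    clean12.samples[0].quantity = Quantity(value=100.0, unit="ng")
    with pytest.raises(UnitMismatchError):
        standard_points_from_document(clean12, "tgt1")


def test_standard_without_cq_excluded_with_warning(clean12):
    react = clean12.experiments[0].runs[0].reactions[0]
    react.data[0].cq = None
    with pytest.warns(UserWarning, match="no Cq"):
        points = standard_points_from_document(clean12, "tgt1")
    assert len(points) == 9


def test_annotate_target_1_2_round_trip(doc12):
    fit = fit_standard_curve(standard_points_from_document(doc12, "tgt1"))
    out = annotate_target(doc12, "tgt1", fit)
    target = out.target("tgt1")
    assert target.amplificationEfficiency == pytest.approx(fit.efficiency)
    assert target.amplificationEfficiencySE == pytest.approx(
        fit.efficiencySE)
    back, _ = read_rdml(write_rdml_bytes(out))
    assert semantic_equal(out, back)
    # only the target changed
    stripped = copy.deepcopy(out)
    stripped.target("tgt1").amplificationEfficiency = None
    stripped.target("tgt1").amplificationEfficiencySE = None
    assert semantic_equal(stripped, doc12)


def test_annotate_target_version_gate(doc11):
    fit = fit_standard_curve(standard_points_from_document(doc11, "tgt1"))
    assert fit.efficiencySE is not None
    with pytest.raises(ElementWrongVersionError):
        annotate_target(doc11, "tgt1", fit)
    out = annotate_target(doc11, "tgt1", fit, include_se=False)
    assert out.target("tgt1").amplificationEfficiencySE is None
    assert out.target("tgt1").amplificationEfficiency == pytest.approx(
        fit.efficiency)
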