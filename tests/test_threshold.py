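import numpy as np
import pytest
from scipy import integrate

from clonedist import (
    Component,
    DegenerateModelError,
    MixtureModel,
    confusion_areas,
    find_threshold,
    sen_spc,
    threshold_report,
)


def make_model(lam1, comp1, comp2):
    return MixtureModel(
        lambda1=lam1, lambda2=1 - lam1, comp1=comp1, comp2=comp2,
        log_likelihood=0.0, n=0, converged=True, n_iter=0,
    )


@pytest.fixture
def gamma_gamma_model():
    return make_model(
        0.5, Component("gamma", (4.0, 0.01)), Component("gamma", (50.0, 0.005))
    )


def quadrature_areas(model, t, t1, t2):
    """Independent oracle: adaptive quadrature of the weighted densities."""
    f1 = lambda v: model.lambda1 * model.comp1.pdf(v)
    f2 = lambda v: model.lambda2 * model.comp2.pdf(v)
    return tuple(
        integrate.quad(f, lo, hi, limit=200)[0]
        for f, lo, hi in [(f1, t1, t), (f1, t, t2), (f2, t1, t), (f2, t, t2)]
    )


def test_areas_match_quadrature(gamma_gamma_model):
    t1, t, t2 = 0.001, 0.1, 0.5
    areas = confusion_areas(gamma_gamma_model, t, t1, t2)
    tp, fn, fp, tn = quadrature_areas(gamma_gamma_model, t, t1, t2)
    assert areas.tp == pytest.approx(tp, abs=1e-6)
    assert areas.fn == pytest.approx(fn, abs=1e-6)
    assert areas.fp == pytest.approx(fp, abs=1e-6)
    assert areas.tn == pytest.approx(tn, abs=1e-6)


def test_boundary_thresholds(gamma_gamma_model):
    t1, t2 = 0.001, 0.5
    at_t1 = confusion_areas(gamma_gamma_model, t1, t1, t2)
    assert at_t1.tp == 0 and at_t1.fp == 0
    at_t2 = confusion_areas(gamma_gamma_model, t2, t1, t2)
    assert at_t2.fn == 0 and at_t2.tn == 0
    sen, spc = sen_spc(at_t2)
    assert (sen, spc) == (1.0, 0.0)
    sen, spc = sen_spc(at_t1)
    assert (sen, spc) == (0.0, 1.0)


def test_threshold_outside_interval_rejected(gamma_gamma_model):
    with pytest.raises(ValueError):
        confusion_areas(gamma_gamma_model, 0.6, 0.001, 0.5)


def test_sen_spc_matches_quadrature_at_midpoint(gamma_gamma_model):
    t1, t2 = 0.001, 0.5
    t = (t1 + t2) / 2
    areas = confusion_areas(gamma_gamma_model, t, t1, t2)
    tp, fn, fp, tn = quadrature_areas(gamma_gamma_model, t, t1, t2)
    sen, spc = sen_spc(areas)
    assert sen == pytest.approx(tp / (tp + fn), abs=1e-6)
    assert spc == pytest.approx(tn / (tn + fp), abs=1e-6)


def test_degenerate_component_mass_raises():
    # comp2 far outside (t1, t2): specificity denominator has no mass
    model = make_model(
        0.5, Component("gaussian", (0.1, 0.02)), Component("gaussian", (50.0, 0.1))
    )
    areas = confusion_areas(model, 0.15, 0.0, 0.3)
    with pytest.raises(DegenerateModelError):
        sen_spc(areas)


def test_symmetric_gaussians_threshold_at_crossing():
    """Equal-weight equal-SD Gaussians: the objective peaks midway."""
    model = make_model(
        0.5, Component("gaussian", (0.10, 0.02)), Component("gaussian", (0.30, 0.02))
    )
    x = np.array([0.0, 0.4])  # fixes t1, t2 symmetrically around 0.2
    result = find_threshold(model, x, grid_size=1000)
    step = (0.4 - 0.0) / 1001
    assert abs(result.threshold - 0.20) <= step


def test_threshold_is_grid_argmax_and_curves_are_monotone(gamma_gamma_model):
    rng = np.random.default_rng(0)
    x = np.concatenate([
        rng.gamma(4.0, 0.01, 300), rng.gamma(50.0, 0.005, 300)
    ])
    result = find_threshold(gamma_gamma_model, x)
    objective = (result.sen_curve + result.spc_curve) / 2
    assert result.threshold == result.grid[int(np.nanargmax(objective))]
    assert result.objective >= np.nanmax(objective) - 1e-12
    assert result.t1 == x.min() and result.t2 == x.max()
    assert result.t1 < result.threshold < result.t2
    assert np.all(np.diff(result.sen_curve) >= -1e-12)
    assert np.all(np.diff(result.spc_curve) <= 1e-12)


def test_grid_refinement_stability(gamma_gamma_model):
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.gamma(4.0, 0.01, 200), rng.gamma(50.0, 0.005, 200)])
    coarse = find_threshold(gamma_gamma_model, x, grid_size=1000)
    fine = find_threshold(gamma_gamma_model, x, grid_size=10_000)
    assert abs(coarse.threshold - fine.threshold) <= (coarse.t2 - coarse.t1) / 1000


def test_tie_resolves_to_smaller_threshold():
    # with weight=1 the objective is SEN alone, which saturates at exactly
    # 1.0 over many grid points: the smallest tied t must be returned
    model = make_model(
        0.5, Component("gaussian", (0.05, 0.005)), Component("gaussian", (0.7, 0.05))
    )
    result = find_threshold(model, np.array([0.02, 0.9]), grid_size=1000, weight=1.0)
    tied = result.sen_curve == 1.0
    assert tied.sum() > 1  # a genuine tie, not a unique max
    assert result.threshold == result.grid[int(np.argmax(tied))]


def test_report_keys(gamma_gamma_model):
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.gamma(4.0, 0.01, 100), rng.gamma(50.0, 0.005, 100)])
    result = find_threshold(gamma_gamma_model, x)
    report = threshold_report(gamma_gamma_model, result)
    assert set(report) == {
        "t1", "t2", "threshold", "family1", "family2", "lambda1", "lambda2",
        "phi1", "phi2", "log_likelihood", "sensitivity", "specificity",
        "n_distances",
    }


def test_weighted_objective_shifts_threshold(gamma_gamma_model):
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.gamma(4.0, 0.01, 200), rng.gamma(50.0, 0.005, 200)])
    sen_heavy = find_threshold(gamma_gamma_model, x, weight=0.9)
    spc_heavy = find_threshold(gamma_gamma_model, x, weight=0.1)
    assert sen_heavy.threshold >= spc_heavy.threshold
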