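"""SCAD penalty primitives and penalized coordinate descent vs oracles."""

import numpy as np
import pytest

from medhaz import (
    ScadAdditiveHazardsCV,
    ScadConfig,
    cross_validate,
    penalized_fit,
    penalized_objective,
    scad_derivative,
    scad_penalty,
    screen,
    solve_statistics,
)
from medhaz.hazard import HazardStatistics, hazard_statistics
from medhaz.scad import _coefficient_path, default_lambda_grid, lambda_max

from conftest import random_survival


# --------------------------------------------------------------------------
# penalty primitives
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "babs,lam,a,expected",
    [
        (0.5, 1.0, 3.7, 1.0),              # first branch returns lambda
        (2.0, 1.0, 3.7, (3.7 - 2.0) / 2.7),  # middle branch
        (3.7, 1.0, 3.7, 0.0),              # flat branch
        (5.0, 1.0, 3.7, 0.0),
        (0.0, 0.3, 2.5, 0.3),
    ],
)
def test_scad_derivative_values(babs, lam, a, expected):
    assert scad_derivative(babs, lam, a) == pytest.approx(expected, abs=1e-12)


def test_scad_derivative_rejects_bad_parameters():
    with pytest.raises(ValueError):
        scad_derivative(1.0, 1.0, 2.0)
    with pytest.raises(ValueError):
        scad_derivative(1.0, 0.0, 3.7)
    with pytest.raises(ValueError):
        scad_derivative(-0.1, 1.0, 3.7)


def test_derivative_is_gradient_of_penalty():
    lam, a = 0.7, 3.7
    grid = np.linspace(1e-4, 4.0, 400)
    h = 1e-6
    numeric = (scad_penalty(grid + h, lam, a) - scad_penalty(grid - h, lam, a)) / (2 * h)
    assert scad_derivative(grid, lam, a) == pytest.approx(numeric, abs=1e-6)


def test_penalty_is_continuous_at_branch_boundaries():
    lam, a = 0.5, 3.7
    for edge in (lam, a * lam):
        lo = scad_penalty(edge - 1e-10, lam, a)
        hi = scad_penalty(edge + 1e-10, lam, a)
        assert lo == pytest.approx(hi, abs=1e-8)


# --------------------------------------------------------------------------
# coordinate descent vs oracles
# --------------------------------------------------------------------------

def _toy_stats():
    # frozen 3-variable problem: well-conditioned, mixed-sign score
    V = np.array([[1.0, 0.3, 0.1], [0.3, 0.8, 0.2], [0.1, 0.2, 1.2]])
    b = np.array([0.9, -0.15, 0.4])
    return HazardStatistics(b=b, V=V, D=np.eye(3), n=50)


def _grid_search_objective(stats, lam, a, lo=-3.0, hi=3.0):
    """Exhaustive coarse-to-fine grid minimisation of the SCAD objective."""
    mask = np.ones(3, dtype=bool)

    def refine(center, half, step):
        axes = [np.arange(c - half, c + half + step / 2, step) for c in center]
        best, best_val = None, np.inf
        for b0 in axes[0]:
            g1, g2 = np.meshgrid(axes[1], axes[2], indexing="ij")
            beta = np.stack([np.full_like(g1, b0), g1, g2], axis=-1)
            quad = 0.5 * np.einsum("...i,ij,...j->...", beta, stats.V, beta) - beta @ stats.b
            pen = scad_penalty(np.abs(beta), lam, a).sum(axis=-1)
            val = quad + pen
            idx = np.unravel_index(np.argmin(val), val.shape)
            if val[idx] < best_val:
                best_val = float(val[idx])
                best = np.array([b0, g1[idx], g2[idx]])
        return best, best_val

    center, _ = refine(np.zeros(3), (hi - lo) / 2, 0.02)
    best, best_val = refine(center, 0.03, 1e-3)
    return best, best_val


@pytest.mark.parametrize("lam", [0.05, 0.2, 0.6])
def test_exact_cd_matches_grid_search(lam):
    stats = _toy_stats()
    cfg = ScadConfig(solver="exact")
    beta, conv = penalized_fit(stats, np.ones(3, dtype=bool), lam, cfg)
    assert conv
    _, oracle_val = _grid_search_objective(stats, lam, cfg.a)
    cd_val = penalized_objective(stats, beta, np.ones(3, dtype=bool), lam, cfg)
    assert cd_val <= oracle_val + 1e-6


def test_vanishing_penalty_recovers_unpenalized_fit(rng):
    Q, t, status = random_survival(rng, n=40, m=3)
    stats = hazard_statistics(Q, t, status)
    free = solve_statistics(stats).estimates
    cfg = ScadConfig(solver="exact", tol=1e-10, max_iter=5000)
    beta, _ = penalized_fit(stats, np.ones(3, dtype=bool), 1e-12, cfg)
    assert beta == pytest.approx(free, abs=1e-6)


def test_large_lambda_zeroes_everything_identity_V(rng):
    b = rng.standard_normal(4)
    stats = HazardStatistics(b=b, V=np.eye(4), D=np.eye(4), n=20)
    lam = float(np.abs(b).max()) * 1.001
    for solver in ("exact", "stepwise"):
        cfg = ScadConfig(solver=solver)
        if solver == "exact":
            beta, _ = penalized_fit(stats, np.ones(4, dtype=bool), lam, cfg)
        else:
            lam_sw = lambda_max(stats, np.ones(4, dtype=bool), cfg) * 1.001
            path, _ = _coefficient_path(
                stats.V, stats.b, np.ones(4, dtype=bool), np.array([lam_sw]), cfg
            )
            beta = path[0]
        assert np.all(beta == 0)


def test_objective_never_increases_across_sweeps(rng):
    Q, t, status = random_survival(rng, n=50, m=5)
    stats = hazard_statistics(Q, t, status)
    mask = np.array([False, True, True, True, True])
    # debug mode asserts sweep-wise monotonicity internally
    penalized_fit(stats, mask, 0.05, ScadConfig(solver="exact"), debug=True)


def test_lasso_mode_is_soft_thresholding_on_identity_V():
    b = np.array([0.9, -0.4, 0.1])
    stats = HazardStatistics(b=b, V=np.eye(3), D=np.eye(3), n=10)
    lam = 0.25
    path, _ = _coefficient_path(
        stats.V, stats.b, np.ones(3, dtype=bool), np.array([lam]),
        ScadConfig(penalty_kind="lasso"),
    )
    expected = np.sign(b) * np.clip(np.abs(b) - lam, 0, None)
    assert path[0] == pytest.approx(expected, abs=1e-10)


def test_unpenalized_columns_stay_free(rng):
    Q, t, status = random_survival(rng, n=60, m=4)
    stats = hazard_statistics(Q, t, status)
    mask = np.array([False, False, True, True])
    beta, _ = penalized_fit(stats, mask, 10.0, ScadConfig(solver="exact"))
    assert np.all(beta[2:] == 0)
    # free block equals its own unpenalized fit once the rest is zeroed
    sub = np.linalg.solve(stats.V[:2, :2], stats.b[:2])
    assert beta[:2] == pytest.approx(sub, abs=1e-6)


def test_path_is_continuous_between_adjacent_lambdas(rng):
    Q, t, status = random_survival(rng, n=80, m=6)
    stats = hazard_statistics(Q, t, status)
    mask = np.ones(6, dtype=bool)
    cfg = ScadConfig()
    grid = default_lambda_grid(lambda_max(stats, mask, cfg), 30, 1e-2)
    path, conv = _coefficient_path(stats.V, stats.b, mask, grid, cfg)
    assert conv
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    assert steps.max() < 2.0  # no wild jumps along the warm-started path


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

def test_single_lambda_grid_shortcircuits(small_data):
    data, _ = small_data
    s1 = screen(data, d=10)
    cfg = ScadConfig(lambda_grid=np.array([0.05]))
    fit = cross_validate(data, s1, cfg, seed=3)
    assert fit.lambda_star == 0.05
    assert len(fit.cv_curve) == 1


def test_duplicated_cohort_selects_same_lambda(small_data):
    """Statistics are per-subject averages: doubling every subject (with
    folds that keep the two copies together) leaves lambda_star unchanged."""
    import dataclasses

    data, _ = small_data
    sub = data.subset(np.arange(120))
    dup = sub.subset(np.tile(np.arange(120), 2))
    s1 = screen(sub, d=8)
    s1d = dataclasses.replace(s1)  # same screened set applies to the duplicate
    rng = np.random.default_rng(0)
    order = rng.permutation(120)
    folds, folds_dup = [], []
    for f in range(4):
        te = order[f * 30 : (f + 1) * 30]
        tr = np.setdiff1d(order, te)
        folds.append((tr, te))
        folds_dup.append((np.concatenate([tr, tr + 120]), np.concatenate([te, te + 120])))
    cfg = ScadConfig(n_folds=4)
    fit = cross_validate(sub, s1, cfg, folds=folds)
    fit_dup = cross_validate(dup, s1d, cfg, folds=folds_dup)
    assert fit_dup.lambda_star == pytest.approx(fit.lambda_star, rel=1e-9)
    assert np.array_equal(fit.selected, fit_dup.selected)


def test_scad_selection_retains_true_mediators(small_scenario):
    """S2 keeps every mediator with alpha*beta != 0 in nearly all replicates."""
    from medhaz import generate

    hits = 0
    for rep in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([21, rep]))
        data, truth = generate(small_scenario, rng=rng)
        fit = cross_validate(data, screen(data), seed=rep)
        hits += np.isin(truth, fit.selected).all()
    assert hits >= 8


def test_cv_curve_minimum_is_lambda_star(small_data):
    data, _ = small_data
    fit = cross_validate(data, screen(data, d=12), seed=1)
    cur = fit.cv_curve
    assert fit.lambda_star == cur.loc[cur["cv_loss"].idxmin(), "lambda"]


def test_config_validation():
    with pytest.raises(ValueError):
        ScadConfig(a=1.5)
    with pytest.raises(ValueError):
        ScadConfig(lambda_grid=np.array([0.1, 0.2]))  # ascending
    with pytest.raises(ValueError):
        ScadConfig(solver="newton")


def test_sklearn_cv_estimator(rng):
    from sklearn.base import clone

    Q, t, status = random_survival(rng, n=100, m=8)
    est = ScadAdditiveHazardsCV(cv=4, n_lambdas=20).fit(
        Q, (t, status), penalize=np.ones(8, dtype=bool)
    )
    assert est.coef_.shape == (8,)
    assert {"lambda", "cv_loss", "n_selected"} <= set(est.cv_curve_.columns)
    clone(est)
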