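"""Group lasso: encoding, solver correctness against closed forms and the
unpenalized MLE, KKT conditions, path behaviour, and CV selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from glbn import CohortTable, VariableSpec, encode, fit_group_lasso, lambda_max
from glbn import grouplasso as gl
from glbn import simulate as sim
from glbn.estimators import GroupLasso, GroupLassoCV
from glbn.schema import SchemaError


def toy_logistic(seed=1, n=300, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = 0.3 + X @ np.linspace(0.8, -0.5, p)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def orthonormal_design(seed=0, n=60, J=5, pj=3):
    """Centered orthonormal columns so the group soft-threshold is exact."""
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, J * pj))
    M -= M.mean(axis=0)
    Q, _ = np.linalg.qr(M)
    X = Q[:, : J * pj]
    y = rng.normal(size=n)
    groups = np.repeat(np.arange(J), pj)
    return gl.GroupedDesign(
        X, y, groups, [f"g{j}" for j in range(J)], [f"c{k}" for k in range(J * pj)]
    )


# -- encoding ---------------------------------------------------------------

def test_encode_grouping_and_reference_levels():
    df = pd.DataFrame(
        {
            "relapse": ["yes", "no", "yes", "no"],
            "tri": ["a", "b", "c", "a"],
            "bin": ["u", "v", "u", "v"],
        }
    )
    specs = [
        VariableSpec("relapse", ("yes", "no"), 0, role="outcome"),
        VariableSpec("tri", ("a", "b", "c"), 1),
        VariableSpec("bin", ("u", "v"), 2),
    ]
    d = encode(CohortTable(df, specs))
    assert d.col_names == ["tri=b", "tri=c", "bin=v"]
    assert list(d.groups) == [0, 0, 1]
    assert d.group_names == ["tri", "bin"]
    assert list(d.y) == [1.0, 0.0, 1.0, 0.0]


def test_encode_rejects_constant_column_and_missing():
    df = pd.DataFrame({"relapse": ["yes", "no"], "c": ["a", "a"]})
    specs = [
        VariableSpec("relapse", ("yes", "no"), 0, role="outcome"),
        VariableSpec("c", ("a", "b"), 1),
    ]
    with pytest.raises(SchemaError, match="constant"):
        encode(CohortTable(df, specs))
    df2 = pd.DataFrame({"relapse": ["yes", "no"], "c": ["a", np.nan]})
    with pytest.raises(SchemaError, match="missing"):
        encode(CohortTable(df2, specs))


# -- solver -----------------------------------------------------------------

def test_zero_penalty_matches_unpenalized_mle():
    X, y = toy_logistic()
    d = gl.GroupedDesign(X, y, np.arange(3), ["a", "b", "c"], ["a", "b", "c"])
    fit = fit_group_lasso(d, 0.0, loss="logistic", tol=1e-10, max_sweeps=200_000)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
    assert np.abs(np.r_[fit.intercept, fit.coef] - ref).max() < 1e-6


@pytest.mark.parametrize("loss", ["squared", "logistic"])
def test_lambda_max_zeroes_all_groups(loss):
    X, y = toy_logistic(seed=3)
    d = gl.GroupedDesign(X, y, np.array([0, 0, 1]), ["g0", "g1"], ["a", "b", "c"])
    lmax = lambda_max(d, loss)
    fit = fit_group_lasso(d, lmax * 1.0001, loss=loss)
    assert np.all(fit.coef == 0.0)
    assert fit.selected_groups == []
    below = fit_group_lasso(d, lmax * 0.9, loss=loss)
    assert below.selected_groups  # just below the bound something activates


def test_orthonormal_group_soft_threshold_closed_form():
    d = orthonormal_design()
    lam = 0.002
    w = np.sqrt(3.0)
    n = d.y.size
    fit = fit_group_lasso(d, lam, loss="squared", tol=1e-12)
    ybar = d.y.mean()
    for j, sl in enumerate(d.group_slices):
        z = d.X[:, sl].T @ (d.y - ybar)
        thresh = max(0.0, 1.0 - n * lam * w / np.linalg.norm(z))
        assert np.allclose(fit.coef[sl], thresh * z, atol=1e-9)
    assert fit.intercept == pytest.approx(ybar, abs=1e-9)


def test_singleton_group_equals_scalar_soft_threshold():
    rng = np.random.default_rng(5)
    x = rng.normal(size=200)
    x = (x - x.mean()) / np.linalg.norm(x - x.mean())  # unit-norm centered
    y = rng.normal(size=200) + 0.5 * x
    d = gl.GroupedDesign(x[:, None], y, np.array([0]), ["g"], ["x"])
    lam = 1e-3
    fit = fit_group_lasso(d, lam, loss="squared", tol=1e-12, weights="none")
    z = float(x @ (y - y.mean()))
    expected = np.sign(z) * max(0.0, abs(z) - 200 * lam)  # x'x = 1
    assert fit.coef[0] == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("loss", ["squared", "logistic"])
def test_kkt_conditions_hold_at_convergence(loss):
    rng = np.random.default_rng(8)
    X = rng.normal(size=(250, 8))
    beta = np.array([1.0, -1.0, 0.5, 0, 0, 0, 0, 0])
    eta = X @ beta
    y = eta + rng.normal(size=250) if loss == "squared" else (
        rng.random(250) < 1 / (1 + np.exp(-eta))
    ).astype(float)
    d = gl.GroupedDesign(
        (X - X.mean(0)) / X.std(0), y, np.repeat(np.arange(4), 2),
        [f"g{j}" for j in range(4)], [f"c{k}" for k in range(8)],
        X.mean(0), X.std(0),
    )
    for lam in (0.0, 0.005, 0.05):
        fit = fit_group_lasso(d, lam, loss=loss, tol=1e-10)
        assert gl.kkt_violation(d, fit) < 1e-6


def test_objective_decreases_with_more_sweeps():
    X, y = toy_logistic(seed=4, n=200, p=6)
    slices = [slice(0, 3), slice(3, 6)]
    w = np.sqrt([3.0, 3.0])
    lam = 0.01
    objs = []
    for budget in (1, 2, 3, 5, 8, 15, 30):
        b0, coef, _, _ = gl._solve(
            X, y, slices, lam, w, "logistic", 0.0, budget, 0.0, np.zeros(6)
        )
        objs.append(gl._objective(X, y, slices, b0, coef, lam, w, "logistic"))
    assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))


def test_nonconvergence_raises_with_last_iterate():
    X, y = toy_logistic(seed=2)
    d = gl.GroupedDesign(X, y, np.arange(3), ["a", "b", "c"], ["a", "b", "c"])
    with pytest.raises(gl.ConvergenceError) as exc:
        fit_group_lasso(d, 1e-6, loss="logistic", tol=1e-14, max_sweeps=2)
    assert hasattr(exc.value, "coef")


def test_selected_group_count_monotone_on_orthonormal_design():
    d = orthonormal_design(seed=2)
    lambdas = gl.default_lambda_grid(d, "squared", n_lambdas=40)
    ints, coefs = gl._solve_path(
        d.X, d.y, d.group_slices, lambdas, np.sqrt([3.0] * 5), "squared", 1e-10, 50_000
    )
    counts = [
        sum(np.linalg.norm(c[sl]) > 0 for sl in d.group_slices) for c in coefs
    ]
    assert all(a <= b for a, b in zip(counts, counts[1:]))


# -- CV selection -------------------------------------------------------------

def test_stratified_folds_balance_and_errors():
    y = np.r_[np.ones(30), np.zeros(70)]
    folds = gl.stratified_folds(y, 10, seed=0)
    for f in range(10):
        assert y[folds == f].sum() == 3
    with pytest.raises(ValueError):
        gl.stratified_folds(y, 101, seed=0)


def test_pure_noise_design_prunes_almost_everything():
    pruned = 0
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 12))
        y = (rng.random(300) < 0.35).astype(float)
        d = gl.GroupedDesign(
            (X - X.mean(0)) / X.std(0), y, np.repeat(np.arange(6), 2),
            [f"g{j}" for j in range(6)], [f"c{k}" for k in range(12)],
        )
        path = gl.cv_select_lambda(d, k=5, seed=seed, loss="logistic", n_lambdas=40)
        pruned += len(gl.selected_variables(path)) <= 1
    assert pruned >= 2


def test_recovery_of_planted_groups_small():
    hits = 0
    for seed in (0, 1, 2):
        table, active = sim.generate_group_sparse_cohort(
            seed=seed, n=600, n_groups=6, n_levels=4, n_active=2, effect=1.2
        )
        d = encode(table)
        path = gl.cv_select_lambda(
            d, k=5, seed=seed, loss="logistic", n_lambdas=50, rule="1se"
        )
        hits += set(active) <= set(gl.selected_variables(path))
    assert hits == 3


def test_cv_selects_lambda_and_reports_path(small_cohort):
    table, _, _ = small_cohort
    work = table.copy()
    work.df = work.df.drop(columns=["participant_id"])
    d = encode(work)
    path = gl.cv_select_lambda(d, k=5, seed=0, n_lambdas=30)
    assert path.lambdas[0] == pytest.approx(lambda_max(d))
    assert path.cv_mean.shape == (30,)
    assert path.selected_lambda == path.lambdas[path.idx_min]
    assert path.idx_1se <= path.idx_min
    fit = path.fit_at()
    assert set(fit.selected_groups) == set(gl.selected_variables(path))


# -- sklearn estimator layer ---------------------------------------------------

def test_estimator_api_roundtrip():
    from sklearn.base import clone

    X, y = toy_logistic(seed=6, n=250, p=4)
    est = GroupLasso(lam=0.01, groups=[0, 0, 1, 1])
    est2 = clone(est)
    est2.fit(X, y)
    proba = est2.predict_proba(X)
    assert proba.shape == (250, 2)
    assert np.allclose(proba.sum(axis=1), 1.0)
    assert est2.get_params()["lam"] == 0.01
    assert len(est2.coef_) == 4


def test_cv_estimator_exposes_path():
    table, active = sim.generate_group_sparse_cohort(
        seed=3, n=500, n_groups=5, n_levels=3, n_active=1, effect=1.5
    )
    d = encode(table)
    est = GroupLassoCV(cv=5, n_lambdas=30, seed=0, rule="1se",
                       groups=d.groups, standardize=False)
    est.fit(d.X, d.y)
    assert est.lambda_ in est.lambdas_
    assert est.cv_errors_.shape == (30,)
    sel = {d.group_names[int(g)] for g in est.selected_groups_}
    assert active[0] in sel
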