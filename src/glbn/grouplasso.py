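"""Group-lasso estimation with a penalty path and cross-validated selection.

The estimator minimises, over coefficient blocks ``beta_j`` (one block per
categorical variable, dummy-coded against its first level) and an unpenalised
intercept ``b0``::

    sum_i loss(y_i, b0 + sum_j x_ij' beta_j)  +  n * lam * sum_j w_j ||beta_j||_2

with squared-error loss, or the logistic negative log-likelihood when the
outcome is binary (the pipeline default: relapse yes/no).  The Euclidean
penalty on whole blocks zeroes entire variables at once, which is the point:
selection happens at the variable level, not per dummy column.

Optimisation is blockwise proximal (majorise-minimise) coordinate descent:
each block is updated by a group soft-threshold of a gradient step whose step
size is the block's curvature bound (``eigmax(X_j'X_j)``, quartered for the
logistic loss).  Each block update can only decrease the objective, blocks hit
exact zeros, and the KKT conditions are checkable at convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .schema import CohortTable, SchemaError, VariableSpec

try:  # compiled inner loops; the numpy path below is the reference fallback
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


# ---------------------------------------------------------------------------
# Design encoding
# ---------------------------------------------------------------------------

@dataclass
class GroupedDesign:
    """Dummy-coded design with group structure and standardization record."""

    X: np.ndarray  # n x p, standardized unless scales is None
    y: np.ndarray  # n, binary {0,1} or numeric
    groups: np.ndarray  # p, group index 0..J-1 per column (contiguous blocks)
    group_names: list[str]
    col_names: list[str]
    centers: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.X.shape[1] != self.groups.size:
            raise SchemaError("groups must index every design column")
        if np.any(np.diff(self.groups) < 0):
            raise SchemaError("group indices must form contiguous blocks")

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def group_slices(self) -> list[slice]:
        out = []
        for j in range(self.n_groups):
            idx = np.flatnonzero(self.groups == j)
            out.append(slice(int(idx[0]), int(idx[-1]) + 1))
        return out


def encode(
    table: CohortTable,
    specs: list[VariableSpec] | None = None,
    outcome: str | None = None,
    standardize: bool = True,
) -> GroupedDesign:
    """Dummy-code a complete categorical table into a grouped design.

    The first level of each variable is the reference (omitted), so a
    variable with L levels contributes L-1 columns sharing one group.
    Columns are centred and scaled to unit variance before penalisation;
    a constant column (a level that never varies) is an error.
    """
    specs = list(specs) if specs is not None else list(table.specs)
    outcome = outcome or table.outcome
    df = table.df

    y_raw = df[outcome]
    if y_raw.isna().any():
        raise SchemaError("outcome column contains missing values")
    out_spec = next(s for s in specs if s.name == outcome)
    y = (y_raw.astype(str) == "yes").to_numpy(dtype=float) if set(
        out_spec.levels
    ) == {"yes", "no"} else y_raw.to_numpy(dtype=float)

    cols, names, groups, gnames = [], [], [], []
    j = 0
    for s in specs:
        if s.name == outcome or s.name not in df.columns:
            continue
        col = df[s.name]
        if col.isna().any():
            raise SchemaError(
                f"column {s.name!r} has missing values; impute before encoding"
            )
        vals = col.astype(str).to_numpy()
        for level in s.levels[1:]:
            d = (vals == level).astype(float)
            if d.std() == 0.0:
                raise SchemaError(
                    f"constant dummy column {s.name}={level}; "
                    "drop the variable or merge levels"
                )
            cols.append(d)
            names.append(f"{s.name}={level}")
            groups.append(j)
        gnames.append(s.name)
        j += 1
    if not cols:
        raise SchemaError("no covariates to encode")
    X = np.column_stack(cols)
    centers = scales = None
    if standardize:
        centers = X.mean(axis=0)
        scales = X.std(axis=0)
        X = (X - centers) / scales
    return GroupedDesign(X, y, np.array(groups), gnames, names, centers, scales)


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, intercept: float, coef: np.ndarray):
        super().__init__(msg)
        self.intercept = intercept
        self.coef = coef


def _group_weights(design: GroupedDesign, scheme: str) -> np.ndarray:
    sizes = np.array([np.sum(design.groups == j) for j in range(design.n_groups)])
    if scheme == "sqrt":
        return np.sqrt(sizes.astype(float))
    if scheme == "none":
        return np.ones(design.n_groups)
    raise ValueError("group_weights must be 'sqrt' or 'none'")


def lambda_max(design: GroupedDesign, loss: str = "logistic", weights: str = "sqrt") -> float:
    """Smallest penalty at which every group is zero (KKT bound at the
    intercept-only model)."""
    n = design.y.size
    w = _group_weights(design, weights)
    r0 = design.y - design.y.mean()
    vals = [
        np.linalg.norm(design.X[:, sl].T @ r0) / (n * w[j])
        for j, sl in enumerate(design.group_slices)
    ]
    return float(max(vals))


def default_lambda_grid(
    design: GroupedDesign,
    loss: str = "logistic",
    weights: str = "sqrt",
    n_lambdas: int = 100,
    ratio: float = 1e-4,
) -> np.ndarray:
    lmax = lambda_max(design, loss, weights)
    return np.geomspace(lmax, lmax * ratio, n_lambdas)


def _objective(
    X, y, groups_sl, intercept, coef, lam, w, loss
) -> float:
    eta = intercept + X @ coef
    if loss == "squared":
        smooth = 0.5 * float(np.sum((y - eta) ** 2))
    else:
        smooth = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    pen = sum(
        w[j] * float(np.linalg.norm(coef[sl])) for j, sl in enumerate(groups_sl)
    )
    return smooth + y.size * lam * pen


@_njit(cache=True)
def _nb_block_solve(ct, dvals, kappa, bout):
    """Exact minimiser of 0.5*(b'Gb - 2c'b)*alpha + nlamw*||b|| in the
    eigenbasis of G: ct = U'c, dvals = eigenvalues, kappa = nlamw/alpha.
    Writes U-basis coefficients into bout; returns ||b||."""
    k = ct.shape[0]
    cn2 = 0.0
    for m in range(k):
        cn2 += ct[m] * ct[m]
    cn = np.sqrt(cn2)
    if cn <= kappa:
        for m in range(k):
            bout[m] = 0.0
        return 0.0
    if kappa == 0.0:
        dmax = 0.0
        for m in range(k):
            if dvals[m] > dmax:
                dmax = dvals[m]
        t2 = 0.0
        for m in range(k):
            dm = dvals[m]
            if dm < 1e-12 * dmax:
                dm = 1e-12 * dmax
            bout[m] = ct[m] / dm
            t2 += bout[m] * bout[m]
        return np.sqrt(t2)
    # bisection on t = ||b||: g(t) = ||c~/(d + kappa/t)|| crosses t once
    dmin = dvals[0]
    for m in range(1, k):
        if dvals[m] < dmin:
            dmin = dvals[m]
    lo = 0.0
    hi = cn / dmin if dmin > 0 else cn / kappa * 1e12
    for _ in range(200):
        t = 0.5 * (lo + hi)
        g2 = 0.0
        for m in range(k):
            v = ct[m] / (dvals[m] + kappa / t)
            g2 += v * v
        if g2 > t * t:
            lo = t
        else:
            hi = t
        if hi - lo <= 1e-14 * (1.0 + hi):
            break
    t = 0.5 * (lo + hi)
    nrm2 = 0.0
    for m in range(k):
        bout[m] = ct[m] / (dvals[m] + kappa / t)
        nrm2 += bout[m] * bout[m]
    return np.sqrt(nrm2)


@_njit(cache=True)
def _nb_sweep(XF, y, eta, r, coef, b0, gs, ge, Upack, dpack, nlamw, logistic, active, work):
    """One pass over the blocks.

    For squared loss, r is the residual y - eta and each block update is the
    exact block minimiser.  For logistic loss, r is the surrogate residual
    4*(y - p) refreshed at sweep start (quadratic majorisation with curvature
    1/4), and block updates minimise the surrogate exactly.
    """
    n = y.shape[0]
    J = gs.shape[0]
    alpha = 0.25 if logistic else 1.0
    if logistic:
        for i in range(n):
            p = 1.0 / (1.0 + np.exp(-eta[i]))
            r[i] = 4.0 * (y[i] - p)
    # intercept: unpenalised least-squares step on the (surrogate) residual
    s = 0.0
    for i in range(n):
        s += r[i]
    d0 = s / n
    b0 += d0
    maxd = abs(d0)
    for i in range(n):
        eta[i] += d0
        r[i] -= d0
    for j in range(J):
        if not active[j]:
            continue
        a, b = gs[j], ge[j]
        k = b - a
        kappa = nlamw[j] / alpha
        # c = X_j' r + G_j b_j  (gradient-adjusted target in original basis)
        for m in range(k):
            g = 0.0
            for i in range(n):
                g += XF[i, a + m] * r[i]
            work[m] = g
        # add G_j b_j = U D U' b_j ; compute via eigenbasis below together
        # rotate: ct = U'(X_j'r) + D U'b_j
        for m in range(k):
            ub = 0.0
            uc = 0.0
            for q in range(k):
                ub += Upack[a + q, m] * coef[a + q]
                uc += Upack[a + q, m] * work[q]
            work[k + m] = uc + dpack[a + m] * ub
        ct = work[k : 2 * k]
        bt = work[2 * k : 3 * k]
        _nb_block_solve(ct, dpack[a:b], kappa, bt)
        # back to original basis and apply delta
        for m in range(k):
            new = 0.0
            for q in range(k):
                new += Upack[a + m, q] * bt[q]
            work[3 * k + m] = new
        changed = False
        for m in range(k):
            d = work[3 * k + m] - coef[a + m]
            ad = abs(d)
            if ad > maxd:
                maxd = ad
            if d != 0.0:
                changed = True
        if changed:
            for m in range(k):
                d = work[3 * k + m] - coef[a + m]
                if d != 0.0:
                    for i in range(n):
                        eta[i] += XF[i, a + m] * d
                        r[i] -= XF[i, a + m] * d
                coef[a + m] = work[3 * k + m]
    return b0, maxd


@_njit(cache=True)
def _nb_solve(XF, y, gs, ge, Upack, dpack, nlamw, logistic, tol, max_sweeps, b0, coef):
    n = y.shape[0]
    p = coef.shape[0]
    J = gs.shape[0]
    eta = np.empty(n)
    for i in range(n):
        s = b0
        for c in range(p):
            if coef[c] != 0.0:
                s += XF[i, c] * coef[c]
        eta[i] = s
    r = np.empty(n)
    if not logistic:
        for i in range(n):
            r[i] = y[i] - eta[i]
    maxk = 0
    for j in range(J):
        if ge[j] - gs[j] > maxk:
            maxk = ge[j] - gs[j]
    work = np.empty(4 * maxk)
    all_active = np.ones(J, np.bool_)
    active = np.empty(J, np.bool_)
    sweeps = 0
    while sweeps < max_sweeps:
        b0, d = _nb_sweep(XF, y, eta, r, coef, b0, gs, ge, Upack, dpack, nlamw, logistic, all_active, work)
        sweeps += 1
        if d < tol:
            return b0, sweeps, True
        while sweeps < max_sweeps:
            anyact = False
            for j in range(J):
                act = False
                for c in range(gs[j], ge[j]):
                    if coef[c] != 0.0:
                        act = True
                        break
                active[j] = act
                anyact = anyact or act
            if not anyact:
                break
            b0, d = _nb_sweep(XF, y, eta, r, coef, b0, gs, ge, Upack, dpack, nlamw, logistic, active, work)
            sweeps += 1
            if d < tol:
                break
    return b0, sweeps, False


def _precompute(X: np.ndarray, slices: list[slice], loss: str):
    """Per-design solver precomputation.

    With numba: Fortran-ordered X, block boundaries, and the eigendecomposition
    of each block Gram matrix X_j'X_j (exact block updates).  Without numba:
    the block curvature bounds for the majorise-minimise fallback.
    """
    if _HAVE_NUMBA:
        p = X.shape[1]
        maxk = max(sl.stop - sl.start for sl in slices)
        Upack = np.zeros((p, maxk))
        dpack = np.zeros(p)
        for sl in slices:
            Xg = X[:, sl]
            dvals, U = np.linalg.eigh(Xg.T @ Xg)
            k = sl.stop - sl.start
            Upack[sl, :k] = U
            dpack[sl] = np.maximum(dvals, 0.0)
        gs = np.array([sl.start for sl in slices], dtype=np.int64)
        ge = np.array([sl.stop for sl in slices], dtype=np.int64)
        return ("nb", np.asfortranarray(X), gs, ge, Upack, dpack)
    return ("py", _block_lipschitz_arrays(X, slices, loss))


def _block_lipschitz_arrays(X: np.ndarray, slices: list[slice], loss: str) -> np.ndarray:
    h = np.empty(len(slices))
    for j, sl in enumerate(slices):
        Xg = X[:, sl]
        h[j] = float(np.linalg.eigvalsh(Xg.T @ Xg).max())
    if loss == "logistic":
        h = 0.25 * h
    return np.maximum(h, 1e-12)


def _solve(
    X: np.ndarray,
    y: np.ndarray,
    slices: list[slice],
    lam: float,
    w: np.ndarray,
    loss: str,
    tol: float,
    max_sweeps: int,
    intercept: float,
    coef: np.ndarray,
    pre=None,
) -> tuple[float, np.ndarray, int, bool]:
    """Block coordinate descent from a warm start; returns the iterate, sweep
    count and convergence flag.  Squared loss: exact block updates.  Logistic
    loss: iteratively reweighted quadratic majorisation (curvature bound 1/4)
    with the same exact block update on the surrogate.  An active-set
    schedule converges on the nonzero blocks between full passes.

    Dispatches to a compiled kernel when numba is importable; the numpy
    majorise-minimise implementation below is the fallback."""
    if pre is None:
        pre = _precompute(X, slices, loss)
    if pre[0] == "nb":
        _, XF, gs, ge, Upack, dpack = pre
        nlamw = y.size * lam * np.asarray(w, dtype=float)
        b0, sweeps, converged = _nb_solve(
            XF,
            np.ascontiguousarray(y, dtype=float),
            gs,
            ge,
            Upack,
            dpack,
            nlamw,
            loss == "logistic",
            tol,
            max_sweeps,
            float(intercept),
            coef,
        )
        return float(b0), coef, int(sweeps), bool(converged)
    return _solve_py(X, y, slices, pre[1], lam, w, loss, tol, max_sweeps, intercept, coef)


def _solve_py(
    X: np.ndarray,
    y: np.ndarray,
    slices: list[slice],
    h: np.ndarray,
    lam: float,
    w: np.ndarray,
    loss: str,
    tol: float,
    max_sweeps: int,
    intercept: float,
    coef: np.ndarray,
) -> tuple[float, np.ndarray, int, bool]:
    n = y.size
    J = len(slices)
    nlam_w = n * lam * w
    eta = intercept + X @ coef

    def sweep(active: np.ndarray) -> float:
        nonlocal intercept, eta
        max_delta = 0.0
        if loss == "squared":
            r = y - eta
            d0 = float(r.mean())
            intercept += d0
            eta += d0
            r -= d0
            for j in np.flatnonzero(active):
                sl = slices[j]
                bj = coef[sl]
                grad = -(X[:, sl].T @ r)
                u = bj - grad / h[j]
                un = float(np.linalg.norm(u))
                scale = max(0.0, 1.0 - nlam_w[j] / (h[j] * un)) if un > 0 else 0.0
                new = scale * u
                delta = new - bj
                dmax = float(np.abs(delta).max()) if delta.size else 0.0
                if dmax > 0:
                    r -= X[:, sl] @ delta
                    eta += X[:, sl] @ delta
                    coef[sl] = new
                max_delta = max(max_delta, dmax, abs(d0))
        else:
            p = expit(eta)
            d0 = -float(np.sum(p - y)) / (0.25 * n)
            intercept += d0
            eta += d0
            p = expit(eta)
            max_delta = abs(d0)
            for j in np.flatnonzero(active):
                sl = slices[j]
                bj = coef[sl]
                grad = X[:, sl].T @ (p - y)
                u = bj - grad / h[j]
                un = float(np.linalg.norm(u))
                scale = max(0.0, 1.0 - nlam_w[j] / (h[j] * un)) if un > 0 else 0.0
                new = scale * u
                delta = new - bj
                dmax = float(np.abs(delta).max()) if delta.size else 0.0
                if dmax > 0:
                    eta += X[:, sl] @ delta
                    coef[sl] = new
                    p = expit(eta)
                max_delta = max(max_delta, dmax)
        return max_delta

    all_groups = np.ones(J, dtype=bool)
    sweeps = 0
    while sweeps < max_sweeps:
        # full pass (lets blocks enter the active set)
        delta = sweep(all_groups)
        sweeps += 1
        if delta < tol:
            return intercept, coef, sweeps, True
        # polish the active set
        while sweeps < max_sweeps:
            active = np.array([np.any(coef[sl] != 0.0) for sl in slices])
            if not active.any():
                break
            delta = sweep(active)
            sweeps += 1
            if delta < tol:
                break
    converged = sweeps < max_sweeps
    return intercept, coef, sweeps, converged


# ---------------------------------------------------------------------------
# Fit containers and spec-level operations
# ---------------------------------------------------------------------------

@dataclass
class GroupLassoFit:
    """A single fit: per-group coefficient blocks at one penalty value.

    ``coef_std`` lives on the standardized scale used during optimisation;
    ``coef`` and ``intercept`` are de-standardized to the original dummy
    (0/1) scale.  A group is *selected* iff its block norm is nonzero.
    """

    lam: float
    loss: str
    intercept: float
    coef: np.ndarray
    coef_std: np.ndarray
    intercept_std: float
    group_names: list[str]
    col_names: list[str]
    groups: np.ndarray
    n_sweeps: int
    converged: bool
    objective: float

    def group_norms(self) -> dict[str, float]:
        return {
            name: float(np.linalg.norm(self.coef_std[self.groups == j]))
            for j, name in enumerate(self.group_names)
        }

    @property
    def selected_groups(self) -> list[str]:
        return [g for g, nrm in self.group_norms().items() if nrm > 0.0]

    def coef_blocks(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for j, g in enumerate(self.group_names):
            idx = np.flatnonzero(self.groups == j)
            out[g] = {self.col_names[k]: float(self.coef[k]) for k in idx}
        return out


def _destandardize(design: GroupedDesign, intercept: float, coef: np.ndarray):
    if design.scales is None:
        return intercept, coef.copy()
    b = coef / design.scales
    b0 = intercept - float(np.sum(b * design.centers))
    return b0, b


def fit_group_lasso(
    design: GroupedDesign,
    lam: float,
    loss: str = "logistic",
    weights: str = "sqrt",
    tol: float = 1e-7,
    max_sweeps: int = 50_000,
    warm_start: tuple[float, np.ndarray] | None = None,
) -> GroupLassoFit:
    """Fit at a single penalty value (see module docstring for the model)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if loss not in ("squared", "logistic"):
        raise ValueError("loss must be 'squared' or 'logistic'")
    slices = design.group_slices
    w = _group_weights(design, weights)
    if warm_start is not None:
        b0, coef = float(warm_start[0]), np.array(warm_start[1], dtype=float)
    else:
        b0, coef = 0.0, np.zeros(design.X.shape[1])
    b0, coef, sweeps, converged = _solve(
        design.X, design.y, slices, lam, w, loss, tol, max_sweeps, b0, coef
    )
    if not converged:
        raise ConvergenceError(
            f"group lasso did not converge in {max_sweeps} sweeps (lam={lam:g})",
            b0,
            coef,
        )
    obj = _objective(design.X, design.y, slices, b0, coef, lam, w, loss)
    ob0, ocoef = _destandardize(design, b0, coef)
    return GroupLassoFit(
        lam=float(lam),
        loss=loss,
        intercept=ob0,
        coef=ocoef,
        coef_std=coef,
        intercept_std=b0,
        group_names=design.group_names,
        col_names=design.col_names,
        groups=design.groups,
        n_sweeps=sweeps,
        converged=converged,
        objective=obj,
    )


def _smooth_loss(X, y, intercept, coef, loss) -> float:
    eta = intercept + X @ coef
    if loss == "squared":
        return 0.5 * float(np.sum((y - eta) ** 2))
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def _solve_path(
    X, y, slices, lambdas, w, loss, tol, max_sweeps, pre=None
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started fits down a decreasing penalty grid (standardized scale).

    Following standard path-solver practice, the path is truncated once the
    model explains more than 99.9% of the null deviance (near-saturation, as
    happens under quasi-separation at tiny penalties); remaining grid points
    inherit the last solution.
    """
    if pre is None:
        pre = _precompute(X, slices, loss)
    p = X.shape[1]
    intercepts = np.zeros(len(lambdas))
    coefs = np.zeros((len(lambdas), p))
    if loss == "squared":
        null_loss = 0.5 * float(np.sum((y - y.mean()) ** 2))
    else:
        p0 = min(max(float(y.mean()), 1e-12), 1 - 1e-12)
        null_loss = -y.size * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
    b0, coef = 0.0, np.zeros(p)
    for i, lam in enumerate(lambdas):
        b0, coef, _, converged = _solve(
            X, y, slices, float(lam), w, loss, tol, max_sweeps, b0, np.array(coef), pre
        )
        dev_ratio = 1.0 - _smooth_loss(X, y, b0, coef, loss) / max(null_loss, 1e-300)
        if not converged and dev_ratio < 0.99:
            raise ConvergenceError(
                f"path fit did not converge at lam={lam:g}", b0, coef
            )
        intercepts[i] = b0
        coefs[i] = coef
        if dev_ratio > 0.999:
            intercepts[i:] = b0
            coefs[i:] = coef
            break
    return intercepts, coefs


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1 per row), stratified by the binary outcome."""
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _cv_error(y_true, eta, loss) -> np.ndarray:
    if loss == "squared":
        return (y_true - eta) ** 2
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return -2.0 * (y_true * np.log(p) + (1 - y_true) * np.log(1 - p))


@dataclass
class PenaltyPath:
    """Per-lambda fits on the full data plus k-fold CV errors and the
    selected penalty (minimum mean CV error by default)."""

    design: GroupedDesign
    lambdas: np.ndarray
    intercepts: np.ndarray  # standardized scale, one per lambda
    coefs: np.ndarray  # L x p, standardized scale
    cv_mean: np.ndarray
    cv_se: np.ndarray
    loss: str
    weights: str
    k: int
    seed: int
    rule: str = "min"

    @property
    def idx_min(self) -> int:
        return int(np.argmin(self.cv_mean))

    @property
    def idx_1se(self) -> int:
        thresh = self.cv_mean[self.idx_min] + self.cv_se[self.idx_min]
        ok = np.flatnonzero(self.cv_mean <= thresh)
        return int(ok[0])  # largest lambda within one SE (grid is decreasing)

    @property
    def selected_index(self) -> int:
        return self.idx_1se if self.rule == "1se" else self.idx_min

    @property
    def selected_lambda(self) -> float:
        return float(self.lambdas[self.selected_index])

    def fit_at(self, index: int | None = None) -> GroupLassoFit:
        i = self.selected_index if index is None else index
        d = self.design
        w = _group_weights(d, self.weights)
        obj = _objective(
            d.X, d.y, d.group_slices, self.intercepts[i], self.coefs[i],
            float(self.lambdas[i]), w, self.loss,
        )
        ob0, ocoef = _destandardize(d, float(self.intercepts[i]), self.coefs[i])
        return GroupLassoFit(
            lam=float(self.lambdas[i]),
            loss=self.loss,
            intercept=ob0,
            coef=ocoef,
            coef_std=self.coefs[i].copy(),
            intercept_std=float(self.intercepts[i]),
            group_names=d.group_names,
            col_names=d.col_names,
            groups=d.groups,
            n_sweeps=0,
            converged=True,
            objective=obj,
        )


def cv_select_lambda(
    design: GroupedDesign,
    lambdas: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    loss: str = "logistic",
    weights: str = "sqrt",
    tol: float = 1e-7,
    max_sweeps: int = 50_000,
    n_lambdas: int = 100,
    rule: str = "min",
) -> PenaltyPath:
    """Penalty path with stratified k-fold CV; the minimum mean CV error
    (deviance for the logistic loss) picks the working penalty."""
    if lambdas is None:
        lambdas = default_lambda_grid(design, loss, weights, n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be decreasing")
    slices = design.group_slices
    w = _group_weights(design, weights)
    folds = stratified_folds(design.y, k, seed)

    errors = np.full((k, len(lambdas)), np.nan)
    for f in range(k):
        tr = folds != f
        te = ~tr
        Xtr, ytr = design.X[tr], design.y[tr]
        ints, coefs = _solve_path(
            Xtr, ytr, slices, lambdas, w, loss, tol, max_sweeps
        )
        eta = ints[:, None] + coefs @ design.X[te].T  # L x n_test
        err = _cv_error(design.y[te][None, :], eta, loss)
        errors[f] = err.mean(axis=1)
    cv_mean = errors.mean(axis=0)
    cv_se = errors.std(axis=0, ddof=1) / np.sqrt(k)

    ints, coefs = _solve_path(
        design.X, design.y, slices, lambdas, w, loss, tol, max_sweeps
    )
    return PenaltyPath(
        design=design,
        lambdas=lambdas,
        intercepts=ints,
        coefs=coefs,
        cv_mean=cv_mean,
        cv_se=cv_se,
        loss=loss,
        weights=weights,
        k=k,
        seed=seed,
        rule=rule,
    )


def selected_variables(path: PenaltyPath) -> list[str]:
    """Names of the variable groups with nonzero blocks at the selected penalty."""
    coef = path.coefs[path.selected_index]
    d = path.design
    return [
        name
        for j, name in enumerate(d.group_names)
        if np.linalg.norm(coef[d.groups == j]) > 0.0
    ]


def kkt_violation(
    design: GroupedDesign, fit: GroupLassoFit, weights: str = "sqrt"
) -> float:
    """Maximum KKT residual of a fit (0 at an exact solution).

    Zero blocks: max(0, ||grad_j|| - n*lam*w_j); active blocks: the norm of
    the stationarity residual grad_j + n*lam*w_j * beta_j/||beta_j||.
    """
    d = design
    n = d.y.size
    w = _group_weights(d, weights)
    eta = fit.intercept_std + d.X @ fit.coef_std
    if fit.loss == "squared":
        g_all = -(d.X.T @ (d.y - eta))
        g0 = -float(np.sum(d.y - eta))
    else:
        p = expit(eta)
        g_all = d.X.T @ (p - d.y)
        g0 = float(np.sum(p - d.y))
    worst = abs(g0) / n
    for j, sl in enumerate(d.group_slices):
        bj = fit.coef_std[sl]
        gj = g_all[sl]
        t = n * fit.lam * w[j]
        if np.linalg.norm(bj) == 0.0:
            worst = max(worst, max(0.0, float(np.linalg.norm(gj)) - t) / n)
        else:
            resid = gj + t * bj / np.linalg.norm(bj)
            worst = max(worst, float(np.linalg.norm(resid)) / n)
    return worst
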