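"""Gaussian linear mixed models with nested random intercepts, parametric
bootstrap model comparison, and Bonferroni post-hoc contrasts.

The response is a per-neuron, per-condition mean of baseline-normalized
firing rate (a continuous quantity), modeled as

    NeuronalActivity ~ fixed effects + (1 | monkey) + (1 | monkey:neuron)

fitted by maximum likelihood (not REML: deviances must be comparable
across fixed-effect structures). Model comparison simulates ``n_boot``
datasets from the fitted null (fixed effects plus fresh random-intercept
and residual draws), refits both models per replicate, and locates the
observed deviance difference in the simulated null distribution, with
``p = (1 + #{boot >= observed}) / (n_boot + 1)``.

The fitter profiles the likelihood over the two variance ratios
``lambda_a = sigma_monkey^2 / sigma^2`` and ``lambda_b =
sigma_neuron^2 / sigma^2``; the marginal covariance is inverted
analytically with the Woodbury identity over the nested grouping, so each
evaluation is a handful of grouped sums. For balanced cell-mean tables
(every neuron contributes every condition cell exactly once, monkeys have
equal neuron counts) the likelihood depends on the data only through
three stratum sums of squares, which makes the large bootstrap
calibration runs tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

_LOG_2PI = float(np.log(2.0 * np.pi))
_Z_BOUNDS = (-15.0, 10.0)  # log variance-ratio box; exp(-15) is an effective zero


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design handling


def _design_matrix(table: pd.DataFrame, fixed: str) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix from a formula (patsy)."""
    import patsy

    if fixed.strip() == "1":
        return np.ones((len(table), 1)), ["Intercept"]
    dm = patsy.dmatrix(fixed, table, return_type="dataframe")
    return dm.to_numpy(dtype=float), list(dm.columns)


def _cellmeans_matrix(
    table: pd.DataFrame, factors: tuple[str, ...]
) -> tuple[np.ndarray, list[tuple], np.ndarray]:
    """One-hot cell-means design over the interaction of ``factors``.

    Returns (X, cell_keys, cell_codes); cells are ordered lexicographically.
    """
    keys = list(map(tuple, table[list(factors)].astype(str).itertuples(index=False)))
    uniq = sorted(set(keys))
    index = {c: j for j, c in enumerate(uniq)}
    codes = np.array([index[k] for k in keys], dtype=int)
    X = np.zeros((len(table), len(uniq)))
    X[np.arange(len(table)), codes] = 1.0
    return X, uniq, codes


class _NestedGrouping:
    """Row ordering and index structure for monkey > neuron nesting."""

    def __init__(self, monkey: np.ndarray, neuron: np.ndarray):
        m_codes = pd.factorize(np.asarray(monkey))[0]
        n_codes = pd.factorize(np.asarray(neuron))[0]
        self.order = np.lexsort((n_codes, m_codes))
        m_sorted = m_codes[self.order]
        n_sorted = n_codes[self.order]
        # neuron runs (neurons are nested: identity = monkey x neuron pair)
        key = pd.factorize(m_sorted.astype(np.int64) * (n_codes.max() + 1) + n_sorted)[0]
        change = np.nonzero(np.diff(key))[0] + 1
        self.neuron_starts = np.concatenate(([0], change))
        self.m_j = np.diff(np.concatenate((self.neuron_starts, [len(key)])))
        self.row_neuron = np.repeat(np.arange(len(self.m_j)), self.m_j)
        # monkey runs over neurons
        m_of_neuron = m_sorted[self.neuron_starts]
        mkey = pd.factorize(m_of_neuron)[0]
        mchange = np.nonzero(np.diff(mkey))[0] + 1
        self.monkey_neuron_starts = np.concatenate(([0], mchange))
        self.g_i = np.diff(np.concatenate((self.monkey_neuron_starts, [len(mkey)])))
        self.neuron_monkey = np.repeat(np.arange(len(self.g_i)), self.g_i)
        self.n = len(key)
        self.n_neurons = len(self.m_j)
        self.n_monkeys = len(self.g_i)

    def apply_w(self, v: np.ndarray, lam_a: float, lam_b: float):
        """(I + lam_b Zb Zb' + lam_a Za Za')^{-1} v via Woodbury; v is (n,) or (n, k)."""
        m_j = self.m_j.astype(float)
        c_j = lam_b / (1.0 + lam_b * m_j)
        s_j = np.add.reduceat(v, self.neuron_starts, axis=0)
        ainv = v - (c_j[self.row_neuron, None] if v.ndim == 2 else c_j[self.row_neuron]) * s_j[self.row_neuron]
        u_j = s_j / ((1.0 + lam_b * m_j)[:, None] if v.ndim == 2 else (1.0 + lam_b * m_j))
        q_i = np.add.reduceat(u_j, self.monkey_neuron_starts, axis=0)
        t_i = np.add.reduceat(m_j / (1.0 + lam_b * m_j), self.monkey_neuron_starts)
        gamma_i = lam_a / (1.0 + lam_a * t_i)
        a_row = 1.0 / (1.0 + lam_b * m_j[self.row_neuron])
        g_row = gamma_i[self.neuron_monkey[self.row_neuron]]
        q_row = q_i[self.neuron_monkey[self.row_neuron]]
        if v.ndim == 2:
            return ainv - (g_row * a_row)[:, None] * q_row
        return ainv - g_row * a_row * q_row

    def log_det(self, lam_a: float, lam_b: float) -> float:
        m_j = self.m_j.astype(float)
        t_i = np.add.reduceat(m_j / (1.0 + lam_b * m_j), self.monkey_neuron_starts)
        return float(np.sum(np.log1p(lam_b * m_j)) + np.sum(np.log1p(lam_a * t_i)))


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the nested-intercept Gaussian LMM."""

    beta: np.ndarray
    colnames: list
    deviance: float  # -2 log likelihood at the ML solution
    sigma2: float  # residual variance
    sigma2_monkey: float
    sigma2_neuron: float
    vcov_beta: np.ndarray
    n: int
    fitted: np.ndarray
    boundary: bool  # a variance component was estimated at (numerical) zero
    grouping: "_NestedGrouping" = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    cells: list | None = None

    @property
    def lam(self) -> tuple[float, float]:
        return (self.sigma2_monkey / self.sigma2, self.sigma2_neuron / self.sigma2)


def _profiled_deviance(
    z: np.ndarray, grouping: _NestedGrouping, X: np.ndarray, y: np.ndarray
):
    lam_a, lam_b = np.exp(np.clip(z, *_Z_BOUNDS))
    Wx = grouping.apply_w(X, lam_a, lam_b)
    Wy = grouping.apply_w(y, lam_a, lam_b)
    xtwx = X.T @ Wx
    xtwy = X.T @ Wy
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(xtwx, xtwy, rcond=None)[0]
    rss = float(y @ Wy - xtwy @ beta)
    rss = max(rss, 1e-300)
    n = grouping.n
    sigma2 = rss / n
    dev = n * (_LOG_2PI + np.log(sigma2)) + n + grouping.log_det(lam_a, lam_b)
    return dev, beta, sigma2, xtwx


def fit_lmm(
    table: pd.DataFrame,
    fixed: str = "C(Scene) * C(Value) * C(Direction)",
    response: str = "NeuronalActivity",
    monkey_col: str = "monkey_ID",
    neuron_col: str = "Neuron_ID",
    starts: tuple[tuple[float, float], ...] = ((0.4, 0.4), (1e-6, 1e-6)),
    _design: tuple[np.ndarray, list] | None = None,
) -> LMMFit:
    """ML fit of ``response ~ fixed + (1|monkey) + (1|monkey:neuron)``.

    Returns estimates, -2 log-likelihood (the deviance used by the
    bootstrap comparison), fitted values, and variance components. A
    variance component estimated at the boundary is reported as zero and
    flagged.
    """
    if table[response].isna().any():
        raise FitError("response contains missing values")
    if _design is None:
        X, colnames = _design_matrix(table, fixed)
    else:
        X, colnames = _design
    grouping = _NestedGrouping(
        table[monkey_col].to_numpy(), table[neuron_col].to_numpy()
    )
    Xs = X[grouping.order]
    ys = table[response].to_numpy(dtype=float)[grouping.order]

    best = None
    for s in starts:
        z0 = np.log(np.maximum(s, 1e-8))
        res = minimize(
            lambda z: _profiled_deviance(z, grouping, Xs, ys)[0],
            z0, method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    dev, beta, sigma2, xtwx = _profiled_deviance(best.x, grouping, Xs, ys)
    lam_a, lam_b = np.exp(np.clip(best.x, *_Z_BOUNDS))
    boundary = bool(best.x[0] < _Z_BOUNDS[0] + 1.0 or best.x[1] < _Z_BOUNDS[0] + 1.0)
    if boundary:
        lam_a = 0.0 if best.x[0] < _Z_BOUNDS[0] + 1.0 else lam_a
        lam_b = 0.0 if best.x[1] < _Z_BOUNDS[0] + 1.0 else lam_b
    vcov = sigma2 * np.linalg.pinv(xtwx)
    fitted_sorted = Xs @ beta
    fitted = np.empty_like(fitted_sorted)
    fitted[grouping.order] = fitted_sorted
    return LMMFit(
        beta=beta, colnames=colnames, deviance=float(dev), sigma2=float(sigma2),
        sigma2_monkey=float(lam_a * sigma2), sigma2_neuron=float(lam_b * sigma2),
        vcov_beta=vcov, n=grouping.n, fitted=fitted, boundary=boundary,
        grouping=grouping, X=Xs, y=ys,
    )


def fit_cellmeans_lmm(
    table: pd.DataFrame,
    factors: tuple[str, ...],
    response: str = "NeuronalActivity",
    monkey_col: str = "monkey_ID",
    neuron_col: str = "Neuron_ID",
) -> LMMFit:
    """Full model parameterized directly by condition-cell means (the same
    column space as the full factorial formula, convenient for contrasts)."""
    X, cells, _ = _cellmeans_matrix(table, factors)
    fit = fit_lmm(
        table, response=response, monkey_col=monkey_col, neuron_col=neuron_col,
        _design=(X, cells),
    )
    fit.cells = cells
    return fit


# ---------------------------------------------------------------------------
# balanced sufficient-statistic path

class _BalancedStats:
    """Stratum sums of squares for a balanced cell-mean table.

    Valid when every neuron contributes every cell exactly once and every
    monkey has the same number of neurons; then the profiled deviance of
    both the cell-means full model and the intercept-only null depends on
    y only through (SSw, SSb, SSm).
    """

    def __init__(self, cell_codes: np.ndarray, neuron_codes: np.ndarray,
                 monkey_of_neuron: np.ndarray):
        self.cells = cell_codes
        self.neurons = neuron_codes
        self.monkey_of_neuron = monkey_of_neuron
        self.m = int(cell_codes.max()) + 1
        self.J = int(neuron_codes.max()) + 1
        self.I = int(monkey_of_neuron.max()) + 1
        self.g = self.J // self.I
        self.n = len(cell_codes)

    @staticmethod
    def check(table: pd.DataFrame, factors, monkey_col, neuron_col):
        _, cells, codes = _cellmeans_matrix(table, factors)
        m = len(cells)
        m_codes = pd.factorize(table[monkey_col].to_numpy())[0]
        n_codes = pd.factorize(table[neuron_col].to_numpy())[0]
        pair = m_codes.astype(np.int64) * (n_codes.max() + 1) + n_codes
        neuron_key, pair_uniq = pd.factorize(pair)
        counts = np.bincount(neuron_key * m + codes, minlength=len(pair_uniq) * m)
        if not np.all(counts == 1):
            return None
        monkey_of_neuron = (np.asarray(pair_uniq) // (n_codes.max() + 1)).astype(int)
        monkey_of_neuron = pd.factorize(monkey_of_neuron)[0]
        g = np.bincount(monkey_of_neuron)
        if len(set(g)) != 1:
            return None
        return _BalancedStats(codes, neuron_key, monkey_of_neuron)

    def suffstats(self, y: np.ndarray):
        """(SSw_full, SSw_null, SSb, SSm, grand, cell_means) for y (n,) or (n, B)."""
        y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, B)
        B = y.shape[1]
        nm = np.zeros((self.J, B))
        np.add.at(nm, self.neurons, y)
        nm /= self.m
        cm = np.zeros((self.m, B))
        np.add.at(cm, self.cells, y)
        cm /= self.J
        mm = np.zeros((self.I, B))
        np.add.at(mm, self.monkey_of_neuron, nm)
        mm /= self.g
        grand = y.mean(axis=0)
        r_null = y - nm[self.neurons]
        ssw_null = (r_null**2).sum(axis=0)
        r_full = r_null - cm[self.cells] + grand
        ssw_full = (r_full**2).sum(axis=0)
        ssb = self.m * ((nm - mm[self.monkey_of_neuron]) ** 2).sum(axis=0)
        ssm = self.m * self.g * ((mm - grand) ** 2).sum(axis=0)
        return ssw_full, ssw_null, ssb, ssm, grand, cm

    def deviance_batch(self, ssw, ssb, ssm):
        """Minimized profiled ML deviance, vectorized over datasets.

        In the balanced design the marginal covariance has three known
        eigen-strata with eigenvalues 1, ``u = 1 + m*lam_b`` and
        ``w = u + m*g*lam_a`` (within neuron, between neurons within
        monkey, between monkeys), so the deviance is

            n log sigma2 + (J - I) log u + I log w + const,
            sigma2 = (SSw + SSb/u + SSm/w) / n,

        subject to ``1 <= u <= w``. Setting each partial derivative to
        zero gives closed-form coordinate updates, which are alternated to
        convergence; the constrained-boundary candidates (``u = 1``,
        ``w = u``, both) have closed forms and the best candidate wins.
        Returns ``(dev, u, w)`` as arrays.
        """
        ssw = np.maximum(np.asarray(ssw, dtype=float), 1e-300)
        ssb = np.asarray(ssb, dtype=float)
        ssm = np.asarray(ssm, dtype=float)
        n, J, I = float(self.n), self.J, self.I
        lam_max = float(np.exp(_Z_BOUNDS[1]))
        u_max = 1.0 + self.m * lam_max
        w_max = u_max + self.m * self.g * lam_max

        def dev_at(u, w):
            sigma2 = (ssw + ssb / u + ssm / w) / n
            return (n * (_LOG_2PI + np.log(np.maximum(sigma2, 1e-300))) + n
                    + (J - I) * np.log(u) + I * np.log(w))

        def u_update(w):
            if J - I <= 0:
                return np.ones_like(ssw)
            return np.minimum(ssb * (n / (J - I) - 1.0) / (ssw + ssm / w), u_max)

        def w_update(u):
            return np.minimum(ssm * (n / I - 1.0) / (ssw + ssb / u), w_max)

        # interior stationary point via alternating closed-form updates
        u = np.maximum(u_update(np.full_like(ssw, np.inf)), 1.0)
        w = np.maximum(w_update(u), u)
        for _ in range(60):
            u_new = np.clip(u_update(w), 1.0, w)
            w_new = np.maximum(w_update(u_new), u_new)
            if np.all(np.abs(u_new - u) < 1e-12 * (1 + u)) and \
               np.all(np.abs(w_new - w) < 1e-12 * (1 + w)):
                u, w = u_new, w_new
                break
            u, w = u_new, w_new
        candidates = [(u, w)]
        # boundary w = u (no monkey variance)
        u_eq = np.clip((ssb + ssm) * (n / J - 1.0) / ssw, 1.0, u_max)
        candidates.append((u_eq, u_eq))
        # boundary u = 1 (no neuron variance)
        ones = np.ones_like(ssw)
        w_b = np.maximum(ssm * (n / I - 1.0) / (ssw + ssb), 1.0)
        candidates.append((ones, w_b))
        candidates.append((ones, ones))

        best_dev = None
        best_u = best_w = None
        for cu, cw in candidates:
            d = dev_at(cu, cw)
            if best_dev is None:
                best_dev, best_u, best_w = d, cu, cw
            else:
                better = d < best_dev
                best_dev = np.where(better, d, best_dev)
                best_u = np.where(better, cu, best_u)
                best_w = np.where(better, cw, best_w)
        return best_dev, best_u, best_w

    def deviance(self, ssw: float, ssb: float, ssm: float) -> tuple[float, tuple]:
        """Minimized profiled ML deviance and the variance ratios
        ``(lam_monkey, lam_neuron)`` at the optimum, for one dataset."""
        d, u, w = self.deviance_batch(np.array([ssw]), np.array([ssb]), np.array([ssm]))
        lam_b = (float(u[0]) - 1.0) / self.m
        lam_a = (float(w[0]) - float(u[0])) / (self.m * self.g)
        return float(d[0]), (lam_a, lam_b)


@dataclass
class ModelComparisonResult:
    deviance_full: float
    deviance_null: float
    observed_diff: float
    n_boot: int
    n_failed: int
    p_boot: float
    seed: int
    boot_diffs: np.ndarray = field(repr=False, default=None)
    varcomps_null: dict = field(default_factory=dict)


def parametric_bootstrap_compare(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ("Scene", "Value", "Direction"),
    response: str = "NeuronalActivity",
    monkey_col: str = "monkey_ID",
    neuron_col: str = "Neuron_ID",
    n_boot: int = 199,
    seed: int = 0,
    method: str = "auto",
) -> ModelComparisonResult:
    """Parametric-bootstrap comparison of the condition-cell full model
    against the intercept-only null, both with nested random intercepts.

    ``method='auto'`` uses the balanced sufficient-statistic path when the
    table is a complete balanced cell-mean design, else the general
    Woodbury path. Replicates whose refit fails are dropped and counted;
    more than 5% failures raises a warning.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    bal = None
    if method in ("auto", "balanced"):
        bal = _BalancedStats.check(table, factors, monkey_col, neuron_col)
        if bal is None and method == "balanced":
            raise FitError("table is not a balanced cell-mean design")

    if bal is not None:
        return _bootstrap_balanced(table, bal, response, n_boot, rng, seed)
    return _bootstrap_general(
        table, factors, response, monkey_col, neuron_col, n_boot, rng, seed
    )


def _varcomps_from_lam(sigma2: float, lam: tuple[float, float]) -> dict:
    return {
        "sigma2_resid": sigma2,
        "sigma2_monkey": lam[0] * sigma2,
        "sigma2_neuron": lam[1] * sigma2,
    }


def _bootstrap_balanced(table, bal: _BalancedStats, response, n_boot, rng, seed):
    y = table[response].to_numpy(dtype=float)
    ssw_f, ssw_n, ssb, ssm, grand, _ = (v if np.ndim(v) == 0 else v[..., 0]
                                        for v in bal.suffstats(y))
    dev_null, lam_null = bal.deviance(float(ssw_n), float(ssb), float(ssm))
    dev_full, lam_full = bal.deviance(float(ssw_f), float(ssb), float(ssm))
    obs = dev_null - dev_full
    if obs < -1e-6:
        raise FitError("nesting violated: full deviance above null deviance")
    obs = max(obs, 0.0)

    # variance components of the fitted null, for simulation
    n, m, g = bal.n, bal.m, bal.g
    la, lb = lam_null
    d_b = 1.0 + m * lb
    d_m = d_b + m * g * la
    sigma2 = (ssw_n + ssb / d_b + ssm / d_m) / n
    s2_mon, s2_neu = la * sigma2, lb * sigma2

    B = int(n_boot)
    eps = rng.normal(0.0, np.sqrt(sigma2), size=(n, B))
    b = rng.normal(0.0, np.sqrt(s2_neu), size=(bal.J, B))
    a = rng.normal(0.0, np.sqrt(s2_mon), size=(bal.I, B))
    ystar = float(grand) + eps + b[bal.neurons] + a[bal.monkey_of_neuron[bal.neurons]]
    ssw_fb, ssw_nb, ssbb, ssmb, _, _ = bal.suffstats(ystar)
    dev_n, _, _ = bal.deviance_batch(ssw_nb, ssbb, ssmb)
    dev_f, _, _ = bal.deviance_batch(ssw_fb, ssbb, ssmb)
    diffs = np.maximum(dev_n - dev_f, 0.0)
    p = (1.0 + np.sum(diffs >= obs)) / (B + 1.0)
    return ModelComparisonResult(
        deviance_full=dev_full, deviance_null=dev_null, observed_diff=obs,
        n_boot=B, n_failed=0, p_boot=float(p), seed=seed, boot_diffs=diffs,
        varcomps_null=_varcomps_from_lam(float(sigma2), lam_null),
    )


def _bootstrap_general(table, factors, response, monkey_col, neuron_col,
                       n_boot, rng, seed):
    X_full, cells, _ = _cellmeans_matrix(table, factors)
    full = fit_lmm(table, response=response, monkey_col=monkey_col,
                   neuron_col=neuron_col, _design=(X_full, cells))
    null = fit_lmm(table, fixed="1", response=response, monkey_col=monkey_col,
                   neuron_col=neuron_col)
    obs = null.deviance - full.deviance
    if obs < -1e-6:
        raise FitError("nesting violated: full deviance above null deviance")
    obs = max(obs, 0.0)

    grouping = null.grouping
    mu = float(null.beta[0])
    s_mon = np.sqrt(null.sigma2_monkey)
    s_neu = np.sqrt(null.sigma2_neuron)
    s_res = np.sqrt(null.sigma2)
    sim_table = table.copy()
    order = grouping.order
    diffs = []
    failed = 0
    for _ in range(int(n_boot)):
        a = rng.normal(0.0, s_mon, size=grouping.n_monkeys)
        b = rng.normal(0.0, s_neu, size=grouping.n_neurons)
        e = rng.normal(0.0, s_res, size=grouping.n)
        y_sorted = mu + a[grouping.neuron_monkey[grouping.row_neuron]] \
            + b[grouping.row_neuron] + e
        ystar = np.empty_like(y_sorted)
        ystar[order] = y_sorted
        sim_table[response] = ystar
        try:
            f = fit_lmm(sim_table, response=response, monkey_col=monkey_col,
                        neuron_col=neuron_col, _design=(X_full, cells))
            n0 = fit_lmm(sim_table, fixed="1", response=response,
                         monkey_col=monkey_col, neuron_col=neuron_col)
            diffs.append(max(n0.deviance - f.deviance, 0.0))
        except Exception:
            failed += 1
    if failed > 0.05 * n_boot:
        warnings.warn(f"{failed}/{n_boot} bootstrap refits failed")
    diffs = np.asarray(diffs)
    p = (1.0 + np.sum(diffs >= obs)) / (len(diffs) + 1.0)
    return ModelComparisonResult(
        deviance_full=full.deviance, deviance_null=null.deviance,
        observed_diff=obs, n_boot=int(n_boot), n_failed=failed,
        p_boot=float(p), seed=seed, boot_diffs=diffs,
        varcomps_null={
            "sigma2_resid": null.sigma2,
            "sigma2_monkey": null.sigma2_monkey,
            "sigma2_neuron": null.sigma2_neuron,
        },
    )


# ---------------------------------------------------------------------------
# post-hoc contrasts


def _emm_vector(fit: LMMFit, cells_in: list[tuple]) -> np.ndarray:
    """Averaging vector over the listed cells (estimated marginal mean)."""
    L = np.zeros(len(fit.cells))
    idx = [fit.cells.index(c) for c in cells_in]
    L[idx] = 1.0 / len(idx)
    return L


def _satterthwaite_df(fit: LMMFit, L: np.ndarray) -> float:
    """Satterthwaite-style df: finite-difference gradient of the contrast
    variance with respect to the variance components, against the inverse
    ML information of those components."""
    grouping, X, y = fit.grouping, fit.X, fit.y
    theta0 = np.array([fit.sigma2, fit.sigma2_monkey, fit.sigma2_neuron])

    def var_l(theta):
        s2, s2a, s2b = np.maximum(theta, 1e-12)
        Wx = grouping.apply_w(X, s2a / s2, s2b / s2)
        xtwx = X.T @ Wx
        return float(s2 * (L @ np.linalg.pinv(xtwx) @ L))

    def dev(theta):
        s2, s2a, s2b = np.maximum(theta, 1e-12)
        lam_a, lam_b = s2a / s2, s2b / s2
        Wx = grouping.apply_w(X, lam_a, lam_b)
        Wy = grouping.apply_w(y, lam_a, lam_b)
        xtwx = X.T @ Wx
        beta = np.linalg.lstsq(xtwx, X.T @ Wy, rcond=None)[0]
        rss = float(y @ Wy - (X.T @ Wy) @ beta)
        return grouping.n * (_LOG_2PI + np.log(s2)) + rss / s2 \
            + grouping.log_det(lam_a, lam_b)

    h = np.maximum(1e-4 * theta0, 1e-8)
    grad = np.empty(3)
    for k in range(3):
        tp, tm = theta0.copy(), theta0.copy()
        tp[k] += h[k]
        tm[k] = max(tm[k] - h[k], 1e-12)
        grad[k] = (var_l(tp) - var_l(tm)) / (tp[k] - tm[k])
    # numerical Hessian of the -2 log likelihood
    H = np.empty((3, 3))
    f0 = dev(theta0)
    for k in range(3):
        for l in range(k, 3):
            tkp, tkm = theta0.copy(), theta0.copy()
            if k == l:
                tkp[k] += h[k]
                tkm[k] = max(tkm[k] - h[k], 1e-12)
                H[k, k] = (dev(tkp) - 2 * f0 + dev(tkm)) / ((tkp[k] - theta0[k]) * (theta0[k] - tkm[k]) + 1e-300)
            else:
                tpp, tpm, tmp, tmm = (theta0.copy() for _ in range(4))
                tpp[k] += h[k]; tpp[l] += h[l]
                tpm[k] += h[k]; tpm[l] = max(tpm[l] - h[l], 1e-12)
                tmp[k] = max(tmp[k] - h[k], 1e-12); tmp[l] += h[l]
                tmm[k] = max(tmm[k] - h[k], 1e-12); tmm[l] = max(tmm[l] - h[l], 1e-12)
                H[k, l] = H[l, k] = (dev(tpp) - dev(tpm) - dev(tmp) + dev(tmm)) / (
                    (tpp[k] - tmp[k]) * (tpp[l] - tpm[l]) + 1e-300
                )
    try:
        vtheta = 2.0 * np.linalg.pinv(H)
        denom = float(grad @ vtheta @ grad)
    except np.linalg.LinAlgError:
        denom = 0.0
    v = var_l(theta0)
    if denom <= 0 or not np.isfinite(denom):
        return float(fit.n - len(fit.beta))
    df = 2.0 * v**2 / denom
    return float(np.clip(df, 1.0, fit.n - 1))


def posthoc_pairwise(
    fit: LMMFit,
    contrasts: list[tuple[str, list[tuple], list[tuple]]],
    m: int | None = None,
    alpha: float = 0.05,
    df_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise contrasts on a cell-means LMM fit.

    Each contrast is ``(label, cells_a, cells_b)`` where the cell lists
    are averaged (estimated marginal means). Returns a table with model
    EMMs and their SEs, t, df, raw and adjusted p, the unadjusted 95% CI
    of the difference, and effect size = difference / residual SD.
    """
    if fit.cells is None:
        raise ValueError("posthoc requires a cell-means fit (fit_cellmeans_lmm)")
    m = m if m is not None else len(contrasts)
    rows = []
    for label, cells_a, cells_b in contrasts:
        try:
            La = _emm_vector(fit, cells_a)
            Lb = _emm_vector(fit, cells_b)
        except ValueError:
            continue  # empty cell: contrast skipped
        L = La - Lb
        est_a, est_b = float(La @ fit.beta), float(Lb @ fit.beta)
        se_a = float(np.sqrt(La @ fit.vcov_beta @ La))
        se_b = float(np.sqrt(Lb @ fit.vcov_beta @ Lb))
        diff = est_a - est_b
        se = float(np.sqrt(L @ fit.vcov_beta @ L))
        if df_method == "satterthwaite":
            df = _satterthwaite_df(fit, L)
        else:
            df = float(fit.n - len(fit.beta))
        t = diff / se if se > 0 else 0.0
        p_raw = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
        half = stats.t.ppf(0.975, df) * se
        rows.append({
            "contrast": label,
            "mean_a": est_a, "se_a": se_a, "mean_b": est_b, "se_b": se_b,
            "t": t, "df": df, "p_raw": p_raw,
            "p_adjusted": min(1.0, m * p_raw),
            "ci_lo": diff - half, "ci_hi": diff + half,
            "effect_size": diff / np.sqrt(fit.sigma2),
            "m": m, "alpha_adjusted": alpha / m,
        })
    return pd.DataFrame(rows)


def value_direction_contrasts(
    scenes: list[str] | None = None,
    values: tuple[str, str] = ("good", "bad"),
    directions: tuple[str, str] = ("contra", "ipsi"),
) -> list[tuple[str, list[tuple], list[tuple]]]:
    """The six pairwise contrasts among the four (value, direction) cells,
    averaged over scenes (cell keys are (Scene, Value, Direction) strings)."""
    from itertools import combinations

    scenes = scenes or ["1", "2", "3", "4"]
    cells = {}
    for v in values:
        for d in directions:
            cells[(v, d)] = [(s, v, d) for s in scenes]
    out = []
    for (a, b) in combinations(cells, 2):
        out.append((f"({a[0]}, {a[1]}) vs ({b[0]}, {b[1]})", cells[a], cells[b]))
    return out


def scene_contrasts(
    scenes: list[str] | None = None,
    values: tuple[str, str] = ("good", "bad"),
    directions: tuple[str, str] = ("contra", "ipsi"),
) -> list[tuple[str, list[tuple], list[tuple]]]:
    """The six pairwise contrasts among the four scenes, averaged over
    (value, direction) cells."""
    from itertools import combinations

    scenes = scenes or ["1", "2", "3", "4"]
    per_scene = {
        s: [(s, v, d) for v in values for d in directions] for s in scenes
    }
    return [(f"Scene {a} vs Scene {b}", per_scene[a], per_scene[b])
            for a, b in combinations(scenes, 2)]
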