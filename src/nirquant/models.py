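"""Calibration models: NIPALS PLSR, RBF support-vector regression, and
Black-winged-Kite-optimized SVR.

All three expose the same ``fit -> model.predict(X)`` contract so the
pipeline can treat them uniformly.  Hyperparameter searches (grid and
metaheuristic) score candidates by k-fold RMSECV with a fold map shared
across all candidates, so their objective values are directly comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVR

from .errors import ConfigError, DimensionError
from .evaluate import cross_val_rmse, kfold_indices

# ----------------------------------------------------------------- PLSR


@dataclass
class PLSRModel:
    """A fitted PLS1 regression.

    ``b`` is the regression-coefficient vector on mean-centered data, so
    predictions are ``(X − x_mean) @ b + y_mean``.  ``cv_curve[k-1]`` is the
    RMSECV obtained with ``k`` latent variables during model selection.
    """

    n_lvs: int
    b: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray   # X-weights W, (p, n_lvs)
    loadings: np.ndarray  # X-loadings P, (p, n_lvs)
    cv_curve: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return (X - self.x_mean) @ self.b + self.y_mean


def _nested_coefs(pls: PLSRegression, ks) -> dict[int, np.ndarray]:
    """Centered-space coefficient vectors for truncations of one NIPALS fit.

    NIPALS components are nested, so the k-component coefficient vector is
    ``B_k = W_k (P_kᵀ W_k)⁻¹ q_k`` using the first k columns of the weights
    and loadings — one fit per fold serves every candidate LV count.
    """
    W = pls.x_weights_
    P = pls.x_loadings_
    q = np.ravel(pls.y_loadings_)
    # components past the effective rank have zero/non-finite weights; clamp
    ok = np.isfinite(W).all(axis=0) & (np.linalg.norm(W, axis=0) > 1e-12)
    k_max = int(np.argmin(ok)) if not ok.all() else W.shape[1]
    k_max = max(k_max, 1)
    out = {}
    for k in ks:
        kk = min(k, k_max)
        Wk, Pk, qk = W[:, :kk], P[:, :kk], q[:kk]
        out[k], *_ = np.linalg.lstsq(np.asarray(Pk.T @ Wk), qk, rcond=None)
        out[k] = Wk @ out[k]
    return out


def _fit_pls_raw(Xc, yc, n_components):
    """NIPALS fit on pre-centered data, silencing benign convergence chatter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xc, yc)
    return pls


def fit_plsr(X, y, max_lvs: int = 20, folds: int = 5, seed: int = 0) -> PLSRModel:
    """PLS1 with the latent-variable count chosen by k-fold cross-validation.

    NIPALS on mean-centered (not variance-scaled) data; candidate LV counts
    1..max_lvs (capped so every training fold keeps more samples than
    components); the count minimizing RMSECV wins, ties to the smaller count.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if folds > n:
        raise DimensionError(f"folds={folds} exceeds n={n}")
    cap = min(max_lvs, p, n - math.ceil(n / folds) - 1)
    cap = max(cap, 1)
    fold_of = kfold_indices(n, folds, seed)
    ks = list(range(1, cap + 1))
    press = np.zeros(cap)  # pooled squared out-of-fold residuals per LV count
    for f in range(folds):
        te = fold_of == f
        tr = ~te
        xm = X[tr].mean(axis=0)
        ym = y[tr].mean()
        pls = _fit_pls_raw(X[tr] - xm, y[tr] - ym, cap)
        for k, bk in _nested_coefs(pls, ks).items():
            resid = y[te] - ((X[te] - xm) @ bk + ym)
            press[k - 1] += float(resid @ resid)
    cv_curve = np.sqrt(press / n)
    n_lvs = int(np.argmin(cv_curve)) + 1  # argmin takes the smallest tied k
    xm = X.mean(axis=0)
    ym = float(y.mean())
    pls = _fit_pls_raw(X - xm, y - ym, n_lvs)
    b = _nested_coefs(pls, [n_lvs])[n_lvs]
    return PLSRModel(
        n_lvs=n_lvs, b=b, x_mean=xm, y_mean=ym,
        weights=pls.x_weights_.copy(), loadings=pls.x_loadings_.copy(),
        cv_curve=cv_curve,
    )


def fit_pls_fixed(X, y, n_lvs: int) -> PLSRModel:
    """PLS1 with a fixed latent-variable count (no model selection)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n_lvs = int(min(n_lvs, X.shape[1], max(X.shape[0] - 1, 1)))
    xm = X.mean(axis=0)
    ym = float(y.mean())
    pls = _fit_pls_raw(X - xm, y - ym, n_lvs)
    b = _nested_coefs(pls, [n_lvs])[n_lvs]
    return PLSRModel(n_lvs=n_lvs, b=b, x_mean=xm, y_mean=ym,
                     weights=pls.x_weights_.copy(), loadings=pls.x_loadings_.copy())


# ------------------------------------------------------------------ SVR


@dataclass(frozen=True)
class SVRHyperparams:
    """RBF-SVR hyperparameters: penalty c, kernel width g, tube width epsilon."""

    c: float
    g: float
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0 or self.epsilon < 0:
            raise ConfigError(f"invalid SVR hyperparameters {self}")


def fit_svr(X, y, hyperparams: SVRHyperparams) -> SVR:
    """Epsilon-insensitive SVR with kernel exp(−g‖x−z‖²), solved by libsvm."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DimensionError("non-finite values in SVR inputs")
    model = SVR(kernel="rbf", C=hyperparams.c, gamma=hyperparams.g,
                epsilon=hyperparams.epsilon, tol=1e-4, max_iter=2_000_000)
    model.fit(X, y)
    return model


def default_c_grid() -> np.ndarray:
    """c = 2^(−2), 2^(−1.5), …, 2^10 (quarter-decade √2 steps)."""
    return 2.0 ** np.arange(-2.0, 10.0 + 1e-9, 0.5)


def default_g_grid() -> np.ndarray:
    """g = 2^(−12), …, 2^2 in √2 steps."""
    return 2.0 ** np.arange(-12.0, 2.0 + 1e-9, 0.5)


def grid_search_svr(X, y, c_grid=None, g_grid=None, folds: int = 5,
                    seed: int = 0, epsilon: float = 0.1):
    """Exhaustive (c, g) grid search scored by k-fold RMSECV.

    Returns ``(SVRHyperparams, rmsecv)`` for the grid minimum; ties break to
    the smaller c, then the smaller g (the iteration order below).
    """
    c_grid = default_c_grid() if c_grid is None else np.asarray(c_grid, float)
    g_grid = default_g_grid() if g_grid is None else np.asarray(g_grid, float)
    if c_grid.size == 0 or g_grid.size == 0:
        raise ConfigError("empty hyperparameter grid")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    fold_of = kfold_indices(y.size, folds, seed)
    best = None
    for c in np.sort(c_grid):
        for g in np.sort(g_grid):
            hp = SVRHyperparams(float(c), float(g), epsilon)
            score = cross_val_rmse(lambda a, b, hp=hp: fit_svr(a, b, hp),
                                   X, y, fold_ids=fold_of)
            if best is None or score < best[1]:
                best = (hp, score)
    return best


# ------------------------------------------------------------------ BKA


@dataclass
class BKAConfig:
    """Black-winged Kite Algorithm settings for (c, g) tuning.

    The search runs in log₂-space of the box ``c_bounds × g_bounds`` so steps
    are scale-invariant.  ``pop_size ≥ 4``; defaults are sized for a
    few-hundred-sample calibration problem.
    """

    pop_size: int = 10
    n_iter: int = 20
    c_bounds: tuple[float, float] = (0.01, 1024.0)
    g_bounds: tuple[float, float] = (1e-4, 1.0)
    seed: int = 0
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigError("population size must be >= 4")
        if self.n_iter < 0:
            raise ConfigError("iteration count must be >= 0")
        for lo, hi in (self.c_bounds, self.g_bounds):
            if not (0 < lo < hi):
                raise ConfigError("bounds must be positive with lower < upper")


@dataclass
class BKAResult:
    """Best point found plus the (non-increasing) best-so-far trace."""

    best_x: np.ndarray
    best_f: float
    trace: list[float] = field(default_factory=list)
    n_evals: int = 0


def bka_optimize(objective, bounds, pop_size: int = 20, n_iter: int = 100,
                 seed: int = 0) -> BKAResult:
    """Minimize ``objective`` over a box with the Black-winged Kite Algorithm.

    Two phases per generation, following the original algorithm's scheme:

    * *attacking* (exploration) — each kite perturbs its own position
      multiplicatively with a step envelope ``0.05·exp(−2(t/T)²)`` that decays
      over time, hovering (``1 + sin r``) or diving (``2r − 1``) depending on
      a random switch;
    * *migration* (exploitation) — kites move relative to the current leader
      with heavy-tailed (Cauchy) steps: followers whose fitness already beats
      a random peer's step away along ``(x − leader)``, others are pulled
      toward the leader.

    Selection is greedy (a move is kept only if it improves that kite), so the
    best-so-far trace is non-increasing.  Candidates are clipped to the box;
    non-finite objective values are treated as +inf (candidate rejected).
    Objective evaluations are cached on the exact position vector.
    """
    bounds = np.asarray(bounds, float)  # (d, 2)
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = lo.size
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}

    def f(x) -> float:
        key = tuple(np.round(x, 12))
        if key not in cache:
            val = objective(np.asarray(x, float))
            cache[key] = float(val) if np.isfinite(val) else float("inf")
        return cache[key]

    X = lo + rng.random((pop_size, d)) * (hi - lo)
    fit = np.array([f(x) for x in X])
    trace = [float(fit.min())]
    T = max(n_iter, 1)
    for t in range(1, n_iter + 1):
        envelope = 0.05 * math.exp(-2.0 * (t / T) ** 2)
        # attacking phase
        for i in range(pop_size):
            r = rng.random()
            if r < 0.9:
                step = envelope * (1.0 + math.sin(r)) * X[i]
            else:
                step = envelope * (2.0 * r - 1.0) * X[i]
            cand = np.clip(X[i] + step, lo, hi)
            fc = f(cand)
            if fc < fit[i]:
                X[i], fit[i] = cand, fc
        # migration phase
        leader = X[int(np.argmin(fit))].copy()
        for i in range(pop_size):
            r = rng.random()
            m = 2.0 * math.sin(r + math.pi / 2.0)
            cauchy = rng.standard_cauchy(d)
            peer = int(rng.integers(pop_size))
            if fit[i] < fit[peer]:
                cand = X[i] + cauchy * (X[i] - leader)
            else:
                cand = X[i] + cauchy * (leader - m * X[i])
            cand = np.clip(cand, lo, hi)
            fc = f(cand)
            if fc < fit[i]:
                X[i], fit[i] = cand, fc
        trace.append(float(fit.min()))
    best_i = int(np.argmin(fit))
    return BKAResult(best_x=X[best_i].copy(), best_f=float(fit[best_i]),
                     trace=trace, n_evals=len(cache))


@dataclass
class BKASVRFit:
    """A BKA-tuned SVR: final refitted model, chosen hyperparameters, trace."""

    model: SVR
    params: SVRHyperparams
    rmsecv: float
    trace: list[float]

    def predict(self, X):
        return self.model.predict(X)


def fit_bka_svr(X, y, config: BKAConfig | None = None, folds: int = 5) -> BKASVRFit:
    """Tune (c, g) with BKA on k-fold RMSECV, then refit on all data.

    The objective is the shared-fold RMSECV of :func:`fit_svr` at
    ``(c, g) = (2^{z0}, 2^{z1})``; the search box is the log₂ image of the
    configured bounds.  Same seed → identical hyperparameters.
    """
    config = config or BKAConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    fold_of = kfold_indices(y.size, folds, config.seed)

    def objective(z):
        hp = SVRHyperparams(float(2.0 ** z[0]), float(2.0 ** z[1]), config.epsilon)
        try:
            return cross_val_rmse(lambda a, b: fit_svr(a, b, hp), X, y,
                                  fold_ids=fold_of)
        except Exception:  # noqa: BLE001 - reject pathological candidates
            return float("inf")

    bounds = np.log2([[config.c_bounds[0], config.c_bounds[1]],
                      [config.g_bounds[0], config.g_bounds[1]]])
    result = bka_optimize(objective, bounds, pop_size=config.pop_size,
                          n_iter=config.n_iter, seed=config.seed)
    params = SVRHyperparams(float(2.0 ** result.best_x[0]),
                            float(2.0 ** result.best_x[1]), config.epsilon)
    model = fit_svr(X, y, params)
    return BKASVRFit(model=model, params=params, rmsecv=result.best_f,
                     trace=result.trace)
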