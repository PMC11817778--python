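"""Competitive Adaptive Reweighted Sampling (CARS) wavelength selection.

CARS whittles the full wavenumber grid down to a small informative subset by
running N Monte-Carlo rounds.  Each round fits a PLS model on a random sample
subset, turns the absolute regression coefficients into weights, keeps a
forced top fraction of variables that shrinks along an exponentially
decreasing function (EDF) of the round index, then resamples variables with
probability proportional to weight ("adaptive reweighted sampling").  Each
round's retained subset is scored by k-fold RMSECV on the full calibration
data; the subset with the lowest RMSECV wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dataset import SpectraSet
from .errors import ConfigError
from .evaluate import cross_val_rmse, kfold_indices
from .models import fit_pls_fixed, fit_plsr


@dataclass
class CARSConfig:
    """CARS settings.

    n_runs
        Number of Monte-Carlo elimination rounds N (default 50).
    mc_sample_ratio
        Fraction of calibration samples drawn (without replacement) per round.
    cv_folds
        Folds for the RMSECV scoring of each round's subset.
    max_lvs
        Cap on the internal PLS latent-variable count; the count itself is
        chosen once by CV on the full calibration data and held fixed.
    """

    n_runs: int = 50
    mc_sample_ratio: float = 0.80
    cv_folds: int = 5
    max_lvs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ConfigError("n_runs must be >= 2")
        if not (0.0 < self.mc_sample_ratio < 1.0):
            raise ConfigError("mc_sample_ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")


@dataclass
class RunRecord:
    """One CARS round: which variables survived and how well they scored."""

    run: int
    retained: np.ndarray
    forced_count: int
    rmsecv: float


@dataclass
class CARSResult:
    """Full CARS history plus the winning subset."""

    runs: list[RunRecord]
    best_run: int
    selected_indices: np.ndarray
    n_variables_total: int
    n_lvs: int

    @property
    def rmsecv_trace(self) -> np.ndarray:
        return np.array([r.rmsecv for r in self.runs])

    @property
    def retained_counts(self) -> np.ndarray:
        return np.array([r.retained.size for r in self.runs])

    @property
    def selected_fraction(self) -> float:
        """|selected| / p — multiply by 100 for the percent-style figure."""
        return self.selected_indices.size / self.n_variables_total


def edf_ratio(i: int, N: int, p: int) -> float:
    """Forced-retention ratio at round i of N over p variables.

    ``r_i = a·e^(−k·i)`` with ``a = (p/2)^(1/(N−1))`` and
    ``k = ln(p/2)/(N−1)``, so round 1 keeps every variable (r₁ = 1) and round
    N keeps exactly two (r_N · p = 2).
    """
    if N < 2:
        raise ConfigError("N must be >= 2")
    if p < 2:
        raise ConfigError("p must be >= 2")
    if not (1 <= i <= N):
        raise ConfigError(f"run index {i} outside 1..{N}")
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = math.log(p / 2.0) / (N - 1)
    return a * math.exp(-k * i)


def run_cars_matrix(X, y, config: CARSConfig | None = None) -> CARSResult:
    """CARS on a plain calibration matrix (see :func:`run_cars`)."""
    config = config or CARSConfig()
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if p < 2:
        raise ConfigError("need at least 2 variables")
    if n < config.cv_folds:
        raise ConfigError(f"need n >= cv_folds, got n={n}")
    rng = np.random.default_rng(config.seed)
    # internal LV count: chosen once by CV on the full data, then held fixed
    n_lvs = fit_plsr(X, y, max_lvs=config.max_lvs, folds=config.cv_folds,
                     seed=config.seed).n_lvs
    fold_of = kfold_indices(n, config.cv_folds, config.seed)
    n_draw = math.ceil(config.mc_sample_ratio * n)

    retained = np.arange(p)
    records: list[RunRecord] = []
    for i in range(1, config.n_runs + 1):
        rows = rng.choice(n, size=n_draw, replace=False)
        model = fit_pls_fixed(X[np.ix_(rows, retained)], y[rows], n_lvs)
        w = np.abs(model.b)
        total = w.sum()
        w = np.full(w.size, 1.0 / w.size) if total == 0 else w / total
        # forced selection: keep the top K_i by weight (EDF schedule)
        K = max(2, math.ceil(edf_ratio(i, config.n_runs, p) * p))
        K = min(K, retained.size)
        order = np.argsort(-w, kind="stable")
        forced = order[:K]
        wf = w[forced] / w[forced].sum()
        # adaptive reweighted sampling: K draws with replacement, keep distinct
        draws = rng.choice(K, size=K, replace=True, p=wf)
        keep_local = np.unique(forced[draws])
        if keep_local.size < 2:
            keep_local = np.unique(np.concatenate([keep_local, forced[:2]]))
        new_retained = np.sort(retained[keep_local])
        score = cross_val_rmse(
            lambda a, b: fit_pls_fixed(a, b, n_lvs),
            X[:, new_retained], y, fold_ids=fold_of,
        )
        if not np.isfinite(score):
            raise ConfigError(f"non-finite RMSECV in CARS run {i}")
        records.append(RunRecord(i, new_retained, K, score))
        retained = new_retained

    # winner: minimal RMSECV; ties -> fewer variables, then the earlier run
    best = min(records, key=lambda r: (r.rmsecv, r.retained.size, r.run))
    return CARSResult(records, best.run, best.retained.copy(), p, n_lvs)


def run_cars(spectra: SpectraSet, target: str, config: CARSConfig | None = None) -> CARSResult:
    """CARS on the calibration partition of a SpectraSet for one target.

    ``target`` is ``"A"``, ``"B"`` or ``"C"`` (sweet-potato, corn, total
    adulterant fraction).  Run this on calibration samples only.
    """
    return run_cars_matrix(spectra.absorbance, spectra.target(target), config)
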