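"""Gaussian-process surrogate over mixed periodic/bounded spaces.

The kernel is a product over dimensions: a squared-exponential factor for
bounded (translation) dimensions and a periodic squared-exponential factor
for angular (torsion/rotation) dimensions, times a signal variance. Inputs
are normalized to the unit cube by the search-space bounds so lengthscales
are comparable across dimensions; energies are median-centered and scaled
by their interquartile range before fitting.

Hyperparameters (per-dimension lengthscales and the signal amplitude) are
set by maximizing the log marginal likelihood with a seeded multi-start
L-BFGS; the observation noise is a fixed small jitter since the backends
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

__all__ = ["SurrogateModel", "fit_surrogate"]


def _pairwise_deltas(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """(n1, n2, d) signed coordinate differences."""
    return X1[:, None, :] - X2[None, :, :]


@dataclass
class SurrogateModel:
    """GP posterior over normalized search-space coordinates.

    Build via :func:`fit_surrogate` (hyperparameter optimization) or
    :meth:`with_data` (same hyperparameters, new observations).
    """

    X: np.ndarray  # (n, d), normalized to [0, 1]
    y: np.ndarray  # (n,), raw energies (eV)
    periodic: np.ndarray  # (d,) bool
    lengthscales: np.ndarray  # (d,), normalized units
    signal_sd: float
    noise: float = 1e-6  # jitter variance on the normalized-energy scale
    y_center: float = 0.0
    y_scale: float = 1.0
    _chol: tuple = field(default=None, repr=False)  # type: ignore[assignment]
    _alpha: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self._chol is None:
            self._factor()

    # -- kernel ------------------------------------------------------------

    def _kernel(self, X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
        d = _pairwise_deltas(X1, X2)
        ls = self.lengthscales
        expo = np.zeros(d.shape[:2])
        for k in range(d.shape[2]):
            if self.periodic[k]:
                expo += 2.0 * np.sin(np.pi * d[:, :, k]) ** 2 / ls[k] ** 2
            else:
                expo += 0.5 * d[:, :, k] ** 2 / ls[k] ** 2
        return self.signal_sd**2 * np.exp(-expo)

    def _factor(self) -> None:
        yn = (self.y - self.y_center) / self.y_scale
        K = self._kernel(self.X, self.X)
        jitter = self.noise
        for _ in range(8):
            try:
                L = cholesky(K + jitter * np.eye(len(K)), lower=True)
                break
            except np.linalg.LinAlgError:
                jitter *= 10.0
        else:
            raise np.linalg.LinAlgError(
                "kernel matrix singular even after jitter escalation"
            )
        self._chol = (L, True)
        self._alpha = cho_solve((L, True), yn)

    # -- public surface ----------------------------------------------------

    @property
    def n_train(self) -> int:
        return len(self.y)

    def predict(self, Xs: np.ndarray, return_std: bool = True):
        """Posterior mean (and standard deviation) in raw energy units."""
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        Ks = self._kernel(Xs, self.X)
        mean_n = Ks @ self._alpha
        mean = mean_n * self.y_scale + self.y_center
        if not return_std:
            return mean
        L = self._chol[0]
        v = np.linalg.solve(L, Ks.T)
        var = self.signal_sd**2 - np.einsum("ij,ij->j", v, v)
        var = np.maximum(var, 0.0)
        return mean, np.sqrt(var) * self.y_scale

    def with_data(self, X: np.ndarray, y: np.ndarray) -> "SurrogateModel":
        """Same hyperparameters, new training set (no refit)."""
        return SurrogateModel(
            X=np.asarray(X, dtype=float),
            y=np.asarray(y, dtype=float),
            periodic=self.periodic,
            lengthscales=self.lengthscales.copy(),
            signal_sd=self.signal_sd,
            noise=self.noise,
            y_center=self.y_center,
            y_scale=self.y_scale,
        )


def _neg_lml(theta: np.ndarray, X: np.ndarray, yn: np.ndarray, periodic: np.ndarray, noise: float) -> float:
    d = X.shape[1]
    ls = np.exp(theta[:d])
    sf = np.exp(theta[d])
    model = SurrogateModel.__new__(SurrogateModel)
    model.periodic = periodic
    model.lengthscales = ls
    model.signal_sd = sf
    K = model._kernel(X, X) + noise * np.eye(len(X))
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return 1e10
    alpha = cho_solve((c, low), yn)
    return float(
        0.5 * yn @ alpha + np.log(np.diag(c)).sum() + 0.5 * len(yn) * np.log(2 * np.pi)
    )


def fit_surrogate(
    X: np.ndarray,
    y: np.ndarray,
    periodic: np.ndarray,
    noise: float = 1e-6,
    n_restarts: int = 3,
    seed: int = 0,
) -> SurrogateModel:
    """Fit hyperparameters by multi-start maximum marginal likelihood.

    ``X`` must already be normalized to the unit cube. Degenerate inputs
    (constant y) collapse to a flat posterior at that constant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 2:
        raise ValueError("need at least two training points")
    if len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least two distinct training points")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite training energies")
    periodic = np.asarray(periodic, dtype=bool)
    d = X.shape[1]

    center = float(np.median(y))
    iqr = float(np.subtract(*np.percentile(y, [75, 25])))
    scale = iqr if iqr > 1e-12 else (float(np.std(y)) or 1.0)
    yn = (y - center) / scale

    # the signal amplitude is bounded below by half the normalized data
    # range: flat-background-dominated samples would otherwise collapse the
    # fitted variance and with it all LCB exploration
    sf_floor = max(0.05, 0.5 * float(yn.max() - yn.min()))
    bounds = [(np.log(0.03), np.log(3.0))] * d + [
        (np.log(sf_floor), np.log(max(20.0, 2.0 * sf_floor)))
    ]
    rng = np.random.default_rng(seed)
    starts = [np.concatenate([np.log(np.full(d, 0.2)), [np.log(max(1.0, sf_floor))]])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        )

    best_theta, best_val = None, np.inf
    for th0 in starts:
        res = minimize(
            _neg_lml,
            th0,
            args=(X, yn, periodic, noise),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 60},
        )
        if res.fun < best_val:
            best_val, best_theta = res.fun, res.x
    assert best_theta is not None

    return SurrogateModel(
        X=X,
        y=y,
        periodic=periodic,
        lengthscales=np.exp(best_theta[:d]),
        signal_sd=float(np.exp(best_theta[d])),
        noise=noise,
        y_center=center,
        y_scale=scale,
    )
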