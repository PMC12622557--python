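"""Active-learning Bayesian optimization over mixed search spaces.

The loop follows the standard surrogate-based global-optimization recipe:
a quasi-random (Sobol) initial design, a GP surrogate refit periodically by
marginal likelihood, and sequential acquisition of the exploratory lower
confidence bound a(x) = μ(x) − κ·σ(x), minimized by seeded multi-start
local optimization. Unphysical or failed evaluations are kept in the
training set with a clamped penalty energy (max observed + 1 eV) so the
surrogate learns to avoid those regions without corrupting the kernel
matrix. Every run is reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .gp import SurrogateModel, fit_surrogate

__all__ = [
    "Dimension",
    "SearchSpace",
    "BOTrace",
    "acquire_next",
    "run_bo",
    "elcb_kappa",
]


def elcb_kappa(t: int, dimension: int, delta: float = 0.1) -> float:
    """Exploratory LCB confidence coefficient, growing with iteration.

    The GP-UCB schedule β_t^0.5 = sqrt(2·log(t^(d/2+2)·π²/(3δ))): a constant
    κ lets a moderately deep, already-tasted well outbid exploration forever,
    whereas the growing coefficient keeps probing uncertain regions late in
    the run. ``t`` is the 1-based evaluation index."""
    t = max(t, 2)
    beta = 2.0 * np.log(t ** (dimension / 2.0 + 2.0) * np.pi**2 / (3.0 * delta))
    return float(np.sqrt(beta))

_KINDS = ("torsion", "translation", "rotation", "generic")


@dataclass(frozen=True)
class Dimension:
    name: str
    kind: str
    lower: float
    upper: float
    periodic: bool

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if not self.upper > self.lower:
            raise ValueError(f"dimension {self.name}: upper must exceed lower")
        if self.kind in ("torsion", "rotation") and not self.periodic:
            raise ValueError(f"dimension {self.name}: angular dims are periodic")


@dataclass
class SearchSpace:
    """Ordered dimensions + a realization map from points to geometries.

    ``invalid_check`` marks realized geometries the sampler should learn to
    avoid (steric clashes, poses outside the interaction shell); they are
    kept in the training set with a clamped penalty energy.
    """

    dims: list[Dimension]
    realize: Callable[[np.ndarray], object] | None = None
    invalid_check: Callable[[object], bool] | None = None

    @property
    def dimension(self) -> int:
        return len(self.dims)

    @property
    def lower(self) -> np.ndarray:
        return np.array([d.lower for d in self.dims])

    @property
    def upper(self) -> np.ndarray:
        return np.array([d.upper for d in self.dims])

    @property
    def periodic(self) -> np.ndarray:
        return np.array([d.periodic for d in self.dims])

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def normalize(self, q: np.ndarray) -> np.ndarray:
        return (np.asarray(q, dtype=float) - self.lower) / self.span

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        return self.lower + np.asarray(u, dtype=float) * self.span

    def wrap(self, q: np.ndarray) -> np.ndarray:
        """Wrap periodic coordinates into their bounds, clip the rest."""
        q = np.array(q, dtype=float)
        per = self.periodic
        q[per] = self.lower[per] + (q[per] - self.lower[per]) % self.span[per]
        q[~per] = np.clip(q[~per], self.lower[~per], self.upper[~per])
        return q

    def periodic_distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Euclidean distance in normalized units, periodic-aware."""
        da = self.normalize(a) - self.normalize(b)
        da = np.atleast_2d(da)
        per = self.periodic
        da[:, per] = (da[:, per] + 0.5) % 1.0 - 0.5
        return np.sqrt((da**2).sum(axis=-1))

    def sobol(self, n: int, seed: int) -> np.ndarray:
        sampler = qmc.Sobol(d=self.dimension, scramble=True, seed=seed)
        n_pow2 = 1 << (max(n - 1, 1)).bit_length()
        return self.denormalize(sampler.random(n_pow2)[:n])


@dataclass
class BOTrace:
    """Iteration log of one BO run."""

    records: pd.DataFrame
    seed: int
    budget: int

    @property
    def best_energy(self) -> float:
        return float(self.records["best"].iloc[-1])

    @property
    def best_point(self) -> np.ndarray:
        ok = self.records[self.records["status"] == "ok"]
        row = ok.loc[ok["energy"].idxmin()]
        return row.filter(like="q").to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False, float_format="%.10g")


def acquire_next(
    model: SurrogateModel,
    space: SearchSpace,
    kappa: float = 2.0,
    seed: int = 0,
    n_starts: int | None = None,
) -> np.ndarray:
    """Minimize the exploratory lower confidence bound μ − κσ.

    Seeded multi-start L-BFGS over the unit cube (periodic dimensions make
    the boundary immaterial); deterministic for a fixed seed. Returns the
    point in raw coordinates.
    """
    d = space.dimension
    n_starts = n_starts or (4 + 2 * d)

    def acq(u: np.ndarray) -> float:
        mu, sd = model.predict(u[None, :])
        return float(mu[0] - kappa * sd[0])

    n_pow2 = 1 << (max(n_starts - 2, 1)).bit_length()
    starts = list(qmc.Sobol(d=d, scramble=True, seed=seed).random(n_pow2)[: n_starts - 1])
    # include the incumbent training minimum as a start
    starts.append(model.X[int(np.argmin(model.y))])
    best_u, best_a = None, np.inf
    for u0 in starts:
        res = minimize(
            acq,
            np.clip(u0, 0.0, 1.0),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d,
            options={"maxiter": 40},
        )
        if res.fun < best_a:
            best_a, best_u = float(res.fun), res.x
    return space.wrap(space.denormalize(best_u))


def run_bo(
    space: SearchSpace,
    calc,
    budget: int,
    init_n: int | None = None,
    kappa: float | str | Callable[[int, int], float] = "elcb",
    seed: int = 0,
    refit_every: int = 10,
    unphysical_check: Callable[[object], bool] | None = None,
) -> tuple[SurrogateModel, BOTrace]:
    """Run the active-learning loop and return surrogate + trace.

    ``kappa`` is either a constant, the string ``"elcb"`` (default: the
    iteration-growing exploratory-LCB schedule of :func:`elcb_kappa`), or a
    callable ``(iteration, dimension) -> float``.

    ``calc.evaluate`` is called on raw search-space points. When
    ``unphysical_check`` is supplied it is applied to the realized geometry;
    flagged or failing evaluations receive a clamped penalty energy and stay
    in the training set. More than 50% failures aborts the run.
    """
    d = space.dimension
    init_n = init_n if init_n is not None else 5 * d
    if not budget >= init_n >= 2:
        raise ValueError("need budget >= init_n >= 2")
    if kappa == "elcb":
        kappa_fn = elcb_kappa
    elif callable(kappa):
        kappa_fn = kappa
    else:
        kappa_fn = lambda t, dim, k=float(kappa): k  # noqa: E731

    X_raw = list(space.sobol(init_n, seed))
    rows = []
    ys: list[float] = []
    statuses: list[str] = []

    check = unphysical_check if unphysical_check is not None else space.invalid_check

    def evaluate(q: np.ndarray) -> tuple[float, str]:
        try:
            if check is not None and space.realize is not None:
                if check(space.realize(q)):
                    return np.nan, "unphysical"
            return float(calc.evaluate(q)), "ok"
        except Exception:
            return np.nan, "failed"

    for q in X_raw:
        e, status = evaluate(q)
        ys.append(e)
        statuses.append(status)

    def clamp(values: list[float], flags: list[str]) -> np.ndarray:
        arr = np.array(values, dtype=float)
        ok = np.array([s == "ok" for s in flags])
        if not ok.any():
            raise RuntimeError("all initial evaluations failed")
        penalty = arr[ok].max() + 1.0
        arr[~ok] = penalty
        return arr

    model = fit_surrogate(
        np.array([space.normalize(q) for q in X_raw]),
        clamp(ys, statuses),
        periodic=space.periodic,
        seed=seed,
    )

    for it in range(init_n, budget):
        if (it - init_n) % refit_every == 0 and it > init_n:
            model = fit_surrogate(
                np.array([space.normalize(q) for q in X_raw]),
                clamp(ys, statuses),
                periodic=space.periodic,
                seed=seed,
            )
        q = acquire_next(model, space, kappa=kappa_fn(it + 1, d), seed=seed + 1000 + it)
        e, status = evaluate(q)
        X_raw.append(q)
        ys.append(e)
        statuses.append(status)
        # unphysical flags are expected and informative; only hard calculator
        # failures count toward the abort threshold
        n_failed = sum(1 for s in statuses if s == "failed")
        if n_failed > 0.5 * len(statuses):
            raise RuntimeError(
                f"aborting: {n_failed}/{len(statuses)} evaluations failed"
            )
        model = model.with_data(
            np.array([space.normalize(p) for p in X_raw]), clamp(ys, statuses)
        )

    y_clamped = clamp(ys, statuses)
    best_so_far = np.minimum.accumulate(
        [y if s == "ok" else np.inf for y, s in zip(ys, statuses)]
    )
    # propagate the first finite best over any leading failures
    best_so_far = np.array(
        [b if np.isfinite(b) else np.nan for b in best_so_far]
    )
    data = {"iteration": np.arange(len(X_raw))}
    for k, dim in enumerate(space.dims):
        data[f"q_{dim.name}"] = [p[k] for p in X_raw]
    data["energy"] = y_clamped
    data["status"] = statuses
    data["best"] = best_so_far
    trace = BOTrace(records=pd.DataFrame(data), seed=seed, budget=budget)
    model = fit_surrogate(
        np.array([space.normalize(q) for q in X_raw]),
        y_clamped,
        periodic=space.periodic,
        seed=seed,
    )
    return model, trace
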