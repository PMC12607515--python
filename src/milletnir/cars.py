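"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

Each Monte Carlo iteration j (j = 1..N):

1. fit a PLS regression on a random 80 % draw of the calibration samples,
   restricted to the currently retained wavelengths, and take the absolute
   regression coefficients |k_i|;
2. forced retention (exponentially decreasing function, EDF): keep the top
   ``ceil(r_j * p)`` wavelengths by |k_i|, where ``r_j = a * exp(-b * j)``
   with a, b fixed by the boundary conditions r_1 = 1 and r_N = 2/p:

       a = (p/2)^(1/(N-1)),     b = ln(p/2)/(N-1);

3. adaptive reweighted sampling (ARS): draw ``ceil(r_j * p)`` wavelengths
   with replacement with probabilities ``w_i = |k_i| / sum |k_i|`` and
   deduplicate — the survivors form the next retained set;
4. score the subset by 10-fold cross-validated RMSECV on the full
   calibration set.

After N iterations the subset with minimal RMSECV wins (earliest iteration
on ties).  The whole run is deterministic given its seed.

The inner PLS is a numpy SIMPLS written for speed (CARS performs thousands
of fits per run); it is cross-checked against scikit-learn's PLSRegression
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EdfSchedule",
    "CarsIterationRecord",
    "CarsResult",
    "edf_schedule",
    "normalized_weights",
    "simpls_coefficients",
    "rmsecv_kfold",
    "run_cars",
    "run_cars_repeated",
    "proportion_of_total",
]


@dataclass
class EdfSchedule:
    """Exponentially decreasing retention-rate schedule."""

    p: int
    n_iterations: int
    a: float
    b: float
    rates: np.ndarray  # r_j for j = 1..N

    def forced_counts(self) -> np.ndarray:
        """Number of wavelengths forcibly retained at each iteration."""
        return np.ceil(self.rates * self.p).astype(int)


def edf_schedule(p: int, n_iterations: int) -> EdfSchedule:
    """Build the EDF schedule with r_1 = 1 and r_N = 2/p."""
    if p <= 2:
        raise ValueError("need p >= 3 (2/p must be < 1)")
    if n_iterations < 2:
        raise ValueError("need at least 2 iterations")
    N = n_iterations
    a = (p / 2.0) ** (1.0 / (N - 1))
    b = np.log(p / 2.0) / (N - 1)
    j = np.arange(1, N + 1)
    rates = a * np.exp(-b * j)
    return EdfSchedule(p=p, n_iterations=N, a=a, b=b, rates=rates)


def normalized_weights(coefs: np.ndarray) -> np.ndarray:
    """ARS sampling weights: w_i = |k_i| / sum |k_i|."""
    coefs = np.asarray(coefs, dtype=float)
    if np.any(coefs < 0):
        raise ValueError("coefficient magnitudes must be non-negative")
    total = coefs.sum()
    if total == 0:
        raise ValueError("all-zero coefficients: weights undefined")
    return coefs / total


def simpls_coefficients(
    X: np.ndarray, y: np.ndarray, ncomp: int
) -> tuple[np.ndarray, float, np.ndarray]:
    """SIMPLS regression of y on X with ``ncomp`` latent components.

    Returns ``(beta, y_mean, x_mean)`` such that predictions are
    ``(Xnew - x_mean) @ beta + y_mean``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    ncomp = min(ncomp, p, n - 1)
    if ncomp < 1:
        raise ValueError("need at least one component")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean

    s = Xc.T @ yc  # p
    R = np.zeros((p, ncomp))
    V = np.zeros((p, ncomp))
    q = np.zeros(ncomp)
    for a in range(ncomp):
        r = s.copy()
        t = Xc @ r
        tnorm = np.linalg.norm(t)
        if tnorm < 1e-14:
            # residual covariance exhausted
            R = R[:, :a]
            q = q[:a]
            break
        t /= tnorm
        r /= tnorm
        p_load = Xc.T @ t
        q[a] = yc @ t
        v = p_load.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p_load)
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-14:
            R[:, a] = r
            R = R[:, : a + 1]
            q = q[: a + 1]
            break
        v /= vnorm
        V[:, a] = v
        R[:, a] = r
        s = s - v * (v @ s)
    beta = R @ q
    return beta, y_mean, x_mean


def rmsecv_kfold(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray | list[int] | None = None,
    k: int = 10,
    ncomp: int = 10,
    seed: int = 0,
) -> float:
    """Root mean square error of k-fold cross-validation on a wavelength
    subset, with a seeded shuffle assigning the folds.

    The per-fold PLS uses ``min(ncomp, |subset|, n_train - 1)`` components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if n < k:
        raise ValueError("fewer samples than folds")
    if subset is None:
        Xs = X
    else:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("empty wavelength subset")
        Xs = X[:, subset]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    sq_errors = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        nc = min(ncomp, Xs.shape[1], mask.sum() - 1)
        beta, y_mean, x_mean = simpls_coefficients(Xs[mask], y[mask], nc)
        pred = (Xs[fold] - x_mean) @ beta + y_mean
        sq_errors[fold] = (y[fold] - pred) ** 2
    return float(np.sqrt(sq_errors.mean()))


@dataclass
class CarsIterationRecord:
    """State after one Monte Carlo iteration."""

    j: int
    retained: np.ndarray  # wavelength indices surviving ARS, sorted
    coefs: np.ndarray  # |k_i| for the retained indices
    weights: np.ndarray  # normalized over the retained indices
    rmsecv: float


@dataclass
class CarsResult:
    """Full CARS trace and the RMSECV-optimal subset."""

    records: list[CarsIterationRecord]
    best_iteration: int  # 1-based j attaining minimal RMSECV
    selected_indices: np.ndarray
    selected_wavelengths: np.ndarray | None
    proportion: float  # 100 * |selected| / p
    schedule: EdfSchedule
    seed: int

    @property
    def rmsecv_trace(self) -> np.ndarray:
        return np.array([rec.rmsecv for rec in self.records])

    @property
    def best_rmsecv(self) -> float:
        return self.records[self.best_iteration - 1].rmsecv

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "best_iteration": self.best_iteration,
            "best_rmsecv": self.best_rmsecv,
            "selected_indices": self.selected_indices.tolist(),
            "selected_wavelengths_nm": (
                None
                if self.selected_wavelengths is None
                else self.selected_wavelengths.tolist()
            ),
            "proportion_percent": self.proportion,
            "edf_a": self.schedule.a,
            "edf_b": self.schedule.b,
            "rmsecv_trace": self.rmsecv_trace.tolist(),
        }


def run_cars(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 500,
    mcs_fraction: float = 0.8,
    k: int = 10,
    ncomp: int = 10,
    seed: int = 0,
    wavelengths: np.ndarray | None = None,
) -> CarsResult:
    """Run CARS on a calibration set.

    Per iteration the generator is consumed in a fixed order (one MCS
    sample draw, then one ARS draw), so the full trace is reproducible
    from the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y are not aligned")
    schedule = edf_schedule(p, n_iterations)
    forced = schedule.forced_counts()
    rng = np.random.default_rng(seed)
    m = max(2, int(round(mcs_fraction * n)))

    retained = np.arange(p)
    records: list[CarsIterationRecord] = []
    for j in range(1, n_iterations + 1):
        sample_idx = rng.choice(n, size=m, replace=False)
        nc = min(ncomp, retained.size, m - 1)
        beta, _, _ = simpls_coefficients(X[np.ix_(sample_idx, retained)], y[sample_idx], nc)
        mags = np.abs(beta)

        n_keep = min(forced[j - 1], retained.size)
        top = np.argsort(mags)[::-1][:n_keep]
        kept = retained[top]
        kept_mags = mags[top]
        if kept_mags.sum() == 0:
            # degenerate fit: fall back to uniform weights over the kept set
            w = np.full(kept.size, 1.0 / kept.size)
        else:
            w = normalized_weights(kept_mags)

        draws = rng.choice(kept.size, size=n_keep, replace=True, p=w)
        survivors = np.unique(draws)
        if survivors.size == 0:  # cannot happen with n_keep >= 1; belt and braces
            survivors = np.array([int(np.argmax(w))])
        next_retained = np.sort(kept[survivors])
        surv_mags = kept_mags[survivors]

        err = rmsecv_kfold(X, y, subset=next_retained, k=k, ncomp=ncomp, seed=seed + j)
        records.append(
            CarsIterationRecord(
                j=j,
                retained=next_retained,
                coefs=surv_mags[np.argsort(kept[survivors])],
                weights=normalized_weights(surv_mags)[np.argsort(kept[survivors])]
                if surv_mags.sum() > 0
                else np.full(survivors.size, 1.0 / survivors.size),
                rmsecv=err,
            )
        )
        retained = next_retained

    traces = np.array([rec.rmsecv for rec in records])
    best = int(np.argmin(traces))  # earliest on ties
    selected = records[best].retained
    return CarsResult(
        records=records,
        best_iteration=best + 1,
        selected_indices=selected,
        selected_wavelengths=None if wavelengths is None else np.asarray(wavelengths)[selected],
        proportion=proportion_of_total(selected.size, p),
        schedule=schedule,
        seed=seed,
    )


def run_cars_repeated(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 50,
    base_seed: int = 0,
    **kwargs,
) -> tuple[CarsResult, list[CarsResult]]:
    """Independent CARS runs with seeds base_seed..base_seed+runs-1;
    returns (the run with minimal RMSECV, all runs)."""
    results = [run_cars(X, y, seed=base_seed + r, **kwargs) for r in range(runs)]
    best = min(results, key=lambda res: res.best_rmsecv)
    return best, results


def proportion_of_total(n_selected: int, p: int) -> float:
    """Selected wavelengths as a percentage of all bands."""
    if not (0 < n_selected <= p):
        raise ValueError("need 0 < n_selected <= p")
    return 100.0 * n_selected / p
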