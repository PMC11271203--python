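"""Per-subject multivariate Granger causality as signed VAR(1) coefficients.

For each target component j the model is

    x_j(t) = sum_i A[i, j] * x_i(t-1) + e_j(t),    t = 2..T,

fitted jointly over all K lagged predictors by least squares (optionally
ridge-regularized).  ``A`` is stored source-major: row i holds the signed
influences of component i on every component at the next sample.

With T on the order of K (e.g. 144 volumes and 114 components) the lagged
design is nearly square and the problem is badly conditioned; the default
unregularized fit then returns the minimum-norm (pseudoinverse) solution and
logs the condition number loudly, and a generalized-cross-validation ridge
heuristic is available for users who prefer a regularized estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import ComponentTimeSeriesSet

logger = logging.getLogger(__name__)

#: Condition number above which the unregularized fit warns and falls back
#: to the minimum-norm solution.
COND_WARN_THRESHOLD = 1e8


@dataclass
class CausalityMatrix:
    """One subject's K x K signed influence coefficients.

    ``coeffs[i, j]`` is the VAR coefficient of component i's previous sample
    in the equation for component j's current sample — row = source,
    column = target.
    """

    coeffs: np.ndarray
    order: int = 1
    subject_id: str | None = None
    ridge_lambda: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[0] != self.coeffs.shape[1]:
            raise ValueError("coeffs must be square")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("coeffs contain non-finite values")

    @property
    def n_components(self) -> int:
        return self.coeffs.shape[0]


def fit_var1(
    timecourses: np.ndarray,
    ridge_lambda: float = 0.0,
    subject_id: str | None = None,
    demean: bool = True,
) -> CausalityMatrix:
    """Fit the lag-1 coefficient matrix of a T x K time-course matrix.

    Columns are demeaned before fitting.  ``ridge_lambda > 0`` solves the
    regularized normal equations; ``ridge_lambda = 0`` (the default) solves
    ordinary least squares, degrading to the minimum-norm solution with a
    logged conditioning warning when the lagged design is (nearly) rank
    deficient.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2:
        raise ValueError("timecourses must be a time x components matrix")
    t, k = tc.shape
    if t < 3:
        raise ValueError("need at least 3 time points to fit a VAR(1)")
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")
    constant = np.flatnonzero(np.ptp(tc, axis=0) == 0)
    if constant.size:
        raise ValueError(
            f"constant time course for component index {constant.tolist()}"
        )
    if demean:
        tc = tc - tc.mean(axis=0)
    x = tc[:-1]  # lagged predictors, rows t-1
    y = tc[1:]   # responses, rows t
    if ridge_lambda > 0:
        gram = x.T @ x + ridge_lambda * np.eye(k)
        coeffs = np.linalg.solve(gram, x.T @ y)
    else:
        cond = np.linalg.cond(x)
        # warn whenever the design is square-ish (< 2 samples per predictor)
        # or numerically ill-conditioned: a 144-volume, 114-component run
        # lands here and must announce that the fit is barely determined
        if t - 1 < 2 * k or cond > COND_WARN_THRESHOLD:
            logger.warning(
                "ill-conditioned VAR(1) design (%d usable samples, %d predictors, "
                "condition number %.3g); returning the minimum-norm solution%s",
                t - 1, k, cond,
                f" for subject {subject_id!r}" if subject_id else "",
            )
        coeffs, *_ = np.linalg.lstsq(x, y, rcond=None)
    return CausalityMatrix(
        coeffs=coeffs, order=1, subject_id=subject_id, ridge_lambda=ridge_lambda
    )


def fit_all_subjects(
    dataset: ComponentTimeSeriesSet,
    ridge_lambda: float = 0.0,
    skip_failures: bool = False,
    demean: bool = True,
) -> list[CausalityMatrix]:
    """Fit one causality matrix per subject, preserving subject order.

    A failing subject aborts the run with a subject-labeled message unless
    ``skip_failures`` is set, in which case the failure is logged and that
    subject is omitted from the output.
    """
    out: list[CausalityMatrix] = []
    for s, subject_id in enumerate(dataset.subject_ids):
        try:
            out.append(
                fit_var1(
                    dataset.data[s],
                    ridge_lambda=ridge_lambda,
                    subject_id=subject_id,
                    demean=demean,
                )
            )
        except ValueError as exc:
            if skip_failures:
                logger.error("skipping subject %r: %s", subject_id, exc)
                continue
            raise ValueError(f"VAR fit failed for subject {subject_id!r}: {exc}") from exc
    return out


def suggest_ridge(
    timecourses: np.ndarray,
    grid: np.ndarray | None = None,
) -> float:
    """Generalized-cross-validation choice of the ridge penalty.

    Minimizes GCV(l) = RSS(l) / (n * (1 - df(l)/n)^2) over a logarithmic
    grid, where df(l) is the effective degrees of freedom of the ridge
    smoother.  Advisory only; the default fit stays unregularized.
    """
    tc = np.asarray(timecourses, dtype=float)
    tc = tc - tc.mean(axis=0)
    x, y = tc[:-1], tc[1:]
    n = x.shape[0]
    svals = np.linalg.svd(x, compute_uv=False)
    if grid is None:
        scale = float(np.median(svals[svals > 0]) ** 2)
        grid = np.logspace(-6, 2, 30) * scale
    best_lam, best_gcv = 0.0, np.inf
    for lam in np.atleast_1d(grid):
        shrink = svals**2 / (svals**2 + lam)
        df = float(shrink.sum())
        gram = x.T @ x + lam * np.eye(x.shape[1])
        resid = y - x @ np.linalg.solve(gram, x.T @ y)
        rss = float((resid**2).sum())
        gcv = rss / (n * (1 - df / n) ** 2) if df < n else np.inf
        if gcv < best_gcv:
            best_lam, best_gcv = float(lam), gcv
    return best_lam
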