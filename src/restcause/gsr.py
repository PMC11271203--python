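"""Global signal regression with mean/scale restoration.

The correction applied to every component signal Y given a subject's global
signal X is: z-score both series, fit the single-regressor least-squares
slope ``a`` (equal to the Pearson correlation for standardized variables),
take the residual, then map the residual back onto Y's original scale:

    eps_normalized = z(Y) - a * z(X)
    corrected      = eps_normalized * sigma_Y + mu_Y

The corrected series keeps Y's mean exactly, is uncorrelated with X, and has
standard deviation sigma_Y * sqrt(1 - r^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ComponentTimeSeriesSet, GlobalSignalSet

#: Default delta degrees of freedom in z-scoring (sample standard deviation).
#: The choice rescales the intermediate standardized residual only; it cancels
#: exactly in the corrected signal.
DEFAULT_DDOF = 1


@dataclass
class GsrResult:
    """Corrected signal plus the fit diagnostics.

    ``slope`` is the standardized regression coefficient and equals ``r``,
    the Pearson correlation between the component signal and the global
    signal; ``mu_y``/``sigma_y`` are the component signal's original mean and
    standard deviation, restored in ``corrected``.
    """

    corrected: np.ndarray
    slope: float
    r: float
    mu_y: float
    sigma_y: float


def zscore(series: np.ndarray, ddof: int = DEFAULT_DDOF, name: str = "series") -> np.ndarray:
    """Standardize to mean 0, standard deviation 1.

    Raises on constant input rather than silently returning zeros: a
    zero-variance signal cannot be standardized and usually indicates a
    broken extraction upstream.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError(f"{name} must be 1-D with at least 2 samples")
    if np.ptp(series) == 0:
        raise ValueError(f"{name} has zero variance and cannot be z-scored")
    sd = series.std(ddof=ddof)
    return (series - series.mean()) / sd


def regress_global(y: np.ndarray, x: np.ndarray, ddof: int = DEFAULT_DDOF) -> GsrResult:
    """Remove the global signal X from component signal Y.

    Both series are standardized, the slope of z(Y) on z(X) is fitted without
    an intercept (analytically zero for centered variables), and the residual
    is denormalized back to Y's mean and standard deviation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"length mismatch: Y has {y.size} samples, X has {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("global signal has no variance")
    mu_y = float(y.mean())
    sigma_y = float(y.std(ddof=ddof))
    zy = zscore(y, ddof=ddof, name="component signal")
    zx = zscore(x, ddof=ddof, name="global signal")
    slope = float(zx @ zy / (zx @ zx))
    eps_normalized = zy - slope * zx
    corrected = eps_normalized * sigma_y + mu_y
    return GsrResult(corrected=corrected, slope=slope, r=slope, mu_y=mu_y, sigma_y=sigma_y)


def apply_gsr(
    dataset: ComponentTimeSeriesSet,
    gs: GlobalSignalSet,
    ddof: int = DEFAULT_DDOF,
) -> ComponentTimeSeriesSet:
    """Regress each subject's global signal out of every component signal."""
    if gs.gs.shape[0] != dataset.n_subjects:
        raise ValueError(
            f"subject mismatch: {dataset.n_subjects} time-series subjects, "
            f"{gs.gs.shape[0]} global signals"
        )
    if gs.gs.shape[1] != dataset.n_timepoints:
        raise ValueError(
            f"time mismatch: {dataset.n_timepoints} volumes, "
            f"global signals have {gs.gs.shape[1]}"
        )
    corrected = np.empty_like(dataset.data)
    for s in range(dataset.n_subjects):
        for k in range(dataset.n_components):
            try:
                corrected[s, :, k] = regress_global(
                    dataset.data[s, :, k], gs.gs[s], ddof=ddof
                ).corrected
            except ValueError as exc:
                raise ValueError(
                    f"GSR failed for subject {dataset.subject_ids[s]!r}, "
                    f"component {dataset.component_ids[k]}: {exc}"
                ) from exc
    return ComponentTimeSeriesSet(
        data=corrected,
        tr_seconds=dataset.tr_seconds,
        subject_ids=list(dataset.subject_ids),
        component_ids=list(dataset.component_ids),
    )
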