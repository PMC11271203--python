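"""Synthetic multi-subject component time series with known causal structure.

Every downstream stage of the pipeline (global signal regression, VAR(1)
causality estimation, aggregation, directional reporting) is testable against
data generated here, because the directed influence matrix, the noise level,
and the global-signal coupling are all known exactly.

The generative model for each subject is a stationary first-order vector
autoregression with an additive shared global signal:

    x_t = A_s' x_{t-1} + g_t * gs_gain + e_t

where ``A_s`` is the subject's (possibly jittered) coefficient matrix stored
source-major (``A[i, j]`` = influence of component i at lag 1 on component j),
``g_t`` is an AR(1) global signal shared by all components of a subject, and
``e_t`` is independent Gaussian innovation noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: AR(1) coefficient of the simulated global signal.  Slow drift of the
#: whole-brain average is emulated with a strongly autocorrelated process;
#: innovations are scaled so the stationary variance is 1.
GS_AR_COEFF = 0.9

#: Burn-in samples discarded so the recorded series start near stationarity.
DEFAULT_BURN_IN = 100

#: Sampling interval of the emulated acquisition, in seconds.
DEFAULT_TR_SECONDS = 2.5


def spectral_radius(matrix: np.ndarray) -> float:
    """Largest absolute eigenvalue of ``matrix``."""
    return float(np.max(np.abs(np.linalg.eigvals(matrix))))


@dataclass
class GroundTruth:
    """True generative parameters of a synthetic dataset.

    Parameters
    ----------
    true_matrix
        K x K coefficients, row = source component, column = target
        component; the diagonal holds self-coupling.  The transition matrix
        of the VAR (its transpose) must have spectral radius < 1 so the
        process is stationary.
    noise_sd
        Innovation standard deviation, scalar or per component; must be > 0.
    gs_gain
        Coupling of the shared global signal into each component (scalar or
        per component).  Zero disables the global signal's influence.
    subject_jitter_sd
        Standard deviation of the Gaussian perturbation added independently
        to every coefficient for every subject, emulating between-subject
        variability.
    seed
        Seed of the generator; identical parameters and seed reproduce the
        dataset bit for bit.
    """

    true_matrix: np.ndarray
    noise_sd: np.ndarray | float = 1.0
    gs_gain: np.ndarray | float = 0.0
    subject_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_matrix = np.asarray(self.true_matrix, dtype=float)
        if self.true_matrix.ndim != 2 or self.true_matrix.shape[0] != self.true_matrix.shape[1]:
            raise ValueError("true_matrix must be square")
        k = self.true_matrix.shape[0]
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (k,)).copy()
        self.gs_gain = np.broadcast_to(np.asarray(self.gs_gain, dtype=float), (k,)).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive for every component")
        if self.subject_jitter_sd < 0:
            raise ValueError("subject_jitter_sd must be nonnegative")
        radius = spectral_radius(self.true_matrix)
        if radius >= 1.0:
            raise ValueError(
                f"true_matrix is non-stationary: spectral radius {radius:.4f} >= 1"
            )

    @property
    def n_components(self) -> int:
        return self.true_matrix.shape[0]


@dataclass
class ComponentTimeSeriesSet:
    """Per-subject matrices of component signals over time (S x T x K)."""

    data: np.ndarray
    tr_seconds: float = DEFAULT_TR_SECONDS
    subject_ids: list[str] = field(default_factory=list)
    component_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be a subjects x time x components array")
        s, t, k = self.data.shape
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:02d}" for i in range(s)]
        if not self.component_ids:
            self.component_ids = list(range(1, k + 1))
        if len(self.subject_ids) != s:
            raise ValueError("subject_ids length does not match data")
        if len(self.component_ids) != k:
            raise ValueError("component_ids length does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_components(self) -> int:
        return self.data.shape[2]


@dataclass
class GlobalSignalSet:
    """One global-signal vector per subject (S x T)."""

    gs: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gs = np.asarray(self.gs, dtype=float)
        if self.gs.ndim != 2:
            raise ValueError("gs must be a subjects x time array")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:02d}" for i in range(self.gs.shape[0])]
        if not np.all(np.isfinite(self.gs)):
            raise ValueError("global signals contain non-finite values")


def null_truth(n_components: int, noise_sd: float = 1.0, seed: int = 0) -> GroundTruth:
    """All-zero influence matrix: every component is white noise."""
    return GroundTruth(
        true_matrix=np.zeros((n_components, n_components)),
        noise_sd=noise_sd,
        seed=seed,
    )


def dominant_source_truth(
    n_components: int,
    source: int = 0,
    coupling: float = 0.35,
    self_coupling: float = 0.3,
    noise_sd: float = 1.0,
    gs_gain: float = 0.0,
    subject_jitter_sd: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Truth with one component driving all others.

    The ``source`` component (0-based index) influences every other component
    with coefficient ``coupling``; all components share the same
    self-coupling.  Because the cross terms form a rank-1 perturbation
    orthogonal to the diagonal, the spectral radius equals ``self_coupling``.
    """
    a = np.eye(n_components) * self_coupling
    a[source, :] = coupling
    a[source, source] = self_coupling
    return GroundTruth(
        true_matrix=a,
        noise_sd=noise_sd,
        gs_gain=gs_gain,
        subject_jitter_sd=subject_jitter_sd,
        seed=seed,
    )


def _subject_matrices(ground_truth: GroundTruth, n_subjects: int, rng: np.random.Generator) -> np.ndarray:
    """Per-subject coefficient matrices, jittered and kept stationary."""
    k = ground_truth.n_components
    a = np.broadcast_to(ground_truth.true_matrix, (n_subjects, k, k)).copy()
    if ground_truth.subject_jitter_sd > 0:
        a += rng.normal(0.0, ground_truth.subject_jitter_sd, size=(n_subjects, k, k))
        for s in range(n_subjects):
            radius = spectral_radius(a[s])
            if radius >= 0.999:
                # jitter pushed this subject out of the stationary region;
                # shrink back rather than aborting the whole draw
                a[s] *= 0.95 / radius
                logger.warning(
                    "subject %d coefficient matrix rescaled: jittered spectral "
                    "radius %.3f", s, radius,
                )
    return a


def generate_var_timeseries(
    n_subjects: int,
    n_timepoints: int,
    n_components: int,
    ground_truth: GroundTruth,
    burn_in: int = DEFAULT_BURN_IN,
    tr_seconds: float = DEFAULT_TR_SECONDS,
) -> tuple[ComponentTimeSeriesSet, GlobalSignalSet]:
    """Simulate S subjects' component time courses and global signals.

    Each subject follows ``x_t = A_s' x_{t-1} + g_t * gs_gain + e_t`` with
    independent Gaussian innovations; the first ``burn_in`` samples are
    discarded so that recorded samples are drawn near the stationary
    distribution.  Identical inputs and seed reproduce the output exactly.
    """
    if n_subjects <= 0 or n_components <= 0:
        raise ValueError("n_subjects and n_components must be positive")
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be at least 10")
    if ground_truth.n_components != n_components:
        raise ValueError(
            f"ground_truth is for {ground_truth.n_components} components, "
            f"requested {n_components}"
        )

    rng = np.random.default_rng(ground_truth.seed)
    a = _subject_matrices(ground_truth, n_subjects, rng)
    total = burn_in + n_timepoints

    gs_innov_sd = np.sqrt(1.0 - GS_AR_COEFF**2)  # unit stationary variance
    gs_innov = rng.normal(0.0, gs_innov_sd, size=(n_subjects, total))
    noise = rng.normal(0.0, 1.0, size=(n_subjects, total, n_components)) * ground_truth.noise_sd

    gs = np.empty((n_subjects, total))
    gs[:, 0] = gs_innov[:, 0]
    for t in range(1, total):
        gs[:, t] = GS_AR_COEFF * gs[:, t - 1] + gs_innov[:, t]

    out = np.empty((n_subjects, total, n_components))
    x = np.zeros((n_subjects, n_components))
    for t in range(total):
        x = (
            np.einsum("sij,si->sj", a, x)
            + gs[:, t, None] * ground_truth.gs_gain
            + noise[:, t]
        )
        out[:, t] = x

    ts = ComponentTimeSeriesSet(data=out[:, burn_in:, :], tr_seconds=tr_seconds)
    gss = GlobalSignalSet(gs=gs[:, burn_in:], subject_ids=list(ts.subject_ids))
    return ts, gss


def _blob_maps(
    grid_shape: tuple[int, int, int],
    n_components: int,
    rng: np.random.Generator,
    max_pairwise_corr: float = 0.5,
    max_tries: int = 100,
) -> np.ndarray:
    """Smooth Gaussian-blob spatial maps with bounded pairwise correlation."""
    coords = np.stack(
        np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    n_voxels = coords.shape[0]
    width = max(min(grid_shape) / 5.0, 1.0)
    for _ in range(max_tries):
        centers = rng.uniform(0, np.array(grid_shape) - 1, size=(n_components, 3))
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        maps = np.exp(-d2 / (2 * width**2))
        c = np.corrcoef(maps.T)
        if n_components == 1 or np.max(np.abs(c[~np.eye(n_components, dtype=bool)])) < max_pairwise_corr:
            return maps
    raise RuntimeError(
        f"could not place {n_components} blobs with pairwise correlation "
        f"< {max_pairwise_corr} in grid {grid_shape}; use a larger grid"
    )


def generate_volumetric_dataset(
    n_subjects: int,
    grid_shape: tuple[int, int, int],
    n_components: int,
    ground_truth: GroundTruth,
    n_timepoints: int = 60,
    voxel_noise_sd: float = 0.1,
    burn_in: int = DEFAULT_BURN_IN,
) -> tuple[np.ndarray, list[np.ndarray], ComponentTimeSeriesSet, GlobalSignalSet]:
    """Compose small volumetric datasets from blob maps and VAR time courses.

    Returns ``(group_maps, subject_data, true_timeseries, global_signals)``
    where ``group_maps`` is voxels x K, each entry of ``subject_data`` is a
    voxels x T matrix ``maps @ timecourses.T`` plus Gaussian voxel noise, and
    the true time courses are returned for oracle comparisons against
    stage-1 dual regression.
    """
    n_voxels = int(np.prod(grid_shape))
    if n_components > n_voxels:
        raise ValueError(
            f"{n_components} components exceed {n_voxels} voxels in grid {grid_shape}"
        )
    ts, gss = generate_var_timeseries(
        n_subjects, n_timepoints, n_components, ground_truth, burn_in=burn_in
    )
    # reproducible but distinct stream for the spatial part
    rng = np.random.default_rng(np.random.SeedSequence([int(ground_truth.seed), 1]))
    maps = _blob_maps(grid_shape, n_components, rng)
    subject_data = []
    for s in range(n_subjects):
        clean = maps @ ts.data[s].T
        noisy = clean + rng.normal(0.0, voxel_noise_sd, size=clean.shape) if voxel_noise_sd > 0 else clean
        subject_data.append(noisy)
    return maps, subject_data, ts, gss
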