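"""Rational DSP replica of the interpreted solver network.

The descrambled network decomposes into recognizable signal-processing
stages: a zero-frequency notch (baseline removal), a low-pass filter
(denoising), and a regularized linear time-distance transform.  This
module rebuilds that pipeline from standard components: linear-phase FIR
filters applied forward-backward (zero phase, so the dipolar oscillation
phase survives), followed by a matrix ``T`` fitted as the Tikhonov-
regularized pseudoinverse mapping a library of filtered traces to their
known distance distributions,

    T = (F F^T + lambda 1)^{-1} F P^T  (transposed),

with the regularization parameter chosen at the corner of the L-curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .forward_model import (DatasetConfig, Dataset, DeerTrace, DistanceDistribution,
                            DistanceGrid, TimeGrid)

__all__ = [
    "FirFilterSpec",
    "TimeDistanceTransform",
    "ReplicaResult",
    "FilterDesignError",
    "design_fir",
    "apply_filter",
    "build_transform",
    "lcurve_lambda",
    "replica_pipeline",
    "train_transform",
    "default_notch_spec",
    "default_lowpass_spec",
    "small_notch_spec",
    "small_lowpass_spec",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = np.logspace(-6, 2, 40)


class FilterDesignError(RuntimeError):
    """Raised when no FIR design meets the requested band edges."""


@dataclass(frozen=True)
class FirFilterSpec:
    """Linear-phase FIR band specification; frequencies normalized to Nyquist = 1."""

    kind: str                # highpass_notch | lowpass
    order: int               # tap count - 1
    passband_edge: float
    stopband_edge: float

    def __post_init__(self) -> None:
        if self.kind not in ("highpass_notch", "lowpass"):
            raise ValueError("kind must be highpass_notch or lowpass")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        for edge in (self.passband_edge, self.stopband_edge):
            if not 0 < edge < 1:
                raise ValueError("band edges must lie in (0, 1)")
        if self.kind == "highpass_notch" and not self.stopband_edge < self.passband_edge:
            raise ValueError("notch needs stopband_edge < passband_edge")
        if self.kind == "lowpass" and not self.passband_edge < self.stopband_edge:
            raise ValueError("lowpass needs passband_edge < stopband_edge")


def default_notch_spec() -> FirFilterSpec:
    """Zero-frequency notch: order 256 high-pass, passband 0.008, stopband 0.001."""
    return FirFilterSpec("highpass_notch", 256, passband_edge=0.008, stopband_edge=0.001)


def default_lowpass_spec() -> FirFilterSpec:
    """Denoising low-pass: order 32, passband 0.01, stopband 0.3."""
    return FirFilterSpec("lowpass", 32, passband_edge=0.01, stopband_edge=0.3)


def small_notch_spec() -> FirFilterSpec:
    """Notch rescaled for 64-point traces (same physical role, fewer samples)."""
    return FirFilterSpec("highpass_notch", 32, passband_edge=0.1, stopband_edge=0.01)


def small_lowpass_spec() -> FirFilterSpec:
    """Low-pass rescaled for 64-point traces."""
    return FirFilterSpec("lowpass", 16, passband_edge=0.35, stopband_edge=0.75)


def design_fir(spec: FirFilterSpec) -> np.ndarray:
    """Equiripple (Parks-McClellan) linear-phase FIR taps for the spec,
    falling back to least-squares if the exchange does not converge.

    The passband is weighted 3:1 over the stopband so the passband
    deviation stays small even for tight transition bands; for the notch
    kind an exact zero at DC is enforced by removing the tap mean.
    """
    numtaps = spec.order + 1
    if spec.kind == "highpass_notch":
        bands = [0.0, spec.stopband_edge, spec.passband_edge, 1.0]
        desired = [0.0, 1.0]
        weight = [1.0, 3.0]
    else:
        bands = [0.0, spec.passband_edge, spec.stopband_edge, 1.0]
        desired = [1.0, 0.0]
        weight = [3.0, 1.0]
    taps = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            taps = sps.remez(numtaps, bands, desired, weight=weight, fs=2.0)
    except Exception:
        taps = None
    if taps is None or not np.all(np.isfinite(taps)):
        try:
            if numtaps % 2 == 0:
                numtaps += 1  # firls requires an odd tap count (Type I)
            desired_ls = [desired[0], desired[0], desired[1], desired[1]]
            taps = sps.firls(numtaps, bands, desired_ls, weight=weight, fs=2.0)
        except Exception as err:
            raise FilterDesignError(f"no FIR design met {spec}") from err
    if not np.all(np.isfinite(taps)):
        raise FilterDesignError(f"FIR design diverged for {spec}")
    if spec.kind == "highpass_notch":
        taps = taps - taps.mean()  # exact zero at DC
    _validate_response(taps, spec)
    return taps


def _validate_response(taps: np.ndarray, spec: FirFilterSpec) -> None:
    """Reject designs whose order is too low for the requested transition band."""
    w, h = sps.freqz(taps, worN=4096, fs=2.0)
    mag = np.abs(h)
    if spec.kind == "highpass_notch":
        passband, stopband = mag[w >= spec.passband_edge], mag[w <= spec.stopband_edge]
    else:
        passband, stopband = mag[w <= spec.passband_edge], mag[w >= spec.stopband_edge]
    if passband.size and passband.min() < 0.5:
        raise FilterDesignError(
            f"{spec}: passband collapses (min |H| = {passband.min():.3f}); "
            "increase the order or widen the transition band")
    if stopband.size and stopband.max() > 0.5:
        raise FilterDesignError(
            f"{spec}: stopband leaks (max |H| = {stopband.max():.3f}); "
            "increase the order or widen the transition band")


def frequency_response(taps: np.ndarray, n_points: int = 2048):
    """(frequencies normalized to Nyquist = 1, complex response)."""
    w, h = sps.freqz(taps, worN=n_points, fs=2.0)
    return w, h


def apply_filter(trace: DeerTrace, taps: np.ndarray) -> DeerTrace:
    """Zero-phase (forward-backward) FIR filtering of a trace."""
    taps = np.asarray(taps, dtype=float)
    n = trace.grid.n
    if n <= taps.size - 1:
        raise ValueError(f"trace of {n} points is not longer than filter order {taps.size - 1}")
    padlen = min(3 * taps.size, n - 1)
    values = sps.filtfilt(taps, [1.0], trace.values, padlen=padlen)
    return DeerTrace(grid=trace.grid, values=values, kind=trace.kind)


@dataclass(frozen=True)
class TimeDistanceTransform:
    """Regularized pseudoinverse T mapping (filtered) traces to distributions."""

    t_matrix: np.ndarray       # n_dist x n_time
    lam: float
    solutions: np.ndarray      # F: filtered traces as columns (n_time x n)
    target_matrix: np.ndarray  # distributions as columns (n_dist x n)

    def __post_init__(self) -> None:
        F, T, Pmat = self.solutions, self.t_matrix, self.target_matrix
        lhs = T @ (F @ F.T + self.lam * np.eye(F.shape[0]))
        rhs = Pmat @ F.T
        scale = max(1.0, np.linalg.norm(rhs))
        if np.linalg.norm(lhs - rhs) > 1e-8 * scale:
            raise ValueError("transform does not satisfy its normal equations")


def build_transform(F: np.ndarray, targets: np.ndarray, lam: float) -> TimeDistanceTransform:
    """Solve the ridge problem  min ||T F - targets||_F^2 + lam ||T||_F^2 :
    ``T = ((F F^T + lam 1)^{-1} F targets^T)^T``."""
    F = np.asarray(F, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if F.shape[1] != targets.shape[1]:
        raise ValueError("solutions and targets must have equal column counts")
    if lam < 0:
        raise ValueError("regularization parameter must be nonnegative")
    gram = F @ F.T + lam * np.eye(F.shape[0])
    if lam == 0 and np.linalg.matrix_rank(F @ F.T) < F.shape[0]:
        raise np.linalg.LinAlgError(
            "F F^T is rank deficient; use lambda > 0 to regularize")
    T = np.linalg.solve(gram, F @ targets.T).T
    return TimeDistanceTransform(t_matrix=T, lam=float(lam),
                                 solutions=F, target_matrix=targets)


def lcurve_lambda(F: np.ndarray, targets: np.ndarray,
                  lambda_grid=DEFAULT_LAMBDA_GRID) -> float:
    """L-curve corner: the lambda of maximum curvature of the
    (log residual norm, log solution norm) curve over the grid."""
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if np.any(lambda_grid <= 0) or np.any(np.diff(lambda_grid) <= 0):
        raise ValueError("lambda grid must be positive and sorted ascending")
    if lambda_grid.size < 3:
        warnings.warn("lambda grid shorter than 3: returning the first value")
        return float(lambda_grid[0])
    F = np.asarray(F, dtype=float)
    targets = np.asarray(targets, dtype=float)
    # eigendecompose F F^T once; each lambda is then a diagonal reweighting
    gram = F @ F.T
    evals, evecs = np.linalg.eigh(gram)
    B = evecs.T @ (F @ targets.T)       # n_time x n_dist
    rho, eta = [], []
    for lam in lambda_grid:
        coeff = B / (evals + lam)[:, None]
        T = (evecs @ coeff).T
        rho.append(np.linalg.norm(T @ F - targets))
        eta.append(np.linalg.norm(T))
    x = np.log10(np.maximum(rho, 1e-300))
    y = np.log10(np.maximum(eta, 1e-300))
    s = np.log10(lambda_grid)
    dx, dy = np.gradient(x, s), np.gradient(y, s)
    ddx, ddy = np.gradient(dx, s), np.gradient(dy, s)
    denom = (dx * dx + dy * dy) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curvature = (dx * ddy - dy * ddx) / denom
    curvature[~np.isfinite(curvature)] = -np.inf
    interior = curvature[1:-1]
    return float(lambda_grid[1 + int(np.argmax(interior))])


@dataclass(frozen=True)
class ReplicaResult:
    """Distance-distribution estimate from the replica pipeline."""

    values: np.ndarray          # nonnegative density estimate (may be all zero)
    grid: DistanceGrid
    normalized: bool            # False when the estimate had no mass to normalize

    @property
    def distribution(self) -> DistanceDistribution:
        if not self.normalized:
            raise ValueError("estimate has zero mass; no distribution available")
        return DistanceDistribution(self.grid, self.values)


def replica_pipeline(trace: DeerTrace, notch_taps: np.ndarray,
                     lowpass_taps: np.ndarray,
                     transform: TimeDistanceTransform,
                     dgrid: DistanceGrid) -> ReplicaResult:
    """Low-pass -> notch -> time-distance transform -> clip -> renormalize."""
    filtered = apply_filter(apply_filter(trace, lowpass_taps), notch_taps)
    raw = transform.t_matrix @ filtered.values
    values = np.clip(raw, 0.0, None)
    mass = np.trapezoid(values, dx=dgrid.step)
    if mass <= 0:
        warnings.warn("replica estimate has zero mass; renormalization skipped")
        return ReplicaResult(values=values, grid=dgrid, normalized=False)
    return ReplicaResult(values=values / mass, grid=dgrid, normalized=True)


def filter_trace(trace: DeerTrace, notch_taps: np.ndarray,
                 lowpass_taps: np.ndarray) -> DeerTrace:
    """The filtering front end of the pipeline (low-pass then notch)."""
    return apply_filter(apply_filter(trace, lowpass_taps), notch_taps)


def train_transform(dataset: Dataset, notch_taps: np.ndarray,
                    lowpass_taps: np.ndarray,
                    lam: float = None,
                    lambda_grid=DEFAULT_LAMBDA_GRID) -> TimeDistanceTransform:
    """Fit T on the dataset's filtered traces; lambda from the L-curve
    unless given explicitly."""
    filtered = np.column_stack([
        filter_trace(rec.trace, notch_taps, lowpass_taps).values
        for rec in dataset.records
    ])
    if lam is None:
        lam = lcurve_lambda(filtered, dataset.targets, lambda_grid)
    return build_transform(filtered, dataset.targets, lam)
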