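"""DEER dipolar physics and synthetic data generation.

Double electron-electron resonance (DEER/PELDOR) measures the magnetic
dipolar coupling between pairs of spin labels attached to a biomolecule.
For an isolated pair at distance ``r`` the orientation-averaged echo
modulation is the dipolar kernel ``gamma(r, t)``, expressible through
Fresnel integrals.  For an ensemble of pairs with distance probability
density ``p(r)`` the observed form factor is the Fredholm integral of the
first kind

    Gamma(t) = integral p(r) * gamma(r, t) dr,

whose inversion for ``p(r)`` is the ill-posed problem the solver networks
in this package are trained on.  This module provides the kernel, the
discretized forward map, and a seeded generator of realistic synthetic
records (mixture-of-Gaussian distance distributions composed with an
exponential intermolecular background, a modulation depth, and white
noise) with known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

__all__ = [
    "PhysicalConstants",
    "CODATA",
    "DistanceGrid",
    "TimeGrid",
    "DistanceDistribution",
    "DipolarKernel",
    "DeerTrace",
    "SyntheticRecord",
    "Dataset",
    "DistributionParams",
    "DatasetConfig",
    "dipolar_coupling",
    "kernel_value",
    "build_kernel",
    "fredholm_forward",
    "sample_distribution",
    "corrupt_trace",
    "generate_dataset",
    "full_grids",
    "small_grids",
    "default_config",
]

# below this value of D*t the closed form is replaced by its analytic
# limit gamma -> 1 to avoid 0/0 (error is O((D*t)^2) ~ 1e-12)
_SMALL_DT = 1e-6


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants entering the dipolar coupling, SI units."""

    mu0: float = 1.25663706212e-6       # vacuum permeability, N A^-2
    hbar: float = 1.054571817e-34       # reduced Planck constant, J s
    gamma_e: float = 1.76085963023e11   # electron magnetogyric ratio, rad s^-1 T^-1

    def __post_init__(self) -> None:
        if not (self.mu0 > 0 and self.hbar > 0 and self.gamma_e > 0):
            raise ValueError("physical constants must be strictly positive")


CODATA = PhysicalConstants()


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform distance grid in nanometres."""

    r_min: float
    r_max: float
    n: int

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ValueError(f"require 0 < r_min < r_max, got [{self.r_min}, {self.r_max}]")
        if self.n < 2:
            raise ValueError("distance grid needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_max, self.n)

    @property
    def step(self) -> float:
        return (self.r_max - self.r_min) / (self.n - 1)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid in microseconds, starting exactly at zero."""

    t_max: float
    n: int

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.n < 2:
            raise ValueError("time grid needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n)

    @property
    def step(self) -> float:
        return self.t_max / (self.n - 1)


@dataclass(frozen=True)
class DistanceDistribution:
    """Probability density per nm on a :class:`DistanceGrid` (unit trapezoidal mass)."""

    grid: DistanceGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n,):
            raise ValueError("density length does not match grid")
        if np.any(values < 0):
            raise ValueError("density must be nonnegative")
        mass = np.trapezoid(values, dx=self.grid.step)
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"density must integrate to 1, got {mass}")

    @classmethod
    def from_unnormalized(cls, grid: DistanceGrid, values: np.ndarray) -> "DistanceDistribution":
        values = np.clip(np.asarray(values, dtype=float), 0.0, None)
        mass = np.trapezoid(values, dx=grid.step)
        if mass <= 0:
            raise ValueError("cannot normalize a zero density")
        return cls(grid, values / mass)

    def mean(self) -> float:
        r = self.grid.values
        return float(np.trapezoid(r * self.values, dx=self.grid.step))

    def std(self) -> float:
        r = self.grid.values
        m = self.mean()
        var = float(np.trapezoid((r - m) ** 2 * self.values, dx=self.grid.step))
        return math.sqrt(max(var, 0.0))


@dataclass(frozen=True)
class DipolarKernel:
    """Discretized kernel matrix ``gamma(r_j, t_i)`` (n_time x n_dist, unitless)."""

    matrix: np.ndarray
    dgrid: DistanceGrid
    tgrid: TimeGrid

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (self.tgrid.n, self.dgrid.n):
            raise ValueError("kernel shape does not match grids")


@dataclass(frozen=True)
class DeerTrace:
    """Unitless amplitude on a :class:`TimeGrid`."""

    grid: TimeGrid
    values: np.ndarray
    kind: str = "clean_form_factor"  # clean_form_factor | with_baseline | noisy

    _KINDS = ("clean_form_factor", "with_baseline", "noisy")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n,):
            raise ValueError("trace length does not match grid")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown trace kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticRecord:
    """One (noisy trace, true distribution) pair plus its nuisance parameters."""

    trace: DeerTrace
    truth: DistanceDistribution
    k_bg: float      # background decay rate, us^-1
    depth: float     # modulation depth, in (0, 1)
    sigma: float     # white-noise standard deviation
    seed: int


@dataclass(frozen=True)
class Dataset:
    """Columns of corrupted traces (inputs X) paired with true densities (targets)."""

    inputs: np.ndarray   # n_time x n_records
    targets: np.ndarray  # n_dist x n_records
    records: tuple
    dgrid: DistanceGrid
    tgrid: TimeGrid

    def __post_init__(self) -> None:
        if self.inputs.shape[1] != self.targets.shape[1]:
            raise ValueError("inputs and targets must have equal column counts")


def dipolar_coupling(r, constants: PhysicalConstants = CODATA):
    """Dipolar coupling D = mu0 gamma_e^2 hbar / (4 pi r^3) in rad/us for r in nm.

    For a pair of electrons at 1 nm this is about 327 rad/us
    (nu = D / 2 pi ~ 52 MHz), the textbook electron-electron dipolar constant.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    r_m = r * 1e-9
    d_si = constants.mu0 * constants.gamma_e**2 * constants.hbar / (4 * np.pi * r_m**3)
    out = d_si * 1e-6  # rad/s -> rad/us
    return out if out.ndim else float(out)


def kernel_value(r, t, constants: PhysicalConstants = CODATA):
    """Orientation-averaged dipolar kernel gamma(r, t) via Fresnel integrals.

    Equal to the powder average ``int_0^1 cos((3 z^2 - 1) D t) dz`` with
    z = cos(theta); the closed form uses the Fresnel integrals in the
    pi/2-argument convention of :func:`scipy.special.fresnel`:

        gamma = sqrt(pi / (6 D t)) * [cos(Dt) C(x) + sin(Dt) S(x)],
        x = sqrt(6 D t / pi).

    At t = 0 the analytic limit 1 is returned without evaluating 0/0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    d = np.asarray(dipolar_coupling(r, constants), dtype=float)
    dt = d * t
    small = dt < _SMALL_DT
    dt_safe = np.where(small, 1.0, dt)
    x = np.sqrt(6.0 * dt_safe / np.pi)
    fr_s, fr_c = special.fresnel(x)
    val = (np.cos(dt_safe) * fr_c + np.sin(dt_safe) * fr_s) / x
    out = np.where(small, 1.0, val)
    return out if out.ndim else float(out)


def build_kernel(dgrid: DistanceGrid, tgrid: TimeGrid,
                 constants: PhysicalConstants = CODATA) -> DipolarKernel:
    """Assemble the n_time x n_dist kernel matrix on the given grids."""
    r = dgrid.values[None, :]
    t = tgrid.values[:, None]
    matrix = kernel_value(r, t, constants)
    return DipolarKernel(matrix=matrix, dgrid=dgrid, tgrid=tgrid)


def fredholm_forward(p: DistanceDistribution, k: DipolarKernel) -> DeerTrace:
    """Clean form factor Gamma(t) by trapezoidal quadrature of the Fredholm integral."""
    if p.grid != k.dgrid:
        raise ValueError("distribution grid does not match kernel distance grid")
    w = np.full(k.dgrid.n, k.dgrid.step)
    w[0] *= 0.5
    w[-1] *= 0.5
    values = k.matrix @ (w * p.values)
    return DeerTrace(grid=k.tgrid, values=values, kind="clean_form_factor")


@dataclass(frozen=True)
class DistributionParams:
    """Sampling ranges for the mixture-of-Gaussians distance distributions."""

    n_components: tuple = (1, 3)       # inclusive range of mixture sizes
    position_range: tuple = (2.2, 6.8)  # nm, must lie inside the grid
    width_range: tuple = (0.15, 0.4)   # nm


def sample_distribution(rng_seed, params: DistributionParams,
                        grid: DistanceGrid) -> DistanceDistribution:
    """Draw a mixture of 1-3 truncated Gaussians on the grid, renormalized.

    ``rng_seed`` may be an integer seed or an existing ``numpy`` Generator.
    """
    lo, hi = params.position_range
    if not (grid.r_min <= lo < hi <= grid.r_max):
        raise ValueError("position range must lie within the distance grid")
    wlo, whi = params.width_range
    if not (0 < wlo <= whi):
        raise ValueError("width range must be positive")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = int(rng.integers(params.n_components[0], params.n_components[1] + 1))
    weights = rng.uniform(0.2, 1.0, size=n)
    weights /= weights.sum()
    centers = rng.uniform(lo, hi, size=n)
    widths = rng.uniform(wlo, whi, size=n)
    r = grid.values
    values = np.zeros_like(r)
    for w, c, s in zip(weights, centers, widths):
        values += w * np.exp(-0.5 * ((r - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
    return DistanceDistribution.from_unnormalized(grid, values)


def corrupt_trace(clean: DeerTrace, depth: float, k_bg: float, sigma: float,
                  rng_seed) -> DeerTrace:
    """Compose background, modulation depth and noise onto a clean form factor.

    Returns ``B(t) * (1 - depth * (1 - Gamma(t))) + eps`` with the canonical
    three-dimensional homogeneous spin-bath background ``B(t) = exp(-k_bg t)``
    and iid Gaussian noise of standard deviation ``sigma``.
    """
    if not (0 < depth < 1):
        raise ValueError("modulation depth must be in (0, 1)")
    if k_bg < 0:
        raise ValueError("background decay rate must be nonnegative")
    if sigma < 0:
        raise ValueError("noise level must be nonnegative")
    t = clean.grid.values
    baseline = np.exp(-k_bg * t)
    values = baseline * (1.0 - depth * (1.0 - clean.values))
    kind = "with_baseline"
    if sigma > 0:
        rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
        values = values + rng.normal(0.0, sigma, size=values.shape)
        kind = "noisy"
    return DeerTrace(grid=clean.grid, values=values, kind=kind)


@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for synthetic record generation."""

    dgrid: DistanceGrid
    tgrid: TimeGrid
    distribution: DistributionParams = field(default_factory=DistributionParams)
    depth_range: tuple = (0.15, 0.5)
    k_bg_range: tuple = (0.02, 0.25)   # us^-1
    sigma_range: tuple = (0.005, 0.03)


def full_grids() -> tuple:
    """Default grids: 256 points on [0, 3.2] us and 256 on [1.5, 8] nm."""
    return DistanceGrid(1.5, 8.0, 256), TimeGrid(3.2, 256)


def small_grids() -> tuple:
    """Reduced-scale grids (64 points) used for fast pipelines and tests.

    The time step keeps the fastest dipolar component at r_min below Nyquist.
    """
    return DistanceGrid(2.5, 6.5, 64), TimeGrid(2.56, 64)


def default_config(dgrid: DistanceGrid, tgrid: TimeGrid) -> DatasetConfig:
    """Default nuisance/distribution ranges, with component positions kept
    away from the grid edges so truncation stays negligible."""
    lo = dgrid.r_min + 0.7
    hi = dgrid.r_max - 1.2
    params = DistributionParams(position_range=(lo, hi))
    return DatasetConfig(dgrid=dgrid, tgrid=tgrid, distribution=params)


def _make_record(seed: int, config: DatasetConfig, kernel: DipolarKernel) -> SyntheticRecord:
    rng = np.random.default_rng(seed)
    truth = sample_distribution(rng, config.distribution, config.dgrid)
    depth = float(rng.uniform(*config.depth_range))
    k_bg = float(rng.uniform(*config.k_bg_range))
    sigma = float(rng.uniform(*config.sigma_range))
    clean = fredholm_forward(truth, kernel)
    trace = corrupt_trace(clean, depth, k_bg, sigma, rng)
    return SyntheticRecord(trace=trace, truth=truth, k_bg=k_bg, depth=depth,
                           sigma=sigma, seed=seed)


def generate_dataset(n_records: int, config: DatasetConfig, rng_seed: int,
                     kernel: DipolarKernel | None = None) -> Dataset:
    """Generate seeded (trace, distribution) pairs; per-record seeds derive
    deterministically from the master seed, so the dataset is a pure function
    of its arguments."""
    if n_records < 1:
        raise ValueError("need at least one record")
    if kernel is None:
        kernel = build_kernel(config.dgrid, config.tgrid)
    child_seeds = np.random.SeedSequence(rng_seed).generate_state(n_records)
    records = tuple(_make_record(int(s), config, kernel) for s in child_seeds)
    inputs = np.column_stack([rec.trace.values for rec in records])
    targets = np.column_stack([rec.truth.values for rec in records])
    return Dataset(inputs=inputs, targets=targets, records=records,
                   dgrid=config.dgrid, tgrid=config.tgrid)
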