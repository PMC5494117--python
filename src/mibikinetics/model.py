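"""Three-compartment kinetic model of a tumor-imaging radiotracer.

The tracer (e.g. the lipophilic cation sestamibi, labelled with a
6-hour-half-life isotope) is injected as an intravenous bolus and exchanges
between three kinetically homogeneous pools:

* ``z`` — blood,
* ``x`` — tumor cells,
* ``y`` — normal (background) cells.

All transfers are first order.  With capture rates ``beta_zx`` (blood→tumor)
and ``beta_zy`` (blood→normal), return rates ``beta_xz`` (tumor→blood) and
``beta_yz`` (normal→blood), a renal/biliary elimination constant ``E`` acting
on the blood pool, and the physical decay constant ``lambda`` acting on every
pool, the system reads::

    dx/dt = beta_zx*z - (beta_xz + lambda)*x
    dy/dt = beta_zy*z - (beta_yz + lambda)*y
    dz/dt = beta_xz*x + beta_yz*y - (beta_zx + beta_zy + E + lambda)*z

so that d(x+y+z)/dt = -lambda*(x+y+z) - E*z.  When E = 0 the total activity
follows pure radioactive decay, n0*exp(-lambda*t); when additionally
lambda = 0 the total is conserved.

The system is linear, so it is solved exactly by a matrix exponential; a
classical fixed-step Runge–Kutta integrator is provided as an independent
numerical cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .errors import RegimeViolationError

__all__ = [
    "KineticParameters",
    "CompartmentState",
    "Trajectory",
    "decay_constant",
    "rhs",
    "simulate_closed_form",
    "simulate_numeric",
    "total_amount",
]

#: Eigenvalue-gap threshold below which the spectral solver defers to the
#: scaling-and-squaring matrix exponential (near-defective rate matrix).
EIGENVALUE_GAP_TOL = 1e-12

_RATE_NAMES = ("lambda_decay", "elim", "beta_zx", "beta_zy", "beta_xz", "beta_yz")


def decay_constant(half_life: float) -> float:
    """Convert a half-life (hours) to a decay constant (per hour), ln2/T."""
    if not half_life > 0:
        raise ValueError(f"half_life must be positive, got {half_life!r}")
    return math.log(2.0) / half_life


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the three-compartment system.

    All rates are in 1/hour; ``n0`` is the injected amount in arbitrary
    activity units (1 by default, so concentrations are fractions of the
    injected dose).
    """

    lambda_decay: float = 0.0
    elim: float = 0.0
    beta_zx: float = 0.0
    beta_zy: float = 0.0
    beta_xz: float = 0.0
    beta_yz: float = 0.0
    n0: float = 1.0

    def __post_init__(self) -> None:
        for name in _RATE_NAMES:
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"{name} must be a finite nonnegative rate, got {value!r}")
        if not (np.isfinite(self.n0) and self.n0 > 0):
            raise ValueError(f"n0 must be positive, got {self.n0!r}")

    @classmethod
    def from_half_life(cls, half_life_h: float, **rates: float) -> "KineticParameters":
        """Build a parameter set from the isotope half-life instead of lambda."""
        return cls(lambda_decay=decay_constant(half_life_h), **rates)

    def validate_regime(self) -> None:
        """Check the tumor-imaging regime: retentive tumor cells
        (beta_xz < beta_yz) and weak normal-cell uptake (beta_zy < beta_zx).

        The fully retentive limit beta_xz = beta_yz = 0 (no return flux at
        all) trivially satisfies the intent and is accepted.
        """
        retentive = self.beta_xz < self.beta_yz or (self.beta_xz == 0 and self.beta_yz == 0)
        if not retentive:
            raise RegimeViolationError(
                f"tumor cells must be more retentive: beta_xz={self.beta_xz} "
                f">= beta_yz={self.beta_yz}"
            )
        if not self.beta_zy < self.beta_zx:
            raise RegimeViolationError(
                f"normal-cell capture must be weaker: beta_zy={self.beta_zy} "
                f">= beta_zx={self.beta_zx}"
            )

    def rate_matrix(self) -> np.ndarray:
        """3x3 rate matrix A such that d[x, y, z]/dt = A @ [x, y, z]."""
        lam = self.lambda_decay
        return np.array(
            [
                [-(self.beta_xz + lam), 0.0, self.beta_zx],
                [0.0, -(self.beta_yz + lam), self.beta_zy],
                [self.beta_xz, self.beta_yz, -(self.beta_zx + self.beta_zy + self.elim + lam)],
            ]
        )

    def with_updates(self, **updates: float) -> "KineticParameters":
        return replace(self, **updates)


@dataclass(frozen=True)
class CompartmentState:
    """Instantaneous concentrations (tumor x, normal y, blood z) at time t."""

    x: float
    y: float
    z: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.z) < 0:
            raise ValueError("concentrations must be nonnegative")


def rhs(state: CompartmentState, params: KineticParameters) -> tuple[float, float, float]:
    """Time derivatives (dx/dt, dy/dt, dz/dt) of the compartment system."""
    lam = params.lambda_decay
    dx = params.beta_zx * state.z - (params.beta_xz + lam) * state.x
    dy = params.beta_zy * state.z - (params.beta_yz + lam) * state.y
    dz = (
        params.beta_xz * state.x
        + params.beta_yz * state.y
        - (params.beta_zx + params.beta_zy + params.elim + lam) * state.z
    )
    return (dx, dy, dz)


@dataclass(frozen=True)
class Trajectory:
    """Solution of the model on a time grid.

    ``times`` is strictly increasing (hours); the three series hold the
    concentrations in tumor cells, normal cells and blood at each grid point.
    ``params`` is the generating parameter set, or None for trajectories read
    back from disk without one.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    params: KineticParameters | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        for name in ("x", "y", "z"):
            series = np.asarray(getattr(self, name), dtype=float)
            if series.shape != times.shape:
                raise ValueError(f"{name} series length {series.shape} != grid {times.shape}")
            object.__setattr__(self, name, series)
        _check_grid(times)
        if min(self.x.min(), self.y.min(), self.z.min()) < 0:
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total(self) -> np.ndarray:
        """Pointwise total amount x + y + z."""
        return self.x + self.y + self.z

    @property
    def contrast(self) -> np.ndarray:
        """Tumor-over-background contrast x - y (may be negative)."""
        return self.x - self.y

    def series(self, compartment: str) -> np.ndarray:
        try:
            return {"tumor": self.x, "normal": self.y, "blood": self.z, "total": self.total}[
                compartment
            ]
        except KeyError:
            raise ValueError(
                f"unknown compartment {compartment!r}; "
                "expected tumor, normal, blood or total"
            ) from None

    def index_at(self, t: float) -> int:
        """Index of the grid point nearest to time t (t must lie on the span)."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise ValueError(
                f"time {t} h outside trajectory span [{self.times[0]}, {self.times[-1]}] h"
            )
        return int(np.argmin(np.abs(self.times - t)))


def _check_grid(times: np.ndarray) -> None:
    if times.ndim != 1 or times.size < 1:
        raise ValueError("time grid must be a non-empty 1-D array")
    if times[0] < 0:
        raise ValueError("time grid must be nonnegative")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("time grid must be strictly increasing (no duplicates)")


def _unit_bolus_closed_form(A: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Solve d v/dt = A v, v(0) = (0, 0, 1), at the given times.

    Spectral decomposition when the spectrum is well separated; otherwise a
    scaling-and-squaring matrix exponential per time point.  Returns a
    (3, T) array.
    """
    w, V = np.linalg.eig(A)
    gaps = np.abs(w[:, None] - w[None, :])[np.triu_indices(3, k=1)]
    degenerate = gaps.min() < EIGENVALUE_GAP_TOL
    ill_conditioned = np.linalg.cond(V) > 1e12
    v0 = np.array([0.0, 0.0, 1.0])
    if degenerate or ill_conditioned:
        return np.column_stack([expm(A * t) @ v0 for t in times])
    coeffs = np.linalg.solve(V, v0.astype(V.dtype))
    sol = (V * coeffs) @ np.exp(np.outer(w, times))
    return np.ascontiguousarray(sol.real)


def simulate_closed_form(params: KineticParameters, times: np.ndarray) -> Trajectory:
    """Exact solution for a bolus injection x(0)=y(0)=0, z(0)=n0.

    The linear system is solved via the eigendecomposition of the rate
    matrix (falling back to a matrix exponential when eigenvalues nearly
    coincide).  The unit-dose solution is scaled by ``n0``, so the response
    is exactly linear in the injected amount.
    """
    times = np.asarray(times, dtype=float)
    _check_grid(times)
    sol = _unit_bolus_closed_form(params.rate_matrix(), times)
    # exact solutions are nonnegative; clip roundoff-level undershoot
    sol = np.maximum(sol, 0.0) * params.n0
    return Trajectory(times=times, x=sol[0], y=sol[1], z=sol[2], params=params)


def simulate_numeric(
    params: KineticParameters, times: np.ndarray, step: float = 1e-3
) -> Trajectory:
    """Classical fixed-step 4th-order Runge–Kutta integration of the system.

    Serves as an independent numerical oracle for :func:`simulate_closed_form`.
    Each inter-grid interval is subdivided into equal substeps no longer than
    ``step``, so the integrator lands exactly on the requested grid.
    """
    times = np.asarray(times, dtype=float)
    _check_grid(times)
    if not step > 0:
        raise ValueError(f"step must be positive, got {step!r}")
    spacing = np.diff(np.concatenate(([0.0], times)))
    positive = spacing[spacing > 0]
    if positive.size and step > positive.min() + 1e-15:
        raise ValueError(
            f"step {step} exceeds the minimum grid spacing {positive.min():.6g}"
        )

    A = params.rate_matrix()

    def f(v: np.ndarray) -> np.ndarray:
        return A @ v

    v = np.array([0.0, 0.0, params.n0])
    t = 0.0
    out = np.empty((3, times.size))
    for i, t_next in enumerate(times):
        span = t_next - t
        if span > 0:
            n_sub = max(1, int(math.ceil(span / step - 1e-12)))
            h = span / n_sub
            for _ in range(n_sub):
                k1 = f(v)
                k2 = f(v + 0.5 * h * k1)
                k3 = f(v + 0.5 * h * k2)
                k4 = f(v + h * k3)
                v = v + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t = t_next
        out[:, i] = v
    out = np.maximum(out, 0.0)
    return Trajectory(times=times, x=out[0], y=out[1], z=out[2], params=params)


def total_amount(traj: Trajectory) -> np.ndarray:
    """Total tracer amount x + y + z along the trajectory."""
    return traj.total
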