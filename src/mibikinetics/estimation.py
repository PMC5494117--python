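"""Parameter estimation from sparse, noisy concentration measurements.

Fitting minimizes the residual functional

    Phi = sum_i (F(t_i) - F_model(t_i))^2

between measured concentrations of one compartment and the closed-form model
curve, by bounded nonlinear least squares with seeded multi-start.  The decay
constant and injected amount are always held fixed (the isotope and the dose
are known); any subset of the transport rates {E, beta_zx, beta_zy, beta_xz,
beta_yz} may be freed.

A single observed compartment cannot separate the two capture rates, so by
default beta_zy is tied to beta_zx/2 (the standard simulation convention for
weak normal-cell uptake) whenever beta_zx is fitted and beta_zy is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, IdentifiabilityError
from .model import KineticParameters, simulate_closed_form
from .washout import PGP_THRESHOLD, WashoutResult, classify_pgp, k_wor

__all__ = [
    "FREE_PARAMETER_NAMES",
    "ObservationSet",
    "FitResult",
    "residual_functional",
    "fit_parameters",
    "two_point_kwor",
]

#: Transport rates that may be freed in a fit (lambda and n0 stay fixed).
FREE_PARAMETER_NAMES = ("elim", "beta_zx", "beta_zy", "beta_xz", "beta_yz")

_DEFAULT_BOUNDS = (0.0, 10.0)  # h^-1, generous for tracer transport rates


@dataclass(frozen=True)
class ObservationSet:
    """Noisy sampled concentrations of one compartment.

    ``noise_model``/``noise_scale``/``seed`` record how the values were
    produced (metadata only; the fit does not use them).
    """

    times: np.ndarray
    values: np.ndarray
    compartment: str = "blood"
    noise_model: str = "gaussian"
    noise_scale: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("observation times must be strictly increasing")
        if values.size and values.min() < 0:
            raise ValueError("observed concentrations must be nonnegative")
        if self.compartment not in ("blood", "tumor", "normal"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit."""

    params: KineticParameters
    free_names: tuple[str, ...]
    phi: float
    converged: bool
    n_iter: int
    seed: int | None = None
    start_values: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "params": {
                "lambda_decay": self.params.lambda_decay,
                "elim": self.params.elim,
                "beta_zx": self.params.beta_zx,
                "beta_zy": self.params.beta_zy,
                "beta_xz": self.params.beta_xz,
                "beta_yz": self.params.beta_yz,
                "n0": self.params.n0,
            },
            "free_names": list(self.free_names),
            "phi": self.phi,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def residual_functional(observed: np.ndarray, modelled: np.ndarray) -> float:
    """Sum of squared deviations between an observed and a modelled series."""
    observed = np.asarray(observed, dtype=float)
    modelled = np.asarray(modelled, dtype=float)
    if observed.shape != modelled.shape:
        raise ValueError(
            f"series lengths differ: {observed.shape} vs {modelled.shape}"
        )
    return float(np.sum((observed - modelled) ** 2))


def fit_parameters(
    obs: ObservationSet,
    free: list[str] | tuple[str, ...],
    fixed: KineticParameters,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    tie_beta_zy: bool | None = None,
    allow_unidentifiable: bool = False,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Fit the chosen transport rates to an observation set.

    Parameters
    ----------
    obs
        Measured concentrations of one compartment.
    free
        Names of the parameters to fit; non-empty subset of
        ``FREE_PARAMETER_NAMES``.  ``lambda_decay`` and ``n0`` always come
        from ``fixed``.
    fixed
        Parameter set supplying every non-fitted value.
    bounds
        Per-parameter ``(low, high)`` intervals; default ``(0, 10)`` 1/h.
    n_starts
        Number of seeded uniform multi-start draws within the bounds.
    tie_beta_zy
        Force ``beta_zy = beta_zx / 2`` during the fit.  Default (None):
        applied automatically when ``beta_zx`` is free and ``beta_zy`` is not.
    weights
        Optional per-observation weights (e.g. inverse variances) applied to
        the squared residuals.

    Raises
    ------
    DegenerateDataError
        If the observations carry no signal (all zero).
    IdentifiabilityError
        If all five rates are freed against a single-compartment curve and
        ``allow_unidentifiable`` is False.
    """
    free = tuple(free)
    if not free:
        raise ValueError("free parameter list must be non-empty")
    unknown = set(free) - set(FREE_PARAMETER_NAMES)
    if unknown:
        raise ValueError(
            f"cannot fit {sorted(unknown)}; eligible parameters are {FREE_PARAMETER_NAMES}"
        )
    if len(set(free)) != len(free):
        raise ValueError("free parameter names must be unique")
    if len(obs) == 0 or not np.any(obs.values > 0):
        raise DegenerateDataError("observations are empty or all zero; nothing to fit")
    if set(free) == set(FREE_PARAMETER_NAMES) and not allow_unidentifiable:
        raise IdentifiabilityError(
            "freeing all five transport rates against a single-compartment curve "
            "is not identifiable; fix or tie at least one rate, or pass "
            "allow_unidentifiable=True"
        )

    if tie_beta_zy is None:
        tie_beta_zy = "beta_zx" in free and "beta_zy" not in free
    if tie_beta_zy and "beta_zy" in free:
        raise ValueError("beta_zy cannot be both free and tied to beta_zx/2")

    bounds = bounds or {}
    lo = np.array([bounds.get(name, _DEFAULT_BOUNDS)[0] for name in free])
    hi = np.array([bounds.get(name, _DEFAULT_BOUNDS)[1] for name in free])
    if np.any(lo >= hi) or np.any(lo < 0):
        raise ValueError("bounds must satisfy 0 <= low < high for every free parameter")

    sqrt_w = None
    if weights is not None:
        sqrt_w = np.sqrt(np.asarray(weights, dtype=float))
        if sqrt_w.shape != obs.values.shape:
            raise ValueError("weights must match the observations")

    def build(theta: np.ndarray) -> KineticParameters:
        updates = dict(zip(free, np.maximum(theta, 0.0)))
        if tie_beta_zy:
            updates["beta_zy"] = updates.get("beta_zx", fixed.beta_zx) / 2.0
        return fixed.with_updates(**updates)

    def residuals(theta: np.ndarray) -> np.ndarray:
        traj = simulate_closed_form(build(theta), obs.times)
        res = traj.series(obs.compartment) - obs.values
        return res * sqrt_w if sqrt_w is not None else res

    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, len(free)))
    best = None
    for theta0 in starts:
        sol = least_squares(
            residuals,
            theta0,
            bounds=(lo, hi),
            gtol=1e-10,
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=500,
        )
        phi = float(np.sum(sol.fun**2))
        if best is None or phi < best[0]:
            best = (phi, sol)
    phi, sol = best
    return FitResult(
        params=build(sol.x),
        free_names=free,
        phi=phi,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        seed=seed,
        start_values={name: float(v) for name, v in zip(free, sol.x)},
    )


def two_point_kwor(
    early: tuple[float, tuple[float, float]],
    late: tuple[float, tuple[float, float]],
    threshold: float = PGP_THRESHOLD,
) -> WashoutResult:
    """K_WOR straight from two measured (tumor, normal) concentration pairs.

    ``early`` and ``late`` are ``(time_h, (tumor, normal))`` tuples.  No model
    fit is involved; this is the literal bedside computation.
    """
    t1, (a1, f1) = early
    t2, (a2, f2) = late
    if not t1 < t2:
        raise ValueError(f"early time {t1} h must precede late time {t2} h")
    k = k_wor(a1, f1, a2, f2)
    return WashoutResult(
        k_wor=k,
        t1=float(t1),
        t2=float(t2),
        a1=float(a1),
        f1=float(f1),
        a2=float(a2),
        f2=float(f2),
        classification=classify_pgp(k, threshold),
        threshold=threshold,
    )
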