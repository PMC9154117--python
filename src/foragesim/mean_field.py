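"""Infinite-population (mean-field) engine.

In the large-population limit the reaction systems of
:mod:`foragesim.model_core` reduce to the mass-action ODEs

    dx_i/dt = q_i x_U - a x_i + r_i x_U x_i - z x_i^2,      x_U = 1 - sum_j x_j,

on the unit simplex.  The uncommitted fraction is eliminated by
conservation, so the state is the n-vector of committed fractions and the
Jacobian spectrum is free of the trivial zero mode.

The canonical scenarios are stiff: the leak a ~ 1e-3 coexists with social
rates ~ 1e2, a five-decade timescale separation.  Integration therefore
uses the implicit BDF method with the analytic Jacobian and tight default
tolerances
(rel 1e-10 / abs 1e-12), which the perturbation-delay measurements need in
order to be tolerance-robust.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .model_core import ReactionSystem, TargetDistribution

log = logging.getLogger(__name__)

__all__ = [
    "MeanFieldState",
    "Trajectory",
    "StabilityReport",
    "IntegrationError",
    "FixedPointError",
    "ConvergenceError",
    "fully_uncommitted",
    "ode_rhs",
    "ode_jacobian",
    "rhs_from_reactions",
    "integrate",
    "find_fixed_point",
    "stability_eigenvalues",
    "convergence_time",
]

_SIMPLEX_TOL = 1e-9


class IntegrationError(RuntimeError):
    """ODE integration failed or violated simplex invariants."""


class FixedPointError(RuntimeError):
    """No interior fixed point found to the required residual."""


class ConvergenceError(RuntimeError):
    """The trajectory never (sustainably) entered the tolerance ball."""


@dataclass(frozen=True)
class MeanFieldState:
    """Committed fractions ``x_1..x_n``; ``x_U`` follows by conservation."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if np.any(x < -_SIMPLEX_TOL) or x.sum() > 1.0 + _SIMPLEX_TOL:
            raise ValueError("state must lie on the unit simplex (within 1e-9)")
        x = x.copy()
        x.flags.writeable = False
        object.__setattr__(self, "x", x)

    @property
    def x_U(self) -> float:
        return 1.0 - float(self.x.sum())

    @property
    def n(self) -> int:
        return int(self.x.size)

    def as_full(self) -> np.ndarray:
        """Full (n+1)-vector ``(x_U, x_1..x_n)``."""
        return np.concatenate(([self.x_U], self.x))


def fully_uncommitted(n: int) -> MeanFieldState:
    """The default initial condition: the whole colony uncommitted."""
    return MeanFieldState(np.zeros(n))


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed mean-field states on a strictly increasing grid."""

    times: np.ndarray
    x: np.ndarray  # shape (T, n), committed fractions

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def x_U(self) -> np.ndarray:
        return 1.0 - self.x.sum(axis=1)

    @property
    def final_state(self) -> MeanFieldState:
        return MeanFieldState(self.x[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: (time, species, fraction)."""
        n = self.x.shape[1]
        species = ["U"] + [f"patch_{i}" for i in range(1, n + 1)]
        full = np.column_stack([self.x_U, self.x])
        records = {
            "time": np.repeat(self.times, n + 1),
            "species": np.tile(species, self.times.size),
            "fraction": full.ravel(),
        }
        return pd.DataFrame(records)


@dataclass(frozen=True)
class StabilityReport:
    """An interior fixed point with its Jacobian spectrum."""

    fixed_point: MeanFieldState
    eigenvalues: np.ndarray
    stable: bool
    residual: float


def _params(system: ReactionSystem) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Extract (q, a, r_i, z) from a compiled system."""
    return (
        system.environment.qualities,
        system.rates.abandonment,
        system.rates.per_patch_recruitment,
        system.rates.stop_signal,
    )


def _state_vector(state: "MeanFieldState | Sequence[float] | np.ndarray") -> np.ndarray:
    if isinstance(state, MeanFieldState):
        return state.x
    return np.asarray(state, dtype=float)


def ode_rhs(
    state: "MeanFieldState | np.ndarray", system: ReactionSystem
) -> np.ndarray:
    """Time derivative of the committed fractions.

    ``dx_U/dt`` is implied by conservation and not returned.
    """
    x = _state_vector(state)
    q, a, r, z = _params(system)
    x_u = 1.0 - x.sum()
    return q * x_u - a * x + r * x_u * x - z * x * x


def ode_jacobian(
    state: "MeanFieldState | np.ndarray", system: ReactionSystem
) -> np.ndarray:
    """Analytic Jacobian of :func:`ode_rhs` in the committed coordinates."""
    x = _state_vector(state)
    q, a, r, z = _params(system)
    x_u = 1.0 - x.sum()
    jac = -np.outer(q + r * x, np.ones_like(x))
    jac[np.diag_indices_from(jac)] += -a + r * x_u - 2.0 * z * x
    return jac


def rhs_from_reactions(
    state: "MeanFieldState | np.ndarray", system: ReactionSystem
) -> np.ndarray:
    """Mass-action right-hand side summed reaction-by-reaction.

    Independent of the closed-form expression in :func:`ode_rhs`; the two
    must agree for every compiled system (cross-checked in the tests).
    """
    x = _state_vector(state)
    full = np.concatenate(([1.0 - x.sum()], x))
    kind, s_a, s_b, rate, net = system.compiled()
    law = np.where(
        kind == 0,
        rate * full[s_a],
        rate * full[s_a] * full[s_b],
    )
    return (net[:, 1:] * law[:, None]).sum(axis=0)


def integrate(
    system: ReactionSystem,
    init: "MeanFieldState | None" = None,
    t_end: float = 400.0,
    *,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-12,
    t_eval: "np.ndarray | None" = None,
    dense_output: bool = False,
):
    """Integrate the mean-field ODE with a stiff-capable adaptive method.

    Returns a :class:`Trajectory` (and the solver object when
    ``dense_output`` is requested).  Simplex violations beyond 1e-9 trigger
    one automatic re-run at 100x tighter tolerances, then an error —
    silently clipping states is deliberately not an option.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be > 0")
    if init is None:
        init = fully_uncommitted(system.n)
    x0 = init.x

    def fun(_t: float, x: np.ndarray) -> np.ndarray:
        return ode_rhs(x, system)

    def jac(_t: float, x: np.ndarray) -> np.ndarray:
        return ode_jacobian(x, system)

    for attempt, (rt, at) in enumerate(
        [(rel_tol, abs_tol), (rel_tol / 100.0, abs_tol / 100.0)]
    ):
        sol = solve_ivp(
            fun, (0.0, float(t_end)), x0, method="BDF", jac=jac,
            rtol=rt, atol=at, t_eval=t_eval, dense_output=dense_output,
        )
        if not sol.success:
            raise IntegrationError(f"ODE integration failed: {sol.message}")
        xs = sol.y.T
        if xs.min() >= -_SIMPLEX_TOL and xs.sum(axis=1).max() <= 1.0 + _SIMPLEX_TOL:
            break
        if attempt == 1:
            raise IntegrationError(
                "simplex invariants violated beyond 1e-9 even at tightened tolerances"
            )
        log.info("simplex invariant marginal; re-running with 100x tighter tolerances")
    traj = Trajectory(sol.t, xs)
    if dense_output:
        return traj, sol
    return traj


def _closed_form_positive_only(q: np.ndarray, a: float, rho: float) -> np.ndarray:
    """Interior fixed point of the positive-only variant.

    x_U = u solves rho u^2 - (rho + a + Q) u + a = 0 (smaller positive
    root, evaluated in its cancellation-free form); then
    x_i = q_i u / (a - rho u), which is exactly proportional to q.
    """
    big_q = q.sum()
    b = rho + a + big_q
    u = 2.0 * a / (b + np.sqrt(b * b - 4.0 * rho * a))
    return q * u / (a - rho * u)


def _closed_form_asocial(q: np.ndarray, a: float) -> np.ndarray:
    """Asocial fixed point: x_i = q_i x_U / a with x_U = a / (a + Q)."""
    x_u = a / (a + q.sum())
    return q * x_u / a


def find_fixed_point(
    system: ReactionSystem,
    init_guess: "MeanFieldState | None" = None,
    *,
    residual_tol: float = 1e-12,
) -> StabilityReport:
    """Locate the interior fixed point and assess its linear stability.

    Closed forms are used where they exist (positive-only and asocial rate
    structures with a > 0); otherwise the root is refined by Newton
    iteration from a long-time integration (or a caller guess).  The
    returned point satisfies ``max |dx_i/dt| < residual_tol``.
    """
    q, a, r, z = _params(system)

    if z == 0.0 and a > 0.0 and np.allclose(r, 0.0):
        x = _closed_form_asocial(q, a)
    elif z == 0.0 and a > 0.0 and r[0] > 0.0 and np.allclose(r, r[0]):
        x = _closed_form_positive_only(q, a, float(r[0]))
    else:
        guesses = []
        if init_guess is not None:
            guesses.append(init_guess.x.astype(float))
        # quality-proportional interior state: exact at z = a*rho and a
        # good basin for nearby parameterisations
        guesses.append(q / (a + q.sum()))
        x = None
        for guess in guesses:
            sol = _scipy_root(
                lambda v: ode_rhs(v, system), guess,
                jac=lambda v: ode_jacobian(v, system), method="hybr", tol=1e-14,
            )
            cand = sol.x
            if (sol.success and np.all(cand > 0.0) and cand.sum() < 1.0
                    and np.all(np.linalg.eigvals(ode_jacobian(cand, system)).real < 0.0)):
                x = cand
                break
        if x is None:
            # settle near the attractor by integration; robust fallback for
            # rate assignments whose fixed point sits far from proportional
            horizon = 10.0 / max(a, 1e-6)
            traj = integrate(system, t_end=horizon, rel_tol=1e-8, abs_tol=1e-10,
                             t_eval=np.array([horizon]))
            x = traj.x[-1].copy()
            sol = _scipy_root(
                lambda v: ode_rhs(v, system), x,
                jac=lambda v: ode_jacobian(v, system), method="hybr", tol=1e-14,
            )
            if sol.success:
                x = sol.x

    # Newton polish to machine-level residual (also tightens closed forms)
    for _ in range(50):
        f = ode_rhs(x, system)
        if np.max(np.abs(f)) < residual_tol / 10.0:
            break
        try:
            step = np.linalg.solve(ode_jacobian(x, system), f)
        except np.linalg.LinAlgError:
            break
        x = x - step

    resid = float(np.max(np.abs(ode_rhs(x, system))))
    if resid >= residual_tol:
        raise FixedPointError(f"fixed-point residual {resid:.3e} >= {residual_tol:.0e}")
    x_u = 1.0 - x.sum()
    if np.any(x <= 0.0) or x_u <= 0.0:
        log.warning("root-finding landed on the simplex boundary: x_U=%.3e", x_u)
        raise FixedPointError("no interior fixed point found (boundary point reached)")
    state = MeanFieldState(x)
    eig = np.linalg.eigvals(ode_jacobian(x, system))
    return StabilityReport(
        fixed_point=state,
        eigenvalues=eig,
        stable=bool(np.all(eig.real < 0.0)),
        residual=resid,
    )


def stability_eigenvalues(
    system: ReactionSystem, state: "MeanFieldState | np.ndarray"
) -> np.ndarray:
    """Jacobian spectrum at a fixed point (analytic differentiation)."""
    x = _state_vector(state)
    resid = float(np.max(np.abs(ode_rhs(x, system))))
    if resid >= 1e-9:
        raise ValueError(f"state is not a fixed point (residual {resid:.3e} >= 1e-9)")
    return np.linalg.eigvals(ode_jacobian(x, system))


def _reference_vector(
    target: "TargetDistribution | MeanFieldState | np.ndarray",
) -> np.ndarray:
    if isinstance(target, TargetDistribution):
        return target.values
    if isinstance(target, MeanFieldState):
        return target.x
    return np.asarray(target, dtype=float)


def convergence_time(
    system: ReactionSystem,
    init: "MeanFieldState | None",
    target: "TargetDistribution | MeanFieldState | np.ndarray",
    tol: float = 1e-4,
    *,
    max_horizon: float = 1e10,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-12,
    check_fixed_point: bool = True,
) -> float:
    """First *sustained* time at which the squared distance drops below tol.

    The squared distance is summed over committed fractions only.  The
    returned time is the last downward tolerance crossing before the
    horizon, so tangential grazing above tol does not count as
    convergence.  Requires the system's own fixed point to satisfy the
    tolerance (otherwise no finite answer exists).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ref = _reference_vector(target)
    if init is None:
        init = fully_uncommitted(system.n)
    if check_fixed_point:
        report = find_fixed_point(system)
        fp_err = float(np.sum((report.fixed_point.x - ref) ** 2))
        if fp_err >= tol:
            raise ConvergenceError(
                f"fixed point misses the reference (R^2 = {fp_err:.3e} >= tol = {tol:g}); "
                "no finite convergence time exists"
            )

    def fun(_t: float, x: np.ndarray) -> np.ndarray:
        return ode_rhs(x, system)

    def jac(_t: float, x: np.ndarray) -> np.ndarray:
        return ode_jacobian(x, system)

    def crossing(_t: float, x: np.ndarray) -> float:
        d = x - ref
        return float(d @ d) - tol

    crossing.terminal = False
    sol = solve_ivp(
        fun, (0.0, float(max_horizon)), init.x, method="BDF", jac=jac,
        rtol=rel_tol, atol=abs_tol, events=crossing,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    final_err = crossing(sol.t[-1], sol.y[:, -1])
    if final_err >= 0.0:
        raise ConvergenceError(
            f"not converged within horizon {max_horizon:g} "
            f"(final R^2 - tol = {final_err:.3e})"
        )
    events = sol.t_events[0]
    if events.size == 0:
        return 0.0  # started inside the ball and never left it
    return float(events[-1])
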