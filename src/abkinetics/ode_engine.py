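"""Mass-action flux evaluation and stiff ODE integration for a ModelSpec.

Each reversible reaction X + Y ⇌ Z contributes a net flux
``J = k_f·[X]·[Y] − k_r·[Z]`` (``k_f·[X]²`` for a self-reaction); the time
derivative of every species is the signed, stoichiometry-weighted sum of the
fluxes of the reactions it takes part in. The networks are stiff — the
2652-species elongation systems span many orders of magnitude in both rate
constants and concentrations — so the default integrator is an implicit
multistep method (SciPy ``BDF``) fed an analytically assembled sparse
Jacobian whose structure is a tridiagonal chain plus dense rows/columns for
the monomer and seed species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .reaction_models import KineticParams, ModelSpec, Reaction

__all__ = [
    "SolverSettings",
    "Trajectory",
    "IntegrationError",
    "reaction_flux",
    "rhs",
    "integrate",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class SolverSettings:
    """Integrator contract.

    ``rel_tol``/``abs_tol`` default to 1e-6 / 1e-12 mM — concentrations span
    roughly ten orders of magnitude across the 2652-species systems, so the
    absolute floor must sit far below the smallest populated species.
    ``method`` is any stiff-capable SciPy method name ("BDF", "Radau",
    "LSODA"); explicit methods are accepted for cross-checks on tiny models.
    """

    rel_tol: float = 1e-6
    abs_tol: float = 1e-12
    max_step: float = np.inf
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Trajectory:
    """Time grid (h) × species-concentration matrix (mM) from one run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    model: ModelSpec
    params: KineticParams

    def species(self, label: str) -> np.ndarray:
        return self.states[:, self.model.index(label)]

    def total_mass(self) -> np.ndarray:
        """Monomer-equivalent mass Σ_s mass(s)·[s] at each time point."""
        return self.states @ self.model.masses

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_h, species, conc_mM)."""
        n_t, n_s = self.states.shape
        return pd.DataFrame(
            {
                "time_h": np.repeat(self.times, n_s),
                "species": np.tile(self.model.species, n_t),
                "conc_mM": self.states.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class _Compiled:
    """ModelSpec + KineticParams flattened into arrays for fast evaluation."""

    def __init__(self, model: ModelSpec, params: KineticParams):
        R = model.n_reactions
        ra = np.empty(R, dtype=np.intp)
        rb = np.empty(R, dtype=np.intp)
        prod = np.empty(R, dtype=np.intp)
        kf = np.empty(R)
        kr = np.empty(R)
        self_rx = np.zeros(R, dtype=bool)
        mult_a = np.empty(R)
        mult_b = np.empty(R)
        for j, rx in enumerate(model.reactions):
            if len(rx.reactants) == 1:
                ra[j] = rb[j] = rx.reactants[0]
                self_rx[j] = True
                mult_a[j] = rx.multiplicity[0]
                mult_b[j] = 0.0
            else:
                ra[j], rb[j] = rx.reactants
                mult_a[j], mult_b[j] = rx.multiplicity
            prod[j] = rx.product
            kf[j] = params.rate(rx.forward) * rx.forward_scale
            kr[j] = params.rate(rx.reverse)
        self.n = model.n_species
        self.ra, self.rb, self.prod = ra, rb, prod
        self.kf, self.kr, self.self_rx = kf, kr, self_rx
        # scatter pattern: 3 stoichiometric entries per reaction
        self.s_idx = np.concatenate([ra, rb, prod])
        self.s_coef = np.concatenate([-mult_a, -mult_b, np.ones(R)])
        # Jacobian pattern: 3 stoich rows × 3 flux-dependency columns
        srow = self.s_idx.reshape(3, R)
        dcol = np.vstack([ra, rb, prod])
        self.j_rows = np.repeat(srow, 3, axis=0).ravel()
        self.j_cols = np.tile(dcol, (3, 1)).ravel()
        self._scoef3 = self.s_coef.reshape(3, R)

    def flux(self, c: np.ndarray) -> np.ndarray:
        return self.kf * c[self.ra] * c[self.rb] - self.kr * c[self.prod]

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        f = self.flux(c)
        d = np.zeros(self.n)
        np.add.at(d, self.s_idx, self.s_coef * np.tile(f, 3))
        return d

    def jac(self, t: float, c: np.ndarray) -> sparse.csc_matrix:
        R = len(self.kf)
        dval = np.empty((3, R))
        # ∂flux/∂[X]; for a self-reaction ra == rb so the first row already
        # evaluates to kf·[X] and doubling it gives the correct 2·kf·[X]
        dval[0] = self.kf * c[self.rb] * np.where(self.self_rx, 2.0, 1.0)
        dval[1] = np.where(self.self_rx, 0.0, self.kf * c[self.ra])
        dval[2] = -self.kr
        vals = (self._scoef3[:, None, :] * dval[None, :, :]).reshape(9 * R)
        return sparse.coo_matrix(
            (vals, (self.j_rows, self.j_cols)), shape=(self.n, self.n)
        ).tocsc()


def reaction_flux(
    state: np.ndarray, params: KineticParams, reaction: Reaction
) -> float:
    """Net mass-action flux (mM·h⁻¹) of one reaction at a given state."""
    kf = params.rate(reaction.forward) * reaction.forward_scale
    kr = params.rate(reaction.reverse)
    if len(reaction.reactants) == 1:
        fwd = kf * state[reaction.reactants[0]] ** 2
    else:
        a, b = reaction.reactants
        fwd = kf * state[a] * state[b]
    return float(fwd - kr * state[reaction.product])


def rhs(state: np.ndarray, params: KineticParams, model: ModelSpec) -> np.ndarray:
    """Time derivative (mM·h⁻¹) of every species at a given state."""
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise ValueError("state length does not match model")
    return _Compiled(model, params).rhs(0.0, state)


def integrate(
    model: ModelSpec,
    initial: np.ndarray,
    params: KineticParams,
    t_grid: np.ndarray,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate the network over ``t_grid`` (hours, increasing from 0).

    Returns a :class:`Trajectory` evaluated exactly on ``t_grid``. Solver
    overshoot may leave concentrations marginally negative (within
    ``abs_tol`` slack); states are reported as solved, and clamping to zero
    is deferred to the observable mapping.
    """
    settings = settings or SolverSettings()
    t_grid = np.asarray(t_grid, dtype=float)
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (model.n_species,):
        raise ValueError("initial state length does not match model")
    if np.any(initial < 0):
        raise ValueError("initial concentrations must be non-negative")
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")

    compiled = _Compiled(model, params)
    kwargs: dict = {}
    if settings.method in ("BDF", "Radau"):
        kwargs["jac"] = compiled.jac
    elif settings.method == "LSODA" and model.n_species <= 64:
        kwargs["jac"] = lambda t, c: compiled.jac(t, c).toarray()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # LSODA chatter on very stiff points
        sol = solve_ivp(
            compiled.rhs,
            (t_grid[0], t_grid[-1]),
            initial,
            method=settings.method,
            t_eval=t_grid,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            max_step=settings.max_step,
            **kwargs,
        )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else 0.0
        raise IntegrationError(
            f"solver {settings.method} failed at t={t_fail:.6g} h: {sol.message}",
            t_fail=t_fail,
        )
    return Trajectory(times=t_grid, states=sol.y.T.copy(), model=model, params=params)
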