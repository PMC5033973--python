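"""Steady-state computation: stiff integration plus Newton polishing.

The solver integrates dx/dt = N v(x) over the free species with a stiff
method until the scaled derivative norm falls below tolerance, then
root-solves the moiety-reduced balance equations to push the residual to
near machine precision.  Conserved totals (ATP+ADP, NAD+ + NADH) are
eliminated exactly through the link matrix, so the Newton step never
wanders off the conservation manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import IntegrationError
from .network import ConservationAnalysis, ModelDefinition

__all__ = ["SteadyState", "integrate_to_steady_state", "refine_newton", "solve_steady_state"]


@dataclass
class SteadyState:
    """Converged concentrations and per-reaction fluxes with diagnostics."""

    model_name: str
    concentrations: dict
    fluxes: dict
    pathway_flux: float
    converged: bool
    method: str
    residual: float          # max |dx/dt| over free species (flux units)
    t_final: float = np.nan
    clamped: bool = False    # negative transients were clamped during rate evaluation
    message: str = ""

    def vector(self, model: ModelDefinition) -> np.ndarray:
        return np.array([self.concentrations[s] for s in model.free_species])

    def as_series(self):
        import pandas as pd

        data = {f"conc:{k}": v for k, v in self.concentrations.items()}
        data.update({f"flux:{k}": v for k, v in self.fluxes.items()})
        data["pathway_flux"] = self.pathway_flux
        data["converged"] = self.converged
        data["residual"] = self.residual
        return pd.Series(data)


class _BudgetExceeded(Exception):
    pass


def _rhs_factory(model: ModelDefinition, cons: ConservationAnalysis,
                 max_nfev: Optional[int] = None):
    free = model.free_species
    idx = {s: i for i, s in enumerate(free)}
    N = model.stoichiometric_matrix()
    flags = {"clamped": False, "nfev": 0}

    def rhs(t, x):
        flags["nfev"] += 1
        if max_nfev is not None and flags["nfev"] > max_nfev:
            raise _BudgetExceeded(t)
        if np.any(x < 0):
            flags["clamped"] = True
        conc = model.state_from_vector(x, clamp=True)
        v = model.rates(conc)
        return N @ v

    return rhs, N, idx, flags


def _package(model, x, method, flags, t_final=np.nan, message=""):
    cons = model.conservation()
    N = model.stoichiometric_matrix()
    conc = model.state_from_vector(np.maximum(x, 0.0))
    v = model.rates(conc)
    dx = N @ v
    residual = float(np.max(np.abs(dx))) if len(dx) else 0.0
    fluxes = dict(zip(model.reaction_names, v))
    return SteadyState(
        model_name=model.name,
        concentrations=conc,
        fluxes={k: float(val) for k, val in fluxes.items()},
        pathway_flux=float(fluxes[model.pathway_flux_reaction]),
        converged=False,
        method=method,
        residual=residual,
        t_final=t_final,
        clamped=flags.get("clamped", False),
        message=message,
    )


def integrate_to_steady_state(
    model: ModelDefinition,
    t_max: float = 1e6,
    tol: float = 1e-9,
    x0: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    max_nfev: int = 60_000,
) -> SteadyState:
    """Integrate with LSODA in geometrically growing time chunks until the
    scaled derivative max |dx_i/dt| / max(|x_i|, 1 mM) drops below ``tol``
    or ``t_max`` is reached.  Returns diagnostics either way; raises
    :class:`IntegrationError` on NaN/divergence or when the right-hand
    side budget ``max_nfev`` is exhausted (a pathological stiff grind),
    carrying the last valid state.
    """
    cons = model.conservation()
    rhs, N, _, flags = _rhs_factory(model, cons, max_nfev=max_nfev)
    x = model.initial_vector() if x0 is None else np.asarray(x0, dtype=float)
    if len(x) == 0:
        ss = _package(model, x, "static", flags, t_final=0.0)
        ss.converged = True
        return ss
    t = 0.0
    t_chunk = 10.0
    converged = False
    while t < t_max:
        t_end = min(t + t_chunk, t_max)
        try:
            sol = solve_ivp(
                rhs, (t, t_end), x, method="LSODA", rtol=rtol, atol=atol,
                dense_output=False,
            )
            if not sol.success:
                # stiff-corner fallback: BDF copes with rough random kinetics
                sol = solve_ivp(rhs, (t, t_end), x, method="BDF", rtol=rtol, atol=atol)
        except _BudgetExceeded as exc:
            raise IntegrationError(
                f"integration budget exhausted near t={float(exc.args[0]):.3g} "
                f"({flags['nfev']} rhs evaluations)",
                last_state=model.state_from_vector(x), t=float(exc.args[0]),
            ) from None
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            raise IntegrationError(
                f"integration failed at t={sol.t[-1]:.3g}: {sol.message}",
                last_state=model.state_from_vector(x), t=sol.t[-1],
            )
        x = sol.y[:, -1]
        t = sol.t[-1]
        dx = rhs(t, x)
        scale = np.maximum(np.abs(x), 1.0)
        if np.max(np.abs(dx) / scale) < tol:
            converged = True
            break
        t_chunk = min(t_chunk * 10.0, 1e4)
    ss = _package(model, x, "LSODA", flags, t_final=t)
    ss.converged = converged
    if not converged:
        ss.message = f"derivative norm {ss.residual:.3g} above tol after t={t:.3g}"
    return ss


def _scaled_residual(model: ModelDefinition, x: np.ndarray) -> float:
    N = model.stoichiometric_matrix()
    conc = model.state_from_vector(np.maximum(x, 0.0))
    dx = N @ model.rates(conc)
    if not len(dx):
        return 0.0
    return float(np.max(np.abs(dx) / np.maximum(np.abs(x), 1.0)))


def refine_newton(model: ModelDefinition, guess: SteadyState, tol: float = 1e-12) -> SteadyState:
    """Polish a near-steady state by root-solving N_R v(x) = 0 on the
    moiety-reduced system.

    All diagnostics are recomputed under *this* model, so the guess may
    come from a related model (warm starts across a parameter scan).
    When the root solve fails, leaves the positive orthant, or does not
    improve the balance residual, the guess state is returned re-packaged
    with a flag instead of raising.
    """
    cons = model.conservation()
    N = model.stoichiometric_matrix()
    NR = N[cons.independent, :] if len(cons.independent) else N
    x_guess = guess.vector(model)
    if len(x_guess) == 0 or not len(NR):
        out = _package(model, x_guess, guess.method, {"clamped": guess.clamped})
        out.converged = True
        return out

    def fun(xi):
        x = cons.expand(xi)
        conc = model.state_from_vector(x, clamp=True)
        return NR @ model.rates(conc)

    flags = {"clamped": guess.clamped}
    base_res = _scaled_residual(model, x_guess)
    best = None
    best_res = np.inf
    for method, options in (("hybr", {"xtol": 1e-12}), ("lm", {})):
        sol = root(fun, cons.reduce(x_guess), method=method, options=options)
        x_try = cons.expand(sol.x)
        if not (np.all(x_try > -1e-9) and np.all(np.isfinite(x_try))):
            continue
        res = _scaled_residual(model, x_try)
        if res < best_res:
            best, best_res = x_try, res
        if res < tol:
            break
    x_new = best if best is not None else x_guess
    ok = best is not None
    if ok and _scaled_residual(model, x_new) <= max(base_res, tol):
        ss = _package(model, x_new, guess.method + "+newton", flags,
                      t_final=guess.t_final)
        ss.converged = _scaled_residual(model, x_new) < max(tol, 1e-8)
        if not ss.converged:
            ss.message = f"Newton residual {ss.residual:.3g} above tolerance"
        return ss
    out = _package(model, x_guess, guess.method, flags, t_final=guess.t_final)
    out.converged = base_res < 1e-8
    out.message = "Newton polish failed, keeping guess"
    return out


def solve_steady_state(
    model: ModelDefinition,
    t_max: float = 1e6,
    tol: float = 1e-9,
    x0: Optional[np.ndarray] = None,
    newton: bool = True,
) -> SteadyState:
    """Two-phase solve: stiff integration then optional Newton polish."""
    ss = integrate_to_steady_state(model, t_max=t_max, tol=tol, x0=x0)
    if newton:
        ss = refine_newton(model, ss)
    return ss
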