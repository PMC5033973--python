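"""Synthetic kinetic parameter sets and noisy observation tables.

The sampler draws every kinetic constant of a model from log-uniform
priors spanning physiological ranges, keeps the equilibrium constants
fixed (they are physical constants, not cell-line properties) and then
derives every reverse maximal rate through the Haldane relation, so each
sampled model is thermodynamically consistent by construction.

The observation generator emulates measured metabolite tables: it solves
the steady state under each treatment (treatments are enzyme-activity
scalings, matching how the pathway inhibitors act in the models),
multiplies each readout by mean-preserving lognormal noise with a chosen
coefficient of variation, and reports mean +/- sd over n replicate
preparations.  :func:`recover_activity_factor` inverts the generator: a
1-D search for the joint activity scaling that best explains an observed
table, used as a parameter-recovery check of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import GlycontrolError, IntegrationError
from .experiments import ObservationTable
from .network import ModelDefinition, build_model, scale_enzyme_activity
from .presets import preset_parameters
from .rate_laws import haldane_vmr
from .steady_state import solve_steady_state

__all__ = [
    "ParameterPrior",
    "sample_model",
    "simulate_observations",
    "recover_activity_factor",
]

#: Readouts reported by the observation generator (flux in model units).
OBSERVATION_READOUTS = ("Glc6P", "Fru6P", "FBP", "DHAP", "ATP")


@dataclass(frozen=True)
class ParameterPrior:
    """Sampling law for random kinetic parameter sets.

    Each constant is drawn log-uniformly within a multiplicative
    ``spread`` window around its physiological reference value and clipped
    to an absolute envelope (``*_range``, mM / flux units /
    dimensionless).  Anchoring the draws to reference values keeps the
    autocatalytic ATP loop of glycolysis viable in most draws --
    independent draws across the full envelopes almost surely collapse the
    pathway into its ATP-depleted dead state.  Equilibrium constants are
    physical constants and are never sampled.
    """

    km_range: tuple = (0.01, 10.0)
    ki_range: tuple = (0.01, 10.0)
    vmax_range: tuple = (1.0, 1000.0)
    l_range: tuple = (1.0, 1e6)
    alpha_range: tuple = (0.1, 10.0)
    km_spread: float = 3.0
    vmax_spread: float = 3.0
    l_spread: float = 10.0
    alpha_spread: float = 2.0

    def __post_init__(self):
        for lo, hi in (self.km_range, self.ki_range, self.vmax_range,
                       self.l_range, self.alpha_range):
            if not (0 < lo < hi):
                raise ValueError("prior ranges must be positive and increasing")
        for s in (self.km_spread, self.vmax_spread, self.l_spread, self.alpha_spread):
            if s < 1:
                raise ValueError("spread factors must be >= 1")


def _classify(name: str) -> Optional[str]:
    if name in ("Keq", "f"):
        return None                      # thermodynamics / isoform fractions
    if name in ("Vmf", "Vmr", "Vm", "k"):
        return "vmax"
    if name == "L":
        return "L"
    if name.startswith(("alpha", "beta")):
        return "alpha"
    if name.startswith("Ki"):
        return "ki"
    if name.startswith(("K", "Ka", "Kb", "Kc", "Kp", "Kq")):
        return "km"
    return None


def _draw(rng, prior: ParameterPrior, kind: str, reference: float) -> float:
    spread, clip = {
        "km": (prior.km_spread, prior.km_range),
        "ki": (prior.km_spread, prior.ki_range),
        "vmax": (prior.vmax_spread, prior.vmax_range),
        "L": (prior.l_spread, prior.l_range),
        "alpha": (prior.alpha_spread, prior.alpha_range),
    }[kind]
    value = reference * float(np.exp(rng.uniform(-np.log(spread), np.log(spread))))
    if kind == "vmax":
        return value      # closure constants sit below the enzymatic envelope
    return float(np.clip(value, *clip))


def _sample_once(prior: ParameterPrior, condition: str, rng) -> ModelDefinition:
    from .network import _kinetics_from_record

    params = preset_parameters(condition)
    for rec in params["reactions"]:
        consts = rec["constants"]
        for name in sorted(consts):
            kind = _classify(name)
            if kind is None or name == "Vmr":
                continue
            consts[name] = _draw(rng, prior, kind, consts[name])
        for iso in rec.get("isoforms") or ():
            for name in sorted(iso):
                kind = _classify(name)
                if kind is None or name == "Vmr" or name == "f":
                    continue
                iso[name] = _draw(rng, prior, kind, iso[name])
    for rec in params["reactions"]:
        target = haldane_vmr(_kinetics_from_record(rec))
        if target is not None:
            rec["constants"]["Vmr"] = target
    return build_model(condition, params)


def sample_model(
    prior: ParameterPrior,
    condition: str = "AS30D",
    seed: int = 0,
    require_live: bool = True,
    max_tries: int = 10,
) -> ModelDefinition:
    """Draw a random, thermodynamically consistent model of the given
    condition's network shape.

    Binding, inhibition, maximal-rate, closure and allosteric constants
    are resampled from the prior; stoichiometry, equilibrium constants and
    isoform fractions keep their reference values; every reverse maximal
    rate is recomputed from the Haldane relation, so Haldane residuals are
    zero by construction.  With ``require_live`` (default) draws that
    relax into the ATP-depleted dead state are rejected and redrawn
    (deterministically, from the same seed), so the returned model
    sustains a positive pathway flux.  Same seed, same model.
    """
    rng = np.random.default_rng(seed)
    last = None
    for attempt in range(max_tries if require_live else 1):
        model = _sample_once(prior, condition, rng)
        model.name = f"{condition}-synthetic-{seed}.{attempt}"
        if not require_live:
            return model
        last = model
        try:
            ss = solve_steady_state(model, t_max=1e5)
        except IntegrationError:
            continue
        if ss.converged and ss.pathway_flux > 1e-6:
            return model
    last.notes += " (warning: no live steady state found within max_tries)"
    return last


def simulate_observations(
    model: ModelDefinition,
    treatments: Mapping[str, Mapping[str, float]],
    noise_cv: float = 0.3,
    n_reps: int = 3,
    seed: int = 0,
    readouts: Sequence[str] = OBSERVATION_READOUTS,
) -> ObservationTable:
    """Noisy steady-state observation table over treatments.

    ``treatments`` maps a label to an enzyme->activity-factor mapping
    (the control condition is the empty mapping).  Noise is multiplicative
    lognormal with the given coefficient of variation, mean-preserving.
    Non-convergent treatments are omitted with a flag row (sd = NaN).
    """
    if not (0.0 <= noise_cv <= 1.0):
        raise ValueError("noise_cv must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    rows = []
    for label, scaling in treatments.items():
        variant = model
        for enzyme, factor in scaling.items():
            variant = scale_enzyme_activity(variant, enzyme, factor)
        try:
            ss = solve_steady_state(variant)
        except IntegrationError:
            ss = None
        if ss is None or not ss.converged:
            rows.append({"metabolite": "_unconverged", "treatment": label,
                         "mean": np.nan, "sd": np.nan, "n": n_reps})
            continue
        values = {m: ss.concentrations[m] for m in readouts}
        values["flux"] = ss.pathway_flux
        for m, truth in values.items():
            if noise_cv == 0.0:
                mean, sd = float(truth), 0.0
            else:
                z = rng.standard_normal(n_reps)
                reps = truth * np.exp(sigma * z - 0.5 * sigma**2)
                mean = float(np.mean(reps))
                sd = float(np.std(reps, ddof=1)) if n_reps > 1 else 0.0
            rows.append({
                "metabolite": m, "treatment": label,
                "mean": mean, "sd": sd, "n": n_reps,
            })
    return ObservationTable(pd.DataFrame(rows))


def recover_activity_factor(
    model: ModelDefinition,
    observed: ObservationTable,
    target_enzymes: Sequence[str],
    treatment: str,
    bounds: tuple = (0.02, 1.5),
    readouts: Sequence[str] = OBSERVATION_READOUTS,
) -> dict:
    """Recover the joint activity scaling of ``target_enzymes`` that best
    explains an observed treatment, by 1-D minimization of squared
    log-residuals between predicted and observed means.

    Returns a dict with ``factor``, ``residual`` and a ``flat_objective``
    flag raised when the objective is too shallow to identify the factor.
    """
    from .steady_state import refine_newton

    obs = observed.subset(treatment)
    names = [m for m in list(readouts) + ["flux"] if m in obs.index]
    if not names:
        raise GlycontrolError(f"no matching readouts for treatment {treatment!r}")
    target = np.log(obs.loc[names, "mean"].to_numpy(dtype=float))
    warm = {"ss": None}

    def objective(factor: float) -> float:
        variant = scale_enzyme_activity(model, list(target_enzymes), factor)
        ss = None
        if warm["ss"] is not None:
            polished = refine_newton(variant, warm["ss"])
            if polished.converged and polished.residual < 1e-8:
                ss = polished
        if ss is None:
            try:
                ss = solve_steady_state(variant)
            except IntegrationError:
                return 1e6
        if not ss.converged:
            return 1e6
        warm["ss"] = ss
        pred = np.array([
            ss.pathway_flux if m == "flux" else ss.concentrations[m] for m in names
        ])
        return float(np.sum((np.log(np.maximum(pred, 1e-12)) - target) ** 2))

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    # Flatness check: compare against the objective at the bounds.
    f_opt = res.fun
    spread = max(objective(bounds[0]), objective(bounds[1])) - f_opt
    return {
        "factor": float(res.x),
        "residual": float(f_opt),
        "flat_objective": bool(spread < 1e-6),
    }
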