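"""Model assembly: species, stoichiometry, conserved moieties, scenarios.

A :class:`ModelDefinition` bundles everything needed to simulate one
cell-line/condition model of tumor glycolysis: the ordered species list
with initial concentrations, the boundary (fixed) species, and the
reaction list, each reaction carrying its stoichiometry and its
:class:`~glycontrol.rate_laws.ReactionKinetics` record.

Moiety conservation (ATP+ADP, NAD+ + NADH) is not declared by hand: it is
recovered as the rational left null space of the stoichiometric matrix
over free species, and the corresponding totals are taken from the initial
concentrations.  The same decomposition supplies the link matrix used by
the steady-state solver and the matrix form of metabolic control analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import sympy as sp

from .errors import ModelBuildError, ParameterError, StateError
from .rate_laws import (
    ACTIVITY_CONSTANTS,
    FAMILIES,
    InhibitionMechanism,
    ReactionKinetics,
    evaluate_rate,
    haldane_residual,
    validate_kinetics,
)

__all__ = [
    "Reaction",
    "ModelDefinition",
    "FeedbackScenario",
    "build_model",
    "apply_feedback_scenario",
    "scale_enzyme_activity",
    "validate_model",
    "ConservationAnalysis",
]

CONDITIONS = ("AS30D", "HeLa_hyper", "HeLa_normo", "HeLa_hypo")

#: Feedback-inhibition scenario labels used in the titration experiments:
#: (a) no Fru1,6BP/DHAP feedback anywhere, (b) on HPI only, (c) on HK only,
#: (d) on HPI+HK, (e) on HPI, HK, TPI and GAPDH (the full model).
SCENARIO_LABELS = ("a", "b", "c", "d", "e")

# Metabolites whose feedback terms the scenarios toggle.
_FEEDBACK_METABOLITES = ("FBP", "DHAP")


@dataclass
class Reaction:
    """One reaction: name, stoichiometry map (species -> coefficient,
    negative for consumption) and kinetics."""

    name: str
    stoichiometry: dict
    kinetics: ReactionKinetics

    def copy(self) -> "Reaction":
        return Reaction(self.name, dict(self.stoichiometry), self.kinetics.copy())


@dataclass
class ModelDefinition:
    """A complete kinetic model of glycolysis for one condition."""

    name: str
    condition: str
    species: list
    initial: dict
    fixed: set
    reactions: list
    pathway_flux_reaction: str
    flux_unit: str = "mM/min"
    notes: str = ""

    # -- structural views -------------------------------------------------
    @property
    def free_species(self) -> list:
        return [s for s in self.species if s not in self.fixed]

    @property
    def reaction_names(self) -> list:
        return [r.name for r in self.reactions]

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(f"no reaction named {name!r} in model {self.name!r}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """N over free species (rows) x reactions (columns)."""
        free = self.free_species
        idx = {s: i for i, s in enumerate(free)}
        N = np.zeros((len(free), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sp_name, coeff in r.stoichiometry.items():
                if sp_name in idx:
                    N[idx[sp_name], j] = coeff
        return N

    # -- evaluation --------------------------------------------------------
    def rates(self, conc: Mapping[str, float]) -> np.ndarray:
        """All reaction rates at a concentration state (mapping must cover
        every species; fixed species may be overridden by the mapping)."""
        return np.array([evaluate_rate(conc, r.kinetics) for r in self.reactions])

    def state_from_vector(self, x: np.ndarray, clamp: bool = False) -> dict:
        """Full concentration dict from a free-species vector.

        With ``clamp`` small negative excursions (possible transiently in
        stiff integration) are clamped to 0 for rate evaluation.
        """
        conc = dict(self.initial)
        for s, v in zip(self.free_species, x):
            conc[s] = max(v, 0.0) if clamp else float(v)
        return conc

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial[s] for s in self.free_species])

    def copy(self) -> "ModelDefinition":
        return ModelDefinition(
            name=self.name,
            condition=self.condition,
            species=list(self.species),
            initial=dict(self.initial),
            fixed=set(self.fixed),
            reactions=[r.copy() for r in self.reactions],
            pathway_flux_reaction=self.pathway_flux_reaction,
            flux_unit=self.flux_unit,
            notes=self.notes,
        )

    def conservation(self) -> "ConservationAnalysis":
        return ConservationAnalysis(self)


class ConservationAnalysis:
    """Rational left-null-space decomposition of the stoichiometric matrix.

    Provides the conservation matrix G (moieties x free species, integer
    entries, G @ N = 0), the conserved totals G @ x0, and the link matrix
    L mapping independent species to the full free-species vector:
    x = L @ x_ind + x_offset with G @ x constant along any trajectory.
    """

    _nullspace_cache: dict = {}

    def __init__(self, model: ModelDefinition):
        self.model = model
        free = model.free_species
        signature = (
            tuple(free),
            tuple(
                (r.name, tuple(sorted(r.stoichiometry.items())))
                for r in model.reactions
            ),
        )
        cached = self._nullspace_cache.get(signature)
        if cached is None:
            N = sp.Matrix(
                [[sp.Rational(Fraction(c).limit_denominator(10**6)) for c in row]
                 for row in model.stoichiometric_matrix().tolist()]
            ) if free else sp.zeros(0, len(model.reactions))
            basis = N.T.nullspace()
            rows = []
            for vec in basis:
                denom = sp.lcm([sp.fraction(sp.nsimplify(v))[1] for v in vec] or [1])
                rows.append([sp.nsimplify(v * denom) for v in vec])
            cached = np.array([[float(v) for v in row] for row in rows]).reshape(
                len(rows), len(free)
            )
            self._nullspace_cache[signature] = cached
        self.G = cached.copy()
        x0 = model.initial_vector()
        n_con = self.G.shape[0]
        self.totals = self.G @ x0 if n_con else np.zeros(0)
        # Pick dependent species = pivot columns of G's rref.
        if n_con:
            _, pivots = sp.Matrix(self.G.tolist()).rref()
            self.dependent = list(pivots)
        else:
            self.dependent = []
        self.independent = [i for i in range(len(free)) if i not in self.dependent]
        # Link matrix: x = L @ x_ind + offset.
        n = len(free)
        ni = len(self.independent)
        L = np.zeros((n, ni))
        offset = np.zeros(n)
        for r, i in enumerate(self.independent):
            L[i, r] = 1.0
        if self.dependent:
            Gd = self.G[:, self.dependent]
            Gi = self.G[:, self.independent]
            # G x = totals  =>  x_dep = Gd^{-1}(totals - Gi x_ind)
            Gd_inv = np.linalg.inv(Gd)
            A = -Gd_inv @ Gi
            b = Gd_inv @ self.totals
            for r, d in enumerate(self.dependent):
                L[d, :] = A[r, :]
                offset[d] = b[r]
        self.L = L
        self.offset = offset

    def reduce(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[self.independent]

    def expand(self, x_ind: np.ndarray) -> np.ndarray:
        return self.L @ np.asarray(x_ind) + self.offset

    def moiety_drift(self, x: np.ndarray) -> float:
        """Max absolute deviation of G @ x from the conserved totals."""
        if not len(self.G):
            return 0.0
        return float(np.max(np.abs(self.G @ np.asarray(x) - self.totals)))


@dataclass(frozen=True)
class FeedbackScenario:
    """Which enzymes keep their Fru1,6BP/DHAP feedback-inhibition terms.

    A flag set to False removes the corresponding inhibition terms
    entirely (Ki -> infinity semantics implemented as term removal).
    """

    hk: bool = True
    hpi: bool = True
    tpi: bool = True
    gapdh: bool = True

    @classmethod
    def from_label(cls, label: str) -> "FeedbackScenario":
        table = {
            "a": cls(False, False, False, False),
            "b": cls(hk=False, hpi=True, tpi=False, gapdh=False),
            "c": cls(hk=True, hpi=False, tpi=False, gapdh=False),
            "d": cls(hk=True, hpi=True, tpi=False, gapdh=False),
            "e": cls(True, True, True, True),
        }
        try:
            return table[label]
        except KeyError:
            raise ValueError(f"unknown scenario label {label!r}") from None


def apply_feedback_scenario(model: ModelDefinition, scenario: FeedbackScenario) -> ModelDefinition:
    """Copy of the model with Fru1,6BP/DHAP feedback terms enabled or
    removed per scenario; all other kinetics are untouched.

    HK and GAPDH carry their inhibition as an optional denominator block
    (flag toggled); TPI carries a single mixed inhibitor (role removed);
    HPI carries an inhibitor list, from which only the feedback
    metabolites are dropped -- the pentose-phosphate inhibitors Ery4P and
    6PG always remain.
    """
    out = model.copy()
    wanted = {"HK": scenario.hk, "HPI": scenario.hpi, "TPI": scenario.tpi,
              "GAPDH": scenario.gapdh}
    names = set(out.reaction_names)
    missing = [n for n in wanted if n not in names]
    if missing:
        raise ModelBuildError(f"scenario refers to absent reactions: {missing}")
    for enzyme, keep in wanted.items():
        kin = out.reaction(enzyme).kinetics
        if keep:
            continue
        if kin.family in ("hk_random_bibi", "gapdh_terbi"):
            kin.options["with_fbp_inhibition"] = False
            kin.roles.pop("I", None)
        elif kin.family == "uni_uni_rev_mm":
            kin.roles.pop("I", None)
        elif kin.family == "hpi_multi_inhib":
            kin.inhibitors = tuple(
                s for s in kin.inhibitors if s not in _FEEDBACK_METABOLITES
            )
    return out


def scale_enzyme_activity(model: ModelDefinition, enzyme, factor: float) -> ModelDefinition:
    """Copy of the model with the activity of one or more enzymes scaled.

    Both maximal rates (forward and, when present, reverse) are multiplied
    by the same factor, so Keq and every binding constant -- hence the
    thermodynamics -- are preserved.
    """
    if factor <= 0:
        raise ValueError(f"activity factor must be > 0 (got {factor})")
    names = [enzyme] if isinstance(enzyme, str) else list(enzyme)
    out = model.copy()
    for name in names:
        kin = out.reaction(name).kinetics
        for c in ACTIVITY_CONSTANTS:
            if c in kin.constants:
                kin.constants[c] = kin.constants[c] * factor
    return out


# ---------------------------------------------------------------------------
# Building and validation
# ---------------------------------------------------------------------------

def _kinetics_from_record(rec: Mapping) -> ReactionKinetics:
    mech = rec.get("mechanism")
    if isinstance(mech, Mapping):
        mech = InhibitionMechanism(mech.get("kind", "competitive"), mech.get("alpha"))
    elif isinstance(mech, str):
        mech = InhibitionMechanism(mech)
    elif mech is None:
        mech = InhibitionMechanism()
    iso = rec.get("isoforms")
    return ReactionKinetics(
        family=rec["family"],
        constants=dict(rec.get("constants", {})),
        roles=dict(rec.get("roles", {})),
        inhibitors=tuple(rec.get("inhibitors", ())),
        mechanism=mech,
        isoforms=None if iso is None else tuple(dict(i) for i in iso),
        options=dict(rec.get("options", {})),
    )


def build_model(condition: str, parameter_source: Mapping) -> ModelDefinition:
    """Assemble and validate a model from a parsed parameter record.

    ``parameter_source`` follows the native parameter schema (see
    :mod:`glycontrol.io_files`): a mapping with ``species`` (name ->
    {initial, fixed}) and ``reactions`` (list of records holding name,
    stoichiometry, family, constants, roles, ...).  Raises
    :class:`ModelBuildError` naming every gap if any declared constant or
    species is missing.
    """
    if condition not in CONDITIONS:
        raise ModelBuildError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    spec = parameter_source
    species = list(spec["species"])
    initial = {s: float(spec["species"][s]["initial"]) for s in species}
    fixed = {s for s in species if spec["species"][s].get("fixed", False)}
    reactions = []
    problems = []
    for rec in spec["reactions"]:
        try:
            kin = _kinetics_from_record(rec)
        except (KeyError, ParameterError) as exc:
            problems.append(f"reaction {rec.get('name', '?')}: {exc}")
            continue
        rxn = Reaction(rec["name"], dict(rec["stoichiometry"]), kin)
        for sp_name in rxn.stoichiometry:
            if sp_name not in initial:
                problems.append(f"reaction {rxn.name}: undeclared species {sp_name!r}")
        for role, sp_name in kin.roles.items():
            if sp_name not in initial:
                problems.append(
                    f"reaction {rxn.name}: role {role} bound to undeclared species {sp_name!r}"
                )
        reactions.append(rxn)
    model = ModelDefinition(
        name=spec.get("name", condition),
        condition=condition,
        species=species,
        initial=initial,
        fixed=fixed,
        reactions=reactions,
        pathway_flux_reaction=spec.get(
            "pathway_flux_reaction", "MCT" if condition.startswith("HeLa") else "LDH"
        ),
        flux_unit=spec.get("flux_unit", "mM/min"),
        notes=spec.get("notes", ""),
    )
    # Evaluate every rate once at the initial state to surface missing
    # constants/species as a single aggregated error.
    for r in model.reactions:
        try:
            evaluate_rate(model.initial, r.kinetics)
        except (ParameterError, StateError) as exc:
            problems.append(f"reaction {r.name}: {exc}")
        for issue in validate_kinetics(r.kinetics):
            problems.append(f"reaction {r.name}: {issue}")
    if problems:
        raise ModelBuildError(
            "model cannot be built:\n  " + "\n  ".join(sorted(set(problems)))
        )
    return model


def validate_model(model: ModelDefinition, haldane_rtol: float = 1e-6) -> dict:
    """Report-only diagnostics: moiety conservation, Haldane residuals,
    unreferenced species and the fixed-species list."""
    report = {
        "model": model.name,
        "fixed_species": sorted(model.fixed),
        "haldane_residuals": {},
        "conserved_moieties": [],
        "unreferenced_species": [],
        "issues": [],
    }
    cons = model.conservation()
    free = model.free_species
    for g, total in zip(cons.G, np.atleast_1d(cons.totals)):
        members = {free[i]: g[i] for i in range(len(free)) if g[i] != 0}
        report["conserved_moieties"].append({"coefficients": members, "total": float(total)})
    # A conservation vector must be in the left null space: check N drift.
    N = model.stoichiometric_matrix()
    if len(cons.G) and np.max(np.abs(cons.G @ N)) > 1e-9:
        report["issues"].append("conservation vectors are not in the left null space")
    # The nucleotide pools must be structurally conserved when free:
    # the pool indicator vector must lie in the left null space of N.
    for pool in (("ATP", "ADP"), ("NAD", "NADH")):
        if all(p in free for p in pool):
            v = np.zeros(len(free))
            for p in pool:
                v[free.index(p)] = 1.0
            if np.max(np.abs(v @ N)) > 1e-9:
                report["issues"].append(
                    f"moiety {'+'.join(pool)} is not conserved by the stoichiometry"
                )
    referenced = set()
    for r in model.reactions:
        referenced.update(r.stoichiometry)
        referenced.update(r.kinetics.roles.values())
        referenced.update(r.kinetics.inhibitors)
    for s in model.species:
        if s not in referenced:
            report["unreferenced_species"].append(s)
    for r in model.reactions:
        res = haldane_residual(r.kinetics)
        if res is not None:
            report["haldane_residuals"][r.name] = res
            if res > haldane_rtol:
                report["issues"].append(
                    f"reaction {r.name}: Haldane residual {res:.3g} > {haldane_rtol:g}"
                )
        for issue in validate_kinetics(r.kinetics, haldane_rtol=haldane_rtol):
            report["issues"].append(f"reaction {r.name}: {issue}")
    return report
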