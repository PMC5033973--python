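"""Enzyme and transporter rate laws for the glycolysis models.

Every reaction in the AS-30D and HeLa models is evaluated by one of the
rate-law *families* below.  A family is a closed-form steady-state rate
equation (reversible Michaelis-Menten, random Bi-Bi, ordered Ter-Bi,
Monod-Wyman-Changeux, ...) whose named constants and ligand-role bindings
live in a :class:`ReactionKinetics` record.  Ligand roles (A, B, C, P, Q,
S, I, ...) are bound explicitly by species *name*, never by position, so
the order in which a reaction's stoichiometry is written can never change
which concentration enters which term of the equation.

Units convention: concentrations in mM, maximal rates (Vmf/Vmr/Vm) in the
flux unit of the model (mM/min by default), all binding and inhibition
constants in mM, Keq dimensionless on the concentration scale (or with the
net mM power implied by the mass-action ratio of the reaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .errors import ParameterError, StateError

__all__ = [
    "ReactionKinetics",
    "InhibitionMechanism",
    "FAMILIES",
    "ACTIVITY_CONSTANTS",
    "evaluate_rate",
    "eval_transporter_rev_mm",
    "eval_hk_random_bibi",
    "eval_hpi_multi_inhib",
    "eval_pfk1_mwc",
    "eval_aldolase_unibi",
    "eval_uni_uni_rev_mm",
    "eval_gapdh_terbi",
    "eval_random_bibi",
    "eval_mass_action",
    "haldane_vmr",
    "haldane_residual",
    "validate_kinetics",
]

#: Names that scale linearly with enzyme amount; activity titrations and
#: flux-control perturbations multiply exactly these.
ACTIVITY_CONSTANTS = ("Vmf", "Vmr", "Vm", "k")

MECHANISMS = ("competitive", "uncompetitive", "mixed")


@dataclass(frozen=True)
class InhibitionMechanism:
    """Reversible-inhibition mechanism selector for multi-inhibitor laws.

    ``mixed`` requires ``alpha`` (> 0), the factor by which the inhibition
    constant changes on the substrate-bound enzyme form; ``alpha`` is shared
    across all inhibitors of the reaction.
    """

    kind: str = "competitive"
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.kind not in MECHANISMS:
            raise ParameterError(f"unknown inhibition mechanism {self.kind!r}")
        if self.kind == "mixed":
            if self.alpha is None:
                raise ParameterError("mixed-type inhibition requires alpha")
            if self.alpha <= 0:
                raise ParameterError("mixed-type alpha must be > 0")


@dataclass
class ReactionKinetics:
    """One reaction's rate-law family plus all named kinetic constants.

    Parameters
    ----------
    family:
        Key into :data:`FAMILIES`.
    constants:
        Named constants (Vmf, Vmr, Keq, Ka, Kb, ..., Ki_<species>, alpha, ...).
    roles:
        Ligand-role binding, role name -> species name.  Role names are the
        ones used in the family's equation (``A``, ``B``, ``C``, ``P``, ``Q``
        for multi-substrate laws; ``S``/``P`` for uni-uni laws; dedicated
        names for the PFK1 law).
    inhibitors:
        Species acting as dead-end inhibitors where the family supports a
        variable-length inhibitor list (the hexose phosphate isomerase law).
        Each inhibitor species ``X`` needs a constant ``Ki_X``.
    mechanism:
        Inhibition mechanism for the multi-inhibitor law.
    isoforms:
        Optional isoform list: each entry a mapping with fraction ``f`` and
        per-isoform constant overrides.  Fractions must sum to 1.
    options:
        Family-specific switches (e.g. ``with_fbp_inhibition`` for HK/GAPDH,
        ``activator_grouping`` for the PFK1 MWC law).
    """

    family: str
    constants: dict = field(default_factory=dict)
    roles: dict = field(default_factory=dict)
    inhibitors: tuple = ()
    mechanism: InhibitionMechanism = field(default_factory=InhibitionMechanism)
    isoforms: Optional[tuple] = None
    options: dict = field(default_factory=dict)

    def copy(self) -> "ReactionKinetics":
        return ReactionKinetics(
            family=self.family,
            constants=dict(self.constants),
            roles=dict(self.roles),
            inhibitors=tuple(self.inhibitors),
            mechanism=self.mechanism,
            isoforms=None if self.isoforms is None else tuple(dict(i) for i in self.isoforms),
            options=dict(self.options),
        )

    # -- convenience accessors -------------------------------------------
    def k(self, name: str) -> float:
        try:
            return float(self.constants[name])
        except KeyError:
            raise ParameterError(
                f"rate law {self.family!r} is missing constant {name!r}"
            ) from None

    def species(self, role: str) -> str:
        try:
            return self.roles[role]
        except KeyError:
            raise ParameterError(
                f"rate law {self.family!r} has no species bound to role {role!r}"
            ) from None


def _conc(state: Mapping[str, float], species: str) -> float:
    try:
        c = float(state[species])
    except KeyError:
        raise StateError(f"species {species!r} absent from concentration state") from None
    if c < 0:
        raise StateError(f"negative concentration for {species!r}: {c}")
    return c


def _pos(k: ReactionKinetics, name: str) -> float:
    v = k.k(name)
    if v <= 0:
        raise ParameterError(f"constant {name!r} must be > 0 (got {v})")
    return v


def _isoforms(k: ReactionKinetics) -> Sequence[dict]:
    """Expand the isoform list to (fraction, merged-constants) records."""
    if not k.isoforms:
        return [{"f": 1.0, **k.constants}]
    total = sum(float(i["f"]) for i in k.isoforms)
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"isoform fractions sum to {total}, expected 1")
    return [{**k.constants, **i} for i in k.isoforms]


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def eval_transporter_rev_mm(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Reversible monosubstrate carrier (GLUT, MCT).

    v = sum_i Vmf * f_i * (S - P/Keq) / ( K_s,i * (1 + P/K_p,i) + S )

    Roles: ``S`` = cis-side substrate (Glc_out for GLUT; Lac_in for MCT),
    ``P`` = trans-side product.  One isoform by default; the HeLa glucose
    carrier uses two (GLUT1/GLUT3) with per-isoform K values.
    """
    S = _conc(state, k.species("S"))
    P = _conc(state, k.species("P"))
    Vmf = k.k("Vmf")
    Keq = _pos(k, "Keq")
    v = 0.0
    for iso in _isoforms(k):
        Ks = float(iso["K_s"])
        Kp = float(iso["K_p"])
        if Ks <= 0 or Kp <= 0:
            raise ParameterError("transporter K_s/K_p must be > 0")
        v += Vmf * float(iso["f"]) * (S - P / Keq) / (Ks * (1.0 + P / Kp) + S)
    return v


def eval_hk_random_bibi(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Hexokinase: random Bi-Bi with optional mixed-type Fru1,6BP inhibition.

    Roles: A = Glc_in, B = ATP, P = Glc6P, Q = ADP, I = Fru1,6BP.
    With ``with_fbp_inhibition`` the denominator gains
    I/Ki + A*I/(alpha2*Ka*Ki) + A*I*B/(alpha1*Ka*Kb*alpha2*Ki); without it
    (or as the two-isoform HeLa form with per-isoform Ka) those terms are
    absent.  alpha1 scales the ternary-complex term A*B/(alpha1*Ka*Kb).
    """
    A = _conc(state, k.species("A"))
    B = _conc(state, k.species("B"))
    P = _conc(state, k.species("P"))
    Q = _conc(state, k.species("Q"))
    Keq = _pos(k, "Keq")
    Vmf = k.k("Vmf")
    inhib = bool(k.options.get("with_fbp_inhibition", False))
    if inhib:
        I = _conc(state, k.species("I"))
    v = 0.0
    for iso in _isoforms(k):
        Ka = float(iso["Ka"])
        Kb = float(iso["Kb"])
        Kp = float(iso["Kp"])
        Kq = float(iso["Kq"])
        a1 = float(iso.get("alpha1", 1.0))
        if min(Ka, Kb, Kp, Kq) <= 0 or a1 <= 0:
            raise ParameterError("hexokinase constants must be > 0")
        num = Vmf * float(iso["f"]) / (a1 * Ka * Kb) * (A * B - P * Q / Keq)
        den = (
            1.0 + A / Ka + B / Kb + A * B / (a1 * Ka * Kb)
            + P / Kp + Q / Kq + P * Q / (Kp * Kq)
            + A * Q / (Ka * Kq) + P * B / (Kp * Kb)
        )
        if inhib:
            Ki = float(iso["Ki"])
            a2 = float(iso.get("alpha2", 1.0))
            if Ki <= 0 or a2 <= 0:
                raise ParameterError("hexokinase Ki/alpha2 must be > 0")
            den += I / Ki + A * I / (a2 * Ka * Ki) + A * I * B / (a1 * Ka * Kb * a2 * Ki)
        v += num / den
    return v


def eval_hpi_multi_inhib(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Hexose phosphate isomerase: reversible uni-uni with multiple
    dead-end inhibitors under a selectable mechanism.

    Roles: S = Glc6P, P = Fru6P.  Inhibitors (Ery4P, 6PG, Fru1,6BP and,
    in the AS-30D model, DHAP) enter as:

    - competitive:    D = 1 + s + p + E
    - uncompetitive:  D = 1 + s*(1+E) + p*(1+E)
    - mixed:          D = 1 + E + (s + p)*(1 + E_alpha)

    with s = S/Ks, p = P/Kp, E = sum_i I_i/Ki_i and
    E_alpha = sum_i I_i/(alpha*Ki_i); numerator Vmf*s - Vmr*p throughout,
    so all three mechanisms vanish at the same equilibrium and coincide
    when every inhibitor concentration is zero.
    """
    S = _conc(state, k.species("S"))
    P = _conc(state, k.species("P"))
    s = S / _pos(k, "K_s")
    p = P / _pos(k, "K_p")
    num = k.k("Vmf") * s - k.k("Vmr") * p
    E = 0.0
    for sp in k.inhibitors:
        E += _conc(state, sp) / _pos(k, f"Ki_{sp}")
    mech = k.mechanism
    if mech.kind == "competitive":
        den = 1.0 + s + p + E
    elif mech.kind == "uncompetitive":
        den = 1.0 + s * (1.0 + E) + p * (1.0 + E)
    else:  # mixed
        alpha = mech.alpha
        if alpha is None:
            raise ParameterError("mixed-type inhibition requires alpha")
        Ea = sum(
            _conc(state, sp) / (alpha * _pos(k, f"Ki_{sp}")) for sp in k.inhibitors
        )
        den = 1.0 + E + (s + p) * (1.0 + Ea)
    return num / den


def eval_pfk1_mwc(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Phosphofructokinase-1: concerted-transition (MWC) law with exclusive
    ligand binding, mixed-type activation by Fru2,6BP, allosteric
    inhibition by ATP and citrate, and a simple reversible MM block for the
    reverse reaction.

    Roles: ``F6P``, ``ATP``, ``F26BP``, ``CIT``, ``ADP``, ``FBP``.

    phi = (F6P/K_F6P) * (1 + F26BP/(alpha*Ka)) / (1 + F26BP/Ka)

    v = Vm * [ (ATP/K_ATP)/(1+ATP/K_ATP)
               * (1 + beta*F26BP/(alpha*Ka)) / (1 + F26BP/(alpha*Ka))
               * phi*(1+phi)^3 / (L_app + (1+phi)^4)
             - (ADP*FBP/(K_ADP*K_FBP*Keq))
               / (1 + ADP/K_ADP + FBP/K_FBP + ADP*FBP/(K_ADP*K_FBP)) ]

    with the apparent transition constant

    L_app = L * (1+CIT/Ki_CIT)^4 * (1+ATP/Ki_ATP)^4 / (1+F26BP/Ka)^4

    under the default ``activator_grouping="divide"``; the alternative
    reading ``"multiply"`` puts the (1+F26BP/Ka)^4 factor in the product
    instead.  alpha (<1 for activation) rescales K_F6P and beta (>1)
    rescales Vm when the activator is bound.
    """
    F6P = _conc(state, k.species("F6P"))
    ATP = _conc(state, k.species("ATP"))
    F26 = _conc(state, k.species("F26BP"))
    CIT = _conc(state, k.species("CIT"))
    ADP = _conc(state, k.species("ADP"))
    FBP = _conc(state, k.species("FBP"))
    Vm = k.k("Vm")
    L = k.k("L")
    if L < 0:
        raise ParameterError("MWC transition constant L must be >= 0")
    Ka = _pos(k, "Ka_F26BP")
    alpha = _pos(k, "alpha")
    beta = _pos(k, "beta")
    act = F26 / Ka
    act_a = F26 / (alpha * Ka)
    phi = (F6P / _pos(k, "K_F6P")) * (1.0 + act_a) / (1.0 + act)
    allo = L * (1.0 + CIT / _pos(k, "Ki_CIT")) ** 4 * (1.0 + ATP / _pos(k, "Ki_ATP")) ** 4
    if k.options.get("activator_grouping", "divide") == "divide":
        allo /= (1.0 + act) ** 4
    else:
        allo *= (1.0 + act) ** 4
    atp_mm = (ATP / _pos(k, "K_ATP")) / (1.0 + ATP / k.k("K_ATP"))
    act_mm = (1.0 + beta * act_a) / (1.0 + act_a)
    forward = atp_mm * act_mm * phi * (1.0 + phi) ** 3 / (allo + (1.0 + phi) ** 4)
    adp = ADP / _pos(k, "K_ADP")
    fbp = FBP / _pos(k, "K_FBP")
    reverse = (adp * fbp / _pos(k, "Keq")) / (1.0 + adp + fbp + adp * fbp)
    return Vm * (forward - reverse)


def eval_aldolase_unibi(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Aldolase: reversible random Uni-Bi.

    Roles: S = Fru1,6BP, P1 = DHAP, P2 = G3P.

    v = (Vmf*S/Ks - Vmr*P1*P2/(Kp1*Kp2))
        / (1 + S/Ks + P1/Kp1 + P2/Kp2 + P1*P2/(Kp1*Kp2))
    """
    s = _conc(state, k.species("S")) / _pos(k, "K_s")
    p1 = _conc(state, k.species("P1")) / _pos(k, "K_p1")
    p2 = _conc(state, k.species("P2")) / _pos(k, "K_p2")
    return (k.k("Vmf") * s - k.k("Vmr") * p1 * p2) / (1.0 + s + p1 + p2 + p1 * p2)


def eval_uni_uni_rev_mm(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Reversible uni-uni Michaelis-Menten (PGAM, ENO, TPI), optionally
    with a single mixed-type inhibitor (the AS-30D TPI form, inhibited by
    Fru1,6BP).

    Without inhibitor: v = (Vmf*s - Vmr*p) / (1 + s + p).
    With inhibitor I:  v = (Vmf*s - Vmr*p)
                           / (1 + I/Ki + (s + p)*(1 + I/(alpha*Ki)))
    """
    s = _conc(state, k.species("S")) / _pos(k, "K_s")
    p = _conc(state, k.species("P")) / _pos(k, "K_p")
    num = k.k("Vmf") * s - k.k("Vmr") * p
    if "I" in k.roles:
        I = _conc(state, k.species("I"))
        Ki = _pos(k, "Ki")
        alpha = _pos(k, "alpha")
        den = 1.0 + I / Ki + (s + p) * (1.0 + I / (alpha * Ki))
    else:
        den = 1.0 + s + p
    return num / den


def eval_gapdh_terbi(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """GAPDH: simplified ordered Ter-Bi, optionally with mixed-type
    Fru1,6BP inhibition.

    Roles: A = NAD+, B = G3P, C = Pi, P = 1,3BPG, Q = NADH, I = Fru1,6BP.

    v = (Vmf*A*B*C/(Ka*Kb*Kc) - Vmr*P*Q/(Kp*Kq)) / D with

    D = 1 + A/Ka + A*B/(Ka*Kb) + A*B*C/(Ka*Kb*Kc) + P*Q/(Kp*Kq) + Q/Kq
        [ + I/Ki + A*B*I/(Ka*Kb*alpha*Ki) + A*B*C*I/(Ka*Kb*Kc*alpha*Ki)
          + P*Q*I/(Kp*Kq*alpha*Ki) ]
    """
    A = _conc(state, k.species("A"))
    B = _conc(state, k.species("B"))
    C = _conc(state, k.species("C"))
    P = _conc(state, k.species("P"))
    Q = _conc(state, k.species("Q"))
    Ka, Kb, Kc = _pos(k, "Ka"), _pos(k, "Kb"), _pos(k, "Kc")
    Kp, Kq = _pos(k, "Kp"), _pos(k, "Kq")
    ab = A * B / (Ka * Kb)
    abc = A * B * C / (Ka * Kb * Kc)
    pq = P * Q / (Kp * Kq)
    num = k.k("Vmf") * abc - k.k("Vmr") * pq
    den = 1.0 + A / Ka + ab + abc + pq + Q / Kq
    if k.options.get("with_fbp_inhibition", False):
        I = _conc(state, k.species("I"))
        aKi = _pos(k, "alpha") * _pos(k, "Ki")
        den += I / k.k("Ki") + (ab + abc + pq) * I / aKi
    return num / den


def _random_bibi_denominator(A, B, P, Q, Ka, Kb, Kp, Kq):
    return (
        1.0 + A / Ka + B / Kb + A * B / (Ka * Kb)
        + P / Kp + Q / Kq + P * Q / (Kp * Kq)
        + A * Q / (Ka * Kq) + P * B / (Kp * Kb)
    )


def eval_random_bibi_keq(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Random bisubstrate MM with Keq-form numerator (pyruvate kinase).

    v = Vmf/(Ka*Kb) * (A*B - P*Q/Keq) / D, with the nine-term random
    Bi-Bi denominator D (1 + A/Ka + B/Kb + AB/KaKb + P/Kp + Q/Kq +
    PQ/KpKq + AQ/KaKq + PB/KpKb).
    """
    A = _conc(state, k.species("A"))
    B = _conc(state, k.species("B"))
    P = _conc(state, k.species("P"))
    Q = _conc(state, k.species("Q"))
    Ka, Kb = _pos(k, "Ka"), _pos(k, "Kb")
    Kp, Kq = _pos(k, "Kp"), _pos(k, "Kq")
    num = k.k("Vmf") / (Ka * Kb) * (A * B - P * Q / _pos(k, "Keq"))
    return num / _random_bibi_denominator(A, B, P, Q, Ka, Kb, Kp, Kq)


def eval_random_bibi_vmr(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Random Bi-Bi reversible MM for non-interacting substrates
    (phosphoglycerate kinase, lactate dehydrogenase).

    v = (Vmf*A*B/(alpha*Ka*Kb) - Vmr*P*Q/(beta*Kp*Kq)) / D with
    D = 1 + A/Ka + B/Kb + A*B/(alpha*Ka*Kb) + P*Q/(beta*Kp*Kq)
        + P/Kp + Q/Kq;  alpha = beta = 1 for the modeled enzymes.
    """
    A = _conc(state, k.species("A"))
    B = _conc(state, k.species("B"))
    P = _conc(state, k.species("P"))
    Q = _conc(state, k.species("Q"))
    Ka, Kb = _pos(k, "Ka"), _pos(k, "Kb")
    Kp, Kq = _pos(k, "Kp"), _pos(k, "Kq")
    a = float(k.constants.get("alpha", 1.0))
    b = float(k.constants.get("beta", 1.0))
    if a <= 0 or b <= 0:
        raise ParameterError("alpha/beta must be > 0")
    ab = A * B / (a * Ka * Kb)
    pq = P * Q / (b * Kp * Kq)
    num = k.k("Vmf") * ab - k.k("Vmr") * pq
    den = 1.0 + A / Ka + B / Kb + ab + pq + P / Kp + Q / Kq
    return num / den


def eval_mass_action(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Irreversible first-order drain v = k * S (closure reactions:
    ATP turnover, NADH reoxidation, hexose-phosphate and triose-phosphate
    branch drains)."""
    return k.k("k") * _conc(state, k.species("S"))


FAMILIES: dict[str, Callable[[Mapping[str, float], ReactionKinetics], float]] = {
    "transporter_rev_mm": eval_transporter_rev_mm,
    "hk_random_bibi": eval_hk_random_bibi,
    "hpi_multi_inhib": eval_hpi_multi_inhib,
    "pfk1_mwc": eval_pfk1_mwc,
    "aldo_unibi": eval_aldolase_unibi,
    "uni_uni_rev_mm": eval_uni_uni_rev_mm,
    "gapdh_terbi": eval_gapdh_terbi,
    "random_bibi_keq": eval_random_bibi_keq,
    "random_bibi_vmr": eval_random_bibi_vmr,
    "mass_action": eval_mass_action,
}

# Alias matching the operation naming used elsewhere.
eval_aldo_unibi = eval_aldolase_unibi


def eval_random_bibi(state, k, form: str = None):
    """Dispatch between the Keq-form (pyruvate kinase) and Vmr-form
    (PGK/LDH) random Bi-Bi equations."""
    form = form or ("keq_form" if "Keq" in k.constants else "vmr_form")
    if form == "keq_form":
        return eval_random_bibi_keq(state, k)
    if form == "vmr_form":
        return eval_random_bibi_vmr(state, k)
    raise ParameterError(f"unknown random Bi-Bi form {form!r}")


def evaluate_rate(state: Mapping[str, float], k: ReactionKinetics) -> float:
    """Evaluate a reaction rate from a concentration state."""
    try:
        fn = FAMILIES[k.family]
    except KeyError:
        raise ParameterError(f"unknown rate-law family {k.family!r}") from None
    return fn(state, k)


# ---------------------------------------------------------------------------
# Thermodynamic (Haldane) consistency
# ---------------------------------------------------------------------------

def haldane_vmr(k: ReactionKinetics) -> Optional[float]:
    """Reverse maximal rate implied by Keq through the Haldane relation.

    Returns None for families whose numerator is written directly in the
    Keq form (carriers, kinases with (AB - PQ/Keq) numerators, the MWC law,
    mass-action drains): those are thermodynamically consistent by
    construction and carry no independent Vmr.
    """
    fam = k.family
    c = k.constants
    if "Keq" not in c:
        return None
    if fam in ("hpi_multi_inhib", "uni_uni_rev_mm"):
        return c["Vmf"] * c["K_p"] / (c["K_s"] * c["Keq"])
    if fam == "aldo_unibi":
        return c["Vmf"] * c["K_p1"] * c["K_p2"] / (c["K_s"] * c["Keq"])
    if fam == "gapdh_terbi":
        return c["Vmf"] * c["Kp"] * c["Kq"] / (c["Ka"] * c["Kb"] * c["Kc"] * c["Keq"])
    if fam == "random_bibi_vmr":
        a = c.get("alpha", 1.0)
        b = c.get("beta", 1.0)
        return c["Vmf"] * b * c["Kp"] * c["Kq"] / (a * c["Ka"] * c["Kb"] * c["Keq"])
    return None


def haldane_residual(k: ReactionKinetics) -> Optional[float]:
    """Relative deviation |Vmr - Vmr_haldane| / Vmr_haldane, or None when
    the family has no independent Vmr or no Keq is recorded."""
    if "Keq" not in k.constants or "Vmr" not in k.constants:
        return None
    target = haldane_vmr(k)
    if target is None:
        return None
    return abs(k.constants["Vmr"] - target) / abs(target)


def with_haldane_vmr(k: ReactionKinetics) -> ReactionKinetics:
    """Copy of the kinetics with Vmr replaced by its Haldane value."""
    out = k.copy()
    target = haldane_vmr(k)
    if target is not None:
        out.constants["Vmr"] = target
    return out


def validate_kinetics(k: ReactionKinetics, haldane_rtol: float = 1e-6) -> list[str]:
    """Sanity checks on one kinetics record; returns a list of issues."""
    issues = []
    if k.family not in FAMILIES:
        return [f"unknown family {k.family!r}"]
    for name, value in k.constants.items():
        if name.startswith(("K", "Ki", "Ka")) and not name.startswith("Keq"):
            if float(value) <= 0:
                issues.append(f"constant {name} must be > 0 (got {value})")
    for vname in ("Vmf", "Vmr", "Vm"):
        if vname in k.constants and float(k.constants[vname]) < 0:
            issues.append(f"{vname} must be >= 0")
    if k.isoforms:
        total = sum(float(i["f"]) for i in k.isoforms)
        if abs(total - 1.0) > 1e-9:
            issues.append(f"isoform fractions sum to {total:.12g}, expected 1")
    res = haldane_residual(k)
    if res is not None and res > haldane_rtol:
        issues.append(f"Haldane residual {res:.3g} exceeds tolerance {haldane_rtol:g}")
    return issues
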