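"""Symbolic (sympy) form of every rate-law family.

Used to emit content MathML for SBML kinetic laws and to manipulate rate
expressions analytically (e.g. closed-form elasticities in downstream
analyses).  Species appear as sympy symbols named after the species;
kinetic constants are substituted numerically.
"""

from __future__ import annotations

from typing import Mapping

import sympy as sp

from .errors import ParameterError
from .rate_laws import ReactionKinetics

__all__ = ["rate_expression"]


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name, nonnegative=True)


def _transporter(kin: ReactionKinetics) -> sp.Expr:
    S = _sym(kin.species("S"))
    P = _sym(kin.species("P"))
    c = kin.constants
    expr = 0
    isoforms = kin.isoforms or ({"f": 1.0, "K_s": c["K_s"], "K_p": c["K_p"]},)
    for iso in isoforms:
        Ks = sp.Float(iso.get("K_s", c.get("K_s")))
        Kp = sp.Float(iso.get("K_p", c.get("K_p")))
        expr += (
            sp.Float(c["Vmf"]) * sp.Float(iso["f"]) * (S - P / sp.Float(c["Keq"]))
            / (Ks * (1 + P / Kp) + S)
        )
    return expr


def _hk(kin: ReactionKinetics) -> sp.Expr:
    A, B = _sym(kin.species("A")), _sym(kin.species("B"))
    P, Q = _sym(kin.species("P")), _sym(kin.species("Q"))
    c = kin.constants
    inhib = bool(kin.options.get("with_fbp_inhibition", False))
    I = _sym(kin.species("I")) if inhib else None
    expr = 0
    isoforms = kin.isoforms or ({"f": 1.0},)
    for iso in isoforms:
        m = {**c, **iso}
        Ka, Kb, Kp, Kq = (sp.Float(m[k]) for k in ("Ka", "Kb", "Kp", "Kq"))
        a1 = sp.Float(m.get("alpha1", 1.0))
        num = sp.Float(c["Vmf"]) * sp.Float(m.get("f", 1.0)) / (a1 * Ka * Kb) * (
            A * B - P * Q / sp.Float(c["Keq"])
        )
        den = (
            1 + A / Ka + B / Kb + A * B / (a1 * Ka * Kb) + P / Kp + Q / Kq
            + P * Q / (Kp * Kq) + A * Q / (Ka * Kq) + P * B / (Kp * Kb)
        )
        if inhib:
            Ki = sp.Float(m["Ki"])
            a2 = sp.Float(m.get("alpha2", 1.0))
            den += I / Ki + A * I / (a2 * Ka * Ki) + A * I * B / (a1 * Ka * Kb * a2 * Ki)
        expr += num / den
    return expr


def _hpi(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    s = _sym(kin.species("S")) / sp.Float(c["K_s"])
    p = _sym(kin.species("P")) / sp.Float(c["K_p"])
    num = sp.Float(c["Vmf"]) * s - sp.Float(c["Vmr"]) * p
    E = sum(_sym(x) / sp.Float(c[f"Ki_{x}"]) for x in kin.inhibitors)
    mech = kin.mechanism
    if mech.kind == "competitive":
        den = 1 + s + p + E
    elif mech.kind == "uncompetitive":
        den = 1 + s * (1 + E) + p * (1 + E)
    else:
        Ea = sum(
            _sym(x) / (sp.Float(mech.alpha) * sp.Float(c[f"Ki_{x}"]))
            for x in kin.inhibitors
        )
        den = 1 + E + (s + p) * (1 + Ea)
    return num / den


def _pfk1(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    F6P, ATP = _sym(kin.species("F6P")), _sym(kin.species("ATP"))
    F26, CIT = _sym(kin.species("F26BP")), _sym(kin.species("CIT"))
    ADP, FBP = _sym(kin.species("ADP")), _sym(kin.species("FBP"))
    Ka = sp.Float(c["Ka_F26BP"])
    alpha, beta = sp.Float(c["alpha"]), sp.Float(c["beta"])
    act = F26 / Ka
    act_a = F26 / (alpha * Ka)
    phi = (F6P / sp.Float(c["K_F6P"])) * (1 + act_a) / (1 + act)
    allo = sp.Float(c["L"]) * (1 + CIT / sp.Float(c["Ki_CIT"])) ** 4 \
        * (1 + ATP / sp.Float(c["Ki_ATP"])) ** 4
    if kin.options.get("activator_grouping", "divide") == "divide":
        allo = allo / (1 + act) ** 4
    else:
        allo = allo * (1 + act) ** 4
    atp_mm = (ATP / sp.Float(c["K_ATP"])) / (1 + ATP / sp.Float(c["K_ATP"]))
    act_mm = (1 + beta * act_a) / (1 + act_a)
    forward = atp_mm * act_mm * phi * (1 + phi) ** 3 / (allo + (1 + phi) ** 4)
    adp = ADP / sp.Float(c["K_ADP"])
    fbp = FBP / sp.Float(c["K_FBP"])
    reverse = (adp * fbp / sp.Float(c["Keq"])) / (1 + adp + fbp + adp * fbp)
    return sp.Float(c["Vm"]) * (forward - reverse)


def _aldo(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    s = _sym(kin.species("S")) / sp.Float(c["K_s"])
    p1 = _sym(kin.species("P1")) / sp.Float(c["K_p1"])
    p2 = _sym(kin.species("P2")) / sp.Float(c["K_p2"])
    return (sp.Float(c["Vmf"]) * s - sp.Float(c["Vmr"]) * p1 * p2) / (
        1 + s + p1 + p2 + p1 * p2
    )


def _uni_uni(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    s = _sym(kin.species("S")) / sp.Float(c["K_s"])
    p = _sym(kin.species("P")) / sp.Float(c["K_p"])
    num = sp.Float(c["Vmf"]) * s - sp.Float(c["Vmr"]) * p
    if "I" in kin.roles:
        I = _sym(kin.species("I"))
        Ki, alpha = sp.Float(c["Ki"]), sp.Float(c["alpha"])
        den = 1 + I / Ki + (s + p) * (1 + I / (alpha * Ki))
    else:
        den = 1 + s + p
    return num / den


def _gapdh(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    A, B, C = (_sym(kin.species(r)) for r in ("A", "B", "C"))
    P, Q = _sym(kin.species("P")), _sym(kin.species("Q"))
    Ka, Kb, Kc = (sp.Float(c[k]) for k in ("Ka", "Kb", "Kc"))
    Kp, Kq = sp.Float(c["Kp"]), sp.Float(c["Kq"])
    ab = A * B / (Ka * Kb)
    abc = A * B * C / (Ka * Kb * Kc)
    pq = P * Q / (Kp * Kq)
    num = sp.Float(c["Vmf"]) * abc - sp.Float(c["Vmr"]) * pq
    den = 1 + A / Ka + ab + abc + pq + Q / Kq
    if kin.options.get("with_fbp_inhibition", False):
        I = _sym(kin.species("I"))
        Ki, alpha = sp.Float(c["Ki"]), sp.Float(c["alpha"])
        den += I / Ki + (ab + abc + pq) * I / (alpha * Ki)
    return num / den


def _bibi_keq(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    A, B = _sym(kin.species("A")), _sym(kin.species("B"))
    P, Q = _sym(kin.species("P")), _sym(kin.species("Q"))
    Ka, Kb, Kp, Kq = (sp.Float(c[k]) for k in ("Ka", "Kb", "Kp", "Kq"))
    num = sp.Float(c["Vmf"]) / (Ka * Kb) * (A * B - P * Q / sp.Float(c["Keq"]))
    den = (
        1 + A / Ka + B / Kb + A * B / (Ka * Kb) + P / Kp + Q / Kq
        + P * Q / (Kp * Kq) + A * Q / (Ka * Kq) + P * B / (Kp * Kb)
    )
    return num / den


def _bibi_vmr(kin: ReactionKinetics) -> sp.Expr:
    c = kin.constants
    A, B = _sym(kin.species("A")), _sym(kin.species("B"))
    P, Q = _sym(kin.species("P")), _sym(kin.species("Q"))
    Ka, Kb, Kp, Kq = (sp.Float(c[k]) for k in ("Ka", "Kb", "Kp", "Kq"))
    a = sp.Float(c.get("alpha", 1.0))
    b = sp.Float(c.get("beta", 1.0))
    ab = A * B / (a * Ka * Kb)
    pq = P * Q / (b * Kp * Kq)
    num = sp.Float(c["Vmf"]) * ab - sp.Float(c["Vmr"]) * pq
    return num / (1 + A / Ka + B / Kb + ab + pq + P / Kp + Q / Kq)


def _mass_action(kin: ReactionKinetics) -> sp.Expr:
    return sp.Float(kin.constants["k"]) * _sym(kin.species("S"))


_BUILDERS = {
    "transporter_rev_mm": _transporter,
    "hk_random_bibi": _hk,
    "hpi_multi_inhib": _hpi,
    "pfk1_mwc": _pfk1,
    "aldo_unibi": _aldo,
    "uni_uni_rev_mm": _uni_uni,
    "gapdh_terbi": _gapdh,
    "random_bibi_keq": _bibi_keq,
    "random_bibi_vmr": _bibi_vmr,
    "mass_action": _mass_action,
}


def rate_expression(kin: ReactionKinetics) -> sp.Expr:
    """Sympy expression of a reaction's rate with constants substituted;
    free symbols are the species concentrations."""
    try:
        builder = _BUILDERS[kin.family]
    except KeyError:
        raise ParameterError(f"no symbolic form for family {kin.family!r}") from None
    return builder(kin)
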