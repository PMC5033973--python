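"""Independent symbolic transcription of every rate equation.

This module is the test-suite oracle: each rate law is transcribed here a
second time, directly as one explicit fraction per equation, sharing no
code with the package implementation.  Tests lambdify these expressions
and compare them against the package's numeric evaluators on random
states.
"""

import sympy as sp


def _s(name):
    return sp.Symbol(name, nonnegative=True)


def transporter(kin):
    c = kin.constants
    S, P = _s(kin.roles["S"]), _s(kin.roles["P"])
    isoforms = kin.isoforms if kin.isoforms else [{"f": 1.0, "K_s": c["K_s"], "K_p": c["K_p"]}]
    total = 0
    for iso in isoforms:
        total += (c["Vmf"] * iso["f"] * (S - P / c["Keq"])) / (
            iso["K_s"] * (1 + P / iso["K_p"]) + S
        )
    return total


def hexokinase(kin):
    c = kin.constants
    A, B = _s(kin.roles["A"]), _s(kin.roles["B"])
    P, Q = _s(kin.roles["P"]), _s(kin.roles["Q"])
    inhib = kin.options.get("with_fbp_inhibition", False)
    isoforms = kin.isoforms if kin.isoforms else [{"f": 1.0}]
    total = 0
    for iso in isoforms:
        m = {**c, **iso}
        Ka, Kb, Kp, Kq = m["Ka"], m["Kb"], m["Kp"], m["Kq"]
        a1 = m.get("alpha1", 1.0)
        den = (1 + A / Ka + B / Kb + A * B / (a1 * Ka * Kb) + P / Kp + Q / Kq
               + P * Q / (Kp * Kq) + A * Q / (Ka * Kq) + P * B / (Kp * Kb))
        if inhib:
            I = _s(kin.roles["I"])
            Ki, a2 = m["Ki"], m.get("alpha2", 1.0)
            den = den + I / Ki + A * I / (a2 * Ka * Ki) + A * I * B / (a1 * Ka * Kb * a2 * Ki)
        total += (c["Vmf"] * m.get("f", 1.0) / (a1 * Ka * Kb)) * (A * B - P * Q / c["Keq"]) / den
    return total


def isomerase(kin):
    c = kin.constants
    S, P = _s(kin.roles["S"]), _s(kin.roles["P"])
    num = c["Vmf"] * S / c["K_s"] - c["Vmr"] * P / c["K_p"]
    E = sum(_s(x) / c[f"Ki_{x}"] for x in kin.inhibitors)
    kind = kin.mechanism.kind
    if kind == "competitive":
        return num / (1 + S / c["K_s"] + P / c["K_p"] + E)
    if kind == "uncompetitive":
        return num / (1 + (S / c["K_s"]) * (1 + E) + (P / c["K_p"]) * (1 + E))
    a = kin.mechanism.alpha
    Ea = sum(_s(x) / (a * c[f"Ki_{x}"]) for x in kin.inhibitors)
    return num / (1 + E + (S / c["K_s"] + P / c["K_p"]) * (1 + Ea))


def pfk1(kin):
    c = kin.constants
    F6P, ATP = _s(kin.roles["F6P"]), _s(kin.roles["ATP"])
    F26, CIT = _s(kin.roles["F26BP"]), _s(kin.roles["CIT"])
    ADP, FBP = _s(kin.roles["ADP"]), _s(kin.roles["FBP"])
    Ka, al, be = c["Ka_F26BP"], c["alpha"], c["beta"]
    phi = (F6P * (1 + F26 / (al * Ka))) / (c["K_F6P"] * (1 + F26 / Ka))
    Lterm = (c["L"] * (1 + CIT / c["Ki_CIT"]) ** 4 * (1 + ATP / c["Ki_ATP"]) ** 4)
    if kin.options.get("activator_grouping", "divide") == "divide":
        Lterm = Lterm / (1 + F26 / Ka) ** 4
    else:
        Lterm = Lterm * (1 + F26 / Ka) ** 4
    fwd = ((ATP / c["K_ATP"]) / (1 + ATP / c["K_ATP"])) \
        * ((1 + be * F26 / (al * Ka)) / (1 + F26 / (al * Ka))) \
        * (phi * (1 + phi) ** 3) / (Lterm + (1 + phi) ** 4)
    rev = (ADP * FBP / (c["K_ADP"] * c["K_FBP"] * c["Keq"])) / (
        ADP / c["K_ADP"] + FBP / c["K_FBP"] + ADP * FBP / (c["K_ADP"] * c["K_FBP"]) + 1
    )
    return c["Vm"] * (fwd - rev)


def aldolase(kin):
    c = kin.constants
    S = _s(kin.roles["S"])
    P1, P2 = _s(kin.roles["P1"]), _s(kin.roles["P2"])
    return (c["Vmf"] * S / c["K_s"] - c["Vmr"] * P1 * P2 / (c["K_p1"] * c["K_p2"])) / (
        1 + S / c["K_s"] + P1 / c["K_p1"] + P2 / c["K_p2"]
        + P1 * P2 / (c["K_p1"] * c["K_p2"])
    )


def uni_uni(kin):
    c = kin.constants
    S, P = _s(kin.roles["S"]), _s(kin.roles["P"])
    num = c["Vmf"] * S / c["K_s"] - c["Vmr"] * P / c["K_p"]
    if "I" in kin.roles:
        I = _s(kin.roles["I"])
        Ki, a = c["Ki"], c["alpha"]
        return num / (1 + I / Ki + (S / c["K_s"] + P / c["K_p"]) * (1 + I / (a * Ki)))
    return num / (1 + S / c["K_s"] + P / c["K_p"])


def gapdh(kin):
    c = kin.constants
    A, B, C = _s(kin.roles["A"]), _s(kin.roles["B"]), _s(kin.roles["C"])
    P, Q = _s(kin.roles["P"]), _s(kin.roles["Q"])
    Ka, Kb, Kc, Kp, Kq = c["Ka"], c["Kb"], c["Kc"], c["Kp"], c["Kq"]
    num = c["Vmf"] * A * B * C / (Ka * Kb * Kc) - c["Vmr"] * P * Q / (Kp * Kq)
    den = (1 + A / Ka + A * B / (Ka * Kb) + A * B * C / (Ka * Kb * Kc)
           + P * Q / (Kp * Kq) + Q / Kq)
    if kin.options.get("with_fbp_inhibition", False):
        I = _s(kin.roles["I"])
        Ki, a = c["Ki"], c["alpha"]
        den = den + I / Ki + A * B * I / (Ka * Kb * a * Ki) \
            + A * B * C * I / (Ka * Kb * Kc * a * Ki) + P * Q * I / (Kp * Kq * a * Ki)
    return num / den


def random_bibi_keq(kin):
    c = kin.constants
    A, B = _s(kin.roles["A"]), _s(kin.roles["B"])
    P, Q = _s(kin.roles["P"]), _s(kin.roles["Q"])
    Ka, Kb, Kp, Kq = c["Ka"], c["Kb"], c["Kp"], c["Kq"]
    return (c["Vmf"] / (Ka * Kb)) * (A * B - P * Q / c["Keq"]) / (
        1 + A / Ka + B / Kb + A * B / (Ka * Kb) + P / Kp + Q / Kq
        + P * Q / (Kp * Kq) + A * Q / (Ka * Kq) + P * B / (Kp * Kb)
    )


def random_bibi_vmr(kin):
    c = kin.constants
    A, B = _s(kin.roles["A"]), _s(kin.roles["B"])
    P, Q = _s(kin.roles["P"]), _s(kin.roles["Q"])
    Ka, Kb, Kp, Kq = c["Ka"], c["Kb"], c["Kp"], c["Kq"]
    a, b = c.get("alpha", 1.0), c.get("beta", 1.0)
    return (c["Vmf"] * A * B / (a * Ka * Kb) - c["Vmr"] * P * Q / (b * Kp * Kq)) / (
        1 + A / Ka + B / Kb + A * B / (a * Ka * Kb) + P * Q / (b * Kp * Kq)
        + P / Kp + Q / Kq
    )


def mass_action(kin):
    return kin.constants["k"] * _s(kin.roles["S"])


BY_FAMILY = {
    "transporter_rev_mm": transporter,
    "hk_random_bibi": hexokinase,
    "hpi_multi_inhib": isomerase,
    "pfk1_mwc": pfk1,
    "aldo_unibi": aldolase,
    "uni_uni_rev_mm": uni_uni,
    "gapdh_terbi": gapdh,
    "random_bibi_keq": random_bibi_keq,
    "random_bibi_vmr": random_bibi_vmr,
    "mass_action": mass_action,
}


def oracle_rate(kin, state):
    """Evaluate the oracle transcription at a concentration state."""
    expr = BY_FAMILY[kin.family](kin)
    symbols = sorted(expr.free_symbols, key=lambda x: x.name)
    fn = sp.lambdify(symbols, expr, "math")
    return float(fn(*[state[s.name] for s in symbols]))
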