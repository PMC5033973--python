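"""Curated (synthetic) reference parameter sets for the cell-line models.

These presets are synthetic stand-ins for the full experimental kinetic
parameter tables of the source cell lines: they combine the kinetic
constants that are printed in the primary literature on tumor glycolysis
(hexose phosphate isomerase inhibition constants Ki_Ery4P = 1e-3 mM,
Ki_Fru1,6BP = 0.06 mM, Ki_6PG = 0.015 mM, Ki_DHAP = 9.4 mM; mixed-type
interaction factor alpha = 2) with standard textbook equilibrium constants
and physiologically plausible Km/Vmax values chosen once so that

* flux control is concentrated in the upstream segment (glucose
  transporter, hexokinase, hexose phosphate isomerase), as measured in
  AS-30D and HeLa cells, with downstream enzymes (ENO, PYK, LDH, PGK,
  PGAM) in catalytic excess and hence nearly flux-neutral;
* steady-state metabolite levels fall in the measured physiological
  ranges (Fru1,6BP of a few mM, DHAP of 1-2 mM, ATP of several mM);
* the feedback loops of the full model (Fru1,6BP on HK, TPI, GAPDH;
  DHAP and Fru1,6BP on HPI) operate near their inhibition constants.

Concentrations are mM; maximal rates are mM/min.  Equilibrium constants
are physical constants and are never sampled or tuned.

Reaction set (AS-30D): GLUT, HK, HPI, PFK1, ALDO, TPI, GAPDH, PGK, PGAM,
ENO, PYK, LDH plus closure reactions (ATPase, NADH oxidase, hexose- and
triose-phosphate branch drains).  HeLa adds the lactate carrier MCT and
models the glucose carrier and hexokinase as two-isoform variants.
"""

from __future__ import annotations

from .network import build_model

__all__ = ["preset_parameters", "preset_model", "KEQ"]

#: Equilibrium constants on the concentration (mM) scale, glycolytic
#: direction. GAPDH's carries one net mM power (Ter-Bi).
KEQ = {
    "GLUT": 1.0,
    "HK": 651.0,
    "HPI": 0.31,
    "PFK1": 276.0,
    "ALDO": 0.099,       # mM; Fru1,6BP -> DHAP + G3P
    "TPI": 0.0455,       # [G3P]/[DHAP]
    "GAPDH": 6.7e-5,     # mM^-1
    "PGK": 1800.0,
    "PGAM": 0.147,
    "ENO": 5.19,
    "PYK": 6500.0,
    "LDH": 16000.0,
    "MCT": 1.0,
}


def _haldane_uni(Vmf, Ks, Kp, Keq):
    return Vmf * Kp / (Ks * Keq)


def _as30d_parameters() -> dict:
    """AS-30D hepatoma model (full feedback form)."""
    species = {
        # free
        "Glc_in": {"initial": 0.7},
        "Glc6P": {"initial": 2.0},
        "Fru6P": {"initial": 0.5},
        "FBP": {"initial": 2.0},
        "DHAP": {"initial": 1.5},
        "G3P": {"initial": 0.07},
        "BPG": {"initial": 0.06},
        "P3G": {"initial": 0.4},
        "P2G": {"initial": 0.05},
        "PEP": {"initial": 0.04},
        "Pyr": {"initial": 0.9},
        "ATP": {"initial": 5.0},
        "ADP": {"initial": 3.0},
        "NAD": {"initial": 0.45},
        "NADH": {"initial": 0.05},
        # boundary
        "Glc_out": {"initial": 5.0, "fixed": True},
        "Lac_in": {"initial": 5.0, "fixed": True},
        "Pi": {"initial": 4.0, "fixed": True},
        "Ery4P": {"initial": 0.002, "fixed": True},
        "PG6": {"initial": 0.02, "fixed": True},
        "F26BP": {"initial": 0.02, "fixed": True},
        "CIT": {"initial": 0.5, "fixed": True},
    }
    hpi = {"Vmf": 1300.0, "K_s": 0.9, "K_p": 0.25}
    hpi["Vmr"] = _haldane_uni(hpi["Vmf"], hpi["K_s"], hpi["K_p"], KEQ["HPI"])
    tpi = {"Vmf": 1600.0, "K_s": 1.6, "K_p": 0.45, "Ki": 5.0, "alpha": 2.0}
    tpi["Vmr"] = _haldane_uni(tpi["Vmf"], tpi["K_s"], tpi["K_p"], KEQ["TPI"])
    pgam = {"Vmf": 500.0, "K_s": 0.5, "K_p": 0.08}
    pgam["Vmr"] = _haldane_uni(pgam["Vmf"], pgam["K_s"], pgam["K_p"], KEQ["PGAM"])
    eno = {"Vmf": 120.0, "K_s": 0.06, "K_p": 0.3}
    eno["Vmr"] = _haldane_uni(eno["Vmf"], eno["K_s"], eno["K_p"], KEQ["ENO"])
    aldo = {"Vmf": 40.0, "K_s": 0.35, "K_p1": 2.0, "K_p2": 1.0, "Keq": KEQ["ALDO"]}
    aldo["Vmr"] = aldo["Vmf"] * aldo["K_p1"] * aldo["K_p2"] / (aldo["K_s"] * aldo["Keq"])
    gapdh = {
        "Vmf": 250.0, "Ka": 0.09, "Kb": 1.0, "Kc": 3.0,
        "Kp": 0.022, "Kq": 0.01, "Keq": KEQ["GAPDH"],
        "Ki": 3.0, "alpha": 2.0,
    }
    gapdh["Vmr"] = (
        gapdh["Vmf"] * gapdh["Kp"] * gapdh["Kq"]
        / (gapdh["Ka"] * gapdh["Kb"] * gapdh["Kc"] * gapdh["Keq"])
    )
    pgk = {"Vmf": 2000.0, "Ka": 0.01, "Kb": 0.35, "Kp": 0.6, "Kq": 0.45,
           "Keq": KEQ["PGK"], "alpha": 1.0, "beta": 1.0}
    pgk["Vmr"] = pgk["Vmf"] * pgk["Kp"] * pgk["Kq"] / (pgk["Ka"] * pgk["Kb"] * pgk["Keq"])
    ldh = {"Vmf": 2500.0, "Ka": 0.01, "Kb": 0.13, "Kp": 4.7, "Kq": 0.5,
           "Keq": KEQ["LDH"], "alpha": 1.0, "beta": 1.0}
    ldh["Vmr"] = ldh["Vmf"] * ldh["Kp"] * ldh["Kq"] / (ldh["Ka"] * ldh["Kb"] * ldh["Keq"])
    reactions = [
        {
            "name": "GLUT",
            "stoichiometry": {"Glc_out": -1, "Glc_in": 1},
            "family": "transporter_rev_mm",
            "roles": {"S": "Glc_out", "P": "Glc_in"},
            "constants": {"Vmf": 22.0, "Keq": KEQ["GLUT"], "K_s": 9.0, "K_p": 9.0},
        },
        {
            "name": "HK",
            "stoichiometry": {"Glc_in": -1, "ATP": -1, "Glc6P": 1, "ADP": 1},
            "family": "hk_random_bibi",
            "roles": {"A": "Glc_in", "B": "ATP", "P": "Glc6P", "Q": "ADP", "I": "FBP"},
            "constants": {
                "Vmf": 24.0, "Keq": KEQ["HK"], "Ka": 0.1, "Kb": 1.0,
                "Kp": 15.0, "Kq": 3.5, "alpha1": 1.0, "alpha2": 1.0, "Ki": 2.2,
            },
            "options": {"with_fbp_inhibition": True},
        },
        {
            "name": "HPI",
            "stoichiometry": {"Glc6P": -1, "Fru6P": 1},
            "family": "hpi_multi_inhib",
            "roles": {"S": "Glc6P", "P": "Fru6P"},
            "inhibitors": ["Ery4P", "PG6", "FBP", "DHAP"],
            "mechanism": {"kind": "competitive"},
            "constants": {
                **hpi, "Keq": KEQ["HPI"],
                "Ki_Ery4P": 0.001, "Ki_PG6": 0.015, "Ki_FBP": 0.06, "Ki_DHAP": 9.4,
            },
        },
        {
            "name": "PFK1",
            "stoichiometry": {"Fru6P": -1, "ATP": -1, "FBP": 1, "ADP": 1},
            "family": "pfk1_mwc",
            "roles": {"F6P": "Fru6P", "ATP": "ATP", "F26BP": "F26BP",
                      "CIT": "CIT", "ADP": "ADP", "FBP": "FBP"},
            "constants": {
                "Vm": 45.0, "K_ATP": 0.06, "K_F6P": 1.0, "Ka_F26BP": 0.0042,
                "Ki_CIT": 6.8, "Ki_ATP": 2.5, "L": 1000.0,
                "alpha": 0.45, "beta": 1.1,
                "K_ADP": 0.54, "K_FBP": 5.0, "Keq": KEQ["PFK1"],
            },
        },
        {
            "name": "ALDO",
            "stoichiometry": {"FBP": -1, "DHAP": 1, "G3P": 1},
            "family": "aldo_unibi",
            "roles": {"S": "FBP", "P1": "DHAP", "P2": "G3P"},
            "constants": aldo,
        },
        {
            "name": "TPI",
            "stoichiometry": {"DHAP": -1, "G3P": 1},
            "family": "uni_uni_rev_mm",
            "roles": {"S": "DHAP", "P": "G3P", "I": "FBP"},
            "constants": {**tpi, "Keq": KEQ["TPI"]},
        },
        {
            "name": "GAPDH",
            "stoichiometry": {"G3P": -1, "NAD": -1, "Pi": -1, "BPG": 1, "NADH": 1},
            "family": "gapdh_terbi",
            "roles": {"A": "NAD", "B": "G3P", "C": "Pi", "P": "BPG", "Q": "NADH",
                      "I": "FBP"},
            "constants": gapdh,
            "options": {"with_fbp_inhibition": True},
        },
        {
            "name": "PGK",
            "stoichiometry": {"BPG": -1, "ADP": -1, "P3G": 1, "ATP": 1},
            "family": "random_bibi_vmr",
            "roles": {"A": "BPG", "B": "ADP", "P": "P3G", "Q": "ATP"},
            "constants": pgk,
        },
        {
            "name": "PGAM",
            "stoichiometry": {"P3G": -1, "P2G": 1},
            "family": "uni_uni_rev_mm",
            "roles": {"S": "P3G", "P": "P2G"},
            "constants": {**pgam, "Keq": KEQ["PGAM"]},
        },
        {
            "name": "ENO",
            "stoichiometry": {"P2G": -1, "PEP": 1},
            "family": "uni_uni_rev_mm",
            "roles": {"S": "P2G", "P": "PEP"},
            "constants": {**eno, "Keq": KEQ["ENO"]},
        },
        {
            "name": "PYK",
            "stoichiometry": {"PEP": -1, "ADP": -1, "Pyr": 1, "ATP": 1},
            "family": "random_bibi_keq",
            "roles": {"A": "PEP", "B": "ADP", "P": "Pyr", "Q": "ATP"},
            "constants": {"Vmf": 400.0, "Keq": KEQ["PYK"], "Ka": 0.4, "Kb": 0.3,
                          "Kp": 10.0, "Kq": 2.6},
        },
        {
            "name": "LDH",
            "stoichiometry": {"Pyr": -1, "NADH": -1, "Lac_in": 1, "NAD": 1},
            "family": "random_bibi_vmr",
            "roles": {"A": "NADH", "B": "Pyr", "P": "Lac_in", "Q": "NAD"},
            "constants": ldh,
        },
        {
            "name": "ATPase",
            "stoichiometry": {"ATP": -1, "ADP": 1},
            "family": "mass_action",
            "roles": {"S": "ATP"},
            "constants": {"k": 2.0},
        },
        {
            "name": "G6P_drain",
            "stoichiometry": {"Glc6P": -1},
            "family": "mass_action",
            "roles": {"S": "Glc6P"},
            "constants": {"k": 0.15},
        },
        {
            "name": "DHAP_drain",
            "stoichiometry": {"DHAP": -1},
            "family": "mass_action",
            "roles": {"S": "DHAP"},
            "constants": {"k": 0.04},
        },
    ]
    return {
        "name": "AS30D",
        "condition": "AS30D",
        "species": species,
        "reactions": reactions,
        "pathway_flux_reaction": "LDH",
        "flux_unit": "mM/min",
        "notes": "curated synthetic stand-in parameter set (AS-30D-like)",
    }


def _hela_parameters(condition: str) -> dict:
    """HeLa-like model; conditions differ in external glucose and carrier/
    hexokinase capacity (glucose-starved cells up-regulate GLUT3 and run
    on a lower-capacity transport step, making GLUT the dominant
    controller under hypoglycemia)."""
    glc_out = {"HeLa_hyper": 25.0, "HeLa_normo": 5.0, "HeLa_hypo": 1.0}[condition]
    glut_vmf = {"HeLa_hyper": 12.0, "HeLa_normo": 11.0, "HeLa_hypo": 18.0}[condition]
    hk_vmf = {"HeLa_hyper": 20.0, "HeLa_normo": 20.0, "HeLa_hypo": 30.0}[condition]
    p = _as30d_parameters()
    p["name"] = condition
    p["condition"] = condition
    p["pathway_flux_reaction"] = "MCT"
    p["notes"] = "curated synthetic stand-in parameter set (HeLa-like)"
    species = p["species"]
    species["Glc_out"]["initial"] = glc_out
    # lactate is exported by the carrier in HeLa: Lac_in becomes free.
    species["Lac_in"] = {"initial": 5.0}
    species["Lac_out"] = {"initial": 2.0, "fixed": True}
    by_name = {r["name"]: r for r in p["reactions"]}
    # two-isoform carrier (GLUT1/GLUT3)
    by_name["GLUT"]["constants"] = {"Vmf": glut_vmf, "Keq": 1.0}
    by_name["GLUT"]["isoforms"] = [
        {"f": 0.65, "K_s": 1.04, "K_p": 1.04},
        {"f": 0.35, "K_s": 9.3, "K_p": 9.3},
    ]
    # two-isoform hexokinase (HKI/HKII), no Fru1,6BP inhibition
    hk = by_name["HK"]
    hk["constants"] = {
        "Vmf": hk_vmf, "Keq": KEQ["HK"], "Kb": 1.1, "Kp": 15.0, "Kq": 3.5,
        "Ka": 0.1,
    }
    hk["isoforms"] = [{"f": 0.7, "Ka": 0.1}, {"f": 0.3, "Ka": 0.4}]
    hk["options"] = {"with_fbp_inhibition": False}
    hk["roles"] = {k: v for k, v in hk["roles"].items() if k != "I"}
    # isomerase: three competitive inhibitors (DHAP only inhibits at
    # supra-physiological levels and is excluded)
    hpi = by_name["HPI"]
    hpi["inhibitors"] = ["Ery4P", "PG6", "FBP"]
    hpi["constants"] = {k: v for k, v in hpi["constants"].items() if k != "Ki_DHAP"}
    # triosephosphate isomerase without feedback
    tpi = by_name["TPI"]
    tpi["roles"] = {"S": "DHAP", "P": "G3P"}
    tpi["constants"] = {k: v for k, v in tpi["constants"].items()
                        if k not in ("Ki", "alpha")}
    # GAPDH without feedback
    gap = by_name["GAPDH"]
    gap["options"] = {"with_fbp_inhibition": False}
    gap["roles"] = {k: v for k, v in gap["roles"].items() if k != "I"}
    gap["constants"] = {k: v for k, v in gap["constants"].items()
                        if k not in ("Ki", "alpha")}
    # HeLa cells run a higher basal ATP demand in culture
    by_name["ATPase"]["constants"]["k"] = 3.0
    # LDH now feeds free intracellular lactate, exported by MCT
    p["reactions"].append(
        {
            "name": "MCT",
            "stoichiometry": {"Lac_in": -1, "Lac_out": 1},
            "family": "transporter_rev_mm",
            "roles": {"S": "Lac_in", "P": "Lac_out"},
            "constants": {"Vmf": 45.0, "Keq": KEQ["MCT"], "K_s": 4.7, "K_p": 4.7},
        }
    )
    return p


def preset_parameters(condition: str) -> dict:
    """Native-schema parameter record for one condition
    (``AS30D``, ``HeLa_hyper``, ``HeLa_normo`` or ``HeLa_hypo``)."""
    if condition == "AS30D":
        return _as30d_parameters()
    if condition in ("HeLa_hyper", "HeLa_normo", "HeLa_hypo"):
        return _hela_parameters(condition)
    raise ValueError(f"unknown condition {condition!r}")


def preset_model(condition: str):
    """Built and validated preset model for one condition."""
    return build_model(condition, preset_parameters(condition))
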