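"""Rate-law correctness: frozen hand-computed values, independent
symbolic-oracle agreement, thermodynamic and structural properties."""

import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from glycontrol import preset_model
from glycontrol.errors import ParameterError, StateError
from glycontrol.rate_laws import (
    InhibitionMechanism,
    ReactionKinetics,
    eval_hk_random_bibi,
    eval_hpi_multi_inhib,
    eval_pfk1_mwc,
    eval_random_bibi,
    eval_transporter_rev_mm,
    eval_uni_uni_rev_mm,
    evaluate_rate,
    haldane_residual,
    haldane_vmr,
    with_haldane_vmr,
)

from conftest import random_state
from oracle import BY_FAMILY, oracle_rate


def _transporter(**over):
    k = ReactionKinetics(
        "transporter_rev_mm",
        constants={"Vmf": 100.0, "Keq": 1.0, "K_s": 1.0, "K_p": 1.0},
        roles={"S": "S_out", "P": "S_in"},
    )
    k.constants.update(over)
    return k


def _hpi(mechanism="competitive", alpha=None, inhibitors=("I1",), **over):
    k = ReactionKinetics(
        "hpi_multi_inhib",
        constants={"Vmf": 10.0, "Vmr": 0.0, "K_s": 1.0, "K_p": 1.0,
                   **{f"Ki_{i}": 1.0 for i in inhibitors}},
        roles={"S": "S", "P": "P"},
        inhibitors=tuple(inhibitors),
        mechanism=InhibitionMechanism(mechanism, alpha),
    )
    k.constants.update(over)
    return k


class TestFrozenValues:
    """Hand-substituted values of each printed equation."""

    def test_carrier_direct_substitution(self):
        k = _transporter()
        v = eval_transporter_rev_mm({"S_out": 5.0, "S_in": 1.0}, k)
        assert v == pytest.approx(400.0 / 7.0, rel=1e-12)

    def test_hexokinase_round_numbers(self):
        k = ReactionKinetics(
            "hk_random_bibi",
            constants={"Vmf": 10.0, "Keq": 1000.0, "Ka": 1.0, "Kb": 1.0,
                       "Kp": 1.0, "Kq": 1.0, "alpha1": 1.0, "alpha2": 1.0,
                       "Ki": 1.0},
            roles={"A": "A", "B": "B", "P": "P", "Q": "Q", "I": "I"},
            options={"with_fbp_inhibition": True},
        )
        state = {"A": 1.0, "B": 1.0, "P": 0.0, "Q": 0.0, "I": 2.0}
        # denominator: 1 + 1 + 1 + 1 + 2 + 2 + 2 = 10; numerator 10
        assert eval_hk_random_bibi(state, k) == pytest.approx(1.0, rel=1e-12)

    def test_isomerase_competitive_and_uncompetitive(self):
        state = {"S": 1.0, "P": 0.0, "I1": 3.0}
        assert eval_hpi_multi_inhib(state, _hpi("competitive")) == pytest.approx(2.0)
        assert eval_hpi_multi_inhib(state, _hpi("uncompetitive")) == pytest.approx(2.0)
        # they diverge as soon as the product appears
        state2 = {"S": 1.0, "P": 0.5, "I1": 3.0}
        vc = eval_hpi_multi_inhib(state2, _hpi("competitive"))
        vu = eval_hpi_multi_inhib(state2, _hpi("uncompetitive"))
        assert vc != pytest.approx(vu)

    def test_aldolase_substitution(self):
        k = ReactionKinetics(
            "aldo_unibi",
            constants={"Vmf": 10.0, "Vmr": 0.0, "K_s": 1.0, "K_p1": 1.0, "K_p2": 1.0},
            roles={"S": "S", "P1": "P1", "P2": "P2"},
        )
        assert evaluate_rate({"S": 1.0, "P1": 0.0, "P2": 0.0}, k) == pytest.approx(5.0)

    def test_uni_uni_substitution(self):
        k = ReactionKinetics(
            "uni_uni_rev_mm",
            constants={"Vmf": 10.0, "Vmr": 0.0, "K_s": 1.0, "K_p": 1.0},
            roles={"S": "S", "P": "P"},
        )
        assert eval_uni_uni_rev_mm({"S": 1.0, "P": 0.0}, k) == pytest.approx(5.0)

    def test_random_bibi_substitution(self):
        k = ReactionKinetics(
            "random_bibi_vmr",
            constants={"Vmf": 10.0, "Vmr": 0.0, "Ka": 1.0, "Kb": 1.0,
                       "Kp": 1.0, "Kq": 1.0, "alpha": 1.0, "beta": 1.0},
            roles={"A": "A", "B": "B", "P": "P", "Q": "Q"},
        )
        state = {"A": 1.0, "B": 1.0, "P": 0.0, "Q": 0.0}
        assert eval_random_bibi(state, k, "vmr_form") == pytest.approx(2.5)


def _model_kinetics():
    """All (reaction, kinetics) pairs of both cell-line models."""
    pairs = []
    for cond in ("AS30D", "HeLa_hypo"):
        m = preset_model(cond)
        for r in m.reactions:
            pairs.append(pytest.param(r.kinetics, id=f"{cond}:{r.name}"))
    return pairs


@pytest.mark.parametrize("kin", _model_kinetics())
def test_matches_independent_symbolic_transcription(kin, rng):
    """Numeric evaluators equal a second, independent transcription of
    each printed equation on 100 random states (rel. error < 1e-10)."""
    expr = BY_FAMILY[kin.family](kin)
    symbols = sorted(expr.free_symbols, key=lambda s: s.name)
    fn = sp.lambdify(symbols, expr, "math")
    species = set(kin.roles.values()) | set(kin.inhibitors)
    for _ in range(100):
        state = random_state(rng, species)
        expected = fn(*[state[s.name] for s in symbols])
        got = evaluate_rate(state, kin)
        assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)


@pytest.mark.parametrize("kin", _model_kinetics())
def test_linear_in_enzyme_activity(kin, rng):
    """Doubling the maximal rates doubles the rate at any state."""
    species = set(kin.roles.values()) | set(kin.inhibitors)
    doubled = kin.copy()
    for name in ("Vmf", "Vmr", "Vm", "k"):
        if name in doubled.constants:
            doubled.constants[name] *= 2.0
    for _ in range(20):
        state = random_state(rng, species)
        assert evaluate_rate(state, doubled) == pytest.approx(
            2.0 * evaluate_rate(state, kin), rel=1e-12, abs=1e-12
        )


class TestThermodynamics:
    def test_carrier_zero_at_equilibrium(self):
        k = _transporter(Keq=3.0)
        assert eval_transporter_rev_mm({"S_out": 6.0, "S_in": 18.0}, k) == 0.0

    def test_two_equal_isoforms_match_single_carrier(self):
        k1 = _transporter()
        k2 = _transporter()
        k2.isoforms = ({"f": 0.5, "K_s": 1.0, "K_p": 1.0},
                       {"f": 0.5, "K_s": 1.0, "K_p": 1.0})
        state = {"S_out": 5.0, "S_in": 1.0}
        assert eval_transporter_rev_mm(state, k2) == pytest.approx(
            eval_transporter_rev_mm(state, k1), rel=1e-14
        )

    @pytest.mark.parametrize("name", ["HPI", "TPI", "ALDO", "GAPDH", "PGK",
                                      "PGAM", "ENO", "LDH"])
    def test_reversible_laws_vanish_at_haldane_equilibrium(self, as30d, name, rng):
        """With Vmr set by the Haldane relation, every reversible law is
        exactly zero when the mass-action ratio equals Keq."""
        kin = with_haldane_vmr(as30d.reaction(name).kinetics)
        Keq = kin.constants["Keq"]
        for _ in range(20):
            state = random_state(rng, set(kin.roles.values()) | set(kin.inhibitors))
            # force the mass-action ratio onto Keq by adjusting one product
            if kin.family in ("hpi_multi_inhib", "uni_uni_rev_mm"):
                state[kin.roles["P"]] = Keq * state[kin.roles["S"]]
            elif kin.family == "aldo_unibi":
                state[kin.roles["P2"]] = Keq * state[kin.roles["S"]] / state[kin.roles["P1"]]
            elif kin.family == "gapdh_terbi":
                state[kin.roles["P"]] = (
                    Keq * state[kin.roles["A"]] * state[kin.roles["B"]]
                    * state[kin.roles["C"]] / state[kin.roles["Q"]]
                )
            elif kin.family == "random_bibi_vmr":
                state[kin.roles["P"]] = (
                    Keq * state[kin.roles["A"]] * state[kin.roles["B"]]
                    / state[kin.roles["Q"]]
                )
            v = evaluate_rate(state, kin)
            scale = kin.constants["Vmf"]
            assert abs(v) < 1e-9 * scale

    def test_keq_form_kinase_zero_at_equilibrium(self):
        k = ReactionKinetics(
            "random_bibi_keq",
            constants={"Vmf": 7.0, "Keq": 2.0, "Ka": 0.3, "Kb": 0.5,
                       "Kp": 1.0, "Kq": 2.0},
            roles={"A": "A", "B": "B", "P": "P", "Q": "Q"},
        )
        state = {"A": 1.0, "B": 1.5, "P": 2.0, "Q": 1.5}  # PQ/AB = 2 = Keq
        assert evaluate_rate(state, k) == pytest.approx(0.0, abs=1e-14)

    def test_haldane_residual_detects_perturbation(self, as30d):
        kin = as30d.reaction("ENO").kinetics.copy()
        assert haldane_residual(kin) == pytest.approx(0.0, abs=1e-12)
        kin.constants["Vmr"] *= 1.10
        assert haldane_residual(kin) == pytest.approx(0.10, rel=1e-9)


class TestInhibitionReductions:
    def test_hexokinase_inhibitor_free_equals_flag_off(self, rng):
        base = preset_model("AS30D").reaction("HK").kinetics
        off = base.copy()
        off.options["with_fbp_inhibition"] = False
        off.roles.pop("I")
        for _ in range(20):
            state = random_state(rng, set(base.roles.values()))
            state["FBP"] = 0.0
            assert eval_hk_random_bibi(state, base) == pytest.approx(
                evaluate_rate(state, off), rel=1e-14
            )

    def test_mechanisms_coincide_without_inhibitors(self, rng):
        for _ in range(20):
            state = {"S": rng.uniform(0.1, 5), "P": rng.uniform(0.1, 5), "I1": 0.0}
            vals = [
                eval_hpi_multi_inhib(state, _hpi(m, alpha=2.0 if m == "mixed" else None))
                for m in ("competitive", "uncompetitive", "mixed")
            ]
            assert max(vals) - min(vals) < 1e-14 * max(1.0, abs(vals[0]))

    def test_mechanisms_preserve_equilibrium(self):
        # Vmr from Haldane with Keq=2: rate 0 at P/S = 2 under all mechanisms
        for mech, alpha in (("competitive", None), ("uncompetitive", None),
                            ("mixed", 2.0)):
            k = _hpi(mech, alpha, Vmr=5.0, Keq=2.0)
            state = {"S": 1.0, "P": 2.0, "I1": 1.7}
            assert evaluate_rate(state, k) == pytest.approx(0.0, abs=1e-14)

    def test_uncompetitive_not_rescued_by_substrate(self):
        """At saturating substrate the uncompetitive law stays suppressed
        while the competitive law recovers the uninhibited limit."""
        state = {"S": 1e7, "P": 0.0, "I1": 3.0}
        vc = eval_hpi_multi_inhib(state, _hpi("competitive"))
        vu = eval_hpi_multi_inhib(state, _hpi("uncompetitive"))
        assert vc == pytest.approx(10.0, rel=1e-4)
        assert vu == pytest.approx(10.0 / 4.0, rel=1e-4)
        assert vu < vc

    def test_mixed_uni_uni_reduces_and_has_alpha_limit(self):
        base = {"Vmf": 10.0, "Vmr": 1.0, "K_s": 0.5, "K_p": 2.0, "Ki": 1.0,
                "alpha": 2.0}
        with_i = ReactionKinetics("uni_uni_rev_mm", dict(base),
                                  roles={"S": "S", "P": "P", "I": "I"})
        without = ReactionKinetics("uni_uni_rev_mm", dict(base),
                                   roles={"S": "S", "P": "P"})
        state = {"S": 1.0, "P": 0.3, "I": 0.0}
        assert evaluate_rate(state, with_i) == pytest.approx(
            evaluate_rate(state, without), rel=1e-14
        )
        # I -> infinity: I * v(I) approaches the closed-form limit
        s = state["S"] / base["K_s"]
        p = state["P"] / base["K_p"]
        num = base["Vmf"] * s - base["Vmr"] * p
        limit = base["Ki"] * num / (1.0 + (s + p) / base["alpha"])
        big = 1e9
        state["I"] = big
        assert big * evaluate_rate(state, with_i) == pytest.approx(limit, rel=1e-6)

    def test_gapdh_inhibited_form_reduces_at_zero_inhibitor(self, as30d, rng):
        base = as30d.reaction("GAPDH").kinetics
        off = base.copy()
        off.options["with_fbp_inhibition"] = False
        off.roles.pop("I")
        for _ in range(100):
            state = random_state(rng, set(base.roles.values()))
            state["FBP"] = 0.0
            assert evaluate_rate(state, base) == pytest.approx(
                evaluate_rate(state, off), rel=1e-14
            )


class TestAllostericLaw:
    def _kin(self, **over):
        kin = preset_model("AS30D").reaction("PFK1").kinetics.copy()
        kin.constants.update(over)
        return kin

    def _state(self, **over):
        state = {"Fru6P": 0.5, "ATP": 2.0, "ADP": 1.0, "FBP": 0.5,
                 "F26BP": 0.02, "CIT": 0.5}
        state.update(over)
        return state

    def test_zero_without_substrates(self):
        v = eval_pfk1_mwc(self._state(Fru6P=0.0, ADP=0.0, FBP=0.0), self._kin())
        assert v == 0.0

    def test_monotone_in_activator_and_inhibitor(self):
        kin = self._kin()
        f26 = np.linspace(1e-4, 0.1, 30)
        rates = [eval_pfk1_mwc(self._state(F26BP=x), kin) for x in f26]
        assert np.all(np.diff(rates) > 0)
        cit = np.linspace(0.0, 5.0, 30)
        rates = [eval_pfk1_mwc(self._state(CIT=x), kin) for x in cit]
        assert np.all(np.diff(rates) < 0)

    def test_hyperbolic_limit_without_allostery(self):
        """L = 0 and no citrate: the substrate dependence loses its
        sigmoidicity (fitted Hill coefficient ~ 1)."""
        from scipy.optimize import curve_fit

        kin = self._kin(L=0.0)
        s = np.logspace(-2, 1.5, 40)
        v = np.array([
            eval_pfk1_mwc(self._state(Fru6P=x, CIT=0.0, ADP=0.0, FBP=0.0), kin)
            for x in s
        ])

        def hill(x, vmax, k, n):
            return vmax * x**n / (k**n + x**n)

        popt, _ = curve_fit(hill, s, v, p0=[v.max(), 1.0, 1.5], maxfev=20000)
        assert popt[2] == pytest.approx(1.0, abs=0.05)

    def test_sigmoidal_with_large_l(self):
        kin = self._kin(L=1e5)
        lo = eval_pfk1_mwc(self._state(Fru6P=0.05, ADP=0.0, FBP=0.0), kin)
        mid = eval_pfk1_mwc(self._state(Fru6P=1.0, ADP=0.0, FBP=0.0), kin)
        # cooperative: 20x substrate gives far more than 20x rate
        assert mid / lo > 50

    def test_activator_grouping_switch_changes_value(self):
        div = self._kin()
        mul = self._kin()
        mul.options = {**mul.options, "activator_grouping": "multiply"}
        state = self._state()
        assert eval_pfk1_mwc(state, div) > eval_pfk1_mwc(state, mul)

    def test_negative_l_rejected(self):
        with pytest.raises(ParameterError):
            eval_pfk1_mwc(self._state(), self._kin(L=-1.0))


class TestKinaseFormEquivalence:
    """The Keq-form and Vmr-form random Bi-Bi laws share numerator (hence
    equilibrium) under the Haldane choice of Vmr, and coincide exactly on
    product-free states; their denominators differ by two cross terms."""

    def _pair(self):
        keq = ReactionKinetics(
            "random_bibi_keq",
            constants={"Vmf": 11.0, "Keq": 40.0, "Ka": 0.3, "Kb": 0.8,
                       "Kp": 2.0, "Kq": 1.1},
            roles={"A": "A", "B": "B", "P": "P", "Q": "Q"},
        )
        c = keq.constants
        vmr = ReactionKinetics(
            "random_bibi_vmr",
            constants={**c, "alpha": 1.0, "beta": 1.0,
                       "Vmr": c["Vmf"] * c["Kp"] * c["Kq"] / (c["Ka"] * c["Kb"] * c["Keq"])},
            roles=dict(keq.roles),
        )
        return keq, vmr

    def test_agree_on_product_free_states(self, rng):
        keq, vmr = self._pair()
        for _ in range(100):
            state = {"A": rng.uniform(0.01, 10), "B": rng.uniform(0.01, 10),
                     "P": 0.0, "Q": 0.0}
            assert evaluate_rate(state, keq) == pytest.approx(
                evaluate_rate(state, vmr), rel=1e-12
            )

    def test_share_equilibrium(self, rng):
        keq, vmr = self._pair()
        for _ in range(50):
            state = {"A": rng.uniform(0.1, 5), "B": rng.uniform(0.1, 5),
                     "Q": rng.uniform(0.1, 5)}
            state["P"] = keq.constants["Keq"] * state["A"] * state["B"] / state["Q"]
            assert abs(evaluate_rate(state, keq)) < 1e-10
            assert abs(evaluate_rate(state, vmr)) < 1e-10


class TestErrors:
    def test_missing_species_is_state_error(self):
        with pytest.raises(StateError):
            eval_transporter_rev_mm({"S_out": 1.0}, _transporter())

    def test_negative_concentration_is_state_error(self):
        with pytest.raises(StateError):
            eval_transporter_rev_mm({"S_out": 1.0, "S_in": -0.1}, _transporter())

    def test_nonpositive_k_is_parameter_error(self):
        with pytest.raises(ParameterError):
            eval_transporter_rev_mm({"S_out": 1.0, "S_in": 1.0},
                                    _transporter(K_s=-1.0))

    def test_missing_constant_is_parameter_error(self):
        k = _transporter()
        del k.constants["Keq"]
        with pytest.raises(ParameterError):
            eval_transporter_rev_mm({"S_out": 1.0, "S_in": 1.0}, k)

    def test_mixed_without_alpha_rejected(self):
        with pytest.raises(ParameterError):
            InhibitionMechanism("mixed")

    def test_bad_isoform_fractions_rejected(self):
        k = _transporter()
        k.isoforms = ({"f": 0.6, "K_s": 1.0, "K_p": 1.0},
                      {"f": 0.6, "K_s": 1.0, "K_p": 1.0})
        with pytest.raises(ParameterError):
            eval_transporter_rev_mm({"S_out": 1.0, "S_in": 1.0}, k)


@settings(max_examples=30, deadline=None)
@given(
    s=st.floats(0.01, 50.0),
    p=st.floats(0.01, 50.0),
    i=st.floats(0.0, 20.0),
)
def test_mechanism_potency_ordering_property(s, p, i):
    """Competitive inhibition is always the mildest mechanism, and on
    substrate-loaded states (s + p >= 2, where the inhibitor mostly meets
    bound enzyme) the full ordering competitive >= mixed (alpha = 2) >=
    uncompetitive holds pointwise."""
    state = {"S": s, "P": p, "I1": i}
    kc = _hpi("competitive", Vmr=0.0)
    km = _hpi("mixed", alpha=2.0, Vmr=0.0)
    ku = _hpi("uncompetitive", Vmr=0.0)
    from glycontrol.rate_laws import eval_hpi_multi_inhib as f
    assert f(state, kc) >= f(state, km) - 1e-12
    if s / 1.0 + p / 1.0 >= 2.0:
        assert f(state, km) >= f(state, ku) - 1e-12
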