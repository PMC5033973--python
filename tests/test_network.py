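"""Model assembly: building, validation, conservation structure,
feedback scenarios and activity scaling."""

import numpy as np
import pytest

from glycontrol import (
    FeedbackScenario,
    apply_feedback_scenario,
    build_model,
    preset_model,
    preset_parameters,
    scale_enzyme_activity,
    validate_model,
)
from glycontrol.errors import ModelBuildError
from glycontrol.rate_laws import evaluate_rate, haldane_residual

from conftest import random_state


class TestBuild:
    def test_as30d_reaction_set(self, as30d):
        names = set(as30d.reaction_names)
        core = {"GLUT", "HK", "HPI", "PFK1", "ALDO", "TPI", "GAPDH",
                "PGK", "PGAM", "ENO", "PYK", "LDH"}
        assert core <= names
        assert "MCT" not in names          # lactate carrier is HeLa-only
        assert len(as30d.reactions) >= 12

    def test_hela_has_carrier_and_isoforms(self, hela_hypo):
        assert "MCT" in hela_hypo.reaction_names
        assert hela_hypo.reaction("GLUT").kinetics.isoforms is not None
        assert hela_hypo.reaction("HK").kinetics.isoforms is not None
        assert "Lac_in" in hela_hypo.free_species

    def test_missing_constant_names_reaction_and_gap(self):
        params = preset_parameters("AS30D")
        rec = next(r for r in params["reactions"] if r["name"] == "PYK")
        del rec["constants"]["Kb"]
        with pytest.raises(ModelBuildError, match="PYK.*Kb"):
            build_model("AS30D", params)

    def test_undeclared_species_rejected(self):
        params = preset_parameters("AS30D")
        params["reactions"][0]["roles"]["S"] = "NoSuchSpecies"
        with pytest.raises(ModelBuildError, match="NoSuchSpecies"):
            build_model("AS30D", params)

    def test_build_is_deterministic(self):
        from glycontrol.io_files import model_to_parameters

        a = model_to_parameters(build_model("AS30D", preset_parameters("AS30D")))
        b = model_to_parameters(build_model("AS30D", preset_parameters("AS30D")))
        assert a == b


class TestConservation:
    def test_nucleotide_pools_in_left_null_space(self, as30d):
        cons = as30d.conservation()
        N = as30d.stoichiometric_matrix()
        assert cons.G.shape[0] >= 2
        assert np.max(np.abs(cons.G @ N)) < 1e-12
        free = as30d.free_species
        for pool in ({"ATP", "ADP"}, {"NAD", "NADH"}):
            v = np.array([1.0 if s in pool else 0.0 for s in free])
            assert np.max(np.abs(v @ N)) < 1e-12

    def test_moiety_totals_constant_along_trajectory(self, as30d):
        from scipy.integrate import solve_ivp

        cons = as30d.conservation()
        N = as30d.stoichiometric_matrix()

        def rhs(t, x):
            return N @ as30d.rates(as30d.state_from_vector(x, clamp=True))

        sol = solve_ivp(rhs, (0, 50.0), as30d.initial_vector(), method="LSODA",
                        rtol=1e-9, atol=1e-10, t_eval=np.linspace(0, 50, 20))
        drift = np.abs(cons.G @ sol.y - (cons.G @ sol.y[:, :1]))
        assert drift.max() < 1e-8

    def test_link_matrix_roundtrip(self, as30d):
        cons = as30d.conservation()
        x = as30d.initial_vector()
        assert np.allclose(cons.expand(cons.reduce(x)), x, atol=1e-12)


class TestValidation:
    def test_valid_model_reports_no_issues(self, as30d):
        report = validate_model(as30d)
        assert report["issues"] == []
        assert set(report["fixed_species"]) >= {"Glc_out", "Pi", "Ery4P",
                                                "PG6", "F26BP", "CIT"}

    def test_stoichiometry_typo_breaks_moiety(self):
        params = preset_parameters("AS30D")
        rec = next(r for r in params["reactions"] if r["name"] == "PYK")
        rec["stoichiometry"]["ATP"] = 2          # typo: should be +1
        m = build_model("AS30D", params)
        report = validate_model(m)
        assert any("ATP+ADP" in issue for issue in report["issues"])

    def test_haldane_violation_quantified(self, as30d):
        m = as30d.copy()
        m.reaction("ENO").kinetics.constants["Vmr"] *= 1.10
        report = validate_model(m)
        assert report["haldane_residuals"]["ENO"] == pytest.approx(0.10, rel=1e-9)
        assert any("ENO" in issue for issue in report["issues"])


class TestFeedbackScenarios:
    def test_scenario_constructors(self):
        a = FeedbackScenario.from_label("a")
        assert not any([a.hk, a.hpi, a.tpi, a.gapdh])
        e = FeedbackScenario.from_label("e")
        assert all([e.hk, e.hpi, e.tpi, e.gapdh])
        b = FeedbackScenario.from_label("b")
        assert b.hpi and not (b.hk or b.tpi or b.gapdh)
        c = FeedbackScenario.from_label("c")
        assert c.hk and not (c.hpi or c.tpi or c.gapdh)
        d = FeedbackScenario.from_label("d")
        assert d.hk and d.hpi and not (d.tpi or d.gapdh)

    def test_scenario_a_removes_all_feedback(self, as30d, rng):
        """With all feedback off, each formerly inhibited enzyme becomes
        insensitive to its feedback metabolite (FBP for HK/TPI/GAPDH;
        FBP and DHAP for HPI -- DHAP stays varied only where it is not a
        reactant of the enzyme itself)."""
        m = apply_feedback_scenario(as30d, FeedbackScenario.from_label("a"))
        varied = {"HK": {"FBP": (0.0, 5.0)},
                  "TPI": {"FBP": (0.0, 5.0)},
                  "GAPDH": {"FBP": (0.0, 5.0)},
                  "HPI": {"FBP": (0.0, 5.0), "DHAP": (0.0, 5.0)}}
        for enzyme, mods in varied.items():
            kin = m.reaction(enzyme).kinetics
            state = random_state(rng, set(kin.roles.values()) | set(kin.inhibitors)
                                 | set(mods))
            hi = dict(state, **{k: v[1] for k, v in mods.items()})
            lo = dict(state, **{k: v[0] for k, v in mods.items()})
            assert evaluate_rate(hi, kin) == pytest.approx(
                evaluate_rate(lo, kin), rel=1e-12
            )

    def test_scenario_e_is_identity(self, as30d, rng):
        m = apply_feedback_scenario(as30d, FeedbackScenario.from_label("e"))
        for r0, r1 in zip(as30d.reactions, m.reactions):
            state = random_state(
                rng, set(r0.kinetics.roles.values()) | set(r0.kinetics.inhibitors)
            )
            assert evaluate_rate(state, r1.kinetics) == evaluate_rate(state, r0.kinetics)

    @pytest.mark.parametrize("label,hpi_sensitive", [
        ("a", False), ("b", True), ("c", False), ("d", True), ("e", True),
    ])
    def test_hpi_feedback_term_presence(self, as30d, label, hpi_sensitive, rng):
        """Finite differences of the HPI rate in the feedback metabolites
        reveal exactly the scenarios that keep its inhibition terms."""
        m = apply_feedback_scenario(as30d, FeedbackScenario.from_label(label))
        kin = m.reaction("HPI").kinetics
        state = random_state(rng, set(kin.roles.values()) | set(kin.inhibitors)
                             | {"FBP", "DHAP"})
        v0 = evaluate_rate(dict(state, FBP=0.1, DHAP=0.1), kin)
        v1 = evaluate_rate(dict(state, FBP=8.0, DHAP=8.0), kin)
        assert (abs(v1 - v0) > 1e-9 * abs(v0)) == hpi_sensitive
        # Ery4P/6PG inhibition must survive every scenario
        v2 = evaluate_rate(dict(state, FBP=0.1, DHAP=0.1, Ery4P=0.05), kin)
        assert v2 != pytest.approx(v0)

    def test_scenario_on_model_without_enzymes_errors(self, as30d):
        m = as30d.copy()
        m.reactions = [r for r in m.reactions if r.name != "TPI"]
        with pytest.raises(ModelBuildError, match="TPI"):
            apply_feedback_scenario(m, FeedbackScenario.from_label("a"))


class TestActivityScaling:
    def test_factor_one_is_identity(self, as30d):
        from glycontrol.io_files import model_to_parameters

        m = scale_enzyme_activity(as30d, "ENO", 1.0)
        assert model_to_parameters(m) == model_to_parameters(as30d)

    def test_rate_scales_linearly(self, as30d, rng):
        m = scale_enzyme_activity(as30d, "ENO", 0.2)
        kin0 = as30d.reaction("ENO").kinetics
        kin1 = m.reaction("ENO").kinetics
        for _ in range(10):
            state = random_state(rng, set(kin0.roles.values()))
            assert evaluate_rate(state, kin1) == pytest.approx(
                0.2 * evaluate_rate(state, kin0), rel=1e-12
            )

    def test_haldane_preserved_under_scaling(self, as30d):
        m = scale_enzyme_activity(as30d, ["ENO", "GAPDH", "LDH"], 0.37)
        for name in ("ENO", "GAPDH", "LDH"):
            assert haldane_residual(m.reaction(name).kinetics) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_nonpositive_factor_rejected(self, as30d):
        with pytest.raises(ValueError):
            scale_enzyme_activity(as30d, "ENO", 0.0)

    def test_unknown_enzyme_rejected(self, as30d):
        with pytest.raises(KeyError):
            scale_enzyme_activity(as30d, "NOPE", 0.5)
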