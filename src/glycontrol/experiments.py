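"""In-silico experiment drivers.

Three computational experiments are reproduced on the glycolysis models:

* :func:`titration_scan` -- enzyme-activity titrations: one or more
  enzymes are scaled jointly over a factor grid (forward and reverse
  maximal rates together) and the steady-state readouts are tabulated.
* :func:`scenario_experiment` -- the same titration repeated under the
  feedback-inhibition scenarios (a)-(e), toggling the Fru1,6BP/DHAP
  inhibition terms on HK, HPI, TPI and GAPDH.
* :func:`ki_scan` -- the inhibition-mechanism experiment on the hexose
  phosphate isomerase: all of its inhibition constants are scaled jointly
  under a competitive, uncompetitive or mixed mechanism and the effect on
  pathway flux, Glc6P and the isomerase's flux-control coefficient is
  recorded.

:func:`compare_observations` is the comparison utility between model
predictions and measured metabolite tables (mean +/- sd over n
preparations, control vs inhibitor treatments).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GlycontrolError, IntegrationError
from .mca import control_coefficients
from .network import (
    FeedbackScenario,
    ModelDefinition,
    apply_feedback_scenario,
    scale_enzyme_activity,
)
from .rate_laws import InhibitionMechanism
from .steady_state import solve_steady_state

__all__ = [
    "ScanResult",
    "ObservationTable",
    "titration_scan",
    "scenario_experiment",
    "ki_scan",
    "compare_observations",
]

#: Default readouts tabulated by every scan (concentrations in mM).
SCAN_READOUTS = ("FBP", "DHAP", "ATP", "Glc6P")

#: Default joint Ki-scale grid: logarithmic over [0.01, 100], 25 points.
DEFAULT_KI_GRID = tuple(np.logspace(-2, 2, 25))


@dataclass
class ScanResult:
    """Tidy table of (scan value, scenario, readouts) rows plus metadata."""

    data: pd.DataFrame
    scan_variable: str
    model_name: str
    metadata: dict = field(default_factory=dict)

    def to_csv(self, path_or_buf=None):
        """Serialize with a JSON metadata header line (comment-prefixed)."""
        header = "# glycontrol-scan " + json.dumps(
            {"scan_variable": self.scan_variable, "model_name": self.model_name,
             "metadata": self.metadata}
        )
        body = self.data.to_csv(index=False)
        text = header + "\n" + body
        if path_or_buf is None:
            return text
        with open(path_or_buf, "w") as fh:
            fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ScanResult":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        first, _, rest = text.partition("\n")
        meta = json.loads(first.replace("# glycontrol-scan ", "", 1))
        df = pd.read_csv(io.StringIO(rest))
        if "scenario" in df.columns:
            # empty labels round-trip as empty strings, not NaN
            df["scenario"] = df["scenario"].fillna("").astype(object)
        return cls(df, meta["scan_variable"], meta["model_name"], meta["metadata"])


@dataclass
class ObservationTable:
    """Measured (or simulated) metabolite/flux table: one row per
    (metabolite, treatment) with mean, sd and replicate count."""

    data: pd.DataFrame   # columns: metabolite, treatment, mean, sd, n

    def __post_init__(self):
        required = {"metabolite", "treatment", "mean", "sd", "n"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"observation table lacks columns {sorted(missing)}")
        if (self.data["sd"] < 0).any() or (self.data["n"] < 1).any():
            raise ValueError("observation table needs sd >= 0 and n >= 1")

    def subset(self, treatment: str) -> pd.DataFrame:
        return self.data[self.data["treatment"] == treatment].set_index("metabolite")


def _scan_row(model, factor, scenario_label, readouts, hpi_control=False):
    try:
        ss = solve_steady_state(model)
    except IntegrationError as exc:
        return {"factor": factor, "scenario": scenario_label, "converged": False,
                "pathway_flux": np.nan,
                **{m: np.nan for m in readouts}}
    row = {
        "factor": factor,
        "scenario": scenario_label,
        "converged": bool(ss.converged),
        "pathway_flux": ss.pathway_flux,
    }
    for m in readouts:
        row[m] = ss.concentrations.get(m, np.nan)
    if hpi_control and ss.converged:
        cc = control_coefficients(
            model, metabolites=("Glc6P",), enzymes=["HPI"], reference=ss
        )
        row["C_J_HPI"] = float(cc.flux_control["HPI"])
    return row


def titration_scan(
    model: ModelDefinition,
    enzymes: Sequence[str],
    factors: Sequence[float],
    readouts: Sequence[str] = SCAN_READOUTS,
    scenario_label: str = "",
) -> ScanResult:
    """Joint activity titration of one or more enzymes.

    Every enzyme in ``enzymes`` is scaled by the same factor (identical
    variation when several enzymes are titrated simultaneously); the
    reference row is factor 1.  Non-convergent points are flagged rows,
    never dropped silently.
    """
    if not enzymes:
        raise ValueError("need at least one enzyme to titrate")
    factors = sorted(set(float(f) for f in factors) | {1.0})
    for f in factors:
        if not (0.0 < f <= 1.5):
            raise ValueError(f"titration factors must lie in (0, 1.5], got {f}")
    rows = []
    for f in factors:
        m = scale_enzyme_activity(model, enzymes, f)
        rows.append(_scan_row(m, f, scenario_label, readouts))
    df = pd.DataFrame(rows).sort_values("factor", ignore_index=True)
    return ScanResult(
        df, "factor", model.name,
        {"enzymes": list(enzymes), "readouts": list(readouts)},
    )


def scenario_experiment(
    model: ModelDefinition,
    scenarios: Sequence[str] = ("a", "b", "c", "d", "e"),
    enzymes: Sequence[str] = ("ENO", "PYK"),
    factors: Sequence[float] = (0.2, 0.25, 0.4, 0.6, 0.8, 1.0),
    readouts: Sequence[str] = SCAN_READOUTS,
) -> ScanResult:
    """ENO+PYK titration repeated under each feedback scenario.

    Scenario (a) removes all Fru1,6BP/DHAP feedback, (b) keeps it on HPI
    only, (c) on HK only, (d) on both, (e) on HPI, HK, TPI and GAPDH (the
    unmodified model).
    """
    frames = []
    for label in scenarios:
        variant = apply_feedback_scenario(model, FeedbackScenario.from_label(label))
        res = titration_scan(variant, enzymes, factors, readouts, scenario_label=label)
        frames.append(res.data)
    df = pd.concat(frames, ignore_index=True)
    return ScanResult(
        df, "factor", model.name,
        {"enzymes": list(enzymes), "scenarios": list(scenarios),
         "readouts": list(readouts)},
    )


def _set_hpi_mechanism(model: ModelDefinition, mechanism, ki_scale: float) -> ModelDefinition:
    out = model.copy()
    kin = out.reaction("HPI").kinetics
    kin.mechanism = mechanism
    for sp in kin.inhibitors:
        kin.constants[f"Ki_{sp}"] = kin.constants[f"Ki_{sp}"] * ki_scale
    return out


def ki_scan(
    model: ModelDefinition,
    mechanism,
    ki_scale_grid: Sequence[float] = DEFAULT_KI_GRID,
    readouts: Sequence[str] = ("Glc6P", "FBP", "DHAP", "ATP"),
) -> ScanResult:
    """Inhibition-mechanism / Ki scan on the hexose phosphate isomerase.

    ``mechanism`` is an :class:`InhibitionMechanism` or one of the strings
    ``competitive``, ``uncompetitive``, ``mixed`` (mixed defaults to
    alpha = 2).  ``ki_scale`` multiplies all of the isomerase's inhibition
    constants jointly; scale 1 is the experimentally determined reference.
    Each converged row carries the isomerase flux-control coefficient
    computed by the standard finite-difference operation (delta 0.01).
    """
    if isinstance(mechanism, str):
        mechanism = InhibitionMechanism(
            mechanism, alpha=2.0 if mechanism == "mixed" else None
        )
    rows = []
    for scale in ki_scale_grid:
        variant = _set_hpi_mechanism(model, mechanism, float(scale))
        row = _scan_row(variant, float(scale), mechanism.kind, readouts,
                        hpi_control=True)
        row["ki_scale"] = row.pop("factor")
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("ki_scale", ignore_index=True)
    return ScanResult(
        df, "ki_scale", model.name,
        {"mechanism": mechanism.kind, "alpha": mechanism.alpha,
         "readouts": list(readouts)},
    )


def compare_observations(
    predictions: Mapping[str, float],
    observed: ObservationTable,
    treatment: str,
    control: str = "control",
) -> pd.DataFrame:
    """Compare model predictions with an observation table.

    For each metabolite present in both the prediction mapping and the
    treatment rows: predicted value, observed mean +/- sd (n), fold-change
    of the observed treatment mean over the control mean, the z-score of
    the prediction under the observed spread, and Welch's two-sample
    t-test between treatment and control summary statistics.  Metabolites
    that cannot be matched are listed with NaN statistics, never dropped
    fatally.
    """
    obs = observed.subset(treatment)
    ctrl = observed.subset(control)
    rows = []
    names = sorted(set(predictions) | set(obs.index))
    for m in names:
        row = {"metabolite": m, "predicted": predictions.get(m, np.nan)}
        if m in obs.index:
            o = obs.loc[m]
            row.update(observed_mean=o["mean"], observed_sd=o["sd"], n=o["n"])
            if o["sd"] > 0:
                row["z"] = (row["predicted"] - o["mean"]) / o["sd"]
            else:
                row["z"] = 0.0 if row["predicted"] == o["mean"] else np.inf
            if m in ctrl.index:
                c = ctrl.loc[m]
                row["fold_change_vs_control"] = o["mean"] / c["mean"]
                if o["n"] >= 2 and c["n"] >= 2 and (o["sd"] > 0 or c["sd"] > 0):
                    t, p = stats.ttest_ind_from_stats(
                        o["mean"], o["sd"], o["n"], c["mean"], c["sd"], c["n"],
                        equal_var=False,
                    )
                    row["t_stat"], row["p_value"] = float(t), float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("metabolite")
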