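"""Native parameter files, result tables and provenance records.

The native parameter format is YAML following the same schema consumed by
:func:`glycontrol.network.build_model`: top-level ``name``, ``condition``,
``species`` (name -> {initial, fixed}) and ``reactions`` (list of records
with name, stoichiometry, family, roles, constants, and optionally
inhibitors/mechanism/isoforms/options).  SBML is the canonical exchange
format; this YAML layer is the human-editable convenience view.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from .network import ModelDefinition, build_model

__all__ = [
    "read_parameters",
    "write_parameters",
    "model_to_parameters",
    "write_results",
    "provenance_record",
]


def read_parameters(path) -> dict:
    with open(path) as fh:
        rec = yaml.safe_load(fh)
    if not isinstance(rec, Mapping) or "reactions" not in rec or "species" not in rec:
        raise ValueError(f"{path}: not a glycontrol parameter file")
    return dict(rec)


def write_parameters(params: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(params), fh, sort_keys=False)


def model_to_parameters(model: ModelDefinition) -> dict:
    """Invert a model back into the native parameter schema."""
    return {
        "name": model.name,
        "condition": model.condition,
        "pathway_flux_reaction": model.pathway_flux_reaction,
        "flux_unit": model.flux_unit,
        "notes": model.notes,
        "species": {
            s: (
                {"initial": float(model.initial[s]), "fixed": True}
                if s in model.fixed else {"initial": float(model.initial[s])}
            )
            for s in model.species
        },
        "reactions": [
            {
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                "family": r.kinetics.family,
                "roles": dict(r.kinetics.roles),
                "constants": {k: float(v) for k, v in r.kinetics.constants.items()},
                **({"inhibitors": list(r.kinetics.inhibitors)}
                   if r.kinetics.inhibitors else {}),
                **({"mechanism": {"kind": r.kinetics.mechanism.kind,
                                  "alpha": r.kinetics.mechanism.alpha}}
                   if r.kinetics.mechanism.kind != "competitive"
                   or r.kinetics.mechanism.alpha is not None else {}),
                **({"isoforms": [dict(i) for i in r.kinetics.isoforms]}
                   if r.kinetics.isoforms else {}),
                **({"options": {k: v for k, v in r.kinetics.options.items()
                                if isinstance(v, (str, int, float, bool))}}
                   if r.kinetics.options else {}),
            }
            for r in model.reactions
        ],
    }


def provenance_record(config: Mapping, seed: Optional[int] = None) -> dict:
    from . import __version__

    return {
        "tool": "glycontrol",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "seed": seed,
        "config": dict(config),
    }


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    fmt: str = "csv",
    provenance: Optional[Mapping] = None,
) -> list:
    """Write named tables to ``out_dir`` as CSV (with a JSON metadata
    header line) or JSON; returns written paths.  A ``provenance.json``
    record accompanies every run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if fmt == "csv":
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                if provenance is not None:
                    fh.write("# glycontrol " + json.dumps(provenance, default=str) + "\n")
                df.to_csv(fh)
        elif fmt == "json":
            path = out / f"{name}.json"
            payload = {"provenance": provenance, "table": json.loads(df.to_json(orient="split"))}
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, default=str)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        written.append(path)
    if provenance is not None:
        ppath = out / "provenance.json"
        with open(ppath, "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
        written.append(ppath)
    return written
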