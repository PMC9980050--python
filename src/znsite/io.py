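"""File formats: model specification (YAML/JSON), tidy observable tables,
and the CSV contracts for titration and binding datasets.

The model file lists residues, microscopic protonation edges (residue,
context pattern, pKa) and binding edges (protonation pattern, either
``dg0_kT`` or ``kd_molar``).  The reference state — fully deprotonated,
metal-free, potential zero — is implicit and recorded for documentation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .model import BindingEdge, ProtonationEdge, SiteModel
from .states import Residue


def model_to_dict(model: SiteModel) -> dict:
    doc = {
        "reference": "fully deprotonated, metal-free state (potential 0)",
        "temperature_K": model.temperature,
        "residues": [
            {
                "name": r.name,
                **({"kind": r.kind} if r.kind else {}),
                **({"tie_group": r.tie_group} if r.tie_group else {}),
            }
            for r in model.residues
        ],
        "protonation_edges": [],
        "binding_edges": [],
    }
    for e in model.edges:
        if isinstance(e, ProtonationEdge):
            doc["protonation_edges"].append(
                {
                    "residue": e.residue,
                    "context": dict(e.context),
                    "zn_bound": bool(e.zn_bound),
                    "pka": float(e.pka),
                    "weight": float(e.weight),
                }
            )
        else:
            doc["binding_edges"].append(
                {
                    "context": dict(e.context),
                    "dg0_kT": float(e.dg0),
                    "weight": float(e.weight),
                }
            )
    return doc


def model_from_dict(doc: dict) -> SiteModel:
    residues = [
        Residue(
            name=r["name"],
            kind=r.get("kind"),
            tie_group=r.get("tie_group"),
        )
        for r in doc["residues"]
    ]
    edges = []
    for e in doc.get("protonation_edges", []):
        edges.append(
            ProtonationEdge(
                residue=e["residue"],
                context=e["context"],
                pka=float(e["pka"]),
                zn_bound=bool(e.get("zn_bound", False)),
                weight=float(e.get("weight", 1.0)),
            )
        )
    for e in doc.get("binding_edges", []):
        if "dg0_kT" in e:
            edges.append(
                BindingEdge(
                    context=e["context"],
                    dg0=float(e["dg0_kT"]),
                    weight=float(e.get("weight", 1.0)),
                )
            )
        else:
            edges.append(
                BindingEdge.from_kd(
                    context=e["context"],
                    kd_molar=float(e["kd_molar"]),
                    weight=float(e.get("weight", 1.0)),
                )
            )
    return SiteModel(
        residues, edges, temperature=float(doc.get("temperature_K", 298.15))
    )


def save_model(model: SiteModel, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_model(path: Union[str, Path]) -> SiteModel:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(doc)


# ---------------------------------------------------------------------------
# Tidy observable tables


def probability_grid(model: SiteModel, ph_values, zn_values) -> pd.DataFrame:
    """Tidy per-state probabilities: (ph, zn_molar, state_index, state, probability)."""
    rows = []
    for ph in ph_values:
        for x in zn_values:
            p = model.probabilities(ph, x)
            for s, pi in zip(model.microstates, p):
                rows.append((ph, x, s.index, s.label, pi))
    return pd.DataFrame(
        rows, columns=["ph", "zn_molar", "state_index", "state", "probability"]
    )


def bound_fraction_grid(model: SiteModel, ph_values, zn_values) -> pd.DataFrame:
    """Tidy bound fractions: (ph, zn_molar, bound_fraction)."""
    rows = [
        (ph, x, model.bound_fraction(ph, x))
        for ph in ph_values
        for x in zn_values
    ]
    return pd.DataFrame(rows, columns=["ph", "zn_molar", "bound_fraction"])


def write_tsv(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Titration and binding CSV contracts


def read_titration_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Long-format titration coordinates: columns ph, residue, frame, lambda.

    A wide file (frame plus one lambda column per residue, single pH given
    as a ``ph`` column) is melted to the long form.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"ph", "residue", "frame", "lambda"} <= cols:
        return df[["ph", "residue", "frame", "lambda"]]
    if "frame" in cols and "ph" in cols:
        residues = [c for c in df.columns if c not in ("frame", "ph")]
        long = df.melt(
            id_vars=["ph", "frame"],
            value_vars=residues,
            var_name="residue",
            value_name="lambda",
        )
        return long[["ph", "residue", "frame", "lambda"]]
    raise ValueError(
        "titration CSV must be long (ph,residue,frame,lambda) or wide "
        "(ph,frame,<residue columns>)"
    )


def read_mst_csv(path: Union[str, Path], sidecar: Union[str, Path, None] = None):
    """Binding titration points with an optional JSON sidecar.

    Required columns: ph, c_zn_molar, signal.  Optional: replicate.  The
    sidecar supplies ``protein_conc_molar`` (and optionally a chelator
    spec); returns ``(DataFrame, metadata dict)``.
    """
    df = pd.read_csv(path)
    required = {"ph", "c_zn_molar", "signal"}
    if not required <= set(df.columns):
        raise ValueError(f"binding CSV needs columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    meta = {}
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
    return df, meta
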