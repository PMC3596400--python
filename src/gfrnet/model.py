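"""Deployable network model: container, prediction, and portable serialization.

A :class:`NetworkModel` bundles everything needed to estimate GFR for a
new patient: the ordered input-variable list, the network topology and
parameters, and the normalization ranges for inputs and output.  Models
are serialized to a human-readable JSON document with canonical key
ordering and full-precision floats, so saved models diff cleanly and
round-trip losslessly (save∘load∘save is byte-identical).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from .ann import NetworkParameters, NetworkTopology, forward
from .io import OUTPUT_VARIABLE
from .preprocessing import NormalizationSpec, denormalize_output, normalize_frame

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1

__all__ = ["NetworkModel", "save_model", "load_model", "predict"]


class ModelFormatError(ValueError):
    """Raised when a model file is corrupt or of an unsupported version."""


@dataclass
class NetworkModel:
    """Topology + parameters + normalization: the complete GFR estimator."""

    variables: List[str]
    topology: NetworkTopology
    parameters: NetworkParameters
    normalization: NormalizationSpec
    provenance: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.variables) != self.topology.n_input:
            raise ValueError(
                f"{len(self.variables)} variables but topology expects "
                f"{self.topology.n_input} inputs"
            )
        if self.parameters.topology != self.topology:
            raise ValueError("parameter shapes do not match the declared topology")
        if OUTPUT_VARIABLE not in self.normalization.ranges:
            raise ValueError("normalization spec must include the output range")
        missing = [
            v for v in self.variables if v != "gender" and v not in self.normalization.ranges
        ]
        if missing:
            raise ValueError(f"normalization spec missing input ranges: {missing}")


def predict(model: NetworkModel, cohort: pd.DataFrame) -> np.ndarray:
    """Estimated GFR (ml/min/1.73 m²) for every cohort record.

    normalize → forward → denormalize; negative outputs (possible for a
    linear output unit extrapolating) are floored at 0 with a warning.
    """
    X = normalize_frame(cohort, model.normalization, model.variables)
    y_scaled = forward(model.parameters, X)
    out = np.asarray(denormalize_output(y_scaled, model.normalization), dtype=float)
    negative = out < 0
    if np.any(negative):
        warnings.warn(
            f"{int(negative.sum())} prediction(s) were negative and floored at 0",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("floored %d negative prediction(s) at 0", int(negative.sum()))
        out = np.where(negative, 0.0, out)
    return out


def _model_to_dict(model: NetworkModel) -> dict:
    p = model.parameters
    return {
        "format_version": FORMAT_VERSION,
        "variables": list(model.variables),
        "topology": {
            "n_input": model.topology.n_input,
            "n_hidden": model.topology.n_hidden,
            "n_output": model.topology.n_output,
        },
        "parameters": {
            "w_hidden": [[float(v) for v in row] for row in p.w_hidden],
            "b_hidden": [float(v) for v in p.b_hidden],
            "w_output": [float(v) for v in p.w_output],
            "b_output": float(p.b_output),
        },
        "normalization": model.normalization.to_dict(),
        "provenance": model.provenance,
    }


def save_model(model: NetworkModel, path) -> None:
    """Write a model as canonical JSON (sorted keys, repr-exact floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(_model_to_dict(model), sort_keys=True, indent=2)
    path.write_text(text + "\n", encoding="utf-8")


def load_model(path) -> NetworkModel:
    """Read a model file, validating version and internal consistency."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"model file {path} is not valid JSON: {exc}") from exc
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {version!r}; supported: {FORMAT_VERSION}"
        )
    for key in ("variables", "topology", "parameters", "normalization"):
        if key not in doc:
            raise ModelFormatError(f"model file {path} missing key {key!r}")
    t = doc["topology"]
    try:
        topology = NetworkTopology(
            n_input=int(t["n_input"]), n_hidden=int(t["n_hidden"]), n_output=int(t["n_output"])
        )
        p = doc["parameters"]
        parameters = NetworkParameters(
            w_hidden=np.array(p["w_hidden"], dtype=float).reshape(
                topology.n_hidden, topology.n_input
            ),
            b_hidden=np.array(p["b_hidden"], dtype=float),
            w_output=np.array(p["w_output"], dtype=float),
            b_output=float(p["b_output"]),
        )
        model = NetworkModel(
            variables=list(doc["variables"]),
            topology=topology,
            parameters=parameters,
            normalization=NormalizationSpec.from_dict(doc["normalization"]),
            provenance=doc.get("provenance", {}),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ModelFormatError(f"model file {path} failed validation: {exc}") from exc
    return model
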