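"""High-level workflows: equation estimates, model training, evaluation.

These functions are what the CLI subcommands (and the reproduction
script) call; they wire the preprocessing, network, GA, and evaluation
modules together with a single seed.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import equations as eq
from .ann import TrainingConfig, forward, mse, topology_search
from .ga import GaConfig, gabp_train
from .io import OUTPUT_VARIABLE
from .model import NetworkModel, predict
from .preprocessing import fit_normalization, normalize_frame, normalize_target

#: input variables of the selected six-variable network
GABP6_VARIABLES = ["sc", "age", "weight", "sun", "height", "gender"]

EQUATION_NAMES = ("cg", "mdrd6", "mdrd4", "ckdepi")


def equation_estimates(
    cohort: pd.DataFrame,
    which: Sequence[str] = EQUATION_NAMES,
    mdrd_dialect: str = "original",
    bsa_formula: str = "dubois",
    racial_coefficient: bool = False,
) -> pd.DataFrame:
    """eGFR by the requested traditional equations, one column per equation."""
    out = {}
    sc = cohort["sc"].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=str)
    for name in which:
        if name == "cg":
            bsa = eq.compute_bsa(
                cohort["height"].to_numpy(dtype=float),
                cohort["weight"].to_numpy(dtype=float),
                formula=bsa_formula,
            )
            out["egfr_cg"] = eq.cockcroft_gault(
                age, cohort["weight"].to_numpy(dtype=float), sc, sex, bsa
            )
        elif name == "mdrd6":
            out["egfr_mdrd6"] = eq.mdrd6(
                sc,
                age,
                sex,
                cohort["sun"].to_numpy(dtype=float),
                cohort["alb"].to_numpy(dtype=float),
                black=racial_coefficient,
            )
        elif name == "mdrd4":
            out["egfr_mdrd4"] = eq.mdrd4(
                sc, age, sex, dialect=mdrd_dialect, black=racial_coefficient
            )
        elif name == "ckdepi":
            out["egfr_ckdepi"] = eq.ckd_epi(sc, age, sex, black=racial_coefficient)
        else:
            raise ValueError(f"unknown equation {name!r}; expected one of {EQUATION_NAMES}")
    return pd.DataFrame(out, index=cohort.index)


def train_model(
    development: pd.DataFrame,
    internal_validation: pd.DataFrame,
    variables: Sequence[str] = GABP6_VARIABLES,
    hidden_range: Iterable[int] = range(1, 14),
    ga_config: Optional[GaConfig] = GaConfig(),
    bp_config: TrainingConfig = TrainingConfig(),
    padding_fraction: float = 0.1,
) -> NetworkModel:
    """Topology search then (GA-initialized) backpropagation on a variable set.

    Passing ``ga_config=None`` trains plain BP from the topology-search
    winner's random initialization instead of GABP.
    """
    variables = list(variables)
    spec = fit_normalization(development, variables + [OUTPUT_VARIABLE], padding_fraction)
    X_dev = normalize_frame(development, spec, variables)
    X_val = normalize_frame(internal_validation, spec, variables)
    y_dev = normalize_target(development, spec)
    y_val = normalize_target(internal_validation, spec)

    topology, table = topology_search(X_dev, y_dev, X_val, y_val, hidden_range, bp_config)
    provenance: Dict = {
        "bp_seed": bp_config.seed,
        "topology_table": {str(k): float(v) for k, v in table.items()},
    }
    if ga_config is None:
        from .ann import NetworkParameters, train_bp

        rng = np.random.default_rng(bp_config.seed)
        params, _ = train_bp(
            X_dev, y_dev, X_val, y_val, NetworkParameters.random(topology, rng), bp_config
        )
        provenance["initializer"] = "random"
    else:
        params, info = gabp_train(
            X_dev, y_dev, X_val, y_val, topology, ga_config, bp_config
        )
        provenance["initializer"] = "ga"
        provenance["ga_seed"] = ga_config.seed
        provenance["ga_best_fitness"] = float(info.ga_history[-1])
    provenance["val_mse"] = mse(forward(params, X_val), y_val)
    return NetworkModel(
        variables=variables,
        topology=topology,
        parameters=params,
        normalization=spec,
        provenance=provenance,
    )


def evaluate_estimates(cohort: pd.DataFrame, estimate_columns: Sequence[str]) -> pd.DataFrame:
    """Metrics table for eGFR columns of a cohort frame carrying ``sgfr``."""
    from .evaluation import metrics_table

    if "sgfr" not in cohort.columns:
        raise ValueError("cohort lacks the reference 'sgfr' column")
    estimates = {c: cohort[c].to_numpy(dtype=float) for c in estimate_columns}
    return metrics_table(estimates, cohort["sgfr"].to_numpy(dtype=float))
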