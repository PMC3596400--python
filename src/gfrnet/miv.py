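"""Mean-impact-value (MIV) importance scoring and backward variable elimination.

The impact of an input variable on a trained network is measured by
perturbing that variable's normalized values by ±δ (multiplying by 1+δ
and 1−δ, clamped to [0, 1]) and averaging the resulting change in the
network output over the cohort: MIV_j = mean(output₊ − output₋).
Binary dummy variables (gender) are the exception: a multiplicative ±δ
probe around x ∈ {0, 1} interrogates the network off the data manifold,
where a saturated sigmoid can report almost no sensitivity; their
impact is therefore the linearized 0/1 contrast scaled to the same
units, MIV = 2δ · mean(output|x=1 − output|x=0).

Variables are ranked by |MIV|; backward elimination repeatedly retrains
(topology search + GA-initialized backpropagation) and drops the
variable with the smallest |MIV| until one remains, keeping the subset
whose internal-validation MSE is smallest.  Because the weakest real
covariate effects live in the slowest-converging directions of gradient
descent, a single network's MIV ranking is noisy; the elimination step
therefore averages signed MIVs over the near-best networks trained
during the topology search together with the final GA-initialized
model, which stabilizes the ranking at no extra training cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .ann import (
    NetworkParameters,
    TrainingConfig,
    forward,
    mse,
    topology_search,
    train_bp,
)
from .ga import GaConfig, gabp_train
from .io import OUTPUT_VARIABLE
from .model import NetworkModel
from .preprocessing import fit_normalization, normalize_frame, normalize_target

__all__ = ["MivReport", "EliminationStep", "EliminationTrace", "compute_miv", "backward_eliminate"]


@dataclass
class MivReport:
    """Signed mean impact values and the |MIV| ranking (rank 1 = largest)."""

    variables: List[str]
    miv: Dict[str, float]
    rank: Dict[str, int]
    delta: float

    @property
    def least_important(self) -> str:
        return max(self.variables, key=lambda v: self.rank[v])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "miv": [self.miv[v] for v in self.variables],
                "abs_miv": [abs(self.miv[v]) for v in self.variables],
                "rank": [self.rank[v] for v in self.variables],
            }
        ).sort_values("rank", ignore_index=True)


#: variables treated as binary dummies (0/1-contrast impact measure)
BINARY_VARIABLES = frozenset({"gender"})


def miv_from_matrix(
    predict_fn,
    X: np.ndarray,
    variables: Sequence[str],
    delta: float = 0.1,
    binary: frozenset = BINARY_VARIABLES,
) -> MivReport:
    """MIV on an already-normalized (n, d) matrix, for any scalar-output model."""
    if not 0 < delta <= 0.5:
        raise ValueError(f"delta must lie in (0, 0.5], got {delta}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("data must be non-empty")
    if X.shape[1] != len(variables):
        raise ValueError(
            f"matrix has {X.shape[1]} columns but {len(variables)} variables given"
        )
    miv: Dict[str, float] = {}
    for j, var in enumerate(variables):
        up, down = X.copy(), X.copy()
        if var in binary:
            up[:, j] = 1.0
            down[:, j] = 0.0
            contrast = float(np.mean(np.asarray(predict_fn(up)) - np.asarray(predict_fn(down))))
            miv[var] = 2.0 * delta * contrast
            continue
        up[:, j] = np.clip(X[:, j] * (1.0 + delta), 0.0, 1.0)
        down[:, j] = np.clip(X[:, j] * (1.0 - delta), 0.0, 1.0)
        miv[var] = float(np.mean(np.asarray(predict_fn(up)) - np.asarray(predict_fn(down))))
    # rank 1 = largest |MIV|; ties broken by variable list order (stable)
    order = sorted(range(len(variables)), key=lambda j: (-abs(miv[variables[j]]), j))
    rank = {variables[j]: r + 1 for r, j in enumerate(order)}
    return MivReport(variables=list(variables), miv=miv, rank=rank, delta=delta)


def compute_miv(model: NetworkModel, data: pd.DataFrame, delta: float = 0.1) -> MivReport:
    """MIV of every input variable of a trained model on a cohort."""
    X = normalize_frame(data, model.normalization, model.variables)
    return miv_from_matrix(
        lambda M: forward(model.parameters, M), X, model.variables, delta
    )


@dataclass
class EliminationStep:
    variables: List[str]
    topology_table: Dict[int, float]
    model: NetworkModel
    val_mse: float
    miv: MivReport
    removed: Optional[str]


@dataclass
class EliminationTrace:
    """Full backward-elimination history; ``selected`` is the best subset."""

    steps: List[EliminationStep] = field(default_factory=list)
    selected_index: int = -1

    @property
    def selected(self) -> EliminationStep:
        return self.steps[self.selected_index]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.steps) + 1),
                "n_variables": [len(s.variables) for s in self.steps],
                "variables": ["+".join(s.variables) for s in self.steps],
                "topology": [str(s.model.topology) for s in self.steps],
                "val_mse": [s.val_mse for s in self.steps],
                "removed": [s.removed if s.removed else "" for s in self.steps],
                "selected": [i == self.selected_index for i in range(len(self.steps))],
            }
        )


def backward_eliminate(
    development: pd.DataFrame,
    internal_validation: pd.DataFrame,
    variables: Sequence[str],
    ga_config: GaConfig = GaConfig(),
    bp_config: TrainingConfig = TrainingConfig(),
    hidden_range: Iterable[int] = range(1, 14),
    delta: float = 0.1,
    padding_fraction: float = 0.1,
    min_variables: int = 1,
    ensemble_tolerance: float = 1.1,
    n_restarts: int = 1,
    max_steps: Optional[int] = None,
) -> EliminationTrace:
    """Backward elimination driven by MIV ranking.

    At each step the current variable subset gets a fresh topology search
    (plain BP per candidate hidden size) followed by GA-initialized
    training at the winning topology.  The variable to drop is decided by
    the signed MIV on the development set, averaged over the final model
    and every topology-search network whose validation MSE is within
    ``ensemble_tolerance`` times the best seen at that step; with
    ``n_restarts`` > 1 the topology search is repeated from additional
    random initializations purely to enrich that ensemble.  The loop
    runs until ``min_variables`` remain (or for at most ``max_steps``
    steps), and the selected model is the step with the smallest
    internal-validation MSE.  MIV is recomputed after every removal
    rather than ranked once up front.
    """
    current = list(variables)
    if len(current) < 2:
        raise ValueError("need at least two variables to eliminate")
    if not 1 <= min_variables <= len(current):
        raise ValueError("min_variables out of range")
    hidden_range = list(hidden_range)
    trace = EliminationTrace()
    step_index = 0
    while True:
        try:
            spec = fit_normalization(
                development, list(current) + [OUTPUT_VARIABLE], padding_fraction
            )
            X_dev = normalize_frame(development, spec, current)
            X_val = normalize_frame(internal_validation, spec, current)
            y_dev = normalize_target(development, spec)
            y_val = normalize_target(internal_validation, spec)

            search_fits = []  # (val_mse, params) per candidate hidden size

            def caching_trainer(Xd, yd, Xv, yv, initial, config):
                p, h = train_bp(Xd, yd, Xv, yv, initial, config)
                search_fits.append((mse(forward(p, Xv), yv), p))
                return p, h

            topology, table = topology_search(
                X_dev, y_dev, X_val, y_val, hidden_range, bp_config,
                trainer=caching_trainer,
            )
            params, info = gabp_train(
                X_dev, y_dev, X_val, y_val, topology, ga_config, bp_config
            )
            # extra GA-initialized restarts at the winning topology enrich
            # the MIV ensemble with independently trained, well-converged fits
            for r in range(1, n_restarts):
                p_r, _ = gabp_train(
                    X_dev,
                    y_dev,
                    X_val,
                    y_val,
                    topology,
                    replace(ga_config, seed=ga_config.seed + 1009 * r),
                    replace(bp_config, seed=bp_config.seed + 1009 * r),
                )
                search_fits.append((mse(forward(p_r, X_val), y_val), p_r))
        except Exception as exc:
            raise type(exc)(
                f"elimination step {step_index + 1} ({len(current)} variables): {exc}"
            ) from exc
        model = NetworkModel(
            variables=list(current),
            topology=topology,
            parameters=params,
            normalization=spec,
            provenance={
                "stage": "backward_eliminate",
                "step": step_index + 1,
                "ga_seed": ga_config.seed,
                "bp_seed": bp_config.seed,
            },
        )
        val_mse = mse(forward(params, X_val), y_val)
        # signed-MIV ensemble: final model plus near-best search networks
        ensemble = [params] + [
            p
            for v, p in search_fits
            if v <= ensemble_tolerance * min(val_mse, min(v2 for v2, _ in search_fits))
        ]
        reports = [
            miv_from_matrix(lambda M: forward(p, M), X_dev, current, delta)
            for p in ensemble
        ]
        mean_miv = {
            v: float(np.mean([r.miv[v] for r in reports])) for v in current
        }
        order = sorted(range(len(current)), key=lambda j: (-abs(mean_miv[current[j]]), j))
        report = MivReport(
            variables=list(current),
            miv=mean_miv,
            rank={current[j]: r + 1 for r, j in enumerate(order)},
            delta=delta,
        )
        removed = report.least_important if len(current) > min_variables else None
        trace.steps.append(
            EliminationStep(
                variables=list(current),
                topology_table=table,
                model=model,
                val_mse=val_mse,
                miv=report,
                removed=removed,
            )
        )
        if removed is None:
            break
        current.remove(removed)
        step_index += 1
        if max_steps is not None and step_index >= max_steps:
            break
    trace.selected_index = int(
        np.argmin([s.val_mse for s in trace.steps])
    )
    return trace
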