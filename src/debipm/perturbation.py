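"""Elasticity of the log stochastic growth rate to life-history traits.

Each of the six perturbable traits (L_b, L_p, L_m, R_m, rB, mu) is nudged
by a small proportional amount (1% by default) and the projection rerun on
the *same* environment-state sequence as the baseline (common random
numbers, so sampling noise cancels in the difference).  The elasticity is
the proportional sensitivity

    e(theta) = [log lambda_s(theta (1 + delta)) - log lambda_s(theta)]
               / log(1 + delta),

a forward-difference estimate of d log(lambda_s) / d log(theta).  The mesh
is rebuilt for perturbed parameters, so perturbing L_m moves the starvation
cutoff and mesh bounds consistently.  The energy-allocation fraction kappa
is excluded by design: it is structurally entangled with L_m and R_m, so a
lone kappa perturbation has no clean interpretation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .environment import FeedingRegime, autocorrelation, good_state_frequency, simulate_state_sequence
from .life_history import PERTURBABLE_PARAMETERS, DEBParams
from .projection import SimConfig, StochasticRunResult, cell_seed, project

__all__ = [
    "ElasticityRecord",
    "DominantParameterMap",
    "elasticity",
    "elasticity_profile",
    "dominant_parameter_map",
]


@dataclass(frozen=True)
class ElasticityRecord:
    parameter: str
    elasticity: float
    delta: float
    base_log_lambda_s: float
    seed: object


def _check_parameter(parameter_name: str) -> str:
    if parameter_name == "kappa":
        raise ValueError(
            "kappa is excluded from perturbation analysis: it sets the "
            "starvation cutoff and is structurally tied to L_m and R_m, so "
            "perturbing it alone is not interpretable"
        )
    if parameter_name not in PERTURBABLE_PARAMETERS:
        raise ValueError(
            f"unknown parameter {parameter_name!r}; perturbable parameters are "
            f"{', '.join(PERTURBABLE_PARAMETERS)}"
        )
    return parameter_name


def _perturbed(params: DEBParams, name: str, factor: float) -> DEBParams:
    updates = {name: getattr(params, name) * factor}
    if name == "L_b":
        # length at birth and the offspring mean are one and the same trait
        updates["offspring_mean"] = params.offspring_mean * factor
    return replace(params, **updates)


def elasticity(
    params: DEBParams,
    regime: FeedingRegime,
    config: SimConfig | None = None,
    parameter_name: str = "L_p",
    delta: float = 0.01,
    method: str = "forward",
    state_sequence: np.ndarray | None = None,
    base_result: StochasticRunResult | None = None,
) -> ElasticityRecord:
    """Elasticity of log(lambda_s) to one trait via proportional perturbation.

    ``method`` is ``"forward"`` (default) or ``"central"``; both share the
    baseline environment-state sequence.  A precomputed ``state_sequence``
    and/or ``base_result`` may be passed to avoid rerunning the baseline.
    """
    _check_parameter(parameter_name)
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    if config is None:
        config = SimConfig()
    if state_sequence is None:
        state_sequence = simulate_state_sequence(regime, config.total_steps, config.seed)
    if base_result is None:
        base_result = project(params, regime, config, state_sequence=state_sequence)

    up = project(
        _perturbed(params, parameter_name, 1.0 + delta),
        regime,
        config,
        state_sequence=state_sequence,
    )
    if method == "forward":
        e = (up.log_lambda_s - base_result.log_lambda_s) / math.log1p(delta)
    elif method == "central":
        down = project(
            _perturbed(params, parameter_name, 1.0 - delta),
            regime,
            config,
            state_sequence=state_sequence,
        )
        e = (up.log_lambda_s - down.log_lambda_s) / (
            math.log1p(delta) - math.log1p(-delta)
        )
    else:
        raise ValueError(f"method must be 'forward' or 'central', got {method!r}")
    return ElasticityRecord(
        parameter=parameter_name,
        elasticity=float(e),
        delta=delta,
        base_log_lambda_s=base_result.log_lambda_s,
        seed=config.seed,
    )


def elasticity_profile(
    params: DEBParams,
    regime: FeedingRegime,
    config: SimConfig | None = None,
    delta: float = 0.01,
    method: str = "forward",
    state_sequence: np.ndarray | None = None,
) -> list[ElasticityRecord]:
    """Elasticities of all six perturbable traits, sharing one baseline run."""
    if config is None:
        config = SimConfig()
    if state_sequence is None:
        state_sequence = simulate_state_sequence(regime, config.total_steps, config.seed)
    base = project(params, regime, config, state_sequence=state_sequence)
    return [
        elasticity(
            params,
            regime,
            config,
            parameter_name=name,
            delta=delta,
            method=method,
            state_sequence=state_sequence,
            base_result=base,
        )
        for name in PERTURBABLE_PARAMETERS
    ]


@dataclass(frozen=True)
class DominantParameterMap:
    """Most-influential trait (max |elasticity|) per (p, q) grid cell."""

    p_values: np.ndarray
    q_values: np.ndarray
    dominant: np.ndarray            # dtype=object, parameter names
    elasticities: dict              # parameter name -> (n_p, n_q) array
    tie: np.ndarray                 # True where the maximum |e| is not unique
    regime_template: FeedingRegime
    seed: int
    delta: float

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: p, q, rho, f, one elasticity column per trait, dominant."""
        rows = []
        for i, p in enumerate(self.p_values):
            for j, q in enumerate(self.q_values):
                row = {
                    "p": p,
                    "q": q,
                    "rho": 1.0 - p - q,
                    "f": q / (p + q),
                    "dominant": self.dominant[i, j],
                    "tie": bool(self.tie[i, j]),
                }
                for name in PERTURBABLE_PARAMETERS:
                    row[f"e_{name}"] = self.elasticities[name][i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def dominant_parameter_map(
    params: DEBParams,
    base_regime: FeedingRegime,
    p_values,
    q_values,
    config: SimConfig | None = None,
    delta: float = 0.01,
    progress=None,
) -> DominantParameterMap:
    """Map of the most-influential trait across a (p, q) grid.

    Per cell, all six elasticities are computed against a shared baseline
    and state sequence; the dominant trait maximises |elasticity|, with
    exact ties broken by the fixed order L_b, L_p, L_m, R_m, rB, mu and
    flagged.
    """
    if config is None:
        config = SimConfig()
    p_values = np.asarray(p_values, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    shape = (len(p_values), len(q_values))
    elas = {name: np.empty(shape) for name in PERTURBABLE_PARAMETERS}
    dominant = np.empty(shape, dtype=object)
    tie = np.zeros(shape, dtype=bool)
    total_cells = shape[0] * shape[1]
    done = 0
    for i, p in enumerate(p_values):
        for j, q in enumerate(q_values):
            if p == 0.0 and q == 0.0:
                raise ValueError("the p = q = 0 cell is a frozen chain; drop it")
            regime = replace(base_regime, p=float(p), q=float(q))
            states = simulate_state_sequence(
                regime, config.total_steps, cell_seed(config.seed, i, j)
            )
            records = elasticity_profile(
                params, regime, config, delta=delta, state_sequence=states
            )
            magnitudes = np.array([abs(r.elasticity) for r in records])
            best = int(np.argmax(magnitudes))
            dominant[i, j] = PERTURBABLE_PARAMETERS[best]
            tie[i, j] = int((magnitudes == magnitudes[best]).sum()) > 1
            for rec in records:
                elas[rec.parameter][i, j] = rec.elasticity
            done += 1
            if progress is not None:
                progress(done, total_cells)
    return DominantParameterMap(
        p_values=p_values,
        q_values=q_values,
        dominant=dominant,
        elasticities=elas,
        tie=tie,
        regime_template=base_regime,
        seed=config.seed,
        delta=delta,
    )
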