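"""Cross-protocol validation metrics.

A parameter estimate obtained from one sweep is judged by how well it
predicts the current recorded under every other protocol.  Errors are
summarised with the normalised root-mean-square error

    NRMSE(y, z) = sqrt(sum (z_i - y_i)^2) / sqrt(sum z_i^2),

which is invariant to the cell's current magnitude (so wells with
different conductances are comparable) and to trace length (so
protocols with different durations are comparable).  Per-well tables of
NRMSE indexed by (fitting sweep, validation sweep) are averaged into a
fitting score E_fit (mean of the matched fit entries) and a prediction
score E_predict (mean over all unmatched pairs).  Repeated sweeps of the
staircase protocol count as separate entries.

Two residual summaries describe *where* a model fails: per-timepoint
noise-weighted residuals averaged across wells, and the ensemble
consistency statistic

    T_i = (ybar_i - z_i) / (sigma_hat + std(y_i) / sqrt(N_predictions)),

large when an ensemble of independently fitted predictions is
consistently wrong in the same direction.  Both are clipped to
[-100, 100] for display.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import MarkovModelSpec
from .protocols import VoltageProtocol
from .simulator import simulate_current
from .traces import SweepTrace

__all__ = [
    "nrmse",
    "cross_validation_table",
    "e_fit",
    "e_predict",
    "weighted_residuals",
    "consistency_T",
]

CLIP = 100.0


def nrmse(y: Sequence[float], z: Sequence[float]) -> float:
    """Root-mean-square error of y against z, normalised by ||z||."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if y.shape != z.shape:
        raise ValueError("y and z must have equal length")
    denom = np.linalg.norm(z)
    if denom == 0.0:
        raise ValueError("reference trace is identically zero")
    return float(np.linalg.norm(z - y) / denom)


def _sweep_label(protocol: str, sweep: int) -> str:
    return f"{protocol}({sweep})"


def cross_validation_table(fits: Sequence[FitResult],
                           validation: Mapping[tuple[str, int], SweepTrace],
                           protocols: Mapping[str, VoltageProtocol],
                           model: MarkovModelSpec) -> pd.DataFrame:
    """NRMSE of every fit against every validation sweep for one well.

    Rows are fitting sweeps, columns validation sweeps (labelled
    ``protocol(sweep)``); the matched entries are fits, all others
    predictions.  ``validation`` maps (protocol, sweep) to the
    postprocessed I_Kr traces, and may include validation-only
    protocols that have no corresponding row.
    """
    col_keys = sorted(validation, key=lambda k: (k[0], k[1]))
    cols = [_sweep_label(*k) for k in col_keys]
    rows = [_sweep_label(f.protocol, f.sweep) for f in fits]
    table = pd.DataFrame(np.nan, index=rows, columns=cols)
    predictions: dict[tuple, np.ndarray] = {}
    for f in fits:
        for key in col_keys:
            proto_name, _ = key
            cache_key = (id(f), proto_name)
            if cache_key not in predictions:
                predictions[cache_key] = simulate_current(
                    model, f.params, protocols[proto_name], f.E_Kr,
                    V_off=f.V_off,
                ).current
            z = validation[key].current
            table.loc[_sweep_label(f.protocol, f.sweep), _sweep_label(*key)] = \
                nrmse(predictions[cache_key], z)
    return table


def _matched(table: pd.DataFrame):
    return [(r, r) for r in table.index if r in table.columns]


def e_fit(table: pd.DataFrame) -> float:
    """Mean NRMSE of the matched (fitting) entries."""
    pairs = _matched(table)
    if not pairs:
        raise ValueError("table has no matched fit entries")
    return float(np.mean([table.loc[r, c] for r, c in pairs]))


def e_predict(table: pd.DataFrame) -> float:
    """Average NRMSE over unmatched (prediction) pairs.

    The double sum over fitting rows and non-matching validation
    columns is normalised by (N_d - 1)^2 with N_d the number of
    validation sweeps — the convention of the source formula.  With one
    validation-only protocol among the columns this equals the number
    of prediction terms, making the score their plain mean.
    """
    n_d = len(table.columns)
    if len(table.index) == 0 or n_d < 2:
        raise ValueError("table needs fitting rows and >= 2 validation columns")
    total = 0.0
    for r in table.index:
        for c in table.columns:
            if c != r:
                val = table.loc[r, c]
                if np.isfinite(val):
                    total += val
    return float(total / (n_d - 1) ** 2)


def weighted_residuals(traces_by_well: Mapping[str, tuple[np.ndarray, np.ndarray, float]]
                       ) -> np.ndarray:
    """Mean across wells of (y_i - z_i)/sigma_hat, clipped to +/-100.

    ``traces_by_well`` maps well id to (model output y, data z,
    sigma_hat).  Positive values mean the model overestimates the
    current.
    """
    if not traces_by_well:
        raise ValueError("no wells supplied")
    acc = None
    for well, (y, z, sigma) in traces_by_well.items():
        if sigma <= 0:
            raise ValueError(f"sigma_hat must be positive (well {well})")
        r = (np.asarray(y, dtype=float) - np.asarray(z, dtype=float)) / sigma
        acc = r if acc is None else acc + r
    mean = acc / len(traces_by_well)
    return np.clip(mean, -CLIP, CLIP)


def consistency_T(predictions: np.ndarray, data: np.ndarray, sigma_hat: float,
                  se_scaling: str = "sqrt") -> np.ndarray:
    """Ensemble consistency statistic per timepoint, clipped to +/-100.

    ``predictions`` is (N_predictions x T); rows must come from fits to
    protocols *other* than the one under evaluation.  The ensemble
    spread enters as a standard error, std(y_i)/sqrt(N); set
    ``se_scaling="n"`` to divide by N instead.
    """
    Y = np.atleast_2d(np.asarray(predictions, dtype=float))
    n_pred = Y.shape[0]
    if n_pred < 2:
        raise ValueError("need at least 2 ensemble predictions")
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    z = np.asarray(data, dtype=float)
    ybar = Y.mean(axis=0)
    spread = Y.std(axis=0, ddof=0)
    denom_n = np.sqrt(n_pred) if se_scaling == "sqrt" else float(n_pred)
    T = (ybar - z) / (sigma_hat + spread / denom_n)
    return np.clip(T, -CLIP, CLIP)
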