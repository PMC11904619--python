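"""Well- and protocol-dependence of kinetic parameter estimates.

Fitting every sweep of every protocol in every well yields a table of
parameter estimates.  On the transformed scale (a = ln A for every
pre-factor or voltage-independent rate parameter, b untouched; the
conductance is excluded since cell-to-cell conductance variation is
expected and uninformative about kinetics) the estimates are modelled
with the two-way fixed-effects linear model

    Y = mu + X_d beta_d + X_w beta_w + E,

where rows of Y are estimates, X_w / X_d encode the well / protocol of
each row, the effects are constrained to sum to zero across levels, and
the errors in each column are IID Gaussian with column-specific
standard deviation sigma_k (maximum-likelihood variance).  Nested
variants fix beta_w = 0 (Md), beta_d = 0 (Mw) or both (M0).

Log-likelihood differences between the full model and each reduced
model quantify the strength of well dependence, LLD(-w) = l(Mwd) -
l(Md), and protocol dependence, LLD(-d) = l(Mwd) - l(Mw).  Large
protocol dependence is the signature of model discrepancy; large well
dependence points at latent per-well experimental effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import FitResult
from .models import MarkovModelSpec
from .synthetic import kinetic_slot_kinds

__all__ = [
    "VARIANTS",
    "LinearEffectsFit",
    "transform_estimates",
    "build_design_matrices",
    "fit_linear_model",
    "lld",
    "lld_table",
]

VARIANTS = ("M0", "Mw", "Md", "Mwd")

_SIGMA_FLOOR = 1e-12  # guards log-likelihood on exactly collinear data


def transform_estimates(fits: Sequence[FitResult],
                        model: MarkovModelSpec) -> pd.DataFrame:
    """Estimate table on the (a = ln A, b) scale, conductance dropped.

    Returns a DataFrame with a (well, protocol, sweep) MultiIndex and
    one column per kinetic parameter, ordered by (well, protocol,
    sweep).
    """
    if any(f.model_name != model.name for f in fits):
        raise ValueError("all fits must come from the same model structure")
    kinds = kinetic_slot_kinds(model)
    names = [f"{'a' if k == 'A' else 'b'}{i + 1}" for i, k in enumerate(kinds)]
    rows, index = [], []
    for f in sorted(fits, key=lambda f: (f.well, f.protocol, f.sweep)):
        p = np.asarray(f.params[: model.n_kinetic_params], dtype=float)
        if np.any(p <= 0):
            raise ValueError("non-positive kinetic parameter in fit results")
        row = [np.log(p[i]) if kinds[i] == "A" else p[i] for i in range(len(p))]
        rows.append(row)
        index.append((f.well, f.protocol, f.sweep))
    return pd.DataFrame(
        rows, columns=names,
        index=pd.MultiIndex.from_tuples(index, names=["well", "protocol", "sweep"]),
    )


def _effect_coding(labels: Sequence, name: str):
    """Sum-to-zero (effects) coding: one column per level minus one.

    The dropped (last) level is encoded as -1 in every column, so the
    expanded effects across all levels sum to zero by construction.
    """
    levels = sorted(set(labels))
    counts = pd.Series(labels).value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise ValueError(f"{name} level(s) with no rows: {empty}")
    n = len(labels)
    X = np.zeros((n, max(len(levels) - 1, 0)))
    pos = {lv: i for i, lv in enumerate(levels)}
    for r, lab in enumerate(labels):
        i = pos[lab]
        if i < len(levels) - 1:
            X[r, i] = 1.0
        else:
            X[r, :] = -1.0
    return X, levels


def build_design_matrices(row_labels: Sequence[tuple]) -> tuple:
    """(X_w, X_d, well levels, protocol levels) from (well, protocol[, sweep]) labels.

    Repeated sweeps of the same protocol share one protocol level.
    """
    wells = [lab[0] for lab in row_labels]
    protocols = [lab[1] for lab in row_labels]
    X_w, well_levels = _effect_coding(wells, "well")
    X_d, proto_levels = _effect_coding(protocols, "protocol")
    return X_w, X_d, well_levels, proto_levels


@dataclass
class LinearEffectsFit:
    variant: str
    mu: np.ndarray  # 1 x P intercept
    beta_w: pd.DataFrame  # wells x P (all-zero for variants without w)
    beta_d: pd.DataFrame  # protocols x P
    sigma_k: np.ndarray  # per-column ML error SD
    loglik: float
    n_rows: int
    residuals: np.ndarray


def fit_linear_model(table: pd.DataFrame, variant: str = "Mwd") -> LinearEffectsFit:
    """Column-wise OLS fit of one model variant with ML variances."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    Y = table.to_numpy(dtype=float)
    n, P = Y.shape
    labels = list(table.index)
    X_w, X_d, well_levels, proto_levels = build_design_matrices(labels)
    # a factor with a single level contributes nothing: the model
    # degenerates to the variant without that effect
    blocks = [np.ones((n, 1))]
    if variant in ("Md", "Mwd") and len(proto_levels) >= 2:
        blocks.append(X_d)
    if variant in ("Mw", "Mwd") and len(well_levels) >= 2:
        blocks.append(X_w)
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "design is rank deficient: well and protocol levels are aliased "
            "(is every (well, protocol) cell supported?)"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid ** 2, axis=0)
    sigma = np.sqrt(np.maximum(rss / n, _SIGMA_FLOOR ** 2))
    loglik = float(np.sum(-0.5 * n * np.log(2 * np.pi * sigma ** 2) - 0.5 * rss / sigma ** 2))

    mu = beta[0]
    k = 1
    if variant in ("Md", "Mwd"):
        coef = beta[k:k + len(proto_levels) - 1]
        k += len(proto_levels) - 1
        full_d = np.vstack([coef, -coef.sum(axis=0)])
    else:
        full_d = np.zeros((len(proto_levels), P))
    if variant in ("Mw", "Mwd"):
        coef = beta[k:k + len(well_levels) - 1]
        full_w = np.vstack([coef, -coef.sum(axis=0)])
    else:
        full_w = np.zeros((len(well_levels), P))
    return LinearEffectsFit(
        variant=variant, mu=mu,
        beta_w=pd.DataFrame(full_w, index=well_levels, columns=table.columns),
        beta_d=pd.DataFrame(full_d, index=proto_levels, columns=table.columns),
        sigma_k=sigma, loglik=loglik, n_rows=n, residuals=resid,
    )


_NESTING = {
    ("Mwd", "Mw"), ("Mwd", "Md"), ("Mwd", "M0"),
    ("Mw", "M0"), ("Md", "M0"),
}


def lld(full: LinearEffectsFit, reduced: LinearEffectsFit) -> float:
    """Log-likelihood difference l(full) - l(reduced) for nested variants."""
    if (full.variant, reduced.variant) not in _NESTING:
        raise ValueError(
            f"{reduced.variant} is not nested in {full.variant}"
        )
    return float(full.loglik - reduced.loglik)


def lld_table(table: pd.DataFrame) -> pd.Series:
    """All four variant likelihoods plus LLD(-w) and LLD(-d)."""
    fits = {v: fit_linear_model(table, v) for v in VARIANTS}
    return pd.Series({
        "l_M0": fits["M0"].loglik,
        "l_Mw": fits["Mw"].loglik,
        "l_Md": fits["Md"].loglik,
        "l_Mwd": fits["Mwd"].loglik,
        "LLD_w": lld(fits["Mwd"], fits["Md"]),
        "LLD_d": lld(fits["Mwd"], fits["Mw"]),
    })
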