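"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda)-CMA-ES with
cumulative step-size adaptation and rank-one plus rank-mu covariance
updates, following Hansen's canonical formulation.  It is a derivative-
free stochastic optimizer well suited to the multimodal, badly scaled
sum-of-squares surfaces that arise when fitting gating-model kinetics,
where restarts from randomized initial means give a practical chance of
escaping local optima.

Only the pieces the fitting pipeline needs are implemented: seeded
reproducible sampling, an optional diagonal initial covariance to encode
per-dimension scales, a target-value stop, and a relative function-value
stagnation stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CMAESResult", "minimize_cmaes", "default_population_size"]


def default_population_size(n_params: int) -> int:
    """The standard population-size heuristic floor(4 + 3 ln n)."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return int(np.floor(4 + 3 * np.log(n_params)))


@dataclass
class CMAESResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    converged: bool
    stop_reason: str
    history: list = field(default_factory=list)  # best f per generation


def minimize_cmaes(f, x0, sigma0: float = 0.3, popsize: int | None = None,
                   scales=None, seed=None, maxevals: int = 10_000,
                   ftol_rel: float = 1e-7, ftol_iters: int = 20,
                   ftarget: float | None = None) -> CMAESResult:
    """Minimize ``f`` starting from mean ``x0`` with step size ``sigma0``.

    ``scales`` (optional, per-dimension) sets the diagonal of the
    initial covariance, encoding the expected magnitude of moves along
    each coordinate; ``sigma0`` is the global step multiplier relative
    to those scales.
    """
    m = np.asarray(x0, dtype=float).copy()
    n = m.size
    lam = popsize or default_population_size(n)
    lam = max(lam, 4)
    mu = lam // 2
    rng = np.random.default_rng(seed)

    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w ** 2)

    cs = (mueff + 2) / (n + mueff + 5)
    ds = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    scales = np.ones(n) if scales is None else np.asarray(scales, dtype=float)
    C = np.diag(scales ** 2)
    sigma = float(sigma0)
    ps = np.zeros(n)
    pc = np.zeros(n)

    x_best = m.copy()
    f_best = np.inf
    n_evals = 0
    gen = 0
    history: list[float] = []
    stop = ""

    while n_evals < maxevals:
        gen += 1
        evals, B = np.linalg.eigh(C)
        evals = np.clip(evals, 1e-30, None)
        D = np.sqrt(evals)
        if D.max() / D.min() > 1e14:
            stop = "condition"
            break

        z = rng.standard_normal((lam, n))
        y = z * D @ B.T  # each row: B @ (D * z_i)
        xs = m + sigma * y
        fs = np.empty(lam)
        for i in range(lam):
            fs[i] = f(xs[i])
        n_evals += lam

        order = np.argsort(fs)
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs[order[0]].copy()
        history.append(float(fs[order[0]]))

        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        m = m + sigma * y_w

        # step-size path (uses C^{-1/2} y_w)
        c_inv_half_yw = B @ ((B.T @ y_w) / D)
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * c_inv_half_yw
        hsig = (np.linalg.norm(ps)
                / np.sqrt(1 - (1 - cs) ** (2 * gen)) / chiN) < (1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
             + cmu * rank_mu)
        C = (C + C.T) / 2
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chiN - 1))

        if ftarget is not None and f_best <= ftarget:
            stop = "ftarget"
            break
        if len(history) >= ftol_iters:
            recent = history[-ftol_iters:]
            span = max(recent) - min(recent)
            if span <= ftol_rel * max(abs(recent[-1]), 1e-12):
                stop = "ftol"
                break
        if sigma * D.max() < 1e-12:
            stop = "sigma"
            break

    if not stop:
        stop = "maxevals"
    converged = stop in ("ftol", "ftarget", "sigma")
    return CMAESResult(x=x_best, fun=f_best, n_evals=n_evals, n_iter=gen,
                       converged=converged, stop_reason=stop, history=history)
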