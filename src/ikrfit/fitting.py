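"""Per-sweep maximum-likelihood fitting of gating models.

Under the additive IID Gaussian noise model the MLE is the nonlinear
least-squares estimate

    theta_hat = argmin_theta sum_i (y_i(theta) - z_i)^2,

minimised here with repeated runs of CMA-ES from randomized initial
guesses.  Initial kinetic parameters (and the conductance) are drawn
log-uniformly, log10(p) ~ U(-7, 1), and resampled until every transition
rate respects the stiffness bounds

    1.67e-5 / ms <= k_max <= 1e5 / ms,

where k_max is the largest value the rate attains over the command
voltage range [-120, +60] mV.  The maximal conductance is additionally
kept inside lenient data-driven bounds derived from the largest current
observed during the -120 mV scaffold step.

The search runs in a transformed space — log10 for pre-factor (A-type),
voltage-independent and conductance parameters, linear for exponent (b)
parameters — matching the scale of the initial-guess prior and keeping
the surface better conditioned.  Bound handling is projection with a
penalty: each proposal is projected onto the feasible box and the
objective is charged a term growing with the projection distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cmaes import default_population_size, minimize_cmaes
from .models import MarkovModelSpec, RateForm, RateKind
from .protocols import SectionTag, SegmentKind, VoltageProtocol
from .simulator import SimulationError, simulate_current
from .traces import SweepTrace

__all__ = [
    "FitConfig",
    "FitResult",
    "objective",
    "check_rate_bounds",
    "conductance_bounds",
    "population_size",
    "sample_initial_guess",
    "fit_sweep",
]

_LOG10E = np.log10(np.e)


@dataclass(frozen=True)
class FitConfig:
    n_repeats: int = 30
    rate_bound_lo: float = 1.67e-5  # 1/ms
    rate_bound_hi: float = 1e5  # 1/ms
    v_low: float = -120.0  # mV, rate-bound voltage range
    v_high: float = 60.0
    init_log10_lo: float = -7.0
    init_log10_hi: float = 1.0
    pop_size_override: int | None = None  # 50 for the Wang model
    c_lo: float = 1e-4  # lenient conductance-bound factors; the reference
    c_hi: float = 1e4   # current during the -120 mV step can be far below
                        # the cell's overall current scale on corrected traces
    sigma0: float = 0.3  # CMA step size, relative to per-dimension scales
    maxevals: int = 10_000
    ftol_rel: float = 1e-7
    ftarget: float | None = None
    polish: bool = True  # trust-region least-squares refinement per repeat
    polish_max_nfev: int = 150
    ramp_substep: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rate_bound_lo < self.rate_bound_hi):
            raise ValueError("rate bounds must satisfy lo < hi")
        if not (self.init_log10_lo < self.init_log10_hi):
            raise ValueError("initial-guess bounds must satisfy lo < hi")
        if not (self.v_low < self.v_high):
            raise ValueError("voltage range must satisfy lo < hi")
        if not (0 < self.c_lo < self.c_hi):
            raise ValueError("conductance factors must satisfy 0 < c_lo < c_hi")


@dataclass
class FitResult:
    """Best parameter estimate for one sweep plus per-repeat diagnostics."""

    well: str
    protocol: str
    sweep: int
    model_name: str
    params: np.ndarray  # kinetics then g, natural units
    sse: float
    rmse: float
    repeats: pd.DataFrame  # repeat, sse, rmse, n_evals, converged
    E_Kr: float
    V_off: float

    @property
    def n_repeats_within_1pct(self) -> int:
        ok = self.repeats["rmse"] <= 1.01 * self.rmse
        return int(ok.sum())


def objective(model: MarkovModelSpec, theta: Sequence[float],
              protocol: VoltageProtocol, data: Sequence[float],
              E_Kr: float, V_off: float = 0.0,
              ramp_substep: float | None = None) -> float:
    """Sum of squared residuals between simulated and observed current."""
    z = np.asarray(data, dtype=float)
    try:
        sim = simulate_current(model, theta, protocol, E_Kr, V_off=V_off,
                               ramp_substep=ramp_substep)
    except (SimulationError, np.linalg.LinAlgError, ValueError, OverflowError) as exc:
        warnings.warn(f"simulation failed during objective evaluation: {exc}")
        return np.inf
    y = sim.current
    if y.shape != z.shape:
        raise ValueError("data is not on the protocol sample grid")
    return float(np.sum((y - z) ** 2))


def _kmax_exponent(form: RateForm, b: float, config: FitConfig) -> float:
    """b-dependent exponent such that k_max = A * exp(exponent)."""
    if form.kind is RateKind.POS_EXP:
        return b * config.v_high
    if form.kind is RateKind.NEG_EXP:
        return -b * config.v_low
    return 0.0


def check_rate_bounds(form: RateForm, A: float, b: float,
                      config: FitConfig = FitConfig()) -> bool:
    """Whether the rate's maximum over the voltage range is in bounds.

    Compared in log space so extreme proposals cannot overflow.
    """
    if A <= 0:
        return False
    log_kmax = np.log(A) + _kmax_exponent(form, b, config)
    return bool(np.log(config.rate_bound_lo) <= log_kmax
                <= np.log(config.rate_bound_hi))


def conductance_bounds(trace: SweepTrace, protocol: VoltageProtocol,
                       E_Kr: float, config: FitConfig = FitConfig()):
    """Lenient (g_lo, g_hi) from the -120 mV scaffold step current."""
    step_mask = np.zeros(len(trace.times), dtype=bool)
    idx = protocol.segment_index(trace.times)
    found = False
    for k, seg in enumerate(protocol.segments):
        if (seg.section_tag is SectionTag.LEAK_RAMP
                and seg.kind is SegmentKind.STEP and seg.v_start == -120.0):
            step_mask |= idx == k
            found = True
    if not found:
        warnings.warn("no -120 mV scaffold step; conductance unbounded")
        return 0.0, np.inf
    peak = float(np.max(np.abs(trace.current[step_mask])))
    if peak == 0.0:
        warnings.warn("zero current during -120 mV step; degenerate bounds")
        return 0.0, np.inf
    g_ref = peak / abs(-120.0 - E_Kr)
    return config.c_lo * g_ref, config.c_hi * g_ref


def population_size(n_params: int, override: int | None = None) -> int:
    """floor(4 + 3 ln n_p), unless an override is given."""
    if override is not None:
        return int(override)
    return default_population_size(n_params)


def _rate_forms(model: MarkovModelSpec) -> list[RateForm]:
    seen: dict[tuple, RateForm] = {}
    for tr in model.transitions:
        seen[(tr.rate.A_index, tr.rate.b_index, tr.rate.kind)] = tr.rate
    return list(seen.values())


def _slot_kinds(model: MarkovModelSpec) -> list[str]:
    kinds = ["A"] * model.total_params  # conductance handled like A (log scale)
    for form in _rate_forms(model):
        if form.b_index is not None:
            kinds[form.b_index] = "b"
    return kinds


def sample_initial_guess(model: MarkovModelSpec, config: FitConfig,
                         g_bounds: tuple[float, float], seed) -> np.ndarray:
    """Log-uniform initial guess respecting rate and conductance bounds.

    Kinetic parameters are drawn with log10(p) ~ U(-7, 1) and the whole
    set resampled until every transition rate passes the k_max bounds.
    The conductance is drawn log-uniformly on the overlap of U(-7, 1)'s
    support with the data-driven bounds, or on the bounds themselves
    when they do not overlap that support (as for high-conductance
    cells).
    """
    rng = np.random.default_rng(seed)
    forms = _rate_forms(model)
    lo, hi = config.init_log10_lo, config.init_log10_hi
    for attempt in range(100_000):
        p = 10.0 ** rng.uniform(lo, hi, size=model.n_kinetic_params)
        ok = all(
            check_rate_bounds(f, p[f.A_index],
                              0.0 if f.b_index is None else p[f.b_index], config)
            for f in forms
        )
        if ok:
            break
    else:
        raise RuntimeError("could not sample a feasible initial guess "
                           "(pathological bounds)")
    g_lo, g_hi = g_bounds
    glo = np.log10(max(g_lo, 1e-12)) if g_lo > 0 else lo
    ghi = np.log10(g_hi) if np.isfinite(g_hi) else hi
    o_lo, o_hi = max(glo, lo), min(ghi, hi)
    if o_lo >= o_hi:  # bounds outside the prior support
        o_lo, o_hi = glo, ghi
    g = 10.0 ** rng.uniform(o_lo, o_hi)
    return np.append(p, g)


class _SearchSpace:
    """Transform between natural parameters and CMA search coordinates."""

    def __init__(self, model: MarkovModelSpec, config: FitConfig,
                 g_bounds: tuple[float, float]):
        self.model = model
        self.config = config
        self.kinds = _slot_kinds(model)
        self.log_mask = np.array([k == "A" for k in self.kinds])
        self.forms = _rate_forms(model)
        g_lo, g_hi = g_bounds
        self.g_box = (
            np.log10(max(g_lo, 1e-12)) if g_lo > 0 else -12.0,
            np.log10(g_hi) if np.isfinite(g_hi) else 12.0,
        )
        # expected move magnitudes: decades for log dims, 1/mV for b dims
        self.scales = np.where(self.log_mask, 8.0, 0.5)

    def encode(self, theta: np.ndarray) -> np.ndarray:
        u = np.asarray(theta, dtype=float).copy()
        u[self.log_mask] = np.log10(u[self.log_mask])
        return u

    def decode(self, u: np.ndarray) -> np.ndarray:
        theta = np.asarray(u, dtype=float).copy()
        theta[self.log_mask] = 10.0 ** theta[self.log_mask]
        return theta

    def repair(self, u: np.ndarray):
        """Project onto the feasible box; return (repaired, violation)."""
        cfg = self.config
        v = 0.0
        u = np.asarray(u, dtype=float).copy()
        log_lo, log_hi = np.log10(cfg.rate_bound_lo), np.log10(cfg.rate_bound_hi)
        for form in self.forms:
            if form.b_index is not None:
                b = u[form.b_index]
                if b < 1e-9:  # keep strictly positive
                    v += (b - 1e-9) ** 2
                    b = 1e-9
                elif b > 1.0:  # absurd exponent; keeps exp() finite
                    v += (b - 1.0) ** 2
                    b = 1.0
                u[form.b_index] = b
            else:
                b = 0.0
            shift = _LOG10E * _kmax_exponent(form, b, cfg)
            a_lo, a_hi = log_lo - shift, log_hi - shift
            a = u[form.A_index]
            if a < a_lo:
                v += (a_lo - a) ** 2
                u[form.A_index] = a_lo
            elif a > a_hi:
                v += (a - a_hi) ** 2
                u[form.A_index] = a_hi
        gi = self.model.conductance_index
        g = np.clip(u[gi], *self.g_box)
        v += (u[gi] - g) ** 2
        u[gi] = g
        return u, v


def fit_sweep(model: MarkovModelSpec, trace: SweepTrace,
              protocol: VoltageProtocol, config: FitConfig = FitConfig(),
              E_Kr: float | None = None, V_off: float | None = None) -> FitResult:
    """Repeated-CMA-ES maximum-likelihood fit of one postprocessed sweep.

    ``E_Kr`` defaults to the Nernst potential of the study solutions and
    ``V_off`` to the trace's inferred offset annotation (0 if absent).
    """
    if E_Kr is None:
        E_Kr = -89.85
    if V_off is None:
        V_off = trace.V_off if trace.V_off is not None else 0.0
    z = trace.current
    g_bounds = conductance_bounds(trace, protocol, E_Kr, config)
    space = _SearchSpace(model, config, g_bounds)
    n = len(z)

    def search_objective(u: np.ndarray) -> float:
        u_rep, viol = space.repair(u)
        sse = objective(model, space.decode(u_rep), protocol, z, E_Kr, V_off,
                        ramp_substep=config.ramp_substep)
        if not np.isfinite(sse):
            return 1e300
        return sse + (1.0 + sse) * viol

    popsize = population_size(
        model.total_params,
        config.pop_size_override if config.pop_size_override is not None
        else (50 if model.name == "Wang" else None),
    )

    pen_scale = np.sqrt(1.0 + float(np.sum(z ** 2)))

    def search_residuals(u: np.ndarray) -> np.ndarray:
        u_rep, viol = space.repair(u)
        try:
            sim = simulate_current(model, space.decode(u_rep), protocol, E_Kr,
                                   V_off=V_off, ramp_substep=config.ramp_substep)
            r = sim.current - z
        except (SimulationError, np.linalg.LinAlgError, ValueError, OverflowError):
            r = np.full(n, 1e120)
        return np.append(r, pen_scale * np.sqrt(viol))

    rows = []
    best_u, best_f = None, np.inf
    for rep in range(config.n_repeats):
        guess_seed = [config.seed, rep]
        theta0 = sample_initial_guess(model, config, g_bounds, guess_seed)
        res = minimize_cmaes(
            search_objective, space.encode(theta0), sigma0=config.sigma0,
            popsize=popsize, scales=space.scales, seed=[config.seed, rep, 1],
            maxevals=config.maxevals, ftol_rel=config.ftol_rel,
            ftarget=config.ftarget,
        )
        u_rep, f_rep, n_ev = res.x, res.fun, res.n_evals
        if config.polish and np.isfinite(f_rep):
            try:
                pol = least_squares(search_residuals, u_rep, method="trf",
                                    max_nfev=config.polish_max_nfev,
                                    xtol=1e-12, ftol=1e-12, gtol=1e-10)
                f_pol = search_objective(pol.x)
                n_ev += pol.nfev
                if f_pol < f_rep:
                    u_rep, f_rep = pol.x, f_pol
            except (ValueError, np.linalg.LinAlgError):
                pass
        rows.append({
            "repeat": rep, "sse": f_rep, "rmse": np.sqrt(max(f_rep, 0) / n),
            "n_evals": n_ev, "converged": res.converged,
            "stop_reason": res.stop_reason,
        })
        if f_rep < best_f:
            best_f, best_u = f_rep, u_rep
    if best_u is None or not np.isfinite(best_f):
        raise RuntimeError(
            f"all {config.n_repeats} optimization repeats failed for "
            f"{trace.well}/{trace.protocol}/{trace.sweep}"
        )
    u_rep, _ = space.repair(best_u)
    theta = space.decode(u_rep)
    sse = objective(model, theta, protocol, z, E_Kr, V_off,
                    ramp_substep=config.ramp_substep)
    return FitResult(
        well=trace.well, protocol=trace.protocol, sweep=trace.sweep,
        model_name=model.name, params=theta, sse=sse,
        rmse=float(np.sqrt(sse / n)), repeats=pd.DataFrame(rows),
        E_Kr=E_Kr, V_off=V_off,
    )
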