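"""Postprocessing of raw sweeps: leak correction, drug subtraction,
reversal-potential inference, noise estimation and quality control.

The pipeline per (well, protocol, sweep) pair is:

1. fit the linear leak model on the leak-ramp section of both the
   pre-drug and post-drug sweeps (I_Kr is negligible in the ramp's
   [-120, -80] mV range, so ordinary least squares of current on
   command voltage identifies g_L and E_L);
2. subtract each sweep's own leak;
3. subtract the leak-corrected post-drug sweep (complete specific
   block, so only residual non-I_Kr current remains there) from the
   leak-corrected pre-drug sweep, isolating I_Kr;
4. on the reversal ramp of the corrected trace, fit an order-4
   polynomial in time, locate the zero crossing t*, and report
   E_obs = V_cmd(t*) and V_off = E_Nernst - E_obs;
5. estimate the noise level as the sample SD over the initial holding
   section, where the corrected current should be flat.

Quality control marks a well as usable only if every sweep passes the
noise, reversal-consistency, staircase-stability and post-drug-residual
criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .protocols import SectionTag, VoltageProtocol
from .traces import LeakModel, SweepTrace

__all__ = [
    "PostprocessError",
    "QCCriteria",
    "fit_leak",
    "leak_subtract",
    "drug_subtract",
    "infer_reversal",
    "compute_voltage_offset",
    "estimate_noise_sd",
    "postprocess_pair",
    "qc_filter",
]


class PostprocessError(RuntimeError):
    pass


@dataclass(frozen=True)
class QCCriteria:
    """Thresholds for well selection.

    The full production rule set lives with the archived data; these are
    package defaults covering the criteria described in the methods, all
    config-overridable.
    """

    max_sigma: float = 50.0  # pA
    max_staircase_drift: float = 0.2  # NRMSE first vs last staircase sweep
    max_Eobs_deviation: float = 15.0  # mV from E_Nernst
    max_postdrug_ratio: float = 0.5  # RMS(post, corrected)/RMS(pre, corrected)

    def __post_init__(self) -> None:
        for name in ("max_sigma", "max_staircase_drift",
                     "max_Eobs_deviation", "max_postdrug_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def fit_leak(trace: SweepTrace, protocol: VoltageProtocol) -> LeakModel:
    """OLS fit of current on command voltage over the leak ramp.

    Only the ramp portion (-120 to -80 mV) is used; the preceding
    constant step is excluded.  Slope gives g_L and intercept -g_L E_L.
    """
    mask = protocol.section_mask(SectionTag.LEAK_RAMP, ramps_only=True)
    if mask.sum() < 3:
        raise PostprocessError("leak ramp has fewer than 3 samples")
    v = protocol.voltage_at(trace.times[mask])
    i = trace.current[mask]
    slope, intercept = np.polyfit(v, i, 1)
    if abs(slope) < 1e-12:
        return LeakModel(g_L=0.0, E_L=0.0, degenerate=True)
    return LeakModel(g_L=float(slope), E_L=float(-intercept / slope))


def leak_subtract(trace: SweepTrace, leak: LeakModel,
                  protocol: VoltageProtocol) -> SweepTrace:
    v_cmd = protocol.voltage_at(trace.times)
    return trace.with_current(trace.current - leak.current(v_cmd), leak=leak)


def drug_subtract(pre: SweepTrace, post: SweepTrace) -> SweepTrace:
    """Pointwise pre-minus-post difference of leak-corrected sweeps."""
    if pre.times.shape != post.times.shape or not np.allclose(pre.times, post.times):
        raise PostprocessError("pre/post sweeps are on different time grids")
    if (pre.well, pre.protocol) != (post.well, post.protocol):
        raise PostprocessError("pre/post sweeps are from different well/protocol")
    out = pre.with_current(pre.current - post.current)
    out.qc_flags = sorted(set(pre.qc_flags) | set(post.qc_flags))
    return out


def infer_reversal(trace: SweepTrace, protocol: VoltageProtocol) -> float:
    """Observed reversal potential from the reversal-ramp zero crossing.

    A degree-4 polynomial is fitted to current versus time over the
    ramp; among its real roots inside the window the one where the
    fitted current descends through zero is taken (along the descending
    ramp the driving force, and hence the current, falls from positive
    to negative as the voltage passes the reversal potential).  Returns
    V_cmd(t*) in the command-voltage frame.
    """
    mask = protocol.section_mask(SectionTag.REVERSAL_RAMP)
    if mask.sum() < 10:
        raise PostprocessError("reversal ramp has fewer than 10 samples")
    t = trace.times[mask]
    i = trace.current[mask]
    # centre time for conditioning
    t0 = t[0]
    coeffs = np.polyfit(t - t0, i, 4)
    poly = np.poly1d(coeffs)
    dpoly = poly.deriv()
    roots = poly.r
    real = roots[np.abs(roots.imag) < 1e-8].real
    window = (real >= -1e-9) & (real <= t[-1] - t0 + 1e-9)
    candidates = [r for r in real[window] if dpoly(r) < 0]
    if not candidates:
        raise PostprocessError(
            "no descending zero crossing of the fitted current in the "
            "reversal-ramp window"
        )
    # earliest descending crossing
    t_star = t0 + min(candidates)
    return float(protocol.voltage_at(t_star))


def compute_voltage_offset(E_obs: float, E_Nernst: float) -> float:
    """Systematic voltage offset V_off = E_Nernst - E_obs."""
    if not (np.isfinite(E_obs) and np.isfinite(E_Nernst)):
        raise ValueError("E_obs and E_Nernst must be finite")
    return float(E_Nernst - E_obs)


def estimate_noise_sd(trace: SweepTrace, protocol: VoltageProtocol) -> float:
    """Sample SD of the current over the initial holding section."""
    first = protocol.segments[0]
    if first.section_tag is not SectionTag.HOLD:
        raise PostprocessError("protocol does not begin with a holding section")
    n_hold = int(np.floor(first.duration / protocol.sample_interval + 1e-9))
    if n_hold < 10:
        raise PostprocessError("holding section shorter than 10 samples")
    return float(np.std(trace.current[:n_hold], ddof=1))


def postprocess_pair(pre: SweepTrace, post: SweepTrace,
                     protocol: VoltageProtocol, E_Nernst: float) -> SweepTrace:
    """Full correction of one pre/post sweep pair to an I_Kr estimate.

    Returns the corrected pre-drug trace annotated with the fitted leak,
    E_obs, V_off and the noise estimate; reversal-inference failure is
    recorded as a QC flag instead of aborting the batch.
    """
    pre_c = leak_subtract(pre, fit_leak(pre, protocol), protocol)
    post_c = leak_subtract(post, fit_leak(post, protocol), protocol)
    corrected = drug_subtract(pre_c, post_c)
    corrected.sigma_hat = estimate_noise_sd(corrected, protocol)
    try:
        corrected.E_obs = infer_reversal(corrected, protocol)
        corrected.V_off = compute_voltage_offset(corrected.E_obs, E_Nernst)
    except PostprocessError:
        corrected.qc_flags.append("no_reversal")
    # stash the post-drug corrected trace size for the QC ratio
    rms_pre = float(np.sqrt(np.mean(pre_c.current ** 2)))
    rms_post = float(np.sqrt(np.mean(post_c.current ** 2)))
    corrected.postdrug_ratio = rms_post / rms_pre if rms_pre > 0 else np.inf
    return corrected


def _nrmse(y: np.ndarray, z: np.ndarray) -> float:
    denom = np.linalg.norm(z)
    if denom == 0:
        return np.inf
    return float(np.linalg.norm(z - y) / denom)


def qc_filter(corrected: Mapping[tuple, SweepTrace], E_Nernst: float,
              criteria: QCCriteria = QCCriteria(),
              staircase: str = "d1",
              raw: Mapping[tuple, SweepTrace] | None = None):
    """Apply QC to postprocessed sweeps; a well passes only if every
    criterion passes on all of its sweeps.

    ``corrected`` maps (well, protocol, sweep) to corrected pre-drug
    traces (as produced by :func:`postprocess_pair`).  The staircase-
    stability criterion compares the first and last staircase repeats on
    the ``raw`` pre-drug recordings when those are supplied (a drifting
    seal leak is invisible after per-sweep leak refitting), otherwise on
    the corrected traces.  Returns ``(passing_wells, flags)`` where
    ``flags`` is a well x criterion boolean table (True = failed).
    """
    wells = sorted({k[0] for k in corrected})
    crits = ["noise", "staircase_drift", "reversal", "postdrug_ratio",
             "missing_staircase"]
    flags = pd.DataFrame(False, index=wells, columns=crits)
    drift_src = raw if raw is not None else corrected
    for well in wells:
        mine = {k: v for k, v in corrected.items() if k[0] == well}
        d1 = [v for (w, p, s), v in sorted(drift_src.items())
              if w == well and p == staircase]
        if len(d1) < 4:
            flags.loc[well, "missing_staircase"] = True
        else:
            drift = _nrmse(d1[0].current, d1[-1].current)
            if not drift <= criteria.max_staircase_drift:
                flags.loc[well, "staircase_drift"] = True
        for tr in mine.values():
            if tr.sigma_hat is not None and tr.sigma_hat > criteria.max_sigma:
                flags.loc[well, "noise"] = True
            if tr.E_obs is None or "no_reversal" in tr.qc_flags or \
                    abs(tr.E_obs - E_Nernst) > criteria.max_Eobs_deviation:
                flags.loc[well, "reversal"] = True
            ratio = getattr(tr, "postdrug_ratio", None)
            if ratio is not None and ratio > criteria.max_postdrug_ratio:
                flags.loc[well, "postdrug_ratio"] = True
    passing = [w for w in wells if not flags.loc[w].any()]
    return passing, flags
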