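"""Synthetic multi-well, multi-protocol experiments.

The generator emulates the statistical structure the downstream analysis
assumes: per-well sweeps of a protocol battery (the staircase fitting
protocol four times, every other protocol once, each repeated after a
complete channel block), with

* additive IID Gaussian measurement noise per sample,
* a linear seal-leak current g_L (V_cmd - E_L),
* a per-well systematic voltage offset, and
* well- and protocol-level heterogeneity applied on the (a = ln A, b)
  scale of the transition rates — the exact additive structure the
  two-way fixed-effects analysis later fits — plus log-normal
  well-to-well variation in maximal conductance.

The post-drug sweeps assume a complete specific block (g = 0), leaving
leak plus noise only, so drug subtraction isolates I_Kr exactly on
average.  Every dataset carries its ground truth so recovery can be
scored by any downstream test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .models import MarkovModelSpec, build_model, default_parameters
from .protocols import ExperimentDesign, VoltageProtocol, default_battery
from .simulator import simulate_current
from .traces import LeakModel, SweepTrace

__all__ = [
    "WellGroundTruth",
    "TruthHyperParams",
    "SyntheticConfig",
    "SyntheticDataset",
    "kinetic_slot_kinds",
    "generate_well_params",
    "generate_sweep",
    "generate_dataset",
]


def kinetic_slot_kinds(model: MarkovModelSpec) -> list[str]:
    """Classify each kinetic parameter slot as 'A' (pre-factor, incl.
    voltage-independent rates) or 'b' (exponent coefficient)."""
    kinds = [""] * model.n_kinetic_params
    for tr in model.transitions:
        kinds[tr.rate.A_index] = "A"
        if tr.rate.b_index is not None:
            kinds[tr.rate.b_index] = "b"
    assert all(kinds)
    return kinds


@dataclass
class WellGroundTruth:
    """True data-generating quantities for one well."""

    well: str
    params: dict[str, np.ndarray]  # protocol -> full parameter vector
    leak: LeakModel
    V_off: float  # mV
    noise_sd: float  # pA
    E_Kr: float = -89.85  # mV
    leak_drift: float = 0.0  # relative g_L change per sweep position
    failure_modes: tuple[str, ...] = ()

    def leak_for(self, position: int) -> LeakModel:
        """Leak model for the sweep at the given schedule position."""
        if self.leak_drift == 0.0:
            return self.leak
        return replace(self.leak, g_L=self.leak.g_L * (1.0 + self.leak_drift * position))


@dataclass(frozen=True)
class TruthHyperParams:
    """Population-level defaults for the synthetic study conditions.

    The source study prints none of these magnitudes; the values below
    are implementer-chosen to resemble a clean automated patch-clamp
    well and are deliberately tunable for power studies.
    """

    noise_sd: float = 20.0  # pA
    g_log_sd: float = 0.3  # lognormal spread of maximal conductance
    g_L_range: tuple[float, float] = (0.1, 2.0)  # nS, uniform
    E_L_range: tuple[float, float] = (-30.0, 10.0)  # mV, uniform
    V_off_sd: float = 2.0  # mV
    a_well_sd: float = 0.10  # well effects on a = ln A
    b_well_sd: float = 0.002  # well effects on b (1/mV)
    a_protocol_sd: float = 0.05
    b_protocol_sd: float = 0.001


@dataclass
class SyntheticConfig:
    model_name: str = "Beattie"
    wells: tuple[str, ...] = ("W01", "W02")
    protocols: Mapping[str, VoltageProtocol] | None = None  # default battery
    base_params: np.ndarray | None = None  # model defaults if None
    hyper: TruthHyperParams = field(default_factory=TruthHyperParams)
    E_Kr: float = -89.85  # mV; the Nernst potential of the study solutions
    sample_interval: float = 1.0  # ms
    validation_only: tuple[str, ...] = ("d6",)
    #: optional QC-failure injection: well -> mode in
    #: {"drift_leak", "noisy", "bad_reversal"}
    failures: Mapping[str, str] = field(default_factory=dict)


def generate_well_params(base_params: Sequence[float], model: MarkovModelSpec,
                         wells: Sequence[str], protocols: Sequence[str],
                         well_effect_sd: float | tuple[float, float],
                         protocol_effect_sd: float | tuple[float, float],
                         seed: int, g_log_sd: float = 0.0):
    """Per-well, per-protocol parameter vectors with additive effects.

    Effects act on a = ln A for pre-factor slots and directly on b for
    exponent slots; they are drawn as zero-mean Gaussians with the given
    standard deviations (a scalar applies to the 'a' scale with the 'b'
    scale set to sd/50, reflecting the ~50x smaller magnitude of b) and
    are re-centred to sum to zero across levels, exactly mirroring the
    structure of the downstream linear-effects model.  The maximal
    conductance is drawn log-normally per well (shared across
    protocols).

    Returns ``(params, effects)`` where ``params[(well, protocol)]`` is
    a full parameter vector and ``effects`` holds the realised matrices
    (wells x slots, protocols x slots) on the transformed scale.
    """

    def _split(sd):
        return sd if isinstance(sd, tuple) else (float(sd), float(sd) / 50.0)

    a_w_sd, b_w_sd = _split(well_effect_sd)
    a_d_sd, b_d_sd = _split(protocol_effect_sd)
    if min(a_w_sd, b_w_sd, a_d_sd, b_d_sd) < 0:
        raise ValueError("effect standard deviations must be non-negative")

    base = np.asarray(base_params, dtype=float)
    kinds = kinetic_slot_kinds(model)
    n_k = model.n_kinetic_params
    rng = np.random.default_rng(seed)

    def _draw(n_levels: int, a_sd: float, b_sd: float) -> np.ndarray:
        sds = np.array([a_sd if k == "A" else b_sd for k in kinds])
        eff = rng.normal(0.0, 1.0, size=(n_levels, n_k)) * sds
        if n_levels > 1:
            eff -= eff.mean(axis=0, keepdims=True)
        else:
            eff[:] = 0.0
        return eff

    well_eff = _draw(len(wells), a_w_sd, b_w_sd)
    proto_eff = _draw(len(protocols), a_d_sd, b_d_sd)
    g_factors = np.exp(rng.normal(0.0, g_log_sd, size=len(wells))) if g_log_sd > 0 \
        else np.ones(len(wells))

    params: dict[tuple[str, str], np.ndarray] = {}
    for wi, well in enumerate(wells):
        for di, proto in enumerate(protocols):
            p = base.copy()
            for k in range(n_k):
                shift = well_eff[wi, k] + proto_eff[di, k]
                if kinds[k] == "A":
                    p[k] = np.exp(np.log(p[k]) + shift)
                else:
                    p[k] = max(p[k] + shift, 1e-9)
            p[model.conductance_index] = base[model.conductance_index] * g_factors[wi]
            params[(well, proto)] = p
    effects = {"well": well_eff, "protocol": proto_eff, "g_factor": g_factors}
    return params, effects


def generate_sweep(truth: WellGroundTruth, model: MarkovModelSpec,
                   protocol: VoltageProtocol, drug_state: str, seed,
                   sweep: int = 1, position: int = 0,
                   ikr_cache: dict | None = None) -> SweepTrace:
    """One synthetic sweep: I_out = I_Kr + I_L + noise (I_Kr = 0 post-drug)."""
    if drug_state not in ("pre", "post"):
        raise ValueError("drug_state must be 'pre' or 'post'")
    times = protocol.times()
    v_cmd = protocol.voltage_at(times)
    if drug_state == "pre":
        key = (truth.well, protocol.name)
        if ikr_cache is not None and key in ikr_cache:
            ikr = ikr_cache[key]
        else:
            ikr = simulate_current(
                model, truth.params[protocol.name], protocol,
                E_Kr=truth.E_Kr, V_off=truth.V_off,
            ).current
            if ikr_cache is not None:
                ikr_cache[key] = ikr
    else:
        ikr = np.zeros_like(times)
    leak = truth.leak_for(position)
    current = ikr + leak.current(v_cmd)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, truth.noise_sd, size=len(times))
    return SweepTrace(truth.well, protocol.name, sweep, drug_state, times, current)


@dataclass
class SyntheticDataset:
    model_name: str
    design: ExperimentDesign
    protocols: dict[str, VoltageProtocol]
    traces: dict[tuple, SweepTrace]
    ground_truth: dict[str, WellGroundTruth]
    E_Kr: float
    effects: dict = field(default_factory=dict)

    def trace(self, well: str, protocol: str, sweep: int, drug_state: str) -> SweepTrace:
        return self.traces[(well, protocol, sweep, drug_state)]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.traces):
            h.update(repr(key).encode())
            h.update(np.ascontiguousarray(self.traces[key].current).tobytes())
        return h.hexdigest()

    def ground_truth_json(self) -> str:
        payload = {}
        for well, gt in self.ground_truth.items():
            payload[well] = {
                "params": {k: list(v) for k, v in gt.params.items()},
                "g_L": gt.leak.g_L,
                "E_L": gt.leak.E_L,
                "V_off": gt.V_off,
                "noise_sd": gt.noise_sd,
                "leak_drift": gt.leak_drift,
                "failure_modes": list(gt.failure_modes),
            }
        return json.dumps({"model": self.model_name, "E_Kr": self.E_Kr,
                           "wells": payload}, indent=1)


def generate_dataset(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Realise the full experimental design for every configured well.

    Per well and drug state the schedule is: d1 twice, each remaining
    protocol once, then d1 twice more; the post-drug block repeats the
    pre-drug order.  Per-sweep noise seeds are derived deterministically
    from the master seed, so identical (config, seed) pairs produce
    bit-identical datasets.
    """
    model = build_model(config.model_name)
    protocols = dict(config.protocols) if config.protocols is not None else \
        default_battery(config.sample_interval)
    base = np.asarray(config.base_params, dtype=float) if config.base_params is not None \
        else default_parameters(model)
    hyper = config.hyper
    design = ExperimentDesign.default(config.wells, list(protocols),
                                      config.validation_only)

    params, effects = generate_well_params(
        base, model, config.wells, list(protocols),
        (hyper.a_well_sd, hyper.b_well_sd),
        (hyper.a_protocol_sd, hyper.b_protocol_sd),
        seed=seed, g_log_sd=hyper.g_log_sd,
    )

    rng = np.random.default_rng([seed, 1])
    truths: dict[str, WellGroundTruth] = {}
    for well in config.wells:
        mode = config.failures.get(well)
        noise_sd = hyper.noise_sd * (10.0 if mode == "noisy" else 1.0)
        v_off = rng.normal(0.0, hyper.V_off_sd)
        if mode == "bad_reversal":
            v_off += 25.0
        gt = WellGroundTruth(
            well=well,
            params={p: params[(well, p)] for p in protocols},
            leak=LeakModel(rng.uniform(*hyper.g_L_range), rng.uniform(*hyper.E_L_range)),
            V_off=v_off,
            noise_sd=noise_sd,
            E_Kr=config.E_Kr,
            leak_drift=0.6 if mode == "drift_leak" else 0.0,
            failure_modes=(mode,) if mode else (),
        )
        truths[well] = gt

    traces: dict[tuple, SweepTrace] = {}
    cache: dict = {}
    for wi, well in enumerate(config.wells):
        for ei, entry in enumerate(design.entries):
            tr = generate_sweep(
                truths[well], model, protocols[entry.protocol],
                entry.drug_state, seed=[seed, 2, wi, ei],
                sweep=entry.sweep, position=ei, ikr_cache=cache,
            )
            traces[tr.key] = tr
    return SyntheticDataset(
        model_name=model.name, design=design, protocols=protocols,
        traces=traces, ground_truth=truths, E_Kr=config.E_Kr, effects=effects,
    )
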