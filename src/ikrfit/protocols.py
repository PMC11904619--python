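"""Voltage-clamp protocols: step/ramp segment tables with a shared scaffold.

Every protocol in the battery carries the same postprocessing scaffold:
a leak section at the start (hold at -80 mV, step to -120 mV, slow ramp
back up to -80 mV, then a +40 mV leak-validation step) and a reversal
section at the end (+40 mV preconditioning step followed by a fast ramp
from -70 mV down to -110 mV, then a return to holding).  The leak ramp
sits in the voltage range where I_Kr is negligible, so the linear leak
model can be fitted there; the reversal ramp sweeps the current through
zero so the observed reversal potential can be read off.

The numeric waveforms of the study's optimised designs d2..d12 are
deposited with the raw data rather than printed, so this module ships a
deterministic staircase-like stand-in for d1 plus seeded random designs
for the rest of the battery, and CSV I/O for user-supplied waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentKind",
    "SectionTag",
    "ProtocolSegment",
    "VoltageProtocol",
    "DesignEntry",
    "ExperimentDesign",
    "HOLDING_POTENTIAL",
    "make_scaffold",
    "staircase_like",
    "generate_random_protocol",
    "default_battery",
    "default_design",
]

HOLDING_POTENTIAL = -80.0  # mV
_V_MIN, _V_MAX = -140.0, 80.0


class SegmentKind(str, Enum):
    STEP = "step"
    RAMP = "ramp"


class SectionTag(str, Enum):
    HOLD = "hold"
    LEAK_RAMP = "leak_ramp"
    LEAK_VALIDATION = "leak_validation"
    MAIN = "main"
    REVERSAL_PRECONDITION = "reversal_precondition"
    REVERSAL_RAMP = "reversal_ramp"


@dataclass(frozen=True)
class ProtocolSegment:
    kind: SegmentKind
    duration: float  # ms
    v_start: float  # mV
    v_end: float  # mV (== v_start for steps)
    section_tag: SectionTag = SectionTag.MAIN

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        for v in (self.v_start, self.v_end):
            if not _V_MIN <= v <= _V_MAX:
                raise ValueError(f"voltage {v} mV outside [{_V_MIN}, {_V_MAX}]")
        if self.kind is SegmentKind.STEP and self.v_start != self.v_end:
            raise ValueError("step segments must have v_end == v_start")


def step(v: float, duration: float, tag: SectionTag = SectionTag.MAIN) -> ProtocolSegment:
    return ProtocolSegment(SegmentKind.STEP, duration, v, v, tag)


def ramp(v0: float, v1: float, duration: float,
         tag: SectionTag = SectionTag.MAIN) -> ProtocolSegment:
    return ProtocolSegment(SegmentKind.RAMP, duration, v0, v1, tag)


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered list of step/ramp segments plus a uniform sample grid."""

    name: str
    segments: tuple[ProtocolSegment, ...]
    sample_interval: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        first = segs[0]
        if not (first.kind is SegmentKind.STEP and first.v_start == HOLDING_POTENTIAL):
            raise ValueError("protocol must begin at the holding potential (-80 mV)")
        tags = [s.section_tag for s in segs]
        if tags.count(SectionTag.REVERSAL_RAMP) != 1:
            raise ValueError("protocol must contain exactly one reversal_ramp segment")
        leak_idx = [i for i, t in enumerate(tags) if t is SectionTag.LEAK_RAMP]
        if not leak_idx or leak_idx[-1] - leak_idx[0] != len(leak_idx) - 1:
            raise ValueError("protocol must contain one contiguous leak_ramp section")
        if leak_idx[0] > 2:
            raise ValueError("leak_ramp section must sit at the start of the protocol")
        rev = segs[tags.index(SectionTag.REVERSAL_RAMP)]
        if not (rev.kind is SegmentKind.RAMP and rev.v_start == -70.0 and rev.v_end == -110.0):
            raise ValueError("reversal ramp must descend from -70 mV to -110 mV")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative segment end-times, prefixed with 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def times(self) -> np.ndarray:
        """The uniform sample grid [0, T) at ``sample_interval``."""
        n = int(np.floor(self.total_duration / self.sample_interval + 1e-9))
        return np.arange(n) * self.sample_interval

    def segment_index(self, t) -> np.ndarray:
        """Segment owning each time; a boundary belongs to the later segment."""
        bounds = self.boundaries
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > bounds[-1] + 1e-9):
            raise ValueError("time outside protocol")
        idx = np.searchsorted(bounds, t, side="right") - 1
        return np.clip(idx, 0, len(self.segments) - 1)

    def voltage_at(self, t):
        """Command voltage at time(s) t: constant on steps, linear on ramps."""
        t = np.asarray(t, dtype=float)
        idx = self.segment_index(t)
        bounds = self.boundaries
        out = np.empty(t.shape if t.shape else (1,), dtype=float)
        tf, idxf = np.atleast_1d(t), np.atleast_1d(idx)
        for k in np.unique(idxf):
            seg = self.segments[k]
            m = idxf == k
            frac = (tf[m] - bounds[k]) / seg.duration
            out[m] = seg.v_start + np.clip(frac, 0.0, 1.0) * (seg.v_end - seg.v_start)
        return float(out[0]) if t.ndim == 0 else out

    def section_mask(self, tag: SectionTag, *, ramps_only: bool = False) -> np.ndarray:
        """Boolean mask over the sample grid selecting a tagged section."""
        t = self.times()
        idx = self.segment_index(t)
        keep = np.zeros(len(t), dtype=bool)
        for k, seg in enumerate(self.segments):
            if seg.section_tag is tag and (not ramps_only or seg.kind is SegmentKind.RAMP):
                keep |= idx == k
        return keep

    # -- CSV round trip ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "section_tag": [s.section_tag.value for s in self.segments],
                "kind": [s.kind.value for s in self.segments],
                "duration_ms": [s.duration for s in self.segments],
                "v_start_mV": [s.v_start for s in self.segments],
                "v_end_mV": [s.v_end for s in self.segments],
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str,
                   sample_interval: float = 1.0) -> "VoltageProtocol":
        segs = tuple(
            ProtocolSegment(
                SegmentKind(row.kind),
                float(row.duration_ms),
                float(row.v_start_mV),
                float(row.v_end_mV),
                SectionTag(row.section_tag),
            )
            for row in df.itertuples()
        )
        return cls(name=name, segments=segs, sample_interval=sample_interval)

    @classmethod
    def from_csv(cls, path_or_buf, name: str,
                 sample_interval: float = 1.0) -> "VoltageProtocol":
        return cls.from_frame(pd.read_csv(path_or_buf), name, sample_interval)


# -- scaffold ----------------------------------------------------------

#: Default scaffold durations (ms).  Voltages come from the protocol
#: design; these durations are package defaults (config-overridable).
SCAFFOLD_DEFAULTS = {
    "hold_start": 250.0,
    "leak_step": 50.0,
    "leak_ramp": 400.0,
    "leak_validation": 200.0,
    "reversal_precondition": 500.0,
    "reversal_ramp": 100.0,
    "hold_end": 500.0,
}


def make_scaffold(durations: dict | None = None):
    """The common leading and trailing segment blocks.

    Leading: hold(-80) -> step(-120) -> ramp(-120 -> -80) -> step(+40).
    Trailing: step(+40) -> ramp(-70 -> -110) -> hold(-80).
    """
    d = dict(SCAFFOLD_DEFAULTS)
    if durations:
        d.update(durations)
    leading = (
        step(HOLDING_POTENTIAL, d["hold_start"], SectionTag.HOLD),
        step(-120.0, d["leak_step"], SectionTag.LEAK_RAMP),
        ramp(-120.0, -80.0, d["leak_ramp"], SectionTag.LEAK_RAMP),
        step(40.0, d["leak_validation"], SectionTag.LEAK_VALIDATION),
    )
    trailing = (
        step(40.0, d["reversal_precondition"], SectionTag.REVERSAL_PRECONDITION),
        ramp(-70.0, -110.0, d["reversal_ramp"], SectionTag.REVERSAL_RAMP),
        step(HOLDING_POTENTIAL, d["hold_end"], SectionTag.HOLD),
    )
    return leading, trailing


def _with_scaffold(name: str, main: Iterable[ProtocolSegment],
                   sample_interval: float, durations: dict | None = None) -> VoltageProtocol:
    leading, trailing = make_scaffold(durations)
    return VoltageProtocol(
        name=name,
        segments=leading + tuple(main) + trailing,
        sample_interval=sample_interval,
    )


def staircase_like(sample_interval: float = 1.0, step_duration: float = 500.0,
                   name: str = "d1") -> VoltageProtocol:
    """Deterministic staircase stand-in for the d1 fitting protocol.

    Ascends from -120 mV to +40 mV in 20 mV steps and descends back,
    spanning the full voltage range between the standard scaffolds.  The
    sequence of depolarising and repolarising steps exercises
    activation, inactivation and recovery, which is what renders the
    kinetic parameters identifiable from a single sweep.
    """
    up = np.arange(-120.0, 41.0, 20.0)
    down = up[::-1][1:]
    main = [step(v, step_duration) for v in np.concatenate([up, down])]
    return _with_scaffold(name, main, sample_interval)


def generate_random_protocol(seed: int, n_main_steps: int = 20,
                             v_bounds: tuple[float, float] = (-120.0, 60.0),
                             dur_bounds: tuple[float, float] = (50.0, 500.0),
                             sample_interval: float = 1.0,
                             name: str | None = None) -> VoltageProtocol:
    """Seeded random step design standing in for the optimised batteries.

    Step voltages are uniform on ``v_bounds`` and durations uniform on
    ``dur_bounds`` (rounded to whole sample intervals so segment
    boundaries stay on the grid).  Identical seeds give identical
    protocols.
    """
    lo, hi = v_bounds
    if lo < -120.0 or hi > 60.0:
        raise ValueError("main-section voltages must lie within [-120, 60] mV")
    rng = np.random.default_rng(seed)
    volts = rng.uniform(lo, hi, size=n_main_steps)
    durs = rng.uniform(*dur_bounds, size=n_main_steps)
    durs = np.maximum(np.round(durs / sample_interval), 1.0) * sample_interval
    main = [step(round(v, 2), d) for v, d in zip(volts, durs)]
    return _with_scaffold(name or f"rand{seed}", main, sample_interval)


def default_battery(sample_interval: float = 1.0, n_protocols: int = 12,
                    seed: int = 20_000, step_duration: float = 500.0
                    ) -> dict[str, VoltageProtocol]:
    """The d1..d12 battery: the staircase plus seeded random designs."""
    battery = {"d1": staircase_like(sample_interval, step_duration=step_duration)}
    for i in range(2, n_protocols + 1):
        battery[f"d{i}"] = generate_random_protocol(
            seed + i, sample_interval=sample_interval, name=f"d{i}"
        )
    return battery


# -- experiment design -------------------------------------------------

@dataclass(frozen=True)
class DesignEntry:
    protocol: str
    sweep: int
    drug_state: str  # "pre" | "post"


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered sweep schedule applied to every well.

    Per drug state: two staircase (d1) sweeps, one sweep of every other
    protocol, then two more d1 sweeps; the post-drug block repeats the
    pre-drug order.  Protocols in ``validation_only`` (d6 by default)
    are recorded but never fitted.
    """

    entries: tuple[DesignEntry, ...]
    wells: tuple[str, ...]
    validation_only: tuple[str, ...] = ("d6",)

    @classmethod
    def default(cls, wells: Sequence[str],
                protocol_names: Sequence[str] | None = None,
                validation_only: Sequence[str] = ("d6",)) -> "ExperimentDesign":
        names = list(protocol_names or [f"d{i}" for i in range(1, 13)])
        if "d1" not in names:
            raise ValueError("the design requires the d1 staircase protocol")
        others = [n for n in names if n != "d1"]
        block = (
            [("d1", 1), ("d1", 2)]
            + [(n, 1) for n in others]
            + [("d1", 3), ("d1", 4)]
        )
        entries = [DesignEntry(p, s, "pre") for p, s in block]
        entries += [DesignEntry(p, s, "post") for p, s in block]
        return cls(tuple(entries), tuple(wells), tuple(validation_only))

    def sweeps(self, drug_state: str | None = None) -> list[DesignEntry]:
        return [e for e in self.entries if drug_state is None or e.drug_state == drug_state]

    def fitting_sweeps(self) -> list[DesignEntry]:
        """Pre-drug sweeps used for fitting (validation-only excluded)."""
        return [
            e for e in self.sweeps("pre") if e.protocol not in self.validation_only
        ]

    def validation_sweeps(self) -> list[DesignEntry]:
        """All pre-drug sweeps, including validation-only protocols."""
        return self.sweeps("pre")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (w, e.protocol, e.sweep, e.drug_state)
            for w in self.wells
            for e in self.entries
        ]
        return pd.DataFrame(rows, columns=["well", "protocol", "sweep", "drug_state"])


def default_design(wells: Sequence[str],
                   protocol_names: Sequence[str] | None = None) -> ExperimentDesign:
    return ExperimentDesign.default(wells, protocol_names)
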