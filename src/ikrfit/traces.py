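"""Shared containers for recorded/synthetic current sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["LeakModel", "SweepTrace"]


@dataclass(frozen=True)
class LeakModel:
    """Linear seal-leak current I_L = g_L (V_cmd - E_L)."""

    g_L: float  # nS
    E_L: float  # mV
    degenerate: bool = False  # set when g_L could not be resolved

    def __post_init__(self) -> None:
        if self.g_L < 0 and not self.degenerate:
            # small negative slopes do occur on noisy ramps; flag rather
            # than reject only when clearly unphysical
            if self.g_L < -1e3:
                raise ValueError("leak conductance implausibly negative")

    def current(self, v_cmd) -> np.ndarray:
        return self.g_L * (np.asarray(v_cmd, dtype=float) - self.E_L)


@dataclass
class SweepTrace:
    """One sampled current trace with its provenance and annotations.

    ``times`` lie on the protocol's uniform sample grid.  Annotations
    are filled during postprocessing: the fitted leak model, the
    observed reversal potential E_obs, the inferred voltage offset
    V_off = E_Nernst - E_obs, the noise estimate sigma_hat, and any QC
    flags raised along the way.
    """

    well: str
    protocol: str
    sweep: int
    drug_state: str  # "pre" | "post"
    times: np.ndarray  # ms
    current: np.ndarray  # pA
    leak: LeakModel | None = None
    E_obs: float | None = None
    V_off: float | None = None
    sigma_hat: float | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.times.shape != self.current.shape:
            raise ValueError("times and current must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sample times must be uniform")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.well, self.protocol, self.sweep, self.drug_state)

    def with_current(self, current: np.ndarray, **annotations) -> "SweepTrace":
        out = replace(self, current=np.asarray(current, dtype=float))
        out.qc_flags = list(self.qc_flags)
        for k, v in annotations.items():
            setattr(out, k, v)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "current_pA": self.current})

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, well: str, protocol: str, sweep: int,
                 drug_state: str) -> "SweepTrace":
        df = pd.read_csv(path_or_buf)
        return cls(well, protocol, sweep, drug_state,
                   df["time_ms"].to_numpy(), df["current_pA"].to_numpy())
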