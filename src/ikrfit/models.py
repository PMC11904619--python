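"""Markov model structures for the rapid delayed rectifier current I_Kr.

Four candidate gating models are provided, all of the same mathematical
form: a continuous-time Markov chain over channel conformations with
voltage-dependent transition rates, observed through the single open
state.  The governing equation is

    dx/dt = Q(V)^T x,

where ``x`` holds the occupancy of each conformational state and
``Q[i, j]`` is the instantaneous i -> j transition rate (so rows of Q sum
to zero).  The macroscopic current is

    I_Kr(t) = g * x_O(t) * (V_m(t) - E_Kr),

with maximal conductance ``g`` (nS), open-state occupancy ``x_O`` and
reversal potential ``E_Kr`` (mV).  Units throughout the package: time in
ms, voltage in mV, rates in 1/ms, conductance in nS, current in pA
(1 nS * 1 mV = 1 pA).

Transition rates are parameterised as ``A * exp(+b V)`` (activation-like),
``A * exp(-b V)`` (deactivation-like) or as voltage-independent constants
(the Wang model's kf/kb pair).  Every model carries its maximal
conductance as a final, additional parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "RateKind",
    "RateForm",
    "Transition",
    "MarkovModelSpec",
    "NernstParams",
    "MODEL_NAMES",
    "build_model",
    "default_parameters",
    "transition_rate",
    "rate_matrix",
    "nernst_potential",
    "steady_state",
]

#: Gas constant, J / (mol K)
GAS_CONSTANT = 8.314462618
#: Faraday constant, C / mol
FARADAY = 96485.33212


class RateKind(str, Enum):
    """Functional form of a transition rate."""

    POS_EXP = "pos_exp"  # A * exp(+b V)
    NEG_EXP = "neg_exp"  # A * exp(-b V)
    CONSTANT = "constant"  # A


@dataclass(frozen=True)
class RateForm:
    """One parameterised transition rate.

    ``A_index`` and ``b_index`` are slots into the model's parameter
    vector; ``b_index`` is ``None`` for constant rates.  Units: A in
    1/ms, b in 1/mV.
    """

    kind: RateKind
    A_index: int
    b_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind is RateKind.CONSTANT:
            if self.b_index is not None:
                raise ValueError("constant rates take no exponent slot")
        elif self.b_index is None:
            raise ValueError(f"{self.kind.value} rates need an exponent slot")


@dataclass(frozen=True)
class Transition:
    from_state: int
    to_state: int
    rate: RateForm


@dataclass(frozen=True)
class MarkovModelSpec:
    """A complete model structure.

    The kinetic parameters occupy slots ``0 .. n_kinetic_params - 1`` of
    the parameter vector; the maximal conductance g occupies the final
    slot (``conductance_index == n_kinetic_params``).
    """

    name: str
    state_names: tuple[str, ...]
    open_index: int
    transitions: tuple[Transition, ...]
    n_kinetic_params: int

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def conductance_index(self) -> int:
        return self.n_kinetic_params

    @property
    def total_params(self) -> int:
        """Kinetic parameters plus the maximal conductance."""
        return self.n_kinetic_params + 1

    def __post_init__(self) -> None:
        n = self.n_states
        if not 0 <= self.open_index < n:
            raise ValueError("open_index out of range")
        seen = set()
        for tr in self.transitions:
            if not (0 <= tr.from_state < n and 0 <= tr.to_state < n):
                raise ValueError("transition state index out of range")
            if tr.from_state == tr.to_state:
                raise ValueError("self-transitions are not allowed")
            key = (tr.from_state, tr.to_state)
            if key in seen:
                raise ValueError(f"duplicate transition {key}")
            seen.add(key)
        # connectivity guarantees a unique global equilibrium
        adj = {i: set() for i in range(n)}
        for tr in self.transitions:
            adj[tr.from_state].add(tr.to_state)
            adj[tr.to_state].add(tr.from_state)
        stack, reached = [0], {0}
        while stack:
            for j in adj[stack.pop()]:
                if j not in reached:
                    reached.add(j)
                    stack.append(j)
        if len(reached) != n:
            raise ValueError(f"transition graph of {self.name!r} is disconnected")

    def export_structure(self) -> dict:
        """Structure table (states, transitions, rate forms) for reuse."""
        return {
            "name": self.name,
            "states": list(self.state_names),
            "open_state": self.state_names[self.open_index],
            "n_kinetic_params": self.n_kinetic_params,
            "total_params": self.total_params,
            "transitions": [
                {
                    "from": self.state_names[tr.from_state],
                    "to": self.state_names[tr.to_state],
                    "kind": tr.rate.kind.value,
                    "A_index": tr.rate.A_index,
                    "b_index": tr.rate.b_index,
                }
                for tr in self.transitions
            ],
        }


@dataclass(frozen=True)
class NernstParams:
    """Ionic conditions determining the potassium Nernst potential."""

    K_out: float  # extracellular [K+], mM
    K_in: float  # intracellular [K+], mM
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.K_out <= 0 or self.K_in <= 0:
            raise ValueError("potassium concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _pos(A: int, b: int) -> RateForm:
    return RateForm(RateKind.POS_EXP, A, b)


def _neg(A: int, b: int) -> RateForm:
    return RateForm(RateKind.NEG_EXP, A, b)


def _const(A: int) -> RateForm:
    return RateForm(RateKind.CONSTANT, A)


def _coi() -> MarkovModelSpec:
    # C <-> O <-> I; four independent rates, eight kinetic parameters.
    C, O, I = 0, 1, 2
    return MarkovModelSpec(
        name="COI",
        state_names=("C", "O", "I"),
        open_index=O,
        transitions=(
            Transition(C, O, _pos(0, 1)),
            Transition(O, C, _neg(2, 3)),
            Transition(O, I, _pos(4, 5)),
            Transition(I, O, _neg(6, 7)),
        ),
        n_kinetic_params=8,
    )


def _beattie() -> MarkovModelSpec:
    # Square scheme C-O-I-IC with Hodgkin-Huxley-style shared rate
    # pairs: activation (k1/k2) and inactivation (k3/k4) act
    # independently, so parallel edges reuse the same parameters.
    C, O, I, IC = 0, 1, 2, 3
    k1, k2, k3, k4 = _pos(0, 1), _neg(2, 3), _pos(4, 5), _neg(6, 7)
    return MarkovModelSpec(
        name="Beattie",
        state_names=("C", "O", "I", "IC"),
        open_index=O,
        transitions=(
            Transition(C, O, k1),
            Transition(O, C, k2),
            Transition(O, I, k3),
            Transition(I, O, k4),
            Transition(IC, I, k1),
            Transition(I, IC, k2),
            Transition(C, IC, k3),
            Transition(IC, C, k4),
        ),
        n_kinetic_params=8,
    )


def _kemp() -> MarkovModelSpec:
    # Five-state scheme: an extra slow closed state C2 feeding the
    # Beattie-style square (C1-O-I-IC), which provides an
    # inactivated <-> closed path that avoids the open state.  The
    # published diagram for this structure is not reproduced here; this
    # transcription is the package's stand-in with the same state count
    # and an independent slow activation rate pair.
    C2, C1, O, I, IC = 0, 1, 2, 3, 4
    k1, k2, k3, k4 = _pos(0, 1), _neg(2, 3), _pos(4, 5), _neg(6, 7)
    k5, k6 = _pos(8, 9), _neg(10, 11)
    return MarkovModelSpec(
        name="Kemp",
        state_names=("C2", "C1", "O", "I", "IC"),
        open_index=O,
        transitions=(
            Transition(C2, C1, k5),
            Transition(C1, C2, k6),
            Transition(C1, O, k1),
            Transition(O, C1, k2),
            Transition(O, I, k3),
            Transition(I, O, k4),
            Transition(IC, I, k1),
            Transition(I, IC, k2),
            Transition(C1, IC, k3),
            Transition(IC, C1, k4),
        ),
        n_kinetic_params=12,
    )


def _wang() -> MarkovModelSpec:
    # Linear chain C1-C2-C3-O-I with a voltage-independent kf/kb pair
    # on the C1<->C2 step; no inactivated-closed shortcut.
    C1, C2, C3, O, I = 0, 1, 2, 3, 4
    return MarkovModelSpec(
        name="Wang",
        state_names=("C1", "C2", "C3", "O", "I"),
        open_index=O,
        transitions=(
            Transition(C2, C3, _pos(0, 1)),
            Transition(C3, C2, _neg(2, 3)),
            Transition(C3, O, _pos(4, 5)),
            Transition(O, C3, _neg(6, 7)),
            Transition(O, I, _pos(8, 9)),
            Transition(I, O, _neg(10, 11)),
            Transition(C1, C2, _const(12)),  # kf
            Transition(C2, C1, _const(13)),  # kb
        ),
        n_kinetic_params=14,
    )


_BUILDERS = {"COI": _coi, "Beattie": _beattie, "Kemp": _kemp, "Wang": _wang}
MODEL_NAMES = tuple(_BUILDERS)

_ALIASES = {
    "coi": "COI",
    "c-o-i": "COI",
    "beattie": "Beattie",
    "kemp": "Kemp",
    "wang": "Wang",
}


def build_model(name: str) -> MarkovModelSpec:
    """Return one of the four supported model structures by name."""
    key = _ALIASES.get(str(name).lower())
    if key is None:
        raise ValueError(
            f"unknown model {name!r}; supported models: {', '.join(MODEL_NAMES)}"
        )
    return _BUILDERS[key]()


# Default parameter values.  The source study prints no literature values
# for any structure; these are implementer-chosen physiological defaults.
# The activation/inactivation pairs follow widely reprinted room-
# temperature hERG kinetics; conductances sit in the range typical of a
# good automated patch-clamp well.
_DEFAULT_PARAMS: dict[str, tuple[float, ...]] = {
    "COI": (
        2.26e-4, 0.0699, 3.45e-5, 0.05462,  # C<->O
        0.0873, 8.91e-3, 5.15e-3, 0.03158,  # O<->I
        100.0,
    ),
    "Beattie": (
        2.26e-4, 0.0699, 3.45e-5, 0.05462,
        0.0873, 8.91e-3, 5.15e-3, 0.03158,
        100.0,
    ),
    "Kemp": (
        2.26e-4, 0.0699, 3.45e-5, 0.05462,
        0.0873, 8.91e-3, 5.15e-3, 0.03158,
        2.0e-3, 0.02, 1.0e-3, 0.03,  # slow C2<->C1 pair
        100.0,
    ),
    "Wang": (
        0.022348, 0.01176, 0.047002, 0.0631,  # C2<->C3
        0.013733, 0.038198, 6.89e-5, 0.04178,  # C3<->O
        0.090821, 0.023391, 0.006497, 0.03268,  # O<->I
        0.023761, 0.036778,  # kf, kb
        100.0,
    ),
}


def default_parameters(model: MarkovModelSpec | str) -> np.ndarray:
    """Implementer-chosen default parameter vector (kinetics then g)."""
    name = model if isinstance(model, str) else model.name
    spec = build_model(name)
    vals = np.asarray(_DEFAULT_PARAMS[spec.name], dtype=float)
    assert vals.size == spec.total_params
    return vals.copy()


def _validate_params(model: MarkovModelSpec, params: Sequence[float]) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if p.shape != (model.total_params,):
        raise ValueError(
            f"{model.name} expects {model.total_params} parameters, got {p.shape}"
        )
    if not np.all(p > 0):
        raise ValueError("all parameters must be strictly positive")
    return p


def transition_rate(form: RateForm, params: Sequence[float], V: float):
    """Evaluate one rate (1/ms) at membrane voltage V (mV)."""
    params = np.asarray(params, dtype=float)
    A = params[form.A_index]
    if A <= 0:
        raise ValueError("rate pre-factor A must be positive")
    if form.kind is RateKind.CONSTANT:
        return A * np.ones_like(np.asarray(V, dtype=float))
    b = params[form.b_index]
    sign = 1.0 if form.kind is RateKind.POS_EXP else -1.0
    return A * np.exp(sign * b * np.asarray(V, dtype=float))


def rate_matrix(model: MarkovModelSpec, params: Sequence[float], V: float) -> np.ndarray:
    """Transition-rate matrix Q(V); Q[i, j] is the i -> j rate, rows sum to 0."""
    p = _validate_params(model, params)
    n = model.n_states
    Q = np.zeros((n, n))
    for tr in model.transitions:
        Q[tr.from_state, tr.to_state] = transition_rate(tr.rate, p, V)
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return Q


def nernst_potential(p: NernstParams) -> float:
    """Potassium Nernst potential (RT/F) ln([K]out/[K]in), in mV."""
    return 1000.0 * GAS_CONSTANT * p.temperature / FARADAY * math.log(p.K_out / p.K_in)


def steady_state(model: MarkovModelSpec, params: Sequence[float], V: float) -> np.ndarray:
    """Equilibrium occupancy at fixed voltage: Q^T x = 0, sum(x) = 1.

    Solved as an overdetermined linear system (null-space solve), not by
    integration.
    """
    Q = rate_matrix(model, params, V)
    n = model.n_states
    A = np.vstack([Q.T, np.ones((1, n))])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if not np.all(np.isfinite(x)):
        raise np.linalg.LinAlgError("steady-state solve failed")
    resid = np.linalg.norm(Q.T @ x, np.inf)
    if resid > 1e-8 or abs(x.sum() - 1.0) > 1e-8:
        raise np.linalg.LinAlgError(
            f"steady state ill-determined for {model.name} at V={V} (residual {resid:.2e})"
        )
    x = np.clip(x, 0.0, None)
    return x / x.sum()
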