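"""Deterministic core of the coupled GTPase circuit.

Seven ordinary differential equations describe the fractional activations
of mGEF, mGAP, active mGTPase (mG*, Arf1), tGEF (GIV) and active tGTPase
(tG*, Gi), plus the secreted growth-factor pool S and the cell number X.
Species interactions are normalized Hill functions ``fact(x)`` rescaled so
that fact(0) = 0, fact(EC50) = 0.5 and fact(x) = 1 for x >= 1.

Three model variants are supported:

* ``coupled`` -- the full closed-loop circuit, in which tGEF and tG*
  feed back onto mGAP (AND or OR logic).
* ``uncoupled_single_switch`` -- the mGTPase switch alone; mGAP relaxes
  to its basal level with no feedback drive.
* ``giv_depleted`` -- the coupled circuit with the maximal fractional
  activation of tGEF forced to 0.1, emulating ~90% GIV knockdown.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import CircuitParameters, HillParams, STATE_NAMES

__all__ = [
    "DegenerateHillError", "NonConvergenceError", "IntegrationError",
    "NonFiniteStateError", "ModelVariant", "CircuitState", "TimeCourse",
    "hill_constants", "normalized_hill", "mgap_drive", "circuit_rhs",
    "pre_equilibrate", "simulate_deterministic", "STIMULUS_50NM",
]

#: dimensionless stimulus equivalent to 50 nM EGF
STIMULUS_50NM = 0.23


class DegenerateHillError(ValueError):
    """Hill parameters for which the normalisation constants do not exist."""


class NonConvergenceError(RuntimeError):
    """Pre-equilibration failed to reach a fixed point within the horizon."""


class IntegrationError(RuntimeError):
    """The ODE integrator reported failure."""


class NonFiniteStateError(ValueError):
    """A state vector contains NaN or infinity."""


# ---------------------------------------------------------------------------
# normalized Hill functions
# ---------------------------------------------------------------------------

def hill_constants(h: HillParams) -> tuple[float, float]:
    """Normalisation constants (B, K) of the normalized Hill function.

    B = (ec50**n - 1) / (2*ec50**n - 1) and K = (B - 1)**(1/n), chosen so
    that B*x**n/(K**n + x**n) passes through (0, 0), (ec50, 0.5), (1, 1).
    Raises :class:`DegenerateHillError` when ec50**n >= 0.5 (B undefined
    or K not real).
    """
    en = h.ec50 ** h.n
    denom = 2.0 * en - 1.0
    if abs(denom) < 1e-12:
        raise DegenerateHillError(
            f"ec50**n = 0.5 for ec50={h.ec50}, n={h.n}: B undefined")
    if en > 0.5:
        raise DegenerateHillError(
            f"ec50**n = {en} > 0.5 for ec50={h.ec50}, n={h.n}: "
            f"B < 1 so K is not real")
    B = (en - 1.0) / denom
    # K**n = B - 1 = en/(1 - 2*en), written to avoid cancellation for
    # very steep (switch-like) Hill functions where en underflows B - 1
    Kn = en / (1.0 - 2.0 * en)
    K = Kn ** (1.0 / h.n)
    return B, K


def normalized_hill(x, h: HillParams):
    """fact(x): the normalized Hill activation of input x.

    Returns B*x**n/(K**n + x**n) for 0 <= x < 1, exactly 1 for x >= 1 and
    0 for x < 0 (inputs can be pushed slightly negative by noise; clamping
    preserves continuity and the [0, 1] range).  Accepts scalars or arrays.
    """
    B, _ = hill_constants(h)
    en = h.ec50 ** h.n
    Kn = en / (1.0 - 2.0 * en)
    x = np.asarray(x, dtype=float)
    xc = np.clip(x, 0.0, 1.0)
    xn = xc ** h.n
    out = B * xn / (Kn + xn)
    out = np.where(x >= 1.0, 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# compiled parameter table (fast repeated evaluation)
# ---------------------------------------------------------------------------

class _HillTable:
    """Precomputed (B, K**n, n) for the nine interaction Hill functions."""

    def __init__(self, hills: Sequence[HillParams]):
        self.B = np.empty(len(hills))
        self.Kn = np.empty(len(hills))
        self.n = np.empty(len(hills))
        for i, h in enumerate(hills):
            B, _ = hill_constants(h)
            en = h.ec50 ** h.n
            self.B[i] = B
            self.Kn[i] = en / (1.0 - 2.0 * en)
            self.n[i] = h.n

    def fact(self, i: int, x):
        """fact_{i} (1-based index), vectorised."""
        j = i - 1
        x = np.asarray(x, dtype=float)
        xn = np.clip(x, 0.0, 1.0) ** self.n[j]
        return np.where(x >= 1.0, 1.0, self.B[j] * xn / (self.Kn[j] + xn))


@dataclass(frozen=True)
class ModelVariant:
    """Which circuit topology and mGAP feedback logic to simulate."""

    kind: str = "coupled"
    gate: str = "AND"

    KINDS = ("coupled", "uncoupled_single_switch", "giv_depleted")
    GATES = ("AND", "OR")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if self.gate.upper() not in self.GATES:
            raise ValueError(f"gate must be one of {self.GATES}")
        object.__setattr__(self, "gate", self.gate.upper())

    @classmethod
    def coupled(cls, gate: str = "AND") -> "ModelVariant":
        return cls("coupled", gate)

    @classmethod
    def uncoupled(cls, gate: str = "AND") -> "ModelVariant":
        return cls("uncoupled_single_switch", gate)

    @classmethod
    def giv_depleted(cls, gate: str = "AND") -> "ModelVariant":
        return cls("giv_depleted", gate)


#: maximal fractional activation of tGEF under GIV depletion (~10% of control)
Y_TGEF_DEPLETED = 0.1


def effective_Y_tGEF(p: CircuitParameters, v: ModelVariant) -> float:
    if v.kind == "giv_depleted":
        return Y_TGEF_DEPLETED
    return p.Y_tGEF_max


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitState:
    """Fractional activations of the five circuit species plus S and X."""

    mGEF: float
    mGAP: float
    mGstar: float
    tGEF: float
    tGstar: float
    S: float
    X: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mGEF, self.mGAP, self.mGstar,
                         self.tGEF, self.tGstar, self.S, self.X])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CircuitState":
        y = np.asarray(y, dtype=float)
        if y.shape != (7,):
            raise ValueError(f"expected shape (7,), got {y.shape}")
        if not np.all(np.isfinite(y)):
            raise NonFiniteStateError(f"non-finite state: {y}")
        return cls(*map(float, y))

    @classmethod
    def uniform(cls, value: float = 0.5) -> "CircuitState":
        return cls(*([value] * 7))


@dataclass(frozen=True)
class TimeCourse:
    """A simulated trajectory on a strictly increasing time grid (min)."""

    t: np.ndarray
    y: np.ndarray          # shape (len(t), 7), columns = STATE_NAMES
    stimulus: float

    def __post_init__(self):
        t = np.asarray(self.t, float)
        y = np.asarray(self.y, float)
        if len(t) != len(y) or len(t) < 2:
            raise ValueError("time grid and states must align, length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    def variable(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index(name)]

    def state_at(self, index: int) -> CircuitState:
        return CircuitState.from_array(self.y[index])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "t_min", self.t)
        df["stimulus"] = self.stimulus
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        df = pd.read_csv(path)
        return cls(df["t_min"].to_numpy(),
                   df[list(STATE_NAMES)].to_numpy(),
                   float(df["stimulus"].iloc[0]))


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def mgap_drive(tGEF, tGstar, p: CircuitParameters, gate: str = "AND",
               ht: _HillTable | None = None):
    """Feedback production drive of mGAP from tGEF and tG*.

    AND logic multiplies the two Hill terms, fact2(tGEF)*fact3(tG*); OR
    logic adds them with rescaling constants,
    c_tGEF*fact2(tGEF) + c_tGstar*fact3(tG*), the constants chosen so the
    two logics share steady states.
    """
    ht = ht or _HillTable(p.hill)
    f2 = ht.fact(2, tGEF)
    f3 = ht.fact(3, tGstar)
    if gate.upper() == "AND":
        return f2 * f3
    if gate.upper() == "OR":
        return p.or_gate_c_tGEF * f2 + p.or_gate_c_tGstar * f3
    raise ValueError(f"unknown gate {gate!r}")


def _rhs(y: np.ndarray, stimulus, p: CircuitParameters, v: ModelVariant,
         ht: _HillTable) -> np.ndarray:
    """Derivatives for state array y with columns (..., 7)."""
    mGEF, mGAP, mG, tGEF, tG, S, X = (y[..., i] for i in range(7))
    Y_tGEF = effective_Y_tGEF(p, v)

    d_mGEF = ((ht.fact(1, stimulus) + p.k_mGEF) * p.Y_mGEF_max - mGEF) \
        / p.tau_mGEF
    if v.kind == "uncoupled_single_switch":
        drive = 0.0
    else:
        drive = mgap_drive(tGEF, tG, p, v.gate, ht)
    d_mGAP = ((drive + p.k_mGAP) * p.Y_mGAP_max - mGAP) / p.tau_mGAP
    d_mG = ((ht.fact(4, mGEF) + p.k_mGstar) * (1.0 - mG)
            - ht.fact(5, mGAP) * mG) / p.tau_mGstar
    d_tGEF = ((ht.fact(6, mG) + p.k_tGEF) * Y_tGEF - tGEF) / p.tau_tGEF
    d_tG = ((ht.fact(7, tGEF) + p.k_tGstar) * (1.0 - tG)
            - ht.fact(8, p.tGAP) * tG) / p.tau_tGstar
    d_S = (p.beta_S * ht.fact(9, mGAP) + p.k_S
           - p.alpha_S * S / (S + p.K2)) * X - p.gamma * S
    d_X = p.lam * S / (S + p.K1) * (1.0 - X / p.K_capacity) - p.mu * X

    return np.stack(np.broadcast_arrays(
        d_mGEF, d_mGAP, d_mG, d_tGEF, d_tG, d_S, d_X), axis=-1)


def circuit_rhs(state: CircuitState | np.ndarray, stimulus: float,
                p: CircuitParameters,
                v: ModelVariant = ModelVariant()) -> np.ndarray:
    """Time derivatives of the seven state variables (units 1/min)."""
    y = state.as_array() if isinstance(state, CircuitState) else \
        np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise NonFiniteStateError(f"non-finite state: {y}")
    if stimulus < 0:
        raise ValueError("stimulus must be >= 0")
    return _rhs(y, stimulus, p, v, _HillTable(p.hill))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

#: integration horizon for pre-equilibration, min (covers 2,400 h)
EQUILIBRATION_HORIZON = 144_000.0


def pre_equilibrate(p: CircuitParameters, v: ModelVariant = ModelVariant(),
                    stimulus: float = 0.0,
                    init: CircuitState | None = None,
                    tol: float = 1e-8) -> CircuitState:
    """Relax the circuit to a steady state at the given (constant) stimulus.

    Integrates from an arbitrary start (all variables 0.5 by default) with
    a stiff adaptive solver, exiting early once the infinity norm of the
    derivatives falls below ``tol``, then polishes the fixed point with a
    Newton-type root solve.  The result is insensitive to the arbitrary
    start at the basal stimulus.
    """
    ht = _HillTable(p.hill)
    y = (init or CircuitState.uniform(0.5)).as_array()
    fun = lambda t, z: _rhs(z, stimulus, p, v, ht)

    def polish(y):
        """Newton polish; accept only a physical, locally stable root."""
        sol = root(lambda z: _rhs(z, stimulus, p, v, ht), y, method="hybr")
        z = sol.x
        if not (sol.success and np.max(np.abs(sol.fun)) < tol):
            return None
        if np.any(z[:5] < -1e-9) or np.any(z[:5] > 2.0) \
                or z[5] < -1e-9 or not -1e-9 <= z[6] <= 1.01 * p.K_capacity:
            return None
        eps = 1e-7
        jac = np.empty((7, 7))
        f0 = _rhs(z, stimulus, p, v, ht)
        for j in range(7):
            dz = z.copy()
            dz[j] += eps
            jac[:, j] = (_rhs(dz, stimulus, p, v, ht) - f0) / eps
        if np.max(np.linalg.eigvals(jac).real) > 1e-9:
            return None
        return z

    # short transient to enter the basin, then Newton; the fast GTPase
    # block settles within a few tens of minutes, only S and X are slow
    t_done, chunk = 0.0, 600.0
    while t_done < EQUILIBRATION_HORIZON:
        sol = solve_ivp(fun, (0.0, chunk), y, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise IntegrationError(sol.message)
        y = sol.y[:, -1]
        t_done += chunk
        z = polish(y)
        if z is not None:
            return CircuitState.from_array(z)
        if np.max(np.abs(_rhs(y, stimulus, p, v, ht))) < tol:
            return CircuitState.from_array(y)
        chunk = min(chunk * 4, EQUILIBRATION_HORIZON - t_done) or chunk

    residual = np.max(np.abs(_rhs(y, stimulus, p, v, ht)))
    raise NonConvergenceError(
        f"pre-equilibration residual {residual:.3e} exceeds tolerance "
        f"after {EQUILIBRATION_HORIZON} min")


def simulate_deterministic(p: CircuitParameters,
                           v: ModelVariant = ModelVariant(),
                           stimulus: float = STIMULUS_50NM,
                           t_span: tuple[float, float] = (0.0, 1440.0),
                           init: CircuitState | None = None,
                           t_eval: np.ndarray | None = None,
                           rtol: float = 1e-8,
                           atol: float = 1e-10) -> TimeCourse:
    """Integrate the circuit ODEs with a stiff-capable adaptive solver.

    The standard stimulation protocol starts from the basal steady state
    (``pre_equilibrate`` at stimulus 0) and switches the stimulus to 0.23,
    the dimensionless equivalent of 50 nM EGF.
    """
    if t_span[1] <= t_span[0]:
        raise ValueError("t_span must be increasing")
    y0 = (init or pre_equilibrate(p, v)).as_array()
    if not np.all(np.isfinite(y0)):
        raise NonFiniteStateError(f"non-finite initial state: {y0}")
    ht = _HillTable(p.hill)
    if t_eval is None:
        t_eval = np.linspace(t_span[0], t_span[1], 721)
    sol = solve_ivp(lambda t, z: _rhs(z, stimulus, p, v, ht),
                    t_span, y0, method="LSODA", t_eval=np.asarray(t_eval),
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"integration failed at stimulus={stimulus}: {sol.message}")
    return TimeCourse(sol.t, sol.y.T, float(stimulus))
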