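"""Stochastic extension: Ornstein-Uhlenbeck noise channels and ensembles.

Noise enters the circuit through mean-reverting OU processes
``tau_noise * d eta = -eta dt + sigma dW``, each with zero mean and
stationary variance ``sigma**2 / (2 * tau_noise)``.  Three configurations
are supported:

* ``stimulus_only`` -- one OU channel added to the EGF stimulus inside the
  receptor-level Hill function.
* ``stimulus_and_species`` -- additionally one independent channel per
  species equation (inside the tau-scaled bracket for the five GTPase
  variables; added directly to dS/dt and dX/dt) plus a perturbation of the
  constant tGAP level.
* ``stimulus_and_connections`` -- additionally one independent channel per
  interaction arrow (added to each Hill activation term) and per nonlinear
  rate of the secretion and cell-number equations.

The default noise update scheme is
``eta_{n+1} = eta_n - eta_n dt + sigma dW + 0.5 sigma^2 (dW^2 - dt)``
(for unit relaxation time); a plain Euler-Maruyama scheme is available via
``scheme="euler_maruyama"``.  For additive noise the extra term has zero
mean, so both schemes share stationary statistics.  The species/cell-number
dynamics are advanced with a fixed-step Euler scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circuit import (CircuitState, ModelVariant, NonFiniteStateError,
                      TimeCourse, _HillTable, effective_Y_tGEF,
                      pre_equilibrate)
from .params import CircuitParameters, STATE_NAMES

__all__ = ["NoiseConfig", "EnsembleSummary", "ou_update",
           "simulate_stochastic", "run_ensemble", "NOISE_MODES"]

logger = logging.getLogger(__name__)

NOISE_MODES = ("stimulus_only", "stimulus_and_species",
               "stimulus_and_connections")

#: fixed channel order: stimulus; per-species (5 GTPase vars, S, X, tGAP);
#: per-connection (fact1..fact8, secretion production, endocytosis, X growth)
SPECIES_CHANNELS = ("mGEF", "mGAP", "mGstar", "tGEF", "tGstar",
                    "S", "X", "tGAP")
LINK_CHANNELS = ("fact1", "fact2", "fact3", "fact4", "fact5", "fact6",
                 "fact7", "fact8", "S_production", "S_endocytosis", "X_growth")


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes, mode and integration settings of the stochastic engine.

    Default amplitudes: 0.02 for the stimulus, species and connection
    channels, except the slow secretion/cell-number equations where the
    species amplitudes are 2e-5 (S) and 2e-6 (X) and the connection
    amplitude of the cell-number equation is 0.002, keeping the noise of
    the same order as the small reaction rates.
    """

    mode: str = "stimulus_only"
    sigma_sti: float = 0.02
    tau_noise: float = 1.0
    sigma_spe: float = 0.02
    sigma_spe_S: float = 2e-5
    sigma_spe_X: float = 2e-6
    sigma_link: float = 0.02
    sigma_link_X: float = 0.002
    dt: float = 0.01
    t_end: float = 1440.0
    n_runs: int = 1000
    seed: int = 0
    scheme: str = "as_printed"
    evaluation_time: float = 1440.0

    def __post_init__(self):
        if self.mode not in NOISE_MODES:
            raise ValueError(f"mode must be one of {NOISE_MODES}")
        if self.scheme not in ("as_printed", "euler_maruyama"):
            raise ValueError("scheme must be 'as_printed' or 'euler_maruyama'")
        for name in ("sigma_sti", "sigma_spe", "sigma_spe_S", "sigma_spe_X",
                     "sigma_link", "sigma_link_X"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tau_noise <= 0 or self.dt <= 0 or self.t_end <= 0:
            raise ValueError("tau_noise, dt and t_end must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def replace(self, **kwargs) -> "NoiseConfig":
        return replace(self, **kwargs)

    # -- channel amplitude vectors -----------------------------------

    def species_sigmas(self) -> np.ndarray:
        s = np.full(len(SPECIES_CHANNELS), self.sigma_spe)
        s[SPECIES_CHANNELS.index("S")] = self.sigma_spe_S
        s[SPECIES_CHANNELS.index("X")] = self.sigma_spe_X
        if self.mode != "stimulus_and_species":
            s[:] = 0.0
        return s

    def link_sigmas(self) -> np.ndarray:
        s = np.full(len(LINK_CHANNELS), self.sigma_link)
        s[LINK_CHANNELS.index("X_growth")] = self.sigma_link_X
        if self.mode != "stimulus_and_connections":
            s[:] = 0.0
        return s

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-variable mean and SD over repeated stochastic runs."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_runs: int
    evaluation_time: float

    def __post_init__(self):
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("standard deviations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": list(self.mean),
            "mean": list(self.mean.values()),
            "sd": [self.sd[k] for k in self.mean],
        })


def ou_update(eta, cfg: NoiseConfig, sigma, dW, scheme: str | None = None):
    """Advance an OU noise value by one step of size ``cfg.dt``.

    ``dW`` is a Wiener increment, Normal(0, dt).  The default scheme is the
    one printed for the model (unit relaxation time shown; the relaxation
    time scales the drift and diffusion):

    ``eta' = eta - eta*dt + sigma*dW + 0.5*sigma**2*(dW**2 - dt)``

    With ``scheme="euler_maruyama"`` the last (zero-mean) term is dropped.
    Accepts scalars or arrays.
    """
    scheme = scheme or cfg.scheme
    tau = cfg.tau_noise
    dt = cfg.dt
    eta = np.asarray(eta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    out = eta - eta * dt / tau + sigma * dW / tau
    if scheme == "as_printed":
        out = out + 0.5 * (sigma / tau) ** 2 * (dW ** 2 - dt)
    elif scheme != "euler_maruyama":
        raise ValueError(f"unknown scheme {scheme!r}")
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# batched fixed-step engine
# ---------------------------------------------------------------------------

def _batch_euler(p: CircuitParameters, v: ModelVariant, stimulus,
                 cfg: NoiseConfig, y0: np.ndarray, batch: int,
                 rng: np.random.Generator,
                 record_times: np.ndarray) -> np.ndarray:
    """Euler-integrate ``batch`` noisy replicates simultaneously.

    ``stimulus`` may be a scalar or a (batch,) vector (one dose per
    replicate).  Returns an array (batch, len(record_times), 7).  Wiener
    increments are drawn per channel per step from the single generator in
    a fixed channel order (stimulus, species, connections), which makes
    trajectories bit-reproducible for a given seed and batch layout.
    """
    ht = _HillTable(p.hill)
    dt = cfg.dt
    sq = np.sqrt(dt)
    n_steps = int(round(cfg.t_end / dt))
    stim = np.broadcast_to(np.asarray(stimulus, float), (batch,)).copy()
    Y_tGEF = effective_Y_tGEF(p, v)
    uncoupled = v.kind == "uncoupled_single_switch"
    use_or = v.gate == "OR"

    sig_spe = cfg.species_sigmas()
    sig_link = cfg.link_sigmas()
    spe_on = np.any(sig_spe > 0)
    link_on = np.any(sig_link > 0)

    y = np.broadcast_to(y0, (batch, 7)).copy()
    eta_sti = np.zeros(batch)
    eta_spe = np.zeros((batch, len(SPECIES_CHANNELS)))
    eta_link = np.zeros((batch, len(LINK_CHANNELS)))

    record_idx = np.rint(np.asarray(record_times, float) / dt).astype(int)
    if np.any(record_idx > n_steps):
        raise ValueError("record time beyond t_end")
    out = np.empty((batch, len(record_idx), 7))
    rec_pos = {step: i for i, step in enumerate(record_idx)}
    if 0 in rec_pos:
        out[:, rec_pos[0], :] = y
    milstein = cfg.scheme == "as_printed"
    tau = cfg.tau_noise
    floored = False

    fact = ht.fact
    for step in range(1, n_steps + 1):
        # --- noise update (noise value at step n+1 drives the state update)
        if cfg.sigma_sti > 0:
            dW = rng.standard_normal(batch) * sq
            eta_sti += (-eta_sti * dt + cfg.sigma_sti * dW) / tau
            if milstein:
                eta_sti += 0.5 * (cfg.sigma_sti / tau) ** 2 * (dW ** 2 - dt)
        if spe_on:
            dW = rng.standard_normal((batch, len(SPECIES_CHANNELS))) * sq
            eta_spe += (-eta_spe * dt + sig_spe * dW) / tau
            if milstein:
                eta_spe += 0.5 * (sig_spe / tau) ** 2 * (dW ** 2 - dt)
        if link_on:
            dW = rng.standard_normal((batch, len(LINK_CHANNELS))) * sq
            eta_link += (-eta_link * dt + sig_link * dW) / tau
            if milstein:
                eta_link += 0.5 * (sig_link / tau) ** 2 * (dW ** 2 - dt)

        mGEF = y[:, 0]; mGAP = y[:, 1]; mG = y[:, 2]
        tGEF = y[:, 3]; tG = y[:, 4]; S = y[:, 5]; X = y[:, 6]
        s = eta_spe.T
        l = eta_link.T

        f1 = fact(1, stim + eta_sti) + l[0]
        if uncoupled:
            drive = 0.0
        else:
            f2 = fact(2, tGEF) + l[1]
            f3 = fact(3, tG) + l[2]
            if use_or:
                drive = p.or_gate_c_tGEF * f2 + p.or_gate_c_tGstar * f3
            else:
                drive = f2 * f3
        f8 = fact(8, p.tGAP + s[7]) + l[7]

        d0 = ((f1 + p.k_mGEF) * p.Y_mGEF_max - mGEF + s[0]) / p.tau_mGEF
        d1 = ((drive + p.k_mGAP) * p.Y_mGAP_max - mGAP + s[1]) / p.tau_mGAP
        d2 = ((fact(4, mGEF) + l[3] + p.k_mGstar) * (1.0 - mG)
              - (fact(5, mGAP) + l[4]) * mG + s[2]) / p.tau_mGstar
        d3 = ((fact(6, mG) + l[5] + p.k_tGEF) * Y_tGEF - tGEF
              + s[3]) / p.tau_tGEF
        d4 = ((fact(7, tGEF) + l[6] + p.k_tGstar) * (1.0 - tG)
              - f8 * tG + s[4]) / p.tau_tGstar
        d5 = (p.beta_S * fact(9, mGAP) + p.k_S + l[8]
              - (p.alpha_S * S / (S + p.K2) + l[9])) * X - p.gamma * S + s[5]
        d6 = (p.lam * S / (S + p.K1) * (1.0 - X / p.K_capacity)
              + l[10]) - p.mu * X + s[6]

        y[:, 0] = mGEF + dt * d0
        y[:, 1] = mGAP + dt * d1
        y[:, 2] = mG + dt * d2
        y[:, 3] = tGEF + dt * d3
        y[:, 4] = tG + dt * d4
        y[:, 5] = S + dt * d5
        y[:, 6] = X + dt * d6

        # S and X are amounts; floor at zero if a noisy step undershoots
        if y[:, 5:7].min() < 0.0:
            y[:, 5:7] = np.maximum(y[:, 5:7], 0.0)
            floored = True

        pos = rec_pos.get(step)
        if pos is not None:
            if not np.all(np.isfinite(y)):
                raise NonFiniteStateError(
                    f"non-finite state at t={step * dt} min "
                    f"(seed={cfg.seed})")
            out[:, pos, :] = y

    if floored:
        logger.warning("S/X floored at 0 during stochastic run "
                       "(seed=%s, mode=%s)", cfg.seed, cfg.mode)
    return out


def simulate_stochastic(p: CircuitParameters, v: ModelVariant,
                        stimulus: float, cfg: NoiseConfig,
                        init: CircuitState | None = None,
                        record_times: np.ndarray | None = None) -> TimeCourse:
    """One noisy trajectory on [0, t_end] min with fixed-step Euler.

    By default starts from the deterministic steady state under the given
    stimulus and records once a minute.
    """
    y0 = (init if init is not None
          else pre_equilibrate(p, v, stimulus)).as_array()
    if record_times is None:
        record_times = np.arange(0.0, cfg.t_end + 1e-9, 1.0)
    record_times = np.asarray(record_times, float)
    rng = np.random.default_rng(cfg.seed)
    out = _batch_euler(p, v, stimulus, cfg, y0, 1, rng, record_times)
    return TimeCourse(record_times, out[0], float(stimulus))


def run_ensemble(p: CircuitParameters, v: ModelVariant, stimulus: float,
                 cfg: NoiseConfig,
                 init: CircuitState | None = None) -> EnsembleSummary:
    """Mean and SD (N-1 denominator) of all variables at the evaluation time.

    Runs ``cfg.n_runs`` independent replicates, each started from the
    deterministic steady state under the given stimulus (or ``init``).
    """
    if cfg.n_runs < 2:
        raise ValueError("run_ensemble needs n_runs >= 2 for an SD")
    y0 = (init if init is not None
          else pre_equilibrate(p, v, stimulus)).as_array()
    rng = np.random.default_rng(cfg.seed)
    out = _batch_euler(p, v, stimulus, cfg, y0, cfg.n_runs, rng,
                       np.array([cfg.evaluation_time]))
    terminal = out[:, 0, :]
    mean = {name: float(m) for name, m in
            zip(STATE_NAMES, terminal.mean(axis=0))}
    sd = {name: float(s) for name, s in
          zip(STATE_NAMES, terminal.std(axis=0, ddof=1))}
    return EnsembleSummary(mean, sd, cfg.n_runs, cfg.evaluation_time)
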