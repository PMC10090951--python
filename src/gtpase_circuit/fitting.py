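"""Parameter constraining against fold-change time-course data.

The experimental readouts are densitometry/FRET fold changes of active
Arf1 (mG*) and active Gi (tG*) over the first 30 min after EGF
stimulation, in control and GIV-depleted cells.  Fitting minimises the
summed normalized RMSE (RMSE divided by the mean of the data) of the
simulated fold-change traces, jointly over both conditions, and accepts a
fit when the mG* error is below 0.2 and the tG* error below 0.45 -- the
same acceptance rule used when the model was originally tuned by hand.
The optimizer is a seeded derivative-free surrogate for that hand tuning
(Latin-hypercube starts refined by Nelder-Mead simplex); no claim of
parameter identifiability is made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize
from scipy.stats import qmc

from .circuit import (ModelVariant, TimeCourse, pre_equilibrate,
                      simulate_deterministic, STIMULUS_50NM)
from .params import CircuitParameters

__all__ = [
    "TimeCourseDataset", "FitReport", "ExponentialFit", "NoFeasiblePointError",
    "NRMSE_THRESHOLDS", "fold_change", "normalized_rmse", "r_squared",
    "fit_exponential", "fit_parameters", "simulate_fold_change",
    "DEFAULT_FREE_PARAMS",
]

#: printed acceptance thresholds on the normalized RMSE, per readout
NRMSE_THRESHOLDS = {"mGstar": 0.2, "tGstar": 0.45}

CONDITION_VARIANTS = {"control": ModelVariant.coupled(),
                      "giv_depleted": ModelVariant.giv_depleted()}


class NoFeasiblePointError(RuntimeError):
    """Fit budget exhausted without meeting the acceptance thresholds."""

    def __init__(self, message: str, report: "FitReport"):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class TimeCourseDataset:
    """Mean +/- SEM fold-change measurements at discrete time points."""

    timepoints: np.ndarray        # min, increasing, includes 0
    mean: np.ndarray              # fold change relative to t=0
    sem: np.ndarray
    condition: str                # control | giv_depleted
    readout: str                  # mGstar | tGstar

    def __post_init__(self):
        t = np.asarray(self.timepoints, float)
        m = np.asarray(self.mean, float)
        s = np.asarray(self.sem, float)
        if not (len(t) == len(m) == len(s)):
            raise ValueError("timepoints, mean and sem must align")
        if t[0] != 0 or not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be increasing and include 0")
        if self.condition not in CONDITION_VARIANTS:
            raise ValueError(f"condition must be one of "
                             f"{tuple(CONDITION_VARIANTS)}")
        if self.readout not in NRMSE_THRESHOLDS:
            raise ValueError("readout must be 'mGstar' or 'tGstar'")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sem", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_min": self.timepoints, "mean_fold_change": self.mean,
            "sem": self.sem, "condition": self.condition,
            "readout": self.readout,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["TimeCourseDataset"]:
        out = []
        for (cond, readout), grp in df.groupby(["condition", "readout"]):
            grp = grp.sort_values("t_min")
            out.append(cls(grp["t_min"].to_numpy(),
                           grp["mean_fold_change"].to_numpy(),
                           grp["sem"].to_numpy(), cond, readout))
        return out


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def fold_change(tc: TimeCourse, readout: str,
                baseline: float | None = None) -> np.ndarray:
    """Trace divided by its value at t = 0 (the pre-stimulus steady state)."""
    trace = tc.variable(readout)
    base = trace[0] if baseline is None else baseline
    if base <= 0:
        raise ValueError(f"zero/negative baseline for {readout}: {base}")
    return trace / base


def normalized_rmse(sim_values, data_mean) -> float:
    """RMSE between simulation and data over the mean of the data values."""
    sim = np.asarray(sim_values, float)
    data = np.asarray(data_mean, float)
    if sim.shape != data.shape or sim.size == 0:
        raise ValueError("sim and data must have equal, nonzero length")
    scale = float(np.mean(data))
    if scale == 0:
        raise ValueError("data mean is zero; normalized RMSE undefined")
    return float(np.sqrt(np.mean((sim - data) ** 2)) / scale)


def r_squared(obs, pred) -> float:
    """1 - SS_res/SS_tot; can be negative for fits worse than the mean."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in observations")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


@dataclass(frozen=True)
class ExponentialFit:
    """Saturating exponential y = A*(1 - exp(-k*t)) + c."""

    amplitude: float
    rate: float
    offset: float
    r2: float
    degenerate: bool = False      # flat data; rate unidentifiable

    def __call__(self, t):
        return self.amplitude * (1 - np.exp(-self.rate * np.asarray(t))) \
            + self.offset


def fit_exponential(t, y) -> ExponentialFit:
    """Least-squares saturating-exponential fit (FRET-style traces)."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(y) < 1e-12 * max(1.0, abs(y[0])):
        return ExponentialFit(0.0, 1.0, float(y.mean()), 1.0, degenerate=True)

    def f(t, A, k, c):
        return A * (1 - np.exp(-k * t)) + c

    span = t[-1] - t[0]
    best = None
    for k0 in (0.1 / span, 1.0 / span, 5.0 / span, 1.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(f, t, y,
                                    p0=[y[-1] - y[0], k0, y[0]],
                                    maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - f(t, *popt)) ** 2))
        if best is None or ss < best[1]:
            best = (popt, ss)
    if best is None:
        raise RuntimeError("exponential fit did not converge")
    A, k, c = best[0]
    return ExponentialFit(float(A), float(abs(k)), float(c),
                          r_squared(y, f(t, A, k, c)))


# ---------------------------------------------------------------------------
# joint parameter fitting
# ---------------------------------------------------------------------------

#: parameters released by default in the joint fit: the basal/maximal rates
#: and half-max constants that shape the Arf1 transient and the Gi rise
DEFAULT_FREE_PARAMS = ("k_mGstar", "k_mGAP", "tau_mGAP",
                       "hill4_ec50", "hill5_ec50", "hill7_ec50")


def simulate_fold_change(p: CircuitParameters, condition: str, readout: str,
                         timepoints: np.ndarray,
                         stimulus: float = STIMULUS_50NM) -> np.ndarray:
    """Fold-change trace of one readout at the data time points."""
    v = CONDITION_VARIANTS[condition]
    basal = pre_equilibrate(p, v)
    tc = simulate_deterministic(p, v, stimulus, (0.0, float(timepoints[-1])),
                                init=basal, t_eval=np.asarray(timepoints),
                                rtol=1e-7, atol=1e-9)
    return fold_change(tc, readout)


def _dataset_predictions(p: CircuitParameters,
                         datasets: list[TimeCourseDataset],
                         stimulus: float) -> dict[str, np.ndarray]:
    """Simulated fold changes for every dataset, one solve per condition."""
    out = {}
    for cond in {ds.condition for ds in datasets}:
        group = [ds for ds in datasets if ds.condition == cond]
        grid = np.unique(np.concatenate([ds.timepoints for ds in group]))
        v = CONDITION_VARIANTS[cond]
        basal = pre_equilibrate(p, v)
        tc = simulate_deterministic(p, v, stimulus, (0.0, float(grid[-1])),
                                    init=basal, t_eval=grid,
                                    rtol=1e-7, atol=1e-9)
        for ds in group:
            idx = np.searchsorted(grid, ds.timepoints)
            out[f"{cond}:{ds.readout}"] = fold_change(tc, ds.readout)[idx]
    return out


@dataclass(frozen=True)
class FitReport:
    """Outcome of the joint time-course fit."""

    params: CircuitParameters
    nrmse: dict[str, float]             # "(condition, readout)" -> value
    r2: dict[str, float]
    passed: dict[str, bool]             # readout -> all-datasets flag
    n_evaluations: int
    objective: float
    free_params: tuple[str, ...] = ()

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())

    def to_dict(self) -> dict:
        return {"fitted_params": self.params.to_dict(),
                "nrmse": self.nrmse, "r2": self.r2,
                "passed": self.passed, "objective": self.objective,
                "n_evaluations": self.n_evaluations,
                "free_params": list(self.free_params)}


def _bounds_for(name: str, init: float) -> tuple[float, float]:
    if "ec50" in name:
        return 0.02, 0.95
    if name.endswith("_n"):
        return 0.3, 6.0
    if name.startswith("Y_"):
        return 0.05, 1.0
    if init == 0:
        return 0.0, 0.5
    return init / 5.0, init * 5.0


def fit_parameters(datasets: list[TimeCourseDataset],
                   init: CircuitParameters,
                   free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
                   budget: int = 400,
                   seed: int = 0,
                   n_starts: int = 4,
                   stimulus: float = STIMULUS_50NM) -> FitReport:
    """Jointly fit the free parameters to all datasets.

    Minimises the equally weighted sum of normalized RMSEs across the
    datasets with a Latin-hypercube of starting points refined by
    Nelder-Mead, within ``budget`` total objective evaluations.  Raises
    :class:`NoFeasiblePointError` (carrying the best report) when the
    printed thresholds are not met.
    """
    if not any(d.condition == "control" for d in datasets):
        raise ValueError("datasets must include the control condition")
    free_params = tuple(dict.fromkeys(free_params))
    init_dict = init.to_dict()
    for name in free_params:
        if name not in init_dict:
            raise KeyError(f"unknown free parameter {name!r}")
    bounds = [_bounds_for(name, init_dict[name]) for name in free_params]

    n_eval = 0

    def build(theta: np.ndarray) -> CircuitParameters:
        p = init
        for name, val, (lo, hi) in zip(free_params, theta, bounds):
            p = p.with_value(name, float(np.clip(val, lo, hi)))
        return p

    def per_dataset(p: CircuitParameters) -> dict[str, float]:
        preds = _dataset_predictions(p, datasets, stimulus)
        return {f"{ds.condition}:{ds.readout}":
                normalized_rmse(preds[f"{ds.condition}:{ds.readout}"],
                                ds.mean)
                for ds in datasets}

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            return sum(per_dataset(build(theta)).values())
        except Exception:
            return 1e6

    # starting points: the supplied init plus a Latin hypercube over bounds
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0s = [np.array([init_dict[name] for name in free_params], float)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(free_params), seed=seed)
        x0s += list(qmc.scale(sampler.random(n_starts - 1), lo, hi))

    per_start = max(20, budget // max(len(x0s), 1))
    best_theta, best_val = x0s[0], objective(x0s[0])
    for x0 in x0s:
        if n_eval >= budget:
            break
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": min(per_start, budget - n_eval),
                                "xatol": 1e-4, "fatol": 1e-5})
        if res.fun < best_val:
            best_theta, best_val = res.x, res.fun

    p_best = build(best_theta)
    nrmse = per_dataset(p_best)
    preds = _dataset_predictions(p_best, datasets, stimulus)
    r2 = {f"{ds.condition}:{ds.readout}":
          r_squared(ds.mean, preds[f"{ds.condition}:{ds.readout}"])
          for ds in datasets}
    passed = {
        readout: all(val < NRMSE_THRESHOLDS[readout]
                     for key, val in nrmse.items()
                     if key.endswith(f":{readout}"))
        for readout in {ds.readout for ds in datasets}
    }
    report = FitReport(p_best, nrmse, r2, passed, n_eval, best_val,
                       free_params)
    if not report.all_passed:
        raise NoFeasiblePointError(
            f"thresholds not met after {n_eval} evaluations; "
            f"best nRMSEs: {nrmse}", report)
    return report
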