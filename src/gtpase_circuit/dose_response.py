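"""Steady-state dose sweeps, EGF unit conversion and DoRA quantification.

Dose-response alignment (DoRA) is quantified by sweeping the stimulus,
collecting steady-state fractional activations, and fitting Hill curves
``a*x**n/(x**n + K) + d`` (or a straight line for the mGEF-mG* pair,
where alignment manifests as linearity) to upstream-downstream pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .circuit import (CircuitState, ModelVariant, TimeCourse,
                      pre_equilibrate, simulate_deterministic)
from .params import CircuitParameters, STATE_NAMES
from .stochastic import NoiseConfig, _batch_euler

__all__ = [
    "EGF_NORMALIZATION_NM", "egf_to_stimulus", "stimulus_to_egf",
    "default_dose_grid", "DoseResponseCurve", "HillFit", "FitError",
    "dose_sweep", "fit_hill", "fit_linear", "dora_report", "fractional_scale",
]

#: EGF concentration (nM) corresponding to one dimensionless stimulus unit
#: (50 nM maps to a stimulus of 0.23)
EGF_NORMALIZATION_NM = 217.4


class FitError(RuntimeError):
    """Nonlinear fit failed from every tried start."""


def egf_to_stimulus(egf_nM):
    """Convert an EGF concentration in nM to the dimensionless stimulus."""
    egf_nM = np.asarray(egf_nM, dtype=float)
    if np.any(egf_nM < 0):
        raise ValueError("EGF concentration must be >= 0")
    out = egf_nM / EGF_NORMALIZATION_NM
    return float(out) if out.ndim == 0 else out


def stimulus_to_egf(stimulus):
    """Inverse of :func:`egf_to_stimulus`."""
    stimulus = np.asarray(stimulus, dtype=float)
    if np.any(stimulus < 0):
        raise ValueError("stimulus must be >= 0")
    out = stimulus * EGF_NORMALIZATION_NM
    return float(out) if out.ndim == 0 else out


#: the seven stimulus values used in the printed dose tables
PRINTED_DOSES = (0.0, 0.00046, 0.0046, 0.046, 0.115, 0.23, 0.46)


def default_dose_grid(n_extra: int = 20) -> np.ndarray:
    """The seven printed doses plus log-spaced filler for smooth fits."""
    extra = np.geomspace(1e-4, 0.46, n_extra)
    return np.unique(np.concatenate([PRINTED_DOSES, extra]))


def fractional_scale(p: CircuitParameters, variable: str) -> float:
    """Maximal attainable value (1 + k) * Y_max of a circuit variable."""
    scales = {
        "mGEF": (1 + p.k_mGEF) * p.Y_mGEF_max,
        "mGAP": (1 + p.k_mGAP) * p.Y_mGAP_max,
        "mGstar": 1 + p.k_mGstar,
        "tGEF": (1 + p.k_tGEF) * p.Y_tGEF_max,
        "tGstar": 1 + p.k_tGstar,
        "S": 1.0,
        "X": 1.0,
    }
    return scales[variable]


@dataclass(frozen=True)
class DoseResponseCurve:
    """Steady-state (mean, SD) of every variable over a stimulus grid."""

    doses: np.ndarray
    response_mean: pd.DataFrame      # len(doses) x 7, columns STATE_NAMES
    response_sd: pd.DataFrame
    x_variable: str = "stimulus"
    y_variable: str = ""

    def __post_init__(self):
        d = np.asarray(self.doses, float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("doses must be strictly increasing")
        if (self.response_sd.to_numpy() < -1e-12).any():
            raise ValueError("response SD must be >= 0")
        object.__setattr__(self, "doses", d)

    def mean(self, variable: str) -> np.ndarray:
        return self.response_mean[variable].to_numpy()

    def sd(self, variable: str) -> np.ndarray:
        return self.response_sd[variable].to_numpy()

    def pair_frame(self, x_variable: str, y_variable: str,
                   p: CircuitParameters | None = None) -> pd.DataFrame:
        """dose, x_mean, x_sd, y_mean, y_sd for one plotted pair.

        With ``p`` given, circuit variables are rescaled to fractional
        activations (divided by their maximal attainable value).
        """
        def axis(var):
            if var == "stimulus":
                return self.doses, np.zeros_like(self.doses)
            if var == "EGF":
                return stimulus_to_egf(self.doses), np.zeros_like(self.doses)
            scale = fractional_scale(p, var) if p is not None else 1.0
            return self.mean(var) / scale, self.sd(var) / scale
        xm, xs = axis(x_variable)
        ym, ys = axis(y_variable)
        return pd.DataFrame({"dose": self.doses, "x_mean": xm, "x_sd": xs,
                             "y_mean": ym, "y_sd": ys})


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill curve a*x**n/(x**n + K) + d."""

    a: float
    n: float
    K: float
    d: float | None
    r2: float

    def __post_init__(self):
        if self.n <= 0 or self.K <= 0:
            raise ValueError("Hill fit requires n > 0 and K > 0")
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")

    def __call__(self, x):
        x = np.asarray(x, float)
        return self.a * x ** self.n / (x ** self.n + self.K) \
            + (self.d or 0.0)


def _r2(y, pred) -> float:
    y = np.asarray(y, float)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in observations")
    return 1.0 - ss_res / ss_tot


def fit_hill(x, y, include_offset: bool | str = "auto") -> HillFit:
    """Multi-start nonlinear least-squares Hill fit.

    Starts span Hill coefficients {0.5, 1, 2, 4} and half-max constants at
    the quartiles of x; the best residual wins, with ties broken by the
    smaller Hill coefficient.  With ``include_offset="auto"`` the offset d
    is retained only when it reduces the residual sum of squares by more
    than 1%.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for a Hill fit")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")

    def run(with_d):
        def f(x, a, n, K, d=0.0):
            return a * x ** n / (x ** n + K) + d
        lo = [0.0, 0.05, 1e-12] + ([-10.0] if with_d else [])
        hi = [1e3, 20.0, 1e9] + ([10.0] if with_d else [])
        amp = max(y.max() - y.min(), 1e-6)
        best = None
        xq = x[x > 0]
        quartiles = np.quantile(xq, [0.25, 0.5, 0.75]) if len(xq) else [1.0]
        tried = []
        for n0 in (0.5, 1.0, 2.0, 4.0):
            for q in quartiles:
                p0 = [amp, n0, q ** n0] + ([float(y.min())] if with_d else [])
                tried.append(p0)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        popt, _ = curve_fit(f, x, y, p0=p0, bounds=(lo, hi),
                                            maxfev=20000)
                except (RuntimeError, ValueError):
                    continue
                ss = float(np.sum((y - f(x, *popt)) ** 2))
                if best is None or ss < best[1] * (1 - 1e-9) or \
                        (abs(ss - best[1]) <= 1e-9 * max(best[1], 1e-300)
                         and popt[1] < best[0][1]):
                    best = (popt, ss)
        if best is None:
            raise FitError(f"Hill fit did not converge; starts tried: {tried}")
        return best

    if include_offset == "auto":
        popt0, ss0 = run(False)
        popt1, ss1 = run(True)
        use_d = ss1 < 0.99 * ss0
        popt, ss = (popt1, ss1) if use_d else (popt0, ss0)
    elif include_offset:
        popt, ss = run(True)
        use_d = True
    else:
        popt, ss = run(False)
        use_d = False

    pred = popt[0] * x ** popt[1] / (x ** popt[1] + popt[2]) \
        + (popt[3] if use_d else 0.0)
    return HillFit(a=float(popt[0]), n=float(popt[1]), K=float(popt[2]),
                   d=float(popt[3]) if use_d else None, r2=_r2(y, pred))


def fit_linear(x, y) -> tuple[float, float, float]:
    """Ordinary least squares line; returns (slope, intercept, r2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), _r2(y, slope * x + intercept)


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def dose_sweep(p: CircuitParameters, v: ModelVariant = ModelVariant(),
               doses: np.ndarray | None = None,
               cfg: NoiseConfig | None = None) -> DoseResponseCurve:
    """Steady-state response statistics of all variables over a dose grid.

    Deterministic (``cfg=None``): pre-equilibrate at stimulus 0 and
    integrate 1,440 min at each dose; the terminal state is the response
    and the SD is zero.  Stochastic: each dose is run as an ensemble of
    ``cfg.n_runs`` noisy replicates started from the deterministic steady
    state under that dose, and mean/SD are taken at the evaluation time.
    All doses and replicates are advanced in one batched Euler pass.
    """
    doses = default_dose_grid() if doses is None else \
        np.unique(np.asarray(doses, float))
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")

    if cfg is None:
        rows = []
        basal = pre_equilibrate(p, v, 0.0)
        for d in doses:
            try:
                tc = simulate_deterministic(p, v, d, (0.0, 1440.0),
                                            init=basal,
                                            t_eval=np.array([0.0, 1440.0]))
            except Exception as exc:
                raise RuntimeError(f"dose sweep failed at dose {d}") from exc
            rows.append(tc.y[-1])
        mean = pd.DataFrame(rows, columns=list(STATE_NAMES))
        sd = pd.DataFrame(np.zeros_like(rows), columns=list(STATE_NAMES))
        return DoseResponseCurve(doses, mean, sd)

    n = cfg.n_runs
    y0 = np.empty((len(doses) * n, 7))
    for i, d in enumerate(doses):
        try:
            ss = pre_equilibrate(p, v, d).as_array()
        except Exception as exc:
            raise RuntimeError(f"dose sweep failed at dose {d}") from exc
        y0[i * n:(i + 1) * n] = ss
    stim = np.repeat(doses, n)
    rng = np.random.default_rng(cfg.seed)
    out = _batch_euler(p, v, stim, cfg, y0, len(stim), rng,
                       np.array([cfg.evaluation_time]))
    terminal = out[:, 0, :].reshape(len(doses), n, 7)
    mean = pd.DataFrame(terminal.mean(axis=1), columns=list(STATE_NAMES))
    sd = pd.DataFrame(terminal.std(axis=1, ddof=1), columns=list(STATE_NAMES))
    return DoseResponseCurve(doses, mean, sd)


#: the upstream-downstream pairs quantified in the DoRA analysis;
#: the mGEF-mG* pair uses a straight line, the rest Hill curves
DORA_PAIRS = (("mGEF", "mGstar", "linear"),
              ("tGEF", "tGstar", "hill"),
              ("EGF", "tGstar", "hill"),
              ("stimulus", "S", "hill"))


def dora_report(p: CircuitParameters,
                doses: np.ndarray | None = None,
                cfg: NoiseConfig | None = None,
                variants: tuple[ModelVariant, ...] = (
                    ModelVariant.coupled(), ModelVariant.uncoupled()),
                ) -> dict[str, dict]:
    """Dose sweeps plus curve fits for the standard DoRA pairs.

    Returns ``{variant_kind: {"curve": DoseResponseCurve, pairs: {...}}}``
    where each pair entry carries the fractional-activation x/y arrays and
    either a :class:`HillFit` or a (slope, intercept, r2) tuple.
    """
    report: dict[str, dict] = {}
    for v in variants:
        curve = dose_sweep(p, v, doses, cfg)
        pairs = {}
        for xvar, yvar, kind in DORA_PAIRS:
            frame = curve.pair_frame(xvar, yvar, p)
            x = frame["x_mean"].to_numpy()
            y = frame["y_mean"].to_numpy()
            if np.ptp(y) < 1e-12:
                fit = None          # flat response (e.g. uncoupled secretion)
            elif kind == "linear":
                fit = fit_linear(x, y)
            else:
                fit = fit_hill(x, y)
            pairs[f"{xvar}:{yvar}"] = {"x": x, "y": y, "kind": kind,
                                       "fit": fit}
        report[v.kind] = {"curve": curve, "pairs": pairs}
    return report
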