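"""Local logarithmic sensitivity of model outputs to kinetic parameters.

Sensitivity is d ln X / d ln alpha, approximated by perturbing each
parameter alpha by +/-10% and differencing the log outputs.  The default
scheme divides the log-difference by 0.2 (the relative perturbation), so
the result is the dimensionless logarithmic gain; a literal scheme
dividing by 0.2*alpha is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import ModelVariant, pre_equilibrate, simulate_deterministic, \
    STIMULUS_50NM
from .fitting import TimeCourseDataset, normalized_rmse, simulate_fold_change
from .params import CircuitParameters

__all__ = ["SensitivityEntry", "log_sensitivity", "sensitivity_table",
           "standard_outputs"]

OutputFn = Callable[[CircuitParameters], float]


@dataclass(frozen=True)
class SensitivityEntry:
    parameter: str
    output: str
    sensitivity: float


def log_sensitivity(output_fn: OutputFn, p: CircuitParameters,
                    param_name: str, scheme: str = "default") -> float:
    """d ln X / d ln alpha by the +/-10% central difference.

    ``scheme="default"``: [ln X(1.1a) - ln X(0.9a)] / 0.2 (dimensionless).
    ``scheme="as_printed"``: the same log-difference divided by 0.2*a.
    The output must be strictly positive at both perturbed values.
    """
    value = p.to_dict().get(param_name)
    if value is None:
        raise KeyError(f"parameter {param_name!r} not found")
    if value == 0:
        raise ValueError(f"{param_name} is zero; relative perturbation "
                         "undefined")
    outputs = []
    for factor in (1.1, 0.9):
        x = output_fn(p.with_value(param_name, value * factor))
        if not np.isfinite(x) or x <= 0:
            raise ValueError(
                f"output must be positive and finite for the log "
                f"sensitivity; got {x} at {param_name}*{factor}")
        outputs.append(np.log(x))
    diff = outputs[0] - outputs[1]
    if scheme == "default":
        return float(diff / 0.2)
    if scheme == "as_printed":
        return float(diff / (0.2 * value))
    raise ValueError("scheme must be 'default' or 'as_printed'")


def standard_outputs(reference: Mapping[str, TimeCourseDataset] | None,
                     stimulus: float = STIMULUS_50NM,
                     variant: ModelVariant = ModelVariant.coupled(),
                     ) -> dict[str, OutputFn]:
    """The four outputs analysed for robustness.

    Trace errors (normalized RMSE of the simulated mG*/tG* fold changes
    against the reference datasets) and the stimulated steady-state
    secretion and cell number.  ``reference`` maps readout name to the
    control dataset; pass None to get the steady-state outputs only.
    """
    out: dict[str, OutputFn] = {}
    if reference:
        def trace_output(readout: str) -> OutputFn:
            ds = reference[readout]

            def fn(p: CircuitParameters) -> float:
                sim = simulate_fold_change(p, "control", readout,
                                           ds.timepoints, stimulus)
                return normalized_rmse(sim, ds.mean)
            return fn
        for readout in reference:
            out[f"nrmse_{readout}"] = trace_output(readout)

    def steady(varname: str) -> OutputFn:
        def fn(p: CircuitParameters) -> float:
            ss = pre_equilibrate(p, variant, stimulus)
            return float(getattr(ss, varname))
        return fn

    out["steady_secretion"] = steady("S")
    out["steady_cell_number"] = steady("X")
    return out


def sensitivity_table(p: CircuitParameters,
                      outputs: Mapping[str, OutputFn],
                      params: Sequence[str] | None = None,
                      scheme: str = "default") -> pd.DataFrame:
    """Sensitivity of every requested output to every requested parameter.

    Defaults to all nonzero kinetic parameters.  Returns a DataFrame
    (parameter, output, sensitivity) sorted by |sensitivity| descending.
    Parameters whose perturbation makes an output non-computable are
    reported as NaN.
    """
    all_names = [name for name, val in p.to_dict().items() if val != 0]
    if params is None:
        params = all_names
    else:
        deduped = list(dict.fromkeys(params))
        if len(deduped) != len(params):
            warnings.warn("duplicate parameter names removed", stacklevel=2)
        params = deduped
        unknown = set(params) - set(p.to_dict())
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")

    rows = []
    for name in params:
        for out_name, fn in outputs.items():
            try:
                s = log_sensitivity(fn, p, name, scheme=scheme)
            except (ValueError, RuntimeError):
                s = float("nan")
            rows.append((name, out_name, s))
    df = pd.DataFrame(rows, columns=["parameter", "output", "sensitivity"])
    return df.reindex(
        df["sensitivity"].abs().sort_values(ascending=False, kind="stable")
        .index).reset_index(drop=True)
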