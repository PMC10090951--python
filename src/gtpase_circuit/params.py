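"""Kinetic parameters of the coupled Arf1/Gi GTPase circuit.

The circuit couples a monomeric GTPase switch (mG, Arf1) to a trimeric
GTPase switch (tG, Gi) through the bifunctional linker GIV (the tGEF), and
feeds a downstream secrete-and-sense module (secreted growth factors S and
cell number X).  Every regulatory interaction is a normalized Hill function
parameterised by a half-maximal activation ``ec50`` and Hill coefficient
``n``; each species equation additionally carries a relaxation time scale
``tau`` (minutes), a basal production rate ``k`` and, for the GEF/GAP
species, a maximal fractional activation ``Y_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

__all__ = ["HillParams", "CircuitParameters", "default_parameters",
           "load_parameters", "save_parameters"]


@dataclass(frozen=True)
class HillParams:
    """Half-maximal activation and Hill coefficient of one interaction.

    ``ec50`` lives on the fractional-activation scale, so it must lie in
    (0, 1).  The pair additionally may not satisfy ``ec50**n == 0.5``: the
    normalisation constant B of the normalized Hill form has ``2*ec50**n - 1``
    in its denominator.
    """

    ec50: float
    n: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ec50 < 1.0:
            raise ValueError(f"ec50 must be in (0,1), got {self.ec50}")
        if self.n <= 0:
            raise ValueError(f"Hill coefficient must be > 0, got {self.n}")
        if abs(self.ec50 ** self.n - 0.5) < 1e-12:
            raise ValueError(
                f"degenerate Hill parameters: ec50**n == 0.5 "
                f"(ec50={self.ec50}, n={self.n})")


# Interactions, in the order their Hill functions enter the equations:
#   1: stimulus -> mGEF        2: tGEF -> mGAP (feedback arm 1)
#   3: tG*  -> mGAP (feedback arm 2, via free Gbetagamma)
#   4: mGEF -> mG* activation  5: mGAP -> mG* deactivation
#   6: mG*  -> tGEF (GIV recruitment)
#   7: tGEF -> tG* activation  8: tGAP -> tG* deactivation
#   9: mGAP -> secretion drive
N_HILL = 9

STATE_NAMES = ("mGEF", "mGAP", "mGstar", "tGEF", "tGstar", "S", "X")


@dataclass(frozen=True)
class CircuitParameters:
    """Full kinetic parameterisation of the circuit and its downstream module."""

    hill: tuple[HillParams, ...]

    # time scales (min)
    tau_mGEF: float = 2.0
    tau_mGAP: float = 10.0
    tau_mGstar: float = 2.0
    tau_tGEF: float = 4.0
    tau_tGstar: float = 4.0

    # basal production rates (dimensionless)
    k_mGEF: float = 0.05
    k_mGAP: float = 0.12
    k_mGstar: float = 0.0
    k_tGEF: float = 0.0
    k_tGstar: float = 0.02

    # maximal fractional activations
    Y_mGEF_max: float = 1.0
    Y_mGAP_max: float = 1.0
    Y_tGEF_max: float = 1.0

    # constant tGAP level (fractional)
    tGAP: float = 0.3

    # secretion / cell-number module
    beta_S: float = 0.003
    k_S: float = 0.0005
    alpha_S: float = 0.002
    gamma: float = 0.01
    K2: float = 1.0
    lam: float = 0.02
    mu: float = 0.005
    K1: float = 0.5
    K_capacity: float = 100.0

    # OR-gate rescaling constants (see mgap_drive)
    or_gate_c_tGEF: float = 0.24
    or_gate_c_tGstar: float = 0.0017

    def __post_init__(self) -> None:
        if len(self.hill) != N_HILL:
            raise ValueError(f"expected {N_HILL} Hill parameter pairs, "
                             f"got {len(self.hill)}")
        for name in ("tau_mGEF", "tau_mGAP", "tau_mGstar",
                     "tau_tGEF", "tau_tGstar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k_mGEF", "k_mGAP", "k_mGstar", "k_tGEF", "k_tGstar",
                     "beta_S", "k_S", "alpha_S", "gamma", "lam", "mu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("Y_mGEF_max", "Y_mGAP_max", "Y_tGEF_max"):
            y = getattr(self, name)
            if not 0.0 < y <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {y}")
        for name in ("K1", "K2", "K_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        d: dict[str, float] = {}
        for i, h in enumerate(self.hill, start=1):
            d[f"hill{i}_ec50"] = h.ec50
            d[f"hill{i}_n"] = h.n
        for key, val in asdict(self).items():
            if key != "hill":
                d[key] = val
        return d

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CircuitParameters":
        d = dict(d)
        hill = tuple(
            HillParams(d.pop(f"hill{i}_ec50"), d.pop(f"hill{i}_n"))
            for i in range(1, N_HILL + 1)
        )
        return cls(hill=hill, **d)

    def replace(self, **kwargs) -> "CircuitParameters":
        return replace(self, **kwargs)

    def with_value(self, name: str, value: float) -> "CircuitParameters":
        """Return a copy with one (possibly Hill) parameter replaced.

        ``name`` is a flat key as produced by :meth:`to_dict`, e.g.
        ``"tau_mGAP"`` or ``"hill4_ec50"``.
        """
        d = self.to_dict()
        if name not in d:
            raise KeyError(f"unknown parameter {name!r}")
        d[name] = value
        return CircuitParameters.from_dict(d)

    def parameter_names(self) -> Iterator[str]:
        return iter(self.to_dict())


def load_parameters(path: str | Path) -> CircuitParameters:
    """Read a flat key-value YAML/JSON parameter file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return CircuitParameters.from_dict(d)


def save_parameters(p: CircuitParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


def default_parameters() -> CircuitParameters:
    """The package's default kinetic parameter set.

    Calibrated so that, at an EGF stimulus of 0.23 (50 nM), active Arf1
    rises ~3-fold within 5 min and relaxes toward baseline by 30 min,
    GIV depletion (Y_tGEF_max = 0.1) yields sustained Arf1 activity, Gi
    activation saturates over 0-30 min, and the steady-state dose-response
    curves show dose-response alignment between mGEF and mG*.
    """
    ref = resources.files("gtpase_circuit").joinpath("data/default_params.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)
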