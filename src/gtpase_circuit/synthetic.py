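"""Synthetic stand-ins for the wet-lab inputs of the pipeline.

Two generators: (i) fold-change time-course datasets with the statistical
structure of densitometry/FRET measurements (mean +/- SEM over a few
biological replicates, sampled at sparse time points), produced by
simulating a known ground-truth parameter set and adding replicate noise;
(ii) PPI fixture graphs with a planted linker node whose deletion fully
rewires the anchor-partner geodesics, providing a known answer for the
network-perturbation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .circuit import ModelVariant, pre_equilibrate, simulate_deterministic, \
    STIMULUS_50NM
from .fitting import TimeCourseDataset, fold_change, CONDITION_VARIANTS
from .network import InteractionGraph
from .params import CircuitParameters, default_parameters

__all__ = ["SyntheticSpec", "generate_timecourses", "generate_ppi_fixture"]

#: experimental sampling grids: pulldown densitometry (mG*) and FRET (tG*)
MGSTAR_GRID = (0.0, 5.0, 15.0, 30.0)
TGSTAR_GRID = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions under which synthetic time courses are generated."""

    params: CircuitParameters = field(default_factory=default_parameters)
    stimulus: float = STIMULUS_50NM
    t_grid_mGstar: tuple[float, ...] = MGSTAR_GRID
    t_grid_tGstar: tuple[float, ...] = TGSTAR_GRID
    noise_scale: float = 0.10      # replicate SD as a fraction of trace mean
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_timecourses(spec: SyntheticSpec
                         ) -> tuple[list[TimeCourseDataset],
                                    dict[str, np.ndarray]]:
    """Simulate ground truth and sample noisy replicate datasets.

    Returns the four datasets (control / GIV-depleted x mG* / tG*) and a
    dict of the noiseless ground-truth fold-change traces keyed by
    ``"{condition}:{readout}"``, for recovery tests.  Replicate noise is
    Gaussian with SD ``noise_scale * mean(trace)``, truncated at zero
    (ratio measurements are positive); the reported SEM is the replicate
    SD over sqrt(n).
    """
    rng = np.random.default_rng(spec.seed)
    datasets: list[TimeCourseDataset] = []
    truth: dict[str, np.ndarray] = {}
    grids = {"mGstar": np.asarray(spec.t_grid_mGstar),
             "tGstar": np.asarray(spec.t_grid_tGstar)}

    for condition, variant in CONDITION_VARIANTS.items():
        basal = pre_equilibrate(spec.params, variant)
        t_end = max(g[-1] for g in grids.values())
        for readout, grid in grids.items():
            tc = simulate_deterministic(spec.params, variant, spec.stimulus,
                                        (0.0, float(t_end)), init=basal,
                                        t_eval=grid)
            trace = fold_change(tc, readout)
            truth[f"{condition}:{readout}"] = trace
            sd = spec.noise_scale * float(trace.mean())
            reps = trace + sd * rng.standard_normal(
                (spec.n_replicates, len(trace)))
            reps = np.maximum(reps, 0.0)
            mean = reps.mean(axis=0)
            sem = (reps.std(axis=0, ddof=1) / np.sqrt(spec.n_replicates)
                   if spec.n_replicates > 1 else np.zeros_like(mean))
            datasets.append(TimeCourseDataset(grid, mean, sem,
                                              condition, readout))
    return datasets, truth


def generate_ppi_fixture(n_nodes: int, n_seeds: int, seed: int = 0
                         ) -> tuple[InteractionGraph, str, list[str]]:
    """Random PPI graph with a planted linker between anchor and partners.

    Construction: the anchor ``ANCHOR`` reaches each of the
    ``n_seeds - 1`` partner seeds only through the linker ``LINKER``
    (unique geodesics of length 2), while a two-hop detour
    ``ANCHOR-DET1-DET2-partner`` guarantees that deleting the linker
    creates strictly longer, entirely new geodesics -- alteration
    fraction exactly 1 for every planted pair.  Remaining nodes are
    random decoration attached off the detour chain.

    Returns (graph, linker name, expected fully-impacted partners).
    """
    n_partners = n_seeds - 1
    if n_seeds < 3:
        raise ValueError("need n_seeds >= 3")
    if n_nodes < 6 or n_nodes < 4 + n_partners or n_seeds > n_nodes:
        raise ValueError(
            f"infeasible sizes: n_nodes={n_nodes}, n_seeds={n_seeds} "
            f"(need n_nodes >= max(6, 4 + n_seeds - 1))")

    rng = np.random.default_rng(seed)
    anchor, linker, d1, d2 = "ANCHOR", "LINKER", "DET1", "DET2"
    partners = [f"P{i}" for i in range(1, n_partners + 1)]
    g = nx.Graph()
    g.add_edge(anchor, linker, combined_score=900)
    g.add_edge(anchor, d1, combined_score=900)
    g.add_edge(d1, d2, combined_score=900)
    for prot in partners:
        g.add_edge(linker, prot, combined_score=900)
        g.add_edge(d2, prot, combined_score=900)

    n_extra = n_nodes - g.number_of_nodes()
    attach_pool = [d1, d2] + partners
    for i in range(n_extra):
        node = f"F{i + 1}"
        host = attach_pool[rng.integers(len(attach_pool))]
        g.add_edge(node, host,
                   combined_score=int(rng.integers(700, 1000)))

    seeds = frozenset([anchor] + partners)
    return InteractionGraph(g, seeds), linker, partners
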