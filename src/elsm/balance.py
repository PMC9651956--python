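"""E/I balance diagnostics and selection of the input-inhibitory weight factor.

Increasing the factor widens the uniform weight distribution of input
synapses onto inhibitory liquid neurons (U[0, factor * 0.4]) while leaving
everything else — topology, recurrent weights, input-excitatory weights —
untouched.  Stronger inhibitory drive sparsifies network activity and pulls
the time-averaged net synaptic drive (g_e - g_i, averaged over excitatory
neurons) toward zero; the factor whose mean net drive is closest to zero
is taken as the E/I-balanced operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .liquid import Liquid, LiquidSpec, build_liquid
from .simulate import (
    SimulationConfig,
    SpikeRaster,
    net_current_stats,
    run,
    spikes_per_neuron,
)


@dataclass
class BalanceReport:
    """Seed- and probe-averaged diagnostics for one inhibitory factor."""

    factor: float
    mean_net_current: float
    std_net_current: float
    spikes_per_neuron: float
    exc_spikes_per_neuron: float
    accuracy: float | None = None
    n_seeds: int = 1


def sweep_inhib_factor(
    spec: LiquidSpec,
    factors: Sequence[float],
    probe_inputs: Sequence[SpikeRaster],
    n_seeds: int = 5,
    config: SimulationConfig | None = None,
    base_seed: int | None = None,
) -> list[BalanceReport]:
    """Diagnose E/I balance for each factor on a fixed synthetic probe set.

    For each liquid seed the reservoir is built once at the first factor
    and rescaled to the others, so across factors only the
    input->inhibitory weight magnitudes differ.  Simulation seeds are tied
    to (liquid seed, probe index) and shared across factors.
    """
    if not factors:
        raise ValueError("factors must be non-empty")
    if not probe_inputs:
        raise ValueError("probe_inputs must be non-empty")
    n_ch = probe_inputs[0].n_sources
    if any(p.n_sources != n_ch for p in probe_inputs):
        raise ValueError("probe inputs must share one channel count")
    if config is None:
        config = SimulationConfig(duration=probe_inputs[0].duration, record_states=True)
    base_seed = spec.seed if base_seed is None else int(base_seed)

    acc: dict[float, dict[str, list[float]]] = {
        f: {"mean": [], "std": [], "spn": [], "exc": []} for f in factors
    }
    for s in range(n_seeds):
        liquid0 = build_liquid(
            replace(spec, inhib_factor=float(factors[0])), n_ch, seed=base_seed + s
        )
        n = liquid0.n_neurons
        exc_ids = liquid0.population.excitatory_ids
        for factor in factors:
            liq = (
                liquid0
                if factor == factors[0]
                else liquid0.with_inhib_factor(float(factor))
            )
            for p_idx, probe in enumerate(probe_inputs):
                sim_cfg = replace(
                    config,
                    record_states=True,
                    seed=(base_seed + s) * 1009 + p_idx,
                )
                raster, trace = run(liq, probe, sim_cfg)
                stats = net_current_stats(trace)
                acc[factor]["mean"].append(stats.mean_net_current)
                acc[factor]["std"].append(stats.std_net_current)
                acc[factor]["spn"].append(spikes_per_neuron(raster, n))
                exc_count = np.isin(raster.sources, exc_ids).sum()
                acc[factor]["exc"].append(exc_count / exc_ids.size)

    return [
        BalanceReport(
            factor=float(f),
            mean_net_current=float(np.mean(acc[f]["mean"])),
            std_net_current=float(np.mean(acc[f]["std"])),
            spikes_per_neuron=float(np.mean(acc[f]["spn"])),
            exc_spikes_per_neuron=float(np.mean(acc[f]["exc"])),
            n_seeds=n_seeds,
        )
        for f in factors
    ]


def select_balanced_factor(reports: Sequence[BalanceReport]) -> float:
    """Factor minimizing |mean net current|; ties go to the smaller factor."""
    if not reports:
        raise ValueError("need at least one report")
    best = min(reports, key=lambda r: (abs(r.mean_net_current), r.factor))
    return best.factor
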