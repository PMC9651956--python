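"""Conductance-based leaky integrate-and-fire dynamics with adaptive threshold.

The membrane potential obeys

    tau_m dV/dt = (E_rest - V) + g_e (E_exc - V) + g_i (E_inh - V)

with dimensionless conductances g_e, g_i that jump by the synaptic weight
on presynaptic spikes and decay exponentially with tau_ge / tau_gi.  A
spike is emitted when V crosses V_th_base + theta, where theta is the
spike-frequency-adaptation (SFA) component of the threshold: it is bumped
by a fixed increment on each spike of an SFA-enabled (excitatory) neuron
and decays exponentially with tau_sfa.  After a spike V is reset and the
neuron is refractory (V clamped at the reset value, integration suspended,
conductances still accumulate and decay).

All operations are vectorized over a population; a single neuron is the
length-1 case.  Integration uses exponential-Euler with the start-of-step
conductances, which is exact for the leak-only membrane and for the
conductance and threshold decays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NeuronParams:
    """Per-population constants; array fields broadcast over neurons.

    Voltages are in mV, times in ms.  The default reversal potentials put
    E_inh below rest (hyperpolarizing) and E_exc above threshold
    (depolarizing) on the shifted 13.5/15 mV scale.
    """

    tau_m: np.ndarray | float = 30.0
    t_ref: np.ndarray | float = 3.0
    tau_sfa: np.ndarray | float = np.nan  # NaN disables SFA for that neuron
    E_rest: float = 13.5
    E_reset: float = 13.5
    E_exc: float = 30.0
    E_inh: float = 0.0
    V_th_base: float = 15.0
    tau_ge: float = 3.0
    tau_gi: float = 10.0
    sfa_increment: float = 1.0

    def __post_init__(self) -> None:
        self.tau_m = np.asarray(self.tau_m, dtype=float)
        self.t_ref = np.asarray(self.t_ref, dtype=float)
        self.tau_sfa = np.asarray(self.tau_sfa, dtype=float)
        if np.any(self.tau_m <= 0) or self.tau_ge <= 0 or self.tau_gi <= 0:
            raise ValueError("time constants must be positive")
        if np.any(self.t_ref <= 0):
            raise ValueError("refractory periods must be positive")
        if self.V_th_base <= self.E_reset:
            raise ValueError("V_th_base must exceed E_reset")

    @property
    def sfa_enabled(self) -> np.ndarray:
        return np.isfinite(self.tau_sfa)

    @classmethod
    def from_population(cls, population, **overrides) -> "NeuronParams":
        """Build params from a liquid population (tau_m, tau_sfa, t_ref)."""
        tau_m = (
            population.tau_m
            if population.tau_m is not None
            else np.full(population.n, 30.0)
        )
        tau_sfa = (
            population.tau_sfa
            if population.tau_sfa is not None
            else np.full(population.n, np.nan)
        )
        t_ref = np.where(population.is_excitatory, 3.0, 2.0)
        return cls(tau_m=tau_m, t_ref=t_ref, tau_sfa=tau_sfa, **overrides)


@dataclass
class NeuronState:
    """Evolving dynamical variables, one entry per neuron."""

    V: np.ndarray  # mV
    g_e: np.ndarray
    g_i: np.ndarray
    theta_sfa: np.ndarray  # mV, adaptive threshold component, >= 0
    refractory_remaining: np.ndarray  # ms

    @property
    def n(self) -> int:
        return int(self.V.size)

    def copy(self) -> "NeuronState":
        return NeuronState(
            self.V.copy(), self.g_e.copy(), self.g_i.copy(),
            self.theta_sfa.copy(), self.refractory_remaining.copy(),
        )


def init_state(n: int, params: NeuronParams, rng: np.random.Generator) -> NeuronState:
    """Fresh state: V ~ U[13.5, 15) mV, conductances and adaptation at zero."""
    V = rng.uniform(params.E_rest, params.V_th_base, size=n)
    zeros = np.zeros(n)
    return NeuronState(V, zeros.copy(), zeros.copy(), zeros.copy(), zeros.copy())


def effective_threshold(state: NeuronState, params: NeuronParams) -> np.ndarray:
    """V_th = V_th_base + theta_sfa."""
    return params.V_th_base + state.theta_sfa


def apply_presynaptic_spike(
    state: NeuronState, weight, inhibitory_source: bool
) -> NeuronState:
    """Instantaneous conductance kick: g_e or g_i increases by the weight.

    ``weight`` may be a scalar or a per-neuron array (zero where no spike
    arrived).  Input-layer and excitatory-liquid sources kick g_e;
    inhibitory-liquid sources kick g_i.
    """
    weight = np.asarray(weight, dtype=float)
    if np.any(weight < 0):
        raise ValueError("synaptic weights must be non-negative")
    if inhibitory_source:
        state.g_i = state.g_i + weight
    else:
        state.g_e = state.g_e + weight
    return state


def step_neuron(
    state: NeuronState, params: NeuronParams, dt: float
) -> tuple[NeuronState, np.ndarray]:
    """Advance every neuron by one step of ``dt`` ms; returns the spike mask.

    Order within the step: integrate V with the start-of-step conductances
    (exponential-Euler), decay conductances and theta exactly, handle the
    refractory clamp, then test V >= V_th_base + theta at the step end.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (
        np.all(np.isfinite(state.V))
        and np.all(np.isfinite(state.g_e))
        and np.all(np.isfinite(state.g_i))
    ):
        raise FloatingPointError("non-finite neuron state")

    g_tot = state.g_e + state.g_i
    denom = 1.0 + g_tot
    V_inf = (params.E_rest + state.g_e * params.E_exc + state.g_i * params.E_inh) / denom
    decay = np.exp(-dt * denom / params.tau_m)
    V_new = V_inf + (state.V - V_inf) * decay

    refractory = state.refractory_remaining > 0
    state.V = np.where(refractory, params.E_reset, V_new)
    state.refractory_remaining = np.maximum(
        state.refractory_remaining - np.where(refractory, dt, 0.0), 0.0
    )

    state.g_e *= np.exp(-dt / params.tau_ge)
    state.g_i *= np.exp(-dt / params.tau_gi)
    sfa_on = params.sfa_enabled
    if np.any(sfa_on):
        theta_decay = np.where(sfa_on, np.exp(-dt / np.where(sfa_on, params.tau_sfa, 1.0)), 1.0)
        state.theta_sfa = state.theta_sfa * theta_decay

    spiked = (~refractory) & (state.V >= effective_threshold(state, params))
    if np.any(spiked):
        state.V = np.where(spiked, params.E_reset, state.V)
        state.refractory_remaining = np.where(
            spiked, np.broadcast_to(params.t_ref, spiked.shape), state.refractory_remaining
        )
        bump = spiked & sfa_on
        if np.any(bump):
            state.theta_sfa = state.theta_sfa + np.where(bump, params.sfa_increment, 0.0)
    return state, spiked
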