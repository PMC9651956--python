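"""Construction of the liquid: a sparse, recurrent reservoir of spiking neurons.

Neurons are placed on a 3D integer lattice and labeled excitatory or
inhibitory (80/20 by default).  Recurrent synapses are realized
independently per ordered pair with the distance-dependent probability

    P(i, j) = C[type] * exp(-(D(i, j) / lambda)^2)

where D is the Euclidean distance between the two lattice sites and C
depends on the synapse type (EE, EI, IE, II).  Weights are drawn uniformly
on [0, upper(type)]; inhibitory influence is carried by the synapse type
(IE/II rows add to the *inhibitory* conductance of their target), never by
a sign on the weight.  Every liquid neuron additionally receives a fixed
number of excitatory-acting input synapses from distinct input channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

RECURRENT_TYPES = ("EE", "EI", "IE", "II")
INPUT_TYPES = ("input-E", "input-I")

#: Connection probability scale per synapse type (pre->post, E/I labels).
DEFAULT_C: dict[str, float] = {"EE": 0.3, "EI": 0.2, "IE": 0.4, "II": 0.1}

#: Upper bound of the uniform weight distribution per recurrent synapse type.
DEFAULT_WEIGHT_UPPER: dict[str, float] = {"EE": 0.6, "EI": 0.4, "IE": 1.2, "II": 0.4}

#: Synaptic transmission delays in milliseconds.
DEFAULT_DELAYS_MS: dict[str, float] = {
    "input": 1.0,
    "EE": 1.5,
    "EI": 0.8,
    "IE": 0.8,
    "II": 0.8,
}


@dataclass(frozen=True)
class GridSpec:
    """A 3D integer lattice with unit spacing holding ``n_neurons`` sites."""

    dims: tuple[int, int, int]
    n_neurons: int

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        capacity = int(np.prod(self.dims))
        if capacity < self.n_neurons:
            raise ValueError(
                f"grid too small: {self.n_neurons} neurons requested but "
                f"dims {self.dims} provide only {capacity} sites"
            )


def default_grid_dims(n: int) -> tuple[int, int, int]:
    """Pick lattice extents for ``n`` neurons close to a 1:1:2 box.

    Searches small boxes with capacity >= n, preferring minimal slack and,
    among those, the aspect ratio closest to 1:1:2.  For n=2000 this yields
    (10, 10, 20), which reproduces the reference mean recurrent degree of
    ~9.5 synapses per neuron.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    a = max(1, round((n / 2) ** (1 / 3)))
    best: tuple[float, float, tuple[int, int, int]] | None = None
    for dx in range(max(1, a - 2), a + 3):
        for dy in range(dx, a + 3):
            dz = math.ceil(n / (dx * dy))
            slack = dx * dy * dz - n
            aspect = abs(dy / dx - 1.0) + abs(dz / dx - 2.0)
            key = (slack, aspect, (dx, dy, dz))
            if best is None or key < best:
                best = key
    assert best is not None
    return best[2]


@dataclass
class LiquidSpec:
    """All hyperparameters needed to construct a liquid.

    ``inhib_factor`` scales the upper bound of the uniform weight
    distribution of input synapses onto *inhibitory* liquid neurons:
    upper = inhib_factor * input_exc_weight_upper, so the baseline factor
    0.5 gives U[0, 0.2] against U[0, 0.4] onto excitatory targets.
    """

    n_neurons: int = 2000
    exc_fraction: float = 0.8
    lambda_: float = 2.0
    C: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_C))
    recurrent_weight_upper: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_UPPER)
    )
    delays_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DELAYS_MS))
    input_in_degree: int = 7
    input_exc_weight_upper: float = 0.4
    inhib_factor: float = 0.5
    tau_mode: str = "fixed"  # "fixed" | "uniform"
    tau_fixed_ms: float = 30.0
    tau_range_ms: tuple[float, float] = (5.0, 55.0)
    sfa_mode: str = "off"  # "off" | "fixed" | "uniform"
    sfa_tau_ms: float = 550.0
    sfa_range_ms: tuple[float, float] = (50.0, 1050.0)
    grid_dims: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.exc_fraction <= 1.0:
            raise ValueError("exc_fraction must lie in [0, 1]")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        for t, p in self.C.items():
            if t not in RECURRENT_TYPES:
                raise ValueError(f"unknown synapse type in C: {t!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"C[{t}]={p} outside [0, 1]")
        for t, u in self.recurrent_weight_upper.items():
            if u < 0:
                raise ValueError(f"weight upper bound for {t} must be >= 0")
        for t, d in self.delays_ms.items():
            if d <= 0:
                raise ValueError(f"delay for {t} must be > 0")
        if self.input_in_degree < 0:
            raise ValueError("input_in_degree must be >= 0")
        if self.input_exc_weight_upper < 0 or self.inhib_factor < 0:
            raise ValueError("input weight bounds must be >= 0")
        if self.tau_mode not in ("fixed", "uniform"):
            raise ValueError(f"unknown tau_mode {self.tau_mode!r}")
        if self.sfa_mode not in ("off", "fixed", "uniform"):
            raise ValueError(f"unknown sfa_mode {self.sfa_mode!r}")
        if self.grid_dims is not None:
            self.grid_dims = tuple(int(d) for d in self.grid_dims)  # type: ignore[assignment]

    @property
    def grid(self) -> GridSpec:
        dims = self.grid_dims or default_grid_dims(self.n_neurons)
        return GridSpec(dims=tuple(dims), n_neurons=self.n_neurons)

    def to_dict(self) -> dict:
        d = {
            "n_neurons": self.n_neurons,
            "exc_fraction": self.exc_fraction,
            "lambda_": self.lambda_,
            "C": dict(self.C),
            "recurrent_weight_upper": dict(self.recurrent_weight_upper),
            "delays_ms": dict(self.delays_ms),
            "input_in_degree": self.input_in_degree,
            "input_exc_weight_upper": self.input_exc_weight_upper,
            "inhib_factor": self.inhib_factor,
            "tau_mode": self.tau_mode,
            "tau_fixed_ms": self.tau_fixed_ms,
            "tau_range_ms": list(self.tau_range_ms),
            "sfa_mode": self.sfa_mode,
            "sfa_tau_ms": self.sfa_tau_ms,
            "sfa_range_ms": list(self.sfa_range_ms),
            "grid_dims": list(self.grid_dims) if self.grid_dims else None,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "LiquidSpec":
        d = dict(d)
        for key in ("tau_range_ms", "sfa_range_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("grid_dims") is not None:
            d["grid_dims"] = tuple(d["grid_dims"])
        return cls(**d)


@dataclass
class SynapseTable:
    """Realized synapses as parallel columns (pre, post, weight, delay, type).

    For input rows ``pre`` indexes input channels; for recurrent rows it
    indexes liquid neurons.  Weights are non-negative conductance
    increments; whether a row excites or inhibits its target is determined
    by ``syn_type`` alone.
    """

    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay_ms: np.ndarray
    syn_type: np.ndarray  # array of strings

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        self.delay_ms = np.asarray(self.delay_ms, dtype=np.float64)
        self.syn_type = np.asarray(self.syn_type, dtype=object)
        if np.any(self.weight < 0):
            raise ValueError("synaptic weights must be non-negative")
        if self.n and np.any(self.delay_ms <= 0):
            raise ValueError("synaptic delays must be positive")

    @property
    def n(self) -> int:
        return int(self.pre.size)

    @classmethod
    def empty(cls) -> "SynapseTable":
        z = np.empty(0)
        return cls(z, z, z, np.empty(0), np.empty(0, dtype=object))

    @classmethod
    def concat(cls, tables: Sequence["SynapseTable"]) -> "SynapseTable":
        return cls(
            np.concatenate([t.pre for t in tables]),
            np.concatenate([t.post for t in tables]),
            np.concatenate([t.weight for t in tables]),
            np.concatenate([t.delay_ms for t in tables]),
            np.concatenate([t.syn_type for t in tables]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "weight": self.weight,
                "delay_ms": self.delay_ms,
                "type": self.syn_type.astype(str),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SynapseTable":
        return cls(
            df["pre"].to_numpy(),
            df["post"].to_numpy(),
            df["weight"].to_numpy(),
            df["delay_ms"].to_numpy(),
            df["type"].to_numpy(dtype=object),
        )

    def to_csv(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly through text
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SynapseTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class NeuronPopulation:
    """Per-neuron static properties of the liquid."""

    positions: np.ndarray  # (n, 3) int
    is_excitatory: np.ndarray  # (n,) bool
    tau_m: np.ndarray | None = None  # ms, per neuron
    tau_sfa: np.ndarray | None = None  # ms, NaN where SFA is off

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    @property
    def excitatory_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_excitatory)

    @property
    def inhibitory_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_excitatory)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "is_excitatory": self.is_excitatory.astype(int),
            }
        )
        if self.tau_m is not None:
            df["tau_m_ms"] = self.tau_m
        if self.tau_sfa is not None:
            df["tau_sfa_ms"] = self.tau_sfa
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NeuronPopulation":
        pos = df[["x", "y", "z"]].to_numpy(dtype=np.int64)
        exc = df["is_excitatory"].to_numpy(dtype=bool)
        tau_m = df["tau_m_ms"].to_numpy() if "tau_m_ms" in df else None
        tau_sfa = df["tau_sfa_ms"].to_numpy() if "tau_sfa_ms" in df else None
        return cls(pos, exc, tau_m, tau_sfa)


# ---------------------------------------------------------------------------
# construction operations


def place_on_grid(n: int, grid: GridSpec) -> np.ndarray:
    """Assign ``n`` neurons to distinct lattice sites in raster order."""
    capacity = int(np.prod(grid.dims))
    if capacity < n:
        raise ValueError(
            f"grid too small: {n} neurons requested, {capacity} sites available"
        )
    sites = np.indices(grid.dims).reshape(3, -1).T
    return np.ascontiguousarray(sites[:n], dtype=np.int64)


def split_ei(n: int, exc_fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Label exactly round(n * exc_fraction) neurons excitatory, at random."""
    if not 0.0 <= exc_fraction <= 1.0:
        raise ValueError("exc_fraction must lie in [0, 1]")
    n_exc = int(round(n * exc_fraction))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_exc]] = True
    return labels


def connection_probability(
    d, syn_type: str, lambda_: float, C: Mapping[str, float]
) -> np.ndarray | float:
    """Distance-dependent connection probability C * exp(-(d/lambda)^2)."""
    if syn_type not in C:
        raise ValueError(f"unknown synapse type {syn_type!r}")
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    p = C[syn_type] * np.exp(-((d / lambda_) ** 2))
    return np.clip(p, 0.0, 1.0)


def sample_recurrent_weight(
    syn_type: str, spec: LiquidSpec, rng: np.random.Generator, size=None
):
    """Draw recurrent weights uniformly on [0, upper(syn_type)]."""
    if syn_type not in RECURRENT_TYPES:
        raise ValueError(f"unknown synapse type {syn_type!r}")
    upper = spec.recurrent_weight_upper[syn_type]
    return rng.uniform(0.0, upper, size=size) if upper > 0 else (
        np.zeros(size) if size is not None else 0.0
    )


def _pair_types(is_exc: np.ndarray) -> np.ndarray:
    """Ordered-pair synapse type matrix: row = pre, column = post."""
    pre = np.where(is_exc, "E", "I")
    return np.char.add(pre[:, None], pre[None, :])


def build_recurrent_synapses(
    population: NeuronPopulation,
    spec: LiquidSpec,
    rng: np.random.Generator,
    weight_rng: np.random.Generator | None = None,
) -> SynapseTable:
    """Realize every ordered pair i != j as an independent Bernoulli draw."""
    if weight_rng is None:
        weight_rng = rng
    n = population.n
    pos = population.positions.astype(np.float64)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=-1)
    prob = np.exp(-d2 / spec.lambda_**2)
    types = _pair_types(population.is_excitatory)
    cmat = np.zeros((n, n))
    for t in RECURRENT_TYPES:
        cmat[types == t] = spec.C.get(t, 0.0)
    prob = np.clip(prob * cmat, 0.0, 1.0)
    np.fill_diagonal(prob, 0.0)
    realized = rng.random((n, n)) < prob
    pre, post = np.nonzero(realized)
    syn_type = types[pre, post]
    weight = np.zeros(pre.size)
    delay = np.zeros(pre.size)
    # weights drawn in a fixed type order so draws are reproducible per seed
    for t in RECURRENT_TYPES:
        mask = syn_type == t
        if mask.any():
            weight[mask] = sample_recurrent_weight(
                t, spec, weight_rng, size=int(mask.sum())
            )
            delay[mask] = spec.delays_ms[t]
    return SynapseTable(pre, post, weight, delay, syn_type.astype(object))


def build_input_synapses(
    n_channels: int,
    population: NeuronPopulation,
    spec: LiquidSpec,
    rng: np.random.Generator,
    weight_rng: np.random.Generator | None = None,
) -> SynapseTable:
    """Give every liquid neuron ``input_in_degree`` synapses from distinct channels.

    All input synapses are excitatory-acting.  Weights onto excitatory
    targets are U[0, input_exc_weight_upper]; onto inhibitory targets the
    upper bound is scaled by ``inhib_factor``.
    """
    if weight_rng is None:
        weight_rng = rng
    k = spec.input_in_degree
    if k == 0:
        return SynapseTable.empty()
    if k > n_channels:
        raise ValueError(
            f"input_in_degree={k} exceeds the number of input channels {n_channels}"
        )
    n = population.n
    pre = np.empty(n * k, dtype=np.int64)
    for i in range(n):
        pre[i * k : (i + 1) * k] = rng.choice(n_channels, size=k, replace=False)
    post = np.repeat(np.arange(n), k)
    target_exc = population.is_excitatory[post]
    upper = np.where(
        target_exc,
        spec.input_exc_weight_upper,
        spec.inhib_factor * spec.input_exc_weight_upper,
    )
    weight = weight_rng.uniform(0.0, 1.0, size=n * k) * upper
    delay = np.full(n * k, spec.delays_ms["input"])
    syn_type = np.where(target_exc, "input-E", "input-I").astype(object)
    return SynapseTable(pre, post, weight, delay, syn_type)


def assign_time_constants(
    population: NeuronPopulation, spec: LiquidSpec, rng: np.random.Generator
) -> NeuronPopulation:
    """Set per-neuron membrane tau and (excitatory-only) SFA tau in place."""
    n = population.n
    if spec.tau_mode == "fixed":
        population.tau_m = np.full(n, spec.tau_fixed_ms)
    else:
        lo, hi = spec.tau_range_ms
        population.tau_m = rng.uniform(lo, hi, size=n)
    tau_sfa = np.full(n, np.nan)
    if spec.sfa_mode != "off":
        exc = population.excitatory_ids
        if spec.sfa_mode == "fixed":
            tau_sfa[exc] = spec.sfa_tau_ms
        else:
            lo, hi = spec.sfa_range_ms
            tau_sfa[exc] = rng.uniform(lo, hi, size=exc.size)
    population.tau_sfa = tau_sfa
    return population


def weight_upper_bounds(spec: LiquidSpec) -> dict[str, float]:
    """Sampling support upper bound per synapse type (incl. input types)."""
    uppers = dict(spec.recurrent_weight_upper)
    uppers["input-E"] = spec.input_exc_weight_upper
    uppers["input-I"] = spec.inhib_factor * spec.input_exc_weight_upper
    return uppers


def quantize_weights(
    table: SynapseTable, bits: int, uppers: Mapping[str, float]
) -> SynapseTable:
    """Round each weight to one of 2^bits uniform levels on [0, upper(type)].

    bits >= 53 exceeds double-precision mantissa resolution over these
    supports, so the table is returned unchanged (the 64-bit path).
    Idempotent: levels map to themselves.
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    if bits >= 53:
        return SynapseTable(
            table.pre.copy(),
            table.post.copy(),
            table.weight.copy(),
            table.delay_ms.copy(),
            table.syn_type.copy(),
        )
    levels = (1 << bits) - 1
    weight = table.weight.copy()
    types = table.syn_type.astype(str)
    for t in np.unique(types):
        upper = uppers[str(t)]
        mask = types == t
        if upper > 0:
            weight[mask] = np.round(weight[mask] / upper * levels) / levels * upper
        else:
            weight[mask] = 0.0
    return SynapseTable(
        table.pre.copy(), table.post.copy(), weight, table.delay_ms.copy(),
        table.syn_type.copy(),
    )


# ---------------------------------------------------------------------------
# the assembled liquid


_STREAMS = ("ei", "rec_topo", "rec_w", "in_topo", "in_w", "tau")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class Liquid:
    """A realized reservoir: population, recurrent and input synapse tables."""

    spec: LiquidSpec
    population: NeuronPopulation
    recurrent: SynapseTable
    inputs: SynapseTable
    n_channels: int
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.population.n

    def mean_recurrent_degree(self) -> float:
        """Total recurrent synapses divided by the number of neurons."""
        return self.recurrent.n / self.population.n

    def with_inhib_factor(self, factor: float) -> "Liquid":
        """Same liquid with only the input->inhibitory weight scale changed.

        Topology, delays, all recurrent weights and the input->excitatory
        weights are shared; the inhibitory-target input weights are rescaled
        by factor / current_factor.
        """
        if factor < 0:
            raise ValueError("factor must be >= 0")
        old = self.spec.inhib_factor
        if old == 0 and factor != 0:
            raise ValueError(
                "cannot rescale from inhib_factor=0; rebuild the liquid instead"
            )
        weight = self.inputs.weight.copy()
        mask = self.inputs.syn_type.astype(str) == "input-I"
        if old > 0:
            weight[mask] *= factor / old
        inputs = SynapseTable(
            self.inputs.pre.copy(), self.inputs.post.copy(), weight,
            self.inputs.delay_ms.copy(), self.inputs.syn_type.copy(),
        )
        return Liquid(
            spec=replace(self.spec, inhib_factor=factor),
            population=self.population,
            recurrent=self.recurrent,
            inputs=inputs,
            n_channels=self.n_channels,
            seed=self.seed,
        )

    def quantized(self, bits: int) -> "Liquid":
        uppers = weight_upper_bounds(self.spec)
        return Liquid(
            spec=self.spec,
            population=self.population,
            recurrent=quantize_weights(self.recurrent, bits, uppers),
            inputs=quantize_weights(self.inputs, bits, uppers),
            n_channels=self.n_channels,
            seed=self.seed,
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": self.spec.to_dict(),
            "n_channels": self.n_channels,
            "seed": self.seed,
        }
        (d / "liquid.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
        self.population.to_frame().to_csv(
            d / "population.csv", index=False, float_format="%.17g"
        )
        self.recurrent.to_csv(d / "recurrent.csv")
        self.inputs.to_csv(d / "inputs.csv")

    @classmethod
    def load(cls, directory) -> "Liquid":
        d = Path(directory)
        meta = yaml.safe_load((d / "liquid.yaml").read_text())
        return cls(
            spec=LiquidSpec.from_dict(meta["spec"]),
            population=NeuronPopulation.from_frame(
                pd.read_csv(d / "population.csv", float_precision="round_trip")
            ),
            recurrent=SynapseTable.from_csv(d / "recurrent.csv"),
            inputs=SynapseTable.from_csv(d / "inputs.csv"),
            n_channels=int(meta["n_channels"]),
            seed=int(meta["seed"]),
        )


def build_liquid(
    spec: LiquidSpec, n_channels: int, seed: int | None = None
) -> Liquid:
    """Construct a liquid from its specification, fully determined by the seed.

    Independent RNG streams are used for the E/I split, recurrent topology,
    recurrent weights, input topology, input weights and time constants, so
    e.g. changing the weight-sampling mode cannot perturb the topology.
    """
    seed = spec.seed if seed is None else int(seed)
    streams = _rng_streams(seed)
    positions = place_on_grid(spec.n_neurons, spec.grid)
    is_exc = split_ei(spec.n_neurons, spec.exc_fraction, streams["ei"])
    population = NeuronPopulation(positions, is_exc)
    recurrent = build_recurrent_synapses(
        population, spec, streams["rec_topo"], weight_rng=streams["rec_w"]
    )
    inputs = build_input_synapses(
        n_channels, population, spec, streams["in_topo"], weight_rng=streams["in_w"]
    )
    assign_time_constants(population, spec, streams["tau"])
    return Liquid(
        spec=spec,
        population=population,
        recurrent=recurrent,
        inputs=inputs,
        n_channels=n_channels,
        seed=seed,
    )
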