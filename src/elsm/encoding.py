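"""Audio-front-end spike encoding: step-forward deltas and event binning.

A cochleogram (channels x frames matrix of intensities normalized to
[0, 1]) is turned into a bipolar spike train per channel by step-forward
encoding: a running baseline b tracks the signal, and whenever the next
value exceeds b + theta (falls below b - theta) a +1 (-1) event is emitted
and the baseline moves up (down) by theta.  The bipolar trains are then
made unipolar by doubling the channel count — positive events in the first
half, negative events in the second half — which is the form the liquid
consumes.

Event streams (e.g. from event cameras / silicon cochleas) are aligned to
a fixed duration by cutting/padding and binned into binary (channel, bin)
occupancy matrices; 1 s at 4 ms bins gives 250 time steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpikeRaster


@dataclass
class Cochleogram:
    """Channels x frames intensity matrix with a fixed frame period."""

    values: np.ndarray
    frame_period_ms: float = 4.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.frame_period_ms <= 0:
            raise ValueError("frame_period_ms must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def normalized(self) -> "Cochleogram":
        """Min-max rescale the whole matrix to [0, 1] (constant -> zeros)."""
        v = self.values
        lo, hi = v.min(), v.max()
        scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        return Cochleogram(scaled, self.frame_period_ms)


@dataclass
class EncoderConfig:
    threshold: float = 0.005
    baseline_init: str = "first-sample"  # "first-sample" | "zero"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.baseline_init not in ("first-sample", "zero"):
            raise ValueError(f"unknown baseline_init {self.baseline_init!r}")


def step_forward_encode(signal: np.ndarray, config: EncoderConfig) -> np.ndarray:
    """Encode one channel into a bipolar {-1, 0, +1} sequence.

    The baseline starts at the first sample (default) or at zero; each
    emitted event moves it by +-threshold.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    theta = config.threshold
    b = signal[0] if (config.baseline_init == "first-sample" and signal.size) else 0.0
    out = np.zeros(signal.size, dtype=np.int8)
    for k, x in enumerate(signal):
        if x > b + theta:
            out[k] = 1
            b += theta
        elif x < b - theta:
            out[k] = -1
            b -= theta
    return out


def encode_cochleogram(coch: Cochleogram, config: EncoderConfig) -> np.ndarray:
    """Run the step-forward encoder independently on every channel."""
    return np.stack([step_forward_encode(row, config) for row in coch.values])


def bipolar_to_unipolar(bipolar: np.ndarray) -> np.ndarray:
    """Split signed events over doubled channels: {-1,0,+1} -> {0,1}.

    Channel c's +1 events land on output channel c, its -1 events on
    channel c + n_channels.
    """
    bipolar = np.atleast_2d(np.asarray(bipolar))
    if not np.isin(bipolar, (-1, 0, 1)).all():
        raise ValueError("bipolar input must contain only -1, 0, +1")
    return np.concatenate([(bipolar == 1), (bipolar == -1)]).astype(np.int8)


def unipolar_to_raster(unipolar: np.ndarray, frame_period_ms: float) -> SpikeRaster:
    """One spike at the frame start for every active (channel, frame) cell."""
    return SpikeRaster.from_binned(unipolar, frame_period_ms)


def align_and_bin(
    events: SpikeRaster, target_duration: float, bin_ms: float
) -> np.ndarray:
    """Cut/pad an event stream to ``target_duration`` and bin it.

    Returns a binary (n_channels, n_bins) matrix: cell (c, b) is 1 iff at
    least one event of channel c falls in [b*bin_ms, (b+1)*bin_ms).  Events
    at or after the target duration are dropped; shorter streams are padded
    with silence.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = int(np.ceil(target_duration / bin_ms))
    out = np.zeros((events.n_sources, n_bins), dtype=np.int8)
    keep = events.times < target_duration
    bins = np.floor(events.times[keep] / bin_ms).astype(np.int64)
    out[events.sources[keep], bins] = 1
    return out
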