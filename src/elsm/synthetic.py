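"""Download-free synthetic fixtures with the structure the pipeline assumes.

Class-structured spike rasters are built from one fixed random template of
(channel, time) events per class; each sample is the template with
Gaussian time jitter and independent event deletion.  This emulates the
key property of cochlear-encoded speech — each class activates a
characteristic subset of channels with a characteristic temporal profile —
without any audio front end.  Float "cochleogram-like" matrices (smoothed
random walks in [0, 1]) exercise the step-forward encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import Cochleogram
from .simulate import SpikeRaster


@dataclass
class TemplateDatasetSpec:
    """Shape and noise parameters of the synthetic classification task.

    Defaults give the demo task: 5 classes on 40 channels over 250 ms with
    ~10 events per channel per template (a density comparable to binned
    cochlear event streams), 4 ms timing jitter (one input bin) and 15%
    event deletion.
    """

    n_classes: int = 5
    n_channels: int = 40
    duration_ms: float = 250.0
    events_per_template: int = 400
    jitter_sd_ms: float = 4.0
    drop_prob: float = 0.15
    n_train_per_class: int = 20
    n_test_per_class: int = 10
    background_rate_hz: float = 0.0  # optional Poisson noise per channel
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")
        if not 0.0 <= self.drop_prob < 1.0:
            raise ValueError("drop_prob must lie in [0, 1)")
        if self.n_classes < 1 or self.n_channels < 1:
            raise ValueError("n_classes and n_channels must be positive")


@dataclass
class TemplateDataset:
    spec: TemplateDatasetSpec
    templates: list[SpikeRaster]
    train_rasters: list[SpikeRaster]
    train_labels: np.ndarray
    test_rasters: list[SpikeRaster]
    test_labels: np.ndarray


def _sample_from_template(
    template: SpikeRaster, spec: TemplateDatasetSpec, rng: np.random.Generator
) -> SpikeRaster:
    keep = rng.random(template.n_events) >= spec.drop_prob
    sources = template.sources[keep]
    times = template.times[keep]
    if spec.jitter_sd_ms > 0:
        times = times + rng.normal(0.0, spec.jitter_sd_ms, size=times.size)
        times = np.clip(times, 0.0, spec.duration_ms)
    if spec.background_rate_hz > 0:
        lam = spec.background_rate_hz * spec.duration_ms / 1000.0
        n_noise = rng.poisson(lam, size=spec.n_channels)
        noise_src = np.repeat(np.arange(spec.n_channels), n_noise)
        noise_t = rng.uniform(0.0, spec.duration_ms, size=noise_src.size)
        sources = np.concatenate([sources, noise_src])
        times = np.concatenate([times, noise_t])
    return SpikeRaster(sources, times, spec.n_channels, spec.duration_ms)


def make_template_dataset(spec: TemplateDatasetSpec) -> TemplateDataset:
    """Generate train/test rasters with labels, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    templates = []
    for _ in range(spec.n_classes):
        src = rng.integers(0, spec.n_channels, size=spec.events_per_template)
        t = rng.uniform(0.0, spec.duration_ms, size=spec.events_per_template)
        templates.append(SpikeRaster(src, t, spec.n_channels, spec.duration_ms))

    def make_split(n_per_class: int):
        rasters, labels = [], []
        for cls in range(spec.n_classes):
            for _ in range(n_per_class):
                rasters.append(_sample_from_template(templates[cls], spec, rng))
                labels.append(cls)
        return rasters, np.asarray(labels)

    train_r, train_y = make_split(spec.n_train_per_class)
    test_r, test_y = make_split(spec.n_test_per_class)
    return TemplateDataset(spec, templates, train_r, train_y, test_r, test_y)


def make_float_signals(
    n_channels: int, n_frames: int, smoothness: float, seed: int
) -> Cochleogram:
    """Smoothed random walks rescaled to [0, 1] per channel.

    ``smoothness`` is the moving-average window in frames applied to the
    walk; smoothness = 0 degenerates to constant channels (which encode to
    all-zero bipolar trains under the first-sample baseline).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    if smoothness <= 0:
        return Cochleogram(np.full((n_channels, n_frames), 0.5), frame_period_ms=4.0)
    w = max(1, int(round(smoothness)))
    steps = rng.normal(size=(n_channels, n_frames + w - 1))
    walk = np.cumsum(steps, axis=1)
    kernel = np.ones(w) / w
    smooth = np.stack([np.convolve(row, kernel, mode="valid") for row in walk])
    lo = smooth.min(axis=1, keepdims=True)
    hi = smooth.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    values = np.where(hi > lo, (smooth - lo) / span, 0.0)
    return Cochleogram(values, frame_period_ms=4.0)
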