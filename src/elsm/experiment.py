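"""End-to-end experiment driver: build -> simulate -> train -> evaluate.

The staged procedure mirrors how the extended model is assembled: first
the input-inhibitory weight factor is tuned for E/I balance, then
spike-frequency adaptation is switched on, then membrane time constants
are heterogenized, and finally the spike-count readout is trained.  The
four ablation columns (B, B+E/I, B+E/I+SFA, ELSM) are runnable as one
call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .balance import select_balanced_factor, sweep_inhib_factor
from .liquid import LiquidSpec, build_liquid
from .readout import DEFAULT_REG_GRID, evaluate, extract_features, fit_readout
from .simulate import SimulationConfig, run, spikes_per_neuron
from .synthetic import TemplateDataset, TemplateDatasetSpec, make_template_dataset

ABLATIONS = ("B", "B+E/I", "B+E/I+SFA", "ELSM")

DEFAULT_FACTOR_GRID = (0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment from a seed."""

    liquid: LiquidSpec = field(default_factory=lambda: LiquidSpec(n_neurons=500))
    dataset: TemplateDatasetSpec = field(default_factory=TemplateDatasetSpec)
    dt_ms: float = 1.0
    reg_grid: tuple[float, ...] = DEFAULT_REG_GRID
    balance_factors: tuple[float, ...] = DEFAULT_FACTOR_GRID
    balance_seeds: int = 5
    balance_probes: int = 20
    n_eval_seeds: int = 1
    quantize_bits: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "liquid": self.liquid.to_dict(),
            "dataset": self.dataset.__dict__.copy(),
            "dt_ms": self.dt_ms,
            "reg_grid": list(self.reg_grid),
            "balance_factors": list(self.balance_factors),
            "balance_seeds": self.balance_seeds,
            "balance_probes": self.balance_probes,
            "n_eval_seeds": self.n_eval_seeds,
            "quantize_bits": self.quantize_bits,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "liquid" in d:
            d["liquid"] = LiquidSpec.from_dict(d["liquid"])
        if "dataset" in d:
            d["dataset"] = TemplateDatasetSpec(**d["dataset"])
        for key in ("reg_grid", "balance_factors"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def ablation_spec(base: LiquidSpec, ablation: str, balanced_factor: float) -> LiquidSpec:
    """The liquid specification of one ablation column.

    B uses the reference factor 0.5, fixed tau, no SFA; B+E/I swaps in the
    balanced factor; B+E/I+SFA adds uniformly distributed SFA time
    constants; ELSM additionally heterogenizes the membrane tau.
    """
    if ablation == "B":
        return replace(base, inhib_factor=0.5, sfa_mode="off", tau_mode="fixed")
    if ablation == "B+E/I":
        return replace(
            base, inhib_factor=balanced_factor, sfa_mode="off", tau_mode="fixed"
        )
    if ablation == "B+E/I+SFA":
        return replace(
            base, inhib_factor=balanced_factor, sfa_mode="uniform", tau_mode="fixed"
        )
    if ablation == "ELSM":
        return replace(
            base, inhib_factor=balanced_factor, sfa_mode="uniform", tau_mode="uniform"
        )
    raise ValueError(f"unknown ablation {ablation!r}")


def evaluate_liquid_task(
    spec: LiquidSpec,
    dataset: TemplateDataset,
    dt_ms: float = 1.0,
    reg_grid: Sequence[float] = DEFAULT_REG_GRID,
    seed: int = 0,
    quantize_bits: int | None = None,
) -> dict:
    """Build one liquid, run the full classification task, report metrics.

    Returns test accuracy, train/test spikes per neuron and the selected
    regularization strength.  Simulation seeds are derived from (seed,
    sample index) so matched-seed comparisons across specs see identical
    initial conditions.
    """
    ds_spec = dataset.spec
    liquid = build_liquid(spec, ds_spec.n_channels, seed=seed)
    if quantize_bits is not None:
        liquid = liquid.quantized(quantize_bits)
    exc_ids = liquid.population.excitatory_ids
    n = liquid.n_neurons

    def featurize(rasters, offset):
        feats, spn = [], []
        for idx, raster in enumerate(rasters):
            cfg = SimulationConfig(
                dt=dt_ms,
                duration=ds_spec.duration_ms,
                seed=(seed * 4099 + offset + idx) % (2**31 - 1),
            )
            out, _ = run(liquid, raster, cfg)
            feats.append(extract_features(out, exc_ids))
            spn.append(spikes_per_neuron(out, n))
        return np.asarray(feats), float(np.mean(spn))

    X_train, spn_train = featurize(dataset.train_rasters, 0)
    X_test, spn_test = featurize(dataset.test_rasters, 10_000)
    model = fit_readout(X_train, dataset.train_labels, reg_grid=reg_grid, seed=seed)
    acc = evaluate(model, X_test, dataset.test_labels)
    return {
        "accuracy": acc,
        "train_accuracy": evaluate(model, X_train, dataset.train_labels),
        "spikes_per_neuron_train": spn_train,
        "spikes_per_neuron_test": spn_test,
        "readout_C": model.C,
        "seed": seed,
    }


def run_experiment(
    config: ExperimentConfig,
    ablations: Sequence[str] = ABLATIONS,
    out_dir=None,
    log=print,
) -> dict:
    """Run the staged experiment and return a machine-readable report."""
    stage = "dataset"
    try:
        dataset = make_template_dataset(
            replace(config.dataset, seed=config.seed)
        )
        probes = dataset.train_rasters[: config.balance_probes]

        stage = "balance-sweep"
        log(f"[elsm] stage {stage}: factors {config.balance_factors}")
        sim_cfg = SimulationConfig(
            dt=config.dt_ms, duration=config.dataset.duration_ms, record_states=True
        )
        reports = sweep_inhib_factor(
            config.liquid,
            list(config.balance_factors),
            probes,
            n_seeds=config.balance_seeds,
            config=sim_cfg,
            base_seed=config.seed,
        )
        factor = select_balanced_factor(reports)
        log(f"[elsm] selected inhibitory factor: {factor}")

        results: dict[str, dict] = {}
        for ablation in ablations:
            stage = f"evaluate:{ablation}"
            spec = ablation_spec(config.liquid, ablation, factor)
            per_seed = []
            for s in range(config.n_eval_seeds):
                metrics = evaluate_liquid_task(
                    spec,
                    dataset,
                    dt_ms=config.dt_ms,
                    reg_grid=config.reg_grid,
                    seed=config.seed + s,
                    quantize_bits=config.quantize_bits,
                )
                per_seed.append(metrics)
            results[ablation] = {
                "accuracy_mean": float(np.mean([m["accuracy"] for m in per_seed])),
                "spikes_per_neuron_mean": float(
                    np.mean([m["spikes_per_neuron_test"] for m in per_seed])
                ),
                "per_seed": per_seed,
            }
            log(
                f"[elsm] {ablation}: accuracy "
                f"{results[ablation]['accuracy_mean']:.3f}, spikes/neuron "
                f"{results[ablation]['spikes_per_neuron_mean']:.2f}"
            )

        report = {
            "selected_factor": factor,
            "balance_reports": [r.__dict__ for r in reports],
            "results": results,
            "seed": config.seed,
            "n_eval_seeds": config.n_eval_seeds,
            "config": config.to_dict(),
        }
    except Exception as exc:  # noqa: BLE001 - name the failing stage
        raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        rows = [
            {
                "ablation": name,
                "accuracy": res["accuracy_mean"],
                "spikes_per_neuron": res["spikes_per_neuron_mean"],
            }
            for name, res in report["results"].items()
        ]
        pd.DataFrame(rows).to_csv(out / "report.csv", index=False)
    return report
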