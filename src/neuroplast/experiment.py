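"""Orchestration: configure, run, and report degeneration experiments.

The public surface follows the model/results convention: a
:class:`DegenerationExperiment` is built from data and configuration, its
:meth:`~DegenerationExperiment.fit` trains the healthy baseline (optionally
compresses it), runs the injury-retraining loop over replicate seeds, and
returns a :class:`DegenerationResults` carrying the per-iteration records,
summary tables in the odd-iteration layout (columns labelled by cumulative
injury percent), plotting, and serialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .compression import CompressionPlan, compress_to_speedup
from .injury import InjurySchedule, cumulative_injured_fraction
from .model_core import NetworkSpec, TrainingConfig, build_network, train
from .plasticity import ExperimentResult, ReadoutConfig, run_degeneration_experiment
from .predictivity import PredictivityConfig
from .synthetic import StimulusDataset, StimulusSpec, generate_dataset

__all__ = [
    "RunConfig",
    "DegenerationExperiment",
    "DegenerationResults",
    "summarize",
    "injury_percent_labels",
]


def injury_percent_labels(gamma: float, iterations) -> list[float]:
    """Cumulative injury percentages (1 dp) for the given iterations."""
    return [round(100 * cumulative_injured_fraction(gamma, n), 1) for n in iterations]


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one experiment run."""

    stimulus_spec: StimulusSpec = field(default_factory=StimulusSpec)
    network_spec: NetworkSpec = field(default_factory=NetworkSpec.desk_scale)
    schedule: InjurySchedule = field(default_factory=InjurySchedule)
    baseline_config: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(epochs=30)
    )
    retrain_config: TrainingConfig = field(default_factory=TrainingConfig)
    readout: ReadoutConfig = field(default_factory=ReadoutConfig)
    compress_target: float | None = None
    seeds: tuple[int, ...] = (0, 1, 2)
    build_seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        d = {
            "stimulus_spec": asdict(self.stimulus_spec),
            "network_spec": self.network_spec.to_dict(),
            "schedule": asdict(self.schedule),
            "baseline_config": asdict(self.baseline_config),
            "retrain_config": asdict(self.retrain_config),
            "readout": asdict(self.readout),
            "compress_target": self.compress_target,
            "seeds": list(self.seeds),
            "build_seed": self.build_seed,
            "output_dir": self.output_dir,
        }
        if d["readout"].get("regions") is not None:
            d["readout"]["regions"] = list(d["readout"]["regions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        readout = dict(d.get("readout", {}))
        if "predictivity_config" in readout:
            readout["predictivity_config"] = PredictivityConfig(
                **readout["predictivity_config"]
            )
        if readout.get("regions") is not None:
            readout["regions"] = tuple(readout["regions"])
        return cls(
            stimulus_spec=StimulusSpec(**d.get("stimulus_spec", {})),
            network_spec=NetworkSpec.from_dict(d["network_spec"])
            if "network_spec" in d else NetworkSpec.desk_scale(),
            schedule=InjurySchedule(**d.get("schedule", {})),
            baseline_config=TrainingConfig(**d.get("baseline_config", {})),
            retrain_config=TrainingConfig(**d.get("retrain_config", {})),
            readout=ReadoutConfig(**readout),
            compress_target=d.get("compress_target"),
            seeds=tuple(d.get("seeds", (0, 1, 2))),
            build_seed=d.get("build_seed", 0),
            output_dir=d.get("output_dir", "results"),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class DegenerationExperiment:
    """In-silico neurodegeneration-with-neuroplasticity experiment (the model).

    Parameters
    ----------
    dataset : StimulusDataset
        Labeled train/test image sets; typically from
        :func:`neuroplast.generate_dataset`.
    network_spec : NetworkSpec, optional
        Architecture of the healthy baseline (default: desk-scale 3-block CNN).
    schedule : InjurySchedule, optional
        Ablation rate and iteration count (default gamma=0.2, n=15).
    baseline_config, retrain_config : TrainingConfig, optional
        Baseline training and per-iteration retraining protocols; retraining
        defaults to the standard 3-epoch budget.
    readout : ReadoutConfig, optional
        Per-iteration representational readouts (RDM tau, predictivity).
    compress_target : float, optional
        If given, the trained baseline is structurally pruned to this FLOP
        speedup (and fine-tuned) before injury begins.
    """

    def __init__(self, dataset: StimulusDataset,
                 network_spec: NetworkSpec | None = None,
                 schedule: InjurySchedule | None = None,
                 baseline_config: TrainingConfig | None = None,
                 retrain_config: TrainingConfig | None = None,
                 readout: ReadoutConfig | None = None,
                 compress_target: float | None = None,
                 finetune_config: TrainingConfig | None = None,
                 build_seed: int = 0):
        n_classes = dataset.train.n_classes
        self.dataset = dataset
        self.network_spec = network_spec or NetworkSpec.desk_scale(
            n_classes=n_classes, input_shape=dataset.train.images.shape[1:]
        )
        if self.network_spec.n_classes != n_classes:
            raise ValueError(
                f"network spec has {self.network_spec.n_classes} classes but the "
                f"dataset has {n_classes}"
            )
        self.schedule = schedule or InjurySchedule()
        self.baseline_config = baseline_config or TrainingConfig(epochs=30)
        self.retrain_config = retrain_config or TrainingConfig()
        self.readout = readout or ReadoutConfig()
        self.compress_target = compress_target
        self.finetune_config = finetune_config
        self.build_seed = build_seed

    @classmethod
    def from_config(cls, config: RunConfig,
                    dataset: StimulusDataset | None = None) -> "DegenerationExperiment":
        dataset = dataset or generate_dataset(config.stimulus_spec)
        return cls(
            dataset=dataset,
            network_spec=config.network_spec,
            schedule=config.schedule,
            baseline_config=config.baseline_config,
            retrain_config=config.retrain_config,
            readout=config.readout,
            compress_target=config.compress_target,
            build_seed=config.build_seed,
        )

    def fit(self, seeds: tuple[int, ...] = (0, 1, 2),
            baseline_network=None) -> "DegenerationResults":
        """Train (or adopt) the baseline, optionally compress, run the loop."""
        plan: CompressionPlan | None = None
        if baseline_network is None:
            network = build_network(self.network_spec, seed=self.build_seed)
            baseline_history = train(network, self.dataset.train, self.baseline_config)
        else:
            network = baseline_network
            baseline_history = []
        if self.compress_target is not None:
            network, plan = compress_to_speedup(
                network, self.compress_target,
                finetune_config=self.finetune_config, dataset=self.dataset,
            )
        result = run_degeneration_experiment(
            network, self.schedule, self.dataset, self.retrain_config,
            readout=self.readout, seeds=tuple(seeds),
        )
        return DegenerationResults(
            model=self, result=result, network=network,
            baseline_history=baseline_history, compression_plan=plan,
        )


class DegenerationResults:
    """Fitted results: per-iteration records, summaries, plots, serialization."""

    def __init__(self, model: DegenerationExperiment, result: ExperimentResult,
                 network, baseline_history: list[dict],
                 compression_plan: CompressionPlan | None = None):
        self.model = model
        self.result = result
        self.network = network
        self.baseline_history = baseline_history
        self.compression_plan = compression_plan

    # -- tabular views --------------------------------------------------
    @property
    def records(self) -> pd.DataFrame:
        """Tidy per-record frame: replicate, iteration, injured_fraction,
        metric, phase, value."""
        return self.result.to_dataframe()

    @property
    def baseline_accuracy(self) -> float:
        return self.result.baseline_accuracy

    def summary_frame(self) -> pd.DataFrame:
        """Mean and sd across replicates per iteration, metric, and phase."""
        df = self.records
        out = (
            df.groupby(["metric", "phase", "iteration"], sort=True)["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"std": "sd", "count": "n_replicates"})
        )
        out["sd"] = out["sd"].fillna(0.0)
        out["injury_percent"] = [
            round(100 * cumulative_injured_fraction(self.result.schedule.gamma, n), 1)
            for n in out["iteration"]
        ]
        return out

    def summary(self, iterations: tuple[int, ...] | None = None) -> pd.DataFrame:
        """Report table: rows (metric, phase), columns labelled by cumulative
        injury percent.  Defaults to iteration 0 plus odd iterations
        (1, 3, ..., n), the conventional reporting layout."""
        n = self.result.schedule.n_iterations
        if iterations is None:
            iterations = (0,) + tuple(range(1, n + 1, 2))
        sf = self.summary_frame()
        sf = sf[sf["iteration"].isin(iterations)]
        cells = {}
        for (metric, phase), group in sf.groupby(["metric", "phase"]):
            row = {}
            for _, r in group.iterrows():
                label = ("0% (healthy)" if r["iteration"] == 0
                         else f"{r['injury_percent']:g}%")
                row[label] = f"{r['mean']:.3f} (±{r['sd']:.3f})"
            cells[(metric, phase)] = row
        labels = ["0% (healthy)"] + [
            f"{p:g}%" for p in injury_percent_labels(
                self.result.schedule.gamma, [i for i in iterations if i > 0]
            )
        ]
        table = pd.DataFrame(cells).T
        table = table.reindex(columns=[l for l in labels if l in table.columns])
        table.index.names = ["metric", "phase"]
        return table

    # -- plotting -------------------------------------------------------
    def plot_decline(self, metric: str = "accuracy", ax=None):
        """Mean ± sd decline-and-recovery curves vs cumulative injury percent."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        sf = self.summary_frame()
        sf = sf[sf["metric"] == metric]
        for phase, style in (("injured", "o--"), ("retrained", "s-")):
            g = sf[sf["phase"] == phase].sort_values("iteration")
            ax.errorbar(g["injury_percent"], g["mean"], yerr=g["sd"],
                        fmt=style, capsize=3, label=phase)
        ax.set_xlabel("cumulative injured synapses (%)")
        ax.set_ylabel(metric)
        ax.legend()
        return ax

    # -- serialization --------------------------------------------------
    def manifest(self) -> dict:
        gamma = self.result.schedule.gamma
        return {
            "package_version": _pkg_version,
            "schedule": asdict(self.result.schedule),
            "seeds": list(self.result.seeds),
            "build_seed": self.model.build_seed,
            "retrain_config": asdict(self.result.retrain_config),
            "baseline_config": asdict(self.model.baseline_config),
            "stimulus_spec": asdict(self.model.dataset.spec),
            "network_spec": self.model.network_spec.to_dict(),
            "compress_target": self.model.compress_target,
            "compression": None if self.compression_plan is None else {
                "target": self.compression_plan.target,
                "achieved": self.compression_plan.achieved,
                "n_removed": self.compression_plan.n_removed,
            },
            "baseline_accuracy": self.baseline_accuracy,
            "injury_percent_labels": injury_percent_labels(
                gamma, range(1, self.result.schedule.n_iterations + 1)
            ),
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "results": outdir / "results.csv",
            "summary": outdir / "summary.csv",
            "manifest": outdir / "manifest.json",
        }
        self.records.to_csv(paths["results"], index=False)
        self.summary_frame().to_csv(paths["summary"], index=False)
        paths["manifest"].write_text(json.dumps(self.manifest(), indent=2))
        return paths


def summarize(results) -> pd.DataFrame:
    """Per-iteration mean ± sd across replicates for one or more results.

    Accepts an :class:`ExperimentResult`, a :class:`DegenerationResults`, or a
    list of either; multiple results must share the same injury schedule
    (mixed schedules are rejected because their iteration axes differ in
    meaning).  Returns a long frame with columns iteration, injury_percent,
    metric, phase, mean, sd, n_replicates.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    unwrapped = [r.result if isinstance(r, DegenerationResults) else r
                 for r in results]
    schedules = {(r.schedule.gamma, r.schedule.n_iterations) for r in unwrapped}
    if len(schedules) > 1:
        raise ValueError(f"mixed injury schedules: {sorted(schedules)}")
    gamma = unwrapped[0].schedule.gamma
    frames = []
    for rep_offset, res in enumerate(unwrapped):
        df = res.to_dataframe()
        df["replicate"] = df["replicate"].astype(str) + f"_run{rep_offset}"
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    out = (
        df.groupby(["metric", "phase", "iteration"], sort=True)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"std": "sd", "count": "n_replicates"})
    )
    out["sd"] = out["sd"].fillna(0.0)
    out["injury_percent"] = [
        round(100 * cumulative_injured_fraction(gamma, n), 1)
        for n in out["iteration"]
    ]
    return out
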