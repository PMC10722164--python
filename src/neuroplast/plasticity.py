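"""Neuroplasticity via constrained retraining, and the degeneration loop.

After each injury step the surviving weights are retrained on the original
training split with a freshly initialized optimizer while dead synapses stay
pinned at exactly zero.  :func:`run_degeneration_experiment` interleaves
injury, evaluation, and retraining over a schedule, repeating the whole
trajectory from the same healthy baseline for several replicate seeds so the
only varying factor is the random order in which synapses die.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._engine import Sequential
from .injury import AblationMask, InjurySchedule, apply_injury_step, apply_mask
from .model_core import (
    TrainingConfig,
    evaluate_accuracy,
    extract_activations,
    train,
)
from .predictivity import PredictivityConfig, composite_score, neural_predictivity
from .rdm import compare_rdms, compute_rdm
from .synthetic import RecordingsMatrix, generate_recordings

__all__ = [
    "IterationRecord",
    "ExperimentResult",
    "ReadoutConfig",
    "retrain",
    "run_degeneration_experiment",
]


@dataclass
class IterationRecord:
    """Quantities measured at one injury iteration (pre- and post-retraining)."""

    iteration: int
    injured_fraction: float
    accuracy_injured: float
    accuracy_retrained: float
    rdm_tau_injured: float | None = None
    rdm_tau_retrained: float | None = None
    predictivity_injured: float | None = None
    predictivity_retrained: float | None = None


@dataclass(frozen=True)
class ReadoutConfig:
    """Which readouts to compute each iteration, and their parameters.

    RDMs are computed on a fixed class-stratified subsample of the test set
    (``rdm_stimuli_per_class`` per class) and compared to the healthy
    baseline's RDM by Kendall's tau.  Predictivity regions default to every
    pooling stage plus the penultimate layer; each region's synthetic
    recordings are a fixed noisy linear readout of the *healthy* network's
    activations there, so recovery of predictivity means recovery of the
    healthy representational basis.
    """

    rdm: bool = True
    rdm_stimuli_per_class: int = 20
    predictivity: bool = False
    regions: tuple[str, ...] | None = None
    n_neurons: int = 50
    recording_noise_sd: float = 0.1
    predictivity_config: PredictivityConfig = field(default_factory=PredictivityConfig)
    seed: int = 0


@dataclass
class ExperimentResult:
    """Per-replicate, per-iteration records of a degeneration experiment."""

    baseline: IterationRecord
    replicates: list[list[IterationRecord]]
    seeds: tuple[int, ...]
    schedule: InjurySchedule
    retrain_config: TrainingConfig
    readout_config: ReadoutConfig

    def __post_init__(self):
        for rep in self.replicates:
            fractions = [r.injured_fraction for r in rep]
            if any(b < a - 1e-12 for a, b in zip(fractions, fractions[1:])):
                raise ValueError("injured fraction must be non-decreasing")

    @property
    def baseline_accuracy(self) -> float:
        return self.baseline.accuracy_retrained

    def to_dataframe(self):
        """Tidy frame: replicate, iteration, injured_fraction, metric, phase, value."""
        import pandas as pd

        metrics = {
            "accuracy": ("accuracy_injured", "accuracy_retrained"),
            "rdm_tau": ("rdm_tau_injured", "rdm_tau_retrained"),
            "predictivity": ("predictivity_injured", "predictivity_retrained"),
        }
        rows = []
        for rep_idx, records in enumerate(self.replicates):
            for rec in [self.baseline] + records:
                for metric, (inj_attr, ret_attr) in metrics.items():
                    for phase, attr in (("injured", inj_attr), ("retrained", ret_attr)):
                        value = getattr(rec, attr)
                        if value is None:
                            continue
                        rows.append({
                            "replicate": rep_idx,
                            "iteration": rec.iteration,
                            "injured_fraction": rec.injured_fraction,
                            "metric": metric,
                            "phase": phase,
                            "value": value,
                        })
        return pd.DataFrame(rows)

    def metric_array(self, metric: str, phase: str) -> np.ndarray:
        """(n_replicates, n_iterations) array for one metric/phase."""
        attr = f"{metric}_{phase}"
        return np.array(
            [[getattr(rec, attr) for rec in records] for records in self.replicates],
            dtype=float,
        )


def retrain(network: Sequential, mask: AblationMask, dataset,
            config: TrainingConfig) -> Sequential:
    """Retrain surviving weights; dead synapses stay exactly zero throughout.

    The optimizer is created fresh (no momentum carried over from any earlier
    training), gradients at masked coordinates are zeroed before each update,
    and masked weights are re-forced to zero after each update — the two-sided
    pin defeats leakage through any optimizer state.
    """
    mask.validate_against(network)
    for layer in network.weight_layers():
        masked = layer.params["W"][mask.masks[layer.name]]
        if masked.size and np.abs(masked).max() != 0.0:
            raise ValueError(
                f"mask not applied: layer {layer.name!r} has nonzero masked weights"
            )
    train(network, dataset, config, mask=mask)
    return network


def _assert_pinned(network: Sequential, mask: AblationMask) -> None:
    for layer in network.weight_layers():
        m = mask.masks[layer.name]
        if m.any() and np.abs(layer.params["W"][m]).max() != 0.0:
            raise AssertionError(f"masked weights drifted in layer {layer.name!r}")


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


class _ReadoutState:
    """Fixed stimulus subset, healthy-baseline RDM, and synthetic recordings."""

    def __init__(self, network: Sequential, dataset, readout: ReadoutConfig):
        self.readout = readout
        self.stimuli = dataset.test.subsample_per_class(
            readout.rdm_stimuli_per_class, seed=readout.seed
        )
        self.healthy_rdm = None
        self.recordings: dict[str, RecordingsMatrix] = {}
        if readout.rdm:
            acts = extract_activations(network, self.stimuli, "penultimate")
            self.healthy_rdm = compute_rdm(acts, condition="healthy")
        if readout.predictivity:
            regions = readout.regions
            if regions is None:
                pools = [l.name for l in network.layers
                         if type(l).__name__ == "MaxPool2d"]
                regions = tuple(pools) + ("penultimate",)
            for i, layer_name in enumerate(regions):
                acts = extract_activations(network, self.stimuli, layer_name)
                self.recordings[layer_name] = generate_recordings(
                    acts,
                    n_neurons=readout.n_neurons,
                    noise_sd=readout.recording_noise_sd,
                    seed=_derived_seed(readout.seed, 0xEC, i),
                    region_label=layer_name,
                )

    def measure(self, network: Sequential, condition: str):
        tau, pred = None, None
        if self.healthy_rdm is not None:
            acts = extract_activations(network, self.stimuli, "penultimate")
            tau = compare_rdms(self.healthy_rdm, compute_rdm(acts, condition))
        if self.recordings:
            scores = {}
            for layer_name, rec in self.recordings.items():
                acts = extract_activations(network, self.stimuli, layer_name)
                scores[layer_name] = neural_predictivity(
                    acts, rec, self.readout.predictivity_config
                )
            pred = composite_score(scores).score
        return tau, pred


def run_degeneration_experiment(network: Sequential, schedule: InjurySchedule,
                                dataset, retrain_config: TrainingConfig,
                                readout: ReadoutConfig | None = None,
                                seeds: tuple[int, ...] = (0, 1, 2),
                                rounding: str = "nearest") -> ExperimentResult:
    """Progressive injury with retraining, replicated over ablation-order seeds.

    For each replicate the pristine baseline weights are restored, then for
    each of ``schedule.n_iterations`` steps: one injury step is drawn and
    imprinted, the *injured* state is evaluated (accuracy and any configured
    readouts) before any retraining gradient, the surviving weights are
    retrained for ``retrain_config.epochs`` epochs, and the *retrained* state
    is evaluated.  Injury randomness uses a dedicated stream per replicate,
    independent of training randomness.  The run is fully determined by
    ``seeds``; the baseline state is restored on exit.
    """
    readout = readout or ReadoutConfig(rdm=False)
    baseline_state = network.state_dict()
    state = _ReadoutState(network, dataset, readout) \
        if (readout.rdm or readout.predictivity) else None

    baseline_acc = evaluate_accuracy(network, dataset.test)
    tau0, pred0 = state.measure(network, "healthy") if state else (None, None)
    baseline_record = IterationRecord(
        iteration=0, injured_fraction=0.0,
        accuracy_injured=baseline_acc, accuracy_retrained=baseline_acc,
        rdm_tau_injured=tau0, rdm_tau_retrained=tau0,
        predictivity_injured=pred0, predictivity_retrained=pred0,
    )

    replicates: list[list[IterationRecord]] = []
    try:
        for seed in seeds:
            network.load_state_dict(baseline_state)
            mask = AblationMask.empty_for(network, seed=seed)
            injury_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 0x1A7])
            )
            records: list[IterationRecord] = []
            for it in range(1, schedule.n_iterations + 1):
                try:
                    mask = apply_injury_step(mask, schedule.gamma, injury_rng,
                                             rounding=rounding)
                    apply_mask(network, mask)
                    acc_inj = evaluate_accuracy(network, dataset.test)
                    tau_inj, pred_inj = state.measure(network, f"injured@{it}") \
                        if state else (None, None)
                    cfg = replace(retrain_config, seed=_derived_seed(seed, it, 0x7E))
                    retrain(network, mask, dataset.train, cfg)
                    _assert_pinned(network, mask)
                    acc_ret = evaluate_accuracy(network, dataset.test)
                    tau_ret, pred_ret = state.measure(network, f"retrained@{it}") \
                        if state else (None, None)
                except Exception as exc:
                    raise RuntimeError(
                        f"degeneration experiment failed at replicate seed {seed}, "
                        f"iteration {it}: {exc}"
                    ) from exc
                records.append(IterationRecord(
                    iteration=it,
                    injured_fraction=mask.injured_fraction,
                    accuracy_injured=acc_inj,
                    accuracy_retrained=acc_ret,
                    rdm_tau_injured=tau_inj,
                    rdm_tau_retrained=tau_ret,
                    predictivity_injured=pred_inj,
                    predictivity_retrained=pred_ret,
                ))
            replicates.append(records)
    finally:
        network.load_state_dict(baseline_state)

    return ExperimentResult(
        baseline=baseline_record,
        replicates=replicates,
        seeds=tuple(int(s) for s in seeds),
        schedule=schedule,
        retrain_config=retrain_config,
        readout_config=readout,
    )
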