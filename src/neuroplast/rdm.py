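"""Representational dissimilarity analysis.

An RDM is a stimulus x stimulus matrix of ``1 - Pearson(r_i, r_j)`` between
activation vectors; representational change across conditions (healthy,
injured, retrained) is quantified by Kendall's tau-b between the strictly
upper-triangular entries of two RDMs over the same stimulus set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_core import ActivationMatrix

__all__ = ["RDM", "compute_rdm", "compare_rdms", "rdm_trajectory",
           "class_block_contrast"]


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with zero diagonal, entries in [0, 2]."""

    values: np.ndarray
    labels: np.ndarray | None = None
    condition: str = ""
    stimulus_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RDM must be square")
        self.values = v

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        """Strictly upper-triangular entries, row-major."""
        iu = np.triu_indices(self.n_stimuli, k=1)
        return self.values[iu]


def compute_rdm(activations: ActivationMatrix, condition: str = "") -> RDM:
    """Pairwise ``1 - Pearson`` dissimilarity between activation rows.

    A constant activation row makes Pearson undefined; such pairs are
    assigned dissimilarity 1 (no evidence of similarity) and a warning is
    emitted.  Entries are clipped to [0, 2] against floating-point overshoot;
    the diagonal is exactly zero.
    """
    v = np.asarray(activations.values, dtype=np.float64)
    if v.shape[0] < 2:
        raise ValueError("need at least 2 stimuli to form an RDM")
    sd = v.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(v)
    d = 1.0 - corr
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant activation row(s); "
            "their dissimilarities set to 1"
        )
        d[constant, :] = 1.0
        d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry
    return RDM(
        values=d,
        labels=None if activations.labels is None else np.asarray(activations.labels),
        condition=condition,
        stimulus_ids=list(activations.stimulus_ids),
    )


def compare_rdms(a: RDM, b: RDM) -> float:
    """Kendall's tau-b between the upper triangles of two aligned RDMs."""
    if a.n_stimuli != b.n_stimuli:
        raise ValueError(
            f"RDMs cover different stimulus counts: {a.n_stimuli} vs {b.n_stimuli}"
        )
    if a.labels is not None and b.labels is not None:
        if not np.array_equal(a.labels, b.labels):
            raise ValueError("RDM stimulus labels do not match")
    if a.stimulus_ids and b.stimulus_ids and a.stimulus_ids != b.stimulus_ids:
        raise ValueError("RDM stimulus identifiers do not match")
    tau = stats.kendalltau(a.upper(), b.upper()).statistic
    return float(tau)


def rdm_trajectory(result) -> "pd.DataFrame":
    """Per-iteration (tau_injured, tau_retrained) vs the healthy baseline.

    Accepts an ``ExperimentResult`` whose records carry RDM readouts and
    returns a tidy frame (replicate, iteration, injured_fraction,
    tau_injured, tau_retrained).
    """
    import pandas as pd

    rows = []
    for rep, records in enumerate(result.replicates):
        for rec in [result.baseline] + records:
            if rec.rdm_tau_injured is None:
                continue
            rows.append({
                "replicate": rep,
                "iteration": rec.iteration,
                "injured_fraction": rec.injured_fraction,
                "tau_injured": rec.rdm_tau_injured,
                "tau_retrained": rec.rdm_tau_retrained,
            })
    return pd.DataFrame(rows)


def class_block_contrast(rdm: RDM) -> tuple[float, float]:
    """(mean within-class, mean between-class) dissimilarity.

    A trained network groups same-class stimuli: within < between.
    """
    if rdm.labels is None:
        raise ValueError("RDM has no stimulus labels")
    labels = np.asarray(rdm.labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(rdm.n_stimuli, k=1)
    upper_same = same[iu]
    upper_vals = rdm.values[iu]
    return float(upper_vals[upper_same].mean()), float(upper_vals[~upper_same].mean())
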