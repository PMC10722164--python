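"""Neural predictivity: how well model activations linearly predict recordings.

The score follows the standard benchmark recipe: reduce activations by PCA
(default 1,000 components, capped by the data), regress onto the recorded
responses with partial least squares (default 25 components), and measure
per-neuron Pearson correlation on held-out stimuli.  Neurons are aggregated
by the median, splits by the mean; regional scores average into a composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning

from .model_core import ActivationMatrix
from .synthetic import RecordingsMatrix

__all__ = ["PredictivityConfig", "PredictivityScore", "neural_predictivity",
           "composite_score"]


@dataclass(frozen=True)
class PredictivityConfig:
    """Cross-validated PCA+PLS pipeline parameters.

    ``n_pca_components``/``n_pls_components`` default to the benchmark
    convention (1000 / 25); both are automatically capped by the available
    stimuli and features.  ``n_splits`` random train/test splits at
    ``train_fraction`` are averaged.
    """

    n_pca_components: int = 1000
    n_pls_components: int = 25
    n_splits: int = 10
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_pca_components < 1 or self.n_pls_components < 1:
            raise ValueError("component counts must be >= 1")
        if self.n_splits < 2:
            raise ValueError(f"n_splits must be >= 2, got {self.n_splits}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class PredictivityScore:
    """Score in [-1, 1]; ``per_region`` is populated for composites."""

    score: float
    region_label: str = ""
    per_split: np.ndarray | None = None
    per_region: dict[str, float] = field(default_factory=dict)

    @property
    def dispersion(self) -> float:
        """Standard deviation over splits (0 if unavailable)."""
        if self.per_split is None or len(self.per_split) < 2:
            return 0.0
        return float(np.std(self.per_split, ddof=1))


def _pearson_rows(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; zero-variance columns score 0."""
    pc = pred - pred.mean(axis=0)
    tc = true - true.mean(axis=0)
    ps = np.sqrt((pc**2).sum(axis=0))
    ts = np.sqrt((tc**2).sum(axis=0))
    denom = ps * ts
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc * tc).sum(axis=0) / denom
    r[~np.isfinite(r)] = 0.0
    return np.clip(r, -1.0, 1.0)


def neural_predictivity(activations: ActivationMatrix,
                        recordings: RecordingsMatrix,
                        config: PredictivityConfig = PredictivityConfig(),
                        ) -> PredictivityScore:
    """Cross-validated linear predictivity of one region's recordings.

    Per split: PCA is fit on the training stimuli's activations and reduces
    them to ``min(n_pca, features, train_count - 1)`` components; PLS with
    ``n_pls`` components maps reduced activations to recordings; per-neuron
    Pearson correlation on the held-out stimuli is aggregated by the median;
    split scores are averaged.  Component counts exceeding the data are
    capped (with a warning when the cap bites hard is unnecessary — capping
    is part of the contract).
    """
    x = np.asarray(activations.values, dtype=np.float64)
    y = np.asarray(recordings.values, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"stimulus misalignment: {x.shape[0]} activation rows vs "
            f"{y.shape[0]} recording rows"
        )
    n = x.shape[0]
    n_train = int(round(config.train_fraction * n))
    n_train = min(max(n_train, 2), n - 1)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xB5]))
    split_scores = np.empty(config.n_splits)
    for s in range(config.n_splits):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        # z-score each neuron on the training split: makes the score exactly
        # invariant to per-neuron affine rescaling of the recordings
        mu = y[tr].mean(axis=0)
        sd = y[tr].std(axis=0)
        sd[sd == 0] = 1.0
        y_z = (y - mu) / sd
        n_pca = min(config.n_pca_components, x.shape[1], n_train - 1)
        pca = PCA(n_components=n_pca, svd_solver="randomized", random_state=0)
        xtr = pca.fit_transform(x[tr])
        xte = pca.transform(x[te])
        n_pls = min(config.n_pls_components, n_pca, n_train - 1)
        pls = PLSRegression(n_components=n_pls, scale=False)
        with warnings.catch_warnings():
            # NIPALS hitting max_iter on near-degenerate splits is benign here
            warnings.simplefilter("ignore", ConvergenceWarning)
            pls.fit(xtr, y_z[tr])
        pred = pls.predict(xte)
        split_scores[s] = float(np.median(_pearson_rows(pred, y[te])))
    return PredictivityScore(
        score=float(split_scores.mean()),
        region_label=recordings.region_label,
        per_split=split_scores,
    )


def composite_score(scores: "dict[str, PredictivityScore] | list[PredictivityScore]",
                    ) -> PredictivityScore:
    """Arithmetic mean of per-region scores with propagated dispersion."""
    if isinstance(scores, dict):
        items = list(scores.items())
    else:
        items = [(s.region_label or f"region{i}", s) for i, s in enumerate(scores)]
    if not items:
        raise ValueError("composite_score requires at least one region")
    per_region = {name: s.score for name, s in items}
    splits = [s.per_split for _, s in items if s.per_split is not None]
    per_split = None
    if splits and all(len(sp) == len(splits[0]) for sp in splits):
        per_split = np.mean(np.stack(splits), axis=0)
    return PredictivityScore(
        score=float(np.mean(list(per_region.values()))),
        region_label="composite",
        per_split=per_split,
        per_region=per_region,
    )
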