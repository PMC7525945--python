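"""Feature-importance via correlation-grouped leave-one-out ablation.

Highly correlated features hide each other's importance: remove one and
its correlate compensates.  The procedure therefore (1) computes the
pairwise Pearson correlation matrix of the 89 features, (2) groups every
pair with |r| above a threshold (0.9 by default) into a single ablation
unit, merging overlapping pairs transitively, and (3) measures, for each
unit, the drop in mean test-fold AUC when the unit's features are removed
and the model retrained with reduced input width — under a seeded,
class-stratified 5-fold cross-validation whose folds are identical for
the baseline and every ablated run (a paired comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import mlp
from .datasets import Standardizer
from .errors import ConfigurationError, InvalidInputError
from .evaluation import roc_auc

log = logging.getLogger(__name__)

CORRELATION_THRESHOLD = 0.9


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with its feature names."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    constant_features: tuple[str, ...] = ()

    def lookup(self, a: str, b: str) -> float:
        i = self.feature_names.index(a)
        j = self.feature_names.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class AblationResult:
    unit: tuple[str, ...]
    baseline_auc: float
    ablated_auc: float

    @property
    def delta(self) -> float:
        """AUC drop; positive means removing the unit hurt."""
        return self.baseline_auc - self.ablated_auc


def correlation_matrix(features: np.ndarray, feature_names) -> CorrelationMatrix:
    """Pairwise Pearson correlations; constants correlate 0 and are flagged."""
    x = np.asarray(features, dtype=float)
    if x.shape[0] < 3:
        raise InvalidInputError(
            f"correlation needs at least 3 records, got {x.shape[0]}"
        )
    names = tuple(feature_names)
    if x.shape[1] != len(names):
        raise InvalidInputError("feature name count does not match matrix width")
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        flagged = tuple(n for n, c in zip(names, constant) if c)
        log.warning("constant features, correlations set to 0: %s", flagged)
    else:
        flagged = ()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.where(np.isnan(corr), 0.0, corr)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, names, flagged)


def correlated_units(
    matrix: CorrelationMatrix, threshold: float = CORRELATION_THRESHOLD
) -> list[tuple[str, ...]]:
    """Partition features into ablation units by |r| > threshold pairing.

    Qualifying pairs sharing a feature are merged transitively (union-
    find), so units are disjoint; everything else is a singleton unit.
    """
    names = matrix.feature_names
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    abs_corr = np.abs(matrix.values)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs_corr[i, j] > threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(find(i), []).append(name)
    # units in layout order of their first member
    return [tuple(members) for _, members in sorted(
        groups.items(), key=lambda kv: names.index(kv[1][0])
    )]


def _cv_auc(
    x: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    config: mlp.ModelConfig,
) -> float:
    """Mean test-fold AUC over pre-computed folds.

    Each fold's training block is sub-split 90/10 into the actual training
    set and the early-stopping validation set.
    """
    aucs = []
    for k, (train_idx, test_idx) in enumerate(folds):
        rng = np.random.default_rng(config.seed + k)
        order = rng.permutation(train_idx)
        n_val = max(1, len(order) // 10)
        val_idx, fit_idx = order[:n_val], order[n_val:]
        scaler = Standardizer().fit(x[fit_idx])
        cfg = mlp.ModelConfig(**{**config.__dict__, "input_dim": x.shape[1]})
        model = mlp.train(
            mlp.build_model(cfg),
            scaler.transform(x[fit_idx]), y[fit_idx],
            scaler.transform(x[val_idx]), y[val_idx],
        )
        probs = mlp.predict_proba(model, scaler.transform(x[test_idx]))
        _, auc_value = roc_auc(probs, y[test_idx])
        aucs.append(auc_value)
    return float(np.mean(aucs))


def ablation_study(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names,
    units: list[tuple[str, ...]],
    folds: int = 5,
    seed: int = 0,
    model_config: mlp.ModelConfig | None = None,
) -> list[AblationResult]:
    """Leave-one-unit-out AUC deltas, sorted by drop (descending).

    The same seeded stratified folds serve the baseline and every ablated
    model, so deltas reflect the removed features, not fold resampling.
    An empty unit is the identity ablation and scores delta 0 exactly.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    names = list(feature_names)
    index = {n: i for i, n in enumerate(names)}
    for unit in units:
        unknown = [f for f in unit if f not in index]
        if unknown:
            raise ConfigurationError(f"unknown feature(s) in ablation unit: {unknown}")
    config = model_config or mlp.ModelConfig(input_dim=x.shape[1], seed=seed)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_indices = [
        (train_idx, test_idx) for train_idx, test_idx in splitter.split(x, y)
    ]
    baseline = _cv_auc(x, y, fold_indices, config)
    log.info("ablation baseline AUC over %d folds: %.4f", folds, baseline)

    results = []
    for unit in units:
        if len(unit) == 0:
            results.append(AblationResult(unit, baseline, baseline))
            continue
        keep = [i for i in range(x.shape[1]) if names[i] not in set(unit)]
        ablated = _cv_auc(x[:, keep], y, fold_indices, config)
        results.append(AblationResult(unit, baseline, ablated))
        log.info("ablated %s: AUC %.4f (delta %+.4f)", unit, ablated, baseline - ablated)
    return sorted(results, key=lambda r: r.delta, reverse=True)


def write_ablation_table(results: list[AblationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tbaseline_auc\tablated_auc\tdelta\n")
        for r in results:
            fh.write(
                f"{'+'.join(r.unit)}\t{r.baseline_auc:.6f}\t"
                f"{r.ablated_auc:.6f}\t{r.delta:.6f}\n"
            )


def write_correlation_matrix(matrix: CorrelationMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(
        matrix.values, index=matrix.feature_names, columns=matrix.feature_names
    ).to_csv(path, sep="\t")
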