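"""Class balancing, train/validation/test splitting, and standardization.

The evaluation protocol balances the corpus by randomly down-sampling the
majority class to the minority-class size, then partitions 80/10/10 into
train/validation/test.  Two split policies exist:

``random``
    genes are shuffled and partitioned, stratified by class so each
    partition keeps the global class balance within one record per class.

``cluster_aware``
    whole orthology clusters are assigned to a single partition, so no
    two members of a cluster (near-identical orthologs) can sit on both
    sides of the train/test boundary.  This removes the data leak that
    inflates random-split performance on multi-species corpora.

Standardization (train-fitted z-scores) is applied before the classifier;
the Standardizer records which partition it was fitted on and refuses to
fit on anything but training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import GeneRecord
from .errors import ConfigurationError, InvalidInputError, StateError

log = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/validation/test partitions plus their provenance."""

    train: list[GeneRecord]
    validation: list[GeneRecord]
    test: list[GeneRecord]
    policy: str
    fractions: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def partitions(self):
        yield "train", self.train
        yield "validation", self.validation
        yield "test", self.test


def _check_fractions(fractions) -> tuple[float, float, float]:
    if len(fractions) != 3:
        raise ConfigurationError("exactly three split fractions are required")
    if any(f <= 0 for f in fractions):
        raise ConfigurationError(f"split fractions must be positive: {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions must sum to 1: {fractions}")
    return tuple(float(f) for f in fractions)


def balance_by_downsampling(
    records: list[GeneRecord], seed: int
) -> list[GeneRecord]:
    """Down-sample the majority class to the minority-class size.

    Sampling is uniform without replacement and deterministic given the
    seed.  Record content is never altered, only membership.
    """
    pos = [r for r in records if r.essential]
    neg = [r for r in records if not r.essential]
    if not pos or not neg:
        raise InvalidInputError(
            f"both classes required for balancing (essential={len(pos)}, "
            f"non-essential={len(neg)})"
        )
    rng = np.random.default_rng(seed)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    keep_idx = rng.choice(len(majority), size=len(minority), replace=False)
    keep = {majority[i].gene_id for i in keep_idx}
    keep.update(r.gene_id for r in minority)
    balanced = [r for r in records if r.gene_id in keep]
    log.info(
        "balanced corpus: %d -> %d records (%d per class)",
        len(records),
        len(balanced),
        len(minority),
    )
    return balanced


def random_split(
    records: list[GeneRecord],
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Seeded, class-stratified shuffle split into train/validation/test.

    Within each class, floor(f*n) records go to train and validation and
    the remainder to test, so per-partition class balance stays within one
    record of the global ratio.
    """
    fractions = _check_fractions(fractions)
    if len(records) < 10:
        raise InvalidInputError("at least 10 records required for a split")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[GeneRecord]] = {"train": [], "validation": [], "test": []}
    for label in (True, False):
        group = [r for r in records if r.essential is label]
        order = rng.permutation(len(group))
        n_train = int(np.floor(fractions[0] * len(group)))
        n_val = int(np.floor(fractions[1] * len(group)))
        for rank, idx in enumerate(order):
            if rank < n_train:
                parts["train"].append(group[idx])
            elif rank < n_train + n_val:
                parts["validation"].append(group[idx])
            else:
                parts["test"].append(group[idx])
    return DatasetSplit(
        parts["train"], parts["validation"], parts["test"],
        "random", fractions, seed,
    )


def cluster_aware_split(
    records: list[GeneRecord],
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Assign whole orthology clusters to one partition each.

    Clusters are shuffled by seed and filled greedily into train, then
    validation, then test; a partition closes once its gene-count target
    is reached.  Realized fractions can deviate from the targets (logged).
    A cluster larger than the train target is forced into train with a
    warning.
    """
    fractions = _check_fractions(fractions)
    if any(r.cluster_id is None for r in records):
        raise InvalidInputError(
            "cluster_aware split requires every record to carry a cluster_id "
            "(use attach_clusters first)"
        )
    clusters: dict[str, list[GeneRecord]] = {}
    for rec in records:
        clusters.setdefault(rec.cluster_id, []).append(rec)
    rng = np.random.default_rng(seed)
    cluster_ids = sorted(clusters)
    rng.shuffle(cluster_ids)

    n = len(records)
    targets = [int(np.floor(fractions[0] * n)), int(np.floor(fractions[1] * n))]
    parts: list[list[GeneRecord]] = [[], [], []]
    for cid in cluster_ids:
        members = clusters[cid]
        if len(members) > targets[0]:
            log.warning(
                "cluster %s (%d genes) exceeds the train target %d; forced "
                "into train",
                cid, len(members), targets[0],
            )
            parts[0].extend(members)
            continue
        for k in range(3):
            if k == 2 or len(parts[k]) < targets[k]:
                parts[k].extend(members)
                break
    realized = tuple(len(p) / n for p in parts)
    log.info(
        "cluster-aware split realized fractions: %.3f/%.3f/%.3f "
        "(targets %.3f/%.3f/%.3f)", *realized, *fractions,
    )
    return DatasetSplit(parts[0], parts[1], parts[2], "cluster_aware", fractions, seed)


def split_records(
    records: list[GeneRecord],
    policy: str,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DatasetSplit:
    """Dispatch on split policy name ('random' or 'cluster_aware')."""
    if policy == "random":
        return random_split(records, fractions, seed)
    if policy == "cluster_aware":
        return cluster_aware_split(records, fractions, seed)
    raise ConfigurationError(f"unknown split policy: {policy!r}")


@dataclass
class Standardizer:
    """Per-feature z-score transform fitted on the training partition only."""

    location: np.ndarray | None = None
    scale: np.ndarray | None = None
    fitted_on: str | None = field(default=None)

    def fit(self, features: np.ndarray, partition: str = "train") -> "Standardizer":
        if partition != "train":
            raise InvalidInputError(
                f"standardizer must be fitted on the train partition, "
                f"not {partition!r} (leakage guard)"
            )
        x = np.asarray(features, dtype=float)
        self.location = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0.0] = 1.0  # constant features pass through centred
        self.scale = sd
        self.fitted_on = partition
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.fitted_on is None:
            raise StateError("standardizer has not been fitted")
        return (np.asarray(features, dtype=float) - self.location) / self.scale


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Persist a split as TSV (gene_id, partition, cluster_id, seed)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tpartition\tcluster_id\tpolicy\tseed\n")
        for name, part in split.partitions():
            for rec in part:
                fh.write(
                    f"{rec.gene_id}\t{name}\t{rec.cluster_id or ''}\t"
                    f"{split.policy}\t{split.seed}\n"
                )
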