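"""End-to-end experiment recipes and run provenance.

``run_leak_experiment`` is the headline recipe: the same balanced corpus
is evaluated under random and cluster-aware splitting with shared
repetition seeds, and the per-metric percent difference

    (non-clustered - clustered) / non-clustered * 100

quantifies how much of the random-split performance is attributable to
orthologous near-duplicates straddling the train/test boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .evaluation import repeated_experiment

log = logging.getLogger(__name__)

_SCALARS = ("auc", "aupr", "sensitivity", "specificity", "ppv", "accuracy")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_leak_experiment(
    records,
    feature_frame,
    n_repetitions: int = 10,
    base_seed: int = 0,
    model_config=None,
    fractions=(0.8, 0.1, 0.1),
) -> dict:
    """Paired random vs cluster-aware evaluation on one balanced corpus.

    Both policies see the same repetition seeds.  Returns the two
    aggregates, the paired per-repetition AUCs, and the percent
    difference per scalar metric (positive = random splitting looks
    better, the leak direction).
    """
    results = {}
    for policy in ("random", "cluster_aware"):
        reports, aggregate = repeated_experiment(
            records,
            feature_frame,
            policy=policy,
            n_repetitions=n_repetitions,
            base_seed=base_seed,
            model_config=model_config,
            fractions=fractions,
        )
        results[policy] = {"reports": reports, "aggregate": aggregate}
    summary = {
        "n_repetitions": n_repetitions,
        "base_seed": base_seed,
        "random": results["random"]["aggregate"],
        "cluster_aware": results["cluster_aware"]["aggregate"],
        "percent_difference": {},
        "paired_auc": list(
            zip(
                results["random"]["aggregate"]["auc_values"],
                results["cluster_aware"]["aggregate"]["auc_values"],
            )
        ),
    }
    for name in _SCALARS:
        rand = results["random"]["aggregate"][f"{name}_mean"]
        clust = results["cluster_aware"]["aggregate"][f"{name}_mean"]
        if rand is None or clust is None or rand == 0:
            summary["percent_difference"][name] = None
        else:
            summary["percent_difference"][name] = (rand - clust) / rand * 100.0
    log.info(
        "leak experiment: AUC %.4f (random) vs %.4f (cluster-aware), "
        "difference %.2f%%",
        summary["random"]["auc_mean"],
        summary["cluster_aware"]["auc_mean"],
        summary["percent_difference"]["auc"],
    )
    return summary


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Provenance record of one CLI run: inputs, outputs, seeds, status."""

    def __init__(self, command: str, config: dict, seed: int | None = None):
        self.data = {
            "command": command,
            "package_version": __version__,
            "config": _jsonable(config),
            "seed": seed,
            "inputs": {},
            "outputs": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "status": "running",
        }

    def add_input(self, path: str | Path) -> None:
        self.data["inputs"][str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"][str(path)] = file_digest(path)

    def finish(self, path: str | Path, status: str = "ok") -> None:
        self.data["status"] = status
        self.data["ended"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
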