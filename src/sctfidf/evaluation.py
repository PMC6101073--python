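"""Majority-based cluster-to-type matching and macro/micro accuracy.

Each predicted cluster is labeled with the most frequent ground-truth
class among its cells (several clusters may map to one class).  Micro
accuracy is the overall fraction of correctly matched cells; macro
accuracy is the unweighted mean of per-class accuracies.  Methods that
over-split are not penalized as long as sub-clusters stay pure.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment

__all__ = ["AccuracyReport", "majority_match", "accuracy"]


@dataclass
class AccuracyReport:
    per_class_accuracy: dict[str, float]
    macro: float
    micro: float
    matching: dict[int, str]
    confusion: pd.DataFrame  # clusters x classes

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": self.per_class_accuracy,
            "macro": self.macro,
            "micro": self.micro,
            "matching": {str(k): v for k, v in self.matching.items()},
            "confusion": self.confusion.to_dict(),
        }

    def __str__(self) -> str:  # human-readable table
        lines = ["cluster -> class matching:"]
        for c, cls in sorted(self.matching.items()):
            lines.append(f"  {c}: {cls}")
        lines.append("per-class accuracy:")
        for cls, acc in sorted(self.per_class_accuracy.items()):
            lines.append(f"  {cls}: {acc:.4f}")
        lines.append(f"macro accuracy: {self.macro:.4f}")
        lines.append(f"micro accuracy: {self.micro:.4f}")
        return "\n".join(lines)


def _truth_vector(assignment: ClusterAssignment, truth, cell_ids) -> list[str]:
    if isinstance(truth, dict):
        if cell_ids is None:
            raise ValueError("cell_ids required when truth is a mapping")
        missing = [c for c in cell_ids if c not in truth]
        if missing:
            raise ValueError(f"cell(s) missing from truth: {missing[:5]}")
        return [truth[c] for c in cell_ids]
    truth = list(truth)
    if len(truth) != assignment.n:
        raise ValueError("truth length does not match assignment")
    return [str(t) for t in truth]


def majority_match(
    assignment: ClusterAssignment, truth, cell_ids: list[str] | None = None
) -> dict[int, str]:
    """Label each cluster with its most frequent ground-truth class.

    ``truth`` is either a mapping cell id -> class (requires
    ``cell_ids`` in assignment order) or a sequence aligned with the
    assignment.  Ties go to the class with fewer cells overall, then
    lexicographically.
    """
    labels = _truth_vector(assignment, truth, cell_ids)
    class_sizes = Counter(labels)
    matching: dict[int, str] = {}
    for c in np.unique(assignment.labels):
        members = [labels[i] for i in np.flatnonzero(assignment.labels == c)]
        counts = Counter(members)
        best = min(
            counts,
            key=lambda cls: (-counts[cls], class_sizes[cls], cls),
        )
        matching[int(c)] = best
    return matching


def accuracy(
    assignment: ClusterAssignment, truth, cell_ids: list[str] | None = None
) -> AccuracyReport:
    """Accuracy report under majority-based cluster-to-class matching.

    ``C_i`` counts cells of class i inside clusters matched to class i;
    micro = sum C_i / sum N_i and macro = mean(C_i / N_i) over the
    classes present in the truth.
    """
    labels = _truth_vector(assignment, truth, cell_ids)
    matching = majority_match(assignment, labels)
    classes = sorted(set(labels))
    n_by_class = Counter(labels)
    empty = [c for c in classes if n_by_class[c] == 0]
    if empty:  # only possible with an explicit class universe; defensive
        warnings.warn(f"classes with zero cells excluded: {empty}")
        classes = [c for c in classes if n_by_class[c] > 0]

    clusters = np.unique(assignment.labels)
    confusion = pd.DataFrame(0, index=clusters, columns=classes, dtype=int)
    for cl, cls in zip(assignment.labels, labels):
        confusion.loc[int(cl), cls] += 1

    correct = {cls: 0 for cls in classes}
    for cl in clusters:
        cls = matching[int(cl)]
        correct[cls] += int(confusion.loc[int(cl), cls])
    per_class = {cls: correct[cls] / n_by_class[cls] for cls in classes}
    micro = sum(correct.values()) / len(labels)
    macro = float(np.mean([per_class[cls] for cls in classes]))
    return AccuracyReport(
        per_class_accuracy=per_class,
        macro=macro,
        micro=float(micro),
        matching=matching,
        confusion=confusion,
    )
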