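"""Pairwise clustering evaluation: sensitivity and specificity.

A clustering is recast as cluster membership lists (CMLs): each molecule
(the list root) maps to the set of other molecules sharing its cluster.
Comparing a predicted and a reference clustering then reduces to set
operations per root, counting every unordered molecule pair exactly once:

* TP -- co-clustered in both;
* FP -- co-clustered in the prediction only;
* FN -- co-clustered in the reference only;
* TN -- co-clustered in neither.

sensitivity = TP / (TP + FN), specificity = TN / (TN + FP); an ideal
clustering attains (1, 1).  The evaluation universe is the molecule set of
the reference clustering: the pseudo-reference procedure drops molecules,
so predictions over the full input must be projectable onto it.  Predicted
molecules outside the universe are ignored; reference molecules missing
from the prediction are treated as predicted singletons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .clustering import Clustering

logger = logging.getLogger(__name__)


class UndefinedMeasureError(ValueError):
    """A measure's denominator is zero (e.g. a reference with no pairs)."""


@dataclass(frozen=True)
class CML:
    """Cluster membership lists: root -> other members of its cluster."""

    lists: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for root, members in self.lists.items():
            if root in members:
                raise ValueError(f"list root {root!r} contained in its own list")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN over unordered molecule pairs of the evaluation universe."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMeasureError("TP + FN = 0: sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMeasureError("TN + FP = 0: specificity undefined")
        return self.tn / (self.tn + self.fp)


def to_cml(clustering: Clustering) -> CML:
    """Represent a partition as cluster membership lists."""
    lists: dict[str, frozenset[str]] = {}
    for members in clustering.clusters().values():
        for root in members:
            lists[root] = frozenset(members - {root})
    return CML(lists=lists)


def cml_to_clustering(cml: CML, method: str = "cml") -> Clustering:
    """Reconstruct the partition; inverse of :func:`to_cml`."""
    assignment: dict[str, int] = {}
    label = 0
    for root in cml.lists:
        if root in assignment:
            continue
        label += 1
        assignment[root] = label
        for other in cml.lists[root]:
            assignment[other] = label
    return Clustering(assignment=assignment, method=method, seed=None)


def confusion(predicted: CML, reference: CML) -> ConfusionCounts:
    """Count pair agreement between predicted and reference co-clustering.

    The universe is the reference molecule set; each unordered pair is
    counted once by restricting per-root sets to later-indexed molecules.
    """
    universe = list(reference.lists)
    uset = set(universe)
    index = {mol: k for k, mol in enumerate(universe)}
    missing = [mol for mol in universe if mol not in predicted.lists]
    if missing:
        logger.warning(
            "%d reference molecule(s) missing from prediction; treated as singletons",
            len(missing),
        )
    empty: frozenset[str] = frozenset()
    tp = fp = fn = 0
    for root in universe:
        k = index[root]
        ref_set = reference.lists[root]
        pred_set = predicted.lists.get(root, empty) & uset
        tp += sum(1 for m in ref_set & pred_set if index[m] > k)
        fn += sum(1 for m in ref_set - pred_set if index[m] > k)
        fp += sum(1 for m in pred_set - ref_set if index[m] > k)
    n = len(universe)
    tn = n * (n - 1) // 2 - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def sensitivity_specificity(counts: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity); raises when a denominator is zero."""
    return counts.sensitivity(), counts.specificity()


def evaluate(predicted: Clustering, reference: Clustering) -> dict:
    """Full evaluation report for a predicted clustering against a reference."""
    pred_cml = to_cml(predicted)
    ref_cml = to_cml(reference)
    counts = confusion(pred_cml, ref_cml)
    universe = set(ref_cml.lists)
    n_ignored = sum(1 for mol in pred_cml.lists if mol not in universe)
    report = {
        "TP": counts.tp,
        "FP": counts.fp,
        "TN": counts.tn,
        "FN": counts.fn,
        "n_universe": len(universe),
        "n_ignored": n_ignored,
    }
    try:
        report["sensitivity"] = counts.sensitivity()
    except UndefinedMeasureError:
        report["sensitivity"] = None
    try:
        report["specificity"] = counts.specificity()
    except UndefinedMeasureError:
        report["specificity"] = None
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
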