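"""Scoring detections against planted truth, and community statistics.

Sensitivity/specificity compare the largest detected community c_L(t) with
the planted trajectory c_T(t) layer by layer:

    TP = sum_t |c_T(t) & c_L(t)|      FN = sum_t |c_T(t) - c_L(t)|
    FP = sum_t |c_L(t) - c_T(t)|      TN = sum_t |V - c_T(t) - c_L(t)|

    S+ = TP / (TP + FN)               S- = TN / (TN + FP)

The four cells always total p * N.  The module also computes per-community
lifespan and maximum size, node loyalty (fraction of layers a node is
labeled), and node recruitment order into a target community.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .graphs import CommunityAssignment, CommunityView


@dataclass(frozen=True)
class ConfusionTotals:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class AssessmentResult:
    sensitivity: float  # S+; NaN when undefined (empty truth)
    specificity: float  # S-
    confusion: ConfusionTotals
    largest_community: int  # id of c_L
    undefined_sensitivity: bool


def largest_community_id(assignment: CommunityAssignment) -> int | None:
    """Id of the community with the greatest total (node, layer) extent.

    Deterministic tie ladder: extent, then smallest first layer, then
    smallest member node at that layer.
    """
    best: tuple | None = None
    best_id = None
    for view in assignment.views():
        first_members = dict(view.members_by_layer)[view.first_layer]
        key = (-view.extent, view.first_layer, min(first_members), view.id)
        if best is None or key < best:
            best = key
            best_id = view.id
    return best_id


def confusion_totals(
    truth_sets: Sequence[set[int]],
    detected_sets: Mapping[int, set[int]],
    node_count: int,
) -> ConfusionTotals:
    tp = fn = fp = tn = 0
    for t, truth in enumerate(truth_sets):
        det = detected_sets.get(t, set())
        tp += len(truth & det)
        fn += len(truth - det)
        fp += len(det - truth)
        tn += node_count - len(truth | det)
    return ConfusionTotals(tp, fn, fp, tn)


def sensitivity_specificity(
    truth_sets: Sequence[set[int]],
    detected: CommunityAssignment,
    node_count: int,
) -> AssessmentResult:
    """Score the largest detected community against the planted trajectory.

    A node counts as a member of c_L(t) if any of its labels at layer t
    equals the largest community's id; overlap with other communities is
    harmless since the formulas operate on node sets.
    """
    n_layers = len(truth_sets)
    cid = largest_community_id(detected)
    members = detected.members(cid) if cid is not None else {}
    members = {t: s for t, s in members.items() if 0 <= t < n_layers}
    for t, s in members.items():
        bad = {v for v in s if not 0 <= v < node_count}
        if bad:
            raise ValueError(f"detected node ids {bad} outside 0..{node_count - 1}")
    conf = confusion_totals(truth_sets, members, node_count)
    undefined = (conf.tp + conf.fn) == 0
    s_plus = math.nan if undefined else conf.tp / (conf.tp + conf.fn)
    s_minus = 1.0 if (conf.tn + conf.fp) == 0 else conf.tn / (conf.tn + conf.fp)
    return AssessmentResult(s_plus, s_minus, conf, -1 if cid is None else cid, undefined)


def per_layer_jaccard(
    truth_sets: Sequence[set[int]],
    detected: CommunityAssignment,
    active_only: bool = True,
) -> list[float]:
    """Jaccard index between c_L(t) and c_T(t), by default on layers where
    the planted community is active."""
    cid = largest_community_id(detected)
    members = detected.members(cid) if cid is not None else {}
    out = []
    for t, truth in enumerate(truth_sets):
        if active_only and not truth:
            continue
        det = members.get(t, set())
        union = truth | det
        out.append(len(truth & det) / len(union) if union else 1.0)
    return out


def community_stats(
    detected: CommunityAssignment, layer_seconds: float = 1.0
) -> list[dict]:
    """Per-community lifespan (seconds, first-to-last layer inclusive) and
    maximum per-layer size."""
    out = []
    for view in detected.views():
        out.append(
            {
                "id": view.id,
                "first_layer": view.first_layer,
                "last_layer": view.last_layer,
                "lifespan": (view.last_layer - view.first_layer + 1) * layer_seconds,
                "max_size": view.max_size,
                "extent": view.extent,
            }
        )
    return out


def node_loyalty(
    detected: CommunityAssignment,
    node_count: int,
    layer_count: int,
    community: int | None = None,
) -> np.ndarray:
    """Fraction of layers at which each node carries >= 1 qualifying label."""
    hits = np.zeros(node_count)
    for (t, v), ids in detected.vertex_labels.items():
        if t >= layer_count or v >= node_count:
            continue
        if community is None or community in ids:
            hits[v] += 1
    return hits / layer_count


def recruitment_order(
    detected: CommunityAssignment, target: int, node_count: int
) -> tuple[np.ndarray, np.ndarray]:
    """First layer each node joins the target community, and mid-ranks.

    Nodes that never join get NaN in both arrays; ties share the mean rank.
    """
    if target not in detected.community_ids():
        raise ValueError(f"unknown community id {target}")
    first = np.full(node_count, np.nan)
    for (t, v), ids in sorted(detected.vertex_labels.items()):
        if target in ids and v < node_count and np.isnan(first[v]):
            first[v] = t
    ranks = np.full(node_count, np.nan)
    joined = ~np.isnan(first)
    if joined.any():
        ranks[joined] = rankdata(first[joined], method="average")
    return first, ranks


def median_recruitment(first_join_runs: Sequence[np.ndarray]) -> np.ndarray:
    """Median first-join layer across runs, ignoring missing (NaN) entries.

    A node missing from every run stays NaN.
    """
    stack = np.vstack(list(first_join_runs))
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(stack, axis=0)
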