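"""Map mixture components to participants and to healthy/unhealthy/mixed labels.

Participants are assigned to the component with the highest averaged
allocation probability (MAP assignment).  Discovered components are mapped
onto dietary labels by a healthfulness score: mean z-scored intake over the
healthy food groups minus the mean over the unhealthy groups.  The highest-
scoring occupied component is labeled healthy, the lowest unhealthy, and all
others mixed.  The score is a reporting convention, not part of the model;
the grouping of foods is configurable and should be reported alongside any
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import defaults
from .dpm import DPMPosterior, _greedy_match

__all__ = [
    "ClusterAssignment",
    "assign_map",
    "component_scores",
    "relabel_components",
    "relabel_trace",
    "assign_labels",
]

LABELS = ("healthy", "unhealthy", "mixed")


@dataclass
class ClusterAssignment:
    """Per-participant component index, dietary label and MAP probability."""

    component_index: np.ndarray      # (n,)
    label: np.ndarray                # (n,) strings
    map_probability: np.ndarray      # (n,) winning allocation probability
    component_labels: dict[int, str] # occupied component -> label


def assign_map(posterior: DPMPosterior) -> tuple[np.ndarray, np.ndarray]:
    """MAP assignment from the averaged allocation-probability matrix.

    Ties break deterministically to the lowest component index and are
    logged with a warning.  Returns (component indices, winning probability).
    """
    probs = np.asarray(posterior.allocation_probs, float)
    if probs.size == 0:
        raise ValueError("empty allocation-probability matrix")
    idx = np.argmax(probs, axis=1)
    winning = probs[np.arange(len(probs)), idx]
    n_max = (probs == winning[:, None]).sum(axis=1)
    ties = np.where(n_max > 1)[0]
    if len(ties):
        warnings.warn(
            f"allocation-probability ties broken to lowest index for "
            f"{len(ties)} row(s), e.g. row {ties[0]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return idx, winning


def component_scores(
    posterior: DPMPosterior,
    healthy_groups=defaults.HEALTHY_GROUPS,
    unhealthy_groups=defaults.UNHEALTHY_GROUPS,
) -> np.ndarray:
    """Healthfulness score per component: mean z-scored intake across the
    healthy groups minus the mean across the unhealthy groups."""
    names = list(posterior.group_names)
    for g in set(healthy_groups) | set(unhealthy_groups):
        if g not in names:
            raise ValueError(f"unknown food group {g!r}; known: {names}")
    cm = posterior.column_means
    cs = posterior.column_sds
    if cm is None or cs is None:
        cm = np.zeros(len(names))
        cs = np.ones(len(names))
    z = (posterior.means - cm[None, :]) / cs[None, :]
    h_idx = [names.index(g) for g in healthy_groups]
    u_idx = [names.index(g) for g in unhealthy_groups]
    return z[:, h_idx].mean(axis=1) - z[:, u_idx].mean(axis=1)


def relabel_components(
    posterior: DPMPosterior,
    healthy_groups=defaults.HEALTHY_GROUPS,
    unhealthy_groups=defaults.UNHEALTHY_GROUPS,
    min_share: float = 0.005,
) -> dict[int, str]:
    """Label each occupied component healthy / unhealthy / mixed.

    Among components holding at least ``min_share`` of participants (and at
    least 2 of them), the highest healthfulness score is labeled healthy, the
    lowest unhealthy, and the remainder mixed; occupied components below the
    share threshold are labeled mixed — a near-singleton component is noise
    and must not claim an extreme label.  With two eligible components only
    the extreme labels are used; with one, the sign of its score decides.
    Score ties break by component index with a warning.
    """
    occupied = list(posterior.occupied_components)
    scores = component_scores(posterior, healthy_groups, unhealthy_groups)

    map_idx = np.argmax(posterior.allocation_probs, axis=1)
    n = len(map_idx)
    sizes = {k: int((map_idx == k).sum()) for k in occupied}
    floor = max(2, int(round(min_share * n)))
    major = [k for k in occupied if sizes[k] >= floor]
    if len(major) < 2:
        major = occupied

    vals = [scores[k] for k in major]
    if len(vals) > 1 and len(set(np.round(vals, 12))) < len(vals):
        warnings.warn(
            "healthfulness-score tie broken by component index",
            RuntimeWarning,
            stacklevel=2,
        )
    # sort descending by score, ascending index on ties
    order = sorted(major, key=lambda k: (-scores[k], k))
    labels: dict[int, str] = {k: "mixed" for k in occupied}
    if len(order) == 1:
        labels[order[0]] = "healthy" if scores[order[0]] >= 0 else "unhealthy"
    else:
        labels[order[0]] = "healthy"
        labels[order[-1]] = "unhealthy"
    return labels


def relabel_trace(
    mean_trace: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Label-switching correction for a trace of component means.

    Each iteration's components are matched to running reference means by
    greedy nearest-mean matching, so that averaging the relabeled trace is
    well-defined.  Returns (relabeled trace, permutations) where
    ``perm[t, s]`` is the original index playing role ``s`` at iteration t.
    """
    trace = np.asarray(mean_trace, float)
    T, K, _ = trace.shape
    out = np.empty_like(trace)
    perms = np.empty((T, K), dtype=int)
    ref = trace[0].copy() if reference is None else np.asarray(reference, float).copy()
    count = 1.0
    for t in range(T):
        perm = _greedy_match(trace[t], ref)
        perms[t] = perm
        out[t] = trace[t][perm]
        ref = (ref * count + out[t]) / (count + 1.0)
        count += 1.0
    return out, perms


def assign_labels(
    posterior: DPMPosterior,
    healthy_groups=defaults.HEALTHY_GROUPS,
    unhealthy_groups=defaults.UNHEALTHY_GROUPS,
) -> ClusterAssignment:
    """MAP assignment plus component labeling in one step."""
    idx, winning = assign_map(posterior)
    comp_labels = relabel_components(posterior, healthy_groups, unhealthy_groups)
    lab = np.array([comp_labels[k] for k in idx], dtype=object)
    return ClusterAssignment(
        component_index=idx,
        label=lab,
        map_probability=winning,
        component_labels=comp_labels,
    )
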