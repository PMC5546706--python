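"""Threshold discretization of meta-gene activities into Boolean trajectories.

Each meta-gene switches ON at the first time its activity magnitude reaches a
given fraction of its peak and (in the default pulse convention) back OFF
when it falls below again; the sign of the regulation lives in the inferred
network edges, not in the state. States are sampled at every switching time
of any node, consecutive duplicates are collapsed, and an always-ON input
node (the pheromone-activated transcription factors) is prepended.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import MetaGeneActivity
from .data import ValidationError


@dataclass
class DiscreteTrajectory:
    """Sequence of distinct Boolean states; input node first, always 1."""

    node_names: list[str]
    states: np.ndarray        # n_steps x n_nodes, entries in {0, 1}
    step_times: np.ndarray    # representative minutes per step

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        self.states = s
        if s.ndim != 2 or s.shape[1] != len(self.node_names):
            raise ValidationError("states shape must be n_steps x n_nodes")
        if not np.isin(s, (0, 1)).all():
            raise ValidationError("states must be 0/1")
        if np.any(s[:, 0] != 1):
            raise ValidationError("input node must be 1 at every step")
        if any(np.array_equal(s[i], s[i + 1]) for i in range(len(s) - 1)):
            raise ValidationError("consecutive duplicate states must be collapsed")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def transitions(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.states[i], self.states[i + 1])
                for i in range(len(self.states) - 1)]


def _node_boolean_trace(activity: np.ndarray, threshold: float,
                        latch: bool) -> np.ndarray:
    on = np.abs(activity) >= threshold
    if latch and on.any():
        on = np.cumsum(on) > 0
    return on.astype(int)


def discretize(activities: list[MetaGeneActivity], threshold: float = 0.5,
               latch: bool = False,
               input_name: str = "input") -> DiscreteTrajectory:
    """Build the discrete trajectory from meta-gene activities.

    threshold is a fraction of each node's peak magnitude, in (0, 1).
    ``latch=True`` keeps a node ON once it has switched (the alternative
    convention for sustained events); the default treats events as pulses.
    """
    if not (0 < threshold < 1):
        raise ValidationError("threshold must lie in (0, 1)")
    if not activities:
        raise ValidationError("no activities to discretize")
    grid = activities[0].grid
    if any(a.grid != grid for a in activities):
        raise ValidationError("activities must share a grid")
    traces = []
    for a in activities:
        peak = np.max(np.abs(a.activity))
        scaled = a.activity / peak if peak > 0 else a.activity
        traces.append(_node_boolean_trace(scaled, threshold, latch))
    bool_matrix = np.vstack(traces).T  # n_times x n_clusters
    if not bool_matrix.any():
        warnings.warn("no node ever crosses the threshold; single-state trajectory",
                      stacklevel=2)
    switch_idx = [0] + [k for k in range(1, len(grid))
                        if not np.array_equal(bool_matrix[k], bool_matrix[k - 1])]
    states, times = [], []
    for k in switch_idx:
        state = np.concatenate(([1], bool_matrix[k]))
        if states and np.array_equal(states[-1], state):
            continue
        states.append(state)
        times.append(grid.times[k])
    names = [input_name] + [f"C{a.cluster}" for a in activities]
    return DiscreteTrajectory(names, np.vstack(states), np.asarray(times, dtype=float))


def first_activation_order(traj: DiscreteTrajectory) -> dict[str, int]:
    """Step index at which each non-input node first switches ON (inf if never)."""
    order = {}
    for j, name in enumerate(traj.node_names):
        if j == 0:
            continue
        on = np.nonzero(traj.states[:, j] == 1)[0]
        order[name] = int(on[0]) if on.size else np.iinfo(np.int32).max
    return order


def trajectory_distance(a: DiscreteTrajectory, b: DiscreteTrajectory) -> float:
    """Kendall-type concordance of first-activation orderings, in [0, 1].

    1 means identical event order; 0 means fully reversed. Nodes that never
    activate rank last; ties count as concordant when tied in both.
    """
    if set(a.node_names) != set(b.node_names):
        raise ValidationError("trajectories must share a node set")
    oa, ob = first_activation_order(a), first_activation_order(b)
    nodes = sorted(oa)
    pairs = list(itertools.combinations(nodes, 2))
    if not pairs:
        return 1.0
    concordant = 0
    for u, v in pairs:
        da = np.sign(oa[u] - oa[v])
        db = np.sign(ob[u] - ob[v])
        if da == db:
            concordant += 1
    return concordant / len(pairs)
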