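"""Reverse engineering of ternary-signed Boolean networks from trajectories.

A network over nodes (input first, then meta-genes) is a signed adjacency
``a[j, i] in {-1, 0, +1}`` for regulation j -> i. Synchronous dynamics:

    h_i = sum_j S_j(t) * a[j, i]
    S_i(t+1) = 1 if h_i > 0, 0 if h_i < 0, S_i(t) if h_i == 0 (hold)

with the input clamped at 1. Because each node's update depends only on its
own incoming signs, consistency with a trajectory factorizes per target: the
set of consistent networks is the Cartesian product of per-target consistent
incoming-sign vectors, so exact counting is a product of small enumerations
(at most 3^7 candidates per target for a 6-cluster trajectory).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import ValidationError
from .discretize import DiscreteTrajectory

logger = logging.getLogger(__name__)

#: Hard cap on materialized networks in minimal_networks.
ENUMERATION_CAP = 10 ** 6


class InfeasibleTrajectoryError(ValidationError):
    """No incoming-sign vector can reproduce a target's transitions."""


@dataclass
class TernaryNetwork:
    """Signed adjacency with synchronous threshold/hold update semantics."""

    node_names: list[str]
    adjacency: np.ndarray          # a[j, i]: sign of edge j -> i
    input_index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=int)
        self.adjacency = a
        n = len(self.node_names)
        if a.shape != (n, n):
            raise ValidationError("adjacency must be n_nodes x n_nodes")
        if not np.isin(a, (-1, 0, 1)).all():
            raise ValidationError("adjacency entries must be in {-1, 0, +1}")
        if np.any(a[:, self.input_index] != 0):
            raise ValidationError("input node must have no incoming edges")

    def edges(self) -> list[tuple[str, str, int]]:
        out = []
        for j, i in zip(*np.nonzero(self.adjacency)):
            out.append((self.node_names[j], self.node_names[i],
                        int(self.adjacency[j, i])))
        return out

    def write_edge_list(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("source\ttarget\tsign\n")
            for s, t, sign in self.edges():
                fh.write(f"{s}\t{t}\t{sign:+d}\n")

    @classmethod
    def read_edge_list(cls, path, node_names: list[str]) -> "TernaryNetwork":
        idx = {n: i for i, n in enumerate(node_names)}
        a = np.zeros((len(node_names), len(node_names)), dtype=int)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("source\t"):
                    continue
                s, t, sign = line.split("\t")
                a[idx[s], idx[t]] = int(sign)
        return cls(node_names, a)


def step(net: TernaryNetwork, state: np.ndarray) -> np.ndarray:
    """One synchronous update; the input component stays 1."""
    state = np.asarray(state, dtype=int)
    if state.shape != (len(net.node_names),):
        raise ValidationError("state length != number of nodes")
    if state[net.input_index] != 1:
        raise ValidationError("input component must be 1")
    h = state @ net.adjacency
    nxt = np.where(h > 0, 1, np.where(h < 0, 0, state))
    nxt[net.input_index] = 1
    return nxt.astype(int)


def _sources_for(target: int, n_nodes: int, input_index: int,
                 allow_self: bool) -> list[int]:
    return [j for j in range(n_nodes) if allow_self or j != target]


def consistent_input_vectors(target: int, traj: DiscreteTrajectory,
                             allow_self: bool = True
                             ) -> tuple[list[int], np.ndarray]:
    """All incoming-sign vectors for ``target`` consistent with the trajectory.

    Enumerates the 3^S sign vectors over the permitted sources and keeps
    those reproducing the target's state at every transition under the
    threshold/hold rule. Returns (source indices, kept vectors as rows).
    Raises :class:`InfeasibleTrajectoryError` (naming the violated
    transition) when nothing survives.
    """
    if target == 0:
        raise ValidationError("the input node has no incoming edges to solve for")
    sources = _sources_for(target, traj.n_nodes, 0, allow_self)
    V = np.array(list(itertools.product((-1, 0, 1), repeat=len(sources))), dtype=int)
    keep = np.ones(len(V), dtype=bool)
    first_violation: dict[int, int] = {}
    for t, (prev, nxt) in enumerate(traj.transitions()):
        h = prev[sources] @ V.T
        pred = np.where(h > 0, 1, np.where(h < 0, 0, prev[target]))
        ok = pred == nxt[target]
        newly = keep & ~ok
        if newly.any() and t not in first_violation:
            first_violation[t] = int(newly.sum())
        keep &= ok
    kept = V[keep]
    if kept.size == 0:
        raise InfeasibleTrajectoryError(
            f"node {traj.node_names[target]!r}: no incoming-sign vector "
            f"reproduces all transitions (violations per transition: {first_violation})"
        )
    return sources, kept


def count_consistent_networks(traj: DiscreteTrajectory,
                              allow_self: bool = True) -> int:
    """Exact count of consistent networks: product of per-target set sizes."""
    total = 1
    for target in range(1, traj.n_nodes):
        try:
            _, kept = consistent_input_vectors(target, traj, allow_self)
        except InfeasibleTrajectoryError as exc:
            logger.warning("infeasible trajectory: %s", exc)
            return 0
        total *= len(kept)
    return total


def _minimal_vectors(kept: np.ndarray) -> np.ndarray:
    """Support-minimal, single-deletion-critical vectors of a consistent set."""
    kept_set = {tuple(v) for v in map(tuple, kept)}
    supports = [frozenset(np.nonzero(v)[0]) for v in kept]
    out = []
    for v, sup in zip(kept, supports):
        if any(other < sup for other in supports):
            continue  # a strictly smaller consistent support exists
        critical = True
        for j in np.nonzero(v)[0]:
            deleted = v.copy()
            deleted[j] = 0
            if tuple(deleted) in kept_set:
                critical = False
                break
        if critical:
            out.append(v)
    return np.array(out, dtype=int) if out else np.empty((0, kept.shape[1]), dtype=int)


def _assemble(traj: DiscreteTrajectory, per_target: list[tuple[list[int], np.ndarray]],
              choice: tuple[int, ...]) -> TernaryNetwork:
    n = traj.n_nodes
    a = np.zeros((n, n), dtype=int)
    for target, ((sources, vecs), pick) in enumerate(zip(per_target, choice), start=1):
        a[sources, target] = vecs[pick]
    return TernaryNetwork(list(traj.node_names), a)


def minimal_networks(traj: DiscreteTrajectory, allow_self: bool = True,
                     cap: int = ENUMERATION_CAP) -> list[TernaryNetwork]:
    """All consistent networks in which every edge is necessary.

    Per target, consistent vectors are filtered to those with inclusion-
    minimal nonzero support that are also single-deletion-critical (zeroing
    any one edge breaks that target's consistency); minimal networks are all
    combinations of these per-target vectors. Every returned network is
    re-verified against the trajectory.
    """
    per_target = []
    counts = []
    for target in range(1, traj.n_nodes):
        sources, kept = consistent_input_vectors(target, traj, allow_self)
        minimal = _minimal_vectors(kept)
        per_target.append((sources, minimal))
        counts.append(len(minimal))
    total = int(np.prod(counts))
    if total > cap:
        raise ValidationError(
            f"{total} minimal networks exceed the enumeration cap {cap}; "
            "use count_minimal_networks for the count only")
    nets = []
    for choice in itertools.product(*(range(c) for c in counts)):
        net = _assemble(traj, per_target, choice)
        assert is_consistent(net, traj), "assembled minimal network failed verification"
        nets.append(net)
    return nets


def count_minimal_networks(traj: DiscreteTrajectory, allow_self: bool = True) -> int:
    total = 1
    for target in range(1, traj.n_nodes):
        try:
            _, kept = consistent_input_vectors(target, traj, allow_self)
        except InfeasibleTrajectoryError as exc:
            logger.warning("infeasible trajectory: %s", exc)
            return 0
        total *= len(_minimal_vectors(kept))
    return total


def is_consistent(net: TernaryNetwork, traj: DiscreteTrajectory) -> bool:
    """Does the network's synchronous dynamics reproduce every transition?"""
    return all(np.array_equal(step(net, prev), nxt)
               for prev, nxt in traj.transitions())


def classify_edges(traj: DiscreteTrajectory, allow_self: bool = True
                   ) -> dict[tuple[str, str], str]:
    """Label each potential edge rigid / interchangeable / forbidden.

    rigid: one and the same nonzero sign in every consistent vector of its
    target; forbidden: zero in all of them; interchangeable: otherwise.
    """
    labels: dict[tuple[str, str], str] = {}
    for target in range(1, traj.n_nodes):
        sources, kept = consistent_input_vectors(target, traj, allow_self)
        for col, j in enumerate(sources):
            signs = set(kept[:, col].tolist())
            key = (traj.node_names[j], traj.node_names[target])
            if signs == {0}:
                labels[key] = "forbidden"
            elif len(signs) == 1:
                labels[key] = "rigid"
            else:
                labels[key] = "interchangeable"
    return labels


def apply_prior_constraints(networks: list[TernaryNetwork],
                            required: list[tuple[str, str, int]] = (),
                            forbidden: list[tuple[str, str]] = ()
                            ) -> list[TernaryNetwork]:
    """Keep networks with every required signed edge and no forbidden edge."""
    req_pairs = {(s, t) for s, t, _ in required}
    if req_pairs & set(map(tuple, forbidden)):
        raise ValidationError("an edge cannot be both required and forbidden")
    out = []
    for net in networks:
        idx = {n: i for i, n in enumerate(net.node_names)}
        for s, t, sign in required:
            if s not in idx or t not in idx:
                raise ValidationError(f"constraint references unknown node {s}->{t}")
            if net.adjacency[idx[s], idx[t]] != sign:
                break
        else:
            if any(net.adjacency[idx[s], idx[t]] != 0 for s, t in forbidden):
                continue
            out.append(net)
    if not out and networks:
        logger.warning("prior constraints eliminated every network")
    return out


@dataclass
class AttractorLandscape:
    """Synchronous attractors of the clamped-input dynamics."""

    attractors: list[tuple[tuple[int, ...], ...]]  # state cycles
    basin_sizes: list[int]
    n_states: int
    state_to_attractor: dict[tuple[int, ...], int] = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "attractors": [["".join(map(str, s)) for s in cyc] for cyc in self.attractors],
            "basins": self.basin_sizes,
            "n_states": self.n_states,
        })


def attractor_landscape(net: TernaryNetwork) -> AttractorLandscape:
    """Enumerate all 2^N free-node states and group them by terminal cycle.

    The input node is clamped at 1 and excluded from the enumeration; every
    state has exactly one successor, so each orbit ends in a unique cycle.
    Cycles are canonicalized to start at their lexicographically smallest
    state.
    """
    n = len(net.node_names)
    free = [i for i in range(n) if i != net.input_index]
    succ: dict[tuple[int, ...], tuple[int, ...]] = {}
    for bits in itertools.product((0, 1), repeat=len(free)):
        state = np.zeros(n, dtype=int)
        state[net.input_index] = 1
        state[free] = bits
        succ[tuple(state)] = tuple(step(net, state))
    attractors: list[tuple[tuple[int, ...], ...]] = []
    attr_index: dict[tuple[int, ...], int] = {}   # state-in-cycle -> attractor id
    state_to_attractor: dict[tuple[int, ...], int] = {}
    for start in succ:
        path = []
        s = start
        while s not in state_to_attractor and s not in attr_index:
            if s in path:
                cyc = path[path.index(s):]
                k = cyc.index(min(cyc))
                cyc = tuple(cyc[k:] + cyc[:k])
                aid = len(attractors)
                attractors.append(cyc)
                for c in cyc:
                    attr_index[c] = aid
                break
            path.append(s)
            s = succ[s]
        aid = state_to_attractor.get(s, attr_index.get(s))
        for p in path:
            state_to_attractor[p] = aid
        state_to_attractor[start] = aid
    basins = [0] * len(attractors)
    for aid in state_to_attractor.values():
        basins[aid] += 1
    return AttractorLandscape(attractors, basins, len(succ), state_to_attractor)
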