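"""Independent brute-force oracles shared by the Boolean-network tests.

These enumerate complete networks and simulate each one with the synchronous
update rule, deliberately ignoring the per-target factorization that the
implementation under test exploits.
"""

import itertools

import numpy as np

import psdanet as pn
from psdanet.discretize import DiscreteTrajectory


def make_trajectory(states, names=None) -> DiscreteTrajectory:
    states = np.asarray(states, dtype=int)
    names = names or ["input"] + [f"C{i}" for i in range(1, states.shape[1])]
    return DiscreteTrajectory(names, states, np.arange(len(states), dtype=float))


def random_trajectory(rng, n_free, n_steps) -> DiscreteTrajectory:
    """Random sequence of distinct states with the input clamped to 1."""
    states = [np.concatenate(([1], rng.integers(0, 2, n_free)))]
    while len(states) < n_steps:
        s = np.concatenate(([1], rng.integers(0, 2, n_free)))
        if not np.array_equal(s, states[-1]):
            states.append(s)
    return make_trajectory(np.vstack(states))


def brute_force_count(traj, allow_self=True) -> int:
    """Count consistent networks by simulating every complete network."""
    n = traj.n_nodes
    slots = [(j, i) for i in range(1, n) for j in range(n)
             if allow_self or j != i]
    count = 0
    for signs in itertools.product((-1, 0, 1), repeat=len(slots)):
        a = np.zeros((n, n), dtype=int)
        for (j, i), s in zip(slots, signs):
            a[j, i] = s
        net = pn.TernaryNetwork(list(traj.node_names), a)
        if pn.is_consistent(net, traj):
            count += 1
    return count


def brute_force_count_vectorized(traj, allow_self=True) -> int:
    """Same oracle for larger node counts, applying the update rule to the
    whole network stack at once."""
    n = traj.n_nodes
    per_target_sources = [[j for j in range(n) if allow_self or j != i]
                          for i in range(1, n)]
    vec_sets = [np.array(list(itertools.product((-1, 0, 1), repeat=len(src))),
                         dtype=np.int8) for src in per_target_sources]
    sizes = [len(v) for v in vec_sets]
    m_total = int(np.prod(sizes))
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in sizes],
                               indexing="ij"), axis=-1).reshape(m_total, -1)
    A = np.zeros((m_total, n, n), dtype=np.int8)
    for k, (src, vecs) in enumerate(zip(per_target_sources, vec_sets)):
        A[:, src, k + 1] = vecs[idx[:, k]]
    ok = np.ones(m_total, dtype=bool)
    for prev, nxt in traj.transitions():
        H = np.einsum("j,mjk->mk", prev.astype(np.int8), A)
        pred = np.where(H > 0, 1, np.where(H < 0, 0, prev))
        pred[:, 0] = 1
        ok &= (pred == nxt).all(axis=1)
    return int(ok.sum())
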