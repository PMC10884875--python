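"""Functional network assignment by consensus community detection.

A group connectome is density-thresholded at several edge densities (default
2-5%, integer steps), communities are detected on each thresholded graph
(Infomap two-level map equation by default, with a deterministic Leiden
modularity alternative), and the per-density partitions are combined through
a consensus-clustering loop: the co-assignment probability matrix is
thresholded at 0.5 and re-clustered until the partitions agree.  Communities
beyond an expected maximum (e.g. 17 networks) are dissolved by reassigning
their parcels to the modal network among spatial neighbors.
"""

from __future__ import annotations

import logging
import random as _random
from typing import Mapping, Sequence

import igraph
import numpy as np

from .datatypes import Connectome, ConsensusAssignment, Partition

logger = logging.getLogger(__name__)

__all__ = [
    "density_threshold",
    "detect_communities",
    "consensus_partition",
    "reassign_excess",
    "adjusted_rand",
    "DEFAULT_DENSITIES",
]

#: Edge density grid (fractions of all possible edges).
DEFAULT_DENSITIES = (0.02, 0.03, 0.04, 0.05)


def density_threshold(conn: Connectome | np.ndarray, density: float) -> np.ndarray:
    """Keep the top ``ceil(density * E)`` weighted edges, zero the rest.

    The diagonal is zeroed first.  Edges are ranked by signed weight (not
    magnitude); ties at the cutoff are broken by lexical (i, j) order, lower
    parcel ids first.  Kept edges preserve their weights.
    """
    m = conn.matrix if isinstance(conn, Connectome) else np.asarray(conn, dtype=float)
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    P = m.shape[0]
    iu, ju = np.triu_indices(P, k=1)
    w = m[iu, ju]
    E = w.size
    k = int(np.ceil(density * E))
    # sort by (-weight, i, j): NaN edges sort last
    order = np.lexsort((ju, iu, -np.nan_to_num(w, nan=-np.inf)))
    keep = order[:k]
    if not np.isfinite(w[keep]).any():
        raise ValueError("density so low (or data so degenerate) that the graph is empty")
    out = np.zeros((P, P))
    out[iu[keep], ju[keep]] = np.nan_to_num(w[keep], nan=0.0)
    out = out + out.T
    return out


def _seeded_igraph_rng(seed: int) -> None:
    igraph.set_random_number_generator(_random.Random(int(seed)))


def _graph_from_weights(W: np.ndarray) -> igraph.Graph:
    P = W.shape[0]
    iu, ju = np.triu_indices(P, k=1)
    nz = W[iu, ju] != 0
    neg = int((W[iu, ju] < 0).sum())
    if neg:
        logger.warning("dropping %d negative-weight edges for community detection", neg)
        nz &= W[iu, ju] > 0
    edges = list(zip(iu[nz].tolist(), ju[nz].tolist()))
    g = igraph.Graph(n=P, edges=edges)
    g.es["weight"] = W[iu[nz], ju[nz]].tolist()
    return g


def detect_communities(
    W: np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
    method: str = "infomap",
) -> Partition:
    """Best partition of a thresholded weighted graph over ``n_reps`` restarts.

    ``method`` is ``"infomap"`` (two-level map equation; restarts are the
    optimizer's trials, objective = codelength, lower better) or ``"leiden"``
    (modularity; best of ``n_reps`` seeded runs, objective = modularity,
    higher better).  Isolated parcels end up in singleton communities.  The
    same seed always yields the same partition.
    """
    W = np.asarray(W, dtype=float)
    g = _graph_from_weights(W)
    if g.ecount() == 0:
        raise ValueError("empty graph: no edges survive thresholding")
    if method == "infomap":
        _seeded_igraph_rng(seed)
        vc = g.community_infomap(edge_weights="weight", trials=int(n_reps))
        labels = np.asarray(vc.membership) + 1
        objective = float(vc.codelength)
    elif method == "leiden":
        import leidenalg as la

        best = None
        for r in range(int(n_reps)):
            part = la.find_partition(
                g, la.ModularityVertexPartition, weights="weight", seed=int(seed) + r
            )
            q = part.quality()
            if best is None or q > best[0]:
                best = (q, part.membership)
        objective = float(best[0])
        labels = np.asarray(best[1]) + 1
    else:
        raise ValueError(f"unknown community method {method!r}")
    return Partition(
        labels=labels,
        objective=objective,
        provenance={"method": method, "n_reps": int(n_reps), "seed": int(seed)},
    )


def consensus_partition(
    partitions: Sequence[Partition],
    threshold: float = 0.5,
    seed: int = 0,
    method: str = "infomap",
    n_reps: int = 50,
    max_iter: int = 20,
) -> ConsensusAssignment:
    """Consensus-clustering loop over per-density partitions.

    The co-assignment probability matrix p(i, j) is the fraction of input
    partitions assigning i and j to the same community.  Entries below
    ``threshold`` are zeroed and the thresholded matrix is re-clustered (as
    many times as there were inputs) to produce a new probability matrix;
    the loop repeats until all partitions agree (p is 0/1) or ``max_iter``
    iterations pass, in which case the last partition is returned flagged as
    unconverged.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions for a consensus")
    P = partitions[0].labels.shape[0]
    if any(p.labels.shape[0] != P for p in partitions):
        raise ValueError("partitions must share the parcel set")

    def coassign(parts: Sequence[np.ndarray]) -> np.ndarray:
        acc = np.zeros((P, P))
        for lab in parts:
            acc += lab[:, None] == lab[None, :]
        acc /= len(parts)
        np.fill_diagonal(acc, 1.0)
        return acc

    labelings = [p.labels for p in partitions]
    prob0 = coassign(labelings)
    prob = prob0
    m = len(partitions)
    converged = False
    final = None
    for it in range(max_iter):
        if np.all((prob == 0) | (prob == 1)):
            final = Partition(labels=_labels_from_binary(prob))
            converged = True
            break
        W = np.where(prob >= threshold, prob, 0.0)
        np.fill_diagonal(W, 0.0)
        labelings = [
            detect_communities(W, n_reps=n_reps, seed=seed + 1000 * it + r, method=method).labels
            for r in range(m)
        ]
        prob = coassign(labelings)
    if final is None:
        final = Partition(labels=labelings[0])
        if np.all((prob == 0) | (prob == 1)):
            converged = True
        else:
            logger.warning("consensus did not converge after %d iterations", max_iter)
    return ConsensusAssignment(probability=prob0, partition=final, converged=converged)


def _labels_from_binary(prob: np.ndarray) -> np.ndarray:
    """Connected components of a 0/1 co-assignment matrix."""
    P = prob.shape[0]
    labels = np.zeros(P, dtype=int)
    nxt = 0
    for i in range(P):
        if labels[i] == 0:
            nxt += 1
            members = np.flatnonzero(prob[i] == 1)
            labels[members] = nxt
            labels[i] = nxt
    return labels


def reassign_excess(
    partition: Partition,
    max_networks: int,
    spatial_neighbors: Mapping[int, Sequence[int]],
    network_names: Mapping[int, str] | None = None,
) -> Partition:
    """Dissolve communities beyond the largest ``max_networks``.

    Communities are ranked by size (descending; ties by lower original id).
    Parcels in communities ranked beyond ``max_networks`` are reassigned to
    the modal retained network among their spatial neighbors (0-based parcel
    ids in ``spatial_neighbors``); a parcel with no neighbor in a retained
    network goes to the globally largest network (logged).  Output ids are
    re-labeled 1..K by descending size.
    """
    labels = partition.labels.copy()
    sizes = np.bincount(labels)[1:]
    order = np.lexsort((np.arange(1, sizes.size + 1), -sizes))
    retained = set((order[:max_networks] + 1).tolist())
    largest = int(order[0] + 1)
    excess = [p for p in range(labels.size) if labels[p] not in retained]
    for p in excess:
        votes: dict[int, int] = {}
        for q in spatial_neighbors.get(p, ()):
            lq = int(labels[q])
            if lq in retained:
                votes[lq] = votes.get(lq, 0) + 1
        if votes:
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            labels[p] = best
        else:
            logger.warning(
                "parcel %d has no neighbor in a retained network; assigned to largest", p
            )
            labels[p] = largest
    # relabel by descending size
    sizes = np.bincount(labels)[1:]
    present = np.flatnonzero(sizes > 0) + 1
    rank = sorted(present, key=lambda c: (-sizes[c - 1], c))
    remap = {int(c): i + 1 for i, c in enumerate(rank)}
    new_labels = np.array([remap[int(v)] for v in labels], dtype=int)
    return Partition(labels=new_labels, provenance={**partition.provenance,
                                                    "reassigned": len(excess)})


def adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index between two labelings (chance-corrected agreement)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    cont = np.zeros((ua.size, ub.size), dtype=np.int64)
    np.add.at(cont, (ia, ib), 1)
    nij = (cont * (cont - 1) // 2).sum()
    ai = cont.sum(axis=1)
    bj = cont.sum(axis=0)
    ra = (ai * (ai - 1) // 2).sum()
    rb = (bj * (bj - 1) // 2).sum()
    n = a.size
    total = n * (n - 1) // 2
    expected = ra * rb / total
    maxi = (ra + rb) / 2
    if maxi == expected:
        return 1.0
    return float((nij - expected) / (maxi - expected))
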