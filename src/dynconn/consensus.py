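"""Consensus community structure across layers and across ensemble runs.

A single representative ("reference") partition per individual is distilled
in two stages.  First, *consensus similarity*: within each detection run the
member layer whose partition is most similar, on average, to all other
layers is selected (similarity is the z-scored Rand index by default).
Second, *iterative consensus* across the ensemble: the node-pair agreement
matrix of the selected partitions is compared against a permutation null
that preserves community sizes, the null expectation is subtracted, the
residual matrix is clustered by Louvain, and the procedure repeats on the
new partition set until all runs agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .coherence import ValidationError
from .community import MultilayerPartition, _louvain_dense

__all__ = [
    "ConsensusPartition",
    "zrand",
    "consensus_similarity",
    "layer_slices",
    "consensus_iterative",
    "individual_consensus",
]


@dataclass
class ConsensusPartition:
    """Single-layer representative labelling with provenance metadata."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = _canonical(np.asarray(self.labels, dtype=int))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1-based ids in order of first appearance."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    lut = {old: new + 1 for new, old in enumerate(order)}
    return np.array([lut[v] for v in labels], dtype=int)


def _pair_counts(labels: np.ndarray) -> tuple[float, np.ndarray]:
    """(number of co-assigned pairs, community sizes)."""
    sizes = np.bincount(labels)
    sizes = sizes[sizes > 0].astype(float)
    return float((sizes * (sizes - 1) / 2).sum()), sizes


def zrand(part1: np.ndarray, part2: np.ndarray) -> float:
    """z-scored Rand index between two labelings (Traud et al. convention).

    The pair-counting statistic w (node pairs co-assigned in both
    partitions) is standardised by its mean and variance under random
    permutations that preserve community sizes; for independent partitions
    z is approximately standard normal.  Degenerate cases with zero
    permutation variance return 0.
    """
    p1 = np.asarray(part1, dtype=int)
    p2 = np.asarray(part2, dtype=int)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValidationError("partitions must be 1-D arrays of equal length")
    n = len(p1)
    if n < 4:
        raise ValidationError("zrand needs at least 4 nodes")
    m = n * (n - 1) / 2.0
    m1, sizes1 = _pair_counts(p1)
    m2, sizes2 = _pair_counts(p2)
    # contingency pair count
    pair_ids = p1.astype(np.int64) * (p2.max() + 1) + p2
    nij = np.bincount(pair_ids).astype(float)
    w = float((nij * (nij - 1) / 2).sum())

    c1 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m1 + 4 * (sizes1**3).sum()
    c2 = n * (n**2 - 3 * n - 2) - 8 * (n + 1) * m2 + 4 * (sizes2**3).sum()
    a = 4 * m1 - 2 * m
    b = 4 * m2 - 2 * m
    var_w = (
        m / 16
        - a**2 * b**2 / (256 * m**2)
        + c1 * c2 / (16 * n * (n - 1) * (n - 2))
        + (a**2 - 4 * c1 - 4 * m)
        * (b**2 - 4 * c2 - 4 * m)
        / (64 * n * (n - 1) * (n - 2) * (n - 3))
    )
    if var_w <= 1e-12:
        return 0.0
    return float((w - m1 * m2 / m) / np.sqrt(var_w))


_SIMILARITIES = {"zrand": zrand, "ari": adjusted_rand_score}


def consensus_similarity(
    partitions: list[np.ndarray], similarity: str = "zrand"
) -> ConsensusPartition:
    """The member partition with the highest mean pairwise similarity to all
    the others; ties resolve to the lowest partition index."""
    if len(partitions) == 0:
        raise ValidationError("consensus_similarity needs at least 1 partition")
    if len(partitions) == 1:
        return ConsensusPartition(
            labels=partitions[0], provenance={"n_members": 1, "index": 0}
        )
    sim = _SIMILARITIES[similarity]
    r = len(partitions)
    s = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            s[i, j] = s[j, i] = sim(partitions[i], partitions[j])
    means = s.sum(axis=1) / (r - 1)
    best = int(np.argmax(means))
    return ConsensusPartition(
        labels=partitions[best],
        provenance={
            "n_members": r,
            "index": best,
            "similarity": similarity,
            "mean_similarity": float(means[best]),
        },
    )


def layer_slices(partition: MultilayerPartition) -> list[np.ndarray]:
    """One single-layer labelling per temporal layer, order preserved."""
    return [partition.labels[:, l].copy() for l in range(partition.n_layers)]


def _agreement(parts: np.ndarray) -> np.ndarray:
    """(n, n) co-assignment frequency over the (R, n) partition array."""
    return (parts[:, :, None] == parts[:, None, :]).mean(axis=0)


def _all_identical(parts: np.ndarray) -> bool:
    canon = np.array([_canonical(p) for p in parts])
    return bool((canon == canon[0]).all())


def consensus_iterative(
    partitions: list[np.ndarray],
    n_null: int = 100,
    seed: int = 0,
    max_rounds: int = 50,
    null_sd_factor: float = 2.0,
) -> ConsensusPartition:
    """Iterative consensus across runs, validated against a permutation null.

    Each round builds the node-pair agreement matrix and a permutation null
    from ``n_null`` community-size-preserving label permutations of the
    inputs.  Pair agreements are thresholded at the null mean plus
    ``null_sd_factor`` null standard deviations (so that, for fully random
    inputs, only a small tail of pairs survives), the residual matrix is
    clustered with Louvain (once per input run, with run-specific seeds),
    and the procedure repeats until every run returns the same partition.
    Non-convergence after ``max_rounds`` returns the modal partition with a
    warning.
    """
    if len(partitions) < 2:
        raise ValidationError("consensus_iterative needs at least 2 partitions")
    parts = np.array([np.asarray(p, dtype=int) for p in partitions])
    r, n = parts.shape
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    rounds = 0
    while rounds < max_rounds:
        if _all_identical(parts):
            return ConsensusPartition(
                labels=parts[0],
                provenance={"n_runs": r, "rounds": rounds, "n_null": n_null},
            )
        agree = _agreement(parts)
        null_vals = np.empty((n_null, len(iu[0])))
        for k in range(n_null):
            permuted = np.array([p[rng.permutation(n)] for p in parts])
            null_vals[k] = _agreement(permuted)[iu]
        threshold = null_vals.mean() + null_sd_factor * null_vals.std()
        residual = agree - threshold
        np.fill_diagonal(residual, 0.0)
        new = np.empty_like(parts)
        for i in range(r):
            new[i] = _louvain_dense(residual, rng) + 1
        parts = new
        rounds += 1
    warnings.warn(
        f"iterative consensus did not converge in {max_rounds} rounds; "
        "returning the modal partition",
        stacklevel=2,
    )
    canon = np.array([_canonical(p) for p in parts])
    uniq, counts = np.unique(canon, axis=0, return_counts=True)
    return ConsensusPartition(
        labels=uniq[np.argmax(counts)],
        provenance={
            "n_runs": r,
            "rounds": rounds,
            "n_null": n_null,
            "converged": False,
        },
    )


def group_consensus(
    individuals: list[ConsensusPartition],
    n_null: int = 100,
    seed: int = 0,
) -> ConsensusPartition:
    """Across-subject consensus over per-individual reference partitions.

    Optional: community architectures are often highly individual, so the
    within-subject consensus is the analysis default and this group-level
    aggregate is provided for exploration only.
    """
    if not individuals:
        raise ValidationError("empty individual list")
    if len(individuals) == 1:
        return individuals[0]
    out = consensus_iterative(
        [c.labels for c in individuals], n_null=n_null, seed=seed
    )
    out.provenance["n_individuals"] = len(individuals)
    return out


def individual_consensus(
    ensemble: list[MultilayerPartition],
    n_null: int = 100,
    seed: int = 0,
    similarity: str = "zrand",
) -> ConsensusPartition:
    """Per-individual reference partition.

    For each detection run, consensus similarity across its temporal layers
    selects one representative single-layer partition; iterative consensus
    across those run representatives yields the individual's reference.
    """
    if not ensemble:
        raise ValidationError("empty ensemble")
    reps = [
        consensus_similarity(layer_slices(p), similarity=similarity).labels
        for p in ensemble
    ]
    if len(reps) == 1:
        out = ConsensusPartition(labels=reps[0])
    else:
        out = consensus_iterative(reps, n_null=n_null, seed=seed)
    out.provenance.update(
        {"n_layers": ensemble[0].n_layers, "n_runs": len(ensemble)}
    )
    return out
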