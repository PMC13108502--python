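"""Nodal dynamic-reconfiguration metrics from multilayer partitions.

Two families of metrics are computed.  Reference-free metrics describe how a
node's community affiliation moves over time: *flexibility* (fraction of
layer transitions at which the label changes) and *promiscuity* (fraction of
all network communities visited at least once).  Reference-anchored metrics
are computed on the *allegiance* matrix — the node-pair co-assignment
frequency over layers — relative to a single-layer reference partition:
*integration* (mean allegiance to out-group nodes), *recruitment* (mean
allegiance to in-group nodes), the *participation coefficient*
P_i = 1 - sum_s (k_is / k_i)^2 and the *within-module degree*
z_i = (k_i - <k_s>) / sigma_ks, both evaluated on allegiance strengths with
the self-allegiance diagonal excluded.  Nodes in the top 5% of z are
*dynamic hubs*; nodes below the z median with P at or above the P median are
*dynamic integrators*.

All metric functions accept either a single :class:`MultilayerPartition` or
an ensemble (list), in which case the metric is computed per run and
averaged, matching how the detection ensemble is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coherence import ValidationError
from .community import MultilayerPartition

__all__ = [
    "AllegianceMatrix",
    "ReferencePartition",
    "allegiance",
    "flexibility",
    "promiscuity",
    "integration",
    "recruitment",
    "participation_coefficient",
    "within_module_degree",
    "classify_roles",
    "node_metric_table",
]


@dataclass
class AllegianceMatrix:
    """Node-by-node co-assignment frequency over temporal layers."""

    values: np.ndarray
    n_layers: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("allegiance must be square")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ReferencePartition:
    """Single-layer community labels used as the reference structure."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValidationError("reference labels must be 1-D")


def _as_list(
    partitions: MultilayerPartition | list[MultilayerPartition],
) -> list[MultilayerPartition]:
    if isinstance(partitions, MultilayerPartition):
        return [partitions]
    if not partitions:
        raise ValidationError("empty partition ensemble")
    return list(partitions)


def _ref_labels(ref: ReferencePartition | np.ndarray) -> np.ndarray:
    if isinstance(ref, ReferencePartition):
        return ref.labels
    return np.asarray(ref, dtype=int)


def allegiance(
    partitions: MultilayerPartition | list[MultilayerPartition],
) -> AllegianceMatrix:
    """Fraction of layers in which each node pair shares a community,
    averaged across the ensemble.  Diagonal is exactly 1."""
    parts = _as_list(partitions)
    n = parts[0].n_nodes
    acc = np.zeros((n, n))
    for p in parts:
        same = (p.labels[:, None, :] == p.labels[None, :, :]).mean(axis=2)
        acc += same
    return AllegianceMatrix(values=acc / len(parts), n_layers=parts[0].n_layers)


def flexibility(
    partitions: MultilayerPartition | list[MultilayerPartition],
) -> np.ndarray:
    """Per-node fraction of the L-1 layer transitions at which the
    community label changes; ensemble-averaged."""
    parts = _as_list(partitions)
    if parts[0].n_layers < 2:
        raise ValidationError("flexibility requires at least 2 layers")
    out = np.zeros(parts[0].n_nodes)
    for p in parts:
        changes = (p.labels[:, 1:] != p.labels[:, :-1]).sum(axis=1)
        out += changes / (p.n_layers - 1)
    return out / len(parts)


def promiscuity(
    partitions: MultilayerPartition | list[MultilayerPartition],
) -> np.ndarray:
    """Fraction of all communities present anywhere in the partition that a
    node joins at least once; computed per run, then ensemble-averaged."""
    parts = _as_list(partitions)
    out = np.zeros(parts[0].n_nodes)
    for p in parts:
        total = len(np.unique(p.labels))
        visited = np.array(
            [len(np.unique(p.labels[i])) for i in range(p.n_nodes)]
        )
        out += visited / total
    return out / len(parts)


def integration(
    alleg: AllegianceMatrix, ref: ReferencePartition | np.ndarray
) -> np.ndarray:
    """Mean allegiance of each node with nodes from *other* reference
    communities.  Undefined (NaN, with a warning) when the reference has a
    single community."""
    labels = _ref_labels(ref)
    a = alleg.values
    if len(np.unique(labels)) < 2:
        warnings.warn("single reference community: integration undefined",
                      stacklevel=2)
        return np.full(alleg.n_nodes, np.nan)
    other = labels[:, None] != labels[None, :]
    return (a * other).sum(axis=1) / other.sum(axis=1)


def recruitment(
    alleg: AllegianceMatrix, ref: ReferencePartition | np.ndarray
) -> np.ndarray:
    """Mean allegiance of each node with the *other* members of its own
    reference community; NaN for singleton reference communities."""
    labels = _ref_labels(ref)
    a = alleg.values
    own = labels[:, None] == labels[None, :]
    np.fill_diagonal(own, False)
    counts = own.sum(axis=1)
    out = np.full(alleg.n_nodes, np.nan)
    ok = counts > 0
    out[ok] = (a * own).sum(axis=1)[ok] / counts[ok]
    if not ok.all():
        warnings.warn("singleton reference community: recruitment undefined "
                      f"for {np.count_nonzero(~ok)} node(s)", stacklevel=2)
    return out


def _offdiag_strengths(
    alleg: AllegianceMatrix, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node allegiance strength to each reference community, diagonal
    excluded.  Returns (k_is with shape (n, n_comms), community ids)."""
    a = alleg.values.copy()
    np.fill_diagonal(a, 0.0)
    comms = np.unique(labels)
    k_is = np.column_stack([a[:, labels == c].sum(axis=1) for c in comms])
    return k_is, comms


def participation_coefficient(
    alleg: AllegianceMatrix, ref: ReferencePartition | np.ndarray
) -> np.ndarray:
    """P_i = 1 - sum_s (k_is / k_i)^2 on allegiance strengths.

    Nodes with zero total strength get P = 0 with a warning.
    """
    labels = _ref_labels(ref)
    k_is, _ = _offdiag_strengths(alleg, labels)
    k_i = k_is.sum(axis=1)
    out = np.zeros(alleg.n_nodes)
    pos = k_i > 0
    if not pos.all():
        warnings.warn(
            f"{np.count_nonzero(~pos)} node(s) with zero allegiance "
            "strength: participation set to 0",
            stacklevel=2,
        )
    frac = k_is[pos] / k_i[pos, None]
    out[pos] = 1.0 - (frac**2).sum(axis=1)
    return out


def within_module_degree(
    alleg: AllegianceMatrix, ref: ReferencePartition | np.ndarray
) -> np.ndarray:
    """z_i: in-module allegiance strength standardised within the node's own
    reference module (population SD; sigma = 0 gives z = 0).  Singleton
    modules are undefined (NaN)."""
    labels = _ref_labels(ref)
    a = alleg.values.copy()
    np.fill_diagonal(a, 0.0)
    out = np.full(alleg.n_nodes, np.nan)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            warnings.warn(f"singleton reference module {c}: z undefined",
                          stacklevel=2)
            continue
        k = a[np.ix_(members, members)].sum(axis=1)
        sd = k.std()  # population convention
        out[members] = 0.0 if sd == 0 else (k - k.mean()) / sd
    return out


def classify_roles(z: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Hub/integrator/other labels from within-module degree and
    participation.

    hub: z at or above the 95th percentile of z.
    integrator: z below the 50th percentile and P at or above the 50th
    percentile.  Percentiles are taken jointly over all nodes (linear
    interpolation); nodes with missing z or P are labelled ``other``.
    """
    z = np.asarray(z, dtype=float)
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(z) & np.isfinite(p)
    if not ok.all():
        warnings.warn(
            f"{np.count_nonzero(~ok)} node(s) with missing z or P "
            "labelled 'other'",
            stacklevel=2,
        )
    roles = np.array(["other"] * len(z), dtype=object)
    if not ok.any():
        return roles
    z95 = np.percentile(z[ok], 95)
    z50 = np.percentile(z[ok], 50)
    p50 = np.percentile(p[ok], 50)
    hub = ok & (z >= z95)
    integ = ok & ~hub & (z < z50) & (p >= p50)
    roles[hub] = "hub"
    roles[integ] = "integrator"
    return roles


def node_metric_table(
    partitions: MultilayerPartition | list[MultilayerPartition],
    ref: ReferencePartition | np.ndarray,
    parcel_ids: list[str] | None = None,
    region_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """All nodal metrics in one table (one row per node)."""
    parts = _as_list(partitions)
    alleg = allegiance(parts)
    n = alleg.n_nodes
    z = within_module_degree(alleg, ref)
    p = participation_coefficient(alleg, ref)
    table = pd.DataFrame(
        {
            "parcel_id": parcel_ids or [f"parcel{i:03d}" for i in range(n)],
            "region": (
                region_labels if region_labels is not None else ["left"] * n
            ),
            "flexibility": flexibility(parts),
            "promiscuity": promiscuity(parts),
            "integration": integration(alleg, ref),
            "recruitment": recruitment(alleg, ref),
            "participation": p,
            "within_module_degree": z,
            "role": classify_roles(z, p),
        }
    )
    return table
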