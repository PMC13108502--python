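"""Pre/post perturbation statistics on nodal dynamic metrics.

For each node a two-sided paired t test compares the post- against the
pre-stimulation metric across subjects (positive t = higher post).  The
*dissimilarity ratio* of a region is the proportion of its nodes with an
uncorrected p below alpha; its sampling variability is assessed by
recomputing it over every 12-of-17 subject subset (full enumeration,
C(17,12) = 6188 subsets, or seeded sampling when the count would exceed the
enumeration budget).  The directional null is built by scrambling the
temporal windows across the pre/post boundary — which, because coherence
layers are window-local, is implemented exactly as a permutation of the
pooled pre+post layers — re-estimating the metric and recording the
whole-brain mean t, repeated ``n_null`` times.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coherence import ConnectivityStack, ParcelTimeSeries, ValidationError, \
    build_connectivity_stack
from .community import ModularityConfig, MultilayerPartition, run_ensemble
from . import metrics as _metrics

__all__ = [
    "TemporalMetricSeries",
    "temporal_points",
    "temporal_metric_series",
    "paired_node_tests",
    "dissimilarity_ratio",
    "bootstrap_dissimilarity",
    "mean_effect_size",
    "scramble_null_mean_t",
]

#: metric names usable in temporal series and null models
REFERENCE_FREE = ("flexibility", "promiscuity")
REFERENCE_BASED = ("integration", "recruitment")
METRICS = REFERENCE_FREE + REFERENCE_BASED

ENUMERATION_BUDGET = 10_000
D_CLAMP = 100.0


def temporal_points(n_layers: int, window: int, overlap: float) -> int:
    """Number of sliding estimation points over the layer sequence.

    With the default 10-layer window at 90% overlap (step 1), 28 layers give
    19 estimation points.
    """
    if not 1 <= window <= n_layers:
        raise ValidationError(
            f"window {window} outside 1..{n_layers} layers"
        )
    if not 0 <= overlap < 1:
        raise ValidationError(f"overlap must be in [0, 1), got {overlap}")
    step = max(1, round(window * (1 - overlap)))
    return (n_layers - window) // step + 1


@dataclass
class TemporalMetricSeries:
    """Sliding-window estimates of one nodal metric over the scan."""

    values: np.ndarray  # (n_points, n_nodes)
    metric: str
    window: int
    overlap: float
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_points(self) -> int:
        return self.values.shape[0]


def _metric_from_ensemble(
    ensemble: list[MultilayerPartition],
    metric: str,
    ref: np.ndarray | None,
) -> np.ndarray:
    if metric == "flexibility":
        return _metrics.flexibility(ensemble)
    if metric == "promiscuity":
        return _metrics.promiscuity(ensemble)
    if metric in REFERENCE_BASED:
        if ref is None:
            raise ValidationError(f"{metric} requires a reference partition")
        alleg = _metrics.allegiance(ensemble)
        fn = _metrics.integration if metric == "integration" \
            else _metrics.recruitment
        return fn(alleg, ref)
    raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")


def temporal_metric_series(
    source: ConnectivityStack | MultilayerPartition | list[MultilayerPartition],
    metric: str,
    window: int = 10,
    overlap: float = 0.9,
    config: ModularityConfig | None = None,
    ref: np.ndarray | None = None,
) -> TemporalMetricSeries:
    """Metric estimated in sliding blocks of consecutive temporal layers.

    Given a connectivity stack, community detection is re-run (as an
    ensemble) on each block; given partitions, their layer slices are
    reused directly.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if isinstance(source, ConnectivityStack):
        n_layers = source.n_layers
    else:
        parts = source if isinstance(source, list) else [source]
        n_layers = parts[0].n_layers
    n_pts = temporal_points(n_layers, window, overlap)
    step = max(1, round(window * (1 - overlap)))
    starts = np.arange(n_pts) * step
    rows = []
    for s in starts:
        if isinstance(source, ConnectivityStack):
            sub = source.subset_layers(int(s), int(s) + window)
            cfg = config or ModularityConfig()
            sub_cfg = ModularityConfig(
                gamma=cfg.gamma, omega=cfg.omega, n_iter=cfg.n_iter,
                seed=cfg.seed + int(s) + 1, coupling=cfg.coupling,
            )
            ensemble = run_ensemble(sub, sub_cfg)
        else:
            ensemble = [
                MultilayerPartition(labels=p.labels[:, s : s + window])
                for p in parts
            ]
        rows.append(_metric_from_ensemble(ensemble, metric, ref))
    return TemporalMetricSeries(
        values=np.array(rows), metric=metric, window=window,
        overlap=overlap, starts=starts,
    )


def paired_node_tests(pre: np.ndarray, post: np.ndarray) -> pd.DataFrame:
    """Two-sided paired t test per node on post - pre across subjects.

    Returns a DataFrame with columns ``t``, ``p`` and ``cohen_d`` (paired:
    mean difference over its SD).  Nodes with zero-variance differences get
    NaN t/p (counted non-significant downstream); their d is clamped to
    +-100 when the mean difference is nonzero.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError(
            f"pre {pre.shape} and post {post.shape} tables differ in shape"
        )
    if pre.shape[0] < 2:
        raise ValidationError("paired tests need at least 2 subjects")
    diff = post - pre
    sd = diff.std(axis=0, ddof=1)
    mean = diff.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_rel(post, pre, axis=0)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        d = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.nan)
    # zero-variance differences: t undefined (scipy yields +-inf), flag missing
    t = np.where(sd == 0, np.nan, t)
    p = np.where(sd == 0, np.nan, p)
    degenerate = (sd == 0) & (mean != 0)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} node(s) with zero-variance nonzero "
            "difference: effect size clamped",
            stacklevel=2,
        )
        d = np.where(degenerate, np.sign(mean) * D_CLAMP, d)
    zero = (sd == 0) & (mean == 0)
    d = np.where(zero, 0.0, d)
    return pd.DataFrame({"t": t, "p": p, "cohen_d": d})


def _region_groups(region_labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(region_labels, dtype=object)
    groups = {
        r: np.flatnonzero(labels == r) for r in ("left", "right", "cerebellum")
    }
    groups["whole_brain"] = np.arange(len(labels))
    return groups


def dissimilarity_ratio(
    tests: pd.DataFrame,
    region_labels: np.ndarray,
    alpha: float = 0.05,
    correction: str | None = None,
) -> dict[str, float]:
    """Per-region proportion of nodes with p < alpha.

    The default follows the uncorrected per-node design; pass
    ``correction="fdr_bh"`` (or any statsmodels method name) to correct
    across nodes first.  NaN p values (undefined tests) count as
    non-significant; empty regions are reported as NaN.
    """
    p = tests["p"].to_numpy(dtype=float)
    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(p)
        adjusted = np.full_like(p, np.nan)
        if ok.any():
            adjusted[ok] = multipletests(p[ok], alpha=alpha,
                                         method=correction)[1]
        p = adjusted
    out = {}
    for region, idx in _region_groups(region_labels).items():
        if len(idx) == 0:
            warnings.warn(f"empty region {region!r}", stacklevel=2)
            out[region] = float("nan")
            continue
        sig = np.nan_to_num(p[idx], nan=1.0) < alpha
        out[region] = float(sig.mean())
    return out


def _subset_iter(n: int, k: int, rng: np.random.Generator):
    total = math.comb(n, k)
    if total <= ENUMERATION_BUDGET:
        return np.array(list(combinations(range(n), k)), dtype=int), True
    picks = np.array(
        [rng.choice(n, size=k, replace=False) for _ in range(ENUMERATION_BUDGET)],
        dtype=int,
    )
    return picks, False


def bootstrap_dissimilarity(
    pre: np.ndarray,
    post: np.ndarray,
    region_labels: np.ndarray,
    subset_size: int = 12,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Dissimilarity-ratio variability over subject subsets.

    Every size-``subset_size`` subject subset is evaluated when their count
    is within the enumeration budget (C(17,12) = 6188 is); otherwise 10,000
    subsets are sampled with the given seed.  Reports, per region, the SD of
    the subset ratios and the 2.5/97.5 percentile bounds (ascending).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    n_subj = pre.shape[0]
    if subset_size > n_subj:
        raise ValidationError(
            f"subset_size {subset_size} exceeds {n_subj} subjects"
        )
    rng = np.random.default_rng(seed)
    subsets, enumerated = _subset_iter(n_subj, subset_size, rng)
    diff = post - pre
    groups = _region_groups(region_labels)
    ratios = {r: np.empty(len(subsets)) for r in groups}
    k = subset_size
    crit = sps.t.ppf(1 - alpha / 2, df=k - 1)
    chunk = max(1, int(2e7 // (k * diff.shape[1])))
    for c0 in range(0, len(subsets), chunk):
        d = diff[subsets[c0 : c0 + chunk]]  # (c, k, n)
        mean = d.mean(axis=1)
        sd = d.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(k))
        sig = np.abs(np.nan_to_num(t, nan=0.0)) > crit
        for r, idx in groups.items():
            ratios[r][c0 : c0 + chunk] = (
                sig[:, idx].mean(axis=1) if len(idx) else np.nan
            )
    out = {}
    for r, vals in ratios.items():
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[r] = {
            "sd": float(vals.std(ddof=1)),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "n_subsets": int(len(subsets)),
            "enumerated": bool(enumerated),
        }
    return out


def mean_effect_size(tests: pd.DataFrame, alpha: float = 0.05) -> float:
    """Mean paired Cohen's d over the nodes significant at alpha.

    NaN (with a warning) when no node is significant.
    """
    p = np.nan_to_num(tests["p"].to_numpy(), nan=1.0)
    sig = p < alpha
    if not sig.any():
        warnings.warn("no significant nodes: mean effect size undefined",
                      stacklevel=2)
        return float("nan")
    return float(np.nanmean(tests["cohen_d"].to_numpy()[sig]))


def _to_stack(data, window_len: int, band) -> ConnectivityStack:
    if isinstance(data, ConnectivityStack):
        return data
    if isinstance(data, ParcelTimeSeries):
        return build_connectivity_stack(data, window_len=window_len, band=band)
    raise ValidationError(f"cannot build a connectivity stack from {type(data)}")


def scramble_null_mean_t(
    pre: list,
    post: list,
    config: ModularityConfig | None = None,
    metric: str = "flexibility",
    n_null: int = 100,
    seed: int = 0,
    n_iter_null: int = 10,
    window_len: int = 20,
    band: tuple[float, float] = (0.06, 0.12),
) -> np.ndarray:
    """Null distribution of the whole-brain mean t under window scrambling.

    Per null iteration and subject, the pooled pre+post temporal windows are
    permuted and re-split into two surrogate conditions, destroying the
    pre/post identity; the metric is re-estimated (a reduced ensemble of
    ``n_iter_null`` detection runs per surrogate condition) and the paired
    tests re-run, recording the mean t over nodes.  Inputs may be time
    series or connectivity stacks: because every coherence layer is computed
    from exactly one window, scrambling windows of the time series is
    equivalent to permuting the pooled layers, which is how it is executed.
    """
    if metric not in REFERENCE_FREE:
        raise ValidationError(
            f"null model supports reference-free metrics {REFERENCE_FREE}"
        )
    if len(pre) != len(post):
        raise ValidationError("pre and post must pair up per subject")
    cfg = config or ModularityConfig()
    stacks_pre = [_to_stack(d, window_len, band) for d in pre]
    stacks_post = [_to_stack(d, window_len, band) for d in post]
    n_subj = len(stacks_pre)
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_null)
    for it in range(n_null):
        metric_pre = []
        metric_post = []
        for s in range(n_subj):
            pooled = np.concatenate(
                [stacks_pre[s].layers, stacks_post[s].layers], axis=0
            )
            perm = rng.permutation(pooled.shape[0])
            half = stacks_pre[s].n_layers
            for which, sel in (("a", perm[:half]), ("b", perm[half:])):
                surrogate = ConnectivityStack(
                    layers=pooled[sel],
                    band=stacks_pre[s].band,
                    window_len=stacks_pre[s].window_len,
                    parcel_ids=list(stacks_pre[s].parcel_ids),
                    region_labels=stacks_pre[s].region_labels,
                )
                sub_cfg = ModularityConfig(
                    gamma=cfg.gamma, omega=cfg.omega, n_iter=n_iter_null,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                ensemble = run_ensemble(surrogate, sub_cfg)
                vals = _metric_from_ensemble(ensemble, metric, None)
                (metric_pre if which == "a" else metric_post).append(vals)
        tests = paired_node_tests(np.array(metric_pre), np.array(metric_post))
        null_means[it] = float(np.nanmean(tests["t"].to_numpy()))
    return null_means
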