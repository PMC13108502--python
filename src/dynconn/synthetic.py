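"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators are provided.  ``generate_planted_stack`` builds a layer
stack of block-structured coherence-like matrices with known node-community
assignments, optionally with designated "switcher" nodes that change
community at chosen layers — the exact ground truth against which community
detection and the dynamic metrics are validated.
``generate_synthetic_bold`` produces band-limited (0.06–0.12 Hz) BOLD-like
parcel time series in which parcels of the same module share a latent
oscillatory signal, so windowed wavelet coherence concentrates within the
analysis band and within modules.  ``generate_two_condition_study`` emulates
a paired pre/post perturbation study: every node switches community between
temporal windows with a baseline probability, and after "stimulation" the
designated effect nodes switch more often, with the planted increase
calibrated to a requested standardized mean difference (Cohen's d across
subjects) of the switching rate.

The study defaults mirror the target scan geometry: 17 subjects, 560
volumes at TR = 2 s, 20-sample windows (28 layers), and a 432-parcel
atlas split into 200 left-cortical, 200 right-cortical, and 32 cerebellar
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .coherence import (
    DEFAULT_BAND,
    DEFAULT_WINDOW_LEN,
    ConnectivityStack,
    ParcelTimeSeries,
    ValidationError,
)
from .community import MultilayerPartition

__all__ = [
    "PlantedMultilayerSpec",
    "SyntheticStudySpec",
    "TwoConditionStudy",
    "default_region_labels",
    "generate_planted_stack",
    "generate_synthetic_bold",
    "generate_two_condition_study",
]


def default_region_labels(n_parcels: int) -> np.ndarray:
    """Left/right/cerebellum split proportional to the 200/200/32 atlas."""
    n_left = int(round(n_parcels * 200 / 432))
    n_right = int(round(n_parcels * 200 / 432))
    n_cb = n_parcels - n_left - n_right
    if n_cb < 1:
        n_cb = 1
        n_right = n_parcels - n_left - n_cb
    return np.asarray(
        ["left"] * n_left + ["right"] * n_right + ["cerebellum"] * n_cb,
        dtype=object,
    )


@dataclass(frozen=True)
class PlantedMultilayerSpec:
    """Parameters of a planted multilayer community structure."""

    n_nodes: int
    n_layers: int
    n_communities: int
    within_weight: float = 0.8
    between_weight: float = 0.2
    switchers: frozenset[int] = frozenset()
    switch_layers: frozenset[int] = frozenset()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities > self.n_nodes:
            raise ValidationError(
                f"{self.n_communities} communities for {self.n_nodes} nodes"
            )
        if not 0 <= self.between_weight < self.within_weight <= 1:
            raise ValidationError(
                "need 0 <= between_weight < within_weight <= 1"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        bad = set(self.switch_layers) - set(range(1, self.n_layers))
        if bad:
            raise ValidationError(
                f"switch_layers outside 1..{self.n_layers - 1}: {sorted(bad)}"
            )
        bad = set(self.switchers) - set(range(self.n_nodes))
        if bad:
            raise ValidationError(f"switchers outside node range: {sorted(bad)}")


def _block_layer(
    labels: np.ndarray,
    within: float,
    between: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Symmetric [0,1] weight matrix from community labels, unit diagonal."""
    same = labels[:, None] == labels[None, :]
    mat = np.where(same, within, between).astype(float)
    if noise_sd > 0:
        n = len(labels)
        jitter = rng.normal(0.0, noise_sd, size=(n, n))
        jitter = np.triu(jitter, 1)
        mat = mat + jitter + jitter.T  # symmetric jitter
        np.clip(mat, 0.0, 1.0, out=mat)  # truncation keeps the coherence range
    np.fill_diagonal(mat, 1.0)
    return mat


def generate_planted_stack(
    spec: PlantedMultilayerSpec,
) -> tuple[ConnectivityStack, MultilayerPartition]:
    """Planted block-structured stack plus its ground-truth partition.

    Nodes start in contiguous near-equal community blocks; at each layer in
    ``switch_layers``, every switcher moves to the next community id
    (cyclically), so ground-truth flexibility is exactly
    ``len(switch_layers) / (n_layers - 1)`` for switchers and 0 otherwise.
    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, L, k = spec.n_nodes, spec.n_layers, spec.n_communities
    base = np.empty(n, dtype=int)
    for c, idx in enumerate(np.array_split(np.arange(n), k)):
        base[idx] = c + 1
    labels = np.empty((n, L), dtype=int)
    current = base.copy()
    switchers = np.fromiter(spec.switchers, dtype=int) if spec.switchers else \
        np.empty(0, dtype=int)
    for l in range(L):
        if l in spec.switch_layers and len(switchers):
            current = current.copy()
            current[switchers] = current[switchers] % k + 1
        labels[:, l] = current
    layers = np.stack(
        [
            _block_layer(labels[:, l], spec.within_weight,
                         spec.between_weight, spec.noise_sd, rng)
            for l in range(L)
        ]
    )
    stack = ConnectivityStack(layers=layers, window_len=DEFAULT_WINDOW_LEN)
    truth = MultilayerPartition(labels=labels)
    return stack, truth


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Parameters of a paired pre/post synthetic study.

    ``effect_size`` is the planted standardized mean difference (Cohen's d
    across subjects) of the post-minus-pre community-switching rate at the
    ``effect_nodes``; with ``effect_size = 0`` the two conditions are drawn
    from identical distributions.
    """

    n_parcels: int
    n_subjects: int = 17
    n_volumes: int = 560
    tr: float = 2.0
    region_labels: np.ndarray | None = None
    effect_nodes: frozenset[int] = frozenset()
    effect_size: float = 0.0
    n_communities: int = 4
    base_switch_prob: float = 0.1
    within_weight: float = 0.8
    between_weight: float = 0.2
    noise_sd: float = 0.05
    bold_noise_sd: float = 0.5
    window_len: int = DEFAULT_WINDOW_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValidationError(f"tr must be positive, got {self.tr}")
        if self.n_volumes < 2:
            raise ValidationError("n_volumes must be >= 2")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be nonnegative")
        bad = set(self.effect_nodes) - set(range(self.n_parcels))
        if bad:
            raise ValidationError(f"effect_nodes outside parcel range: {sorted(bad)}")
        if self.region_labels is None:
            object.__setattr__(
                self, "region_labels", default_region_labels(self.n_parcels)
            )

    @property
    def n_windows(self) -> int:
        return self.n_volumes // self.window_len

    @property
    def parcel_ids(self) -> list[str]:
        return [f"parcel{i:03d}" for i in range(self.n_parcels)]


def _bandlimited_latent(
    n_volumes: int,
    tr: float,
    rng: np.random.Generator,
    band: tuple[float, float] = DEFAULT_BAND,
    n_components: int = 8,
) -> np.ndarray:
    """Unit-variance sum of sinusoids with frequencies uniform in the band."""
    t = np.arange(n_volumes) * tr
    freqs = rng.uniform(band[0], band[1], size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    sig = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def generate_synthetic_bold(
    spec: SyntheticStudySpec,
    module_assignment: np.ndarray,
    seed: int | None = None,
) -> ParcelTimeSeries:
    """Module-coupled, band-limited parcel time series, z-scored per parcel.

    ``module_assignment`` is either a static per-parcel labelling (shape
    ``(n_parcels,)``) or a per-window labelling (shape
    ``(n_parcels, n_windows)``); in the latter case each parcel follows the
    latent signal of its current module within each window.
    """
    assign = np.asarray(module_assignment, dtype=int)
    if assign.shape[0] != spec.n_parcels:
        raise ValidationError(
            f"module_assignment covers {assign.shape[0]} parcels, "
            f"spec has {spec.n_parcels}"
        )
    if assign.ndim == 1:
        assign = np.repeat(assign[:, None], max(spec.n_windows, 1), axis=1)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    modules = np.unique(assign)
    latents = {
        int(m): _bandlimited_latent(spec.n_volumes, spec.tr, rng)
        for m in modules
    }
    values = rng.normal(0.0, spec.bold_noise_sd,
                        size=(spec.n_volumes, spec.n_parcels))
    w = spec.window_len
    for win in range(assign.shape[1]):
        lo, hi = win * w, min((win + 1) * w, spec.n_volumes)
        for i in range(spec.n_parcels):
            values[lo:hi, i] += latents[int(assign[i, win])][lo:hi]
    # trailing partial window follows the last window's assignment
    if assign.shape[1] * w < spec.n_volumes:
        lo = assign.shape[1] * w
        for i in range(spec.n_parcels):
            values[lo:, i] += latents[int(assign[i, -1])][lo:]
    values -= values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    values /= sd
    return ParcelTimeSeries(
        values=values,
        tr=spec.tr,
        parcel_ids=spec.parcel_ids,
        region_labels=spec.region_labels,
    )


def _switch_prob_for_effect(
    p_base: float, effect_size: float, n_transitions: int
) -> float:
    """Post-condition switch probability planting a given Cohen's d.

    Per subject the pre/post switch counts are Binomial(m, p) and
    Binomial(m, p'); d = m (p' - p) / sqrt(m [p(1-p) + p'(1-p')]) is solved
    for p' (clipped to 0.95 if the requested d is unattainable).
    """
    if effect_size == 0:
        return p_base
    m = n_transitions

    def gap(p_post: float) -> float:
        sd = np.sqrt(p_base * (1 - p_base) + p_post * (1 - p_post))
        return np.sqrt(m) * (p_post - p_base) / sd - effect_size

    hi = 0.95
    if gap(hi) < 0:
        return hi
    return float(brentq(gap, p_base, hi))


@dataclass
class TwoConditionStudy:
    """Paired pre/post data for every subject, plus the generating truth."""

    pre: list
    post: list
    truth_pre: list[MultilayerPartition]
    truth_post: list[MultilayerPartition]
    spec: SyntheticStudySpec

    @property
    def n_subjects(self) -> int:
        return len(self.pre)


def _sample_window_labels(
    spec: SyntheticStudySpec,
    switch_prob: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-window community labels; node i switches between consecutive
    windows with probability switch_prob[i], moving to a random other
    community."""
    n, L, k = spec.n_parcels, spec.n_windows, spec.n_communities
    base = np.empty(n, dtype=int)
    for c, idx in enumerate(np.array_split(np.arange(n), k)):
        base[idx] = c + 1
    labels = np.empty((n, L), dtype=int)
    labels[:, 0] = base
    for l in range(1, L):
        labels[:, l] = labels[:, l - 1]
        flips = rng.random(n) < switch_prob
        if flips.any() and k > 1:
            jump = rng.integers(1, k, size=int(flips.sum()))
            labels[flips, l] = (labels[flips, l - 1] - 1 + jump) % k + 1
    return labels


def generate_two_condition_study(
    spec: SyntheticStudySpec,
    output: str = "partitions",
) -> TwoConditionStudy:
    """Paired pre/post study with a planted post-condition switching increase.

    ``output`` selects the representation of each subject-condition dataset:
    ``"partitions"`` returns the generating node-by-window community labels
    (fast; exact ground truth), ``"stack"`` returns block-structured
    connectivity layers built from those labels, and ``"timeseries"``
    returns module-coupled BOLD-like signals from which the full pipeline
    (coherence onward) can run.
    """
    if output not in ("partitions", "stack", "timeseries"):
        raise ValidationError(f"unknown output kind {output!r}")
    rng = np.random.default_rng(spec.seed)
    m = spec.n_windows - 1
    if m < 1:
        raise ValidationError("study needs at least 2 temporal windows")
    p_post_effect = _switch_prob_for_effect(
        spec.base_switch_prob, spec.effect_size, m
    )
    effect = np.fromiter(spec.effect_nodes, dtype=int) if spec.effect_nodes \
        else np.empty(0, dtype=int)

    pre_data, post_data = [], []
    truth_pre, truth_post = [], []
    for _s in range(spec.n_subjects):
        for cond, store, truths in (
            ("pre", pre_data, truth_pre),
            ("post", post_data, truth_post),
        ):
            probs = np.full(spec.n_parcels, spec.base_switch_prob)
            if cond == "post":
                probs[effect] = p_post_effect
            labels = _sample_window_labels(spec, probs, rng)
            truths.append(MultilayerPartition(labels=labels))
            if output == "partitions":
                store.append(MultilayerPartition(labels=labels.copy()))
            elif output == "stack":
                layers = np.stack(
                    [
                        _block_layer(labels[:, l], spec.within_weight,
                                     spec.between_weight, spec.noise_sd, rng)
                        for l in range(spec.n_windows)
                    ]
                )
                store.append(
                    ConnectivityStack(
                        layers=layers,
                        window_len=spec.window_len,
                        parcel_ids=spec.parcel_ids,
                        region_labels=spec.region_labels,
                    )
                )
            else:
                store.append(
                    generate_synthetic_bold(
                        spec, labels,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
    return TwoConditionStudy(
        pre=pre_data,
        post=post_data,
        truth_pre=truth_pre,
        truth_post=truth_post,
        spec=spec,
    )
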