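"""Time-resolved functional connectivity from band-averaged wavelet coherence.

Parcel time series are tiled into fixed-length, nonoverlapping temporal
windows; within each window the magnitude-squared wavelet coherence
(complex Morlet, smoothed in time and scale) is averaged over the scales
whose equivalent Fourier frequency falls in the analysis band, yielding one
symmetric connectivity matrix ("temporal layer") per window.  The default
geometry — 20-sample (40 s at TR = 2 s) windows and a 0.06–0.12 Hz band —
tiles a 560-volume resting-state scan into 28 layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import fftconvolve

__all__ = [
    "ParcelTimeSeries",
    "ConnectivityStack",
    "count_windows",
    "cycles_in_window",
    "wavelet_coherence_pair",
    "build_connectivity_stack",
]

#: complex Morlet with omega0 = 6 in PyWavelets' cmorB-C parametrisation:
#: psi(t) ~ exp(-t^2/B) exp(2*pi*i*C*t) with B = 2, 2*pi*C = 6.
MORLET_OMEGA0 = 6.0
_CMOR_C = MORLET_OMEGA0 / (2.0 * np.pi)
WAVELET_NAME = f"cmor2.0-{_CMOR_C:.12f}"

DEFAULT_BAND = (0.06, 0.12)
DEFAULT_WINDOW_LEN = 20
VOICES_PER_OCTAVE = 12
#: boxcar width of the scale smoothing, in octaves
SCALE_SMOOTH_OCTAVES = 0.6

REGIONS = ("left", "right", "cerebellum")


class ValidationError(ValueError):
    """Raised when an input object violates its declared invariants."""


@dataclass
class ParcelTimeSeries:
    """Parcellated BOLD signals: one column per parcel, one row per volume.

    Parameters
    ----------
    values : (n_volumes, n_parcels) float array
    tr : sampling interval in seconds (repetition time)
    parcel_ids : ordered parcel labels
    region_labels : per-parcel region, one of ``left``/``right``/``cerebellum``
    """

    values: np.ndarray
    tr: float
    parcel_ids: list[str]
    region_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (volumes x parcels) array")
        if self.tr <= 0:
            raise ValidationError(f"tr must be positive, got {self.tr}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            raise ValidationError(
                f"non-finite values at (row, col) {bad[:5].tolist()}"
                + ("..." if len(bad) > 5 else "")
            )
        n_parcels = self.values.shape[1]
        if len(self.parcel_ids) != n_parcels:
            raise ValidationError(
                f"{len(self.parcel_ids)} parcel ids for {n_parcels} columns"
            )
        if len(self.region_labels) != n_parcels:
            raise ValidationError(
                f"{len(self.region_labels)} region labels for {n_parcels} parcels"
            )
        unknown = set(self.region_labels) - set(REGIONS)
        if unknown:
            raise ValidationError(f"unknown region labels: {sorted(unknown)}")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityStack:
    """Ordered temporal layers of symmetric coherence matrices in [0, 1]."""

    layers: np.ndarray  # (n_layers, n, n)
    band: tuple[float, float] = DEFAULT_BAND
    window_len: int = DEFAULT_WINDOW_LEN
    parcel_ids: list[str] = field(default_factory=list)
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValidationError("layers must be (n_layers, n, n)")
        n = self.layers.shape[1]
        if not self.parcel_ids:
            self.parcel_ids = [f"parcel{i:03d}" for i in range(n)]
        if self.region_labels is None:
            self.region_labels = np.asarray(["left"] * n, dtype=object)

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def validate(self) -> None:
        if np.any(self.layers < -1e-9) or np.any(self.layers > 1 + 1e-9):
            raise ValidationError("layer entries outside [0, 1]")
        if not np.allclose(self.layers, np.swapaxes(self.layers, 1, 2), atol=1e-9):
            raise ValidationError("layers are not symmetric")

    def subset_layers(self, start: int, stop: int) -> "ConnectivityStack":
        """A new stack restricted to layers ``start:stop`` (same nodes)."""
        return ConnectivityStack(
            layers=self.layers[start:stop].copy(),
            band=self.band,
            window_len=self.window_len,
            parcel_ids=list(self.parcel_ids),
            region_labels=self.region_labels,
        )


def count_windows(n_volumes: int, window_len: int) -> int:
    """Number of nonoverlapping windows tiling the scan left to right.

    The trailing partial window is discarded; 560 volumes with a 20-sample
    window give 28 layers.
    """
    if window_len < 1:
        raise ValidationError(f"window_len must be >= 1, got {window_len}")
    n = n_volumes // window_len
    if n == 0:
        warnings.warn(
            f"{n_volumes} volumes shorter than one {window_len}-sample window",
            stacklevel=2,
        )
    return n


def cycles_in_window(window_seconds: float, freq: float) -> float:
    """Number of oscillation cycles a window of given duration contains."""
    if window_seconds < 0 or freq < 0:
        raise ValidationError("window_seconds and freq must be nonnegative")
    return window_seconds * freq


def _scale_grid(tr: float, f_min: float = 0.04, f_max: float = 0.2) -> np.ndarray:
    """Geometric scale grid (in samples) covering at least [f_min, f_max] Hz."""
    s_min = _CMOR_C / (f_max * tr)
    s_max = _CMOR_C / (f_min * tr)
    n = int(np.ceil(VOICES_PER_OCTAVE * np.log2(s_max / s_min))) + 1
    return s_min * 2.0 ** (np.arange(n) / VOICES_PER_OCTAVE)


def _scale_frequencies(scales: np.ndarray, tr: float) -> np.ndarray:
    return pywt.scale2frequency(WAVELET_NAME, scales) / tr


def _time_kernels(scales: np.ndarray, n_samples: int) -> list[np.ndarray]:
    """Per-scale Gaussian time-smoothing kernels (std = scale, in samples)."""
    kernels = []
    for s in scales:
        half = int(min(max(np.ceil(3.0 * s), 1), n_samples))
        t = np.arange(-half, half + 1, dtype=float)
        k = np.exp(-(t**2) / (2.0 * s**2))
        kernels.append(k / k.sum())
    return kernels


def _scale_kernel() -> np.ndarray:
    width = int(round(SCALE_SMOOTH_OCTAVES * VOICES_PER_OCTAVE))
    width = max(width // 2 * 2 + 1, 1)  # odd
    return np.ones(width) / width


def _smooth_time(arr: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    """Smooth along the last axis, one kernel per leading (scale) index."""
    out = np.empty_like(arr)
    for si, k in enumerate(kernels):
        shape = (1,) * (arr.ndim - 2) + (len(k),)
        out[si] = fftconvolve(arr[si], k.reshape(shape), mode="same", axes=-1)
    return out


def _smooth_scale(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Boxcar smooth along the first (scale) axis, zero-padded ends."""
    shape = (len(kernel),) + (1,) * (arr.ndim - 1)
    return fftconvolve(arr, kernel.reshape(shape), mode="same", axes=0)


def _cwt(seg: np.ndarray, scales: np.ndarray, tr: float) -> np.ndarray:
    """CWT of (n_signals, n_samples) -> (n_scales, n_signals, n_samples)."""
    coef, _ = pywt.cwt(seg, scales, WAVELET_NAME, sampling_period=tr, axis=-1)
    return coef


def _coherence_matrix(
    seg: np.ndarray,
    tr: float,
    band: tuple[float, float],
    chunk: int = 16,
) -> np.ndarray:
    """Band-averaged wavelet coherence between all columns of one window.

    ``seg`` is (n_samples, n_parcels).  Returns an (n, n) matrix; entries
    involving a constant (zero-variance) parcel are NaN.
    """
    n_t, n_p = seg.shape
    scales = _scale_grid(tr)
    freqs = _scale_frequencies(scales, tr)
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    if not band_mask.any():
        raise ValidationError(f"no wavelet scales inside band {band}")
    kernels = _time_kernels(scales, n_t)
    box = _scale_kernel()

    x = seg.T - seg.T.mean(axis=1, keepdims=True)
    const = seg.std(axis=0) == 0.0

    w = _cwt(x, scales, tr)  # (S, P, T)
    wn = w / scales[:, None, None]

    # smoothed auto-spectra (real, nonnegative): diagonal of the cross tensor
    auto = _smooth_scale(_smooth_time(np.abs(wn) ** 2, kernels), box)
    auto = np.maximum(auto, 0.0)

    out = np.full((n_p, n_p), np.nan)
    wn_conj = np.conj(wn)
    for i0 in range(0, n_p, chunk):
        i1 = min(i0 + chunk, n_p)
        cross = wn[:, i0:i1, None, :] * wn_conj[:, None, :, :]  # (S, c, P, T)
        sm = _smooth_scale(_smooth_time(cross, kernels), box)
        num = np.abs(sm) ** 2
        den = auto[:, i0:i1, None, :] * auto[:, None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = num / den
        out[i0:i1] = np.nanmean(r2[band_mask], axis=(0, 3))
    out[const, :] = np.nan
    out[:, const] = np.nan
    # numerical guard: Cauchy-Schwarz bounds coherence by 1
    np.clip(out, 0.0, 1.0, out=out)
    return out


def wavelet_coherence_pair(
    x: np.ndarray,
    y: np.ndarray,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Band- and time-averaged magnitude-squared wavelet coherence of x and y.

    Symmetric in its arguments and equal to 1 (to numerical precision) when
    the signals are identical, because the numerator and denominator undergo
    identical time/scale smoothing.  A constant signal has undefined
    coherence and yields NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.std() == 0.0 or y.std() == 0.0:
        warnings.warn("constant signal: coherence undefined, returning NaN",
                      stacklevel=2)
        return float("nan")
    mat = _coherence_matrix(np.column_stack([x, y]), tr, band)
    return float(mat[0, 1])


def build_connectivity_stack(
    ts: ParcelTimeSeries,
    window_len: int = DEFAULT_WINDOW_LEN,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ConnectivityStack:
    """Tile the scan into nonoverlapping windows and estimate one coherence
    layer per window.

    Diagonals are set to 1.  Edges of any parcel that is constant within a
    window are imputed as 0 for that layer (with a warning) so the node set
    stays fixed across layers.
    """
    n_win = count_windows(ts.n_volumes, window_len)
    cyc = cycles_in_window(window_len * ts.tr, band[0])
    if cyc < 2:
        warnings.warn(
            f"window holds only {cyc:.2f} cycles at {band[0]} Hz (< 2); "
            "coherence estimates will be unstable",
            stacklevel=2,
        )
    n = ts.n_parcels
    layers = np.empty((n_win, n, n))
    imputed = 0
    for w in range(n_win):
        seg = ts.values[w * window_len : (w + 1) * window_len]
        mat = _coherence_matrix(seg, ts.tr, band)
        bad = ~np.isfinite(mat)
        np.fill_diagonal(bad, False)
        if bad.any():
            imputed += 1
            mat[bad] = 0.0
        mat = 0.5 * (mat + mat.T)
        np.fill_diagonal(mat, 1.0)
        layers[w] = mat
    if imputed:
        warnings.warn(
            f"imputed 0 for undefined coherence in {imputed} layer(s) "
            "(constant parcel within window)",
            stacklevel=2,
        )
    return ConnectivityStack(
        layers=layers,
        band=band,
        window_len=window_len,
        parcel_ids=list(ts.parcel_ids),
        region_labels=ts.region_labels,
    )
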