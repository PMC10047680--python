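"""Resting-state summary derivatives.

Each operation collapses the time axis of a 4D functional volume to a
single 3D map (ten maps for dual regression): regional homogeneity
(ReHo, Kendall's coefficient of concordance over a voxel
neighbourhood), (fractional) amplitude of low-frequency fluctuations
(ALFF/fALFF), binarized and weighted degree and eigenvector centrality
of the voxelwise correlation graph, local functional connectivity
density (LFCD), voxel-mirrored homotopic connectivity (VMHC), and dual
regression against group spatial templates.  ``compute_all`` stacks the
full derivative set in a fixed channel order (9 voxelwise maps + one
channel per template).

Conventions adopted throughout:

* the correlation of any pair involving a constant series is 0;
* spectral amplitude is ``2 |X_k| / n`` from an unwindowed DFT of the
  linearly detrended series;
* the mirror axis is the first array axis (voxel ``i`` pairs with
  ``Nx - 1 - i``).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import (
    ConfigurationError,
    ConvergenceError,
    ShapeError,
    ValidationError,
)
from .volume_io import SummaryStack, Volume4D, stack_channels

__all__ = [
    "SummaryConfig",
    "reho",
    "alff",
    "falff",
    "degree_centrality",
    "eigenvector_centrality",
    "lfcd",
    "vmhc",
    "dual_regression",
    "compute_all",
    "VOXELWISE_CHANNELS",
]

VOXELWISE_CHANNELS = (
    "reho",
    "alff",
    "falff",
    "dc_bin",
    "dc_weighted",
    "ec_bin",
    "ec_weighted",
    "lfcd",
    "vmhc",
)


@dataclass(frozen=True)
class SummaryConfig:
    """Band limits, correlation threshold and neighbourhood size.

    The low-frequency band defaults to the standard 0.01-0.08 Hz ALFF
    band; the full band for fALFF runs to 0.25 Hz.
    """

    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    full_band_high_hz: float = 0.25
    corr_threshold: float = 0.25
    neighborhood: int = 26
    detrend: bool = True
    power_max_iter: int = 1000
    power_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not 0 <= self.band_low_hz < self.band_high_hz <= self.full_band_high_hz:
            raise ValidationError(
                "need 0 <= band_low_hz < band_high_hz <= full_band_high_hz"
            )
        if not -1 < self.corr_threshold < 1:
            raise ValidationError("corr_threshold must be in (-1, 1)")
        if self.neighborhood not in (6, 18, 26):
            raise ValidationError("neighborhood must be 6, 18 or 26")


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def _standardize(series: np.ndarray) -> np.ndarray:
    """Z-score along the last axis; constant series become all-zero rows,
    which realises the r = 0 convention for their correlations."""
    mu = series.mean(axis=-1, keepdims=True)
    sd = series.std(axis=-1, keepdims=True)
    out = np.zeros_like(series, dtype=np.float64)
    np.divide(series - mu, sd, out=out, where=sd > 0)
    return out


# ---------------------------------------------------------------------------
# ReHo
# ---------------------------------------------------------------------------

def reho(vol: Volume4D, cfg: SummaryConfig = SummaryConfig()) -> np.ndarray:
    """Kendall's coefficient of concordance over each voxel's neighbourhood.

    For the K in-mask series (voxel plus neighbours), with mid-rank ties
    and the tie-correction term in the denominator:

        W = 12 * sum_t (S_t - K(n+1)/2)^2 / (K^2 (n^3 - n) - K * sum_j T_j)

    where ``S_t`` is the rank sum across the K series at timepoint t and
    ``T_j = sum (t_g^3 - t_g)`` over tied groups of series j.
    """
    n = vol.n_timepoints
    if n < 3:
        raise ValidationError("ReHo needs at least 3 timepoints")
    mask = vol.get_mask()
    data = vol.data
    # mid-ranks over time per voxel
    ranks = sp_stats.rankdata(data, axis=3)
    # tie correction per voxel series: sum over tied groups of (g^3 - g)
    tcorr = np.zeros(vol.spatial_shape)
    for idx in np.ndindex(vol.spatial_shape):
        if not mask[idx]:
            continue
        _, counts = np.unique(data[idx], return_counts=True)
        tcorr[idx] = np.sum(counts**3 - counts)

    offsets = _neighbor_offsets(cfg.neighborhood)
    shape = vol.spatial_shape
    rank_sum = np.where(mask[..., None], ranks, 0.0).copy()
    kcount = mask.astype(np.float64)
    tsum = np.where(mask, tcorr, 0.0).copy()

    def _shift(arr: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros_like(arr)
        src = [slice(max(0, -o), arr.shape[i] - max(0, o)) for i, o in enumerate(off)]
        dst = [slice(max(0, o), arr.shape[i] - max(0, -o)) for i, o in enumerate(off)]
        out[tuple(dst)] = arr[tuple(src)]
        return out

    masked_ranks = np.where(mask[..., None], ranks, 0.0)
    masked_t = np.where(mask, tcorr, 0.0)
    for off in offsets:
        rank_sum += _shift(masked_ranks, off)
        kcount += _shift(mask.astype(np.float64), off)
        tsum += _shift(masked_t, off)

    mean_rank = kcount * (n + 1) / 2.0
    s = np.sum((rank_sum - mean_rank[..., None]) ** 2, axis=3)
    denom = kcount**2 * (n**3 - n) - kcount * tsum
    out = np.zeros(shape)
    valid = mask & (denom > 0)
    out[valid] = 12.0 * s[valid] / denom[valid]
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Spectral maps
# ---------------------------------------------------------------------------

def _amplitude_spectrum(vol: Volume4D, cfg: SummaryConfig):
    """Single-sided amplitude ``2|X_k|/n`` per voxel and the bin grid."""
    n = vol.n_timepoints
    if n < 8:
        raise ValidationError("spectral maps need at least 8 timepoints")
    data = vol.data
    if cfg.detrend:
        data = sp_signal.detrend(data, axis=3, type="linear")
    spec = np.abs(np.fft.rfft(data, axis=3)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=vol.tr_seconds)
    return spec, freqs


def _band_bins(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    sel = (freqs >= low) & (freqs <= high)
    sel[0] = False  # DC excluded
    return sel


def alff(vol: Volume4D, cfg: SummaryConfig = SummaryConfig()) -> np.ndarray:
    """Mean spectral amplitude over the low-frequency band (DC excluded)."""
    spec, freqs = _amplitude_spectrum(vol, cfg)
    sel = _band_bins(freqs, cfg.band_low_hz, cfg.band_high_hz)
    if not sel.any():
        raise ConfigurationError(
            f"band [{cfg.band_low_hz}, {cfg.band_high_hz}] Hz contains no DFT "
            f"bin; resolvable bins span {freqs[1]:.4g}-{freqs[-1]:.4g} Hz "
            f"in steps of {freqs[1]:.4g} Hz"
        )
    out = spec[..., sel].mean(axis=3)
    out[~vol.get_mask()] = 0.0
    return out


def falff(vol: Volume4D, cfg: SummaryConfig = SummaryConfig()) -> np.ndarray:
    """Ratio of band amplitude to full-band amplitude; 0 where the
    denominator vanishes."""
    spec, freqs = _amplitude_spectrum(vol, cfg)
    sel = _band_bins(freqs, cfg.band_low_hz, cfg.band_high_hz)
    full = _band_bins(freqs, 0.0, cfg.full_band_high_hz)
    if not sel.any():
        raise ConfigurationError(
            f"band [{cfg.band_low_hz}, {cfg.band_high_hz}] Hz contains no DFT bin"
        )
    num = spec[..., sel].sum(axis=3)
    den = spec[..., full].sum(axis=3)
    out = np.zeros(vol.spatial_shape)
    np.divide(num, den, out=out, where=den > 0)
    out[~vol.get_mask()] = 0.0
    out[vol.data.var(axis=3) == 0] = 0.0  # constant series: amplitude is 0
    return out


# ---------------------------------------------------------------------------
# Correlation-graph maps
# ---------------------------------------------------------------------------

def _corr_matrix(vol: Volume4D) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlation of in-mask voxel series.

    Returns (r, mask_indices).  Constant series correlate 0 with
    everything (and with themselves).
    """
    if vol.n_timepoints < 3:
        raise ValidationError("correlation maps need at least 3 timepoints")
    mask = vol.get_mask()
    idx = np.nonzero(mask)
    if idx[0].size < 2:
        raise ValidationError("need at least 2 in-mask voxels")
    z = _standardize(vol.data[idx])
    r = (z @ z.T) / vol.n_timepoints
    return r, mask


def degree_centrality(
    vol: Volume4D, cfg: SummaryConfig = SummaryConfig(), weighted: bool = False
) -> np.ndarray:
    """Count (binarized) or sum (weighted) of suprathreshold correlations
    of each in-mask voxel with every other in-mask voxel, self excluded."""
    r, mask = _corr_matrix(vol)
    np.fill_diagonal(r, 0.0)
    above = r >= cfg.corr_threshold
    vals = (r * above).sum(axis=1) if weighted else above.sum(axis=1).astype(float)
    out = np.zeros(vol.spatial_shape)
    out[mask] = vals
    return out


def eigenvector_centrality(
    vol: Volume4D, cfg: SummaryConfig = SummaryConfig(), weighted: bool = False
) -> np.ndarray:
    """Leading-eigenvector centrality of the thresholded correlation graph.

    The similarity matrix is made nonnegative by the ``(1 + r) / 2``
    rescale: binarized entries are 1 where ``r >= corr_threshold`` (the
    diagonal, r = 1, included), weighted entries keep ``(1 + r) / 2``.
    Power iteration from the uniform vector returns the nonnegative
    unit-norm leading eigenvector.
    """
    r, mask = _corr_matrix(vol)
    above = r >= cfg.corr_threshold
    np.fill_diagonal(above, True)
    if weighted:
        m = np.where(above, (1.0 + r) / 2.0, 0.0)
        np.fill_diagonal(m, 1.0)
    else:
        m = above.astype(np.float64)
    v = np.full(m.shape[0], 1.0 / np.sqrt(m.shape[0]))
    for _ in range(cfg.power_max_iter):
        w = m @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        resid = np.linalg.norm(w - v)
        v = w
        if resid < cfg.power_tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration did not converge (residual {resid:.3e})"
        )
    out = np.zeros(vol.spatial_shape)
    out[mask] = v
    return out


def lfcd(vol: Volume4D, cfg: SummaryConfig = SummaryConfig()) -> np.ndarray:
    """Local functional connectivity density.

    From each in-mask seed, grow a face-adjacent (6-connectivity)
    cluster admitting in-mask voxels whose correlation *with the seed*
    is at or above the threshold; the map holds the cluster size
    (seed included).
    """
    if vol.n_timepoints < 3:
        raise ValidationError("LFCD needs at least 3 timepoints")
    mask = vol.get_mask()
    if mask.sum() < 2:
        raise ValidationError("need at least 2 in-mask voxels")
    z = _standardize(vol.data)
    n = vol.n_timepoints
    shape = vol.spatial_shape
    offsets = _neighbor_offsets(6)
    out = np.zeros(shape)
    seeds = list(zip(*np.nonzero(mask)))
    for seed in seeds:
        zs = z[seed]
        visited = {seed}
        queue = deque([seed])
        size = 1
        while queue:
            cur = queue.popleft()
            for off in offsets:
                nb = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if not all(0 <= nb[i] < shape[i] for i in range(3)):
                    continue
                if nb in visited or not mask[nb]:
                    continue
                visited.add(nb)
                if (zs @ z[nb]) / n >= cfg.corr_threshold:
                    queue.append(nb)
                    size += 1
        out[seed] = size
    return out


def vmhc(vol: Volume4D, cfg: SummaryConfig = SummaryConfig()) -> np.ndarray:
    """Pearson correlation of every voxel with its first-axis mirror.

    Voxels whose mirror partner (or themselves) is out of mask get 0.
    """
    if vol.n_timepoints < 3:
        raise ValidationError("VMHC needs at least 3 timepoints")
    mask = vol.get_mask()
    z = _standardize(vol.data)
    zf = z[::-1]
    out = (z * zf).sum(axis=3) / vol.n_timepoints
    out[~(mask & mask[::-1])] = 0.0
    return out


# ---------------------------------------------------------------------------
# Dual regression
# ---------------------------------------------------------------------------

def dual_regression(
    vol: Volume4D, templates: list[np.ndarray]
) -> SummaryStack:
    """Two-stage least squares against group spatial templates.

    Stage 1 regresses each timepoint's in-mask image on the template
    vectors, giving a (t x S) time-course matrix; stage 2 regresses each
    voxel's series on those time courses, giving one subject-specific
    spatial map per template.
    """
    s = len(templates)
    if s < 1:
        raise ValidationError("need at least one template")
    if vol.n_timepoints <= s:
        raise ValidationError("need more timepoints than templates")
    for m in templates:
        if np.asarray(m).shape != vol.spatial_shape:
            raise ShapeError("template grid does not match volume grid")
    mask = vol.get_mask()
    p = np.stack([np.asarray(m)[mask] for m in templates], axis=1)  # V x S
    if np.linalg.matrix_rank(p) < s:
        raise ValidationError("rank-deficient design in spatial regression stage")
    x = vol.data[mask]  # V x t
    tcs, *_ = np.linalg.lstsq(p, x, rcond=None)  # S x t
    tcs = tcs.T  # t x S
    if np.linalg.matrix_rank(tcs) < s:
        raise ValidationError("rank-deficient design in temporal regression stage")
    coefs, *_ = np.linalg.lstsq(tcs, x.T, rcond=None)  # S x V
    maps = []
    for j in range(s):
        m = np.zeros(vol.spatial_shape)
        m[mask] = coefs[j]
        maps.append(m)
    return stack_channels(maps, [f"dr_{j + 1:02d}" for j in range(s)])


# ---------------------------------------------------------------------------
# Full derivative set
# ---------------------------------------------------------------------------

def compute_all(
    vol: Volume4D,
    templates: list[np.ndarray] | None = None,
    cfg: SummaryConfig = SummaryConfig(),
) -> SummaryStack:
    """All summary derivatives in fixed channel order.

    Channels: reho, alff, falff, dc_bin, dc_weighted, ec_bin,
    ec_weighted, lfcd, vmhc, then one dual-regression map per template
    (19 channels with the default 10 templates).
    """
    maps = [
        reho(vol, cfg),
        alff(vol, cfg),
        falff(vol, cfg),
        degree_centrality(vol, cfg, weighted=False),
        degree_centrality(vol, cfg, weighted=True),
        eigenvector_centrality(vol, cfg, weighted=False),
        eigenvector_centrality(vol, cfg, weighted=True),
        lfcd(vol, cfg),
        vmhc(vol, cfg),
    ]
    names = list(VOXELWISE_CHANNELS)
    if templates:
        dr = dual_regression(vol, templates)
        maps.extend(dr.data[..., j] for j in range(dr.n_channels))
        names.extend(dr.channel_names)
    return stack_channels(maps, names)
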