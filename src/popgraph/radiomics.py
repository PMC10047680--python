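"""Per-ROI radiomic features on level-1 wavelet sub-bands.

For each atlas region the structural volume contributes 19 first-order
(histogram) features and 22 grey-level co-occurrence (GLCM) texture
features on each of the 8 level-1 wavelet sub-bands (low/high-pass
along each axis: LLL ... HHH), i.e. (19 + 22) x 8 = 328 features per
ROI and 328 x 148 = 48,544 per subject with the default 148-region
parcellation.

The decomposition is undecimated (stationary): each sub-band keeps the
input grid, so the atlas mask applies unchanged.  Filters are the 8-tap
Daubechies (db4) bank scaled by 1/sqrt(2) per axis, which preserves
total energy across the 8 sub-bands under periodic boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import convolve1d

from .errors import ShapeError, SizingError, ValidationError
from .volume_io import LabelMap

__all__ = [
    "RadiomicsConfig",
    "RadiomicVector",
    "wavelet_subbands",
    "first_order_features",
    "glcm_features",
    "glcm_matrix",
    "extract_subject",
    "SUBBAND_NAMES",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
]

SUBBAND_NAMES = tuple(
    "".join(c) for c in itertools.product("LH", repeat=3)
)  # LLL, LLH, ..., HHH

FIRST_ORDER_NAMES = (
    "energy",
    "total_energy",
    "entropy",
    "minimum",
    "percentile10",
    "percentile90",
    "maximum",
    "mean",
    "median",
    "interquartile_range",
    "range",
    "mean_absolute_deviation",
    "robust_mean_absolute_deviation",
    "root_mean_squared",
    "standard_deviation",
    "skewness",
    "kurtosis",
    "variance",
    "uniformity",
)

GLCM_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "idm",
    "idmn",
    "id",
    "idn",
    "inverse_variance",
    "maximum_probability",
    "sum_entropy",
    "sum_of_squares",
)

# the 13 unique direction offsets at distance 1 (one of each +/- pair)
DEFAULT_OFFSETS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


@dataclass(frozen=True)
class RadiomicsConfig:
    wavelet_family: str = "db4"  # 8-tap Daubechies
    boundary_mode: str = "symmetric"  # or "periodic"
    glcm_levels: int = 32
    glcm_offsets: tuple = DEFAULT_OFFSETS
    discretization: str = "fixed_bin_count"  # or "fixed_bin_width"
    bin_width: float = 1.0
    histogram_bins: int = 32  # first-order entropy/uniformity discretization

    def __post_init__(self) -> None:
        if self.glcm_levels < 2:
            raise ValidationError("glcm_levels must be >= 2")
        if self.boundary_mode not in ("symmetric", "periodic"):
            raise ValidationError("boundary_mode must be symmetric or periodic")
        if self.discretization not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValidationError("unknown discretization")
        seen = set()
        for off in self.glcm_offsets:
            if off == (0, 0, 0):
                raise ValidationError("offsets must be nonzero")
            neg = tuple(-o for o in off)
            if neg in seen:
                raise ValidationError(f"antiparallel offsets {off}/{neg}")
            seen.add(off)


@dataclass
class RadiomicVector:
    """Flat feature vector with (roi_id, subband, feature) provenance."""

    values: np.ndarray
    index: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.index) != self.values.size:
            raise ShapeError("index length must match number of values")


# ---------------------------------------------------------------------------
# Wavelet sub-bands
# ---------------------------------------------------------------------------

def wavelet_subbands(
    vol: np.ndarray, cfg: RadiomicsConfig = RadiomicsConfig()
) -> dict[str, np.ndarray]:
    """Undecimated level-1 separable decomposition: 8 named sub-bands.

    Low/high-pass filters are applied along each of the 3 axes in all
    2^3 combinations without downsampling, so every sub-band shares the
    input grid.  Filters are normalised by 1/sqrt(2) per axis: for an
    orthonormal family with periodic boundaries the sub-band energies
    then sum to the input energy.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3:
        raise ShapeError("expected a 3D volume")
    wav = pywt.Wavelet(cfg.wavelet_family)
    lo = np.asarray(wav.dec_lo) / np.sqrt(2.0)
    hi = np.asarray(wav.dec_hi) / np.sqrt(2.0)
    if min(vol.shape) < len(lo):
        raise SizingError(
            f"every dim must be >= filter length {len(lo)}; got {vol.shape}"
        )
    mode = "reflect" if cfg.boundary_mode == "symmetric" else "wrap"
    out: dict[str, np.ndarray] = {}
    for name in SUBBAND_NAMES:
        band = vol
        for axis, letter in enumerate(name):
            filt = lo if letter == "L" else hi
            band = convolve1d(band, filt, axis=axis, mode=mode)
        out[name] = band
    return out


# ---------------------------------------------------------------------------
# First-order features
# ---------------------------------------------------------------------------

def first_order_features(
    values: np.ndarray, cfg: RadiomicsConfig = RadiomicsConfig(), roi_id=None
) -> dict[str, float]:
    """The 19 standard first-order statistics of an ROI's intensities.

    Entropy and uniformity use a ``histogram_bins``-bin histogram over
    the ROI's min-max range; moments use population (1/N) denominators.
    A constant ROI has entropy 0 and uniformity 1.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValidationError(f"empty ROI (roi_id={roi_id})")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    rng_ = x.max() - x.min()
    if rng_ > 0:
        hist, _ = np.histogram(x, bins=cfg.histogram_bins, range=(x.min(), x.max()))
        p = hist[hist > 0] / n
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float(((hist / n) ** 2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    robust = x[(x >= p10) & (x <= p90)]
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd**3)
        kurt = float(((x - mean) ** 4).mean() / sd**4)  # non-excess
    else:
        skew, kurt = 0.0, 0.0
    feats = {
        "energy": float((x**2).sum()),
        "total_energy": float((x**2).sum()),  # unit voxel volume
        "entropy": entropy,
        "minimum": float(x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "maximum": float(x.max()),
        "mean": float(mean),
        "median": float(p50),
        "interquartile_range": float(p75 - p25),
        "range": float(rng_),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": float(
            np.abs(robust - robust.mean()).mean()
        ),
        "root_mean_squared": float(np.sqrt((x**2).mean())),
        "standard_deviation": float(sd),
        "skewness": skew,
        "kurtosis": kurt,
        "variance": float(var),
        "uniformity": uniformity,
    }
    return feats


# ---------------------------------------------------------------------------
# GLCM features
# ---------------------------------------------------------------------------

def _discretize(x: np.ndarray, cfg: RadiomicsConfig) -> np.ndarray:
    """Map ROI intensities to levels 0..L-1."""
    if cfg.discretization == "fixed_bin_count":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.shape, dtype=np.int64)
        g = np.floor((x - lo) / (hi - lo) * cfg.glcm_levels).astype(np.int64)
        return np.clip(g, 0, cfg.glcm_levels - 1)
    g = np.floor(x / cfg.bin_width).astype(np.int64)
    return g - g.min()


def glcm_matrix(
    values: np.ndarray,
    roi_mask: np.ndarray,
    offset: tuple[int, int, int],
    cfg: RadiomicsConfig = RadiomicsConfig(),
    levels: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix for one offset,
    restricted to voxel pairs that both lie inside the ROI."""
    if levels is None:
        full = np.zeros(values.shape, dtype=np.int64)
        full[roi_mask] = _discretize(values[roi_mask], cfg)
        levels = full
    ng = int(levels[roi_mask].max()) + 1
    shape = values.shape
    src = tuple(
        slice(max(0, -o), shape[i] - max(0, o)) for i, o in enumerate(offset)
    )
    dst = tuple(
        slice(max(0, o), shape[i] - max(0, -o)) for i, o in enumerate(offset)
    )
    valid = roi_mask[src] & roi_mask[dst]
    a = levels[src][valid]
    b = levels[dst][valid]
    counts = np.zeros((ng, ng))
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T  # symmetric
    total = counts.sum()
    return counts / total if total > 0 else counts


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    """The 22 texture features of one normalised co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = (i * px).sum()  # symmetric: mu_x == mu_y
    sig_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    eps = np.finfo(float).tiny

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=float)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())

    joint_entropy = float(-(p * np.log2(p + eps))[p > 0].sum())
    hx = float(-(px * np.log2(px + eps))[px > 0].sum())
    # entropies of the product distribution for information measures
    pxy = np.outer(px, px)
    hxy1 = float(-(p * np.log2(pxy + eps))[p > 0].sum())
    hxy2 = float(-(pxy * np.log2(pxy + eps))[pxy > 0].sum())

    diff_avg = float((k_diff * p_diff).sum())
    sig2 = sig_x**2
    contrast = float((((ii - jj) ** 2) * p).sum())
    if sig2 > 0:
        correlation = float(
            (((ii - mu_x) * (jj - mu_x) * p).sum()) / sig2
        )
    else:
        correlation = 1.0
    if hx > 0:
        imc1 = (joint_entropy - hxy1) / hx
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))
    else:
        imc1, imc2 = 0.0, 0.0

    off_diag = ii != jj
    inv_var = float(
        (p[off_diag] / ((ii - jj)[off_diag] ** 2)).sum()
    ) if off_diag.any() else 0.0

    nd = (ng - 1) ** 2 if ng > 1 else 1
    n1 = ng - 1 if ng > 1 else 1
    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": float((ii * p).sum()),
        "cluster_prominence": float((((ii + jj - 2 * mu_x) ** 4) * p).sum()),
        "cluster_shade": float((((ii + jj - 2 * mu_x) ** 3) * p).sum()),
        "cluster_tendency": float((((ii + jj - 2 * mu_x) ** 2) * p).sum()),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": diff_avg,
        "difference_entropy": float(
            -(p_diff * np.log2(p_diff + eps))[p_diff > 0].sum()
        ),
        "difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "joint_energy": float((p**2).sum()),
        "joint_entropy": joint_entropy,
        "imc1": float(imc1),
        "imc2": float(imc2),
        "idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "idmn": float((p / (1.0 + (ii - jj) ** 2 / nd)).sum()),
        "id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / n1)).sum()),
        "inverse_variance": inv_var,
        "maximum_probability": float(p.max()),
        "sum_entropy": float(-(p_sum * np.log2(p_sum + eps))[p_sum > 0].sum()),
        "sum_of_squares": float((((ii - mu_x) ** 2) * p).sum()),
    }


def glcm_features(
    values: np.ndarray,
    roi_mask: np.ndarray,
    cfg: RadiomicsConfig = RadiomicsConfig(),
    roi_id=None,
) -> dict[str, float]:
    """22 GLCM features, averaged over the 13 distance-1 offsets.

    Intensities are discretized within the ROI; co-occurrences are
    accumulated symmetrically per offset over in-ROI voxel pairs,
    normalised per offset, and features averaged across offsets with
    at least one valid pair.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() < 2:
        raise ValidationError(f"ROI needs >= 2 voxels (roi_id={roi_id})")
    levels = np.zeros(values.shape, dtype=np.int64)
    levels[roi_mask] = _discretize(np.asarray(values, float)[roi_mask], cfg)
    acc: dict[str, float] = {k: 0.0 for k in GLCM_NAMES}
    n_used = 0
    for off in cfg.glcm_offsets:
        p = glcm_matrix(values, roi_mask, off, cfg, levels=levels)
        if p.sum() == 0:
            continue
        stats = _glcm_stats(p)
        for k in GLCM_NAMES:
            acc[k] += stats[k]
        n_used += 1
    if n_used == 0:
        raise ValidationError(
            f"no valid co-occurrence pairs in ROI (roi_id={roi_id})"
        )
    return {k: v / n_used for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Per-subject extraction
# ---------------------------------------------------------------------------

def extract_subject(
    vol: np.ndarray, atlas: LabelMap, cfg: RadiomicsConfig = RadiomicsConfig()
) -> RadiomicVector:
    """328 features per ROI: (19 first-order + 22 GLCM) x 8 sub-bands.

    Ordering is (roi ascending, sub-band LLL..HHH, first-order names
    then GLCM names) and is bit-stable across runs.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.shape != atlas.data.shape:
        raise ShapeError(
            f"volume grid {vol.shape} != atlas grid {atlas.data.shape}"
        )
    bands = wavelet_subbands(vol, cfg)
    values: list[float] = []
    index: list[tuple[int, str, str]] = []
    for rid in atlas.region_ids:
        roi = atlas.data == rid
        if not roi.any():
            raise ValidationError(f"empty ROI (roi_id={rid})")
        for sb in SUBBAND_NAMES:
            band = bands[sb]
            fo = first_order_features(band[roi], cfg, roi_id=rid)
            gl = glcm_features(band, roi, cfg, roi_id=rid)
            for name in FIRST_ORDER_NAMES:
                values.append(fo[name])
                index.append((rid, sb, name))
            for name in GLCM_NAMES:
                values.append(gl[name])
                index.append((rid, sb, name))
    return RadiomicVector(values=np.array(values), index=index)
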