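"""Synthetic inputs with planted, directly checkable structure.

Everything downstream of this module is testable without any scanner
data: a mirrored Destrieux-style parcellation (74 regions per
hemisphere by default), 4D resting-state volumes with named planted
properties (mirror symmetry, locally homogeneous blocks, template
mixtures, bin-aligned pure tones, white noise), disjoint unit-norm
group spatial templates, and labelled two-class cohorts whose
structural features are shifted in designated regions.

The first array axis is the left-right (mirror) axis throughout; voxel
``i`` mirrors voxel ``Nx - 1 - i``.  All outputs are deterministic
functions of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SizingError, ValidationError
from .volume_io import LabelMap, Volume4D, write_labelmap, write_volume

__all__ = [
    "FixtureConfig",
    "SubjectFixture",
    "make_atlas",
    "make_rsfmri",
    "make_templates",
    "make_cohort",
    "save_cohort",
]

RSFMRI_STRUCTURES = (
    "mirror_symmetric",
    "locally_homogeneous",
    "template_mixture",
    "white_noise",
    "pure_tone",
)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: a 61x73x61 voxel grid, TR 2 s,
    74 cortical regions per hemisphere and 10 group spatial templates.
    Tests use much smaller grids through the same code paths.
    """

    grid_shape: tuple[int, int, int] = (61, 73, 61)
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    n_regions_per_hemisphere: int = 74
    n_templates: int = 10
    seed: int = 0
    noise_sd: float = 1.0
    planted_freq_hz: float = 0.05
    effect_size: float = 1.0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValidationError("grid_shape must be 3 positive ints")
        if self.n_timepoints < 1 or self.tr_seconds <= 0:
            raise ValidationError("n_timepoints and tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0.0 < self.planted_freq_hz < nyquist):
            raise ValidationError(
                f"planted_freq_hz must lie in (0, {nyquist}) for TR "
                f"{self.tr_seconds}"
            )


@dataclass
class SubjectFixture:
    """One synthetic subject: a structural volume and a functional run."""

    subject_id: str
    smri: np.ndarray
    fmri: Volume4D
    label: int


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def _bisect_box(labels: np.ndarray, box: tuple, n: int, next_label: int) -> int:
    """Recursively split ``box`` into ``n`` contiguous sub-boxes, writing
    labels ``next_label .. next_label+n-1``; returns the next free label."""
    (x0, x1), (y0, y1), (z0, z1) = box
    if n == 1:
        labels[x0:x1, y0:y1, z0:z1] = next_label
        return next_label + 1
    sizes = (x1 - x0, y1 - y0, z1 - z0)
    axis = int(np.argmax(sizes))
    n1 = n // 2
    n2 = n - n1
    length = sizes[axis]
    # split position proportional to region counts; both halves must be able
    # to host their share of regions
    cut = int(round(length * n1 / n))
    cut = max(cut, 1)
    cut = min(cut, length - 1)
    lo, hi = box[axis]
    box_a = list(box)
    box_b = list(box)
    box_a[axis] = (lo, lo + cut)
    box_b[axis] = (lo + cut, hi)
    nl = _bisect_box(labels, tuple(box_a), n1, next_label)
    return _bisect_box(labels, tuple(box_b), n2, nl)


def make_atlas(config: FixtureConfig) -> LabelMap:
    """Mirrored parcellation with ``2 * n_regions_per_hemisphere`` regions.

    The left hemisphere (first-axis indices ``< Nx // 2``) is carved into
    contiguous boxes by recursive bisection; the right hemisphere mirrors
    it with labels offset by ``n_regions_per_hemisphere``.  For odd first
    axes the central sagittal plane stays background so mirroring is
    exact.
    """
    nx, ny, nz = config.grid_shape
    n = config.n_regions_per_hemisphere
    half = nx // 2
    if half * ny * nz < n or half < 1:
        raise SizingError(
            f"grid {config.grid_shape} cannot host {n} regions per hemisphere"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    try:
        _bisect_box(labels, ((0, half), (0, ny), (0, nz)), n, 1)
    except RecursionError as exc:  # pragma: no cover - pathological sizes
        raise SizingError("grid too small to bisect") from exc
    left = labels[:half]
    if len(np.unique(left[left > 0])) != n:
        raise SizingError(
            f"grid {config.grid_shape} too small for {n} nonempty regions"
        )
    # mirror: voxel i <-> nx-1-i; right-hemisphere labels offset by n
    flipped = labels[::-1].copy()
    right = np.where(flipped > 0, flipped + n, 0)
    labels = np.where(labels > 0, labels, right)
    return LabelMap(data=labels)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def make_templates(config: FixtureConfig) -> list[np.ndarray]:
    """Spatially disjoint, nonnegative, unit-L2-norm 3D group maps.

    Disjoint supports make the maps exactly orthogonal, which lets dual
    regression recover planted mixtures exactly in the noise-free case.
    """
    n = config.n_templates
    if n < 1:
        raise ValidationError("n_templates must be >= 1")
    nx, ny, nz = config.grid_shape
    boxes = np.zeros(config.grid_shape, dtype=np.int32)
    _bisect_box(boxes, ((0, nx), (0, ny), (0, nz)), n, 1)
    maps: list[np.ndarray] = []
    for t in range(1, n + 1):
        m = np.zeros(config.grid_shape)
        idx = np.nonzero(boxes == t)
        if idx[0].size == 0:
            raise SizingError(f"grid too small for {n} disjoint templates")
        # smooth bump: distance to box centre, highest in the middle
        centre = [c.mean() for c in idx]
        d2 = sum((c - mu) ** 2 for c, mu in zip(idx, centre))
        vals = 1.0 / (1.0 + d2 / (1.0 + d2.max()))
        m[idx] = vals
        m /= np.linalg.norm(m)
        maps.append(m)
    return maps


# ---------------------------------------------------------------------------
# rs-fMRI volumes
# ---------------------------------------------------------------------------

def _tone_bin(config: FixtureConfig) -> int:
    """Nearest DFT bin to the planted frequency, excluding DC and Nyquist."""
    n, tr = config.n_timepoints, config.tr_seconds
    k = int(round(config.planted_freq_hz * n * tr))
    return int(np.clip(k, 1, max(1, (n - 1) // 2)))


def make_rsfmri(
    config: FixtureConfig,
    structure: str = "white_noise",
    return_truth: bool = False,
):
    """4D volume with the named planted property.

    structure:
      * ``mirror_symmetric`` — the series at voxel ``(i,y,z)`` equals the
        series at ``(Nx-1-i,y,z)`` before independent noise is added.
      * ``locally_homogeneous`` — every voxel of an atlas region shares a
        latent series plus independent noise; background is pure noise.
      * ``template_mixture`` — sum over templates of map x timecourse,
        plus noise.
      * ``white_noise`` — iid Gaussian noise (unit variance).
      * ``pure_tone`` — every voxel is a sinusoid at the planted frequency
        snapped to a DFT bin, with random amplitude and phase, plus noise.

    With ``return_truth=True`` also returns a dict with the planted
    latent quantities (block map, templates and timecourses, tone bin).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    t = config.n_timepoints
    truth: dict = {}

    if structure == "white_noise":
        data = rng.standard_normal(shape + (t,))
    elif structure == "mirror_symmetric":
        data = rng.standard_normal(shape + (t,))
        nx = shape[0]
        data[nx - nx // 2:] = data[: nx // 2][::-1]
        data = data + config.noise_sd * rng.standard_normal(data.shape)
    elif structure == "locally_homogeneous":
        atlas = make_atlas(config)
        data = np.zeros(shape + (t,))
        for rid in atlas.region_ids:
            latent = rng.standard_normal(t)
            data[atlas.data == rid] = latent
        noise = rng.standard_normal(data.shape)
        data[atlas.data == 0] = noise[atlas.data == 0]
        data = data + config.noise_sd * rng.standard_normal(data.shape)
        truth["block_map"] = atlas
    elif structure == "template_mixture":
        maps = make_templates(config)
        tcs = rng.standard_normal((t, len(maps)))
        data = np.tensordot(np.stack(maps, axis=-1), tcs.T, axes=([3], [0]))
        data = data + config.noise_sd * rng.standard_normal(data.shape)
        truth["templates"] = maps
        truth["timecourses"] = tcs
    elif structure == "pure_tone":
        k = _tone_bin(config)
        freq = k / (t * config.tr_seconds)
        times = np.arange(t) * config.tr_seconds
        amp = rng.uniform(0.5, 1.5, size=shape)
        phase = rng.uniform(0, 2 * np.pi, size=shape)
        data = amp[..., None] * np.sin(
            2 * np.pi * freq * times[None, None, None, :] + phase[..., None]
        )
        data = data + config.noise_sd * rng.standard_normal(data.shape)
        truth["tone_bin"] = k
        truth["tone_freq_hz"] = freq
    else:
        raise ValidationError(
            f"unknown structure {structure!r}; expected one of "
            f"{RSFMRI_STRUCTURES}"
        )

    vol = Volume4D(data=data, tr_seconds=config.tr_seconds)
    return (vol, truth) if return_truth else vol


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def make_cohort(
    config: FixtureConfig,
    n_subjects: int,
    class_balance: float = 0.5,
    shifted_rois: list[int] | None = None,
    functional_effect: float = 0.0,
    atlas: LabelMap | None = None,
) -> tuple[list[SubjectFixture], np.ndarray]:
    """Two-class cohort with a structural effect planted in chosen ROIs.

    Each subject gets an sMRI-like intensity volume (per-ROI base
    intensity, subject-level jitter and voxel noise) and a
    template-mixture functional run.  Class-1 subjects have the mean
    intensity of ``shifted_rois`` (default: the first 10 region ids)
    raised by ``config.effect_size``.  With ``functional_effect > 0``,
    class-1 subjects additionally carry a stronger low-frequency
    oscillation on the first template's support, so functional summary
    maps also separate the classes.
    """
    if n_subjects < 4:
        raise ValidationError("n_subjects must be >= 4")
    if not 0.0 < class_balance < 1.0:
        raise ValidationError("class_balance must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    if atlas is None:
        atlas = make_atlas(config)
    region_ids = atlas.region_ids
    if shifted_rois is None:
        shifted_rois = region_ids[: min(10, len(region_ids))]

    n1 = int(round(n_subjects * class_balance))
    labels = np.zeros(n_subjects, dtype=int)
    labels[:n1] = 1
    rng.shuffle(labels)

    base = {rid: rng.uniform(80.0, 120.0) for rid in region_ids}
    templates = make_templates(config)
    t = config.n_timepoints
    k = _tone_bin(config)
    freq = k / (t * config.tr_seconds)
    times = np.arange(t) * config.tr_seconds
    tone = np.sin(2 * np.pi * freq * times)

    subjects: list[SubjectFixture] = []
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        label = int(labels[s])
        smri = config.noise_sd * sub_rng.standard_normal(config.grid_shape)
        for rid in region_ids:
            roi = atlas.data == rid
            mean = base[rid] + config.noise_sd * sub_rng.standard_normal()
            if label == 1 and rid in shifted_rois:
                mean += config.effect_size
            smri[roi] += mean
        tcs = sub_rng.standard_normal((t, len(templates)))
        fdata = np.tensordot(
            np.stack(templates, axis=-1), tcs.T, axes=([3], [0])
        )
        if functional_effect > 0 and label == 1:
            fdata += functional_effect * templates[0][..., None] * tone
        fdata += config.noise_sd * sub_rng.standard_normal(fdata.shape)
        fmri = Volume4D(data=fdata, tr_seconds=config.tr_seconds)
        subjects.append(
            SubjectFixture(
                subject_id=f"sub-{s:04d}", smri=smri, fmri=fmri, label=label
            )
        )
    return subjects, labels


def save_cohort(
    subjects: list[SubjectFixture],
    atlas: LabelMap,
    config: FixtureConfig,
    out_dir: str | Path,
    train_fraction: float = 0.8,
) -> Path:
    """Write NIfTI volumes, a subject table and a parameter manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labelmap(atlas, out / "atlas.nii.gz")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(subjects))
    n_train = int(round(train_fraction * len(subjects)))
    split = np.array(["test"] * len(subjects), dtype=object)
    split[order[:n_train]] = "train"
    rows = []
    for sub, sp in zip(subjects, split):
        write_volume(
            Volume4D(sub.smri, tr_seconds=config.tr_seconds),
            out / f"{sub.subject_id}_smri.nii.gz",
        )
        write_volume(sub.fmri, out / f"{sub.subject_id}_fmri.nii.gz")
        rows.append((sub.subject_id, sub.label, sp))
    pd.DataFrame(rows, columns=["subject_id", "label", "split"]).to_csv(
        out / "subjects.tsv", sep="\t", index=False
    )
    with open(out / "manifest.cfg", "w") as fh:
        for key, val in vars(config).items():
            fh.write(f"{key} = {val}\n")
    return out
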