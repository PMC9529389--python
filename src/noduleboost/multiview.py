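"""Multiview patch extraction around candidate positions.

Each candidate becomes a stack of axial views: square crops at several side
lengths (default 20, 30, 40 pixels) centered on the candidate voxel, each
spline-resized to a common network input size and stacked as channels,
smallest receptive field first.  The small views resolve the lesion itself;
the large views add surrounding context, which is what lets the classifier
tell a blob from the cross-section of a vessel.

Crops at the volume border are completed by edge replication, and each view
is standardized to zero mean / unit variance (with a variance floor) as the
last step — self-normalizing networks expect standardized inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import Candidate

__all__ = [
    "ViewConfig",
    "MultiviewPatch",
    "crop_view",
    "resize_spline",
    "extract_multiview",
    "extract_all",
    "write_archive",
    "read_archive",
    "archive_image_count",
]

VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class ViewConfig:
    """Geometry of the multiview input.

    crop_sizes are the receptive-field side lengths in pixels; target_size is
    the common side length the network consumes (224 in the full-scale
    profile, 32 at desk scale); interpolation_order is the spline order used
    for the resize (0..5, cubic by default).  emit_3d additionally stores a
    cube of each side length per candidate for bookkeeping, without feeding
    the network.
    """

    crop_sizes: tuple[int, ...] = (20, 30, 40)
    target_size: int = 32
    interpolation_order: int = 3
    emit_3d: bool = False

    def __post_init__(self) -> None:
        if len(self.crop_sizes) == 0:
            raise ValueError("crop_sizes must be non-empty")
        if any(s < 2 for s in self.crop_sizes):
            raise ValueError("crop sizes must all be >= 2")
        if list(self.crop_sizes) != sorted(set(self.crop_sizes)):
            raise ValueError("crop_sizes must be strictly increasing")
        if self.target_size < 2:
            raise ValueError("target_size must be >= 2")
        if not 0 <= self.interpolation_order <= 5:
            raise ValueError("interpolation_order must be in [0, 5]")

    @property
    def n_views(self) -> int:
        return len(self.crop_sizes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ViewConfig":
        d = dict(d)
        if "crop_sizes" in d:
            d["crop_sizes"] = tuple(d["crop_sizes"])
        return cls(**d)


@dataclass(frozen=True)
class MultiviewPatch:
    """The stacked, resized views of one candidate: the network input.

    views has shape (n_views, target_size, target_size), channel order
    matching crop_sizes (smallest receptive field first); label is ±1.
    """

    views: np.ndarray
    label: int
    candidate_id: str

    def __post_init__(self) -> None:
        v = self.views
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValueError(f"views must be (n_views, s, s), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("views contain non-finite values")
        if self.label not in (-1, 1):
            raise ValueError(f"label must be ±1, got {self.label}")


def crop_view(
    volume: np.ndarray, position: tuple[int, int, int], size: int
) -> np.ndarray:
    """Axial size×size window centered on the candidate voxel.

    The crop is taken in the candidate's z-slice.  The candidate occupies
    index size//2 along each in-plane axis (for even sizes, index size/2).
    Windows that cross the volume boundary are filled by edge replication.

    Raises
    ------
    IndexError
        If the position lies outside the volume, naming the offending axis.
    """
    z, y, x = position
    for axis, (idx, dim) in enumerate(zip((z, y, x), volume.shape)):
        if not 0 <= idx < dim:
            raise IndexError(
                f"candidate position {position} outside volume along axis "
                f"{'zyx'[axis]} (index {idx}, extent {dim})"
            )
    half = size // 2
    rows = np.clip(np.arange(y - half, y - half + size), 0, volume.shape[1] - 1)
    cols = np.clip(np.arange(x - half, x - half + size), 0, volume.shape[2] - 1)
    return volume[z][np.ix_(rows, cols)]


def crop_cube(
    volume: np.ndarray, position: tuple[int, int, int], size: int
) -> np.ndarray:
    """size³ cube centered on the candidate, edge-replicated at borders."""
    z, y, x = position
    half = size // 2
    planes = np.clip(np.arange(z - half, z - half + size), 0, volume.shape[0] - 1)
    rows = np.clip(np.arange(y - half, y - half + size), 0, volume.shape[1] - 1)
    cols = np.clip(np.arange(x - half, x - half + size), 0, volume.shape[2] - 1)
    return volume[np.ix_(planes, rows, cols)]


def resize_spline(patch: np.ndarray, target_size: int, order: int = 3) -> np.ndarray:
    """Spline-resize a square patch to target_size × target_size.

    The zoom factor target_size / source_size is applied identically to both
    axes with endpoint-aligned resampling (first and last samples of each
    axis map onto each other), so the operation is pure interpolation and an
    identity when sizes already match.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1]:
        raise ValueError(f"patch must be square 2D, got shape {patch.shape}")
    src = patch.shape[0]
    if src == target_size:
        return patch.copy()
    out = ndimage.zoom(
        patch, target_size / src, order=order, mode="nearest", grid_mode=False
    )
    if out.shape != (target_size, target_size):  # guard float rounding in zoom
        raise AssertionError(f"resize produced {out.shape}, wanted {target_size}")
    return out


def normalize_views(views: np.ndarray) -> np.ndarray:
    """Per-view z-score with a variance floor.

    Each channel is shifted to zero mean and scaled by sqrt(var + floor); a
    constant view therefore maps to all-zeros instead of dividing by zero.
    """
    out = np.empty_like(views, dtype=np.float64)
    for i, v in enumerate(views):
        var = v.var()
        if var <= VARIANCE_FLOOR:  # constant view: define its z-score as 0
            out[i] = 0.0
        else:
            out[i] = (v - v.mean()) / np.sqrt(var + VARIANCE_FLOOR)
    return out


def extract_multiview(
    volume: np.ndarray, candidate: Candidate, cfg: ViewConfig
) -> MultiviewPatch:
    """Crop, resize and standardize all views of one candidate."""
    views = np.stack(
        [
            resize_spline(
                crop_view(volume, candidate.position, s),
                cfg.target_size,
                cfg.interpolation_order,
            )
            for s in cfg.crop_sizes
        ]
    )
    return MultiviewPatch(
        views=normalize_views(views),
        label=candidate.label,
        candidate_id=candidate.candidate_id,
    )


def extract_all(
    volume: np.ndarray, candidates: list[Candidate], cfg: ViewConfig
) -> list[MultiviewPatch]:
    return [extract_multiview(volume, c, cfg) for c in candidates]


def archive_image_count(
    n_candidates: int, n_views: int, emit_3d: bool = False
) -> int:
    """Number of view images an archive holds: candidates × views (×2 with
    the optional per-view 3D cubes)."""
    return n_candidates * n_views * (2 if emit_3d else 1)


# ---------------------------------------------------------------------------
# patch archive: one NPZ per candidate + a manifest CSV


def write_archive(
    out_dir: str | Path,
    volume: np.ndarray,
    candidates: list[Candidate],
    cfg: ViewConfig,
) -> Path:
    """Extract every candidate and write the patch archive.

    Layout: ``<out_dir>/<candidate_id>.npz`` holding the normalized channel
    stack under key ``views`` (plus raw ``cube_<size>`` arrays when emit_3d),
    and ``manifest.csv`` with columns candidate_id,label,n_views,target_size.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cand in candidates:
        patch = extract_multiview(volume, cand, cfg)
        arrays = {"views": patch.views.astype(np.float32)}
        if cfg.emit_3d:
            for s in cfg.crop_sizes:
                arrays[f"cube_{s}"] = crop_cube(volume, cand.position, s).astype(
                    np.float32
                )
        np.savez(out_dir / f"{cand.candidate_id}.npz", **arrays)
        rows.append((cand.candidate_id, 1 if cand.label > 0 else 0,
                     cfg.n_views, cfg.target_size))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["candidate_id", "label", "n_views", "target_size"])
        writer.writerows(rows)
    return out_dir


def read_archive(archive_dir: str | Path) -> list[MultiviewPatch]:
    """Load patches back in manifest order (labels mapped 0/1 → ∓1)."""
    archive_dir = Path(archive_dir)
    patches = []
    with open(archive_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            with np.load(archive_dir / f"{row['candidate_id']}.npz") as data:
                views = np.asarray(data["views"], dtype=np.float64)
            patches.append(
                MultiviewPatch(
                    views=views,
                    label=1 if int(row["label"]) == 1 else -1,
                    candidate_id=row["candidate_id"],
                )
            )
    return patches
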