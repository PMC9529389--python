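"""Synthetic CT-like phantom volumes with labeled nodule / nonnodule candidates.

The generator emulates the setting of false-positive reduction in pulmonary
nodule CAD: roughly spherical bright blobs (nodules, the positive class)
embedded in a noisy background together with bright tubular vessel segments,
which are the classic intensity-similar confusers that make the nonnodule
class hard. Candidate positions are the classification unit; labels are +1
(nodule) and -1 (nonnodule). Everything is driven by one explicit seed so a
config reproduces its volume bit for bit.

Intensities are in arbitrary units, not Hounsfield: the downstream classifier
standardizes each patch, so only contrast ratios matter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "PhantomConfig",
    "Candidate",
    "PlacementError",
    "generate_phantom",
    "save_phantom",
    "load_volume",
    "load_candidates",
    "save_candidates",
]

#: Pairwise candidate-center separation, in voxels.  Equal to the largest
#: default view crop so that no two training patches overlap at their center.
MIN_CANDIDATE_SEPARATION = 40.0

#: Fraction of nodule contrast given to vessel segments.  Vessels stay bright
#: enough to confuse an intensity-only classifier but thin/partial-volume
#: dimming keeps small-nodule vs thick-vessel comparisons well ordered.
VESSEL_CONTRAST_FACTOR = 0.6

BACKGROUND_LEVEL = 100.0


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all candidates."""


@dataclass(frozen=True)
class Candidate:
    """A voxel position proposed for nodule-vs-nonnodule classification.

    ``label`` is +1 for nodule, -1 for nonnodule (stored 1/0 on disk).
    """

    position: tuple[int, int, int]  # (z, y, x), 0-based
    label: int
    candidate_id: str

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic volume.

    Defaults are the package's standard bench: a volume roomy enough to hold
    100 well-separated candidates, balanced classes, and nodule contrast six
    times the background noise (a clearly-visible-nodule regime).
    """

    volume_shape: tuple[int, int, int] = (160, 384, 384)  # (z, y, x)
    n_nodules: int = 50
    n_nonnodules: int = 50
    nodule_diameter_range: tuple[float, float] = (8.0, 18.0)  # voxels
    nodule_contrast: float = 60.0  # intensity units above background
    background_noise_sd: float = 10.0
    vessel_count: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodules < 0 or self.n_nonnodules < 0:
            raise ValueError("candidate counts must be nonnegative")
        lo, hi = self.nodule_diameter_range
        if not (0 < lo <= hi):
            raise ValueError("nodule_diameter_range must satisfy 0 < min <= max")
        if hi >= min(self.volume_shape):
            raise ValueError(
                "max nodule diameter must be strictly smaller than every volume dimension"
            )
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("volume_shape", "nodule_diameter_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    n: int,
    margin: int,
    existing: list[np.ndarray],
    max_attempts_per_point: int = 400,
) -> list[np.ndarray]:
    """Rejection-sample `n` centers >= MIN_CANDIDATE_SEPARATION apart."""
    centers = list(existing)
    placed: list[np.ndarray] = []
    lo = np.array([margin] * 3)
    hi = np.array(shape) - margin
    if np.any(hi <= lo):
        raise PlacementError(f"volume {shape} too small for margin {margin}")
    for _ in range(n):
        for _attempt in range(max_attempts_per_point):
            p = rng.integers(lo, hi)
            if all(
                np.linalg.norm(p - q) >= MIN_CANDIDATE_SEPARATION for q in centers
            ):
                centers.append(p)
                placed.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {n} candidates with separation "
                f"{MIN_CANDIDATE_SEPARATION} in volume {shape}; "
                "reduce counts or enlarge the volume"
            )
    return placed


def _add_gaussian_blob(
    volume: np.ndarray, center: np.ndarray, sigma: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian blob in-place, rendered on a local window."""
    r = int(np.ceil(4 * sigma))
    zc, yc, xc = (int(c) for c in center)
    z0, z1 = max(zc - r, 0), min(zc + r + 1, volume.shape[0])
    y0, y1 = max(yc - r, 0), min(yc + r + 1, volume.shape[1])
    x0, x1 = max(xc - r, 0), min(xc + r + 1, volume.shape[2])
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1) - zc,
        np.arange(y0, y1) - yc,
        np.arange(x0, x1) - xc,
        indexing="ij",
    )
    d2 = zz**2 + yy**2 + xx**2
    volume[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _add_vessel(
    volume: np.ndarray,
    rng: np.random.Generator,
    amplitude: float,
) -> np.ndarray:
    """Stamp a random-orientation bright cylinder; return its voxel centers.

    The tube is rendered by marching along a random direction and adding a
    Gaussian cross-section of sigma = radius at unit steps.  Each stamp is
    scaled by 1/(radius*sqrt(2*pi)) so the summed on-axis profile of the
    overlapping stamps equals `amplitude`, giving a smooth cylinder of
    radius ~1-2 voxels at the requested peak intensity.
    """
    shape = np.array(volume.shape)
    start = rng.uniform(0.15, 0.85, size=3) * shape
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    length = rng.uniform(40.0, 120.0)
    radius = rng.uniform(1.0, 2.0)
    step_amplitude = amplitude / (radius * np.sqrt(2.0 * np.pi))
    n_steps = int(length)
    path = []
    for t in range(n_steps):
        p = start + t * direction
        if np.any(p < 2) or np.any(p >= shape - 2):
            break
        _add_gaussian_blob(volume, np.round(p), sigma=radius, amplitude=step_amplitude)
        path.append(np.round(p).astype(int))
    return np.array(path) if path else np.empty((0, 3), dtype=int)


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, list[Candidate]]:
    """Generate a phantom volume and its candidate table.

    Returns a float32 volume of ``config.volume_shape`` and a list of
    ``n_nodules + n_nonnodules`` candidates.  Nodules are Gaussian blobs with
    sigma = diameter/4 (so the full-width at ~0.6 amplitude matches the drawn
    diameter); nonnodule candidates sit on vessel voxels or plain background,
    alternating, all pairwise separated by the largest view crop size.

    Identical config (including seed) gives bit-identical output.

    Raises
    ------
    PlacementError
        If rejection sampling cannot honour the separation constraint.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.volume_shape
    volume = np.full(shape, BACKGROUND_LEVEL, dtype=np.float64)
    if config.background_noise_sd > 0:
        volume += rng.normal(0.0, config.background_noise_sd, size=shape)

    vessel_amplitude = VESSEL_CONTRAST_FACTOR * config.nodule_contrast
    vessel_voxels: list[np.ndarray] = []
    for _ in range(config.vessel_count):
        path = _add_vessel(volume, rng, vessel_amplitude)
        if len(path):
            vessel_voxels.append(path)
    vessel_voxels_arr = (
        np.concatenate(vessel_voxels) if vessel_voxels else np.empty((0, 3), dtype=int)
    )

    margin = int(np.ceil(config.nodule_diameter_range[1]))
    nodule_centers = _place_centers(rng, shape, config.n_nodules, margin, [])

    diam_lo, diam_hi = config.nodule_diameter_range
    for center in nodule_centers:
        diameter = rng.uniform(diam_lo, diam_hi)
        _add_gaussian_blob(
            volume, center, sigma=diameter / 4.0, amplitude=config.nodule_contrast
        )

    # Nonnodules: alternate vessel-voxel and pure-background placements.
    # Vessel placements draw from the set of vessel voxels still separated
    # from every taken center; when that set is empty the candidate falls
    # back to a background position.
    taken = [np.asarray(c, dtype=float) for c in nodule_centers]
    in_bounds = (
        np.all(vessel_voxels_arr >= margin, axis=1)
        & np.all(vessel_voxels_arr < np.array(shape) - margin, axis=1)
        if len(vessel_voxels_arr)
        else np.zeros(0, dtype=bool)
    )
    vessel_pool = vessel_voxels_arr[in_bounds]
    nonnodule_centers: list[np.ndarray] = []
    max_attempts = 400
    for i in range(config.n_nonnodules):
        placed = False
        if i % 2 == 0 and len(vessel_pool):
            taken_arr = np.array(taken)
            dists = np.linalg.norm(
                vessel_pool[:, None, :] - taken_arr[None, :, :], axis=2
            )
            valid = vessel_pool[np.all(dists >= MIN_CANDIDATE_SEPARATION, axis=1)]
            if len(valid):
                p = valid[rng.integers(len(valid))]
                taken.append(np.asarray(p, dtype=float))
                nonnodule_centers.append(np.asarray(p))
                placed = True
        if not placed:
            for _ in range(max_attempts):
                p = rng.integers([margin] * 3, np.array(shape) - margin)
                if all(
                    np.linalg.norm(p - q) >= MIN_CANDIDATE_SEPARATION for q in taken
                ):
                    taken.append(np.asarray(p, dtype=float))
                    nonnodule_centers.append(np.asarray(p))
                    placed = True
                    break
        if not placed:
            raise PlacementError(
                f"could not place nonnodule candidate {i} with separation "
                f"{MIN_CANDIDATE_SEPARATION} in volume {shape}"
            )

    candidates = [
        Candidate(tuple(int(v) for v in c), +1, f"nod{i:04d}")
        for i, c in enumerate(nodule_centers)
    ] + [
        Candidate(tuple(int(v) for v in c), -1, f"non{i:04d}")
        for i, c in enumerate(nonnodule_centers)
    ]
    return volume.astype(np.float32), candidates


# ---------------------------------------------------------------------------
# disk I/O: NIfTI-1 volume + CSV candidate table


def save_phantom(
    volume: np.ndarray,
    candidates: list[Candidate],
    volume_path: str | Path,
    candidates_path: str | Path,
) -> None:
    """Write the volume as NIfTI-1 (.nii.gz) and candidates as CSV."""
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine=np.eye(4))
    nib.save(img, str(volume_path))
    save_candidates(candidates, candidates_path)


def save_candidates(candidates: list[Candidate], path: str | Path) -> None:
    """CSV schema: candidate_id,z,y,x,label with label stored as 0/1."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["candidate_id", "z", "y", "x", "label"])
        for c in candidates:
            writer.writerow(
                [c.candidate_id, *c.position, 1 if c.label > 0 else 0]
            )


def load_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float32)


def load_candidates(path: str | Path) -> list[Candidate]:
    """Read the 0/1-labelled CSV back into ±1-labelled candidates."""
    out: list[Candidate] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = 1 if int(row["label"]) == 1 else -1
            out.append(
                Candidate(
                    (int(row["z"]), int(row["y"]), int(row["x"])),
                    label,
                    row["candidate_id"],
                )
            )
    return out
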