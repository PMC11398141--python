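"""CT preprocessing chain and 2.5D sample construction.

Pipeline for each volume:

1. **HU windowing** — clip to [level - width/2, level + width/2]; the
   soft-tissue window width 200 / level 40 gives [-60, 140] HU, which
   brackets liver parenchyma and hypodense lesions.
2. **Min-max normalization** to [0, 1] using the *window bounds* as fixed
   extremes, so intensities are comparable across volumes.
3. **CLAHE** per slice (contrast-limited adaptive histogram equalization)
   to raise local lesion/parenchyma contrast.
4. **2.5D stacking** — each training sample is the target slice plus its
   two axial neighbors as three channels (edge slices replicate), paired
   with the center slice's binary liver/tumor masks.
5. **Augmentation** — random crop, horizontal/vertical flips, and +-90
   degree rotations, applied identically to image and masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

DEFAULT_WINDOW_WIDTH = 200.0   # HU
DEFAULT_WINDOW_LEVEL = 40.0    # HU


@dataclass
class Slice25DSample:
    image: np.ndarray   # (3, H, W) float in [0, 1]
    target: np.ndarray  # (2, H, W) binary {liver, tumor} of the center slice

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[0] != 3:
            raise ValueError(f"image must be (3,H,W), got {self.image.shape}")
        if self.target.shape != (2,) + self.image.shape[1:]:
            raise ValueError(
                f"target shape {self.target.shape} does not match image "
                f"{self.image.shape}")


def window_bounds(width: float = DEFAULT_WINDOW_WIDTH,
                  level: float = DEFAULT_WINDOW_LEVEL) -> tuple[float, float]:
    return level - width / 2.0, level + width / 2.0


def window_clip(volume: np.ndarray, width: float = DEFAULT_WINDOW_WIDTH,
                level: float = DEFAULT_WINDOW_LEVEL) -> np.ndarray:
    """Clip HU values into the window [level - width/2, level + width/2]."""
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    lo, hi = window_bounds(width, level)
    return np.clip(volume, lo, hi)


def minmax_normalize(volume: np.ndarray, width: float = DEFAULT_WINDOW_WIDTH,
                     level: float = DEFAULT_WINDOW_LEVEL) -> np.ndarray:
    """Scale a windowed volume to [0, 1] using the fixed window bounds."""
    lo, hi = window_bounds(width, level)
    return ((np.asarray(volume, dtype=np.float32) - lo) / (hi - lo)).clip(0, 1)


def clahe_equalize(image: np.ndarray, clip_limit: float = 0.01,
                   tiles: int = 8) -> np.ndarray:
    """CLAHE on a single [0,1] slice; constant slices pass through."""
    image = np.asarray(image, dtype=np.float32)
    if image.max() - image.min() <= 0:
        return image.copy()
    kernel = (max(1, image.shape[0] // tiles), max(1, image.shape[1] // tiles))
    out = exposure.equalize_adapthist(image.astype(np.float64),
                                      kernel_size=kernel,
                                      clip_limit=clip_limit)
    return out.astype(np.float32)


def preprocess_volume(volume: np.ndarray, width: float = DEFAULT_WINDOW_WIDTH,
                      level: float = DEFAULT_WINDOW_LEVEL,
                      use_clahe: bool = True, clip_limit: float = 0.01,
                      tiles: int = 8) -> np.ndarray:
    """Full intensity chain: window -> fixed min-max -> per-slice CLAHE."""
    out = minmax_normalize(window_clip(volume, width, level), width, level)
    if use_clahe:
        out = np.stack([clahe_equalize(s, clip_limit, tiles) for s in out])
    return out.astype(np.float32)


def masks_from_labels(label_slice: np.ndarray) -> np.ndarray:
    """(2, H, W) binary masks: liver = label >= 1 (lesions are liver tissue),
    tumor = label == 2."""
    label_slice = np.asarray(label_slice)
    return np.stack([(label_slice >= 1), (label_slice == 2)]
                    ).astype(np.float32)


def stack_25d(volume: np.ndarray, labels: np.ndarray, index: int
              ) -> Slice25DSample:
    """Build the 3-channel 2.5D sample centered on slice ``index``.

    Neighbors are edge-replicated at the first and last slice.
    """
    volume = np.asarray(volume)
    n = volume.shape[0]
    if n == 0:
        raise ValueError("volume has no slices")
    if not 0 <= index < n:
        raise IndexError(f"slice index {index} out of range [0,{n})")
    lo, hi = max(0, index - 1), min(n - 1, index + 1)
    image = np.stack([volume[lo], volume[index], volume[hi]]
                     ).astype(np.float32)
    return Slice25DSample(image=image,
                          target=masks_from_labels(labels[index]))


def _crop(sample: Slice25DSample, size: int, rng: np.random.Generator
          ) -> Slice25DSample:
    img, tgt = sample.image, sample.target
    h, w = img.shape[1:]
    if h < size or w < size:
        ph, pw = max(0, size - h), max(0, size - w)
        pad = ((0, 0), (0, ph), (0, pw))
        img = np.pad(img, pad, mode="reflect")
        tgt = np.pad(tgt, pad, mode="reflect")
        h, w = img.shape[1:]
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return Slice25DSample(image=img[:, top:top + size, left:left + size],
                          target=tgt[:, top:top + size, left:left + size])


def augment(sample: Slice25DSample, rng: np.random.Generator,
            crop_size: int | None = None) -> Slice25DSample:
    """Random crop / flips / +-90 degree rotation, identical on image and
    masks; deterministic for a fixed generator state."""
    if crop_size is not None:
        sample = _crop(sample, crop_size, rng)
    img, tgt = sample.image, sample.target
    if rng.random() < 0.5:
        img, tgt = img[:, :, ::-1], tgt[:, :, ::-1]      # horizontal flip
    if rng.random() < 0.5:
        img, tgt = img[:, ::-1, :], tgt[:, ::-1, :]      # vertical flip
    k = int(rng.choice([0, 1, 3]))                        # none / left / right
    if k:
        img = np.rot90(img, k=k, axes=(1, 2))
        tgt = np.rot90(tgt, k=k, axes=(1, 2))
    return Slice25DSample(image=np.ascontiguousarray(img),
                          target=np.ascontiguousarray(tgt))


def select_slice_indices(labels: np.ndarray, rng: np.random.Generator,
                         empty_keep_fraction: float = 0.1) -> list[int]:
    """Training slice selection: keep every slice with liver present plus a
    random fraction of liver-free slices (limits trivial negatives)."""
    indices = []
    for i in range(labels.shape[0]):
        if (labels[i] >= 1).any() or rng.random() < empty_keep_fraction:
            indices.append(i)
    return indices


def split_volumes(n_volumes: int, seed: int, val_fraction: float = 0.2
                  ) -> tuple[list[int], list[int]]:
    """Random volume-level train/validation split (default 8:2)."""
    order = np.random.default_rng(seed).permutation(n_volumes)
    n_val = max(1, int(round(val_fraction * n_volumes))) if n_volumes > 1 else 0
    return sorted(order[n_val:].tolist()), sorted(order[:n_val].tolist())


# -- NIfTI I/O -------------------------------------------------------------

def load_nifti(path) -> np.ndarray:
    """Load a NIfTI volume as (slices, H, W)."""
    import nibabel as nib

    data = np.asanyarray(nib.load(str(path)).dataobj)
    # NIfTI stores (x, y, z); present as (z, y, x) slice-major
    return np.transpose(data, (2, 1, 0))


def save_nifti(path, volume: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    """Save a (slices, H, W) volume; ``spacing`` is (z, y, x) in mm."""
    import nibabel as nib

    data = np.transpose(np.asarray(volume), (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def export_slice_png(path, image: np.ndarray):
    """Write a [0,1] slice as an 8-bit grayscale PNG for inspection."""
    import imageio.v3 as iio

    iio.imwrite(str(path), (np.clip(image, 0, 1) * 255).astype(np.uint8))
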