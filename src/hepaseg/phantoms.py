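"""Synthetic CT phantoms with liver/tumor ground truth.

Each phantom is an HU-valued volume containing one ellipsoidal "liver"
against a darker background, with 0-3 hypodense ellipsoidal "tumors"
strictly inside the liver, plus Gaussian noise.  Labels (0 = background,
1 = liver, 2 = tumor) follow the generating geometry exactly, so every
downstream stage — windowing, CLAHE, 2.5D stacking, training, evaluation —
can be exercised without any external dataset.

Default intensities (liver 60 HU, tumor 20 HU, background -100 HU)
straddle the soft-tissue window [-60, 140] so that windowing is
non-trivial, and keep the lesion/parenchyma contrast low, mimicking the
low-contrast regime that makes real lesion segmentation hard.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import save_nifti


@dataclass
class PhantomSpec:
    shape: tuple = (12, 96, 96)          # (slices, H, W)
    background_hu: float = -100.0
    liver_hu_mean: float = 60.0
    liver_hu_std: float = 10.0           # per-voxel tissue texture
    tumor_hu_mean: float = 20.0
    tumor_hu_std: float = 10.0
    noise_std: float = 5.0               # global acquisition noise
    n_tumors: tuple = (0, 3)             # inclusive count range
    tumor_radius: tuple = (3.0, 8.0)     # in-plane semi-axis range (voxels)
    liver_semiaxes_z: tuple = (3.0, 5.0)
    liver_semiaxes_xy: tuple = (18.0, 32.0)
    hyperdense_tumors: bool = False
    seed: int = 0

    def __post_init__(self):
        if any(s < m for s, m in zip(self.shape, (3, 32, 32))):
            raise ValueError(f"shape {self.shape} below minimum (3,32,32)")
        if not self.hyperdense_tumors and \
                self.tumor_hu_mean >= self.liver_hu_mean:
            raise ValueError("hypodense tumors require tumor HU < liver HU")


@dataclass
class PhantomGeometry:
    """Analytic description of the generated shapes (voxel coordinates)."""

    liver_center: tuple
    liver_semiaxes: tuple                 # (z, y, x)
    tumors: list                          # list of (center, semiaxes)


def _ellipsoid_field(shape, center, semiaxes) -> np.ndarray:
    """Quadratic form of the ellipsoid, <= 1 inside."""
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    return (((zz - center[0]) / semiaxes[0]) ** 2
            + ((yy - center[1]) / semiaxes[1]) ** 2
            + ((xx - center[2]) / semiaxes[2]) ** 2)


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    return _ellipsoid_field(shape, center, semiaxes) <= 1.0


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray, PhantomGeometry]:
    """Generate one (volume_HU, labels, geometry) triple.

    Deterministic for a fixed ``spec.seed`` (an explicit ``rng`` overrides
    the seed, for use inside dataset generation).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    nz, ny, nx = spec.shape

    # liver: randomly posed axis-aligned ellipsoid, fully inside the volume
    az = rng.uniform(*spec.liver_semiaxes_z)
    ay = rng.uniform(*spec.liver_semiaxes_xy)
    ax = rng.uniform(*spec.liver_semiaxes_xy)
    az = min(az, (nz - 1) / 2.0 - 0.5)
    ay = min(ay, (ny - 1) / 2.0 - 2.0)
    ax = min(ax, (nx - 1) / 2.0 - 2.0)
    cz = rng.uniform(az + 0.5, nz - 1 - az - 0.5)
    cy = rng.uniform(ay + 1.0, ny - 1 - ay - 1.0)
    cx = rng.uniform(ax + 1.0, nx - 1 - ax - 1.0)
    liver_center, liver_axes = (cz, cy, cx), (az, ay, ax)
    liver_field = _ellipsoid_field(spec.shape, liver_center, liver_axes)
    liver = liver_field <= 1.0

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[liver] = 1

    # tumors: propose a center inside a shrunken liver, then verify
    # voxel-exact containment against the liver's analytic equation
    tumors = []
    n_target = int(rng.integers(spec.n_tumors[0], spec.n_tumors[1] + 1))
    attempts = 0
    while len(tumors) < n_target:
        attempts += 1
        if attempts > 200:
            raise RuntimeError(
                f"could not place {n_target} tumors of radius "
                f"{spec.tumor_radius} inside liver semi-axes {liver_axes}")
        r = rng.uniform(*spec.tumor_radius)
        rz = max(1.0, min(r / 2.0, az - 1.0))
        shrunk = (az - rz, ay - r, ax - r)
        if min(shrunk) <= 0.5:
            continue
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rho = rng.uniform(0, 1) ** (1 / 3)
        center = (cz + u[0] * rho * shrunk[0],
                  cy + u[1] * rho * shrunk[1],
                  cx + u[2] * rho * shrunk[2])
        tumor_mask = _ellipsoid_mask(spec.shape, center, (rz, r, r))
        if not tumor_mask.any() or (liver_field[tumor_mask] > 1.0).any():
            continue
        tumors.append((center, (rz, r, r)))
        labels[tumor_mask] = 2

    geometry = PhantomGeometry(liver_center=liver_center,
                               liver_semiaxes=liver_axes, tumors=tumors)

    volume = np.full(spec.shape, spec.background_hu, dtype=np.float32)
    liver_only = labels == 1
    tumor_vox = labels == 2
    volume[liver_only] = spec.liver_hu_mean + rng.normal(
        0.0, spec.liver_hu_std, int(liver_only.sum()))
    volume[tumor_vox] = spec.tumor_hu_mean + rng.normal(
        0.0, spec.tumor_hu_std, int(tumor_vox.sum()))
    if spec.noise_std > 0:
        volume += rng.normal(0.0, spec.noise_std,
                             spec.shape).astype(np.float32)
    return volume.astype(np.float32), labels, geometry


def generate_volumes(n_volumes: int, spec: PhantomSpec | None = None,
                     seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n_volumes`` (volume, labels) pairs in memory.

    Volume ``i`` uses an independent child seed derived from ``seed``, so
    any volume can be regenerated without the others.
    """
    spec = spec or PhantomSpec()
    pairs = []
    for i in range(n_volumes):
        child = _child_seed(seed, i)
        vol, lab, _ = generate_phantom(
            PhantomSpec(**{**asdict(spec), "seed": child}))
        pairs.append((vol, lab))
    return pairs


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.default_rng([seed, index]).integers(2 ** 31))


def generate_dataset(out_dir, n_volumes: int, spec: PhantomSpec | None = None,
                     seed: int = 0) -> Path:
    """Write NIfTI volume/label pairs plus a JSON manifest.

    The manifest records the spec and every per-volume seed, so the exact
    dataset can be regenerated from it.
    Returns the manifest path.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    spec = spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_volumes):
        child = _child_seed(seed, i)
        vol, lab, _ = generate_phantom(
            PhantomSpec(**{**asdict(spec), "seed": child}))
        vpath, lpath = f"volume-{i:03d}.nii.gz", f"labels-{i:03d}.nii.gz"
        save_nifti(out_dir / vpath, vol)
        save_nifti(out_dir / lpath, lab)
        entries.append({"index": i, "seed": child, "volume": vpath,
                        "labels": lpath})
    manifest = {"spec": asdict(spec), "master_seed": seed,
                "n_volumes": n_volumes, "volumes": entries}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_dataset(manifest_path) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load (volume, labels) pairs listed in a dataset manifest."""
    from .preprocessing import load_nifti

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    pairs = []
    for entry in manifest["volumes"]:
        vol = load_nifti(root / entry["volume"]).astype(np.float32)
        lab = load_nifti(root / entry["labels"]).astype(np.uint8)
        pairs.append((vol, lab))
    return pairs


def regenerate_from_manifest(manifest_path
                             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rebuild the dataset purely from the manifest's recorded seeds."""
    manifest = json.loads(Path(manifest_path).read_text())
    spec = manifest["spec"]
    pairs = []
    for entry in manifest["volumes"]:
        vol, lab, _ = generate_phantom(
            PhantomSpec(**{**spec, "seed": entry["seed"],
                           "shape": tuple(spec["shape"]),
                           "n_tumors": tuple(spec["n_tumors"]),
                           "tumor_radius": tuple(spec["tumor_radius"]),
                           "liver_semiaxes_z": tuple(spec["liver_semiaxes_z"]),
                           "liver_semiaxes_xy": tuple(
                               spec["liver_semiaxes_xy"])}))
        pairs.append((vol, lab))
    return pairs
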