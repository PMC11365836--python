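"""NIfTI volume I/O, preprocessing, and dataset manifests."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import zoom

from .phantom import DomainSample

__all__ = ["read_volume", "write_volume", "preprocess", "ManifestEntry",
           "DatasetManifest", "save_dataset", "load_samples"]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got {data.ndim}D")
    return np.ascontiguousarray(data), img.affine


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None
                 ) -> None:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("only 3D volumes are written")
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def preprocess(volume: np.ndarray, mask: np.ndarray | None,
               target_shape: tuple[int, int, int] | None = None,
               normalize: bool = True):
    """Resample to ``target_shape`` and min-max normalise to [0, 1].

    The image is resampled trilinearly, the mask by nearest neighbour so it
    stays binary.  A constant image cannot be normalised; it comes back as
    all-zeros with a warning.
    """
    vol = np.asarray(volume, dtype=np.float32)
    if target_shape is not None:
        target_shape = tuple(int(t) for t in target_shape)
        if any(t <= 0 for t in target_shape):
            raise ValueError("target_shape must be positive")
        if target_shape[0] % 16 or target_shape[1] % 16:
            raise ValueError(
                "in-plane target dims must be divisible by 16 (the encoder's "
                "cumulative pooling factor at default depth)")
        if vol.shape != target_shape:
            factors = [t / s for t, s in zip(target_shape, vol.shape)]
            vol = zoom(vol, factors, order=1)
            # zoom can over/undershoot by one voxel on awkward ratios
            if vol.shape != target_shape:
                raise ValueError(
                    f"resampling produced {vol.shape}, wanted {target_shape}")
            if mask is not None:
                mask = zoom(mask.astype(np.uint8), factors, order=0)
    if normalize:
        lo, hi = float(vol.min()), float(vol.max())
        if hi - lo < 1e-12:
            warnings.warn("constant volume cannot be min-max normalised; "
                          "returning zeros", stacklevel=2)
            vol = np.zeros_like(vol)
        else:
            vol = (vol - lo) / (hi - lo)
    if mask is not None:
        mask = np.ascontiguousarray(mask.astype(np.uint8))
    return np.ascontiguousarray(vol, dtype=np.float32), mask


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    domain_id: str
    role: str                 # "source" | "target"
    split: str                # "train" | "val" | "test"
    image_path: str
    mask_path: str | None = None


@dataclass
class DatasetManifest:
    """Index of a dataset on disk; validates split hygiene on load/save."""

    entries: list[ManifestEntry]

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.role not in ("source", "target"):
                raise ValueError(f"{e.sample_id}: bad role {e.role!r}")
            if e.split not in ("train", "val", "test"):
                raise ValueError(f"{e.sample_id}: bad split {e.split!r}")
            if e.sample_id in seen and seen[e.sample_id] != e.split:
                raise ValueError(
                    f"sample {e.sample_id!r} appears in splits "
                    f"{seen[e.sample_id]!r} and {e.split!r}")
            seen[e.sample_id] = e.split
            if e.role == "source" and e.mask_path is None:
                raise ValueError(f"source sample {e.sample_id} has no mask")

    def save(self, path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(
            {"entries": [asdict(e) for e in self.entries]}, indent=2))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        data = json.loads(Path(path).read_text())
        man = cls(entries=[ManifestEntry(**e) for e in data["entries"]])
        man.validate()
        return man

    def select(self, domain_id=None, split=None, role=None):
        out = self.entries
        if domain_id is not None:
            out = [e for e in out if e.domain_id == domain_id]
        if split is not None:
            out = [e for e in out if e.split == split]
        if role is not None:
            out = [e for e in out if e.role == role]
        return out


def save_dataset(samples_by_split: dict[str, list[DomainSample]], role: str,
                 out_dir, manifest: DatasetManifest | None = None
                 ) -> DatasetManifest:
    """Write (image, mask) NIfTI pairs and extend/build a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest or DatasetManifest(entries=[])
    for split, samples in samples_by_split.items():
        for s in samples:
            img_path = out_dir / f"{s.sample_id}_img.nii.gz"
            write_volume(s.volume, img_path)
            mask_path = None
            if s.mask is not None:
                mask_path = out_dir / f"{s.sample_id}_mask.nii.gz"
                write_volume(s.mask.astype(np.uint8), mask_path)
            manifest.entries.append(ManifestEntry(
                sample_id=s.sample_id, domain_id=s.domain_id, role=role,
                split=split, image_path=str(img_path),
                mask_path=str(mask_path) if mask_path else None))
    manifest.validate()
    return manifest


def load_samples(manifest: DatasetManifest, base_dir=None, **select
                 ) -> list[DomainSample]:
    """Materialise DomainSamples for the selected manifest entries."""
    base = Path(base_dir) if base_dir else None
    out = []
    for e in manifest.select(**select):
        ipath = Path(e.image_path)
        if base and not ipath.is_absolute():
            ipath = base / ipath
        vol, _ = read_volume(ipath)
        mask = None
        if e.mask_path:
            mpath = Path(e.mask_path)
            if base and not mpath.is_absolute():
                mpath = base / mpath
            mask, _ = read_volume(mpath)
            mask = mask.astype(np.uint8)
        out.append(DomainSample(volume=np.asarray(vol, dtype=np.float32),
                                mask=mask, domain_id=e.domain_id,
                                sample_id=e.sample_id))
    return out
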