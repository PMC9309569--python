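"""Deterministic volume-to-slice preprocessing for structural MRI.

The pipeline consumes registered, skull-stripped T1 volumes (NIfTI) and
produces a labelled 2-D slice dataset:

1. resample each volume to a common 128×128×128 grid (trilinear);
2. min–max normalise voxel intensities to [0, 255];
3. extract 20 coronal slices per subject, centred on the coronal midline at a
   spacing that spans the central ~30% of the axis (where the hippocampus
   lies);
4. shuffle all slices and split 8:1:1 into train/validation/test.

Registration to a template (e.g. FSL FLIRT against MNI152) and skull
stripping (e.g. BET with fractional intensity 0.65) are upstream,
external-tool steps: this module expects their outputs.

The split is slice-level by default, i.e. slices of one subject may land in
different partitions; pass ``by_subject=True`` to :func:`split_dataset` for a
leakage-free subject-level split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "LABELS",
    "Volume",
    "SliceDataset",
    "minmax_normalize",
    "resize_volume",
    "extract_coronal_slices",
    "build_slice_dataset",
    "split_dataset",
    "load_manifest",
    "export_png",
    "load_png_dataset",
]

#: Diagnostic classes in canonical order.
LABELS = ("AD", "MCI", "HC")

SPLITS = ("train", "val", "test")


@dataclass
class Volume:
    """One subject's 3-D scalar volume with orientation and label metadata."""

    voxels: np.ndarray
    subject_id: str = ""
    label: str | None = None
    coronal_axis: int = 1

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-axis volume, got shape {self.voxels.shape}")
        if not (0 <= self.coronal_axis <= 2):
            raise ValueError("coronal_axis must be 0, 1 or 2")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @classmethod
    def from_nifti(cls, path, subject_id: str | None = None, label: str | None = None) -> "Volume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        codes = nib.aff2axcodes(img.affine)
        coronal = next((i for i, c in enumerate(codes) if c in ("A", "P")), None)
        if coronal is None:
            warnings.warn(
                f"{path}: could not identify the coronal axis from orientation "
                f"codes {codes}; assuming axis 1"
            )
            coronal = 1
        sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
        return cls(voxels=data, subject_id=sid, label=label, coronal_axis=coronal)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        # identity affine is RAS, so axis 1 is the anterior-posterior (coronal) axis
        if self.coronal_axis != 1:
            raise ValueError("NIfTI export assumes coronal_axis == 1")
        nib.save(nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), np.eye(4)), str(path))


def minmax_normalize(v: Volume) -> Volume:
    """Affinely map voxel intensities onto [0, 255].

    A constant volume has no intensity range to map; it becomes all-zero with
    a warning.
    """
    vox = v.voxels.astype(np.float32)
    if not np.isfinite(vox).all():
        raise ValueError(f"volume {v.subject_id!r} contains non-finite voxels")
    lo, hi = float(vox.min()), float(vox.max())
    if hi == lo:
        warnings.warn(f"volume {v.subject_id!r} is constant; normalising to all zeros")
        return replace(v, voxels=np.zeros_like(vox))
    return replace(v, voxels=(vox - lo) / (hi - lo) * 255.0)


def resize_volume(v: Volume, target: tuple[int, int, int] = (128, 128, 128)) -> Volume:
    """Trilinear resample to ``target``; linear kernels cannot overshoot."""
    if any(t <= 0 for t in target):
        raise ValueError(f"target shape must be positive, got {target}")
    if tuple(v.shape) == tuple(target):
        return replace(v, voxels=v.voxels.astype(np.float32))
    out = _sk_resize(
        v.voxels.astype(np.float32),
        target,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return replace(v, voxels=out.astype(np.float32))


def extract_coronal_slices(v: Volume, n_slices: int = 20, step: int | None = None) -> list[np.ndarray]:
    """Deterministically pick ``n_slices`` coronal slices around the midline.

    The default spacing makes the selected span cover roughly the central 30%
    of the coronal axis.  Returns 2-D arrays built from the two non-coronal
    axes, in anterior-to-posterior index order.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    length = v.shape[v.coronal_axis]
    if step is None:
        step = max(1, round(0.3 * length / n_slices))
    required = (n_slices - 1) * step + 1
    if length < required:
        raise ValueError(
            f"coronal axis of {v.subject_id!r} has {length} slices but "
            f"{required} are required for n_slices={n_slices}, step={step}"
        )
    start = length // 2 - ((n_slices - 1) * step) // 2
    start = max(0, min(start, length - 1 - (n_slices - 1) * step))
    idx = start + np.arange(n_slices) * step
    stack = np.take(v.voxels, idx, axis=v.coronal_axis)
    return [np.take(stack, i, axis=v.coronal_axis) for i in range(n_slices)]


@dataclass
class SliceDataset:
    """Labelled 2-D grayscale slices with subject provenance and split tags."""

    images: np.ndarray  # (N, H, W) float32 in [0, 255]
    labels: np.ndarray  # (N,) str
    subject_ids: np.ndarray  # (N,) str
    split: np.ndarray = field(default=None)  # (N,) str in {"", "train", "val", "test"}

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.split is None:
            self.split = np.full(len(self.labels), "", dtype="<U5")
        self.split = np.asarray(self.split)
        n = len(self.images)
        if not (len(self.labels) == len(self.subject_ids) == len(self.split) == n):
            raise ValueError("images, labels, subject_ids and split must be equal length")

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LABELS}

    def split_counts(self) -> dict[str, int]:
        return {s: int((self.split == s).sum()) for s in SPLITS}

    def subset(self, mask: np.ndarray) -> "SliceDataset":
        return SliceDataset(
            images=self.images[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            split=self.split[mask],
        )

    def partition(self, split: str) -> "SliceDataset":
        if split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        return self.subset(self.split == split)


def build_slice_dataset(
    volumes: list[Volume],
    n_slices: int = 20,
    resize_target: tuple[int, int, int] | None = (128, 128, 128),
    step: int | None = None,
) -> SliceDataset:
    """Compose resample → normalise → slice over a labelled cohort.

    Slice order is stable given the input volume order: all slices of the
    first volume, then the second, and so on.
    """
    if not volumes:
        raise ValueError("no volumes given")
    images, labels, sids = [], [], []
    for vol in volumes:
        if vol.label is None:
            raise ValueError(f"volume {vol.subject_id!r} has no class label")
        v = resize_volume(vol, resize_target) if resize_target is not None else vol
        v = minmax_normalize(v)
        for sl in extract_coronal_slices(v, n_slices=n_slices, step=step):
            images.append(sl)
            labels.append(vol.label)
            sids.append(vol.subject_id)
    return SliceDataset(
        images=np.stack(images),
        labels=np.array(labels),
        subject_ids=np.array(sids),
    )


def split_dataset(
    ds: SliceDataset,
    ratios: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
    by_subject: bool = False,
) -> SliceDataset:
    """Random 8:1:1 train/val/test partition of the shuffled slices.

    Counts use floor allocation for validation and test, remainder to train
    (10,060 slices → 8,048 / 1,006 / 1,006).  ``by_subject=True`` assigns
    whole subjects to partitions instead, which prevents the subject leakage
    inherent in slice-level splitting (slice-level is the default because the
    slices, not the subjects, are shuffled).
    """
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    total = sum(ratios)

    def allocate(n: int) -> tuple[int, int, int]:
        n_val = n * ratios[1] // total
        n_test = n * ratios[2] // total
        return n - n_val - n_test, n_val, n_test

    split = np.full(len(ds), "", dtype="<U5")
    if by_subject:
        subjects = np.array(sorted(set(ds.subject_ids.tolist())))
        order = rng.permutation(len(subjects))
        n_train, n_val, _ = allocate(len(subjects))
        tags = {}
        for rank, subj_idx in enumerate(order):
            tag = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
            tags[subjects[subj_idx]] = tag
        for i, sid in enumerate(ds.subject_ids):
            split[i] = tags[sid]
    else:
        order = rng.permutation(len(ds))
        n_train, n_val, _ = allocate(len(ds))
        split[order[:n_train]] = "train"
        split[order[n_train : n_train + n_val]] = "val"
        split[order[n_train + n_val :]] = "test"
    return SliceDataset(
        images=ds.images, labels=ds.labels, subject_ids=ds.subject_ids, split=split
    )


# ---------------------------------------------------------------------------
# on-disk interfaces: manifest CSV, PNG slices + index CSV
# ---------------------------------------------------------------------------

def load_manifest(manifest_csv) -> list[Volume]:
    """Read a cohort manifest (columns: subject_id, path, label) into Volumes."""
    table = pd.read_csv(manifest_csv)
    needed = {"subject_id", "path", "label"}
    if not needed.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(needed)}, got {list(table.columns)}")
    root = Path(manifest_csv).parent
    volumes = []
    for row in table.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = root / path
        if not path.exists():
            raise FileNotFoundError(f"volume listed in manifest not found: {path}")
        volumes.append(Volume.from_nifti(path, subject_id=str(row.subject_id), label=row.label))
    return volumes


def export_png(ds: SliceDataset, outdir) -> Path:
    """Write slices as 8-bit grayscale PNGs plus an index CSV; returns the index path."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "slices").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(ds)):
        rel = f"slices/{i:06d}_{ds.subject_ids[i]}.png"
        img = np.clip(np.round(ds.images[i]), 0, 255).astype(np.uint8)
        iio.imwrite(outdir / rel, img)
        rows.append(
            {
                "path": rel,
                "subject_id": ds.subject_ids[i],
                "label": ds.labels[i],
                "split": ds.split[i],
            }
        )
    index_path = outdir / "index.csv"
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path


def load_png_dataset(index_csv) -> SliceDataset:
    """Load a dataset previously written by :func:`export_png`."""
    import imageio.v3 as iio

    table = pd.read_csv(index_csv, keep_default_na=False)
    root = Path(index_csv).parent
    images = np.stack([iio.imread(root / p).astype(np.float32) for p in table["path"]])
    return SliceDataset(
        images=images,
        labels=table["label"].to_numpy(dtype=str),
        subject_ids=table["subject_id"].to_numpy(dtype=str),
        split=table["split"].to_numpy(dtype=str),
    )
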