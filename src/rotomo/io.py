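"""Reading and writing stacks, masks, volumes and tab-separated tables.

Multi-page TIFF is the interchange format for frames, masks and volumes
(one page per frame or z-slice, 32-bit float by default, pixel size recorded
in the TIFF resolution tags and a JSON sidecar).  Angle and track tables are
plain TSV so runs are human-diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError
from .phantom import ProjectionFrame, ProjectionStack, Volume3D
from .preprocess import CellMask
from .rotation_tracking import AngleSeries, FeatureTrack

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "write_masks",
    "read_masks",
    "write_angles_tsv",
    "read_angles_tsv",
    "write_tracks_tsv",
    "write_circles_tsv",
]

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def _resolution_tag(pixel_size: float) -> tuple:
    # TIFF resolution is pixels per unit; record pixels per centimetre
    per_cm = 1e4 / pixel_size  # pixel_size in micrometres
    return (per_cm, per_cm)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stack(stack: ProjectionStack, path: str | Path) -> Path:
    """Write a projection stack as a 32-bit float multi-page TIFF.

    Truth angles, when present, go to an ``angles.tsv`` sidecar next to the
    stack; pixel size is stored in the resolution tags and a JSON sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = stack.as_array().astype(np.float32)
    tifffile.imwrite(
        path, data, resolution=_resolution_tag(stack.pixel_size),
        resolutionunit="CENTIMETER",
    )
    _sidecar(path).write_text(
        json.dumps({"pixel_size_um": stack.pixel_size, "n_frames": len(stack)})
    )
    if stack.truth_angles is not None:
        write_angles_tsv(stack.truth_angles, path.parent / "angles.tsv",
                         column="truth_angle_deg")
    return path


def _scale_integers(data: np.ndarray) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        return data.astype(np.float32) / np.iinfo(data.dtype).max
    return data


def read_stack(path: str | Path) -> ProjectionStack:
    """Read a multi-page TIFF stack or a directory of single-page frames.

    Float inputs are taken as-is; integer inputs are scaled by their dtype
    maximum into [0, 1].  A ``angles.tsv`` sidecar, when present, populates
    the truth angles; the pixel size comes from the JSON sidecar (1.0 µm
    when absent).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValidationError(f"no image frames found in {path}")
        pages = []
        for p in files:
            if p.suffix.lower() == ".png":
                import imageio.v3 as iio

                img = iio.imread(p)
            else:
                img = tifffile.imread(p)
            if img.ndim != 2:
                raise ValidationError(f"frame {p.name} is not a single 2D image")
            if pages and img.shape != pages[0].shape:
                raise ValidationError(
                    f"frame {p.name} has shape {img.shape}, expected {pages[0].shape}"
                )
            pages.append(_scale_integers(img))
        data = np.stack(pages)
        meta_path = _sidecar(path / "stack.tif")
        angles_path = path / "angles.tsv"
    else:
        if not path.exists():
            raise ValidationError(f"stack file {path} does not exist")
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        data = _scale_integers(data)
        meta_path = _sidecar(path)
        angles_path = path.parent / "angles.tsv"

    pixel_size = 1.0
    if meta_path.exists():
        pixel_size = float(json.loads(meta_path.read_text())["pixel_size_um"])
    truth = read_angles_tsv(angles_path) if angles_path.exists() else None
    if truth is not None and len(truth) != len(data):
        truth = None  # sidecar does not belong to this stack
    frames = [
        ProjectionFrame(pixels=data[i], pixel_size=pixel_size, index=i)
        for i in range(len(data))
    ]
    return ProjectionStack(frames=frames, truth_angles=truth)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF, one page per vertical slice."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, vol.data.astype(np.float32),
        resolution=_resolution_tag(vol.voxel_size), resolutionunit="CENTIMETER",
    )
    _sidecar(path).write_text(json.dumps({"voxel_size_um": vol.voxel_size}))
    return path


def read_volume(path: str | Path) -> Volume3D:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume file {path} does not exist")
    data = tifffile.imread(path)
    voxel_size = 1.0
    if _sidecar(path).exists():
        voxel_size = float(json.loads(_sidecar(path).read_text())["voxel_size_um"])
    return Volume3D(data=data, voxel_size=voxel_size)


def write_masks(masks: list[CellMask], path: str | Path) -> Path:
    """Write binary masks as an 8-bit multi-page TIFF (0/255)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([m.pixels for m in masks]).astype(np.uint8) * 255
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def read_masks(path: str | Path) -> list[CellMask]:
    data = tifffile.imread(Path(path))
    if data.ndim == 2:
        data = data[None]
    return [CellMask(pixels=page > 127) for page in data]


def write_angles_tsv(
    angles: AngleSeries | np.ndarray,
    path: str | Path,
    column: str = "angle_deg",
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(angles, AngleSeries):
        src = angles.source_feature
        if src is None:
            src = np.full(len(angles), -1, dtype=int)
        lines = ["frame\tangle_deg\tsource_feature"]
        for i, (a, s) in enumerate(zip(angles.fused, src)):
            lines.append(f"{i}\t{a:.6f}\t{int(s)}")
    else:
        lines = [f"frame\t{column}"]
        for i, a in enumerate(np.asarray(angles, dtype=float)):
            lines.append(f"{i}\t{a:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_angles_tsv(path: str | Path) -> np.ndarray:
    """Read the angle column of an angles TSV (truth or estimated)."""
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    col = 1 if len(header) > 1 else 0
    return np.array([float(ln.split("\t")[col]) for ln in lines[1:]])


def write_tracks_tsv(tracks: list[FeatureTrack], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["frame\tfeature_id\trow\tcol\tvalid"]
    for tr in tracks:
        for i in range(len(tr.valid)):
            r, c = tr.positions[i]
            lines.append(
                f"{i}\t{tr.feature_id}\t{r:.4f}\t{c:.4f}\t{int(tr.valid[i])}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_circles_tsv(circles, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["frame\trow\tcol\tradius"]
    for i, c in enumerate(circles):
        lines.append(f"{i}\t{c.center_row:.4f}\t{c.center_col:.4f}\t{c.radius:.4f}")
    path.write_text("\n".join(lines) + "\n")
    return path
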