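"""Domain data types, NIfTI volume I/O, masked feature extraction and standardization.

The central objects are :class:`MultiparametricStack` (a set of co-registered
3-D parameter maps plus a binary region-of-interest mask) and
:class:`FeatureMatrix` (the masked voxels flattened to an ``N x P`` matrix in a
fixed raster order, with the voxel coordinates retained so results can be
scattered back onto the grid).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "MultiparametricStack",
    "FeatureMatrix",
    "GridMismatchError",
    "read_stack",
    "extract_features",
    "standardize",
    "scatter_to_grid",
    "write_segmentation",
]

#: Canonical parameter order used throughout the package.
DEFAULT_PARAMS = ("ADC", "T2_pre", "T2_post", "T2star_pre", "T2star_post")


class GridMismatchError(ValueError):
    """Raised when volumes in a stack do not share a common grid."""


@dataclass
class MultiparametricStack:
    """Co-registered 3-D scalar parameter maps with a binary mask.

    Parameters
    ----------
    maps
        Ordered mapping from parameter name to 3-D float array (e.g. ADC in
        1e-6 mm^2/s, T2/T2* relaxation times in ms).
    mask
        Boolean 3-D array, same shape as every map.
    spacing
        Voxel dimensions in mm.
    affine
        4x4 voxel-to-world affine carried through to all outputs.
    """

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.mask.shape}")
        for name, vol in self.maps.items():
            vol = np.asarray(vol, dtype=float)
            self.maps[name] = vol
            if vol.shape != self.mask.shape:
                raise GridMismatchError(
                    f"grid mismatch: map {name!r} has shape {vol.shape}, "
                    f"mask has shape {self.mask.shape}"
                )
        if not self.mask.any():
            raise ValueError("empty mask")
        for name, vol in self.maps.items():
            if not np.isfinite(vol[self.mask]).all():
                bad = np.argwhere(self.mask & ~np.isfinite(vol))
                raise ValueError(
                    f"non-finite values in map {name!r} inside mask at voxels "
                    f"{bad[:5].tolist()}{'...' if len(bad) > 5 else ''}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.maps)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureMatrix:
    """``N x P`` feature matrix for the mask-true voxels of a stack.

    Row ``i`` holds the concatenated parameter values of the voxel at
    ``coords[i]``; rows follow a deterministic raster scan of the mask
    (last axis fastest). ``loc``/``scale`` record the per-column shift and
    scale applied when ``standardized`` is true.
    """

    X: np.ndarray
    coords: np.ndarray
    param_names: tuple[str, ...]
    grid_shape: tuple[int, int, int]
    standardized: bool = False
    loc: np.ndarray | None = None
    scale: np.ndarray | None = None
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.X.ndim != 2 or self.coords.shape != (self.X.shape[0], 3):
            raise ValueError("X must be N x P with matching N x 3 coords")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def read_stack(
    paths: Mapping[str, str | Path], mask_path: str | Path
) -> MultiparametricStack:
    """Load named NIfTI parameter maps and a binary mask into a validated stack.

    The mask is thresholded at 0.5; any values other than {0, 1} after
    thresholding comparison (i.e. values not close to 0 or 1) are an error.
    Affines are required to agree within 1e-4 across all volumes.
    """
    mask_img = nib.load(str(mask_path))
    mask_data = np.asanyarray(mask_img.dataobj, dtype=float)
    if mask_data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {mask_data.shape}")
    rounded = np.round(mask_data)
    if not np.all(np.isin(rounded, (0.0, 1.0))) or not np.allclose(
        mask_data, rounded, atol=0.499
    ):
        bad = np.unique(mask_data[~np.isin(rounded, (0.0, 1.0))])
        raise ValueError(f"mask is not binary; found values {bad[:5]}")
    mask = mask_data > 0.5

    affine = np.asarray(mask_img.affine, dtype=float)
    maps: dict[str, np.ndarray] = {}
    for name, p in paths.items():
        img = nib.load(str(p))
        data = np.asanyarray(img.dataobj, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"map {name!r} must be 3-D, got shape {data.shape}")
        if data.shape != mask.shape:
            raise GridMismatchError(
                f"grid mismatch: map {name!r} has shape {data.shape}, "
                f"mask has shape {mask.shape}"
            )
        if not np.allclose(img.affine, affine, atol=1e-4):
            raise GridMismatchError(
                f"affine mismatch between map {name!r} and mask (tolerance 1e-4)"
            )
        maps[name] = data

    zooms = mask_img.header.get_zooms()[:3]
    return MultiparametricStack(
        maps=maps, mask=mask, spacing=tuple(float(z) for z in zooms), affine=affine
    )


def extract_features(stack: MultiparametricStack) -> FeatureMatrix:
    """Flatten the mask-true voxels of a stack into a feature matrix.

    Rows follow C-order raster scan of the grid (last axis fastest), so the
    mapping is bit-stable across runs for identical input.
    """
    coords = np.argwhere(stack.mask)  # C-order: last axis fastest
    cols = []
    for name, vol in stack.maps.items():
        col = vol[stack.mask]
        if not np.isfinite(col).all():
            bad = coords[~np.isfinite(col)]
            raise ValueError(
                f"non-finite values in map {name!r} at voxels {bad[:5].tolist()}"
            )
        cols.append(col)
    X = np.column_stack(cols)
    return FeatureMatrix(
        X=X,
        coords=coords,
        param_names=stack.param_names,
        grid_shape=stack.shape,
        standardized=False,
    )


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Z-score each column over the masked voxels (sample SD, ddof=1).

    Zero-variance columns are mapped to all-zero and flagged in
    ``zero_variance``.  The operation is idempotent: mean 0 / SD 1 is a fixed
    point, so standardizing twice equals standardizing once (within 1e-12).
    """
    loc = fm.X.mean(axis=0)
    n = fm.X.shape[0]
    scale = fm.X.std(axis=0, ddof=1) if n > 1 else np.zeros(fm.p)
    zero_var = scale <= 0
    safe_scale = np.where(zero_var, 1.0, scale)
    Z = (fm.X - loc) / safe_scale
    Z[:, zero_var] = 0.0
    return FeatureMatrix(
        X=Z,
        coords=fm.coords.copy(),
        param_names=fm.param_names,
        grid_shape=fm.grid_shape,
        standardized=True,
        loc=loc,
        scale=safe_scale,
        zero_variance=zero_var,
    )


def scatter_to_grid(
    values: np.ndarray,
    coords: np.ndarray,
    grid_shape: Sequence[int],
    fill: float = 0.0,
) -> np.ndarray:
    """Scatter per-voxel values back onto the 3-D grid (inverse of extraction)."""
    values = np.asarray(values)
    out = np.full(tuple(grid_shape), fill, dtype=values.dtype)
    out[tuple(coords.T)] = values
    return out


def write_segmentation(seg, out_dir: str | Path, affine: np.ndarray | None = None):
    """Write a segmentation to ``out_dir`` as NIfTI volumes plus a JSON sidecar.

    Outputs one integer label volume (0 = outside mask, 1..K = classes), K
    probability volumes, and ``segmentation.json`` with class metadata,
    fractions and convergence records.  Returns the list of written paths.
    """
    from .evaluate import SegmentationResult  # local import to avoid cycle

    if not isinstance(seg, SegmentationResult):
        raise TypeError("seg must be a SegmentationResult")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)

    written: list[Path] = []
    label_path = out_dir / "labels.nii.gz"
    nib.save(nib.Nifti1Image(seg.labels.astype(np.int16), affine), str(label_path))
    written.append(label_path)

    for k in range(seg.n_classes):
        name = seg.class_info[k]["name"]
        p = out_dir / f"prob_{k + 1}_{name}.nii.gz"
        nib.save(
            nib.Nifti1Image(seg.probabilities[..., k].astype(np.float32), affine),
            str(p),
        )
        written.append(p)

    sidecar = out_dir / "segmentation.json"
    meta = {
        "classes": _jsonable(seg.class_info),
        "metadata": _jsonable(seg.metadata),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    written.append(sidecar)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    return obj
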