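"""Readers and writers for every external format the pipeline touches.

Volumes and spatial component maps travel as NIfTI-1 (via nibabel),
realignment parameters and ICA mixing matrices as whitespace-delimited
text, avalanche tables as TSV. The initial-sample trim applied after
acquisition (to discard T1-relaxation transients) lives here too, so the
volume series, the mixing matrix and the motion trace stay in lockstep.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass
class VolumeSeries:
    """A 4D BOLD recording: spatial grid x time.

    ``data`` is (x, y, z, t) in arbitrary units, ``affine`` the 4x4
    voxel-to-world transform, ``tr_s`` the sampling interval in seconds
    (0.1 s for a 10 Hz acquisition), and ``mask`` an optional 3D boolean
    brain mask.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float = 0.1
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValueError("time axis must have at least one volume")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must equal spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters per volume.

    ``rotations`` is T x 3 in radians, ``translations`` T x 3 in mm.
    """

    rotations: np.ndarray
    translations: np.ndarray

    def __post_init__(self) -> None:
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if self.rotations.shape != self.translations.shape:
            raise ValueError("rotations and translations must have the same shape")
        if self.rotations.shape[1] != 3:
            raise FormatError("expected 3 rotation and 3 translation columns")

    def __len__(self) -> int:
        return self.rotations.shape[0]


@dataclass
class MixingMatrix:
    """ICA temporal mixing matrix: rows = time points, columns = components."""

    values: np.ndarray
    component_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mixing matrix entries must be finite")
        if self.component_ids is None:
            self.component_ids = [str(i) for i in range(self.values.shape[1])]
        if len(self.component_ids) != self.values.shape[1]:
            raise ValueError("component_ids length must match column count")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class SpatialMaps:
    """ICA spatial z-score maps, one 3D map per component (4th axis)."""

    zmaps: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.zmaps = np.asarray(self.zmaps, dtype=float)
        if self.zmaps.ndim != 4:
            raise FormatError(f"expected 4D z-maps, got {self.zmaps.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_components(self) -> int:
        return self.zmaps.shape[3]


def read_volume_series(
    path: str | Path, tr_s: float | None = None
) -> VolumeSeries:
    """Read a 4D NIfTI-1 volume series (optionally gzipped).

    The repetition time comes from the header's pixdim[4]; an explicit
    ``tr_s`` argument overrides it (fast-sequence headers are often
    wrong), with a warning when the two disagree by more than 1%.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(f"expected 4D volume series in {path}, got {data.ndim}D")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_s is None:
        if header_tr <= 0:
            raise FormatError(
                f"header field pixdim[4] (TR) missing or nonpositive in {path}; "
                "pass tr_s explicitly"
            )
        tr = header_tr
    else:
        tr = tr_s
        if header_tr > 0 and abs(header_tr - tr_s) / tr_s > 0.01:
            logger.warning(
                "TR mismatch: header says %.4f s, config says %.4f s; using config",
                header_tr,
                tr_s,
            )
    return VolumeSeries(data=data, affine=img.affine, tr_s=tr)


def write_volume_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a :class:`VolumeSeries` as NIfTI-1, stamping TR in the header."""
    img = nib.Nifti1Image(series.data, series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_spatial_maps(path: str | Path) -> SpatialMaps:
    """Read 4D ICA z-score maps (4th axis = component)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(f"expected 4D z-maps in {path}, got {data.ndim}D")
    return SpatialMaps(zmaps=data, affine=img.affine)


def write_spatial_maps(maps: SpatialMaps, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(maps.zmaps, maps.affine), str(path))


def read_motion_params(
    path: str | Path, columns: str = "rot-first"
) -> MotionTrace:
    """Read a plain-text 6-column realignment-parameter file.

    The standard file has one row per volume. With ``columns="rot-first"``
    (the MCFLIRT convention) columns 1-3 are rotations in radians and 4-6
    translations in mm; ``"trans-first"`` swaps the two triples.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise FormatError(f"{path}: empty realignment file")
    arr = np.asarray(rows, dtype=float)
    if columns == "rot-first":
        return MotionTrace(rotations=arr[:, :3], translations=arr[:, 3:])
    if columns == "trans-first":
        return MotionTrace(rotations=arr[:, 3:], translations=arr[:, :3])
    raise ValueError("columns must be 'rot-first' or 'trans-first'")


def write_motion_params(
    trace: MotionTrace, path: str | Path, columns: str = "rot-first"
) -> None:
    if columns == "rot-first":
        arr = np.hstack([trace.rotations, trace.translations])
    else:
        arr = np.hstack([trace.translations, trace.rotations])
    np.savetxt(path, arr, fmt="%.10g")


def read_mixing_matrix(path: str | Path) -> MixingMatrix:
    """Read a whitespace-delimited numeric mixing matrix (rows = time)."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row, expected {width} columns"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise FormatError(f"{path}: empty mixing matrix")
    return MixingMatrix(values=np.asarray(rows, dtype=float))


def write_mixing_matrix(matrix: MixingMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.values, fmt="%.10g")


def trim_initial(series_like, n: int):
    """Drop the first ``n`` samples/volumes/rows.

    Applies consistently to :class:`VolumeSeries` (time axis),
    :class:`MixingMatrix` (rows), :class:`MotionTrace` (rows) and plain
    1D/2D arrays (first axis), so companion objects stay aligned.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if isinstance(series_like, VolumeSeries):
        if n >= series_like.n_volumes:
            raise ValueError(f"cannot trim {n} of {series_like.n_volumes} volumes")
        return dataclasses.replace(series_like, data=series_like.data[..., n:])
    if isinstance(series_like, MixingMatrix):
        if n >= len(series_like):
            raise ValueError(f"cannot trim {n} of {len(series_like)} rows")
        return MixingMatrix(
            values=series_like.values[n:], component_ids=list(series_like.component_ids)
        )
    if isinstance(series_like, MotionTrace):
        if n >= len(series_like):
            raise ValueError(f"cannot trim {n} of {len(series_like)} rows")
        return MotionTrace(
            rotations=series_like.rotations[n:],
            translations=series_like.translations[n:],
        )
    arr = np.asarray(series_like)
    if n >= arr.shape[0]:
        raise ValueError(f"cannot trim {n} of {arr.shape[0]} samples")
    return arr[n:]


def check_aligned(*objects) -> int:
    """Assert that companion series objects have equal time length.

    Returns the common length. Accepts VolumeSeries, MixingMatrix,
    MotionTrace and arrays.
    """
    lengths = []
    for obj in objects:
        if isinstance(obj, VolumeSeries):
            lengths.append(obj.n_volumes)
        elif isinstance(obj, (MixingMatrix, MotionTrace)):
            lengths.append(len(obj))
        else:
            lengths.append(np.asarray(obj).shape[0])
    if len(set(lengths)) > 1:
        raise ValueError(f"length mismatch between companion series: {lengths}")
    return lengths[0]


AVALANCHE_TABLE_COLUMNS = [
    "component",
    "peak_index",
    "peak_time_s",
    "value",
    "lifetime_samples",
    "size",
    "motion_excluded",
    "dscore_resp",
    "dscore_cardiac",
]


def write_avalanche_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the avalanche/peak table as TSV with the canonical columns."""
    missing = [c for c in AVALANCHE_TABLE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"avalanche table missing columns: {missing}")
    records[AVALANCHE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_avalanche_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
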