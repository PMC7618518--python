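"""File formats: localization CSVs (ThunderSTORM-compatible dialect),
multipage 16-bit TIFF frame stacks, spectral-count CSVs, gene lists, and
reconstruction images with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localization import LOC_COLUMNS, SRImage
from .simulate import CameraModel, FrameStack

#: Internal column name -> exported CSV header.
CSV_DIALECT = {
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "intensity_photon": "intensity [photon]",
    "offset_photon": "offset [photon]",
    "uncertainty_nm": "uncertainty [nm]",
}
_FROM_CSV = {v: k for k, v in CSV_DIALECT.items()}


def write_localizations(table: pd.DataFrame, path) -> None:
    out = table[[c for c in LOC_COLUMNS if c in table.columns]].rename(
        columns=CSV_DIALECT)
    out.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={c: _FROM_CSV.get(c.strip(), c.strip())
                            for c in df.columns})
    missing = [c for c in ("frame", "x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"localization CSV missing columns: {missing}")
    return df


def write_stack(stack: FrameStack, path) -> None:
    """Multipage 16-bit TIFF (counts clipped to the uint16 range)."""
    data = np.clip(np.rint(stack.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16),
                     photometric="minisblack",
                     metadata={"pixel_size_nm": stack.camera.pixel_size_nm})


def read_stack(path, camera: CameraModel | None = None) -> FrameStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if camera is None:
        camera = CameraModel(width=frames.shape[2], height=frames.shape[1])
    return FrameStack(frames=frames.astype(float), camera=camera)


def write_sr_image(image: SRImage, path) -> None:
    """Reconstruction as TIFF plus a JSON sidecar with the bin size."""
    path = Path(path)
    data = np.clip(np.rint(image.counts), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "bin_size_nm": image.bin_size_nm,
        "origin_nm": list(image.origin_nm),
        "total_localizations": int(image.counts.sum()),
    }, indent=2))


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=False)


def read_count_matrix(path) -> pd.DataFrame:
    """Spectral-count CSV with schema validation: metadata columns
    ``protein_id``, ``gene``, ``unique_peptides`` and at least one
    ``<condition>_rep<k>`` column per condition."""
    from .proteomics import META_COLUMNS, replicate_columns

    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"count matrix {path}: missing column(s) {missing}")
    conds = replicate_columns(df)
    if not conds:
        raise ValueError(f"count matrix {path}: no <condition>_rep<k> "
                         "count columns found")
    for cond, cols in conds.items():
        vals = df[cols].to_numpy()
        if (vals < 0).any():
            raise ValueError(f"count matrix {path}: negative counts in "
                             f"condition {cond!r}")
    return df


__all__ = ["CSV_DIALECT", "read_localizations", "write_localizations",
           "read_stack", "write_stack", "write_sr_image",
           "read_count_matrix", "write_count_matrix"]
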