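"""File I/O: TIFF stacks, CSV tables, plain-text IRF histograms, run configs.

Conventions:

* spot stacks are multi-page TIFF, one square image per page, integer
  counts;
* FLIM stacks are multi-page TIFF with one page per time bin (page k is
  the (rows, cols) count image of bin k), loaded into (rows, cols, N);
* output maps are 32-bit float TIFF with masked pixels as NaN;
* CSV is written with 17 significant digits so values round-trip exactly;
* a run's configuration is echoed verbatim to ``config.yaml`` in the
  output directory for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_spot_stack",
    "write_spot_stack",
    "read_flim_stack",
    "write_flim_stack",
    "write_map",
    "read_irf_histogram",
    "write_irf_histogram",
    "write_table",
    "read_table",
    "write_run_config",
]

FLOAT_FMT = "%.17g"


def read_spot_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF of square spot images into (n, s, s)."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D pages")
    if arr.shape[1] != arr.shape[2]:
        raise ValueError(
            f"{path}: pages are {arr.shape[1]}x{arr.shape[2]}, expected square"
        )
    return arr


def write_spot_stack(path: str | Path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    tifffile.imwrite(str(path), stack.astype(np.uint16))


def read_flim_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF (one page per time bin) into (rows, cols, N)."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected one page per time bin")
    return np.moveaxis(arr, 0, -1)


def write_flim_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (rows, cols, N) stack as one TIFF page per time bin."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("FLIM stack must be 3-D (rows, cols, N)")
    tifffile.imwrite(str(path), np.moveaxis(stack, -1, 0).astype(np.uint16))


def write_map(path: str | Path, image: np.ndarray) -> None:
    """Write a floating-point map (NaN = masked) as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_irf_histogram(path: str | Path) -> np.ndarray:
    """Read a plain-text IRF histogram, one count per line."""
    values = np.loadtxt(str(path), dtype=np.float64, ndmin=1)
    if values.ndim != 1 or values.size == 0:
        raise ValueError(f"{path}: expected one value per line")
    return values


def write_irf_histogram(path: str | Path, histogram: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(histogram, dtype=np.float64),
               fmt=FLOAT_FMT)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """CSV with full-precision floats; masked values become empty fields."""
    table.to_csv(str(path), index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def write_run_config(out_dir: str | Path, config: Mapping) -> Path:
    """Echo the run configuration (plus package version) to config.yaml."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(config)
    payload["parafit_version"] = __version__
    path = out_dir / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path
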