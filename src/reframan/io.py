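"""Frame and result file formats: 16-bit PGM + JSON sidecars.

All on-disk formats are text or simple portable graymaps so outputs diff
cleanly in tests: frames as binary 16-bit PGM with a ``.json`` truth sidecar,
spectra as two-column delimited text (see :mod:`reframan.spectral_core`),
models and calibration logs as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .instrument_sim import SensorFrame

__all__ = ["write_frame", "read_frame", "read_frame_dir"]


def write_frame(frame: SensorFrame, path: str | Path) -> Path:
    """Write a frame as 16-bit PGM plus a JSON sidecar next to it."""
    path = Path(path).with_suffix(".pgm")
    counts = np.clip(np.round(frame.counts), 0, 65535).astype(np.uint16)
    iio.imwrite(path, counts)
    path.with_suffix(".json").write_text(json.dumps(frame.sidecar, indent=1, default=str))
    return path


def read_frame(path: str | Path) -> SensorFrame:
    """Read a PGM frame and its JSON sidecar (sidecar optional)."""
    path = Path(path)
    counts = np.asarray(iio.imread(path), dtype=float)
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return SensorFrame(counts, sidecar)


def read_frame_dir(directory: str | Path) -> list[SensorFrame]:
    """Read every ``*.pgm`` frame in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.pgm"))
    if not paths:
        raise FileNotFoundError(f"no .pgm frames in {directory}")
    return [read_frame(p) for p in paths]
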