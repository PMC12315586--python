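"""File I/O: MRC2014 volumes/stacks, particle tables (TSV), FRC curves, config.

The MRC reader/writer covers the subset this package produces and consumes:
mode 2 (float32) single volumes and image stacks with the pixel size stored
in the cell dimensions. Particle metadata travels as tab-separated tables
with a named header; unknown columns are preserved on round trips. Euler
angles are ZYZ degrees, shifts in pixels (conventions in geometry module).
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fourier import DensityVolume

_MRC_HEADER = struct.Struct("<10i6f3i3f3i")  # words 1..25 of the 1024-byte header


class MRCError(ValueError):
    pass


def write_mrc(path, data: np.ndarray | DensityVolume, pixel_size: float | None = None):
    """Write a volume (L,L,L) or stack (N,L,L) as MRC2014 mode-2 float."""
    if isinstance(data, DensityVolume):
        pixel_size = data.pixel_size
        data = data.grid
    if pixel_size is None:
        raise ValueError("pixel_size required")
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    nz, ny, nx = arr.shape
    header = bytearray(1024)
    _MRC_HEADER.pack_into(
        header,
        0,
        nx, ny, nz,  # nx ny nz
        2,  # mode 2 = float32
        0, 0, 0,  # nxstart..
        nx, ny, nz,  # mx my mz
        nx * pixel_size, ny * pixel_size, nz * pixel_size,  # cella
        90.0, 90.0, 90.0,  # cellb
        1, 2, 3,  # mapc mapr maps
        float(arr.min()), float(arr.max()), float(arr.mean()),  # dmin dmax dmean
        0, 0, 0,  # ispg, nsymbt, extra start
    )
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))  # rms
    path = Path(path)
    with open(path, "wb") as f:
        f.write(bytes(header))
        # axis order: MRC stores x fastest; our arrays are (section, row, col)
        f.write(arr.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (data, pixel_size). Stacks come back (N,L,L)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise MRCError(f"{path}: truncated header (offset {len(raw)})")
    vals = _MRC_HEADER.unpack_from(raw, 0)
    nx, ny, nz, mode = vals[0], vals[1], vals[2], vals[3]
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise MRCError(f"{path}: missing MAP stamp at offset 208")
    if mode != 2:
        raise MRCError(f"{path}: unsupported mode {mode} (offset 12); need mode 2")
    cella_x = vals[10]
    mx = vals[7]
    pixel = cella_x / mx if mx else 1.0
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    start = 1024 + nsymbt
    count = nx * ny * nz
    if len(raw) < start + 4 * count:
        raise MRCError(f"{path}: data truncated at offset {len(raw)}")
    data = np.frombuffer(raw, dtype="<f4", count=count, offset=start)
    data = data.reshape(nz, ny, nx).copy()
    if nz == 1:
        data = data[0]
    return data, float(pixel)


def read_volume(path) -> DensityVolume:
    data, pixel = read_mrc(path)
    return DensityVolume(np.asarray(data, dtype=np.float32), pixel)


# ---------------------------------------------------------------------------
# particle table
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = [
    "index",
    "defocus_u",
    "defocus_v",
    "astig_angle",
    "voltage",
    "cs",
    "amp_contrast",
    "class_id",
    "class_score",
    "phi",
    "theta",
    "psi",
    "shift_x",
    "shift_y",
    "state",
    "half",
]

TABLE_HEADER_COMMENT = (
    "# probinitio particle table v1. Euler angles ZYZ degrees "
    "(R = Rz(phi) Ry(theta) Rz(psi) acting on Fourier coords); shifts in "
    "pixels of the original box (content translated by +s)."
)


class SchemaError(ValueError):
    pass


def write_particle_table(path, table: pd.DataFrame):
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    path = Path(path)
    with open(path, "w") as f:
        f.write(TABLE_HEADER_COMMENT + "\n")
        table.to_csv(f, sep="\t", index=False, float_format="%.10g")


def read_particle_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# class FRC curves
# ---------------------------------------------------------------------------


def write_class_frcs(path, classes, box: int, pixel_size: float):
    """One curve per class: columns class_id, shell, resolution(A), frc."""
    rows = []
    for ci in classes:
        if ci.frc is None:
            continue
        for s, v in enumerate(ci.frc):
            res = box * pixel_size / s if s else np.inf
            rows.append((ci.class_id, s, res, v))
    df = pd.DataFrame(rows, columns=["class_id", "shell", "resolution", "frc"])
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_class_frcs(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        int(cid): grp.sort_values("shell")["frc"].to_numpy()
        for cid, grp in df.groupby("class_id")
    }


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """User-facing knobs; defaults follow the published constants."""

    nsample: int = 5000  # balanced particle samples per iteration
    nstates: int = 1
    het_mode: str = "independent"  # or "docked"
    symmetry: str = "C1"
    initial_epsilon: float = 10.0  # degrees
    final_lp: float | None = None  # user override, A (coarser only)
    tau: float = 3.0
    lam: float = 1.0
    icm_levels: int = 64
    icm_sweeps: int = 10
    shift_bound: float = 6.0  # px at the original box
    mask_diameter_frac: float = 0.9
    coupling: bool = True
    angular_oversampling: float = 1.25  # grid step = this / r_lp radians
    seed: int = 0
    output_dir: str | None = None
    stage_iter_override: dict = field(default_factory=dict)  # {stage: iters}, logged

    def to_json(self) -> str:
        d = asdict(self)
        d["stage_iter_override"] = {str(k): v for k, v in d["stage_iter_override"].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["stage_iter_override"] = {
            int(k): v for k, v in d.get("stage_iter_override", {}).items()
        }
        return cls(**d)
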