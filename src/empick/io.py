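"""File formats: MRC micrographs, EMAN2-style .box files, plain-text network
configs, and the trained-model container.

The MRC reader/writer handles the 2-D single-image case of the MRC2014
format (modes 0, 1, 2 and 6) directly over the 1024-byte header with numpy;
PNG/TIFF micrographs are read through imageio as a fallback.  Internally all
coordinates are 0-based, row-major, y downward with the box origin at its
top-left corner; the EMAN2 bottom-left-origin convention of .box files is
produced by a y-axis flip applied only at this module's boundary.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import numpy as np

from .network import NetworkConfig, NetworkState
from .recognition import Candidate

__all__ = [
    "FormatError",
    "read_micrograph",
    "write_micrograph",
    "read_mrc",
    "write_mrc",
    "write_box_file",
    "read_box_file",
    "write_config",
    "read_config",
    "save_model",
    "load_model",
]


class FormatError(ValueError):
    """A file does not parse as the format its extension claims."""


_MRC_HEADER_BYTES = 1024
_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a 2-D MRC image (modes 0/1/2/6, either endianness).

    Returns (intensities as float64, pixel size in Angstrom — 0.0 when the
    header carries no cell dimensions).  A volume with NZ > 1 is rejected;
    NZ == 1 is accepted as a single image.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(
            f"{path}: truncated MRC header ({len(raw)} < {_MRC_HEADER_BYTES} "
            "bytes at offset 0)")
    for endian in ("<", ">"):
        head_i = np.frombuffer(raw[:_MRC_HEADER_BYTES], dtype=endian + "i4")
        head_f = np.frombuffer(raw[:_MRC_HEADER_BYTES], dtype=endian + "f4")
        nx, ny, nz, mode = (int(v) for v in head_i[:4])
        if mode in _MRC_MODES and 1 <= nx < 1 << 20 and 1 <= ny < 1 << 20:
            break
    else:
        raise FormatError(
            f"{path}: unrecognized MRC mode {int(head_i[3])} at byte offset 12")
    if nz > 1:
        raise FormatError(f"{path}: NZ={nz} is a stack/volume, not a 2-D image")
    nsymbt = int(head_i[23])
    offset = _MRC_HEADER_BYTES + nsymbt
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder(endian)
    need = offset + nx * ny * dtype.itemsize
    if len(raw) < need:
        raise FormatError(
            f"{path}: truncated MRC data, expected {need} bytes, file ends at "
            f"byte offset {len(raw)}")
    data = np.frombuffer(raw, dtype=dtype, count=nx * ny, offset=offset)
    mx = int(head_i[7])
    cella = float(head_f[10])
    pixel_size = cella / mx if mx > 0 and cella > 0 else 0.0
    return data.reshape(ny, nx).astype(np.float64), pixel_size


def write_mrc(path, image: np.ndarray, pixel_size: float = 0.0) -> None:
    """Write a 2-D image as MRC2014 mode 2 (float32, little-endian)."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("write_mrc expects a 2-D image")
    ny, nx = img.shape
    head_i = np.zeros(256, dtype="<i4")
    head_f = head_i.view("<f4")
    head_i[0:3] = (nx, ny, 1)
    head_i[3] = 2                       # mode 2 = float32
    head_i[7:10] = (nx, ny, 1)          # sampling grid
    if pixel_size > 0:
        head_f[10:13] = (nx * pixel_size, ny * pixel_size, pixel_size)
    head_f[13:16] = (90.0, 90.0, 90.0)
    head_i[16:19] = (1, 2, 3)
    head_f[19] = float(img.min())
    head_f[20] = float(img.max())
    head_f[21] = float(img.mean())
    head_i[27] = 20140                  # format version
    head_i[52] = int.from_bytes(b"MAP ", "little")
    head_i[53] = int.from_bytes(bytes((0x44, 0x44, 0, 0)), "little")
    head_f[54] = float(img.std())
    with open(path, "wb") as fh:
        fh.write(head_i.tobytes())
        fh.write(img.tobytes())


_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_micrograph(path) -> np.ndarray:
    """Read a micrograph as a float64 2-D grid (MRC, or PNG/TIFF fallback)."""
    p = Path(path)
    if p.suffix.lower() in _IMAGE_EXTS:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(p), dtype=np.float64)
        if img.ndim == 3:  # collapse color planes
            img = img.mean(axis=2)
        return img
    data, _ = read_mrc(p)
    return data


def write_micrograph(path, image: np.ndarray, pixel_size: float = 0.0) -> None:
    p = Path(path)
    if p.suffix.lower() in _IMAGE_EXTS:
        import imageio.v3 as iio

        img = np.asarray(image, dtype=np.float64)
        lo, hi = img.min(), img.max()
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        iio.imwrite(p, (scaled * 65535).astype(np.uint16))
        return
    write_mrc(p, image, pixel_size)


# ---------------------------------------------------------------------------
# EMAN2 .box files
# ---------------------------------------------------------------------------

def write_box_file(candidates, box_side: int, path, image_height: int) -> int:
    """Write picked boxes in the EMAN2 convention.

    One tab-separated line per particle: x, y, box_w, box_h, where (x, y) is
    the box corner with the origin at the image bottom-left and y upward;
    the internal top-left/y-down coordinates are flipped here
    (y_file = image_height - y_internal - box_side).  Candidates are written
    in descending score order.  Returns the number of lines written.
    """
    lines = []
    for c in sorted(candidates, key=lambda c: -c.score):
        y_file = image_height - c.y - box_side
        lines.append(f"{int(c.x)}\t{int(y_file)}\t{int(box_side)}\t{int(box_side)}")
    Path(path).write_text("".join(line + "\n" for line in lines))
    return len(lines)


def read_box_file(path, image_height: int) -> list[Candidate]:
    """Read an EMAN2 .box file back into internal top-left coordinates.

    Scores are not stored in .box files and come back as NaN.
    """
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: expected 'x y w h'")
        x, y, w, h = (int(float(v)) for v in parts[:4])
        out.append(Candidate(x=x, y=image_height - y - h, score=float("nan")))
    return out


# ---------------------------------------------------------------------------
# plain-text network configuration
# ---------------------------------------------------------------------------

def _schedule_to_text(config: NetworkConfig) -> str:
    cells = []
    for (n, s) in config.schedule:
        cells.append(f"{n}@{s}x{s}")
    return ", ".join(cells)


def _schedule_from_text(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for cell in text.split(","):
        cell = cell.strip()
        n, dims = cell.split("@")
        w, h = dims.lower().split("x")
        if w != h:
            raise FormatError(f"non-square map size {cell!r}")
        out.append((int(n), int(w)))
    return tuple(out)


def write_config(config: NetworkConfig, path) -> None:
    """Serialize a network config as a human-readable key = value file; the
    layer schedule is written in the n@SxS table style."""
    cp = configparser.ConfigParser()
    cp["network"] = {
        "box_side": str(config.box_side),
        "schedule": _schedule_to_text(config),
        "activation": config.activation,
        "normalize_input": str(config.normalize_input),
        "shared_bias": str(config.shared_bias),
    }
    with open(path, "w") as fh:
        cp.write(fh)


def read_config(path) -> NetworkConfig:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise FormatError(f"{path}: unreadable config file")
    try:
        sec = cp["network"]
        return NetworkConfig(
            box_side=int(sec["box_side"]),
            schedule=_schedule_from_text(sec["schedule"]),
            activation=sec.get("activation", "sigmoid"),
            normalize_input=sec.getboolean("normalize_input", True),
            shared_bias=sec.getboolean("shared_bias", False),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad config ({exc})") from exc


# ---------------------------------------------------------------------------
# trained-model container
# ---------------------------------------------------------------------------

_MODEL_VERSION = 1


def save_model(state: NetworkState, path) -> None:
    """Save the trained network (config embedded, versioned) in one file."""
    cfg = state.config
    payload = {
        "format_version": np.array(_MODEL_VERSION),
        "config_json": np.frombuffer(json.dumps({
            "box_side": cfg.box_side,
            "schedule": list(list(p) for p in cfg.schedule),
            "activation": cfg.activation,
            "normalize_input": cfg.normalize_input,
            "shared_bias": cfg.shared_bias,
        }).encode(), dtype=np.uint8),
        "out_weights": state.out_weights,
        "out_bias": np.array(state.out_bias),
        "rng_seed": np.array(state.rng_seed),
    }
    for i, (w, b) in enumerate(zip(state.conv_weights, state.conv_biases)):
        payload[f"conv_w_{i}"] = w
        payload[f"conv_b_{i}"] = b
    np.savez(path, **payload)


def load_model(path) -> NetworkState:
    try:
        with np.load(path) as z:
            version = int(z["format_version"])
            if version != _MODEL_VERSION:
                raise FormatError(f"{path}: unsupported model version {version}")
            cfg_raw = json.loads(bytes(z["config_json"]).decode())
            config = NetworkConfig(
                box_side=int(cfg_raw["box_side"]),
                schedule=tuple(tuple(p) for p in cfg_raw["schedule"]),
                activation=cfg_raw["activation"],
                normalize_input=bool(cfg_raw["normalize_input"]),
                shared_bias=bool(cfg_raw["shared_bias"]),
            )
            conv_w, conv_b = [], []
            for i in range(3):
                conv_w.append(np.array(z[f"conv_w_{i}"]))
                conv_b.append(np.array(z[f"conv_b_{i}"]))
            return NetworkState(
                config=config,
                conv_weights=conv_w,
                conv_biases=conv_b,
                out_weights=np.array(z["out_weights"]),
                out_bias=float(z["out_bias"]),
                rng_seed=int(z["rng_seed"]),
            )
    except (KeyError, OSError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: not a readable model file ({exc})") from exc
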