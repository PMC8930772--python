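"""ImageJ/FIJI region-of-interest export for segmented cells.

Writes each cell's convex-hull polygon as an ImageJ ``.roi`` record
(big-endian binary, polygon type) bundled in a zip archive — the format
FIJI's ROI manager reads — plus a plain ``polygons.json`` mirror and a
hull-rendered label TIFF.  A compact reader is included so round trips
can be verified; vertices are integer pixel centres, so the short-based
encoding is exact.

Note ImageJ stores x = column, y = row; this module's public API is
(row, col) throughout and converts at the byte boundary.
"""

from __future__ import annotations

import json
import struct
import zipfile
from pathlib import Path

import numpy as np
import tifffile

from .infer import SegmentationResult

__all__ = ["encode_polygon_roi", "decode_roi", "export_rois", "read_roi_zip"]

_HEADER_SIZE = 64
_POLYGON = 0
_VERSION = 227


def encode_polygon_roi(vertices_rc: np.ndarray) -> bytes:
    """Encode an (n, 2) array of integer (row, col) vertices as a .roi record."""
    v = np.asarray(vertices_rc)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 2:
        raise ValueError("need an (n>=2, 2) vertex array")
    rows = np.round(v[:, 0]).astype(int)
    cols = np.round(v[:, 1]).astype(int)
    top, left = int(rows.min()), int(cols.min())
    bottom, right = int(rows.max()), int(cols.max())
    n = len(v)
    header = struct.pack(
        ">4sh b b hhhh h ffff h i i i h h b b h i i",
        b"Iout",
        _VERSION,
        _POLYGON,
        0,
        top,
        left,
        bottom,
        right,
        n,
        0.0,
        0.0,
        0.0,
        0.0,
        0,  # stroke width
        0,  # shape roi size
        0,  # stroke color
        0,  # fill color
        0,  # subtype
        0,  # options
        0,  # arrow style
        0,  # arrow head size
        0,  # rounded rect arc size
        0,  # position
        0,  # header2 offset
    )
    assert len(header) == _HEADER_SIZE
    xs = (cols - left).astype(">i2").tobytes()
    ys = (rows - top).astype(">i2").tobytes()
    return header + xs + ys


def decode_roi(blob: bytes) -> np.ndarray:
    """Decode a polygon .roi record back to (n, 2) (row, col) vertices."""
    if blob[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI record")
    roi_type = blob[6]
    if roi_type != _POLYGON:
        raise ValueError(f"unsupported ROI type {roi_type}")
    top, left, bottom, right, n = struct.unpack(">hhhhh", blob[8:18])
    xs = np.frombuffer(blob, dtype=">i2", count=n, offset=_HEADER_SIZE).astype(int)
    ys = np.frombuffer(blob, dtype=">i2", count=n, offset=_HEADER_SIZE + 2 * n).astype(int)
    return np.stack([ys + top, xs + left], axis=1)


def export_rois(result: SegmentationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write rois.zip, polygons.json and labels.tif for a segmentation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    zip_path = out / "rois.zip"
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for inst in result.instances:
            zf.writestr(
                f"cell_{inst.instance_id:04d}.roi",
                encode_polygon_roi(inst.hull_polygon),
            )
    polygons = {
        str(inst.instance_id): np.asarray(inst.hull_polygon).astype(int).tolist()
        for inst in result.instances
    }
    json_path = out / "polygons.json"
    json_path.write_text(json.dumps(polygons, indent=1))
    labels_path = out / "labels.tif"
    tifffile.imwrite(labels_path, result.label_image().astype(np.int32))
    return {"rois": zip_path, "polygons": json_path, "labels": labels_path}


def read_roi_zip(path: str | Path) -> dict[int, np.ndarray]:
    """Read a rois.zip archive into {instance_id: (n, 2) (row, col) vertices}."""
    out: dict[int, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        for name in sorted(zf.namelist()):
            stem = Path(name).stem
            inst_id = int(stem.split("_")[-1])
            out[inst_id] = decode_roi(zf.read(name))
    return out
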