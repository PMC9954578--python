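"""Reader/writer for the IDX format used by the MNIST distribution.

Big-endian layout.  An image file starts with magic 2051 followed by the
number of images, rows and columns (four 32-bit integers), then unsigned
pixel bytes; a label file starts with magic 2049 and the item count, then
one label byte per item.  Pixels are normalised to [0, 1] by dividing by
255 and flattened row-major.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .encoding import IntensityVector, LabelCode

__all__ = ["read_idx", "write_idx", "IdxFormatError"]

IMAGE_MAGIC = 2051
LABEL_MAGIC = 2049


class IdxFormatError(ValueError):
    """Malformed IDX file; the message names the byte offset."""


def _read_u32(buf: bytes, offset: int, path) -> int:
    if offset + 4 > len(buf):
        raise IdxFormatError(f"{path}: truncated header at offset {offset}")
    return struct.unpack_from(">I", buf, offset)[0]


def read_idx(images_path, labels_path, n_classes: int = 10):
    """Parse an IDX image/label file pair into encoder-ready samples.

    Returns a list of (IntensityVector, LabelCode) pairs.  Raises
    :class:`IdxFormatError` on a wrong magic number, a truncated file, or
    an image/label count mismatch.
    """
    img_buf = Path(images_path).read_bytes()
    lbl_buf = Path(labels_path).read_bytes()

    magic = _read_u32(img_buf, 0, images_path)
    if magic != IMAGE_MAGIC:
        raise IdxFormatError(
            f"{images_path}: bad image magic {magic} at offset 0 "
            f"(expected {IMAGE_MAGIC})")
    n = _read_u32(img_buf, 4, images_path)
    rows = _read_u32(img_buf, 8, images_path)
    cols = _read_u32(img_buf, 12, images_path)
    need = 16 + n * rows * cols
    if len(img_buf) < need:
        raise IdxFormatError(
            f"{images_path}: truncated pixel data at offset {len(img_buf)} "
            f"(need {need} bytes)")

    magic = _read_u32(lbl_buf, 0, labels_path)
    if magic != LABEL_MAGIC:
        raise IdxFormatError(
            f"{labels_path}: bad label magic {magic} at offset 0 "
            f"(expected {LABEL_MAGIC})")
    n_lbl = _read_u32(lbl_buf, 4, labels_path)
    if n_lbl != n:
        raise IdxFormatError(
            f"{labels_path}: {n_lbl} labels for {n} images "
            f"(count field at offset 4)")
    if len(lbl_buf) < 8 + n:
        raise IdxFormatError(
            f"{labels_path}: truncated label data at offset {len(lbl_buf)} "
            f"(need {8 + n} bytes)")

    pixels = np.frombuffer(img_buf, dtype=np.uint8, count=n * rows * cols,
                           offset=16).reshape(n, rows * cols)
    labels = np.frombuffer(lbl_buf, dtype=np.uint8, count=n, offset=8)
    return [(IntensityVector(px / 255.0), LabelCode(int(lb), n_classes))
            for px, lb in zip(pixels, labels)]


def write_idx(images_path, labels_path, images: np.ndarray,
              labels: np.ndarray) -> None:
    """Write uint8 images (n × rows × cols) and labels to an IDX pair."""
    images = np.ascontiguousarray(images, dtype=np.uint8)
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    n, rows, cols = images.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", IMAGE_MAGIC, n, rows, cols))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", LABEL_MAGIC, n))
        fh.write(labels.tobytes())
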