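"""Label images and TIFF I/O with pixel-size metadata.

Images are written as plain (multi-page) TIFF; the physical pixel size
travels in a small YAML sidecar next to the TIFF because baseline TIFF
has no reliable, toolchain-independent place for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml


@dataclass
class LabelImage:
    """Integer-labelled 2-D segmentation.

    ``labels`` uses 0 for background and consecutive positive integers
    for objects, ordered by descending pixel area where produced by
    :func:`vesitrack.golgi.segment_channel`.
    """

    labels: np.ndarray
    pixel_size: float  # µm per pixel
    channel: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.pixel_size <= 0 or not np.isfinite(self.pixel_size):
            raise ValueError("pixel_size must be positive and finite")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    def areas_px(self) -> np.ndarray:
        """Pixel count per label, index i-1 for label i."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)
        return counts[1:]

    def areas_um2(self) -> np.ndarray:
        return self.areas_px() * self.pixel_size**2

    def mask(self) -> np.ndarray:
        return self.labels > 0


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_image(image: np.ndarray, path: str | Path, pixel_size: float,
                meta: dict | None = None) -> None:
    """Write a 2-D image or stack as TIFF plus a metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")
    sidecar = {"pixel_size_um": float(pixel_size)}
    if meta:
        sidecar.update(meta)
    _sidecar(path).write_text(yaml.safe_dump(sidecar))


def read_image(path: str | Path) -> tuple[np.ndarray, float, dict]:
    """Read a TIFF and its sidecar; returns (array, pixel_size_um, meta)."""
    path = Path(path)
    arr = tifffile.imread(path)
    meta: dict = {}
    pixel_size = 1.0
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
        pixel_size = float(meta.pop("pixel_size_um", 1.0))
    return arr, pixel_size, meta


def write_label_image(label_image: LabelImage, path: str | Path) -> None:
    write_image(label_image.labels.astype(np.int32), path, label_image.pixel_size,
                meta={"channel": label_image.channel, **label_image.meta})


def read_label_image(path: str | Path) -> LabelImage:
    arr, pixel_size, meta = read_image(path)
    channel = meta.pop("channel", None)
    return LabelImage(arr.astype(np.int64), pixel_size, channel=channel, meta=meta)
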