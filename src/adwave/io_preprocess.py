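"""Slice loading, normalization, resizing, and cohort manifests.

Input slices are 8-bit grayscale or RGB PNG files.  A cohort is described by
a plain-text manifest (TSV) with columns ``subject_id``, ``label``, ``path``
(one row per slice file, optional ``slice_index`` column); labels are the
strings ``patient``/``control`` or the integers +1/-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

log = logging.getLogger(__name__)

WORKING_SIZE = (256, 256)
LABEL_PATIENT = 1
LABEL_CONTROL = -1

_LABEL_STRINGS = {"patient": LABEL_PATIENT, "control": LABEL_CONTROL,
                  "1": LABEL_PATIENT, "-1": LABEL_CONTROL}
_RGB_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageSlice:
    """A single 2-D slice with intensities in [0, 1]."""

    pixels: np.ndarray
    source_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageSlice.pixels must be 2-D")


@dataclass
class SubjectStack:
    """Ordered slices of one subject plus its class label (+1 patient, -1 control)."""

    slices: list[ImageSlice]
    label: int
    subject_id: str = ""

    def pixel_array(self) -> np.ndarray:
        """(n_slices, H, W) array; all slices must share dimensions."""
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"slices have mixed dimensions: {sorted(shapes)}")
        return np.stack([s.pixels for s in self.slices])


def parse_label(value) -> int:
    key = str(value).strip().lower()
    if key not in _LABEL_STRINGS:
        raise ValueError(f"unrecognized label {value!r}; expected patient/control or +1/-1")
    return _LABEL_STRINGS[key]


def load_slice(path, source_id: str = "", slice_index: int = 0) -> ImageSlice:
    """Read a PNG slice, collapse RGB to luminance, min-max rescale to [0, 1].

    A constant (zero-variance) image maps to all zeros with a logged warning
    so degenerate inputs flow through the pipeline instead of raising.
    """
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _RGB_LUMA
    if arr.ndim != 2:
        raise OSError(f"{path}: not a single-channel or RGB raster")
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        log.warning("%s: constant image, normalized to all zeros", path)
        arr = np.zeros_like(arr)
    return ImageSlice(arr, source_id=source_id, slice_index=slice_index)


def save_slice(slice_: ImageSlice, path) -> None:
    """Write as 8-bit grayscale PNG (quantized to 1/255)."""
    q = np.clip(np.rint(slice_.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(q, mode="L").save(path, format="PNG")


def resize_to_working(slice_: ImageSlice, size: tuple[int, int] = WORKING_SIZE) -> ImageSlice:
    """Bilinear resize to the working resolution; identity if already there."""
    h, w = slice_.pixels.shape
    if (h, w) < (8, 8):
        raise ValueError(f"input dimensions {h}x{w} below minimum 8x8")
    if (h, w) == size:
        return ImageSlice(slice_.pixels.copy(), slice_.source_id, slice_.slice_index)
    im = Image.fromarray(slice_.pixels.astype(np.float32), mode="F")
    # PIL sizes are (width, height)
    out = np.asarray(im.resize((size[1], size[0]), Image.BILINEAR), dtype=float)
    return ImageSlice(np.clip(out, 0.0, 1.0), slice_.source_id, slice_.slice_index)


def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=["subject_id", "label", "path", "slice_index"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(
    path,
    resize: bool = True,
    size: tuple[int, int] = WORKING_SIZE,
    slice_range: tuple[int, int] | None = None,
) -> list[SubjectStack]:
    """Load a cohort from a manifest TSV.

    ``slice_range=(lo, hi)`` keeps only slice indices in [lo, hi); it replaces
    the manual central-slice selection used on clinical data.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"subject_id", "label", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(table.columns))}")
    base = Path(path).parent
    stacks: list[SubjectStack] = []
    for sid, group in table.groupby("subject_id", sort=True):
        if "slice_index" in group.columns:
            group = group.sort_values("slice_index")
            indices = group["slice_index"].astype(int).tolist()
        else:
            indices = list(range(len(group)))
        labels = {parse_label(v) for v in group["label"]}
        if len(labels) != 1:
            raise ValueError(f"subject {sid} has conflicting labels")
        slices = []
        for idx, p in zip(indices, group["path"]):
            if slice_range is not None and not (slice_range[0] <= idx < slice_range[1]):
                continue
            fp = Path(p)
            if not fp.is_absolute():
                fp = base / fp
            s = load_slice(fp, source_id=str(sid), slice_index=idx)
            slices.append(resize_to_working(s, size) if resize else s)
        stacks.append(SubjectStack(slices, label=labels.pop(), subject_id=str(sid)))
    return stacks
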