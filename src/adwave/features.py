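"""Per-subject feature vectors from wavelet pyramids.

The primary features are the magnitudes of the six directional DTCWT
subbands at one scale, flattened per slice and concatenated across the
subject's slices (slice-major, then orientation, then row-major pixels).
For a 32-slice stack of 256x256 images at the default scale this yields
6 * 16 * 16 = 1536 features per slice and 49,152 per subject.

A critically sampled real DWT provides the baseline feature set: the
approximation plus the three detail subbands at the chosen scale,
4 * (N / 2^scale)^2 values per slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .dtcwt import dtcwt_forward
from .filters import FilterBankSet
from .io_preprocess import SubjectStack

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "default_scale",
    "extract_dtcwt_features",
    "extract_dwt_features",
    "build_feature_matrix",
    "save_features",
    "load_features",
]

#: subband side length whose magnitudes reproduce 1536 features per slice
_TARGET_SUBBAND_SIDE = 16


def default_scale(image_size: int) -> int:
    """The scale whose directional subbands are 16x16 (level 4 for 256)."""
    scale = int(np.log2(image_size // _TARGET_SUBBAND_SIDE))
    if 2 ** scale * _TARGET_SUBBAND_SIDE != image_size:
        raise ValueError(f"image size {image_size} has no 16x16 subband scale")
    return scale


@dataclass
class FeatureVector:
    values: np.ndarray
    subject_id: str
    label: int
    layout: dict = field(default_factory=dict)


@dataclass
class FeatureMatrix:
    """Subjects x features matrix with labels in {+1 patient, -1 control}."""

    X: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]
    layout: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count does not match label count")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be +1/-1, got {sorted(bad)}")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def _check_stack(stack: SubjectStack, scale: int) -> np.ndarray:
    pix = stack.pixel_array()
    h, w = pix.shape[-2:]
    if h != w:
        raise ValueError(f"slices must be square, got {h}x{w}")
    if scale < 1 or 2 ** scale > h:
        raise ValueError(f"scale {scale} beyond decomposition depth for {h}x{w} slices")
    return pix


def extract_dtcwt_features(
    stack: SubjectStack, scale: int | None = None, fbs: FilterBankSet | None = None
) -> FeatureVector:
    """Magnitudes of the six directional subbands at ``scale``, all slices.

    Magnitude (complex modulus) is used rather than real/imaginary parts:
    it is the near-shift-invariant quantity, and it reproduces the
    1536-per-slice layout.
    """
    pix = _check_stack(stack, scale or 1)
    if scale is None:
        scale = default_scale(pix.shape[-1])
        _check_stack(stack, scale)
    pyr = dtcwt_forward(pix, levels=scale, fbs=fbs)
    mags = np.abs(pyr.highpass[scale - 1])  # (n_slices, 6, h, w)
    layout = {
        "transform": "dtcwt",
        "scale": scale,
        "n_slices": pix.shape[0],
        "per_slice": int(np.prod(mags.shape[1:])),
        "order": "slice-major, then orientation, then row-major pixels",
    }
    return FeatureVector(mags.reshape(-1), stack.subject_id, stack.label, layout)


def extract_dwt_features(
    stack: SubjectStack, scale: int | None = None, wavelet: str = "bior2.2"
) -> FeatureVector:
    """Baseline: approximation + detail coefficients of a real DWT at ``scale``."""
    pix = _check_stack(stack, scale or 1)
    if scale is None:
        scale = default_scale(pix.shape[-1])
        _check_stack(stack, scale)
    coeffs = pywt.wavedec2(pix, wavelet, mode="periodization", level=scale, axes=(-2, -1))
    bands = np.stack([coeffs[0], *coeffs[1]], axis=-3)  # (n_slices, 4, h, w)
    layout = {
        "transform": "dwt",
        "wavelet": wavelet,
        "scale": scale,
        "n_slices": pix.shape[0],
        "per_slice": int(np.prod(bands.shape[1:])),
        "order": "slice-major, then subband (A,H,V,D), then row-major pixels",
    }
    return FeatureVector(bands.reshape(-1), stack.subject_id, stack.label, layout)


def build_feature_matrix(
    stacks: list[SubjectStack],
    transform: str = "dtcwt",
    scale: int | None = None,
    fbs: FilterBankSet | None = None,
) -> FeatureMatrix:
    if transform == "dtcwt":
        vecs = [extract_dtcwt_features(s, scale, fbs) for s in stacks]
    elif transform == "dwt":
        vecs = [extract_dwt_features(s, scale) for s in stacks]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    lengths = {len(v.values) for v in vecs}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent feature lengths {sorted(lengths)}")
    return FeatureMatrix(
        np.stack([v.values for v in vecs]),
        np.array([v.label for v in vecs]),
        [v.subject_id for v in vecs],
        layout=vecs[0].layout if vecs else {},
    )


def save_features(fm: FeatureMatrix, path) -> None:
    """Tab-separated subjects x features table plus a JSON layout sidecar."""
    df = pd.DataFrame(fm.X)
    df.insert(0, "subject_id", fm.subject_ids)
    df.insert(1, "label", fm.labels)
    df.to_csv(path, sep="\t", index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump(fm.layout, fh, indent=2)


def load_features(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    try:
        with open(str(path) + ".json") as fh:
            layout = json.load(fh)
    except FileNotFoundError:
        layout = {}
    return FeatureMatrix(
        df.drop(columns=["subject_id", "label"]).to_numpy(dtype=float),
        df["label"].to_numpy(dtype=int),
        df["subject_id"].astype(str).tolist(),
        layout=layout,
    )
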