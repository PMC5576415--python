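"""Two-class synthetic brain phantoms.

Each subject is a stack of 2-D slices through an elliptical "brain": a
textured cortical band at the rim, a brighter interior, and two dark
ventricles near the midline.  The patient class enlarges the ventricles and
thins the cortical band in proportion to ``effect_size`` — a cartoon of the
atrophy pattern that separates dementia patients from controls on axial MRI
slices.  Per-subject jitter of the geometry models anatomical variability,
a smooth through-plane profile varies structure size across the slices of a
stack, and i.i.d. Gaussian noise is added per pixel.

At ``effect_size = 0`` the two classes are drawn from exactly the same
distribution, which calibrates the null behavior of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_preprocess import (
    LABEL_CONTROL,
    LABEL_PATIENT,
    ImageSlice,
    SubjectStack,
    save_slice,
    write_manifest,
)

__all__ = ["PhantomSpec", "generate_subject", "generate_cohort", "write_cohort_png"]

# class-effect coefficients: ventricle enlargement / cortical thinning per
# unit effect_size (chosen so effect_size = 1 is an unmistakable difference)
_VENTRICLE_GAIN = 0.45
_CORTEX_THINNING = 0.25


@dataclass
class PhantomSpec:
    image_size: int = 256
    n_slices: int = 32
    effect_size: float = 1.0
    noise_sd: float = 0.05
    texture_scale: float = 8.0  # larger -> coarser cortical texture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _soft_mask(rho: np.ndarray, edge: float, width: float) -> np.ndarray:
    """Smoothstep of (edge - rho), ~width wide, in [0, 1]."""
    t = np.clip((edge - rho) / width + 0.5, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def generate_subject(spec: PhantomSpec, label: int, subject_seed: int | None = None) -> SubjectStack:
    """One subject's slice stack; reproducible given (spec.seed, subject_seed)."""
    if label not in (LABEL_PATIENT, LABEL_CONTROL):
        raise ValueError("label must be +1 (patient) or -1 (control)")
    rng = np.random.default_rng(spec.seed if subject_seed is None else subject_seed)
    S = spec.image_size
    yy, xx = np.meshgrid(np.linspace(-1, 1, S), np.linspace(-1, 1, S), indexing="ij")
    soft = 3.0 / S  # edge softness in normalized units (~1.5 px)

    # per-subject anatomy (label-independent so effect_size=0 is a true null)
    brain_a = 0.62 * (1 + 0.03 * rng.standard_normal())  # vertical semi-axis
    brain_b = 0.78 * (1 + 0.03 * rng.standard_normal())
    cortex_th = 0.18 * (1 + 0.10 * rng.standard_normal())
    vent_dx = 0.16 * (1 + 0.08 * rng.standard_normal())
    vent_a = 0.28 * (1 + 0.08 * rng.standard_normal())
    vent_b = 0.10 * (1 + 0.08 * rng.standard_normal())
    wobble_phase = rng.uniform(0, 2 * np.pi)

    is_patient = label == LABEL_PATIENT
    if is_patient:
        vent_a *= 1 + _VENTRICLE_GAIN * spec.effect_size
        vent_b *= 1 + _VENTRICLE_GAIN * spec.effect_size
        cortex_th *= max(0.3, 1 - _CORTEX_THINNING * spec.effect_size)

    # one cortical texture field per subject, shared across slices
    sigma = S / (4.0 * spec.texture_scale)
    tex = gaussian_filter(rng.standard_normal((S, S)), sigma, mode="wrap")
    tex /= tex.std() + 1e-12

    slices = []
    half = (spec.n_slices - 1) / 2.0 if spec.n_slices > 1 else 1.0
    for z in range(spec.n_slices):
        u = (z - half) / (half + 1.0)  # in (-1, 1)
        prof = np.sqrt(max(0.2, 1.0 - u * u))  # through-plane size profile
        wob = 0.02 * np.sin(2 * np.pi * u + wobble_phase)  # smooth drift

        a, b = brain_a * prof, brain_b * prof
        rho = np.sqrt(((yy - wob) / a) ** 2 + (xx / b) ** 2)
        brain = _soft_mask(rho, 1.0, soft / min(a, b))
        inner = _soft_mask(rho, 1.0 - cortex_th, soft / min(a, b))
        cortex = brain - inner

        img = 0.55 * inner + cortex * np.clip(0.75 + 0.15 * tex, 0.0, 1.0)
        for sx in (-1.0, 1.0):
            va, vb = vent_a * prof, vent_b * prof
            rv = np.sqrt(((yy - wob - 0.02) / va) ** 2 + ((xx - sx * vent_dx) / vb) ** 2)
            vent = _soft_mask(rv, 1.0, soft / min(va, vb)) * inner
            img = img * (1 - vent) + 0.08 * vent

        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        slices.append(ImageSlice(np.clip(img, 0.0, 1.0), slice_index=z))
    return SubjectStack(slices, label=label)


def generate_cohort(
    spec: PhantomSpec, n_patients: int, n_controls: int
) -> tuple[list[SubjectStack], np.ndarray]:
    """Independent subjects with per-subject seeds derived from the master seed."""
    if n_patients < 1 or n_controls < 1:
        raise ValueError("cohort needs at least one subject per class")
    n = n_patients + n_controls
    seeds = np.random.SeedSequence(spec.seed).generate_state(n) % (2 ** 31 - 1)
    labels = np.array([LABEL_PATIENT] * n_patients + [LABEL_CONTROL] * n_controls)
    stacks = []
    for i, (lab, sd) in enumerate(zip(labels, seeds)):
        stack = generate_subject(spec, int(lab), subject_seed=int(sd))
        tag = "pat" if lab == LABEL_PATIENT else "ctl"
        stack.subject_id = f"{tag}{i:04d}"
        for s in stack.slices:
            s.source_id = stack.subject_id
        stacks.append(stack)
    return stacks, labels


def write_cohort_png(stacks: list[SubjectStack], outdir) -> Path:
    """PNG tree + manifest, shaped exactly like real-data input."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack in stacks:
        sdir = outdir / stack.subject_id
        sdir.mkdir(exist_ok=True)
        for s in stack.slices:
            rel = Path(stack.subject_id) / f"slice_{s.slice_index:03d}.png"
            save_slice(s, outdir / rel)
            rows.append(
                {
                    "subject_id": stack.subject_id,
                    "label": "patient" if stack.label == LABEL_PATIENT else "control",
                    "path": str(rel),
                    "slice_index": s.slice_index,
                }
            )
    manifest = outdir / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest
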