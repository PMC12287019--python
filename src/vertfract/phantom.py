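"""Synthetic sagittal-spine phantom generator.

Produces 2-D grayscale images containing a vertical stack of bright,
rounded-rectangular "vertebral bodies" (VBs, labeled L1..L5 superior to
inferior) on a dark background, together with exact per-vertebra ground-truth
masks and normal/fractured labels.  Fractured vertebrae are modeled as
anterior wedge-compression deformities: column heights shrink linearly from
``1 - height_loss_fraction`` at the anterior (left) edge to 1 at the
posterior edge, with an optional jittered superior boundary.  A smooth
multiplicative bias field and additive Gaussian noise emulate the intensity
inhomogeneity and noise that the preprocessing stage is meant to mitigate.

All randomness is driven by the spec's ``seed``; identical specs yield
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import json

import numpy as np

__all__ = ["PhantomSpec", "PhantomCase", "generate_case", "generate_dataset"]

LEVEL_NAMES = ("L1", "L2", "L3", "L4", "L5")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, deformation and intensity parameters of one phantom image.

    Lengths are in pixels, intensities in 8-bit gray levels.
    """

    image_height: int = 256
    image_width: int = 256
    n_vertebrae: int = 5
    vb_height: int = 28
    vb_width: int = 44
    disc_gap: int = 10
    corner_radius: int = 4
    fracture_levels: frozenset[int] = frozenset()
    height_loss_fraction: float = 0.4
    boundary_irregularity: float = 1.0
    foreground_mean: float = 170.0
    background_mean: float = 40.0
    noise_sd: float = 5.0
    bias_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if not (0.0 <= self.height_loss_fraction < 1.0):
            raise ValueError("height_loss_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        stack = self.n_vertebrae * self.vb_height + (self.n_vertebrae - 1) * self.disc_gap
        # 4-px guard band keeps every truth mask clear of the image border
        if stack > self.image_height - 8:
            raise ValueError("stacked vertebrae do not fit inside image_height")
        if self.vb_width > self.image_width - 8:
            raise ValueError("vb_width does not fit inside image_width")
        bad = [i for i in self.fracture_levels if not 0 <= i < self.n_vertebrae]
        if bad:
            raise ValueError(f"fracture_levels out of range: {bad}")

    def level_name(self, index: int) -> str:
        if index < len(LEVEL_NAMES):
            return LEVEL_NAMES[index]
        return f"L{index + 1}"

    def to_json(self) -> str:
        d = asdict(self)
        d["fracture_levels"] = sorted(self.fracture_levels)
        return json.dumps(d, indent=2)


@dataclass
class PhantomCase:
    """One synthetic spine image with its ground truth."""

    image: np.ndarray                 # uint8 (H, W)
    truth_masks: list[np.ndarray]     # bool (H, W), one per vertebra, disjoint
    labels: list[int]                 # 0 normal, 1 fractured, per vertebra
    spec: PhantomSpec
    case_id: str = "case000"

    @property
    def level_names(self) -> list[str]:
        return [self.spec.level_name(i) for i in range(len(self.truth_masks))]


def _vb_template(spec: PhantomSpec) -> np.ndarray:
    """Rounded rectangle of vb_height x vb_width (bool)."""
    h, w, r = spec.vb_height, spec.vb_width, spec.corner_radius
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.ones((h, w), dtype=bool)
    if r > 0:
        for cy in (r - 0.5, h - r - 0.5):
            for cx in (r - 0.5, w - r - 0.5):
                corner_y = yy < r if cy < h / 2 else yy >= h - r
                corner_x = xx < r if cx < w / 2 else xx >= w - r
                corner = corner_y & corner_x
                outside = (yy - cy) ** 2 + (xx - cx) ** 2 > r**2
                mask &= ~(corner & outside)
    return mask


def _wedge_mask(template: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Anterior wedge compression: per-column height scaled linearly from
    (1 - height_loss_fraction) on the left to 1 on the right, pixels removed
    from the superior (top) edge; superior boundary optionally jittered."""
    h, w = template.shape
    frac = spec.height_loss_fraction
    cols = np.arange(w)
    scale = (1.0 - frac) + frac * cols / max(w - 1, 1)
    jitter = np.zeros(w)
    if spec.boundary_irregularity > 0:
        raw = rng.normal(0.0, spec.boundary_irregularity, size=w)
        # smooth along columns so the boundary stays a plausible cortical edge
        kernel = np.array([0.25, 0.5, 0.25])
        jitter = np.convolve(raw, kernel, mode="same")
    out = np.zeros_like(template)
    heights = template.sum(axis=0)
    for j in cols:
        col = np.flatnonzero(template[:, j])
        if col.size == 0:
            continue
        keep = int(round(heights[j] * scale[j] + jitter[j]))
        keep = max(1, min(col.size, keep))
        out[col[-keep:], j] = True  # inferior endplate kept fixed
    return out


def _bias_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude]: sum of
    two low-frequency separable cosines with random phases."""
    if amplitude == 0:
        return np.ones(shape)
    h, w = shape
    y = np.arange(h)[:, None] / h
    x = np.arange(w)[None, :] / w
    phases = rng.uniform(0, 2 * np.pi, size=4)
    f = (np.cos(2 * np.pi * y + phases[0]) * np.cos(2 * np.pi * x + phases[1])
         + np.cos(np.pi * y + phases[2]) * np.cos(np.pi * x + phases[3]))
    f = f / np.max(np.abs(f)) if np.max(np.abs(f)) > 0 else f
    return 1.0 + amplitude * f


def generate_case(spec: PhantomSpec, case_id: str = "case000") -> PhantomCase:
    """Render one phantom image plus truth masks and labels.

    Deterministic: the same spec (including its seed) yields identical bytes.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_height, spec.image_width
    template = _vb_template(spec)
    stack = spec.n_vertebrae * spec.vb_height + (spec.n_vertebrae - 1) * spec.disc_gap
    top = (H - stack) // 2
    left = (W - spec.vb_width) // 2

    masks: list[np.ndarray] = []
    labels: list[int] = []
    for i in range(spec.n_vertebrae):
        fractured = i in spec.fracture_levels
        vb = _wedge_mask(template, spec, rng) if fractured else template
        full = np.zeros((H, W), dtype=bool)
        y0 = top + i * (spec.vb_height + spec.disc_gap)
        full[y0:y0 + spec.vb_height, left:left + spec.vb_width] = vb
        masks.append(full)
        labels.append(int(fractured))

    img = np.full((H, W), spec.background_mean, dtype=float)
    for m in masks:
        img[m] = spec.foreground_mean
    img *= _bias_field((H, W), spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(H, W))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomCase(image=img, truth_masks=masks, labels=labels, spec=spec, case_id=case_id)


def generate_dataset(
    spec_template: PhantomSpec,
    n_cases: int = 63,
    fracture_prevalence: float = 0.3,
    seed: int = 0,
) -> tuple[list[PhantomCase], "pd.DataFrame"]:
    """Generate a cohort of phantom cases with Bernoulli fracture labels.

    Per-vertebra fracture indicators are i.i.d. Bernoulli(fracture_prevalence).
    Returns the cases and a tidy manifest (case_id, level, label).
    """
    import pandas as pd

    if not 0.0 <= fracture_prevalence <= 1.0:
        raise ValueError("fracture_prevalence must be in [0, 1]")
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    rows = []
    for c in range(n_cases):
        fractured = rng.random(spec_template.n_vertebrae) < fracture_prevalence
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            spec_template,
            fracture_levels=frozenset(np.flatnonzero(fractured).tolist()),
            seed=case_seed,
        )
        case_id = f"case{c:03d}"
        case = generate_case(spec, case_id=case_id)
        cases.append(case)
        for i, lab in enumerate(case.labels):
            rows.append({"case_id": case_id, "level": spec.level_name(i), "label": lab})
    manifest = pd.DataFrame(rows)
    return cases, manifest
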