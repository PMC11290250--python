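"""Synthetic transcranial-sonography (TCS) phantom generator.

Produces labeled speckle-noise grayscale images that mimic the gross
appearance of axial midbrain TCS scans: a mid-gray parenchyma background, a
darker (hypoechoic) butterfly-shaped midbrain built from two overlapping
rotated ellipses, and — for the abnormal class — one bright (hyperechoic)
patch of random size and position inside the midbrain, standing in for
substantia-nigra hyperechogenicity.  Multiplicative gamma-distributed
speckle (Nakagami-type intensity statistics; the ``speckle_shape`` parameter
is the gamma shape, small values = harsher speckle) is applied to the smooth
anatomical template and the result is clipped to [0, 1].

The generator is the test bed for the whole pipeline: it is deterministic
per (label, params, seed), one global seed fans out to per-sample seeds via
a counter, and with default parameters the two classes are separable by a
trivial brightness-threshold classifier, which guarantees the learning task
downstream is solvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "LABELS",
    "PhantomParams",
    "LabeledSample",
    "generate_image",
    "generate_dataset",
    "midbrain_mask",
    "brightness_feature",
    "threshold_separability",
    "write_dataset",
    "load_manifest",
]

LABELS = ("normal", "abnormal")


@dataclass
class PhantomParams:
    """Geometry and noise settings of the phantom.

    image_size : pixels per side (square), generated at full resolution and
        downsampled later by the pipeline.
    background_level : mean parenchyma echo intensity in [0, 1].
    speckle_shape : gamma shape of the multiplicative speckle field; the
        field has mean 1 and standard deviation ``1/sqrt(speckle_shape)``.
    midbrain_axes : (semi-major, semi-minor) in pixels of each of the two
        ellipses whose union forms the butterfly.
    lesion_intensity_delta : additive brightness of the hyperechoic patch.
    lesion_radius_range : (min, max) lesion radius in pixels.
    """

    image_size: int = 448
    background_level: float = 0.5
    speckle_shape: float = 8.0
    midbrain_axes: tuple[float, float] = (110.0, 60.0)
    lesion_intensity_delta: float = 0.3
    lesion_radius_range: tuple[float, float] = (12.0, 32.0)
    midbrain_level_factor: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 224:
            raise ValueError("image_size must be >= 224")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be > 0")
        if self.lesion_intensity_delta < 0 or self.lesion_intensity_delta > 1:
            raise ValueError("lesion_intensity_delta must lie in [0, 1]")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("lesion_radius_range must satisfy 0 < min <= max")


@dataclass
class LabeledSample:
    """One grayscale image with its class label."""

    image: np.ndarray
    label: str
    sample_id: str
    provenance: str | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2 or self.image.shape[0] != self.image.shape[1]:
            raise ValueError("image must be square 2-D")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.provenance is None:
            self.provenance = self.sample_id


_GEOM_CACHE: dict = {}


def midbrain_mask(params: PhantomParams) -> np.ndarray:
    """Boolean butterfly mask: union of two rotated overlapping ellipses."""
    key = (params.image_size, params.midbrain_axes)
    if key in _GEOM_CACHE:
        return _GEOM_CACHE[key][0]
    n = params.image_size
    a, b = params.midbrain_axes
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    mask = np.zeros((n, n), dtype=bool)
    # the two "wings", tilted towards each other and laterally offset
    for sign in (-1.0, 1.0):
        theta = sign * np.deg2rad(25.0)
        ox, oy = cx + sign * 0.55 * a, cy
        dx, dy = xx - ox, yy - oy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # distance-to-boundary map, used to keep lesions inside the butterfly
    _GEOM_CACHE[key] = (mask, ndimage.distance_transform_edt(mask))
    return mask


def _interior_distance(params: PhantomParams) -> np.ndarray:
    midbrain_mask(params)
    return _GEOM_CACHE[(params.image_size, params.midbrain_axes)][1]


_TPL_CACHE: dict = {}


def _template(params: PhantomParams) -> np.ndarray:
    key = (params.image_size, params.background_level,
           params.midbrain_axes, params.midbrain_level_factor)
    if key not in _TPL_CACHE:
        n = params.image_size
        tpl = np.full((n, n), params.background_level)
        tpl[midbrain_mask(params)] = params.background_level \
            * params.midbrain_level_factor
        # smooth tissue boundaries so edges are not single-pixel steps
        _TPL_CACHE[key] = ndimage.gaussian_filter(tpl, sigma=n / 90.0)
    return _TPL_CACHE[key]


def _lesion_profile(params: PhantomParams, rng: np.random.Generator):
    """Smooth-edged disk inside the midbrain; returns (profile, core mask)."""
    n = params.image_size
    lo, hi = params.lesion_radius_range
    radius = rng.uniform(lo, hi)
    candidates = np.flatnonzero(_interior_distance(params) >= radius)
    if candidates.size == 0:
        candidates = np.flatnonzero(midbrain_mask(params))
    pick = candidates[rng.integers(candidates.size)]
    cy, cx = divmod(int(pick), n)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    dist = np.hypot(yy - cy, xx - cx)
    edge = max(2.0, 0.2 * radius)
    profile = np.clip((radius - dist) / edge + 1.0, 0.0, 1.0)
    core = dist <= radius
    return profile, core


def generate_image(label: str, params: PhantomParams | None = None,
                   seed: int = 0, return_masks: bool = False):
    """Render one phantom; deterministic per (label, params, seed).

    With ``return_masks=True`` also returns the generator's internal masks
    (midbrain butterfly and lesion core) for contrast verification.
    """
    params = params or PhantomParams()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    texture_ss, lesion_ss = np.random.SeedSequence(seed).spawn(2)
    tpl = _template(params)
    lesion_mask = np.zeros_like(tpl, dtype=bool)
    # lesion placement randoms are always drawn from their own stream, so
    # delta -> 0 degrades abnormal to normal bit-for-bit
    profile, core = _lesion_profile(params, np.random.default_rng(lesion_ss))
    if label == "abnormal":
        tpl = tpl + params.lesion_intensity_delta * profile
        lesion_mask = core
    rng = np.random.default_rng(texture_ss)
    shape = params.speckle_shape
    field = rng.gamma(shape, 1.0 / shape, size=tpl.shape)
    field = ndimage.gaussian_filter(field, sigma=1.0)
    field /= field.mean()
    img = np.clip(tpl * field, 0.0, 1.0)
    sample = LabeledSample(image=img, label=label,
                           sample_id=f"{label}-{seed:08d}")
    if return_masks:
        return sample, {"midbrain": midbrain_mask(params),
                        "lesion": lesion_mask}
    return sample


def generate_dataset(n_abnormal: int, n_normal: int,
                     params: PhantomParams | None = None,
                     seed: int = 0) -> list[LabeledSample]:
    """Generate the requested class counts; reproducible under ``seed``.

    Per-sample seeds are derived from the global seed via a counter, so any
    subset of the dataset is reproducible independent of generation order.
    """
    if n_abnormal < 0 or n_normal < 0:
        raise ValueError("counts must be >= 0")
    params = params or PhantomParams()
    samples = []
    for i, label in enumerate(
            ["abnormal"] * n_abnormal + ["normal"] * n_normal):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                  % (2 ** 31))
        s = generate_image(label, params, seed=sub)
        s.sample_id = f"{label}-{i:05d}"
        s.provenance = s.sample_id
        samples.append(s)
    return samples


def brightness_feature(image: np.ndarray, params: PhantomParams) -> float:
    """Mean of the top-1% brightest pixels inside the midbrain butterfly."""
    vals = np.asarray(image)[midbrain_mask(params)]
    k = max(1, int(round(0.01 * vals.size)))
    return float(np.sort(vals)[-k:].mean())


def threshold_separability(samples: list[LabeledSample],
                           params: PhantomParams) -> float:
    """Best single-threshold accuracy of the brightness feature.

    This is the sanity bound for the learning task: a CNN has to beat a
    one-dimensional threshold on midbrain peak brightness.
    """
    feats = np.array([brightness_feature(s.image, params) for s in samples])
    y = np.array([1 if s.label == "abnormal" else 0 for s in samples])
    order = np.argsort(feats)
    f, yy = feats[order], y[order]
    # sweep all midpoints; abnormal is the brighter class
    best = max(np.mean(yy == 1), np.mean(yy == 0))
    for i in range(len(f) - 1):
        thr = 0.5 * (f[i] + f[i + 1])
        best = max(best, np.mean((feats > thr) == (y == 1)))
    return float(best)


def write_dataset(samples: list[LabeledSample], out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs into per-class folders plus a manifest CSV."""
    out = Path(out_dir)
    rows = []
    for s in samples:
        rel = Path(s.label) / f"{s.sample_id}.png"
        (out / s.label).mkdir(parents=True, exist_ok=True)
        arr = np.clip(np.round(s.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / rel)
        rows.append({"sample_id": s.sample_id, "path": str(rel),
                     "label": s.label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_manifest(manifest: str | Path) -> list[LabeledSample]:
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.csv"
    root = manifest.parent
    df = pd.read_csv(manifest)
    samples = []
    for row in df.itertuples():
        img = np.asarray(Image.open(root / row.path).convert("L"),
                         dtype=np.float64) / 255.0
        samples.append(LabeledSample(image=img, label=row.label,
                                     sample_id=str(row.sample_id)))
    return samples
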