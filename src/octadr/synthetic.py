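"""Synthetic OCTA angiogram phantoms with ground-truth vessel masks.

Real en-face angiograms show bright branching vasculature on a darker
speckled background, with a capillary-free disc (the foveal avascular
zone, FAZ) at the image centre.  Diabetic retinopathy reduces capillary
density, thins vessels and enlarges the FAZ.  The generator emulates
exactly those class markers: vessel trees are grown from the image
border toward the centre by a branching random walk, rendered as
anti-aliased tubes, and a DR-class spec deletes a fraction of segments
and widens the avascular disc before rendering.

Every sample is a pure function of its :class:`PhantomSpec` (seed
included), so downstream stages are testable without any private data.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "rasterize_centerlines",
    "generate_cohort",
    "dr_spec",
    "ndr_spec",
]

#: intensity of the vessel plateau before shading, on a [0, 1] scale
_VESSEL_LEVEL = 0.85
#: mean background level before speckle and shading
_BACKGROUND_LEVEL = 0.18


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic angiogram.

    Sizes and radii are in pixels; ``vessel_width_px`` is the mean
    caliber and ``vessel_width_sd_px`` its spread.  ``dropout_rate``
    is the fraction of grown segments deleted before rendering (the
    capillary-dropout marker of the DR class).
    """

    image_size: int = 256
    n_trees: int = 12
    branch_prob: float = 0.35
    vessel_width_px: float = 3.0
    vessel_width_sd_px: float = 1.0
    faz_radius_px: float = 20.0
    dropout_rate: float = 0.0
    noise_sigma: float = 0.08
    contrast_drift: float = 0.3
    seed: int = 0
    label: str = "NDR"
    bright_vessels: bool = True

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if self.n_trees < 0:
            raise ValueError(f"n_trees must be >= 0, got {self.n_trees}")
        for name in ("branch_prob", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.vessel_width_px <= 0:
            raise ValueError(f"vessel_width_px must be positive, got {self.vessel_width_px}")
        if self.vessel_width_sd_px < 0:
            raise ValueError(f"vessel_width_sd_px must be >= 0, got {self.vessel_width_sd_px}")
        if not 0 < self.faz_radius_px < self.image_size / 2:
            raise ValueError(
                f"faz_radius_px must be in (0, image_size/2), got {self.faz_radius_px}"
            )
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.contrast_drift < 0:
            raise ValueError(f"contrast_drift must be >= 0, got {self.contrast_drift}")
        if self.label not in ("DR", "NDR"):
            raise ValueError(f"label must be 'DR' or 'NDR', got {self.label!r}")


@dataclass
class PhantomSample:
    """One rendered phantom: image, exact truth mask, label and provenance."""

    image: np.ndarray  # H x W float64 in [0, 1]
    truth_mask: np.ndarray  # H x W uint8 {0, 1}
    label: str
    spec: PhantomSpec
    centerlines: list = field(default_factory=list)  # [(points Nx2 float, width), ...]


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec) -> list[tuple[np.ndarray, float]]:
    """Grow one vessel tree from a random border point toward the centre.

    Returns a list of (polyline points, width) segments; daughter
    branches get thinner, mimicking real arteriolar trees.
    """
    size = spec.image_size
    center = np.array([size / 2.0, size / 2.0])
    side = rng.integers(0, 4)
    t = rng.uniform(0.1, 0.9) * size
    start = {
        0: np.array([0.0, t]),
        1: np.array([size - 1.0, t]),
        2: np.array([t, 0.0]),
        3: np.array([t, size - 1.0]),
    }[int(side)]
    width = max(0.8, rng.normal(spec.vessel_width_px, spec.vessel_width_sd_px))
    segments: list[tuple[np.ndarray, float]] = []
    # stack of (position, direction, width, remaining growth steps)
    direction = center - start
    direction /= np.linalg.norm(direction) + 1e-12
    stack = [(start, direction, width, int(size * 0.9))]
    max_branches = 24
    n_branches = 0
    step_len = 3.0
    while stack:
        pos, d, w, steps = stack.pop()
        pts = [pos.copy()]
        while steps > 0:
            steps -= 1
            # meander but keep a weak pull toward the centre
            ang = rng.normal(0.0, 0.35)
            c, s = np.cos(ang), np.sin(ang)
            d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
            pull = center - pos
            pull /= np.linalg.norm(pull) + 1e-12
            d = 0.85 * d + 0.15 * pull
            d /= np.linalg.norm(d) + 1e-12
            pos = pos + step_len * d
            if not (0 <= pos[0] < size and 0 <= pos[1] < size):
                break
            if np.linalg.norm(pos - center) < spec.faz_radius_px:
                break  # capillaries terminate at the avascular zone
            pts.append(pos.copy())
            if (
                n_branches < max_branches
                and len(pts) > 4
                and rng.random() < spec.branch_prob * 0.25
            ):
                n_branches += 1
                ang_b = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.1)
                cb, sb = np.cos(ang_b), np.sin(ang_b)
                db = np.array([cb * d[0] - sb * d[1], sb * d[0] + cb * d[1]])
                stack.append((pos.copy(), db, max(0.8, w * 0.75), steps // 2))
        if len(pts) >= 2:
            segments.append((np.asarray(pts), w))
    return segments


def rasterize_centerlines(
    centerlines: list[tuple[np.ndarray, float]], image_size: int, faz_radius_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Render centerlines into (anti-aliased intensity, binary truth mask).

    Each polyline is densified to sub-pixel spacing, splatted onto the
    grid, and inflated to its caliber via a Euclidean distance
    transform; a linear 1-px falloff at the tube edge gives the
    anti-aliased profile, and the exact truth is that profile
    thresholded at 0.5.  Pixels inside the FAZ disc are cleared before
    thresholding, so truth and rendering always agree.
    """
    size = image_size
    aa = np.zeros((size, size), dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size]
    faz = (yy - size / 2.0) ** 2 + (xx - size / 2.0) ** 2 < faz_radius_px**2
    for pts, width in centerlines:
        hit = np.zeros((size, size), dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            n = max(2, int(np.ceil(np.linalg.norm(b - a) / 0.5)) + 1)
            line = a[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (b - a)[None, :]
            ij = np.round(line).astype(int)
            ok = (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
            hit[ij[ok, 0], ij[ok, 1]] = True
        if not hit.any():
            continue
        dist = ndimage.distance_transform_edt(~hit)
        prof = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
        np.maximum(aa, prof, out=aa)
    aa[faz] = 0.0
    mask = (aa >= 0.5).astype(np.uint8)
    return aa, mask


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one seeded phantom from its spec.

    The background is a speckled field under a smooth multiplicative
    shading drift (exercising local contrast equalization downstream);
    vessels are composited on top as bright (or dark, per
    ``bright_vessels``) anti-aliased tubes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size

    segments: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_trees):
        segments.extend(_grow_tree(rng, spec))
    if spec.dropout_rate > 0 and segments:
        keep = rng.random(len(segments)) >= spec.dropout_rate
        segments = [s for s, k in zip(segments, keep) if k]

    aa, mask = rasterize_centerlines(segments, size, spec.faz_radius_px)

    background = _BACKGROUND_LEVEL + rng.normal(0.0, spec.noise_sigma, (size, size))
    vessel_level = _VESSEL_LEVEL if spec.bright_vessels else 1.0 - _VESSEL_LEVEL
    img = background + aa * (vessel_level - background)
    # low-frequency multiplicative shading
    field_ = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 6.0)
    field_ /= np.abs(field_).max() + 1e-12
    img = img * (1.0 + spec.contrast_drift * field_)
    img = np.clip(img, 0.0, 1.0)

    return PhantomSample(image=img, truth_mask=mask, label=spec.label, spec=spec, centerlines=segments)


def ndr_spec(image_size: int = 256, **overrides) -> PhantomSpec:
    """Healthy-class defaults: dense capillaries, small FAZ."""
    s = image_size / 256.0
    base = PhantomSpec(
        image_size=image_size,
        faz_radius_px=20.0 * s,
        dropout_rate=0.0,
        label="NDR",
    )
    return replace(base, **overrides)


def dr_spec(image_size: int = 256, **overrides) -> PhantomSpec:
    """DR-class defaults: capillary dropout, thinner vessels, enlarged FAZ."""
    s = image_size / 256.0
    base = PhantomSpec(
        image_size=image_size,
        faz_radius_px=40.0 * s,
        dropout_rate=0.4,
        vessel_width_px=2.2,
        label="DR",
    )
    return replace(base, **overrides)


def _sample_seed(cohort_seed: int, label: str, index: int) -> int:
    """Deterministic per-sample seed from the cohort seed (fixed splitting rule)."""
    h = hashlib.sha256(f"{cohort_seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def generate_cohort(
    n_per_class: int,
    out_dir: str | Path | None = None,
    *,
    image_size: int = 256,
    seed: int = 0,
    dr_overrides: dict | None = None,
    ndr_overrides: dict | None = None,
) -> tuple[list[PhantomSample], list[dict]]:
    """Generate a balanced DR/NDR cohort; optionally write images + CSV manifest.

    Per-sample seeds are derived from the cohort seed by a fixed hash
    rule, so two calls with the same seed are pixel-identical.
    Returns ``(samples, manifest_rows)``.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    samples: list[PhantomSample] = []
    manifest: list[dict] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for label in ("DR", "NDR"):
        maker = dr_spec if label == "DR" else ndr_spec
        overrides = (dr_overrides if label == "DR" else ndr_overrides) or {}
        for i in range(n_per_class):
            s = _sample_seed(seed, label, i)
            spec = maker(image_size=image_size, seed=s, **overrides)
            sample = generate_phantom(spec)
            samples.append(sample)
            sid = f"{label.lower()}_{i:03d}"
            row = {
                "id": sid,
                "image_path": "",
                "mask_path": "",
                "label": label,
                "seed": s,
            }
            if out is not None:
                ip = out / f"{sid}_image.png"
                mp = out / f"{sid}_mask.png"
                iio.imwrite(ip, (sample.image * 255).round().astype(np.uint8))
                iio.imwrite(mp, (sample.truth_mask * 255).astype(np.uint8))
                row["image_path"] = str(ip)
                row["mask_path"] = str(mp)
            manifest.append(row)
    if out is not None:
        with open(out / "manifest.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["id", "image_path", "mask_path", "label", "seed"])
            w.writeheader()
            w.writerows(manifest)
    return samples, manifest
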