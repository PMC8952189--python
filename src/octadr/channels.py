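"""Signed distance morphology and the 3-channel composite image.

The third CNN channel encodes vessel caliber: for each pixel inside
the segmented vasculature, the Euclidean distance to the nearest
background pixel (large at the core of thick vessels, ~1 at capillary
centerlines).  The full signed map — positive inside vessels, negative
outside — is computed and exportable; the composite keeps only the
interior (positive) part, normalized to [0, 1].

Discrete boundary convention: the grid has no zero level set of its
own, so a foreground pixel adjacent to background carries phi = 1
(its distance to the nearest background pixel) rather than 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

__all__ = ["SignedDistanceMap", "CompositeImage", "signed_distance", "make_composite"]

CONVENTION = "positive inside vessels, negative outside, Euclidean metric"


@dataclass
class SignedDistanceMap:
    """Per-pixel signed Euclidean distance to the vessel boundary."""

    phi: np.ndarray  # H x W float64, pixel units
    convention: str = CONVENTION


@dataclass
class CompositeImage:
    """H x W x 3 CNN input: (enhanced gray, binary mask, normalized interior distance)."""

    channels: np.ndarray  # H x W x 3 float32/float64
    subject_id: str = ""
    label: str | None = None  # "DR" | "NDR" | None

    @property
    def side(self) -> int:
        return self.channels.shape[0]

    def save(self, path) -> None:
        tifffile.imwrite(path, self.channels.astype(np.float32))

    @classmethod
    def load(cls, path, subject_id: str = "", label: str | None = None) -> "CompositeImage":
        arr = tifffile.imread(path)
        return cls(channels=np.asarray(arr), subject_id=subject_id, label=label)


def signed_distance(mask: np.ndarray) -> SignedDistanceMap:
    """Signed Euclidean distance transform of a binary vessel mask.

    Foreground pixels get +distance to the nearest background pixel,
    background pixels -distance to the nearest foreground pixel.  An
    all-foreground (all-background) mask has no boundary; every pixel
    is assigned +diagonal (-diagonal) and a warning is emitted.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary {0, 1}")
    m = m.astype(bool)
    diag = float(np.hypot(*m.shape))
    if m.all():
        warnings.warn("all-foreground mask: signed distance saturated at +diagonal")
        return SignedDistanceMap(phi=np.full(m.shape, diag))
    if not m.any():
        warnings.warn("all-background mask: signed distance saturated at -diagonal")
        return SignedDistanceMap(phi=np.full(m.shape, -diag))
    inside = ndimage.distance_transform_edt(m)  # distance to nearest 0
    outside = ndimage.distance_transform_edt(~m)
    phi = np.where(m, inside, -outside)
    return SignedDistanceMap(phi=phi)


def make_composite(
    gray: np.ndarray,
    mask: np.ndarray,
    phi: SignedDistanceMap | np.ndarray,
    norm_constant: float | str = "per-image-max",
    *,
    subject_id: str = "",
    label: str | None = None,
) -> CompositeImage:
    """Stack (gray, mask, interior distance / norm) into the CNN input.

    ``norm_constant`` may be a positive real, or "per-image-max" to
    normalize by the largest interior distance of this mask (1.0 when
    the mask is empty).  Channel 3 is clamped to [0, 1] and is zero
    wherever the mask is zero.
    """
    g = np.asarray(gray, dtype=np.float64)
    m = np.asarray(mask, dtype=np.float64)
    p = phi.phi if isinstance(phi, SignedDistanceMap) else np.asarray(phi, dtype=np.float64)
    if not (g.shape == m.shape == p.shape):
        raise ValueError(
            f"shape mismatch: gray {g.shape}, mask {m.shape}, phi {p.shape}"
        )
    interior = np.maximum(p, 0.0) * (m > 0)
    if norm_constant == "per-image-max":
        norm = float(interior.max()) or 1.0
    else:
        norm = float(norm_constant)
        if norm <= 0:
            raise ValueError(f"norm_constant must be positive, got {norm}")
    ch3 = np.clip(interior / norm, 0.0, 1.0)
    stack = np.stack([g, m, ch3], axis=-1)
    return CompositeImage(channels=stack, subject_id=subject_id, label=label)
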